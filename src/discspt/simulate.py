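"""Synthetic trajectory generation.

Trajectories follow Markov-switching Brownian motion: a hidden state chain
switches at frame boundaries between K diffusive states, and each frame-to-
frame displacement is isotropic Gaussian with per-coordinate variance
2·D_state·Δt. Motion is confined to the disc (or lobule rectangle) by
specular reflection. Observed positions optionally carry i.i.d. Gaussian
localization noise; noise-free positions and the hidden state sequence are
retained for validation only.

The presets encode the experimental conditions: a three-state model for
dark-adapted discs whose slowest state is the transient rhodopsin cluster
(~90 nm radius), the middle state the rhodopsin dimer (~2 nm radius), with
stationary occupancies 20/50/30 % and a 100 ms slow-state dwell time.
"""

from __future__ import annotations

import copy
import logging
from dataclasses import dataclass

import numpy as np

from .params import AcquisitionParams, DiscGeometry
from .trajectories import Trajectory, TrajectorySet

logger = logging.getLogger(__name__)

__all__ = [
    "DiffusiveStateModel",
    "ClusterKinetics",
    "simulate_trajectories",
    "apply_localization_noise",
    "sample_track_lengths",
    "reversible_switching_model",
    "preset",
    "PRESET_NAMES",
]


@dataclass(frozen=True)
class DiffusiveStateModel:
    """K-state diffusive switching model.

    ``diffusion_coefficients`` are per-state D in µm²/s; ``transition_matrix``
    holds per-frame transition probabilities (row-stochastic); the chain must
    be irreducible so the stationary occupancies are well defined.
    """

    diffusion_coefficients: np.ndarray
    transition_matrix: np.ndarray
    initial_distribution: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "diffusion_coefficients",
            np.atleast_1d(np.asarray(self.diffusion_coefficients, dtype=float)),
        )
        object.__setattr__(
            self, "transition_matrix",
            np.atleast_2d(np.asarray(self.transition_matrix, dtype=float)),
        )
        object.__setattr__(
            self, "initial_distribution",
            np.atleast_1d(np.asarray(self.initial_distribution, dtype=float)),
        )
        K = self.n_states
        A = self.transition_matrix
        if A.shape != (K, K):
            raise ValueError("transition_matrix must be K x K")
        if self.initial_distribution.shape != (K,):
            raise ValueError("initial_distribution must have length K")
        if np.any(self.diffusion_coefficients <= 0):
            raise ValueError("all diffusion coefficients must be > 0")
        if np.any(A < 0) or np.any(np.abs(A.sum(axis=1) - 1.0) > 1e-12):
            raise ValueError("transition_matrix rows must be probabilities summing to 1")
        if abs(self.initial_distribution.sum() - 1.0) > 1e-12 or np.any(
            self.initial_distribution < 0
        ):
            raise ValueError("initial_distribution must sum to 1")
        if not self._irreducible():
            # e.g. the identity matrix (frozen states); occupancies are then
            # start-condition dependent and stationary_distribution() refuses.
            logger.warning("transition matrix is reducible; no unique stationary distribution")

    @property
    def n_states(self) -> int:
        return len(self.diffusion_coefficients)

    def _irreducible(self) -> bool:
        reach = (self.transition_matrix > 0) | np.eye(self.n_states, dtype=bool)
        for _ in range(self.n_states):
            reach = reach | (reach @ reach)
        return bool(reach.all())

    def stationary_distribution(self) -> np.ndarray:
        """Unique stationary distribution of the per-frame chain."""
        if not self._irreducible():
            raise ValueError("reducible chain has no unique stationary distribution")
        vals, vecs = np.linalg.eig(self.transition_matrix.T)
        i = np.argmin(np.abs(vals - 1.0))
        pi = np.real(vecs[:, i])
        pi = np.abs(pi)
        return pi / pi.sum()

    def dwell_times(self, frame_interval: float) -> np.ndarray:
        """Per-state mean dwell time τ_k = Δt / (1 − A_kk) in seconds."""
        akk = np.diag(self.transition_matrix)
        return frame_interval / (1.0 - akk)


def reversible_switching_model(
    diffusion_coefficients,
    occupancies,
    dwell_slowest: float,
    frame_interval: float,
) -> DiffusiveStateModel:
    """Build a reversible K-state model with prescribed stationary occupancies.

    Uses the generator Q_kj = φ·π_j (k ≠ j), which is reversible with
    stationary distribution π; φ is set so the first state's dwell time
    1/(φ·(1−π_1)) equals ``dwell_slowest``. The per-frame matrix is
    A = I + Δt·Q, valid while Δt·φ·(1−π_k) < 1 for every k.
    """
    D = np.atleast_1d(np.asarray(diffusion_coefficients, dtype=float))
    pi = np.atleast_1d(np.asarray(occupancies, dtype=float))
    pi = pi / pi.sum()
    K = len(D)
    if K == 1:
        return DiffusiveStateModel(D, np.ones((1, 1)), np.ones(1))
    phi = 1.0 / (dwell_slowest * (1.0 - pi[0]))
    A = frame_interval * phi * np.tile(pi, (K, 1))
    np.fill_diagonal(A, 0.0)
    np.fill_diagonal(A, 1.0 - A.sum(axis=1))
    if np.any(np.diag(A) <= 0):
        raise ValueError("frame interval too long for the requested dwell times")
    return DiffusiveStateModel(D, A, pi)


@dataclass(frozen=True)
class ClusterKinetics:
    """Kinetics and rendering parameters of transient clusters in a disc.

    Clusters nucleate as a Poisson process (``nucleation_rate`` per second,
    per disc), biased towards the disc centre with Gaussian radial scale
    ``radial_placement_scale``, live an exponential ``mean_lifetime`` and
    diffuse with ``cluster_diffusion``. Rendering uses a Gaussian PSF of
    ``psf_sigma``, ``brightness`` expected photons per cluster per frame, a
    dim monomer background, Poisson shot noise and additive Gaussian read
    noise on top of a constant camera offset.
    """

    nucleation_rate: float = 15.0
    mean_lifetime: float = 0.100
    cluster_diffusion: float = 0.078
    radial_placement_scale: float = 1.5
    brightness: float = 2000.0
    monomer_count: int = 40
    monomer_brightness: float = 150.0
    monomer_diffusion: float = 0.4
    psf_sigma: float = 0.15
    background_photons: float = 20.0
    read_noise_std: float = 2.0
    camera_offset: float = 100.0
    cluster_radius_m: float = 90e-9

    def __post_init__(self) -> None:
        for name in (
            "nucleation_rate", "mean_lifetime", "cluster_diffusion",
            "radial_placement_scale", "brightness", "monomer_brightness",
            "psf_sigma", "background_photons", "read_noise_std",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


def sample_track_lengths(
    mean_length: float, min_length: int, n: int, seed=None
) -> np.ndarray:
    """Sample track lengths from a shifted-geometric distribution.

    Lengths are ``min_length + G`` with G geometric (support 0, 1, 2, …) and
    mean ``mean_length − min_length``, matching the experimental protocol of
    a hard minimum (>15 frames) and a given mean (~35 frames).
    """
    if mean_length <= min_length:
        raise ValueError("mean_length must exceed min_length")
    rng = np.random.default_rng(seed)
    p = 1.0 / (1.0 + mean_length - min_length)
    return min_length + rng.geometric(p, size=n) - 1


def _reflect_disc(p0: np.ndarray, step: np.ndarray, radius: float) -> np.ndarray:
    """Advance from p0 by step inside a centred disc with specular reflection."""
    p = p0.copy()
    d = step.copy()
    for _ in range(64):
        q = p + d
        if q @ q <= radius * radius:
            return q
        # first intersection of the segment with the circle
        a = d @ d
        b = 2.0 * (p @ d)
        c = p @ p - radius * radius
        disc = max(b * b - 4 * a * c, 0.0)
        t = (-b + np.sqrt(disc)) / (2 * a)
        t = min(max(t, 0.0), 1.0)
        hit = p + t * d
        n = hit / np.linalg.norm(hit)
        rem = (1.0 - t) * d
        d = rem - 2.0 * (rem @ n) * n
        p = hit
    return p  # pathological step; stop at the boundary


def _reflect_rect(q: np.ndarray, half_w: float, half_h: float) -> np.ndarray:
    """Fold a point into the centred rectangle by mirror reflection."""
    out = q.copy()
    for i, half in enumerate((half_w, half_h)):
        period = 4.0 * half
        v = (out[i] + half) % period
        out[i] = (period - v if v > 2.0 * half else v) - half
    return out


def simulate_trajectories(
    model: DiffusiveStateModel,
    geometry: DiscGeometry,
    acq: AcquisitionParams,
    n_traj: int,
    lengths=None,
    mean_length: float = 35.0,
    min_length: int = 16,
    seed=None,
) -> TrajectorySet:
    """Simulate switching-diffusion trajectories confined to ``geometry``.

    Each trajectory starts uniformly inside the geometry; the hidden state
    evolves per frame by ``model.transition_matrix``; displacements are
    isotropic Gaussian with per-coordinate variance 2·D·Δt, reflected
    specularly at the boundary. Lengths may be supplied or are drawn from
    the shifted-geometric sampler. Fully reproducible for a fixed seed.
    """
    if n_traj < 1:
        raise ValueError("n_traj must be >= 1")
    rng = np.random.default_rng(seed)
    if lengths is None:
        lengths = sample_track_lengths(mean_length, min_length, n_traj, rng)
    lengths = np.asarray(lengths, dtype=np.int64)
    if np.any(lengths < 2):
        raise ValueError("every trajectory needs at least 2 frames")
    dt = acq.frame_interval
    max_sigma = np.sqrt(2.0 * model.diffusion_coefficients.max() * dt)
    if geometry.shape == "disc" and geometry.disc_diameter < max_sigma:
        logger.warning("geometry smaller than one diffusive step std")
    elif geometry.shape == "rectangle" and min(geometry.width, geometry.height) < max_sigma:
        logger.warning("geometry smaller than one diffusive step std")

    cum_A = np.cumsum(model.transition_matrix, axis=1)
    cum_pi = np.cumsum(model.initial_distribution)
    centre = np.asarray(geometry.centre, dtype=float)
    sig = np.sqrt(2.0 * model.diffusion_coefficients * dt)

    starts = geometry.sample_uniform(n_traj, rng)
    trajs = []
    for i in range(n_traj):
        L = int(lengths[i])
        n_steps = L - 1
        states = np.empty(n_steps, dtype=np.int64)
        u = rng.uniform(size=n_steps)
        s = int(np.searchsorted(cum_pi, u[0]))
        noise = rng.standard_normal((n_steps, 2))
        pos = np.empty((L, 2))
        pos[0] = starts[i]
        for t in range(n_steps):
            states[t] = s
            step = sig[s] * noise[t]
            p_rel = pos[t] - centre
            if geometry.shape == "disc":
                pos[t + 1] = centre + _reflect_disc(p_rel, step, geometry.radius)
            elif geometry.shape == "rectangle":
                pos[t + 1] = centre + _reflect_rect(
                    p_rel + step, geometry.width / 2.0, geometry.height / 2.0
                )
            else:
                pos[t + 1] = pos[t] + step
            if t + 1 < n_steps:
                s = int(np.searchsorted(cum_A[s], u[t + 1]))
        trajs.append(
            Trajectory(track_id=i, frames=np.arange(L), positions=pos, true_states=states)
        )
    return TrajectorySet(trajs)


def apply_localization_noise(
    trajs: TrajectorySet, sigma: float, seed=None
) -> TrajectorySet:
    """Add i.i.d. zero-mean Gaussian localization error of std ``sigma`` (µm).

    Noise-free positions are retained as ``true_positions`` for validation;
    inference reads only the observed positions.
    """
    if sigma < 0:
        raise ValueError("sigma must be non-negative")
    rng = np.random.default_rng(seed)
    out = []
    for t in trajs:
        true_pos = t.true_positions if t.true_positions is not None else t.positions
        noisy = t.positions + (
            rng.normal(0.0, sigma, size=t.positions.shape) if sigma > 0 else 0.0
        )
        out.append(
            Trajectory(
                track_id=t.track_id,
                frames=t.frames.copy(),
                positions=noisy,
                true_states=None if t.true_states is None else t.true_states.copy(),
                true_positions=true_pos.copy(),
            )
        )
    return TrajectorySet(out)


PRESET_NAMES = ("dark", "light_noGTP", "dark_MCD", "single_state")

#: Radii (m) assigned to the cluster (slowest state) and the dimer.
CLUSTER_RADIUS_M = 90e-9
DIMER_RADIUS_M = 2e-9


def _dark_diffusion_coefficients():
    # D1/D2 from the extended Saffman-Delbruck relation at the cluster and
    # dimer radii; D3 = 3 * D2 places the ensemble-median D_100ms inside the
    # 0.1-0.6 um^2/s literature range.
    from .hydrodynamics import SDParams, sd_diffusion

    sd = SDParams()
    d1 = sd_diffusion(CLUSTER_RADIUS_M, sd)
    d2 = sd_diffusion(DIMER_RADIUS_M, sd)
    return np.array([d1, d2, 3.0 * d2])


def preset(name: str):
    """Return ``(model, geometry, acq, kinetics)`` for a named condition.

    ``dark``: three states (cluster / dimer / fast), occupancies 20/50/30 %,
    slow-state dwell 100 ms. ``light_noGTP``: slow-state occupancy raised by
    lengthening its dwell time (light without GTP). ``dark_MCD``:
    cholesterol-depleted, state-2 dominant. ``single_state``: one free state.
    """
    acq = AcquisitionParams()
    geometry = DiscGeometry()
    if name == "dark":
        model = reversible_switching_model(
            _dark_diffusion_coefficients(), [0.20, 0.50, 0.30],
            dwell_slowest=0.100, frame_interval=acq.frame_interval,
        )
        kinetics = ClusterKinetics()
    elif name == "light_noGTP":
        model = reversible_switching_model(
            _dark_diffusion_coefficients(), [0.40, 0.35, 0.25],
            dwell_slowest=0.250, frame_interval=acq.frame_interval,
        )
        kinetics = ClusterKinetics(mean_lifetime=0.250)
    elif name == "dark_MCD":
        model = reversible_switching_model(
            _dark_diffusion_coefficients(), [0.10, 0.60, 0.30],
            dwell_slowest=0.100, frame_interval=acq.frame_interval,
        )
        kinetics = ClusterKinetics(radial_placement_scale=4.0)
    elif name == "single_state":
        model = DiffusiveStateModel([0.4], [[1.0]], [1.0])
        kinetics = ClusterKinetics(nucleation_rate=0.0, monomer_count=0)
    else:
        raise ValueError(
            f"unknown preset {name!r}; available presets: {', '.join(PRESET_NAMES)}"
        )
    return model, geometry, acq, kinetics
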