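"""Synthetic semi-multimolecule fluorescence movies.

Transient clusters nucleate in the disc as a Poisson process, biased
towards the disc centre (Gaussian radial weight), live exponential
lifetimes, diffuse, and are rendered as Gaussian PSF spots over a dim
monomer background with Poisson shot noise and Gaussian camera read noise.
Ground-truth per-frame cluster positions and birth/death frames are
returned alongside the rendered stack for end-to-end validation of the
detection → linking → lifetime pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .params import AcquisitionParams, DiscGeometry
from .simulate import ClusterKinetics, _reflect_disc

__all__ = ["MovieStack", "simulate_cluster_movie"]


@dataclass
class MovieStack:
    """Fluorescence movie: (n_frames, height, width) intensities plus the
    pixel size (µm) and frame interval (s)."""

    data: np.ndarray
    pixel_size: float
    frame_interval: float

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3 or self.data.shape[0] < 2:
            raise ValueError("movie needs shape (n_frames >= 2, height, width)")
        if self.data.shape[1] == 0 or self.data.shape[2] == 0:
            raise ValueError("zero-size image")
        if np.any(self.data < 0):
            raise ValueError("intensities must be non-negative")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def shape(self) -> tuple:
        return self.data.shape

    def pixel_to_um(self, rc: np.ndarray) -> np.ndarray:
        """Convert (row, col) pixel coordinates to (x, y) µm, origin at the
        image centre (pixel centres at integer coordinates)."""
        rc = np.asarray(rc, dtype=float)
        h, w = self.data.shape[1:]
        x = (rc[..., 1] - (w - 1) / 2.0) * self.pixel_size
        y = (rc[..., 0] - (h - 1) / 2.0) * self.pixel_size
        return np.stack([x, y], axis=-1)

    def um_to_pixel(self, xy: np.ndarray) -> np.ndarray:
        """Convert (x, y) µm to (row, col) pixels (inverse of pixel_to_um)."""
        xy = np.asarray(xy, dtype=float)
        h, w = self.data.shape[1:]
        col = xy[..., 0] / self.pixel_size + (w - 1) / 2.0
        row = xy[..., 1] / self.pixel_size + (h - 1) / 2.0
        return np.stack([row, col], axis=-1)


def _render_spot(img: np.ndarray, row: float, col: float, photons: float,
                 sigma_px: float) -> None:
    """Add a Gaussian spot (total ``photons``) in place."""
    h, w = img.shape
    half = int(np.ceil(4.0 * sigma_px))
    r0, r1 = int(np.floor(row)) - half, int(np.floor(row)) + half + 1
    c0, c1 = int(np.floor(col)) - half, int(np.floor(col)) + half + 1
    r0c, r1c = max(r0, 0), min(r1, h)
    c0c, c1c = max(c0, 0), min(c1, w)
    if r0c >= r1c or c0c >= c1c:
        return
    rr = np.arange(r0c, r1c)[:, None]
    cc = np.arange(c0c, c1c)[None, :]
    amp = photons / (2.0 * np.pi * sigma_px**2)
    img[r0c:r1c, c0c:c1c] += amp * np.exp(
        -((rr - row) ** 2 + (cc - col) ** 2) / (2.0 * sigma_px**2)
    )


def _sample_biased_positions(n, radius, scale, rng):
    """Centre-biased positions in the disc: 2-D Gaussian of std ``scale``
    truncated to the disc (rejection sampling)."""
    out = np.empty((n, 2))
    filled = 0
    while filled < n:
        cand = rng.normal(0.0, scale, size=(2 * (n - filled) + 8, 2))
        ok = cand[np.einsum("ij,ij->i", cand, cand) <= radius**2]
        take = min(len(ok), n - filled)
        out[filled : filled + take] = ok[:take]
        filled += take
    return out


def simulate_cluster_movie(
    kinetics: ClusterKinetics,
    geometry: DiscGeometry | None = None,
    acq: AcquisitionParams | None = None,
    n_frames: int = 300,
    margin_px: int = 8,
    seed=None,
) -> tuple[MovieStack, pd.DataFrame]:
    """Simulate a cluster movie; returns ``(movie, ground_truth)``.

    Ground truth is a table ``cluster_id, frame, x_um, y_um, intensity``
    with one row per frame in which a cluster is alive, plus the attributes
    ``birth_time``, ``death_time`` retrievable per cluster from its rows.
    A cluster is rendered in frame k when it is alive at sample time k·Δt.
    """
    geometry = geometry or DiscGeometry()
    acq = acq or AcquisitionParams()
    if n_frames < 2:
        raise ValueError("n_frames must be >= 2")
    if geometry.shape != "disc":
        raise ValueError("cluster movies are rendered in disc geometry")
    rng = np.random.default_rng(seed)
    dt = acq.frame_interval
    radius = geometry.radius
    npix = int(np.ceil(geometry.disc_diameter / acq.pixel_size)) + 2 * margin_px
    total_t = n_frames * dt

    # nucleation events
    n_events = rng.poisson(kinetics.nucleation_rate * total_t)
    births = np.sort(rng.uniform(0.0, total_t, size=n_events))
    lifetimes = rng.exponential(kinetics.mean_lifetime, size=n_events)
    starts = _sample_biased_positions(
        n_events, radius, max(kinetics.radial_placement_scale, 1e-9), rng
    )

    sig_step = np.sqrt(2.0 * kinetics.cluster_diffusion * dt)
    records = []
    cluster_frames: list[list] = []
    for i in range(n_events):
        f0 = int(np.ceil(births[i] / dt))
        f1 = int(np.ceil((births[i] + lifetimes[i]) / dt)) - 1
        f1 = min(f1, n_frames - 1)
        if f1 < f0 or f0 >= n_frames:
            cluster_frames.append([])
            continue
        pos = starts[i]
        rows = []
        for f in range(f0, f1 + 1):
            rows.append((i, f, pos[0], pos[1], kinetics.brightness))
            pos = _reflect_disc(pos, sig_step * rng.standard_normal(2), radius)
        records.extend(rows)
        cluster_frames.append(rows)
    truth = pd.DataFrame(
        records, columns=["cluster_id", "frame", "x_um", "y_um", "intensity"]
    )
    truth["birth_time"] = births[truth["cluster_id"]] if len(truth) else []
    truth["lifetime"] = lifetimes[truth["cluster_id"]] if len(truth) else []
    # every nucleation event, including clusters too short-lived to appear
    # in any frame (frame rows alone would bias lifetimes upward)
    truth.attrs["events"] = pd.DataFrame(
        {
            "cluster_id": np.arange(n_events),
            "birth_time": births,
            "lifetime": lifetimes,
            "x0_um": starts[:, 0],
            "y0_um": starts[:, 1],
        }
    )

    # monomer background particles (present throughout)
    n_mono = int(kinetics.monomer_count)
    mono_pos = (
        geometry.sample_uniform(n_mono, rng) - np.asarray(geometry.centre)
        if n_mono else np.empty((0, 2))
    )
    mono_sig = np.sqrt(2.0 * kinetics.monomer_diffusion * dt)

    sigma_px = kinetics.psf_sigma / acq.pixel_size
    centre_px = (npix - 1) / 2.0
    frames = np.empty((n_frames, npix, npix), dtype=np.uint16)
    by_frame: dict[int, list] = {}
    for rows in cluster_frames:
        for row in rows:
            by_frame.setdefault(row[1], []).append(row)
    for f in range(n_frames):
        photons = np.full((npix, npix), kinetics.background_photons, dtype=float)
        for (_, _, x, y, bright) in by_frame.get(f, []):
            _render_spot(
                photons, y / acq.pixel_size + centre_px,
                x / acq.pixel_size + centre_px, bright, sigma_px,
            )
        for m in range(n_mono):
            _render_spot(
                photons, mono_pos[m, 1] / acq.pixel_size + centre_px,
                mono_pos[m, 0] / acq.pixel_size + centre_px,
                kinetics.monomer_brightness, sigma_px,
            )
            mono_pos[m] = _reflect_disc(
                mono_pos[m], mono_sig * rng.standard_normal(2), radius
            )
        counts = (
            rng.poisson(photons).astype(float)
            + kinetics.camera_offset
            + rng.normal(0.0, kinetics.read_noise_std, size=photons.shape)
        )
        frames[f] = np.clip(np.rint(counts), 0, 65535).astype(np.uint16)
    movie = MovieStack(frames, pixel_size=acq.pixel_size, frame_interval=dt)
    return movie, truth
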