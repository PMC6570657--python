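"""Variational-Bayes HMM over single-particle displacement sequences.

Model: each displacement x_t (µm, at fixed Δt) is emitted by a hidden state
k as an isotropic zero-mean 2-D Gaussian with per-coordinate variance
2·D_k·Δt; the hidden state evolves as a first-order Markov chain per frame.
Conjugate priors — a gamma over each state's step precision λ_k =
1/(2·D_k·Δt), Dirichlets over each transition row and over the initial
distribution — give closed-form VBEM updates (Beal-style): the E-step runs
forward-backward under expected log-parameters, the M-step adds expected
counts to the prior. The evidence lower bound (ELBO) is exact for this
conjugate family, non-decreasing over iterations, and serves as the
model-selection criterion: the number of diffusive states is the K whose
best restart attains the maximal ELBO (maximum evidence).

Reported states are always ordered by ascending diffusion coefficient.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.special import digamma, gammaln
from sklearn.base import BaseEstimator

from ._fb import e_step, viterbi
from .params import AcquisitionParams
from .trajectories import TrajectorySet

logger = logging.getLogger(__name__)

__all__ = [
    "StepSeries",
    "VBPosterior",
    "HMMSummary",
    "ModelSelectionResult",
    "VariationalBayesDiffusionHMM",
    "DiffusionHMMSelector",
    "extract_steps",
    "vb_fit",
    "select_model",
    "bootstrap_uncertainty",
    "summarize_model",
    "decode_states",
]


@dataclass(frozen=True)
class StepSeries:
    """Concatenated 2-D displacement sequences at fixed frame interval.

    ``steps`` has shape (total_steps, 2); ``lengths`` gives steps per
    trajectory in order; ``frame_interval`` is Δt in seconds.
    """

    steps: np.ndarray
    lengths: np.ndarray
    frame_interval: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "steps", np.asarray(self.steps, dtype=float))
        object.__setattr__(self, "lengths", np.asarray(self.lengths, dtype=np.int64))
        if self.steps.ndim != 2 or self.steps.shape[1] != 2:
            raise ValueError("steps must have shape (n, 2)")
        if self.lengths.sum() != len(self.steps):
            raise ValueError("lengths must sum to the number of steps")
        if np.any(self.lengths < 1):
            raise ValueError("each sequence needs at least one step")
        if not np.all(np.isfinite(self.steps)):
            raise ValueError("steps must be finite")

    @property
    def n_sequences(self) -> int:
        return len(self.lengths)

    @property
    def n_steps(self) -> int:
        return len(self.steps)


def extract_steps(
    trajset: TrajectorySet, acq: AcquisitionParams | None = None
) -> StepSeries:
    """Displacement sequences from a trajectory set (frames must be
    consecutive, which :class:`~discspt.trajectories.Trajectory` enforces)."""
    acq = acq or AcquisitionParams()
    steps = [t.steps() for t in trajset]
    if not steps:
        raise ValueError("empty trajectory set")
    return StepSeries(
        steps=np.concatenate(steps, axis=0),
        lengths=np.array([len(s) for s in steps]),
        frame_interval=acq.frame_interval,
    )


@dataclass
class VBPosterior:
    """Conjugate posterior over HMM parameters.

    ``gamma_shape``/``gamma_rate`` parameterize the per-state gamma posterior
    over step precision λ_k; ``trans_counts`` and ``init_counts`` are the
    Dirichlet posteriors; ``expected_step_counts`` are ΣE[z_tk].
    States are stored in ascending order of diffusion coefficient.
    """

    gamma_shape: np.ndarray
    gamma_rate: np.ndarray
    trans_counts: np.ndarray
    init_counts: np.ndarray
    expected_step_counts: np.ndarray
    elbo: float
    elbo_history: np.ndarray
    converged: bool
    frame_interval: float
    prior_gamma_shape: float
    prior_gamma_rate: float
    prior_trans: float
    prior_init: float

    @property
    def n_states(self) -> int:
        return len(self.gamma_shape)

    def d_point(self) -> np.ndarray:
        """Posterior-mean diffusion coefficients (µm²/s)."""
        a, b = self.gamma_shape, self.gamma_rate
        # E[1/lambda] = b/(a-1); fall back to 1/E[lambda] for tiny shapes
        ev = np.where(a > 1.0, b / np.maximum(a - 1.0, 1e-12), b / a)
        return ev / (2.0 * self.frame_interval)

    def transmat_point(self) -> np.ndarray:
        return self.trans_counts / self.trans_counts.sum(axis=1, keepdims=True)

    def startprob_point(self) -> np.ndarray:
        return self.init_counts / self.init_counts.sum()


@dataclass(frozen=True)
class HMMSummary:
    """Point summary of a fitted model (states ascending in D)."""

    d_states: np.ndarray          # µm²/s
    occupancies: np.ndarray       # step fraction
    dwell_times: np.ndarray       # s
    transition_rates: np.ndarray  # s⁻¹ off-diagonal, 0 on diagonal
    transition_matrix: np.ndarray


@dataclass
class ModelSelectionResult:
    """Maximum-evidence model selection over K = 1..K_max."""

    k_values: np.ndarray
    elbos: np.ndarray
    best_k: int
    posteriors: dict
    summary: HMMSummary
    n_effective_states: int
    bootstrap: dict | None = None


def _dirichlet_kl(counts: np.ndarray, prior: float) -> float:
    counts = np.atleast_1d(counts)
    a0 = np.full_like(counts, prior)
    s, s0 = counts.sum(), a0.sum()
    return float(
        gammaln(s) - gammaln(s0)
        - np.sum(gammaln(counts) - gammaln(a0))
        + np.sum((counts - a0) * (digamma(counts) - digamma(s)))
    )


def _gamma_kl(a: float, b: float, a0: float, b0: float) -> float:
    return float(
        (a - a0) * digamma(a) - gammaln(a) + gammaln(a0)
        + a0 * (np.log(b) - np.log(b0)) + a * (b0 - b) / b
    )


class VariationalBayesDiffusionHMM(BaseEstimator):
    """VB-HMM with state-dependent diffusion, scikit-learn style.

    Parameters
    ----------
    n_states : int
        Number of diffusive states K.
    frame_interval : float
        Δt in seconds.
    n_restarts : int
        Independent VBEM restarts; the restart with the highest ELBO wins.
    max_iter, tol : int, float
        Per-restart VBEM cap and relative-ELBO convergence tolerance.
    trans_prior, init_prior : float
        Symmetric Dirichlet concentrations (per element).
    precision_prior_strength : float
        Pseudo-counts of the gamma prior on step precision; its mean is
        matched to the pooled moment estimator of the data.
    localization_sigma, correct_localization :
        Optional static-error correction: subtract σ²/Δt from the reported
        diffusion coefficients (off by default; the uncorrected estimate
        matches the reference analysis).
    random_state : int
        Master seed; restart r of a K-state fit draws from the derived
        stream (random_state, K, r) so results are order-independent.

    Attributes (after ``fit``) — states sorted by ascending D:
    ``D_``, ``occupancy_``, ``dwell_times_``, ``transmat_``, ``startprob_``,
    ``transition_rates_``, ``elbo_``, ``converged_``, ``posterior_``.
    """

    def __init__(
        self,
        n_states: int = 3,
        frame_interval: float = 1.0 / 30.0,
        n_restarts: int = 25,
        max_iter: int = 500,
        tol: float = 1e-8,
        trans_prior: float = 1.0,
        init_prior: float = 1.0,
        precision_prior_strength: float = 1.0,
        localization_sigma: float = 0.0,
        correct_localization: bool = False,
        random_state: int = 0,
    ):
        self.n_states = n_states
        self.frame_interval = frame_interval
        self.n_restarts = n_restarts
        self.max_iter = max_iter
        self.tol = tol
        self.trans_prior = trans_prior
        self.init_prior = init_prior
        self.precision_prior_strength = precision_prior_strength
        self.localization_sigma = localization_sigma
        self.correct_localization = correct_localization
        self.random_state = random_state

    # ------------------------------------------------------------------ fit

    def fit(self, X, lengths=None):
        """Fit on displacement vectors X (n_steps, 2); ``lengths`` lists the
        steps per trajectory (default: one sequence)."""
        X, lengths = self._validate(X, lengths)
        K = self.n_states
        if len(X) < K:
            raise ValueError(f"need at least K={K} steps, got {len(X)}")
        s_padded, lengths_arr = self._pad_sq_norms(X, lengths)
        best = None
        for r in range(self.n_restarts):
            rng = np.random.default_rng([self.random_state, self.n_states, r])
            post = self._run_vbem(s_padded, lengths_arr, rng=rng)
            if best is None or post.elbo > best.elbo:
                best = post
        self._finalize(best)
        return self

    def _validate(self, X, lengths):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != 2:
            raise ValueError("X must be (n_steps, 2) displacement vectors")
        if lengths is None:
            lengths = [len(X)]
        lengths = np.asarray(lengths, dtype=np.int64)
        if lengths.sum() != len(X):
            raise ValueError("lengths must sum to n_steps")
        return X, lengths

    def _pad_sq_norms(self, X, lengths):
        """Squared step norms padded to (n_seq, T_max)."""
        sq = np.einsum("ij,ij->i", X, X)
        n_seq, T = len(lengths), int(lengths.max())
        out = np.zeros((n_seq, T))
        offs = np.concatenate([[0], np.cumsum(lengths)])
        for i in range(n_seq):
            out[i, : lengths[i]] = sq[offs[i] : offs[i + 1]]
        return out, lengths

    def _init_posterior(self, s_padded, lengths, rng, K, a0, b0):
        """Data-driven randomized initial posterior."""
        sq = _active_values(s_padded, lengths)
        N = sq.size
        n_seq = len(lengths)
        # spread initial variances over the data quantile range with jitter
        qs = np.sort(rng.uniform(0.05, 0.95, size=K))
        v = np.quantile(sq, qs) / 2.0
        v = np.maximum(v * rng.lognormal(0.0, 0.4, size=K), 1e-12)
        a = np.full(K, a0 + N / K)
        b = a * v
        stick = rng.uniform(0.5, 0.95)
        trans = np.full((K, K), (1.0 - stick) / max(K - 1, 1)) if K > 1 else np.ones((1, 1))
        if K > 1:
            np.fill_diagonal(trans, stick)
        trans_counts = self.trans_prior + (N / K) * trans
        init_counts = np.full(K, self.init_prior + n_seq / K)
        return a, b, trans_counts, init_counts

    def _run_vbem(
        self, s_padded, lengths, rng=None, init=None, max_iter=None
    ) -> VBPosterior:
        K = self.n_states
        sq = _active_values(s_padded, lengths)
        N = sq.size
        vbar = max(float(np.mean(sq)) / 2.0, 1e-15)
        a0 = float(self.precision_prior_strength)
        b0 = a0 * vbar  # prior mean precision = pooled moment estimator
        if init is not None:
            a, b, trans_counts, init_counts = (x.copy() for x in init)
        else:
            a, b, trans_counts, init_counts = self._init_posterior(
                s_padded, lengths, rng, K, a0, b0
            )
        max_iter = max_iter or self.max_iter
        elbos = []
        converged = False
        Nk = None
        for _ in range(max_iter):
            # expected log-parameters (tilted, sub-normalized weights)
            e_lam = a / b
            e_lnlam = digamma(a) - np.log(b)
            ln_pi = digamma(init_counts) - digamma(init_counts.sum())
            ln_A = digamma(trans_counts) - digamma(trans_counts.sum(axis=1))[:, None]
            loglik, Nk, Sk, xi, gamma0 = e_step(
                s_padded, lengths, e_lam, e_lnlam, np.exp(ln_A), np.exp(ln_pi)
            )
            kl = (
                _dirichlet_kl(init_counts, self.init_prior)
                + sum(_dirichlet_kl(trans_counts[k], self.trans_prior) for k in range(K))
                + sum(_gamma_kl(a[k], b[k], a0, b0) for k in range(K))
            )
            elbo = loglik - kl
            elbos.append(elbo)
            if len(elbos) > 1 and abs(elbos[-1] - elbos[-2]) <= self.tol * abs(elbos[-1]):
                converged = True
            # M-step: prior plus expected counts
            a = a0 + Nk
            b = b0 + 0.5 * Sk
            trans_counts = self.trans_prior + xi
            init_counts = self.init_prior + gamma0
            if converged:
                break
        if not converged:
            warnings.warn("VBEM did not converge within max_iter", RuntimeWarning)
        return VBPosterior(
            gamma_shape=a,
            gamma_rate=b,
            trans_counts=trans_counts,
            init_counts=init_counts,
            expected_step_counts=Nk,
            elbo=elbos[-1],
            elbo_history=np.asarray(elbos),
            converged=converged,
            frame_interval=self.frame_interval,
            prior_gamma_shape=a0,
            prior_gamma_rate=b0,
            prior_trans=self.trans_prior,
            prior_init=self.init_prior,
        )

    def _finalize(self, post: VBPosterior):
        order = np.argsort(post.d_point())
        post.gamma_shape = post.gamma_shape[order]
        post.gamma_rate = post.gamma_rate[order]
        post.trans_counts = post.trans_counts[np.ix_(order, order)]
        post.init_counts = post.init_counts[order]
        post.expected_step_counts = post.expected_step_counts[order]
        self.posterior_ = post
        D = post.d_point()
        if self.correct_localization and self.localization_sigma > 0:
            D = np.maximum(
                D - self.localization_sigma**2 / self.frame_interval, 1e-6
            )
        self.D_ = D
        self.occupancy_ = post.expected_step_counts / post.expected_step_counts.sum()
        self.transmat_ = post.transmat_point()
        self.startprob_ = post.startprob_point()
        with np.errstate(divide="ignore"):
            self.dwell_times_ = self.frame_interval / (1.0 - np.diag(self.transmat_))
        rates = self.transmat_ / self.frame_interval
        np.fill_diagonal(rates, 0.0)
        self.transition_rates_ = rates
        self.elbo_ = post.elbo
        self.converged_ = post.converged
        self.n_states_ = post.n_states
        return self

    # -------------------------------------------------------------- predict

    def predict(self, X, lengths=None):
        """Viterbi state labels (ascending-D convention), one per step."""
        from sklearn.utils.validation import check_is_fitted

        check_is_fitted(self, "posterior_")
        X, lengths = self._validate(X, lengths)
        s_padded, lengths_arr = self._pad_sq_norms(X, lengths)
        v = 2.0 * self.posterior_.d_point() * self.frame_interval
        lnB = (
            -np.log(2.0 * np.pi * v)[None, None, :]
            - 0.5 * s_padded[:, :, None] / v[None, None, :]
        )
        paths = viterbi(
            np.ascontiguousarray(lnB),
            lengths_arr,
            np.log(self.transmat_),
            np.log(np.maximum(self.startprob_, 1e-300)),
        )
        return [paths[i, : lengths_arr[i]].copy() for i in range(len(lengths_arr))]

    def score(self, X=None, y=None):
        """Evidence lower bound of the fitted model (nats)."""
        return self.elbo_

    def summary(self) -> HMMSummary:
        return HMMSummary(
            d_states=self.D_.copy(),
            occupancies=self.occupancy_.copy(),
            dwell_times=self.dwell_times_.copy(),
            transition_rates=self.transition_rates_.copy(),
            transition_matrix=self.transmat_.copy(),
        )


def _active_values(padded: np.ndarray, lengths: np.ndarray) -> np.ndarray:
    mask = np.arange(padded.shape[1])[None, :] < lengths[:, None]
    return padded[mask]


class DiffusionHMMSelector(BaseEstimator):
    """Maximum-evidence selection of the number of diffusive states.

    Fits :class:`VariationalBayesDiffusionHMM` for K = 1..``k_max`` and
    keeps the K with the highest ELBO (ties within ``tol`` broken towards
    smaller K). States whose expected step count falls below
    ``pruning_floor`` are dropped from the reported summary.
    """

    def __init__(
        self,
        k_max: int = 5,
        frame_interval: float = 1.0 / 30.0,
        n_restarts: int = 25,
        max_iter: int = 500,
        tol: float = 1e-8,
        pruning_floor: float = 1.0,
        random_state: int = 0,
        **fit_params,
    ):
        self.k_max = k_max
        self.frame_interval = frame_interval
        self.n_restarts = n_restarts
        self.max_iter = max_iter
        self.tol = tol
        self.pruning_floor = pruning_floor
        self.random_state = random_state
        self.fit_params = fit_params

    def fit(self, X, lengths=None):
        if len(np.asarray(X)) < self.k_max:
            raise ValueError("need at least k_max steps")
        models = {}
        elbos = np.empty(self.k_max)
        for K in range(1, self.k_max + 1):
            m = VariationalBayesDiffusionHMM(
                n_states=K,
                frame_interval=self.frame_interval,
                n_restarts=self.n_restarts,
                max_iter=self.max_iter,
                tol=self.tol,
                random_state=self.random_state,
                **self.fit_params,
            ).fit(X, lengths)
            models[K] = m
            elbos[K - 1] = m.elbo_
            logger.info("K=%d: ELBO=%.3f", K, m.elbo_)
        # argmax with parsimony tie-break: smaller K wins within tol
        best_k = 1
        for K in range(2, self.k_max + 1):
            if elbos[K - 1] > elbos[best_k - 1] + self.tol * abs(elbos[K - 1]):
                best_k = K
        self.models_ = models
        self.elbos_ = elbos
        self.best_k_ = best_k
        self.best_model_ = models[best_k]
        self._prune()
        return self

    def _prune(self):
        m = self.best_model_
        keep = m.posterior_.expected_step_counts >= self.pruning_floor
        self.n_effective_states_ = int(keep.sum())
        if keep.all():
            self.summary_ = m.summary()
        else:
            occ = m.occupancy_[keep]
            sub = m.transmat_[np.ix_(keep, keep)]
            sub = sub / sub.sum(axis=1, keepdims=True)
            rates = sub / self.frame_interval
            np.fill_diagonal(rates, 0.0)
            with np.errstate(divide="ignore"):
                dwell = self.frame_interval / (1.0 - np.diag(sub))
            self.summary_ = HMMSummary(
                d_states=m.D_[keep],
                occupancies=occ / occ.sum(),
                dwell_times=dwell,
                transition_rates=rates,
                transition_matrix=sub,
            )

    def predict(self, X, lengths=None):
        return self.best_model_.predict(X, lengths)


# ------------------------------------------------------------- thin wrappers


def vb_fit(
    steps: StepSeries,
    K: int,
    n_restarts: int = 25,
    max_iter: int = 500,
    tol: float = 1e-8,
    seed: int = 0,
    **kwargs,
) -> VBPosterior:
    """Fit a K-state VB-HMM on a step series; returns the best posterior."""
    model = VariationalBayesDiffusionHMM(
        n_states=K,
        frame_interval=steps.frame_interval,
        n_restarts=n_restarts,
        max_iter=max_iter,
        tol=tol,
        random_state=seed,
        **kwargs,
    ).fit(steps.steps, steps.lengths)
    return model.posterior_


def select_model(
    steps: StepSeries,
    k_max: int = 5,
    n_restarts: int = 25,
    max_iter: int = 500,
    seed: int = 0,
    n_boot: int = 0,
    **kwargs,
) -> ModelSelectionResult:
    """Maximum-evidence model selection, optionally with bootstrap spread."""
    sel = DiffusionHMMSelector(
        k_max=k_max,
        frame_interval=steps.frame_interval,
        n_restarts=n_restarts,
        max_iter=max_iter,
        random_state=seed,
        **kwargs,
    ).fit(steps.steps, steps.lengths)
    boot = None
    if n_boot > 0:
        boot = bootstrap_uncertainty(steps, sel.best_k_, n_boot=n_boot, seed=seed)
    return ModelSelectionResult(
        k_values=np.arange(1, k_max + 1),
        elbos=sel.elbos_,
        best_k=sel.best_k_,
        posteriors={k: m.posterior_ for k, m in sel.models_.items()},
        summary=sel.summary_,
        n_effective_states=sel.n_effective_states_,
        bootstrap=boot,
    )


def bootstrap_uncertainty(
    steps: StepSeries,
    K: int,
    n_boot: int = 100,
    seed: int = 0,
    n_restarts: int = 3,
    max_iter: int = 300,
    force_identity: bool = False,
    **kwargs,
) -> dict:
    """Trajectory-level bootstrap of the K-state fit.

    Whole trajectories are resampled with replacement (steps within a
    trajectory are dependent); each replicate is refit at fixed K and
    states are matched across replicates by ascending D. Returns arrays of
    shape (n_boot, K) for ``d``, ``occupancy`` and ``dwell``.
    """
    if steps.n_sequences < 2:
        raise ValueError("bootstrap requires at least 2 trajectories")
    rng = np.random.default_rng([seed, 7, K])
    offs = np.concatenate([[0], np.cumsum(steps.lengths)])
    d = np.empty((n_boot, K))
    occ = np.empty((n_boot, K))
    dwell = np.empty((n_boot, K))
    for b in range(n_boot):
        if force_identity:
            idx = np.arange(steps.n_sequences)
        else:
            idx = rng.integers(0, steps.n_sequences, size=steps.n_sequences)
        X = np.concatenate([steps.steps[offs[i] : offs[i + 1]] for i in idx])
        lengths = steps.lengths[idx]
        m = VariationalBayesDiffusionHMM(
            n_states=K,
            frame_interval=steps.frame_interval,
            n_restarts=n_restarts,
            max_iter=max_iter,
            random_state=int(rng.integers(0, 2**31 - 1)),
            **kwargs,
        ).fit(X, lengths)
        d[b] = m.D_
        occ[b] = m.occupancy_
        dwell[b] = m.dwell_times_
    return {"d": d, "occupancy": occ, "dwell": dwell}


def summarize_model(
    post: VBPosterior, acq: AcquisitionParams | None = None
) -> HMMSummary:
    """Point summary (D, occupancy, dwell, rates) of a fitted posterior."""
    dt = acq.frame_interval if acq is not None else post.frame_interval
    A = post.transmat_point()
    rates = A / dt
    np.fill_diagonal(rates, 0.0)
    occ = post.expected_step_counts / post.expected_step_counts.sum()
    with np.errstate(divide="ignore"):
        dwell = dt / (1.0 - np.diag(A))
    return HMMSummary(
        d_states=post.d_point(),
        occupancies=occ,
        dwell_times=dwell,
        transition_rates=rates,
        transition_matrix=A,
    )


def decode_states(post: VBPosterior, trajset: TrajectorySet) -> list[np.ndarray]:
    """Viterbi per-step state labels under posterior-mean parameters."""
    acq = AcquisitionParams(frame_interval=post.frame_interval)
    series = extract_steps(trajset, acq)
    model = VariationalBayesDiffusionHMM(
        n_states=post.n_states, frame_interval=post.frame_interval, n_restarts=1
    )
    model.posterior_ = post
    model.transmat_ = post.transmat_point()
    model.startprob_ = post.startprob_point()
    return model.predict(series.steps, series.lengths)
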