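"""Time-averaged MSD analysis and the effective D_100ms estimator.

For a trajectory r(0..N) the time-averaged mean square displacement at lag n
uses all overlapping pairs: MSD(n) = mean_i |r(i+n) − r(i)|². For free 2-D
diffusion with static localization error σ per coordinate,
MSD(nΔt) = 4·D·nΔt + 4σ², so an ordinary least-squares line over the lags
within 100 ms (three lags at 30 frames/s) with a free intercept estimates
D_100ms = slope/4 while the intercept absorbs the 4σ² offset.

Trajectory filtering mirrors the experimental protocol: tracks shorter than
16 frames are dropped, and tracks whose MSD–Δt curve bends (confinement by
disc incisures) are dropped by requiring R² > 0.8 of a linear fit over the
first quarter of available lags.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .params import AcquisitionParams
from .trajectories import Trajectory, TrajectorySet

logger = logging.getLogger(__name__)

__all__ = [
    "MSDCurve",
    "MSDFit",
    "FilterReport",
    "compute_msd",
    "fit_d100ms",
    "msd_r_squared",
    "filter_trajectories",
    "summarize_d100ms",
    "compare_distributions",
]


@dataclass(frozen=True)
class MSDCurve:
    """Time-averaged MSD versus lag time.

    ``lags`` are in seconds (multiples of Δt, lag 0 excluded), ``msd`` in
    µm², ``n_pairs`` counts the displacement pairs averaged per lag.
    """

    lags: np.ndarray
    msd: np.ndarray
    n_pairs: np.ndarray


@dataclass(frozen=True)
class MSDFit:
    """Linear MSD fit: ``d_100ms`` (µm²/s), intercept (µm²), the filter R²
    (computed over the first quarter of available lags) and the number of
    lags used for the slope."""

    d_100ms: float
    intercept: float
    r_squared: float
    n_lags_fit: int


@dataclass(frozen=True)
class FilterReport:
    n_input: int
    n_removed_length: int
    n_removed_r2: int

    @property
    def n_kept(self) -> int:
        return self.n_input - self.n_removed_length - self.n_removed_r2


def compute_msd(
    traj: Trajectory, max_lag: int | None = None, acq: AcquisitionParams | None = None
) -> MSDCurve:
    """Time-averaged MSD with overlapping windows up to ``max_lag`` frames."""
    acq = acq or AcquisitionParams()
    n = len(traj)
    if n < 2:
        raise ValueError("trajectory must have at least 2 frames")
    if max_lag is None:
        max_lag = n - 1
    if max_lag > n - 1:
        raise ValueError("max_lag exceeds trajectory length - 1")
    pos = traj.positions
    lags = np.arange(1, max_lag + 1)
    msd = np.empty(max_lag)
    n_pairs = np.empty(max_lag, dtype=np.int64)
    for k, lag in enumerate(lags):
        d = pos[lag:] - pos[:-lag]
        msd[k] = np.mean(np.einsum("ij,ij->i", d, d))
        n_pairs[k] = n - lag
    return MSDCurve(lags=lags * acq.frame_interval, msd=msd, n_pairs=n_pairs)


def _ols_line(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """Least-squares slope, intercept and R² of y on x."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    xm, ym = x.mean(), y.mean()
    sxx = np.sum((x - xm) ** 2)
    slope = np.sum((x - xm) * (y - ym)) / sxx
    intercept = ym - slope * xm
    ss_res = np.sum((y - slope * x - intercept) ** 2)
    ss_tot = np.sum((y - ym) ** 2)
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else (1.0 if ss_res == 0 else -np.inf)
    return slope, intercept, r2


def msd_r_squared(curve: MSDCurve, clip_factor: float = 0.25) -> float:
    """R² of a linear fit over the first ``clip_factor`` of available lags.

    This is the goodness-of-fit used by the confinement filter (bent,
    plateauing curves fit a line poorly). At least 2 lags are always used.
    """
    n_fit = max(2, int(np.floor(clip_factor * len(curve.lags))))
    _, _, r2 = _ols_line(curve.lags[:n_fit], curve.msd[:n_fit])
    return r2


def fit_d100ms(
    curve: MSDCurve,
    acq: AcquisitionParams | None = None,
    window: float = 0.100,
) -> MSDFit:
    """Fit D_100ms: OLS of MSD on lag time over all lags ≤ ``window`` seconds.

    The slope/4 is the effective diffusion coefficient within 100 ms; the
    free intercept absorbs the 4σ² localization offset. The reported R² is
    the confinement-filter statistic over the first quarter of lags.
    """
    acq = acq or AcquisitionParams()
    use = curve.lags <= window + 1e-12
    if np.count_nonzero(use) < 2:
        raise ValueError("need at least 2 lags within the fit window")
    slope, intercept, _ = _ols_line(curve.lags[use], curve.msd[use])
    return MSDFit(
        d_100ms=slope / 4.0,
        intercept=intercept,
        r_squared=msd_r_squared(curve),
        n_lags_fit=int(np.count_nonzero(use)),
    )


def filter_trajectories(
    trajset: TrajectorySet,
    acq: AcquisitionParams | None = None,
    min_frames: int = 16,
    r2_min: float = 0.8,
) -> tuple[TrajectorySet, FilterReport]:
    """Apply the experimental trajectory filters.

    Removes tracks with fewer than ``min_frames`` frames (protocol:
    minimum length >15 frames) and tracks whose MSD–Δt curve is not
    well fit by a line (R² ≤ ``r2_min``), which removes incisure-confined,
    plateauing tracks.
    """
    acq = acq or AcquisitionParams()
    kept, n_len, n_r2 = [], 0, 0
    for t in trajset:
        if len(t) < min_frames:
            n_len += 1
            continue
        curve = compute_msd(t, acq=acq)
        if msd_r_squared(curve) <= r2_min:
            n_r2 += 1
            continue
        kept.append(t)
    report = FilterReport(
        n_input=len(trajset), n_removed_length=n_len, n_removed_r2=n_r2
    )
    if not kept:
        logger.warning("all trajectories removed by filters")
    logger.info(
        "filter: %d in, %d removed (length), %d removed (R^2), %d kept",
        report.n_input, n_len, n_r2, report.n_kept,
    )
    return TrajectorySet(kept), report


def summarize_d100ms(fits, bin_width: float = 0.05):
    """Histogram counts, bin edges and median of a collection of D_100ms.

    Returns ``(counts, edges, median)``; ``bin_width`` is presentational
    (µm²/s). Raises on empty input.
    """
    values = np.asarray([f.d_100ms if isinstance(f, MSDFit) else f for f in fits], float)
    if values.size == 0:
        raise ValueError("no fits to summarize")
    lo = min(0.0, values.min())
    hi = values.max() + bin_width
    edges = np.arange(lo, hi + bin_width, bin_width)
    counts, edges = np.histogram(values, bins=edges)
    return counts, edges, float(np.median(values))


def compare_distributions(a, b) -> tuple[float, float]:
    """Mann–Whitney U comparison of two samples.

    Returns ``(U, two-sided p)`` with midrank tie handling: the p-value is
    exact (enumeration) when the smaller sample has ≤ 8 values and there are
    no ties, otherwise a normal approximation with tie and continuity
    corrections is used.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method="auto")
    return float(res.statistic), float(res.pvalue)
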