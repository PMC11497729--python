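"""Error metrics and model comparisons.

MAPE (mean absolute percentage error) is always computed on the SUVR scale:
Centiloids cross zero, so a relative error there is undefined, while SUVR is
bounded well away from zero.  The sliding-window profile recomputes MAPE
within overlapping 25-Centiloid windows along the amyloid axis (predicted
burden by default) to expose burden-dependent accuracy, with 95% percentile
bootstrap confidence bands resampling participants within each window.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .scale import CentiloidMap, default_centiloid_map

__all__ = [
    "ErrorProfile",
    "ComparisonResult",
    "SpearmanResult",
    "mape",
    "regional_mape",
    "sliding_window_mape",
    "compare_profiles",
    "spearman_ci",
]


def mape(predicted, actual) -> float:
    """``100 * mean(|predicted - actual| / actual)`` over paired forecasts."""
    p = np.asarray(predicted, dtype=float).ravel()
    a = np.asarray(actual, dtype=float).ravel()
    if p.shape != a.shape:
        raise ValueError(f"length mismatch: predicted {p.shape} vs actual {a.shape}")
    if p.size == 0:
        raise ValueError("cannot compute MAPE of empty vectors")
    if np.any(a <= 0):
        raise ValueError("actual values must be strictly positive for a relative error")
    return float(100.0 * np.mean(np.abs(p - a) / a))


def regional_mape(predicted, actual, region_names) -> pd.Series:
    """Column-wise MAPE of two (participants x regions) matrices, keyed by region."""
    p = np.asarray(predicted, dtype=float)
    a = np.asarray(actual, dtype=float)
    if p.shape != a.shape:
        raise ValueError(f"shape mismatch: {p.shape} vs {a.shape}")
    if p.shape[1] != len(region_names):
        raise ValueError(f"{p.shape[1]} columns but {len(region_names)} region names")
    values = [mape(p[:, j], a[:, j]) for j in range(p.shape[1])]
    return pd.Series(values, index=list(region_names), name="mape_pct")


@dataclass
class ErrorProfile:
    """Sliding-window MAPE curve with bootstrap confidence bands.

    Windows with fewer than the minimum participant count are reported empty
    (NaN point estimate and bands, count retained).
    """

    window_centers: np.ndarray      # Centiloids
    window_width: float             # Centiloids
    mape_point: np.ndarray          # % per window
    ci_low: np.ndarray
    ci_high: np.ndarray
    n_in_window: np.ndarray
    n_boot: int
    axis_variable: str              # "predicted" or "observed"
    seed: int | None = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "window_center_cl": self.window_centers,
            "mape": self.mape_point,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "n": self.n_in_window,
        })

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    def to_json(self) -> str:
        def _lst(a):
            return [None if isinstance(v, float) and np.isnan(v) else v for v in a.tolist()]
        return json.dumps({
            "window_centers": self.window_centers.tolist(),
            "window_width": self.window_width,
            "mape_point": _lst(self.mape_point),
            "ci_low": _lst(self.ci_low),
            "ci_high": _lst(self.ci_high),
            "n_in_window": self.n_in_window.tolist(),
            "n_boot": self.n_boot,
            "axis_variable": self.axis_variable,
            "seed": self.seed,
        })


def sliding_window_mape(
    predicted,
    actual,
    cmap: CentiloidMap | None = None,
    window_width: float = 25.0,
    step: float = 1.0,
    n_boot: int = 1000,
    min_n: int = 10,
    axis: str = "predicted",
    seed: int | None = None,
    centers=None,
) -> ErrorProfile:
    """MAPE across a sliding Centiloid window with a percentile bootstrap.

    ``predicted`` and ``actual`` are paired mean cortical SUVR values.  The
    window slides along the Centiloid transform of the axis variable
    (predicted burden by default); membership is the half-open interval
    ``[center - width/2, center + width/2)``.  Within each window the MAPE is
    computed on the SUVR scale, and participants are resampled with
    replacement ``n_boot`` times for a 95% percentile CI.
    """
    if axis not in ("predicted", "observed"):
        raise ValueError("axis must be 'predicted' or 'observed'")
    if window_width <= 0:
        raise ValueError("window_width must be > 0")
    p = np.asarray(predicted, dtype=float).ravel()
    a = np.asarray(actual, dtype=float).ravel()
    if p.shape != a.shape:
        raise ValueError("predicted and actual must be paired")
    cmap = cmap or default_centiloid_map()
    axis_cl = cmap.to_centiloid(p if axis == "predicted" else a)
    if centers is None:
        lo = float(np.floor(axis_cl.min()))
        hi = float(np.ceil(axis_cl.max()))
        centers = np.arange(lo, hi + step / 2, step)
    centers = np.asarray(centers, dtype=float)
    rng = np.random.default_rng(seed)
    pct_err = 100.0 * np.abs(p - a) / a
    point = np.full(centers.size, np.nan)
    ci_lo = np.full(centers.size, np.nan)
    ci_hi = np.full(centers.size, np.nan)
    counts = np.zeros(centers.size, dtype=int)
    half = window_width / 2.0
    for i, c in enumerate(centers):
        in_win = (axis_cl >= c - half) & (axis_cl < c + half)
        m = int(in_win.sum())
        counts[i] = m
        if m < min_n:
            continue
        errs = pct_err[in_win]
        point[i] = float(errs.mean())
        idx = rng.integers(0, m, size=(n_boot, m))
        boot = errs[idx].mean(axis=1)
        ci_lo[i] = float(np.percentile(boot, 2.5))
        ci_hi[i] = float(np.percentile(boot, 97.5))
    return ErrorProfile(centers, window_width, point, ci_lo, ci_hi, counts,
                        n_boot, axis, seed)


@dataclass
class ComparisonResult:
    """Centiloid ranges where one profile's 95% CI lies wholly below the other's.

    A is "significantly better" in a window iff ``A.ci_high < B.ci_low``
    (non-overlapping CIs, conservative).  Contiguous significant windows are
    merged into (start, end) center ranges; ``crossover_cl`` is the last
    window center of the first significant run — the amyloid level up to
    which one model significantly outperformed the other.
    """

    a_better_ranges: list[tuple[float, float]]
    b_better_ranges: list[tuple[float, float]]
    crossover_cl: float | None

    def swapped(self) -> "ComparisonResult":
        return ComparisonResult(self.b_better_ranges, self.a_better_ranges,
                                self.crossover_cl)


def _runs(centers: np.ndarray, mask: np.ndarray) -> list[tuple[float, float]]:
    ranges = []
    start = None
    for c, m in zip(centers, mask):
        if m and start is None:
            start = c
        elif not m and start is not None:
            ranges.append((float(start), float(prev)))
            start = None
        prev = c
    if start is not None:
        ranges.append((float(start), float(centers[-1])))
    return ranges


def compare_profiles(profile_a: ErrorProfile, profile_b: ErrorProfile) -> ComparisonResult:
    """Window-wise significance comparison of two error profiles on a shared grid."""
    if (profile_a.window_centers.shape != profile_b.window_centers.shape
            or not np.allclose(profile_a.window_centers, profile_b.window_centers)):
        raise ValueError("profiles must share the same window grid")
    if profile_a.window_width != profile_b.window_width:
        raise ValueError("profiles must share the same window width")
    centers = profile_a.window_centers
    valid = ~(np.isnan(profile_a.mape_point) | np.isnan(profile_b.mape_point))
    a_better = valid & (profile_a.ci_high < profile_b.ci_low)
    b_better = valid & (profile_b.ci_high < profile_a.ci_low)
    a_ranges = _runs(centers, a_better)
    b_ranges = _runs(centers, b_better)
    first_start = None
    crossover = None
    for r in a_ranges[:1] + b_ranges[:1]:
        if first_start is None or r[0] < first_start:
            first_start = r[0]
            crossover = r[1]
    return ComparisonResult(a_ranges, b_ranges, crossover)


@dataclass(frozen=True)
class SpearmanResult:
    rho: float
    ci_low: float
    ci_high: float
    n: int
    n_boot: int


def spearman_ci(x, y, n_boot: int = 1000, seed: int | None = None) -> SpearmanResult:
    """Spearman rank correlation with a 95% percentile bootstrap CI.

    Ties receive average ranks; the bootstrap resamples participants.  A
    constant input leaves the correlation undefined and raises ``ValueError``.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.shape != y.shape:
        raise ValueError("x and y must be paired")
    n = x.size
    if n < 10:
        raise ValueError(f"need at least 10 pairs, got {n}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for a constant input")
    rho = float(stats.spearmanr(x, y).statistic)
    rng = np.random.default_rng(seed)
    boots = np.empty(n_boot)
    for b in range(n_boot):
        idx = rng.integers(0, n, size=n)
        xb, yb = x[idx], y[idx]
        if np.ptp(xb) == 0 or np.ptp(yb) == 0:
            boots[b] = np.nan
            continue
        boots[b] = stats.spearmanr(xb, yb).statistic
    boots = boots[~np.isnan(boots)]
    return SpearmanResult(rho, float(np.percentile(boots, 2.5)),
                          float(np.percentile(boots, 97.5)), n, n_boot)
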