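"""Predictive ceiling via asymptotic regression.

A biomarker whose mean response flattens at some amyloid burden cannot drive
forecasts beyond the corresponding PET value: the model's predictions saturate.
Fitting the classical 3-parameter asymptotic regression

    predicted = a + (b - a) * exp(-c * observed)

of model-predicted mean cortical SUVR (y) on observed mean cortical SUVR (x)
by nonlinear least squares quantifies that ceiling: the horizontal asymptote
``a`` is the maximum forecast the model can produce — the biomarker's
predictive range — reported with Wald (a +/- 1.96*se) confidence intervals
from the Jacobian-based covariance, in both SUVR and Centiloids.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .scale import CentiloidMap, default_centiloid_map

__all__ = ["AsymptoteFit", "PredictiveRange", "fit_asymptotic",
           "predictive_range", "range_error_summary"]

_FLAT_VARIANCE = 1e-8


@dataclass
class AsymptoteFit:
    """Result of the 3-parameter asymptotic regression (all values in SUVR)."""

    asym: float          # horizontal asymptote a
    y0: float            # value at x = 0 (parameter b)
    rate: float          # decay rate c (1/SUVR), > 0 when converged
    se_asym: float
    ci_low: float        # Wald 95% CI on the asymptote
    ci_high: float
    rss: float
    n: int
    converged: bool
    iterations: int
    message: str = ""
    extrapolated: bool = False  # asymptote far beyond the span of the data


def _model(theta: np.ndarray, x: np.ndarray) -> np.ndarray:
    a, b, c = theta
    return a + (b - a) * np.exp(-c * x)


def _profiled_start(x: np.ndarray, y: np.ndarray, x_range: float) -> np.ndarray:
    """Best (a, b, c) over a log-spaced c grid, solving a and b linearly."""
    best = None
    for c in np.geomspace(0.05 / x_range, 50.0 / x_range, 120):
        e = np.exp(-c * x)
        design = np.column_stack([1.0 - e, e])
        coef, *_ = np.linalg.lstsq(design, y, rcond=None)
        rss = float(np.sum((design @ coef - y) ** 2))
        if best is None or rss < best[0]:
            best = (rss, np.array([coef[0], coef[1], c]))
    return best[1]


def fit_asymptotic(observed, predicted, init: tuple[float, float, float] | None = None,
                   max_nfev: int = 2000) -> AsymptoteFit:
    """Fit ``predicted = a + (b - a) exp(-c * observed)`` by Levenberg-Marquardt.

    Default initialization: ``a0 = max(predicted)``, ``b0 = min(predicted)``,
    ``c0 = 1 / range(observed)``; on non-convergence the fit restarts from up
    to three perturbed initializations.  Standard errors come from the
    Jacobian-based covariance at the solution; the 95% CI on the asymptote is
    ``a +/- 1.96 se``.  Degenerate, essentially constant ``predicted`` falls
    back to the sample mean with the standard error of the mean.
    """
    x = np.asarray(observed, dtype=float).ravel()
    y = np.asarray(predicted, dtype=float).ravel()
    if x.shape != y.shape:
        raise ValueError("observed and predicted must be paired")
    n = x.size
    if n < 10:
        raise ValueError(f"need at least 10 points, got {n}")
    x_range = float(np.ptp(x))
    if x_range == 0:
        raise ValueError("observed values span a degenerate range")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("inputs must be finite")

    if float(np.var(y)) < _FLAT_VARIANCE:
        mean = float(y.mean())
        se = float(y.std(ddof=1) / np.sqrt(n)) if n > 1 else 0.0
        return AsymptoteFit(mean, mean, 1.0 / x_range, se,
                            mean - 1.96 * se, mean + 1.96 * se,
                            float(np.sum((y - mean) ** 2)), n, True, 0,
                            "flat-data fallback: predicted variance below threshold")

    def residuals(theta):
        return _model(theta, x) - y

    # Candidate starts: the heuristic triple, plus the best point of a profile
    # over c (the model is linear in a and b for fixed c, so each c costs one
    # 2-parameter linear solve).  The profile guards against the near-linear
    # local minimum (c -> 0, a -> infinity) that LM falls into when most of
    # the data lie on the rising limb.
    starts = [np.array(init, dtype=float)] if init is not None else []
    starts.append(np.array([float(y.max()), float(y.min()), 1.0 / x_range]))
    starts.append(_profiled_start(x, y, x_range))

    candidates = []
    total_nfev = 0
    for theta0 in starts:
        for factor in (1.0, 0.8, 1.25, 1.5):
            res = least_squares(residuals, theta0 * np.array([1.0, 1.0, factor]),
                                method="lm", max_nfev=max_nfev)
            total_nfev += res.nfev
            candidates.append(res)
            if res.success and res.x[2] > 0:
                break  # this start reached a saturating solution
    # prefer saturating (c > 0) successful fits, then by residual cost
    best = min(candidates,
               key=lambda r: (not (r.success and r.x[2] > 0), not r.success, r.cost))

    theta = best.x
    rss = float(2.0 * best.cost)
    converged = bool(best.success and theta[2] > 0)
    dof = max(n - 3, 1)
    s2 = rss / dof
    try:
        jtj = best.jac.T @ best.jac
        cov = np.linalg.inv(jtj) * s2
        se_a = float(np.sqrt(max(cov[0, 0], 0.0)))
    except np.linalg.LinAlgError:
        se_a = float("nan")
        converged = False
    y_span = float(y.max() - y.min())
    return AsymptoteFit(
        asym=float(theta[0]), y0=float(theta[1]), rate=float(theta[2]),
        se_asym=se_a,
        ci_low=float(theta[0] - 1.96 * se_a),
        ci_high=float(theta[0] + 1.96 * se_a),
        rss=rss, n=n, converged=converged, iterations=int(total_nfev),
        message=best.message,
        extrapolated=bool(theta[0] > y.max() + y_span),
    )


@dataclass(frozen=True)
class PredictiveRange:
    """A fit's asymptote expressed on both scales."""

    asym_suvr: float
    ci_low_suvr: float
    ci_high_suvr: float
    asym_cl: float
    ci_low_cl: float
    ci_high_cl: float


def predictive_range(fit: AsymptoteFit, cmap: CentiloidMap | None = None) -> PredictiveRange:
    """Convert a converged fit's asymptote and CI to Centiloids."""
    if not fit.converged:
        raise ValueError(
            "asymptotic fit did not converge; inspect fit.message / fit.iterations "
            "before interpreting a predictive range"
        )
    cmap = cmap or default_centiloid_map()
    return PredictiveRange(
        fit.asym, fit.ci_low, fit.ci_high,
        float(cmap.to_centiloid(fit.asym)),
        float(cmap.to_centiloid(fit.ci_low)),
        float(cmap.to_centiloid(fit.ci_high)),
    )


def range_error_summary(
    fits: dict[str, AsymptoteFit],
    mapes: dict[str, float],
    cmap: CentiloidMap | None = None,
) -> pd.DataFrame:
    """Error-vs-range tradeoff table across biomarkers.

    One row per biomarker with its global MAPE and predictive range (CL, with
    CI), sorted by range (descending).  ``pareto`` flags biomarkers not
    dominated by any other (no competitor has both lower error and larger
    range); ``extrapolated`` marks asymptotes far beyond the span of the
    predictions, i.e. ceilings the cohort's range cannot pin down.
    """
    if set(fits) != set(mapes):
        raise ValueError("fits and mapes must cover the same biomarkers")
    cmap = cmap or default_centiloid_map()
    rows = []
    for name, fit in fits.items():
        pr = predictive_range(fit, cmap)
        rows.append({"biomarker": name, "mape_pct": float(mapes[name]),
                     "range_cl": pr.asym_cl, "ci_low_cl": pr.ci_low_cl,
                     "ci_high_cl": pr.ci_high_cl, "extrapolated": fit.extrapolated})
    df = pd.DataFrame(rows).sort_values("range_cl", ascending=False).reset_index(drop=True)
    pareto = []
    for _, r in df.iterrows():
        dominated = bool(np.any(
            (df["mape_pct"] < r["mape_pct"]) & (df["range_cl"] > r["range_cl"])
        ))
        pareto.append(not dominated)
    df["pareto"] = pareto
    return df
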