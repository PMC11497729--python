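"""Figure helpers: error-profile curves and the error-vs-range tradeoff plane."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402


def plot_error_profiles(profiles: dict, path=None, ax=None):
    """Sliding-window MAPE curves with CI bands, one line per analyte."""
    if ax is None:
        _fig, ax = plt.subplots(figsize=(7, 4.5))
    for name, p in profiles.items():
        ax.plot(p.window_centers, p.mape_point, label=name)
        ax.fill_between(p.window_centers, p.ci_low, p.ci_high, alpha=0.2)
    ax.set_xlabel(f"{profiles and next(iter(profiles.values())).axis_variable} amyloid burden (Centiloids)")
    ax.set_ylabel("MAPE (%)")
    ax.legend()
    ax.set_title("Forecast error across the amyloid range")
    if path is not None:
        ax.figure.savefig(path, bbox_inches="tight")
        plt.close(ax.figure)
    return ax


def plot_tradeoff(tradeoff, path=None, ax=None):
    """Predictive range (y, CL with CI) against global MAPE (x, %).

    The upper-left corner is best: low error, large predictive range.
    """
    if ax is None:
        _fig, ax = plt.subplots(figsize=(6, 4.5))
    yerr = [tradeoff["range_cl"] - tradeoff["ci_low_cl"],
            tradeoff["ci_high_cl"] - tradeoff["range_cl"]]
    ax.errorbar(tradeoff["mape_pct"], tradeoff["range_cl"], yerr=yerr, fmt="o")
    for _, r in tradeoff.iterrows():
        ax.annotate(r["biomarker"], (r["mape_pct"], r["range_cl"]),
                    textcoords="offset points", xytext=(5, 5), fontsize=8)
    ax.set_xlabel("global MAPE (%)")
    ax.set_ylabel("predictive range (Centiloids)")
    ax.set_title("Predictive range vs forecast error")
    if path is not None:
        ax.figure.savefig(path, bbox_inches="tight")
        plt.close(ax.figure)
    return ax
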