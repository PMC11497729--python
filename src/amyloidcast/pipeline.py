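"""End-to-end orchestration: simulate -> split -> tune -> train -> evaluate -> ceiling.

One cohort, one shared train/test split, one model per analyte, so that all
between-analyte comparisons are paired.  Stage seeds are derived from the
master seed by hashing ``(master_seed, analyte_name, stage_name)``, so adding
or removing an analyte never perturbs the results of the others.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .atlas import RegionSpec, default_atlas, read_atlas
from .ceiling import AsymptoteFit, fit_asymptotic, predictive_range, range_error_summary
from .cohort import (BiomarkerSpec, default_biomarker_specs, generate_cohort,
                     read_biomarker_specs, read_cohort, write_cohort)
from .evaluation import (ComparisonResult, ErrorProfile, compare_profiles, mape,
                         regional_mape, sliding_window_mape, spearman_ci)
from .network import (DEFAULT_GRID, NetworkConfig, build_network, grid_search,
                      train)
from .scale import default_centiloid_map, mean_cortical_suvr, split_cohort

__all__ = ["PipelineConfig", "AnalyteReport", "RunReport", "run_pipeline",
           "load_config", "read_cohort", "write_cohort"]


def derive_seed(master_seed: int, *tokens) -> int:
    """Deterministic stage seed from the master seed and a token path (< 2**31)."""
    key = "|".join([str(master_seed), *map(str, tokens)])
    digest = hashlib.sha256(key.encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31 - 1)


@dataclass
class PipelineConfig:
    """Everything a run needs; see the bundled demo config for a YAML example."""

    n: int = 346
    cohort_csv: str | None = None          # load instead of simulating when set
    biomarker_specs: list[BiomarkerSpec] = field(default_factory=default_biomarker_specs)
    analytes: list[str] | None = None      # default: every spec / every cohort analyte
    atlas: list[RegionSpec] = field(default_factory=default_atlas)
    master_seed: int = 0
    train_fraction: float = 0.8
    stratified_split: bool = False
    grid: list[NetworkConfig] = field(default_factory=lambda: list(DEFAULT_GRID))
    window_width: float = 25.0
    window_step: float = 1.0
    n_boot: int = 1000
    min_n: int = 10
    window_axis: str = "predicted"
    make_plots: bool = False

    @classmethod
    def from_dict(cls, d: dict, base_dir: Path | None = None) -> "PipelineConfig":
        d = dict(d)
        base = Path(base_dir) if base_dir else Path.cwd()
        if "biomarker_specs" in d:
            v = d["biomarker_specs"]
            d["biomarker_specs"] = (read_biomarker_specs(base / v) if isinstance(v, str)
                                    else [BiomarkerSpec(**s) for s in v])
        if isinstance(d.get("atlas"), str):
            d["atlas"] = read_atlas(base / d["atlas"])
        if "grid" in d:
            d["grid"] = [NetworkConfig(hidden_widths=tuple(g.get("hidden_widths", (64, 64, 32))),
                                       dropout_rate=g.get("dropout_rate", 0.1),
                                       learning_rate=g.get("learning_rate", 1e-3),
                                       epochs=g.get("epochs", 100),
                                       batch_size=g.get("batch_size", 32))
                         for g in d["grid"]]
        if d.get("cohort_csv"):
            d["cohort_csv"] = str(base / d["cohort_csv"])
        return cls(**d)


def load_config(path) -> PipelineConfig:
    """Load a pipeline config from YAML or JSON."""
    path = Path(path)
    doc = yaml.safe_load(path.read_text(encoding="utf-8"))
    if not isinstance(doc, dict):
        raise ValueError(f"config {path} must be a mapping")
    return PipelineConfig.from_dict(doc, base_dir=path.parent)


@dataclass
class AnalyteReport:
    """Per-analyte results: correlation, errors, error profile, ceiling."""

    analyte: str
    spearman_rho: float
    spearman_ci: tuple[float, float]
    global_mape: float
    low_range_mape: float                  # MAPE among test scans observed < 40 CL
    regional_mape: pd.Series
    profile: ErrorProfile
    asymptote: AsymptoteFit
    range_cl: float
    range_ci_cl: tuple[float, float]
    error: str | None = None

    def to_dict(self) -> dict:
        return {
            "analyte": self.analyte,
            "spearman_rho": self.spearman_rho,
            "spearman_ci": list(self.spearman_ci),
            "global_mape": self.global_mape,
            "low_range_mape": self.low_range_mape,
            "regional_mape": self.regional_mape.to_dict(),
            "profile": json.loads(self.profile.to_json()),
            "asymptote_suvr": self.asymptote.asym,
            "asymptote_converged": self.asymptote.converged,
            "asymptote_extrapolated": self.asymptote.extrapolated,
            "range_cl": self.range_cl,
            "range_ci_cl": list(self.range_ci_cl),
            "error": self.error,
        }


@dataclass
class RunReport:
    """Full-run results with provenance; regenerable bit-for-bit from config + seed."""

    analytes: dict[str, AnalyteReport]
    failures: dict[str, str]
    comparisons: dict[str, ComparisonResult]
    tradeoff: pd.DataFrame
    master_seed: int
    n: int
    partial: bool
    version: str = __version__

    def to_json(self) -> str:
        def _default(o):
            if isinstance(o, (np.bool_,)):
                return bool(o)
            if isinstance(o, np.integer):
                return int(o)
            if isinstance(o, np.floating):
                return float(o)
            raise TypeError(f"not JSON serializable: {type(o)}")

        return json.dumps({
            "version": self.version,
            "master_seed": self.master_seed,
            "n": self.n,
            "partial": self.partial,
            "failures": self.failures,
            "analytes": {k: v.to_dict() for k, v in self.analytes.items()},
            "comparisons": {
                k: {"a_better_ranges": v.a_better_ranges,
                    "b_better_ranges": v.b_better_ranges,
                    "crossover_cl": v.crossover_cl}
                for k, v in self.comparisons.items()
            },
            "tradeoff": self.tradeoff.to_dict(orient="records"),
        }, indent=1, sort_keys=True, default=_default)

    def to_markdown(self) -> str:
        lines = [
            "# amyloidcast run report",
            "",
            f"- cohort size: {self.n}",
            f"- master seed: {self.master_seed}",
            f"- package version: {self.version}",
            f"- partial: {self.partial}",
            "",
            "## Per-analyte summary",
            "",
            "| analyte | Spearman rho (95% CI) | global MAPE % | MAPE <40 CL % | predictive range CL (95% CI) |",
            "|---|---|---|---|---|",
        ]
        for name, r in self.analytes.items():
            flag = " *" if r.asymptote.extrapolated else ""
            lines.append(
                f"| {name} | {r.spearman_rho:.3f} ({r.spearman_ci[0]:.3f}, {r.spearman_ci[1]:.3f}) "
                f"| {r.global_mape:.1f} | {r.low_range_mape:.1f} "
                f"| {r.range_cl:.1f} ({r.range_ci_cl[0]:.1f}, {r.range_ci_cl[1]:.1f}){flag} |"
            )
        if any(r.asymptote.extrapolated for r in self.analytes.values()):
            lines.append("")
            lines.append("\* asymptote lies beyond the cohort's burden range "
                         "and is not identified by these data.")
        if self.failures:
            lines += ["", "## Failures", ""]
            lines += [f"- {k}: {v}" for k, v in self.failures.items()]
        lines += ["", "## Error/range tradeoff", "",
                  self.tradeoff.to_markdown(index=False)]
        return "\n".join(lines) + "\n"


def _evaluate_analyte(name, cohort, split, config: PipelineConfig, cmap,
                      id_index) -> AnalyteReport:
    x_all = cohort.analyte(name)
    Y_all = cohort.regional_suvr
    obs_mc_all = cohort.mean_cortical()
    tr = np.array([id_index[i] for i in split.train_ids])
    te = np.array([id_index[i] for i in split.test_ids])

    rho = spearman_ci(x_all, obs_mc_all, n_boot=config.n_boot,
                      seed=derive_seed(config.master_seed, name, "spearman"))

    best_cfg, _scores = grid_search(
        x_all[tr], Y_all[tr], config.grid,
        seed=derive_seed(config.master_seed, name, "grid"),
    )
    net = build_network(best_cfg, Y_all.shape[1])
    model = train(net, x_all[tr], Y_all[tr], best_cfg, input_analyte=name,
                  output_region_names=cohort.region_names,
                  split_meta={"train_fraction": config.train_fraction,
                              "split_seed": split.seed})

    pred_regional = model.predict(x_all[te], warn_extrapolation=False)
    actual_regional = Y_all[te]
    pred_mc = np.array([mean_cortical_suvr(r, cohort.region_atlas) for r in pred_regional])
    obs_mc = obs_mc_all[te]

    global_mape = mape(pred_mc, obs_mc)
    low = cmap.to_centiloid(obs_mc) < 40.0
    low_mape = mape(pred_mc[low], obs_mc[low]) if low.sum() >= 3 else float("nan")
    reg_mape = regional_mape(pred_regional, actual_regional, cohort.region_names)
    profile = sliding_window_mape(
        pred_mc, obs_mc, cmap, window_width=config.window_width,
        step=config.window_step, n_boot=config.n_boot, min_n=config.min_n,
        axis=config.window_axis,
        seed=derive_seed(config.master_seed, name, "window"),
        centers=np.arange(-10.0, 120.0 + config.window_step / 2, config.window_step),
    )
    # ceiling fitted on all participants' predictions: the plateau is carried
    # by the minority of high-amyloid scans, and the held-out fifth alone
    # leaves the asymptote unidentified at this cohort size
    pred_mc_all = np.array([
        mean_cortical_suvr(r, cohort.region_atlas)
        for r in model.predict(x_all, warn_extrapolation=False)
    ])
    fit = fit_asymptotic(obs_mc_all, pred_mc_all)
    pr = predictive_range(fit, cmap)
    return AnalyteReport(
        analyte=name, spearman_rho=rho.rho, spearman_ci=(rho.ci_low, rho.ci_high),
        global_mape=global_mape, low_range_mape=low_mape, regional_mape=reg_mape,
        profile=profile, asymptote=fit, range_cl=pr.asym_cl,
        range_ci_cl=(pr.ci_low_cl, pr.ci_high_cl),
    )


def run_pipeline(config: PipelineConfig, output_dir=None) -> RunReport:
    """Execute every stage for every analyte on a shared cohort split.

    Per-analyte failures are recorded and the run continues for the remaining
    analytes, marking the report partial.  With ``output_dir`` set, all
    artifacts (cohort CSV, split plan, per-analyte models and profiles, report
    JSON/Markdown, tradeoff CSV, optional plots) are written there.
    """
    cmap = default_centiloid_map()
    if config.cohort_csv:
        cohort = read_cohort(config.cohort_csv, config.atlas)
    else:
        cohort = generate_cohort(
            config.n, config.biomarker_specs, config.atlas,
            seed=derive_seed(config.master_seed, "cohort"),
        )
    analytes = config.analytes or cohort.biomarker_names
    id_index = {pid: i for i, pid in enumerate(cohort.participant_ids)}

    strata = None
    if config.stratified_split:
        from .scale import amyloid_status
        strata = [amyloid_status(v) for v in cohort.mean_cortical()]
    split = split_cohort(cohort.participant_ids, config.train_fraction,
                         seed=derive_seed(config.master_seed, "split"), strata=strata)

    reports: dict[str, AnalyteReport] = {}
    failures: dict[str, str] = {}
    for name in analytes:
        try:
            reports[name] = _evaluate_analyte(name, cohort, split, config, cmap, id_index)
        except Exception as exc:  # keep going for the other analytes
            failures[name] = f"{type(exc).__name__}: {exc}"

    comparisons = {
        f"{a}_vs_{b}": compare_profiles(reports[a].profile, reports[b].profile)
        for a, b in combinations(reports, 2)
    }
    tradeoff = (range_error_summary(
        {k: r.asymptote for k, r in reports.items() if r.asymptote.converged},
        {k: r.global_mape for k, r in reports.items() if r.asymptote.converged},
        cmap,
    ) if reports else pd.DataFrame())

    report = RunReport(reports, failures, comparisons, tradeoff,
                       config.master_seed, cohort.n, partial=bool(failures))

    if output_dir is not None:
        out = Path(output_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_cohort(cohort, out / "cohort.csv")
        (out / "split.json").write_text(split.to_json(), encoding="utf-8")
        for name, r in reports.items():
            r.profile.to_csv(out / f"profile_{name}.csv")
            r.regional_mape.to_csv(out / f"regional_mape_{name}.csv")
        if not tradeoff.empty:
            tradeoff.to_csv(out / "tradeoff.csv", index=False)
        (out / "report.json").write_text(report.to_json(), encoding="utf-8")
        (out / "report.md").write_text(report.to_markdown(), encoding="utf-8")
        if config.make_plots and reports:
            from .plotting import plot_error_profiles, plot_tradeoff
            plot_error_profiles({k: r.profile for k, r in reports.items()},
                                out / "error_profiles.svg")
            if not tradeoff.empty:
                plot_tradeoff(tradeoff, out / "tradeoff.svg")
    return report
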