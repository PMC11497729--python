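"""Synthetic cohort generator.

Emulates the statistical structure of an aging-cohort CSF + amyloid-PET
dataset: a latent amyloid burden per participant (Centiloids) drawn from a
three-stratum mixture (clearly negative < 10 CL, intermediate 10-30 CL,
elevated > 30 CL), CSF biomarkers that are monotone saturating functions of
the latent burden with biomarker-specific plateaus, and 37 regional PET SUVR
values that accumulate in a staged spatial order and share a participant-level
noise factor so the regional outputs are positively correlated.

The default biomarker presets encode the qualitative behaviour of three
analyte classes: a pT217/T217-like occupancy (steep, low-noise, mean response
flat beyond 63 CL), a pT231/T231-like occupancy (noisier, responsive through
87 CL) and an Abeta42/Abeta40-like ratio (decreasing, plateau near 85 CL).
These ceilings are simulation ground truth for recovery tests, not estimates.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml
from scipy.special import expit

from .atlas import RegionSpec, default_atlas

__all__ = [
    "BiomarkerSpec",
    "SyntheticCohort",
    "DEFAULT_MIXTURE_WEIGHTS",
    "default_biomarker_specs",
    "sample_latent_amyloid",
    "biomarker_response",
    "regional_suvr_profile",
    "generate_cohort",
    "read_biomarker_specs",
    "write_biomarker_specs",
    "read_cohort",
    "write_cohort",
]

#: Stratum proportions: <10 CL, 10-30 CL, >30 CL.
DEFAULT_MIXTURE_WEIGHTS: tuple[float, float, float] = (0.592, 0.11, 0.298)

_STRATUM_EDGES = (10.0, 30.0)  # Centiloid boundaries between strata
_POSITIVE_TAIL_MEAN = 35.0     # mean of the shifted-exponential positive tail
_LATENT_MAX = 120.0            # truncation of the positive tail
_SUVR_FLOOR = 0.5              # physical lower clamp on simulated SUVR


@dataclass(frozen=True)
class BiomarkerSpec:
    """Response curve of one CSF analyte to latent amyloid burden.

    The mean response is ``floor + direction * span * logistic(steepness *
    (min(latent, ceiling) - midpoint))``: a logistic rise (or fall, for
    direction -1 analytes like Abeta42/Abeta40) that is exactly flat beyond
    ``ceiling`` Centiloids.  Gaussian noise with SD ``noise_sd`` is added; with
    ``proportional_noise`` the SD scales with the mean response instead.
    """

    name: str
    floor: float
    span: float
    midpoint: float
    steepness: float
    ceiling: float
    noise_sd: float
    direction: int = 1
    proportional_noise: bool = False

    def __post_init__(self) -> None:
        if self.span <= 0:
            raise ValueError(f"{self.name}: span must be > 0")
        if self.steepness <= 0:
            raise ValueError(f"{self.name}: steepness must be > 0")
        if self.ceiling <= self.midpoint:
            raise ValueError(
                f"{self.name}: ceiling ({self.ceiling}) must exceed midpoint ({self.midpoint})"
            )
        if self.noise_sd < 0:
            raise ValueError(f"{self.name}: noise_sd must be >= 0")
        if self.direction not in (1, -1):
            raise ValueError(f"{self.name}: direction must be +1 or -1")

    def mean_response(self, latent):
        """Noise-free analyte value at the given latent burden (Centiloids)."""
        x = np.minimum(np.asarray(latent, dtype=float), self.ceiling)
        return self.floor + self.direction * self.span * expit(
            self.steepness * (x - self.midpoint)
        )


def default_biomarker_specs() -> list[BiomarkerSpec]:
    """The three bundled analyte presets (tau occupancies in %, ratio unitless)."""
    return [
        BiomarkerSpec("pT217_T217", floor=2.5, span=18.0, midpoint=30.0,
                      steepness=0.09, ceiling=63.0, noise_sd=0.35, direction=1),
        BiomarkerSpec("pT231_T231", floor=1.5, span=14.0, midpoint=60.0,
                      steepness=0.035, ceiling=87.0, noise_sd=0.9, direction=1),
        BiomarkerSpec("AB42_AB40", floor=0.095, span=0.05, midpoint=55.0,
                      steepness=0.03, ceiling=85.0, noise_sd=0.0035, direction=-1),
    ]


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def sample_latent_amyloid(
    n: int,
    mixture_weights: Sequence[float] = DEFAULT_MIXTURE_WEIGHTS,
    seed=None,
) -> np.ndarray:
    """Draw latent amyloid burdens (Centiloids) from the 3-stratum mixture.

    Strata: uniform(-5, 10) CL for the clearly-negative stratum, uniform(10,
    30) for intermediate, and 30 + Exp(mean 35) truncated at 120 CL for the
    elevated stratum (right-skewed positive tail).  Weights must sum to 1.
    """
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    w = np.asarray(mixture_weights, dtype=float)
    if w.shape != (3,) or np.any(w < 0):
        raise ValueError("mixture_weights must be 3 non-negative proportions")
    total = float(w.sum())
    if abs(total - 1.0) > 1e-9:
        raise ValueError(f"mixture_weights must sum to 1, got sum {total}")
    rng = _as_rng(seed)
    stratum = rng.choice(3, size=n, p=w)
    u = rng.random(n)
    out = np.empty(n)
    lo = stratum == 0
    mid = stratum == 1
    hi = stratum == 2
    out[lo] = -5.0 + 15.0 * u[lo]
    out[mid] = _STRATUM_EDGES[0] + (_STRATUM_EDGES[1] - _STRATUM_EDGES[0]) * u[mid]
    # inverse-CDF of an exponential truncated at (LATENT_MAX - 30)
    span = _LATENT_MAX - _STRATUM_EDGES[1]
    trunc_mass = 1.0 - np.exp(-span / _POSITIVE_TAIL_MEAN)
    out[hi] = _STRATUM_EDGES[1] - _POSITIVE_TAIL_MEAN * np.log1p(-u[hi] * trunc_mass)
    return out


def biomarker_response(latent, spec: BiomarkerSpec, seed=None) -> np.ndarray:
    """Noisy analyte value(s) for latent burden(s) under ``spec``."""
    rng = _as_rng(seed)
    mean = spec.mean_response(latent)
    if spec.noise_sd == 0:
        return mean
    sd = spec.noise_sd * np.abs(mean) if spec.proportional_noise else spec.noise_sd
    return mean + rng.normal(0.0, 1.0, size=np.shape(mean)) * sd


def _region_mean(latent, region: RegionSpec) -> np.ndarray:
    # steepness such that `rate` is the SUVR/CL slope at mid-rise
    k = 4.0 * region.rate / (region.max_suvr - 1.0)
    x = np.asarray(latent, dtype=float)
    return 1.0 + (region.max_suvr - 1.0) * expit(k * (x - region.onset_cl))


def regional_suvr_profile(
    latent,
    atlas: Sequence[RegionSpec] | None = None,
    shared_noise_sd: float = 0.06,
    region_noise_sd: float = 0.05,
    seed=None,
) -> np.ndarray:
    """Regional SUVR values for latent burden(s).

    Each region follows its logistic accumulation curve; a participant-level
    shared Gaussian term (same draw added to every region) induces positive
    inter-regional covariance, and independent per-region noise is added on
    top.  Returns shape ``(n_regions,)`` for scalar latent, else
    ``(n, n_regions)``.  Values are clamped at 0.5 SUVR.
    """
    atlas = list(atlas) if atlas is not None else default_atlas()
    if not atlas:
        raise ValueError("atlas must be non-empty")
    rng = _as_rng(seed)
    x = np.atleast_1d(np.asarray(latent, dtype=float))
    mat = np.column_stack([_region_mean(x, r) for r in atlas])
    if shared_noise_sd > 0:
        mat = mat + rng.normal(0.0, shared_noise_sd, size=(x.size, 1))
    if region_noise_sd > 0:
        mat = mat + rng.normal(0.0, region_noise_sd, size=mat.shape)
    mat = np.maximum(mat, _SUVR_FLOOR)
    return mat[0] if np.isscalar(latent) or np.ndim(latent) == 0 else mat


@dataclass
class SyntheticCohort:
    """A generated cohort: latent truth, analyte matrix and regional SUVR matrix."""

    participant_ids: list[str]
    latent_amyloid: np.ndarray
    biomarker_names: list[str]
    biomarker_values: np.ndarray   # participants x analytes
    regional_suvr: np.ndarray      # participants x regions
    region_atlas: list[RegionSpec]
    seed: int | None = None
    covariates: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        n = len(self.participant_ids)
        if self.latent_amyloid.shape != (n,):
            raise ValueError("latent_amyloid length does not match participants")
        if self.biomarker_values.shape != (n, len(self.biomarker_names)):
            raise ValueError("biomarker matrix shape inconsistent")
        if self.regional_suvr.shape != (n, len(self.region_atlas)):
            raise ValueError("regional matrix shape inconsistent")
        if not np.all(np.isfinite(self.regional_suvr)):
            raise ValueError("regional SUVR contains non-finite values")

    @property
    def n(self) -> int:
        return len(self.participant_ids)

    @property
    def region_names(self) -> list[str]:
        return [r.name for r in self.region_atlas]

    def analyte(self, name: str) -> np.ndarray:
        """Column of analyte values by name."""
        try:
            j = self.biomarker_names.index(name)
        except ValueError:
            raise KeyError(f"analyte {name!r} not in cohort ({self.biomarker_names})")
        return self.biomarker_values[:, j]

    def mean_cortical(self) -> np.ndarray:
        """Mean cortical SUVR per participant over the atlas summary regions."""
        idx = [i for i, r in enumerate(self.region_atlas) if r.is_summary_region]
        if not idx:
            raise ValueError("atlas flags no summary regions")
        return self.regional_suvr[:, idx].mean(axis=1)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"participant_id": self.participant_ids,
                           "latent_centiloid": self.latent_amyloid})
        for j, name in enumerate(self.biomarker_names):
            df[name] = self.biomarker_values[:, j]
        for j, r in enumerate(self.region_atlas):
            df[r.name] = self.regional_suvr[:, j]
        if self.covariates is not None:
            for c in self.covariates.columns:
                df[c] = np.asarray(self.covariates[c])
        return df


def generate_cohort(
    n: int,
    biomarker_specs: Sequence[BiomarkerSpec] | None = None,
    atlas: Sequence[RegionSpec] | None = None,
    mixture_weights: Sequence[float] = DEFAULT_MIXTURE_WEIGHTS,
    seed: int | None = None,
    shared_noise_sd: float = 0.06,
    region_noise_sd: float = 0.05,
) -> SyntheticCohort:
    """Generate a full synthetic cohort; byte-identical for identical inputs + seed."""
    if n < 1:
        raise ValueError(f"cohort size must be >= 1, got {n}")
    specs = list(biomarker_specs) if biomarker_specs is not None else default_biomarker_specs()
    if not specs:
        raise ValueError("need at least one biomarker spec")
    names = [s.name for s in specs]
    if len(set(names)) != len(names):
        raise ValueError(f"duplicate biomarker names: {names}")
    atlas = list(atlas) if atlas is not None else default_atlas()
    ss = np.random.SeedSequence(seed if seed is not None else None)
    child = ss.spawn(2 + len(specs))
    latent = sample_latent_amyloid(n, mixture_weights, np.random.default_rng(child[0]))
    bio = np.column_stack([
        biomarker_response(latent, s, np.random.default_rng(c))
        for s, c in zip(specs, child[1:-1])
    ])
    regional = regional_suvr_profile(
        latent, atlas, shared_noise_sd, region_noise_sd, np.random.default_rng(child[-1])
    )
    ids = [f"SYN{i:04d}" for i in range(1, n + 1)]
    return SyntheticCohort(ids, latent, names, bio, regional, atlas, seed=seed)


# ---------------------------------------------------------------------------
# serialization

def write_biomarker_specs(specs: Sequence[BiomarkerSpec], path) -> None:
    """Write biomarker specs to YAML (or JSON if the suffix is .json)."""
    docs = [s.__dict__.copy() for s in specs]
    path = Path(path)
    text = (json.dumps(docs, indent=2) if path.suffix == ".json"
            else yaml.safe_dump(docs, sort_keys=False))
    path.write_text(text, encoding="utf-8")


def read_biomarker_specs(path) -> list[BiomarkerSpec]:
    """Read biomarker specs from a YAML or JSON document."""
    text = Path(path).read_text(encoding="utf-8")
    docs = yaml.safe_load(text)
    return [BiomarkerSpec(**d) for d in docs]


def write_cohort(cohort: SyntheticCohort, path) -> None:
    """Write the cohort CSV (participant_id, latent_centiloid, analytes, regions)."""
    cohort.to_frame().to_csv(path, index=False)


def read_cohort(path, atlas: Sequence[RegionSpec] | None = None) -> SyntheticCohort:
    """Read a cohort CSV back into a :class:`SyntheticCohort`.

    Region columns are identified by the atlas names (all must be present);
    remaining numeric columns besides ``participant_id``/``latent_centiloid``
    are treated as analytes; non-numeric extras are kept as covariates.
    Numeric round trip through :func:`write_cohort` is exact to 1e-12.
    """
    atlas = list(atlas) if atlas is not None else default_atlas()
    df = pd.read_csv(path)
    if df.empty:
        raise ValueError(f"cohort file {path} has a header but no participants")
    if "participant_id" not in df.columns:
        raise ValueError("cohort CSV is missing required column 'participant_id'")
    region_names = [r.name for r in atlas]
    missing = [r for r in region_names if r not in df.columns]
    if missing:
        raise ValueError(f"cohort CSV is missing region columns: {missing}")
    regional = df[region_names]
    bad = regional.apply(pd.to_numeric, errors="coerce").isna()
    if bad.to_numpy().any():
        rows = sorted({int(i) + 2 for i in np.where(bad.to_numpy())[0]})  # 1-based incl. header
        raise ValueError(f"non-numeric regional SUVR cells at CSV rows {rows[:10]}")
    latent = (df["latent_centiloid"].to_numpy(dtype=float)
              if "latent_centiloid" in df.columns else np.full(len(df), np.nan))
    reserved = {"participant_id", "latent_centiloid", *region_names}
    extras = [c for c in df.columns if c not in reserved]
    analytes = [c for c in extras if pd.api.types.is_numeric_dtype(df[c])]
    covars = [c for c in extras if c not in analytes]
    return SyntheticCohort(
        participant_ids=[str(p) for p in df["participant_id"]],
        latent_amyloid=latent,
        biomarker_names=analytes,
        biomarker_values=df[analytes].to_numpy(dtype=float) if analytes else np.empty((len(df), 0)),
        regional_suvr=regional.to_numpy(dtype=float),
        region_atlas=atlas,
        covariates=df[covars] if covars else None,
    )
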