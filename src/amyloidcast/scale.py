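"""SUVR <-> Centiloid conversion, cortical summary measures, and cohort splitting.

The Centiloid scale is a harmonized amyloid-PET scale anchored so that young
amyloid-negative controls average 0 and typical Alzheimer-disease patients
average 100.  For a fixed tracer and processing pipeline the relation between
a mean cortical SUVR (cerebellar-cortex reference) and Centiloids is affine.
The default map used throughout this package is the exact affine fit through
the two published anchor points (1.42 SUVR, 16.4 CL) and (2.60 SUVR, 69.5 CL),
which gives slope 45.0 CL/SUVR and intercept -47.5 CL.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "CentiloidMap",
    "DEFAULT_ANCHORS",
    "POSITIVITY_THRESHOLD_SUVR",
    "SplitPlan",
    "amyloid_status",
    "centiloid_to_suvr",
    "default_centiloid_map",
    "fit_centiloid_map",
    "mean_cortical_suvr",
    "split_cohort",
    "suvr_to_centiloid",
]

#: Published (SUVR, Centiloid) anchor pairs for the PiB / cerebellar-cortex pipeline.
DEFAULT_ANCHORS: tuple[tuple[float, float], ...] = ((1.42, 16.4), (2.60, 69.5))

#: Mean cortical SUVR above which a scan is called amyloid positive (strictly greater).
POSITIVITY_THRESHOLD_SUVR: float = 1.42


@dataclass(frozen=True)
class CentiloidMap:
    """Affine SUVR -> Centiloid transform: ``CL = slope * SUVR + intercept``.

    Parameters
    ----------
    slope : float
        Centiloids per SUVR unit; must be strictly positive so the map is
        invertible and order preserving.
    intercept : float
        Centiloid value at SUVR 0.
    anchors : tuple of (SUVR, Centiloid) pairs
        The calibration points the map was fitted to (provenance only).
    """

    slope: float
    intercept: float
    anchors: tuple[tuple[float, float], ...] = ()

    def __post_init__(self) -> None:
        if not math.isfinite(self.slope) or not math.isfinite(self.intercept):
            raise ValueError("CentiloidMap parameters must be finite")
        if self.slope <= 0:
            raise ValueError(f"CentiloidMap slope must be > 0, got {self.slope}")

    def to_centiloid(self, suvr):
        return self.slope * np.asarray(suvr, dtype=float) + self.intercept

    def to_suvr(self, centiloid):
        return (np.asarray(centiloid, dtype=float) - self.intercept) / self.slope

    def to_json(self) -> str:
        return json.dumps(
            {"slope": self.slope, "intercept": self.intercept,
             "anchors": [list(a) for a in self.anchors]}
        )

    @classmethod
    def from_json(cls, text: str) -> "CentiloidMap":
        d = json.loads(text)
        return cls(d["slope"], d["intercept"],
                   tuple(tuple(a) for a in d.get("anchors", [])))


def fit_centiloid_map(anchor_pairs: Sequence[tuple[float, float]]) -> CentiloidMap:
    """Least-squares affine fit of Centiloids on SUVR through anchor pairs.

    With exactly two anchors the fit interpolates them exactly.  Raises
    ``ValueError`` if fewer than two pairs are given or all SUVR values
    coincide (singular fit).
    """
    pairs = [(float(s), float(c)) for s, c in anchor_pairs]
    if len(pairs) < 2:
        raise ValueError("need at least 2 anchor pairs to fit a CentiloidMap")
    suvr = np.array([p[0] for p in pairs])
    cl = np.array([p[1] for p in pairs])
    if np.ptp(suvr) == 0:
        raise ValueError(
            f"anchor SUVR values are all {suvr[0]}: affine fit is singular"
        )
    slope, intercept = np.polyfit(suvr, cl, 1)
    return CentiloidMap(float(slope), float(intercept), tuple(pairs))


def default_centiloid_map() -> CentiloidMap:
    """The affine map through the two published anchors (slope 45, intercept -47.5)."""
    return fit_centiloid_map(DEFAULT_ANCHORS)


def suvr_to_centiloid(suvr, cmap: CentiloidMap | None = None):
    """Convert SUVR value(s) to Centiloids under ``cmap`` (default map if None)."""
    cmap = cmap or default_centiloid_map()
    return cmap.to_centiloid(suvr)


def centiloid_to_suvr(centiloid, cmap: CentiloidMap | None = None):
    """Convert Centiloid value(s) to SUVR; exact inverse of :func:`suvr_to_centiloid`."""
    cmap = cmap or default_centiloid_map()
    return cmap.to_suvr(centiloid)


def mean_cortical_suvr(regional_row, atlas) -> float:
    """Arithmetic mean SUVR over the atlas's cortical summary regions.

    ``regional_row`` may be a mapping / pandas Series keyed by region name, or
    a 1-D array ordered like ``atlas``.  Only regions flagged
    ``is_summary_region`` enter the mean; a missing flagged region raises
    ``KeyError`` naming it.
    """
    summary = [r for r in atlas if r.is_summary_region]
    if not summary:
        raise ValueError("atlas flags no summary regions")
    if hasattr(regional_row, "keys"):  # mapping or pandas Series
        values = []
        for r in summary:
            try:
                values.append(float(regional_row[r.name]))
            except (KeyError, IndexError):
                raise KeyError(f"summary region {r.name!r} missing from regional row")
        return float(np.mean(values))
    row = np.asarray(regional_row, dtype=float)
    if row.shape[-1] != len(atlas):
        raise ValueError(
            f"regional row has {row.shape[-1]} values but atlas has {len(atlas)} regions"
        )
    idx = [i for i, r in enumerate(atlas) if r.is_summary_region]
    return float(np.mean(row[..., idx], axis=-1))


def amyloid_status(mean_cortical: float, threshold_suvr: float = POSITIVITY_THRESHOLD_SUVR) -> bool:
    """True (positive) iff mean cortical SUVR is strictly greater than the threshold."""
    x = float(mean_cortical)
    if not math.isfinite(x):
        raise ValueError("mean cortical SUVR must be finite")
    return x > threshold_suvr


@dataclass(frozen=True)
class SplitPlan:
    """A train/test partition of participant ids."""

    train_ids: tuple
    test_ids: tuple
    train_fraction: float
    seed: int | None
    stratified: bool = False

    def __post_init__(self) -> None:
        overlap = set(self.train_ids) & set(self.test_ids)
        if overlap:
            raise ValueError(f"train/test overlap: {sorted(overlap)[:5]}")

    @property
    def n(self) -> int:
        return len(self.train_ids) + len(self.test_ids)

    def to_json(self) -> str:
        return json.dumps(
            {"train_ids": list(self.train_ids), "test_ids": list(self.test_ids),
             "train_fraction": self.train_fraction, "seed": self.seed,
             "stratified": self.stratified}
        )

    @classmethod
    def from_json(cls, text: str) -> "SplitPlan":
        d = json.loads(text)
        return cls(tuple(d["train_ids"]), tuple(d["test_ids"]),
                   d["train_fraction"], d["seed"], d["stratified"])


def _train_count(n: int, fraction: float) -> int:
    # round half toward more training data
    return int(math.floor(fraction * n + 0.5))


def split_cohort(
    ids: Sequence,
    train_fraction: float = 0.8,
    seed: int | None = None,
    strata: Sequence | None = None,
) -> SplitPlan:
    """Random train/test partition of participant ids.

    ``train_fraction`` must lie strictly in (0, 1); the train count is
    ``round(train_fraction * n)`` with ties resolved toward more training
    data (346 participants at 0.8 give 277 train / 69 test).  When ``strata``
    is given (one label per id, e.g. amyloid status) the split is performed
    within each stratum so the class proportions match within one participant
    per stratum.
    """
    ids = list(ids)
    n = len(ids)
    if n < 5:
        raise ValueError(f"need at least 5 participants to split, got {n}")
    if not (0.0 < train_fraction < 1.0):
        raise ValueError(f"train_fraction must be in (0, 1), got {train_fraction}")
    rng = np.random.default_rng(seed)
    stratified = strata is not None
    if stratified:
        if len(strata) != n:
            raise ValueError("strata must have one label per id")
        train: list = []
        test: list = []
        for label in sorted(set(strata), key=repr):
            members = [i for i, s in zip(ids, strata) if s == label]
            k = _train_count(len(members), train_fraction)
            perm = rng.permutation(len(members))
            train.extend(members[i] for i in perm[:k])
            test.extend(members[i] for i in perm[k:])
    else:
        k = _train_count(n, train_fraction)
        perm = rng.permutation(n)
        train = [ids[i] for i in perm[:k]]
        test = [ids[i] for i in perm[k:]]
    return SplitPlan(tuple(train), tuple(test), train_fraction, seed, stratified)
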