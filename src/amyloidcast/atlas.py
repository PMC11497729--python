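"""Regional atlas used for the 37 bilateral amyloid-PET output regions.

The default atlas carries the 34 Desikan-Killiany cortical labels
(bilateral-averaged) plus three composite labels (gyrus rectus, lateral
temporal, prefrontal composite) for a total of 37 regions.  Seven regions form
the mean-cortical summary composite: precuneus, superior frontal, rostral
middle frontal, lateral and medial orbitofrontal, and superior and middle
temporal.

Each region carries parameters for the synthetic cohort generator: the
Centiloid level at which its accumulation curve is at mid-rise (``onset_cl``),
the accumulation rate at mid-rise (SUVR per Centiloid), and its SUVR plateau.
Onsets follow the staged spatial ordering of amyloid deposition — gyrus rectus
and lateral temporal cortex accumulate early, precuneus and prefrontal cortex
late — with the tiers spread over roughly 15-100 CL so that the 7-region
summary measure stays sensitive across the whole Centiloid range the analysis
studies.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

__all__ = ["RegionSpec", "default_atlas", "read_atlas", "write_atlas", "summary_region_names"]


@dataclass(frozen=True)
class RegionSpec:
    """One bilateral cortical region of the output parcellation.

    ``onset_cl`` is the latent amyloid level (Centiloids) at the midpoint of
    the region's accumulation curve, ``rate`` the accumulation slope there in
    SUVR per Centiloid, and ``max_suvr`` the plateau the region saturates at
    (reference-region-normalized baseline is ~1.0).
    """

    name: str
    onset_cl: float
    rate: float
    max_suvr: float
    is_summary_region: bool = False

    def __post_init__(self) -> None:
        if self.onset_cl < 0:
            raise ValueError(f"{self.name}: onset_cl must be >= 0, got {self.onset_cl}")
        if self.rate <= 0:
            raise ValueError(f"{self.name}: rate must be > 0, got {self.rate}")
        if self.max_suvr <= 1.0:
            raise ValueError(f"{self.name}: max_suvr must exceed 1.0, got {self.max_suvr}")


def _r(name, onset, max_suvr, summary=False) -> RegionSpec:
    # rate chosen so the logistic steepness 4*rate/(max_suvr-1) is ~0.09/CL,
    # i.e. a rise width of ~45 CL per region
    return RegionSpec(name, onset, round(0.0225 * (max_suvr - 1.0), 4), max_suvr, summary)


_DEFAULT_REGIONS: tuple[RegionSpec, ...] = (
    # --- early tier: medial/ventral frontal and lateral temporal cortex ---
    _r("gyrus_rectus", 15.0, 3.4),
    _r("lateral_temporal", 20.0, 3.5),
    _r("superior_temporal", 25.0, 3.8, summary=True),
    _r("bankssts", 28.0, 3.2),
    _r("inferior_temporal", 30.0, 3.3),
    _r("fusiform", 33.0, 3.1),
    _r("temporal_pole", 35.0, 3.0),
    _r("entorhinal", 36.0, 2.9),
    _r("middle_temporal", 38.0, 3.8, summary=True),
    _r("parahippocampal", 42.0, 2.9),
    # --- middle tier: cingulate, insula, parietal association cortex ---
    _r("insula", 45.0, 3.1),
    _r("rostral_anterior_cingulate", 47.0, 3.4),
    _r("lateral_orbitofrontal", 50.0, 3.8, summary=True),
    _r("caudal_anterior_cingulate", 52.0, 3.3),
    _r("posterior_cingulate", 54.0, 3.4),
    _r("isthmus_cingulate", 56.0, 3.2),
    _r("inferior_parietal", 58.0, 3.4),
    _r("supramarginal", 60.0, 3.2),
    _r("medial_orbitofrontal", 62.0, 3.8, summary=True),
    _r("superior_parietal", 64.0, 3.1),
    _r("pars_opercularis", 66.0, 3.2),
    _r("pars_triangularis", 68.0, 3.2),
    # --- late tier: prefrontal, precuneus, occipital, sensorimotor cortex ---
    _r("pars_orbitalis", 70.0, 3.3),
    _r("frontal_pole", 72.0, 3.4),
    _r("caudal_middle_frontal", 74.0, 3.3),
    _r("prefrontal_composite", 76.0, 3.4),
    _r("precuneus", 78.0, 3.8, summary=True),
    _r("lingual", 80.0, 3.0),
    _r("lateral_occipital", 84.0, 3.0),
    _r("cuneus", 88.0, 2.9),
    _r("transverse_temporal", 90.0, 3.1),
    _r("postcentral", 92.0, 2.9),
    _r("superior_frontal", 95.0, 3.8, summary=True),
    _r("precentral", 98.0, 2.9),
    _r("paracentral", 102.0, 2.9),
    _r("pericalcarine", 106.0, 2.9),
    _r("rostral_middle_frontal", 110.0, 3.8, summary=True),
)

assert len(_DEFAULT_REGIONS) == 37
assert sum(r.is_summary_region for r in _DEFAULT_REGIONS) == 7


def default_atlas() -> list[RegionSpec]:
    """The default 37-region atlas (fresh list; specs are frozen)."""
    return list(_DEFAULT_REGIONS)


def summary_region_names(atlas: Iterable[RegionSpec]) -> list[str]:
    return [r.name for r in atlas if r.is_summary_region]


def write_atlas(atlas: Iterable[RegionSpec], path) -> None:
    """Write an atlas CSV with columns region_name, onset_cl, rate, max_suvr, is_summary_region."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(["region_name", "onset_cl", "rate", "max_suvr", "is_summary_region"])
        for r in atlas:
            w.writerow([r.name, r.onset_cl, r.rate, r.max_suvr, int(r.is_summary_region)])


def read_atlas(path) -> list[RegionSpec]:
    """Read an atlas CSV written by :func:`write_atlas`."""
    path = Path(path)
    regions: list[RegionSpec] = []
    with open(path, newline="", encoding="utf-8") as fh:
        for row in csv.DictReader(fh):
            regions.append(
                RegionSpec(
                    row["region_name"],
                    float(row["onset_cl"]),
                    float(row["rate"]),
                    float(row["max_suvr"]),
                    bool(int(row["is_summary_region"])),
                )
            )
    if not regions:
        raise ValueError(f"atlas file {path} contains no regions")
    return regions
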