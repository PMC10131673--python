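"""PASI domain types and score arithmetic.

The Psoriasis Area and Severity Index (PASI) summarises psoriasis severity
as a weighted sum over four body regions.  For each region r a clinician
assigns an area band A_r in {0..6} (the fraction of the region's skin that
is involved, binned) and three ordinal severities in {0..4}: erythema E_r
(redness), induration I_r (plaque thickness) and desquamation D_r
(scaling).  The total score is

    PASI = sum_r  w_r * A_r * (E_r + I_r + D_r),

with region weights w_head=0.1, w_trunk=0.3, w_upper=0.2, w_lower=0.4,
giving a range of 0-72.  Severity bands used for stratified reporting are
low (PASI <= 5), medium (5 < PASI <= 10) and high (PASI > 10).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

__all__ = [
    "Region",
    "RegionAssessment",
    "RegionWeights",
    "VisitAssessment",
    "DEFAULT_WEIGHTS",
    "area_percent_to_band",
    "compose_pasi",
    "severity_band",
    "round_half_away",
    "read_visits_csv",
    "write_visits_csv",
    "visits_to_frame",
]


class PasiDomainError(ValueError):
    """A value lies outside the PASI score domain."""


class PasiStructureError(ValueError):
    """A visit is structurally invalid (missing/duplicate region)."""


class Region(str, enum.Enum):
    HEAD = "head"
    TRUNK = "trunk"
    UPPER_LIMB = "upper_limb"
    LOWER_LIMB = "lower_limb"

    def __str__(self) -> str:  # so CSV cells read naturally
        return self.value


#: Standard PASI region weights; they sum to 1.
DEFAULT_WEIGHTS: Mapping[Region, float] = {
    Region.HEAD: 0.1,
    Region.TRUNK: 0.3,
    Region.UPPER_LIMB: 0.2,
    Region.LOWER_LIMB: 0.4,
}

#: Label counts for the subscore classification formulation.
N_AREA_LABELS = 7
N_SEVERITY_LABELS = 5

SUBSCORE_NAMES = ("area_band", "erythema", "induration", "desquamation")


@dataclass(frozen=True)
class RegionWeights:
    """Per-region weights of the PASI composition; must sum to 1."""

    head: float = 0.1
    trunk: float = 0.3
    upper_limb: float = 0.2
    lower_limb: float = 0.4

    def __post_init__(self) -> None:
        total = self.head + self.trunk + self.upper_limb + self.lower_limb
        if abs(total - 1.0) > 1e-9:
            raise PasiDomainError(f"region weights must sum to 1, got {total}")

    def __getitem__(self, region: Region) -> float:
        return getattr(self, Region(region).value)


@dataclass(frozen=True)
class RegionAssessment:
    """The four PASI subscores for one body region."""

    region: Region
    area_band: int
    erythema: int
    induration: int
    desquamation: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "region", Region(self.region))
        if not 0 <= self.area_band <= 6:
            raise PasiDomainError(f"area_band must be in 0..6, got {self.area_band}")
        for name in ("erythema", "induration", "desquamation"):
            v = getattr(self, name)
            if not 0 <= v <= 4:
                raise PasiDomainError(f"{name} must be in 0..4, got {v}")

    @property
    def severity_sum(self) -> int:
        """E + I + D for this region."""
        return self.erythema + self.induration + self.desquamation

    def as_tuple(self) -> tuple[int, int, int, int]:
        return (self.area_band, self.erythema, self.induration, self.desquamation)


def round_half_away(x: float, decimals: int = 1) -> float:
    """Round with ties going away from zero (0.05 -> 0.1, -0.05 -> -0.1).

    Python's built-in ``round`` is banker's rounding; clinical score tables
    round half away from zero, so that rule is used everywhere a score is
    reported.
    """
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def area_percent_to_band(percent: float) -> int:
    """Bin a percentage of involved skin area into the PASI area band 0-6.

    Bands: 0% -> 0; (0,10)% -> 1; [10,30)% -> 2; [30,50)% -> 3;
    [50,70)% -> 4; [70,90)% -> 5; [90,100]% -> 6.
    """
    if not 0.0 <= percent <= 100.0:
        raise PasiDomainError(f"percent must be in [0, 100], got {percent}")
    if percent == 0.0:
        return 0
    for band, upper in ((1, 10.0), (2, 30.0), (3, 50.0), (4, 70.0), (5, 90.0)):
        if percent < upper:
            return band
    return 6


def compose_pasi(
    regions: Iterable[RegionAssessment],
    weights: RegionWeights | Mapping[Region, float] | None = None,
) -> float:
    """Compose the total PASI from exactly one assessment per body region.

    Returns ``sum_r w_r * A_r * (E_r + I_r + D_r)`` rounded half away from
    zero to one decimal.  The arithmetic is done in exact decimal so that
    e.g. 0.4 * 3 * 10 contributes exactly 12.0.
    """
    if weights is None:
        weights = RegionWeights()
    regions = list(regions)
    seen = [a.region for a in regions]
    if sorted(r.value for r in seen) != sorted(r.value for r in Region):
        raise PasiStructureError(
            f"need exactly one assessment per region, got {[str(r) for r in seen]}"
        )
    total = Decimal(0)
    for a in regions:
        w = weights[a.region] if not isinstance(weights, RegionWeights) else weights[a.region]
        total += Decimal(repr(w)) * a.area_band * a.severity_sum
    return float(total.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def severity_band(pasi: float) -> str:
    """Severity stratum of a total PASI: low (<=5), medium (5,10], high (>10)."""
    if not 0.0 <= pasi <= 72.0:
        raise PasiDomainError(f"pasi must be in [0, 72], got {pasi}")
    if pasi <= 5.0:
        return "low"
    if pasi <= 10.0:
        return "medium"
    return "high"


@dataclass
class VisitAssessment:
    """Four region assessments plus the composed total PASI for one visit."""

    patient_id: str
    visit_id: str
    regions: list[RegionAssessment]
    pasi: float = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        composed = compose_pasi(self.regions)
        if self.pasi is None:
            self.pasi = composed
        elif abs(self.pasi - composed) > 1e-9:
            raise PasiDomainError(
                f"stored pasi {self.pasi} disagrees with composed {composed} "
                f"for visit {self.patient_id}/{self.visit_id}"
            )

    def region(self, region: Region) -> RegionAssessment:
        region = Region(region)
        for a in self.regions:
            if a.region is region:
                return a
        raise PasiStructureError(f"region {region} missing")

    @property
    def severity(self) -> str:
        return severity_band(self.pasi)


VISIT_CSV_COLUMNS = [
    "patient_id",
    "visit_id",
    "region",
    "area_band",
    "erythema",
    "induration",
    "desquamation",
]


def visits_to_frame(visits: Iterable[VisitAssessment], include_pasi: bool = True) -> pd.DataFrame:
    rows = []
    for v in visits:
        for a in v.regions:
            row = {
                "patient_id": v.patient_id,
                "visit_id": v.visit_id,
                "region": a.region.value,
                "area_band": a.area_band,
                "erythema": a.erythema,
                "induration": a.induration,
                "desquamation": a.desquamation,
            }
            if include_pasi:
                row["pasi"] = v.pasi
            rows.append(row)
    cols = VISIT_CSV_COLUMNS + (["pasi"] if include_pasi else [])
    return pd.DataFrame(rows, columns=cols)


def read_visits_csv(path: str | Path) -> list[VisitAssessment]:
    """Read the long-format visit table (one row per region) into visits.

    Schema violations are reported with 1-based data row numbers so a bad
    cell can be found in a spreadsheet.
    """
    df = pd.read_csv(path)
    missing = [c for c in VISIT_CSV_COLUMNS if c not in df.columns]
    if missing:
        raise PasiStructureError(f"{path}: missing columns {missing}")
    visits: list[VisitAssessment] = []
    for (pid, vid), group in df.groupby(["patient_id", "visit_id"], sort=False):
        regions = []
        for idx, row in group.iterrows():
            try:
                regions.append(
                    RegionAssessment(
                        region=Region(row["region"]),
                        area_band=int(row["area_band"]),
                        erythema=int(row["erythema"]),
                        induration=int(row["induration"]),
                        desquamation=int(row["desquamation"]),
                    )
                )
            except ValueError as exc:
                raise PasiDomainError(f"{path}: row {idx + 1}: {exc}") from exc
        try:
            visits.append(VisitAssessment(patient_id=str(pid), visit_id=str(vid), regions=regions))
        except ValueError as exc:
            raise PasiStructureError(f"{path}: visit {pid}/{vid}: {exc}") from exc
    return visits


def write_visits_csv(visits: Iterable[VisitAssessment], path: str | Path) -> None:
    """Write visits with their composed ``pasi`` column."""
    visits_to_frame(visits, include_pasi=True).to_csv(path, index=False)
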