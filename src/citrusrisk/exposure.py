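"""Deterministic dietary exposure: chronic NEDI/HQc and acute IESTI/HQa.

Chronic exposure follows the national-estimated-daily-intake model

    NEDI = STMR * Fi / bw        (mg/kg bw/day)
    HQc  = NEDI / ADI,  %ADI = 100 * HQc

where STMR is the residue value used for the intake (per-sample: that
sample's own concentration; survey-level: the median over detected samples),
Fi the mean daily consumption of the commodity and bw body weight.

Acute exposure uses the case-based international estimate of short-term
intake (IESTI), selected by the edible unit weight Ue against the 25 g
threshold and the large portion LP:

    case 1  (Ue < 25 g):       IESTI = LP * HR / bw
    case 2a (25 g <= Ue < LP): IESTI = (Ue * HR * v + (LP - Ue) * HR) / bw
    case 2b (Ue >= LP):        IESTI = Ue * HR * v / bw

with HR the highest residue and v the between-individual variability factor
(default 3). HQa = IESTI / ARfD. Cumulative risk per sample is the hazard
index HI = sum of HQs over the pesticides detected in that sample; HI > 1
flags a sample as potentially unacceptable for consumption.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import pandas as pd

from .core_data import Percentage, ReferenceSet, ResidueTable
from .errors import ReferenceLookupError, ValidationError

#: Ue threshold (kg) separating IESTI case 1 from the case-2 family
UNIT_WEIGHT_THRESHOLD_KG = 0.025


@dataclass(frozen=True)
class PopulationProfile:
    """Consumption parameters for one population group.

    bw: body weight (kg); fi: mean daily commodity consumption (kg/day);
    lp: large portion, the 97.5th-percentile single-day consumption (kg);
    v: between-individual variability factor (dimensionless, default 3).
    """

    group: str
    bw: float
    fi: float
    lp: float
    v: float = 3.0

    def __post_init__(self) -> None:
        if min(self.bw, self.fi, self.lp, self.v) <= 0:
            raise ValidationError(f"profile {self.group!r}: all parameters must be positive")


@dataclass(frozen=True)
class CommodityUnit:
    """Edible-portion weight (kg) of one unit of a commodity."""

    commodity: str
    ue: float

    def __post_init__(self) -> None:
        if self.ue <= 0:
            raise ValidationError(f"unit weight for {self.commodity!r} must be positive")


# Default profiles: body weights are conventional adult/child reference
# values; fi and lp are plausible placeholders for a citrus-eating
# population and must be replaced with survey-specific values for any real
# assessment (see docs/methods.md).
DEFAULT_PROFILES: tuple[PopulationProfile, ...] = (
    PopulationProfile(group="adults", bw=70.0, fi=0.04, lp=0.30, v=3.0),
    PopulationProfile(group="children", bw=20.0, fi=0.03, lp=0.20, v=3.0),
)

DEFAULT_UNITS: tuple[CommodityUnit, ...] = (
    CommodityUnit("orange", 0.14),
    CommodityUnit("lemon", 0.06),
    CommodityUnit("tangerine", 0.07),
    CommodityUnit("grapefruit", 0.26),
)


def nedi(stmr: float, profile: PopulationProfile) -> float:
    """National estimated daily intake: STMR × Fi / bw (mg/kg bw/day)."""
    if stmr < 0:
        raise ValidationError("residue value must be >= 0")
    return stmr * profile.fi / profile.bw


def chronic_hq(nedi_value: float, adi: float) -> tuple[float, float]:
    """Chronic hazard quotient and %ADI: (NEDI/ADI, 100×NEDI/ADI)."""
    if adi <= 0:
        raise ValidationError("ADI must be positive")
    hq = nedi_value / adi
    return hq, 100.0 * hq


@dataclass(frozen=True)
class AcuteIntake:
    """IESTI value with the case that produced it."""

    iesti: float  # mg/kg bw/day
    case_used: str  # "1" | "2a" | "2b"


def iesti(hr: float, unit: CommodityUnit, profile: PopulationProfile) -> AcuteIntake:
    """Case-based short-term intake for the highest residue *hr* (mg/kg).

    The case is selected by the edible unit weight: below 25 g a single
    portion mixes many units (case 1); between 25 g and the large portion
    one unit at the variability factor dominates (case 2a); a unit at least
    as large as the portion is eaten alone (case 2b, the ue = lp boundary is
    value-neutral by continuity).
    """
    if hr < 0:
        raise ValidationError("highest residue must be >= 0")
    ue, lp, v, bw = unit.ue, profile.lp, profile.v, profile.bw
    if ue < UNIT_WEIGHT_THRESHOLD_KG:
        return AcuteIntake(lp * hr / bw, "1")
    if ue < lp:
        return AcuteIntake((ue * hr * v + (lp - ue) * hr) / bw, "2a")
    return AcuteIntake(ue * hr * v / bw, "2b")


def acute_hq(iesti_value: float, arfd: Optional[float]) -> tuple[Optional[float], Optional[float]]:
    """Acute hazard quotient and %ARfD; ``(None, None)`` when no ARfD is set."""
    if arfd is None:
        return None, None
    if arfd <= 0:
        raise ValidationError("ARfD must be positive")
    hq = iesti_value / arfd
    return hq, 100.0 * hq


@dataclass(frozen=True)
class HazardIndex:
    """Cumulative hazard for one sample: HI = Σ HQ with per-pesticide shares."""

    sample_id: str
    group: str
    kind: str  # "chronic" | "acute"
    hi: float
    contributions: Mapping[str, float] = field(default_factory=dict)


def hazard_index(
    hqs: Mapping[str, float], sample_id: str = "", group: str = "", kind: str = ""
) -> HazardIndex:
    """Sum per-pesticide hazard quotients into an HI with contribution shares."""
    if any(v < 0 for v in hqs.values()):
        raise ValidationError("hazard quotients must be >= 0")
    hi = float(sum(hqs.values()))
    contributions = {k: v / hi for k, v in hqs.items()} if hi > 0 else {}
    return HazardIndex(sample_id=sample_id, group=group, kind=kind, hi=hi, contributions=contributions)


@dataclass(frozen=True)
class SurveyAssessment:
    """Per-sample hazard indices for every population group plus exceedance rates."""

    per_sample: pd.DataFrame  # sample_id, group, kind, hi, top_contributor, n_skipped
    exceedance: Mapping[tuple[str, str], Percentage]  # (group, kind) -> share HI > 1
    per_pesticide: pd.DataFrame  # survey-level chronic/acute exposure per pesticide

    def hi_frame(self, group: str, kind: str) -> pd.Series:
        sel = self.per_sample
        sel = sel[(sel["group"] == group) & (sel["kind"] == kind)]
        return sel.set_index("sample_id")["hi"]


def _unit_lookup(units: Sequence[CommodityUnit]) -> dict[str, CommodityUnit]:
    return {u.commodity: u for u in units}


def survey_exposure(
    table: ResidueTable,
    refs: ReferenceSet,
    profile: PopulationProfile,
    units: Sequence[CommodityUnit] = DEFAULT_UNITS,
) -> pd.DataFrame:
    """Survey-level per-pesticide exposure: STMR = median of detected residues,
    HR = maximum (worst case). One row per detected pesticide with NEDI, HQc,
    %ADI, IESTI (case recorded), HQa, %ARfD."""
    by_unit = _unit_lookup(units)
    rows = []
    det = table.detections
    for name, grp in det.groupby("pesticide", sort=True):
        info = refs.get(name)
        stmr = float(grp["concentration"].median())
        hr_idx = grp["concentration"].idxmax()
        hr = float(grp.loc[hr_idx, "concentration"])
        hr_commodity = str(grp.loc[hr_idx, "commodity"])
        nedi_v = nedi(stmr, profile)
        hq_c, pct_adi = chronic_hq(nedi_v, info.adi)
        intake = iesti(hr, by_unit[hr_commodity], profile)
        hq_a, pct_arfd = acute_hq(intake.iesti, info.arfd)
        rows.append(
            {
                "pesticide": name,
                "group": profile.group,
                "stmr": stmr,
                "nedi": nedi_v,
                "hq_c": hq_c,
                "pct_adi": pct_adi,
                "hr": hr,
                "case_used": intake.case_used,
                "iesti": intake.iesti,
                "hq_a": hq_a,
                "pct_arfd": pct_arfd,
            }
        )
    return pd.DataFrame(rows)


def assess_survey(
    table: ResidueTable,
    refs: ReferenceSet,
    profiles: Sequence[PopulationProfile] = DEFAULT_PROFILES,
    units: Sequence[CommodityUnit] = DEFAULT_UNITS,
    policy: str = "strict",
) -> SurveyAssessment:
    """Per-sample chronic and acute hazard indices for each population group.

    Chronic HQs use each sample's own measured concentration as the residue
    value; acute HQs use the sample's concentration as the HR with the
    case-based IESTI. Pesticides with no ARfD are skipped in the acute sum
    (counted in ``n_skipped``). ``policy="lenient"`` downgrades missing
    reference entries to warnings.
    """
    by_unit = _unit_lookup(units)
    det = table.detections
    rows = []
    for profile in profiles:
        for sample_id, commodity in table.samples.items():
            sample_det = det[det["sample_id"] == sample_id]
            hq_chronic: dict[str, float] = {}
            hq_acute: dict[str, float] = {}
            n_skipped = 0
            for _, row in sample_det.iterrows():
                try:
                    info = refs.get(row["pesticide"])
                except ReferenceLookupError:
                    if policy == "strict":
                        raise
                    warnings.warn(
                        f"no reference entry for {row['pesticide']!r}; skipped", stacklevel=2
                    )
                    n_skipped += 1
                    continue
                conc = float(row["concentration"])
                hq_c, _ = chronic_hq(nedi(conc, profile), info.adi)
                hq_chronic[info.pesticide] = hq_c
                intake = iesti(conc, by_unit[str(row["commodity"])], profile)
                hq_a, _ = acute_hq(intake.iesti, info.arfd)
                if hq_a is None:
                    n_skipped += 1
                else:
                    hq_acute[info.pesticide] = hq_a
            for kind, hqs in (("chronic", hq_chronic), ("acute", hq_acute)):
                hi = hazard_index(hqs, sample_id=sample_id, group=profile.group, kind=kind)
                top = max(hi.contributions, key=hi.contributions.get) if hi.contributions else None
                rows.append(
                    {
                        "sample_id": sample_id,
                        "commodity": commodity,
                        "group": profile.group,
                        "kind": kind,
                        "hi": hi.hi,
                        "top_contributor": top,
                        "n_skipped": n_skipped,
                    }
                )
    per_sample = pd.DataFrame(rows)
    exceedance = {}
    for profile in profiles:
        for kind in ("chronic", "acute"):
            sel = per_sample[(per_sample["group"] == profile.group) & (per_sample["kind"] == kind)]
            exceedance[(profile.group, kind)] = Percentage.from_ratio(
                (sel["hi"] > 1.0).sum() / len(sel)
            )
    per_pesticide = pd.concat(
        [survey_exposure(table, refs, p, units) for p in profiles], ignore_index=True
    )
    return SurveyAssessment(
        per_sample=per_sample, exceedance=exceedance, per_pesticide=per_pesticide
    )
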