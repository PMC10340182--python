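"""Matrix residual-risk ranking of detected pesticides.

Implements the UK Veterinary Residues Committee-style matrix scoring scheme:
each pesticide gets component scores for acute toxicity (A, from LD50),
toxic potency (B, from ADI), dietary share of the commodity (C), frequency
of dosing (D, from FOD), evidence of high-exposure groups (E, fixed), and
observed residue level relative to the MRL (F). The composite score

    S = (A + B) * C + (D + E) * F

places each pesticide into a low (< 15), medium (15 to < 20) or high (>= 20)
risk band.

The component score bins are scheme configuration, not survey data; the
defaults here are 4-level reconstructions (WHO acute-hazard LD50 classes,
ADI decades, diet-share and FOD bands) and can be overridden wholesale via
:class:`ScoreTable`.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import pandas as pd

from .core_data import PesticideInfo, ReferenceSet, ResidueTable
from .errors import ConfigurationError, ValidationError

#: risk-band labels in increasing severity
BANDS = ("low", "medium", "high")


@dataclass(frozen=True)
class ScoreBins:
    """Step function mapping a positive real input to an integer score.

    ``edges`` are the internal cut points (strictly increasing); ``scores``
    has ``len(edges) + 1`` entries, one per interval. ``upper_inclusive``
    selects whether a value equal to an edge falls in the lower interval
    (True: intervals are (lo, hi]) or the upper one (False: [lo, hi)).
    """

    edges: Sequence[float]
    scores: Sequence[int]
    upper_inclusive: bool = True

    def __post_init__(self) -> None:
        if len(self.scores) != len(self.edges) + 1:
            raise ConfigurationError("scores must have exactly len(edges)+1 entries")
        if any(b <= a for a, b in zip(self.edges, self.edges[1:])):
            raise ConfigurationError("bin edges must be strictly increasing")
        if any(s <= 0 for s in self.scores):
            raise ConfigurationError("bin scores must be positive integers")

    def score(self, value: float) -> int:
        if value < 0:
            raise ValidationError(f"bin input must be >= 0, got {value}")
        if self.upper_inclusive:
            i = bisect.bisect_left(self.edges, value)
        else:
            i = bisect.bisect_right(self.edges, value)
        return int(self.scores[i])


@dataclass(frozen=True)
class ScoreTable:
    """Full scheme configuration: per-component bins, fixed E, band edges."""

    # LD50 (mg/kg bw): lower = more acutely toxic = higher score
    a_bins: ScoreBins = field(
        default_factory=lambda: ScoreBins(edges=(50.0, 500.0, 2000.0), scores=(4, 3, 2, 1))
    )
    # ADI (mg/kg bw/day): lower = more potent = higher score
    b_bins: ScoreBins = field(
        default_factory=lambda: ScoreBins(edges=(0.001, 0.01, 0.1), scores=(4, 3, 2, 1))
    )
    # share of the commodity in total diet (fraction): higher = higher score
    c_bins: ScoreBins = field(
        default_factory=lambda: ScoreBins(
            edges=(0.01, 0.05, 0.10), scores=(1, 2, 3, 4), upper_inclusive=False
        )
    )
    # FOD (percent): higher = higher score
    d_bins: ScoreBins = field(
        default_factory=lambda: ScoreBins(
            edges=(5.0, 25.0, 75.0), scores=(1, 2, 3, 4), upper_inclusive=False
        )
    )
    e_fixed: int = 3  # no data on high-exposure groups
    band_edges: tuple[float, float] = (15.0, 20.0)
    grouped: bool = True  # S = (A+B)C + (D+E)F; False gives literal A + BC + D + EF

    def __post_init__(self) -> None:
        lo, hi = self.band_edges
        if not lo < hi:
            raise ConfigurationError("band edges must be strictly increasing")


DEFAULT_SCORE_TABLE = ScoreTable()


@dataclass(frozen=True)
class ResidualLevelCounts:
    """Per-pesticide sample counts by residue level relative to the MRL.

    f0: residue-free samples; f1: detected below 1 MRL; f2: >= 1 and < 10
    MRL; f3: >= 10 MRL. A ratio of exactly 1 falls in f2 ("at or above").
    """

    f0: int
    f1: int
    f2: int
    f3: int

    def __post_init__(self) -> None:
        if min(self.f0, self.f1, self.f2, self.f3) < 0:
            raise ValidationError("residual-level counts must be non-negative")
        if self.n == 0:
            raise ValidationError("residual-level counts must cover at least one sample")

    @property
    def n(self) -> int:
        return self.f0 + self.f1 + self.f2 + self.f3


def residual_level_score(counts: ResidualLevelCounts) -> float:
    """Weighted mean residue-level score F = (f0·1 + f1·2 + f2·3 + f3·4)/n ∈ [1, 4]."""
    return (counts.f0 * 1 + counts.f1 * 2 + counts.f2 * 3 + counts.f3 * 4) / counts.n


def residual_level_counts(
    table: ResidueTable, refs: ReferenceSet, pesticide: str
) -> ResidualLevelCounts:
    """Tally a survey's samples into MRL-relative level classes for one pesticide."""
    det = table.detections
    det = det[det["pesticide"] == pesticide]
    f1 = f2 = f3 = 0
    for _, row in det.iterrows():
        ratio = row["concentration"] / refs.mrl(pesticide, row["commodity"])
        if ratio >= 10:
            f3 += 1
        elif ratio >= 1:
            f2 += 1
        else:
            f1 += 1
    return ResidualLevelCounts(f0=table.n_samples - (f1 + f2 + f3), f1=f1, f2=f2, f3=f3)


def frequency_of_dosing(n_applications: float, growth_days: float) -> float:
    """FOD in percent: 100 × application days / growth days."""
    if growth_days <= 0:
        raise ValidationError("growth_days must be positive")
    if n_applications < 0:
        raise ValidationError("n_applications must be >= 0")
    return 100.0 * n_applications / growth_days


def component_scores(
    info: PesticideInfo,
    diet_proportion: float,
    fod: float,
    table: ScoreTable = DEFAULT_SCORE_TABLE,
) -> tuple[int, int, int, int, int]:
    """Look up (A, B, C, D, E) for one pesticide under a score table."""
    if not 0 <= diet_proportion <= 1:
        raise ValidationError("diet_proportion must lie in [0, 1]")
    return (
        table.a_bins.score(info.ld50),
        table.b_bins.score(info.adi),
        table.c_bins.score(diet_proportion),
        table.d_bins.score(fod),
        table.e_fixed,
    )


def residual_risk_score(
    a: float, b: float, c: float, d: float, e: float, f: float, grouped: bool = True
) -> float:
    """Composite score S = (A+B)·C + (D+E)·F (grouped scheme form).

    ``grouped=False`` evaluates the literal ungrouped reading
    A + B·C + D + E·F instead.
    """
    if min(a, b, c, d, e, f) < 0:
        raise ValidationError("component scores must be >= 0")
    if grouped:
        return (a + b) * c + (d + e) * f
    return a + b * c + d + e * f


def classify_band(s: float, table: ScoreTable = DEFAULT_SCORE_TABLE) -> str:
    """Risk band of a composite score: low < 15 <= medium < 20 <= high (defaults)."""
    if s < 0:
        raise ValidationError("composite score must be >= 0")
    lo, hi = table.band_edges
    if s < lo:
        return "low"
    if s < hi:
        return "medium"
    return "high"


@dataclass(frozen=True)
class RiskScore:
    """Component and composite scores for one pesticide, with its band."""

    pesticide: str
    a: int
    b: int
    c: int
    d: int
    e: int
    f: float
    s: float
    band: str


def rank_pesticides(
    table: ResidueTable,
    refs: ReferenceSet,
    diet_proportion: float,
    fod: dict[str, float] | float,
    score_table: ScoreTable = DEFAULT_SCORE_TABLE,
    pesticides: Optional[Sequence[str]] = None,
) -> pd.DataFrame:
    """Score every detected pesticide in a survey and sort by composite S.

    ``fod`` may be a single frequency-of-dosing percentage applied to all
    pesticides or a per-pesticide mapping. Returns a DataFrame with columns
    pesticide, a..f, s, band, sorted by decreasing S.
    """
    names = list(pesticides) if pesticides is not None else sorted(
        table.detections["pesticide"].unique()
    )
    rows = []
    for name in names:
        info = refs.get(name)
        fod_p = fod[name] if isinstance(fod, dict) else fod
        a, b, c, d, e = component_scores(info, diet_proportion, fod_p, score_table)
        f = residual_level_score(residual_level_counts(table, refs, name))
        s = residual_risk_score(a, b, c, d, e, f, grouped=score_table.grouped)
        rows.append(
            RiskScore(name, a, b, c, d, e, f, s, classify_band(s, score_table)).__dict__
        )
    out = pd.DataFrame(rows)
    return out.sort_values("s", ascending=False).reset_index(drop=True)


def band_shares(ranked: pd.DataFrame) -> dict[str, float]:
    """Percentage of pesticides in each band (whole-percent convention kept raw)."""
    total = len(ranked)
    if total == 0:
        return {b: 0.0 for b in BANDS}
    return {b: 100.0 * (ranked["band"] == b).sum() / total for b in BANDS}
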