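"""Residue-survey data model, CSV I/O and survey-level descriptive statistics.

The atomic datum is one measured pesticide concentration in one fruit sample
(:class:`ResidueRecord`). A :class:`ResidueTable` collects records together
with the full sample roster, so that residue-free samples still count in
denominators. Reference toxicology (LD50, ADI, ARfD, MRL, approval status)
lives in :class:`ReferenceSet`.

Descriptive statistics follow surveillance conventions: detection frequency
and multi-residue shares are reported as whole percents (raw ratio retained),
and the MRL comparison is inclusive — a concentration *at or above* the legal
limit counts as an exceedance.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, NamedTuple, Optional, Sequence

import pandas as pd

from .errors import (
    ReferenceLookupError,
    SchemaError,
    UndefinedRatioError,
    ValidationError,
)

COMMODITIES = ("orange", "lemon", "tangerine", "grapefruit", "other")

#: wildcard commodity accepted in reference tables (one MRL for all citrus)
ANY_COMMODITY = "*"


def round_half_up(x: float) -> int:
    """Round to the nearest integer, halves away from zero (reporting convention)."""
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


class Percentage(NamedTuple):
    """A ratio reported both raw (0-100 float) and rounded to a whole percent."""

    raw: float
    rounded: int

    @classmethod
    def from_ratio(cls, ratio: float) -> "Percentage":
        raw = 100.0 * ratio
        return cls(raw=raw, rounded=round_half_up(raw))


@dataclass(frozen=True)
class ResidueRecord:
    """One pesticide measurement in one sample.

    ``detected=False`` marks a non-detect; its concentration is stored as 0
    and the record never contributes to detection-based summaries.
    """

    sample_id: str
    commodity: str
    pesticide: str
    concentration: float
    detected: bool = True

    def __post_init__(self) -> None:
        if self.concentration < 0:
            raise ValidationError(
                f"negative concentration {self.concentration} for sample "
                f"{self.sample_id!r}, pesticide {self.pesticide!r}"
            )


@dataclass(frozen=True)
class CsvDialect:
    """Column-name mapping for residue CSVs with non-canonical headers."""

    sample_id: str = "sample_id"
    commodity: str = "commodity"
    pesticide: str = "pesticide"
    concentration: str = "concentration_mg_kg"
    detected: Optional[str] = "detected"  # optional column; inferred if absent


class ResidueTable:
    """A residue survey: per-sample, per-pesticide concentrations.

    Parameters
    ----------
    records
        Rows of the survey. ``(sample_id, pesticide)`` pairs must be unique.
    samples
        Optional explicit roster mapping sample id -> commodity. Defaults to
        the samples appearing in ``records``. Samples with no detected
        residues still belong to the roster and count in all denominators.
    pesticides
        Optional explicit analyte panel. Defaults to pesticides appearing in
        ``records``.
    """

    def __init__(
        self,
        records: Iterable[ResidueRecord],
        samples: Optional[Mapping[str, str]] = None,
        pesticides: Optional[Sequence[str]] = None,
    ) -> None:
        recs = list(records)
        frame = pd.DataFrame(
            {
                "sample_id": [r.sample_id for r in recs],
                "commodity": [r.commodity for r in recs],
                "pesticide": [r.pesticide for r in recs],
                "concentration": [0.0 if not r.detected else r.concentration for r in recs],
                "detected": [r.detected for r in recs],
            }
        ).astype(
            {
                "sample_id": str,
                "commodity": str,
                "pesticide": str,
                "concentration": float,
                "detected": bool,
            }
        )
        if len(frame) and frame.duplicated(["sample_id", "pesticide"]).any():
            dup = frame[frame.duplicated(["sample_id", "pesticide"])].iloc[0]
            raise ValidationError(
                f"duplicate (sample_id, pesticide) pair: ({dup.sample_id!r}, {dup.pesticide!r})"
            )
        if samples is None:
            samples = dict(zip(frame["sample_id"], frame["commodity"]))
        else:
            samples = dict(samples)
            unknown = set(frame["sample_id"]) - set(samples)
            if unknown:
                raise ValidationError(f"records reference samples not in roster: {sorted(unknown)}")
        if pesticides is None:
            pesticides = sorted(frame["pesticide"].unique()) if len(frame) else []
        else:
            pesticides = list(pesticides)
            unknown = set(frame["pesticide"]) - set(pesticides)
            if unknown:
                raise ValidationError(f"records reference pesticides not in panel: {sorted(unknown)}")
        self.frame = frame
        self.samples: dict[str, str] = samples
        self.pesticides: list[str] = pesticides

    # -- basic accessors -------------------------------------------------

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def detections(self) -> pd.DataFrame:
        """Only the detected rows (the survey's positive findings)."""
        return self.frame[self.frame["detected"]]

    def __len__(self) -> int:
        return len(self.frame)

    # -- I/O --------------------------------------------------------------

    @classmethod
    def from_csv(cls, path, dialect: CsvDialect = CsvDialect()) -> "ResidueTable":
        """Read a residue CSV. Raises :class:`SchemaError` on missing columns
        and :class:`ValidationError` (citing the row) on negative values."""
        raw = pd.read_csv(path)
        required = {
            "sample_id": dialect.sample_id,
            "commodity": dialect.commodity,
            "pesticide": dialect.pesticide,
            "concentration": dialect.concentration,
        }
        for canonical, col in required.items():
            if col not in raw.columns:
                raise SchemaError(f"missing required column {col!r} (for {canonical})")
        neg = raw.index[raw[dialect.concentration] < 0]
        if len(neg):
            raise ValidationError(
                f"negative concentration at row {int(neg[0])} "
                f"(value {raw.loc[neg[0], dialect.concentration]})"
            )
        if dialect.detected is not None and dialect.detected in raw.columns:
            det = raw[dialect.detected].astype(bool)
        else:
            det = raw[dialect.concentration] > 0
        records = [
            ResidueRecord(
                sample_id=str(row[dialect.sample_id]),
                commodity=str(row[dialect.commodity]),
                pesticide=str(row[dialect.pesticide]),
                concentration=float(row[dialect.concentration]),
                detected=bool(d),
            )
            for (_, row), d in zip(raw.iterrows(), det)
        ]
        return cls(records)

    def to_csv(self, path, dialect: CsvDialect = CsvDialect()) -> None:
        out = self.frame.rename(
            columns={
                "sample_id": dialect.sample_id,
                "commodity": dialect.commodity,
                "pesticide": dialect.pesticide,
                "concentration": dialect.concentration,
                "detected": dialect.detected or "detected",
            }
        )
        out.to_csv(path, index=False)

    # -- descriptive statistics -------------------------------------------

    def _require_samples(self) -> None:
        if self.n_samples == 0:
            raise UndefinedRatioError("survey has no samples; frequencies are undefined")

    def detection_frequency(self, pesticide: str) -> Percentage:
        """Share of all samples in which *pesticide* was detected."""
        self._require_samples()
        det = self.detections
        hits = det[det["pesticide"] == pesticide]["sample_id"].nunique()
        return Percentage.from_ratio(hits / self.n_samples)

    def residue_counts_per_sample(self) -> pd.Series:
        """Number of distinct detected pesticides per sample (0 for clean samples)."""
        counts = self.detections.groupby("sample_id")["pesticide"].nunique()
        return counts.reindex(self.samples.keys(), fill_value=0).astype(int)

    def multiresidue_distribution(self) -> tuple[dict[int, int], Percentage]:
        """Distribution of residue counts over samples and the ≥2-residue share.

        Returns ``(dist, pct)`` where ``dist[k]`` is the number of samples
        carrying exactly *k* distinct residues (including ``k=0``) and ``pct``
        is the percentage of samples with two or more residues.
        """
        self._require_samples()
        per_sample = self.residue_counts_per_sample()
        dist = per_sample.value_counts().sort_index().to_dict()
        multi = int((per_sample >= 2).sum())
        return {int(k): int(v) for k, v in dist.items()}, Percentage.from_ratio(
            multi / self.n_samples
        )


@dataclass(frozen=True)
class PesticideInfo:
    """Reference toxicology and regulation for one pesticide.

    ``mrl`` maps commodity -> legal limit (mg/kg); the wildcard key ``"*"``
    supplies a single citrus-wide MRL. ``arfd`` may be ``None`` for compounds
    with no acute reference dose (acute risk then not computable).
    """

    pesticide: str
    ld50: float  # mg/kg bw, acute oral rat
    adi: float  # mg/kg bw/day
    arfd: Optional[float]  # mg/kg bw/day
    mrl: Mapping[str, float] = field(default_factory=dict)  # commodity -> mg/kg
    approved: bool = True

    def __post_init__(self) -> None:
        if self.ld50 <= 0 or self.adi <= 0:
            raise ValidationError(f"{self.pesticide}: LD50 and ADI must be positive")
        if self.arfd is not None and self.arfd <= 0:
            raise ValidationError(f"{self.pesticide}: ARfD must be positive when present")
        for c, m in self.mrl.items():
            if m <= 0:
                raise ValidationError(f"{self.pesticide}: MRL for {c!r} must be positive")

    def mrl_for(self, commodity: str) -> Optional[float]:
        if commodity in self.mrl:
            return self.mrl[commodity]
        return self.mrl.get(ANY_COMMODITY)


class ReferenceSet:
    """Lookup table of :class:`PesticideInfo`, keyed by pesticide name."""

    def __init__(self, infos: Iterable[PesticideInfo]) -> None:
        self._by_name = {i.pesticide: i for i in infos}

    def __contains__(self, pesticide: str) -> bool:
        return pesticide in self._by_name

    def __iter__(self):
        return iter(self._by_name.values())

    def __len__(self) -> int:
        return len(self._by_name)

    def get(self, pesticide: str) -> PesticideInfo:
        try:
            return self._by_name[pesticide]
        except KeyError:
            raise ReferenceLookupError(f"no reference entry for pesticide {pesticide!r}") from None

    def mrl(self, pesticide: str, commodity: str, strict: bool = True) -> Optional[float]:
        info = self.get(pesticide)
        m = info.mrl_for(commodity)
        if m is None and strict:
            raise ReferenceLookupError(f"no MRL for ({pesticide!r}, {commodity!r})")
        return m

    @classmethod
    def from_csv(cls, path) -> "ReferenceSet":
        """Read the reference CSV: pesticide, ld50_mg_kg, adi_mg_kg_bw,
        arfd_mg_kg_bw (blank allowed), commodity, mrl_mg_kg, eu_approved."""
        raw = pd.read_csv(path)
        required = ["pesticide", "ld50_mg_kg", "adi_mg_kg_bw", "commodity", "mrl_mg_kg"]
        for col in required:
            if col not in raw.columns:
                raise SchemaError(f"missing required column {col!r} in reference table")
        infos = []
        for name, grp in raw.groupby("pesticide", sort=True):
            first = grp.iloc[0]
            arfd = first.get("arfd_mg_kg_bw")
            arfd = None if pd.isna(arfd) else float(arfd)
            approved = bool(first["eu_approved"]) if "eu_approved" in grp.columns else True
            mrl = {str(r["commodity"]): float(r["mrl_mg_kg"]) for _, r in grp.iterrows()}
            infos.append(
                PesticideInfo(
                    pesticide=str(name),
                    ld50=float(first["ld50_mg_kg"]),
                    adi=float(first["adi_mg_kg_bw"]),
                    arfd=arfd,
                    mrl=mrl,
                    approved=approved,
                )
            )
        return cls(infos)

    def to_csv(self, path) -> None:
        rows = []
        for info in self:
            for commodity, mrl in info.mrl.items():
                rows.append(
                    {
                        "pesticide": info.pesticide,
                        "ld50_mg_kg": info.ld50,
                        "adi_mg_kg_bw": info.adi,
                        "arfd_mg_kg_bw": info.arfd,
                        "commodity": commodity,
                        "mrl_mg_kg": mrl,
                        "eu_approved": info.approved,
                    }
                )
        pd.DataFrame(rows).to_csv(path, index=False)


@dataclass(frozen=True)
class MrlExceedance:
    """Result of screening a survey against MRLs."""

    record_flags: pd.Series  # aligned with table.frame index
    sample_flags: pd.Series  # indexed by sample id
    pct_samples: Percentage

    @property
    def n_flagged_samples(self) -> int:
        return int(self.sample_flags.sum())


def mrl_exceedance(
    table: ResidueTable, refs: ReferenceSet, policy: str = "strict"
) -> MrlExceedance:
    """Flag records at or above their MRL and summarize per sample.

    The comparison is inclusive (concentration >= MRL counts). Under
    ``policy="lenient"`` a missing MRL produces a warning and the record is
    skipped; under ``"strict"`` it raises :class:`ReferenceLookupError`.
    """
    if table.n_samples == 0:
        raise UndefinedRatioError("survey has no samples; exceedance rate is undefined")
    flags = pd.Series(False, index=table.frame.index)
    for idx, row in table.detections.iterrows():
        try:
            limit = refs.mrl(row["pesticide"], row["commodity"], strict=True)
        except ReferenceLookupError:
            if policy == "strict":
                raise
            warnings.warn(
                f"no MRL for ({row['pesticide']!r}, {row['commodity']!r}); record skipped",
                stacklevel=2,
            )
            continue
        flags.loc[idx] = row["concentration"] >= limit
    by_sample = table.frame.assign(flag=flags).groupby("sample_id")["flag"].any()
    sample_flags = by_sample.reindex(table.samples.keys(), fill_value=False).astype(bool)
    return MrlExceedance(
        record_flags=flags,
        sample_flags=sample_flags,
        pct_samples=Percentage.from_ratio(sample_flags.sum() / table.n_samples),
    )


def matrix_effect(response_in_matrix: float, response_in_solvent: float) -> float:
    """Matrix effect in percent: 100 × (response in matrix) / (response in solvent).

    A value near 100% means no signal suppression or enhancement by the fruit
    matrix. QC utility for chromatographic method checks.
    """
    if response_in_solvent <= 0:
        raise ValidationError("solvent response must be positive")
    return 100.0 * response_in_matrix / response_in_solvent


# thin functional wrappers mirroring the table methods

def detection_frequency(table: ResidueTable, pesticide: str) -> Percentage:
    return table.detection_frequency(pesticide)


def multiresidue_distribution(table: ResidueTable) -> tuple[dict[int, int], Percentage]:
    return table.multiresidue_distribution()
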