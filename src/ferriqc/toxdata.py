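"""Toxicity-record handling: screening, geometric-mean aggregation, ACR.

Ecotoxicity endpoints for a single chemical are collected per species from
the literature (acute: LC50/EC50/IC50; chronic: NOEC/LOEC/MATC plus chronic
EC50/LC50).  Records are aggregated by geometric mean first to a species
value (the species mean acute/chronic value, SMAV/"AVE" or "CVE") and then
to a genus value (GMAV), the inputs to every downstream criteria
derivation.  The acute-to-chronic ratio (ACR) is estimated from species
with matched acute and chronic tests.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

ACUTE_ENDPOINTS = frozenset({"LC50", "EC50", "IC50"})
CHRONIC_ENDPOINTS = frozenset({"NOEC", "LOEC", "MATC", "EC50", "LC50"})

#: multiplicative factors to the canonical unit, μg/L
_UNIT_FACTORS = {"ug/L": 1.0, "µg/L": 1.0, "μg/L": 1.0, "mg/L": 1000.0, "ng/L": 1e-3}


class TestType(str, Enum):
    acute = "acute"
    chronic = "chronic"


TestType.__test__ = False  # keep pytest from collecting the enum by name


class ValidationError(ValueError):
    """A record or argument violates an input contract."""


@dataclass(frozen=True)
class ToxicityRecord:
    """One endpoint measurement for one species, concentration in μg/L."""

    species_latin: str
    genus: str
    test_type: TestType
    endpoint: str
    concentration: float
    source_id: str = ""
    taxon_group: str = ""
    notes: str = ""
    exclude: bool = False


@dataclass(frozen=True)
class SpeciesValue:
    """Geometric-mean species toxicity value (SMAV / AVE / CVE), μg/L."""

    species_latin: str
    genus: str
    test_type: TestType
    n_records: int
    value: float
    record_ids: tuple[int, ...] = ()


@dataclass(frozen=True)
class GenusValue:
    """Geometric-mean genus toxicity value (GMAV), μg/L."""

    genus: str
    test_type: TestType
    n_species: int
    value: float


@dataclass(frozen=True)
class AcrPair:
    species_latin: str
    acute_value_matched: float
    chronic_value: float

    @property
    def ratio(self) -> float:
        return self.acute_value_matched / self.chronic_value


@dataclass(frozen=True)
class AcrEstimate:
    """Acute-to-chronic ratio: per-species ratios and their geometric mean."""

    per_species: tuple[AcrPair, ...]
    overall: float
    pairing_policy: str = "same_source"


@dataclass
class ScreeningReport:
    """Outcome of record screening: keeps accepted ∪ rejected == input."""

    accepted: list[ToxicityRecord] = field(default_factory=list)
    rejected: list[tuple[int, ToxicityRecord | None, str]] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(line, rule) for line, _rec, rule in self.rejected],
            columns=["line", "rule"],
        )


def geometric_mean(values: Sequence[float]) -> float:
    """Geometric mean exp(mean(log v)) of positive concentrations.

    Scale-equivariant and order-independent; raises :class:`ValidationError`
    on an empty list or any nonpositive/non-finite entry, naming the
    offending value.
    """
    vals = list(values)
    if not vals:
        raise ValidationError("geometric mean of an empty list")
    for v in vals:
        if not math.isfinite(v) or v <= 0:
            raise ValidationError(f"nonpositive or non-finite concentration: {v!r}")
    return float(np.exp(np.mean(np.log(vals))))


def screen_records(
    records: Iterable[ToxicityRecord],
) -> ScreeningReport:
    """Screen records against required-field, endpoint and positivity rules.

    Rejections are reported, never raised: the report partitions the input
    into accepted and rejected (with the violated rule per rejection).
    Records explicitly flagged ``exclude`` (curated outlier elimination)
    are rejected with rule ``"excluded by curator flag"``.
    """
    report = ScreeningReport()
    for i, rec in enumerate(records):
        rule = _screening_rule_violated(rec)
        if rule is None:
            report.accepted.append(rec)
        else:
            report.rejected.append((i, rec, rule))
            logger.info("record %d rejected: %s", i, rule)
    return report


def _screening_rule_violated(rec: ToxicityRecord) -> str | None:
    if not rec.species_latin or not str(rec.species_latin).strip():
        return "missing species name"
    if not rec.genus or not str(rec.genus).strip():
        return "missing genus"
    if rec.exclude:
        return "excluded by curator flag"
    if not math.isfinite(rec.concentration) or rec.concentration <= 0:
        return "nonpositive concentration"
    tt = TestType(rec.test_type)
    if tt is TestType.acute and rec.endpoint not in ACUTE_ENDPOINTS:
        return "endpoint not allowed for acute"
    if tt is TestType.chronic and rec.endpoint not in CHRONIC_ENDPOINTS:
        return "endpoint not allowed for chronic"
    return None


def species_values(
    records: Sequence[ToxicityRecord], test_type: TestType | str
) -> list[SpeciesValue]:
    """One geometric-mean SpeciesValue per distinct species of ``test_type``."""
    tt = TestType(test_type)
    groups: dict[str, list[tuple[int, ToxicityRecord]]] = {}
    genus_of: dict[str, str] = {}
    for i, rec in enumerate(records):
        if TestType(rec.test_type) is not tt:
            continue
        groups.setdefault(rec.species_latin, []).append((i, rec))
        prev = genus_of.setdefault(rec.species_latin, rec.genus)
        if prev != rec.genus:
            raise ValidationError(
                f"species {rec.species_latin!r} mapped to two genera: "
                f"{prev!r} and {rec.genus!r}"
            )
    out = []
    for species in sorted(groups):
        members = groups[species]
        value = geometric_mean([r.concentration for _, r in members])
        out.append(
            SpeciesValue(
                species_latin=species,
                genus=genus_of[species],
                test_type=tt,
                n_records=len(members),
                value=value,
                record_ids=tuple(i for i, _ in members),
            )
        )
    return out


def genus_values(svalues: Sequence[SpeciesValue]) -> list[GenusValue]:
    """One geometric-mean GenusValue per genus (GMAV for acute input)."""
    if not svalues:
        return []
    tts = {TestType(s.test_type) for s in svalues}
    if len(tts) != 1:
        raise ValidationError("genus aggregation requires a single test_type")
    groups: dict[str, list[SpeciesValue]] = {}
    for s in svalues:
        groups.setdefault(s.genus, []).append(s)
    return [
        GenusValue(
            genus=genus,
            test_type=next(iter(tts)),
            n_species=len(members),
            value=geometric_mean([m.value for m in members]),
        )
        for genus, members in sorted(groups.items())
    ]


def compute_acr(
    acute_records: Sequence[ToxicityRecord],
    chronic_records: Sequence[ToxicityRecord],
    pairing_policy: str = "same_source",
) -> AcrEstimate:
    """Acute-to-chronic ratio from species present in both record sets.

    Per species, ratio = gm(matched acute records) / gm(all chronic
    records).  Under ``same_source`` (the default) the acute side is
    restricted to records whose ``source_id`` also appears among that
    species' chronic records — the matched-test convention; a candidate
    species with no shared source is excluded and logged.  Under
    ``all_records`` every acute record of the species enters.  The overall
    ACR is the geometric mean of the per-species ratios.
    """
    if pairing_policy not in ("same_source", "all_records"):
        raise ValidationError(f"unknown pairing policy {pairing_policy!r}")
    by_sp_acute: dict[str, list[ToxicityRecord]] = {}
    for rec in acute_records:
        by_sp_acute.setdefault(rec.species_latin, []).append(rec)
    by_sp_chronic: dict[str, list[ToxicityRecord]] = {}
    for rec in chronic_records:
        by_sp_chronic.setdefault(rec.species_latin, []).append(rec)

    pairs: list[AcrPair] = []
    for species in sorted(set(by_sp_acute) & set(by_sp_chronic)):
        acute = by_sp_acute[species]
        chronic = by_sp_chronic[species]
        if pairing_policy == "same_source":
            shared = {r.source_id for r in chronic}
            acute = [r for r in acute if r.source_id in shared]
            if not acute:
                logger.info(
                    "ACR: species %s has no acute record sharing a chronic "
                    "source; excluded from pairing",
                    species,
                )
                continue
        pairs.append(
            AcrPair(
                species_latin=species,
                acute_value_matched=geometric_mean([r.concentration for r in acute]),
                chronic_value=geometric_mean([r.concentration for r in chronic]),
            )
        )
    if not pairs:
        raise ValidationError("ACR not computable: no species paired")
    overall = geometric_mean([p.ratio for p in pairs])
    return AcrEstimate(
        per_species=tuple(pairs), overall=overall, pairing_policy=pairing_policy
    )


def read_toxicity_csv(path: str | Path) -> list[ToxicityRecord]:
    """Read a toxicity table (CSV, UTF-8) into records in μg/L.

    Expected columns: species, genus, test_type, endpoint, value, unit,
    source_id and optionally exclude, taxon_group, notes.  Values with
    thousands separators are rejected; units are converted on read via the
    explicit ``unit`` column.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    required = {"species", "genus", "test_type", "endpoint", "value", "unit"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"toxicity table missing columns: {sorted(missing)}")
    records = []
    for i, row in df.iterrows():
        raw = str(row["value"]).strip()
        if "," in raw:
            raise ValidationError(f"line {i + 2}: thousands separator in value {raw!r}")
        try:
            value = float(raw)
        except ValueError as exc:
            raise ValidationError(f"line {i + 2}: unparseable value {raw!r}") from exc
        unit = str(row["unit"]).strip()
        if unit not in _UNIT_FACTORS:
            raise ValidationError(f"line {i + 2}: unknown unit {unit!r}")
        records.append(
            ToxicityRecord(
                species_latin=str(row["species"]).strip(),
                genus=str(row["genus"]).strip(),
                test_type=TestType(str(row["test_type"]).strip()),
                endpoint=str(row["endpoint"]).strip(),
                concentration=value * _UNIT_FACTORS[unit],
                source_id=str(row.get("source_id", "")).strip(),
                taxon_group=str(row.get("taxon_group", "")).strip(),
                notes=str(row.get("notes", "")).strip(),
                exclude=str(row.get("exclude", "")).strip().lower()
                in ("1", "true", "yes"),
            )
        )
    return records


def write_toxicity_csv(records: Sequence[ToxicityRecord], path: str | Path) -> None:
    """Write records back in the same schema (μg/L) for round-tripping."""
    pd.DataFrame(
        {
            "species": [r.species_latin for r in records],
            "genus": [r.genus for r in records],
            "test_type": [TestType(r.test_type).value for r in records],
            "endpoint": [r.endpoint for r in records],
            "value": [repr(r.concentration).rstrip("0").rstrip(".")
                      if r.concentration == int(r.concentration)
                      else repr(r.concentration)
                      for r in records],
            "unit": ["ug/L"] * len(records),
            "source_id": [r.source_id for r in records],
            "exclude": ["true" if r.exclude else "" for r in records],
            "notes": [r.notes for r in records],
        }
    ).to_csv(path, index=False)
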