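"""End-to-end derivation: records → aggregates → criteria by each method."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from . import criteria as crit
from . import ssd as ssdmod
from .toxdata import (
    AcrEstimate,
    GenusValue,
    SpeciesValue,
    TestType,
    ToxicityRecord,
    compute_acr,
    genus_values,
    screen_records,
    species_values,
)


@dataclass
class DerivationRun:
    """Everything one derivation pass produced, for reporting."""

    acute_species: list[SpeciesValue]
    chronic_species: list[SpeciesValue]
    acute_genera: list[GenusValue]
    chronic_genera: list[GenusValue]
    acr: AcrEstimate
    results: dict[str, crit.CriteriaResult]
    n_rejected: int


def derive(
    records: Sequence[ToxicityRecord],
    methods: Sequence[str] = ("AF", "TPR", "SSD"),
    acr_policy: str = "same_source",
    saf: float = crit.DEFAULT_SAF,
    laf: float = crit.DEFAULT_LAF,
    min_chronic_n: int = crit.DEFAULT_MIN_CHRONIC_N,
    candidates: Sequence[str] = ssdmod.DEFAULT_CANDIDATES,
) -> DerivationRun:
    """Screen, aggregate and run the selected criteria derivation methods."""
    report = screen_records(records)
    accepted = report.accepted
    acute_records = [r for r in accepted if TestType(r.test_type) is TestType.acute]
    chronic_records = [r for r in accepted if TestType(r.test_type) is TestType.chronic]
    acute_sp = species_values(accepted, TestType.acute)
    chronic_sp = species_values(accepted, TestType.chronic)
    acute_gen = genus_values(acute_sp) if acute_sp else []
    chronic_gen = genus_values(chronic_sp) if chronic_sp else []
    acr = compute_acr(acute_records, chronic_records, acr_policy)

    results: dict[str, crit.CriteriaResult] = {}
    if "AF" in methods:
        results["AF"] = crit.af_method(acute_sp, acr.overall)
    if "TPR" in methods:
        results["TPR"] = crit.tpr_method(acute_gen, acr.overall)
    if "SSD" in methods:
        results["SSD"] = crit.ssd_method(
            acute_sp,
            chronic_sp,
            acr.overall,
            saf=saf,
            laf=laf,
            min_chronic_n=min_chronic_n,
            candidates=candidates,
        )
    return DerivationRun(
        acute_species=acute_sp,
        chronic_species=chronic_sp,
        acute_genera=acute_gen,
        chronic_genera=chronic_gen,
        acr=acr,
        results=results,
        n_rejected=len(report.rejected),
    )
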