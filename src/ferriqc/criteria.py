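"""Water-quality criteria derivation: AF, TPR and SSD methods.

Three internationally used routes from aggregated toxicity values to
criteria:

* **AF (assessment factor)** — the most sensitive species' acute value
  (ATV) divided by an empirical factor; here the acute-to-chronic ratio
  (ACR) serves as the factor, giving a single chronic-protective value.
* **TPR (toxicity percentage ranking)** — the US EPA 1985 procedure: from
  the four genus mean acute values (GMAVs) whose cumulative probability
  P = R/(N+1) is nearest 0.05, a weighted log-linear extrapolation gives
  the final acute value (FAV); the criteria maximum concentration is
  CMC = FAV/2, and the criteria continuous concentration CCC is the
  minimum of the final chronic value FCV = FAV/ACR, the final plant value
  and the final residual value (the latter two when available).
* **SSD** — fit the species sensitivity distribution, take the acute HC5
  and divide by a short-term assessment factor for the short-term
  criterion (SWQC = HC5/SAF); the long-term criterion uses a chronic-SSD
  HC5 over the long-term factor when enough chronic species exist, else
  the fallback LWQC = acute HC5 / ACR.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from . import ssd as ssdmod
from .toxdata import GenusValue, SpeciesValue, ValidationError

logger = logging.getLogger(__name__)

#: default minimum chronic species count to fit a chronic SSD directly
DEFAULT_MIN_CHRONIC_N = 8
DEFAULT_SAF = 2.0
DEFAULT_LAF = 2.0


@dataclass
class CriteriaResult:
    """Criteria from one derivation method, with every intermediate (μg/L)."""

    method: str
    swqc: float | None = None
    lwqc: float | None = None
    intermediates: dict = field(default_factory=dict)
    provenance: list[str] = field(default_factory=list)

    def log(self, msg: str) -> None:
        self.provenance.append(msg)
        logger.info("[%s] %s", self.method, msg)


def af_method(
    acute_species_values: Sequence[SpeciesValue], acr: float
) -> CriteriaResult:
    """Assessment-factor criterion: minimum species acute value / ACR."""
    if not acute_species_values:
        raise ValidationError("AF method requires at least one acute species value")
    if acr <= 0:
        raise ValidationError("ACR must be positive")
    most_sensitive = min(acute_species_values, key=lambda s: s.value)
    atv = most_sensitive.value
    wqc = atv / acr
    res = CriteriaResult(method="AF", lwqc=wqc)
    res.intermediates.update({"atv": atv, "acr": acr})
    res.log(
        f"most sensitive species {most_sensitive.species_latin} "
        f"ATV={atv:.6g} μg/L; WQC = ATV/ACR = {wqc:.6g} μg/L"
    )
    return res


def tpr_fav(genus_acute_values: Sequence[GenusValue]) -> tuple[float, dict]:
    """Final acute value from the four GMAVs nearest cumulative P = 0.05.

    GMAVs are ranked ascending with P_R = R/(N+1); the four genera with
    smallest |P − 0.05| (ties toward lower rank) enter the extrapolation

        S² = [Σ(lnG)² − (ΣlnG)²/4] / [ΣP − (Σ√P)²/4]
        L  = (ΣlnG − S·Σ√P) / 4
        FAV = exp(S·√0.05 + L)

    which is exact for lnG linear in √P and returns the common value for
    four identical GMAVs.
    """
    gv = sorted(genus_acute_values, key=lambda g: g.value)
    n = len(gv)
    if n < 4:
        raise ValidationError("TPR FAV requires at least 4 genera")
    P = np.arange(1, n + 1) / (n + 1)
    order = sorted(range(n), key=lambda i: (abs(P[i] - 0.05), i))[:4]
    order.sort()
    G = np.array([gv[i].value for i in order])
    Pq = P[order]
    lnG = np.log(G)
    num = float(np.sum(lnG**2) - np.sum(lnG) ** 2 / 4)
    den = float(np.sum(Pq) - np.sum(np.sqrt(Pq)) ** 2 / 4)
    S = math.sqrt(num / den) if num > 1e-30 else 0.0
    L = float((np.sum(lnG) - S * np.sum(np.sqrt(Pq))) / 4)
    fav = math.exp(S * math.sqrt(0.05) + L)
    diagnostics = {
        "genera": [gv[i].genus for i in order],
        "gmavs": G.tolist(),
        "P": Pq.tolist(),
        "S": S,
        "L": L,
        "n_genera": n,
    }
    return fav, diagnostics


def tpr_method(
    genus_acute_values: Sequence[GenusValue],
    acr: float,
    fpv: float | None = None,
    frv: float | None = None,
) -> CriteriaResult:
    """TPR criteria: CMC = FAV/2; CCC = min of populated {FCV, FPV, FRV}."""
    if acr <= 0:
        raise ValidationError("ACR must be positive")
    fav, diag = tpr_fav(genus_acute_values)
    return tpr_assemble(fav, acr, fpv=fpv, frv=frv, diagnostics=diag)


def tpr_assemble(
    fav: float,
    acr: float,
    fpv: float | None = None,
    frv: float | None = None,
    diagnostics: dict | None = None,
) -> CriteriaResult:
    """Assemble TPR criteria from a given FAV (separable for injection)."""
    cmc = fav / 2.0
    fcv = fav / acr
    candidates = {"fcv": fcv}
    res = CriteriaResult(method="TPR")
    if fpv is not None:
        candidates["fpv"] = fpv
    else:
        res.log("no final plant value available; FPV skipped")
    if frv is not None:
        candidates["frv"] = frv
    else:
        res.log("no final residual value available; FRV skipped")
    ccc = min(candidates.values())
    res.swqc = cmc
    res.lwqc = ccc
    res.intermediates.update(
        {"fav": fav, "acr": acr, "cmc": cmc, "fcv": fcv, "ccc": ccc}
    )
    if fpv is not None:
        res.intermediates["fpv"] = fpv
    if frv is not None:
        res.intermediates["frv"] = frv
    if diagnostics:
        res.intermediates["fav_diagnostics"] = diagnostics
    res.log(f"FAV={fav:.6g}; CMC=FAV/2={cmc:.6g}; CCC=min{candidates}={ccc:.6g}")
    return res


def ssd_method(
    acute_species_values: Sequence[SpeciesValue],
    chronic_species_values: Sequence[SpeciesValue] | None,
    acr: float,
    saf: float = DEFAULT_SAF,
    laf: float = DEFAULT_LAF,
    min_chronic_n: int = DEFAULT_MIN_CHRONIC_N,
    candidates: Sequence[str] = ssdmod.DEFAULT_CANDIDATES,
) -> CriteriaResult:
    """SSD criteria: SWQC = acute HC5/SAF; LWQC from chronic SSD or ACR fallback."""
    if saf <= 0 or laf <= 0 or acr <= 0:
        raise ValidationError("SAF, LAF and ACR must be positive")
    if len(acute_species_values) < 3:
        raise ValidationError("SSD method requires at least 3 acute species values")
    res = CriteriaResult(method="SSD")

    acute_points = ssdmod.points_from_species_values(acute_species_values)
    acute_fit = ssdmod.select_best_model(
        ssdmod.fit_candidates(acute_points, candidates)
    )
    hc5_acute = acute_fit.hc5
    res.swqc = hc5_acute / saf
    res.intermediates.update(
        {
            "hc5_acute": hc5_acute,
            "saf": saf,
            "laf": laf,
            "acr": acr,
            "acute_fit": acute_fit.to_dict(),
        }
    )
    res.log(
        f"acute SSD: {acute_fit.model} r2={acute_fit.r2:.4f} "
        f"HC5={hc5_acute:.6g}; SWQC=HC5/SAF={res.swqc:.6g}"
    )

    n_chronic = len(chronic_species_values) if chronic_species_values else 0
    if n_chronic >= min_chronic_n:
        chronic_points = ssdmod.points_from_species_values(chronic_species_values)
        chronic_fit = ssdmod.select_best_model(
            ssdmod.fit_candidates(chronic_points, candidates)
        )
        res.lwqc = chronic_fit.hc5 / laf
        res.intermediates["hc5_chronic"] = chronic_fit.hc5
        res.intermediates["chronic_fit"] = chronic_fit.to_dict()
        res.log(
            f"chronic SSD: {chronic_fit.model} HC5={chronic_fit.hc5:.6g}; "
            f"LWQC=HC5/LAF={res.lwqc:.6g}"
        )
    else:
        res.lwqc = hc5_acute / acr
        res.log(
            f"chronic species count {n_chronic} < {min_chronic_n}: "
            f"LWQC falls back to acute HC5/ACR = {res.lwqc:.6g}"
        )
    return res


def round_sig(x: float, sig: int = 3) -> float:
    """Round to ``sig`` significant figures (display convention)."""
    if x == 0 or not math.isfinite(x):
        return x
    return round(x, -int(math.floor(math.log10(abs(x)))) + (sig - 1))


def comparison_table(results: Sequence[CriteriaResult]) -> str:
    """Human-readable side-by-side summary of the derivation methods."""
    lines = [f"{'method':<6} {'SWQC (μg/L)':>14} {'LWQC (μg/L)':>14}"]
    for r in results:
        sw = f"{round_sig(r.swqc):g}" if r.swqc is not None else "-"
        lw = f"{round_sig(r.lwqc):g}" if r.lwqc is not None else "-"
        lines.append(f"{r.method:<6} {sw:>14} {lw:>14}")
    return "\n".join(lines)
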