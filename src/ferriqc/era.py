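"""Risk-quotient ecological risk assessment against derived criteria.

Each monitored site contributes a measured environmental concentration
(MEC, here the reported site mean); the risk quotient is QR = MEC/PNEC
with the predicted no-effect concentration (PNEC) set to a derived
criterion.  A short-term (acute) quotient uses the SWQC and a long-term
(chronic) quotient the LWQC.  Quotients classify as low (< 0.1), medium
(0.1–1, boundaries included) or high (> 1); sites reporting a standard
deviation additionally get an interval quotient from mean ± SD.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from enum import Enum
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .toxdata import ValidationError

logger = logging.getLogger(__name__)

RISK_FLAGS = frozenset({"near_contaminated_site", "emergency_event", "season_split"})


class RiskClass(str, Enum):
    low = "low"
    medium = "medium"
    high = "high"
    not_computable = "not_computable"


@dataclass(frozen=True)
class ExposureRecord:
    """One site's summarised iron exposure (all concentrations μg/L)."""

    site_id: str
    province: str = ""
    basin: str = ""
    reach: str = ""
    mean_conc: float | None = None
    sd_conc: float | None = None
    min_conc: float | None = None
    max_conc: float | None = None
    year_range: str = ""
    source_id: str = ""
    flags: frozenset[str] = frozenset()

    def __post_init__(self):
        present = [v for v in (self.mean_conc, self.min_conc, self.max_conc)
                   if v is not None]
        if not present:
            raise ValidationError(
                f"site {self.site_id!r}: no mean/min/max concentration"
            )
        if any(v < 0 for v in present) or (
            self.sd_conc is not None and self.sd_conc < 0
        ):
            raise ValidationError(f"site {self.site_id!r}: negative concentration")
        if (
            self.min_conc is not None
            and self.mean_conc is not None
            and self.max_conc is not None
            and not (self.min_conc <= self.mean_conc <= self.max_conc)
        ):
            raise ValidationError(
                f"site {self.site_id!r}: min ≤ mean ≤ max violated"
            )
        unknown = set(self.flags) - RISK_FLAGS
        if unknown:
            raise ValidationError(f"site {self.site_id!r}: unknown flags {unknown}")


@dataclass
class RiskResult:
    site_id: str
    sqr: float | None = None
    lqr: float | None = None
    sqr_range: tuple[float, float] | None = None
    lqr_range: tuple[float, float] | None = None
    risk_class_s: RiskClass = RiskClass.not_computable
    risk_class_l: RiskClass = RiskClass.not_computable
    basin: str = ""
    province: str = ""


@dataclass
class BasinSummary:
    basin: str
    n_sites: int
    mean_sqr: float
    mean_lqr: float
    class_counts_s: dict = field(default_factory=dict)
    class_counts_l: dict = field(default_factory=dict)


def risk_quotient(mec: float, pnec: float) -> float:
    """QR = MEC/PNEC; linear in MEC, inversely linear in PNEC."""
    if pnec <= 0:
        raise ValidationError(f"PNEC must be positive, got {pnec}")
    if mec < 0:
        raise ValidationError(f"MEC must be nonnegative, got {mec}")
    return mec / pnec


def classify(q: float) -> RiskClass:
    """low iff q < 0.1; medium iff 0.1 ≤ q ≤ 1; high iff q > 1.

    The boundaries 0.1 and 1 both fall in the medium class so the three
    classes partition the nonnegative line.
    """
    if q < 0:
        raise ValidationError("risk quotient must be nonnegative")
    if q < 0.1:
        return RiskClass.low
    if q <= 1.0:
        return RiskClass.medium
    return RiskClass.high


def assess(
    exposures: Iterable[ExposureRecord],
    swqc: float,
    lwqc: float,
    screen: bool = False,
) -> list[RiskResult]:
    """Per-site acute/chronic quotients and classes against SWQC/LWQC.

    Records without a reported mean yield ``not_computable`` results (they
    stay in the output but are excluded from summaries); with ``screen``
    set, records flagged near a contaminated site or an emergency event
    are dropped with a log line before assessment.
    """
    if swqc <= 0 or lwqc <= 0:
        raise ValidationError("criteria must be positive")
    results = []
    for rec in exposures:
        if screen and (
            {"near_contaminated_site", "emergency_event"} & set(rec.flags)
        ):
            logger.info("site %s screened out (flags %s)", rec.site_id, set(rec.flags))
            continue
        res = RiskResult(site_id=rec.site_id, basin=rec.basin, province=rec.province)
        if rec.mean_conc is not None:
            res.sqr = risk_quotient(rec.mean_conc, swqc)
            res.lqr = risk_quotient(rec.mean_conc, lwqc)
            res.risk_class_s = classify(res.sqr)
            res.risk_class_l = classify(res.lqr)
            if rec.sd_conc is not None:
                lo = max(rec.mean_conc - rec.sd_conc, 0.0)  # clip below at 0
                hi = rec.mean_conc + rec.sd_conc
                res.sqr_range = (lo / swqc, hi / swqc)
                res.lqr_range = (lo / lwqc, hi / lwqc)
        else:
            logger.info("site %s has no mean concentration: not computable",
                        rec.site_id)
        results.append(res)
    return results


def class_tally(
    results: Sequence[RiskResult], which: str = "s"
) -> dict:
    """Counts and percentage shares per risk class over computable results."""
    attr = "risk_class_s" if which == "s" else "risk_class_l"
    qattr = "sqr" if which == "s" else "lqr"
    computable = [r for r in results if getattr(r, qattr) is not None]
    if not computable:
        raise ValidationError("no computable risk quotients to tally")
    counts = Counter(getattr(r, attr).value for r in computable)
    n = len(computable)
    return {
        "n": n,
        "counts": {c.value: counts.get(c.value, 0)
                   for c in (RiskClass.low, RiskClass.medium, RiskClass.high)},
        "proportions": {c.value: counts.get(c.value, 0) / n
                        for c in (RiskClass.low, RiskClass.medium, RiskClass.high)},
        "mean": sum(getattr(r, qattr) for r in computable) / n,
    }


def summarize(
    results: Sequence[RiskResult], group_by: str = "basin"
) -> list[BasinSummary]:
    """Arithmetic mean quotients and class counts per basin or province."""
    if group_by not in ("basin", "province"):
        raise ValidationError(f"cannot group by {group_by!r}")
    computable = [r for r in results if r.sqr is not None]
    if not computable:
        raise ValidationError("no computable risk quotients to summarize")
    groups: dict[str, list[RiskResult]] = {}
    for r in computable:
        groups.setdefault(getattr(r, group_by), []).append(r)
    out = []
    for key in sorted(groups):
        members = groups[key]
        out.append(
            BasinSummary(
                basin=key,
                n_sites=len(members),
                mean_sqr=sum(m.sqr for m in members) / len(members),
                mean_lqr=sum(m.lqr for m in members) / len(members),
                class_counts_s=dict(Counter(m.risk_class_s.value for m in members)),
                class_counts_l=dict(Counter(m.risk_class_l.value for m in members)),
            )
        )
    return out


def province_basin_map() -> dict[str, str]:
    """Editable shipped helper map from Chinese province to river basin."""
    with resources.as_file(
        resources.files("ferriqc.data") / "province_basins.csv"
    ) as p:
        df = pd.read_csv(p)
    return dict(zip(df["province"], df["basin"]))


def read_exposure_csv(path: str | Path) -> list[ExposureRecord]:
    """Read an exposure table (CSV) into records, converting units to μg/L."""
    from .toxdata import _UNIT_FACTORS

    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    if "site_id" not in df.columns:
        raise ValidationError("exposure table missing site_id column")
    records = []
    for i, row in df.iterrows():
        unit = str(row.get("unit", "ug/L")).strip() or "ug/L"
        if unit not in _UNIT_FACTORS:
            raise ValidationError(f"line {i + 2}: unknown unit {unit!r}")
        k = _UNIT_FACTORS[unit]

        def num(col):
            raw = str(row.get(col, "")).strip()
            return float(raw) * k if raw else None

        flags = frozenset(
            f.strip() for f in str(row.get("flags", "")).split(";") if f.strip()
        )
        records.append(
            ExposureRecord(
                site_id=str(row["site_id"]).strip(),
                province=str(row.get("province", "")).strip(),
                basin=str(row.get("basin", "")).strip(),
                reach=str(row.get("reach", "")).strip(),
                mean_conc=num("mean"),
                sd_conc=num("sd"),
                min_conc=num("min"),
                max_conc=num("max"),
                year_range=str(row.get("year_range", "")).strip(),
                source_id=str(row.get("source_id", "")).strip(),
                flags=flags,
            )
        )
    return records


def results_frame(results: Sequence[RiskResult]) -> pd.DataFrame:
    """Per-site quotients and classes as a DataFrame (CSV-ready)."""
    return pd.DataFrame(
        {
            "site_id": [r.site_id for r in results],
            "province": [r.province for r in results],
            "basin": [r.basin for r in results],
            "sqr": [r.sqr for r in results],
            "lqr": [r.lqr for r in results],
            "sqr_lo": [r.sqr_range[0] if r.sqr_range else None for r in results],
            "sqr_hi": [r.sqr_range[1] if r.sqr_range else None for r in results],
            "lqr_lo": [r.lqr_range[0] if r.lqr_range else None for r in results],
            "lqr_hi": [r.lqr_range[1] if r.lqr_range else None for r in results],
            "risk_class_s": [r.risk_class_s.value for r in results],
            "risk_class_l": [r.risk_class_l.value for r in results],
        }
    )
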