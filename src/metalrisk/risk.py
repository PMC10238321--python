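"""Deterministic dietary risk characterisation for metal residues.

Four standard USEPA-style quantities are computed per brand × tissue ×
metal group from the mean residue concentration C (µg/g wet weight):

* **EDI** — estimated daily intake, ``C · FIR / BW`` in µg per kg body
  weight per day, with the tissue-specific ingestion rate FIR (g/day) and
  body weight BW (kg).
* **THQ** — target hazard quotient, chronic intake relative to the oral
  reference dose RfD (mg/kg/day).
* **HI**  — hazard index, the sum of the THQs of all metals in a group.
* **TR**  — target cancer risk, intake times the oral carcinogenic potency
  slope CPSo (per mg/kg/day); only metals with a defined slope get one.

Formula modes
-------------
The source publication states THQ and TR equations whose time factors and
unit factors do not reproduce its own printed tables, so both readings are
implemented explicitly:

* ``published`` (default) — reproduces the printed tables:
  ``THQ = EDI · 10⁻³ / RfD`` (the ED·EF/AT time factor collapses to 1) and
  ``TR = EDI_mg · CPSo = EDI · 10⁻⁶ · CPSo``.
* ``stated`` — the equations exactly as written: THQ additionally carries
  the non-cancer time factor ED·EF/(AT·365) (= 30/70 at the defaults) and
  TR keeps the written 10⁻³ instead of the published 10⁻⁶, hence
  ``TR_published = 10⁻³ · TR_stated``.

The published THQ/HI tables carry a "× 10⁻³" scale label that conflicts
dimensionally with their own intake column; printed numerals are matched
as numerals and the label is treated as display metadata.  All chained
quantities are computed from the raw group means, never from rounded
intermediates.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import pandas as pd

from .io import ConcentrationTable
from .registry import ExposureParams, ReferenceRegistry

Mode = Literal["published", "stated"]
MODES = ("published", "stated")

__all__ = [
    "edi", "thq", "hazard_index", "tr", "assess",
    "RiskResult", "GroupRisk", "risk_frames", "MODES",
]


def _check_mode(mode: str) -> None:
    if mode not in MODES:
        raise ValueError(f"mode must be one of {MODES}, got {mode!r}")


def edi(c: float, fir: float, bw: float) -> float:
    """Estimated daily intake, µg per kg body weight per day."""
    if c < 0:
        raise ValueError(f"concentration must be >= 0, got {c}")
    if not fir > 0:
        raise ValueError(f"ingestion rate must be > 0, got {fir}")
    if not bw > 0:
        raise ValueError(f"body weight must be > 0, got {bw}")
    return c * fir / bw


def thq(c: float, fir: float, params: ExposureParams, rfd: float,
        mode: Mode = "published") -> float:
    """Target hazard quotient of one metal in one tissue."""
    _check_mode(mode)
    if not rfd > 0:
        raise ValueError(f"reference dose must be > 0, got {rfd}")
    value = edi(c, fir, params.bw) * 1e-3 / rfd
    if mode == "stated":
        value *= params.ed_noncancer * params.ef / (params.at_years * 365.0)
    return value


def hazard_index(thqs: Iterable[float]) -> float:
    """Sum of hazard quotients; raises on an empty collection."""
    values = list(thqs)
    if not values:
        raise ValueError("hazard index of an empty THQ collection")
    return sum(values)


def tr(c: float, fir: float, params: ExposureParams, cpso: float,
       mode: Mode = "published") -> float:
    """Target (lifetime incremental) cancer risk of one metal."""
    _check_mode(mode)
    if not cpso > 0:
        raise ValueError(f"potency slope must be > 0, got {cpso}")
    time_factor = params.ed_cancer * params.ef / (params.at_years * 365.0)
    value = edi(c, fir, params.bw) * 1e-3 * cpso * time_factor
    if mode == "published":
        value *= 1e-3
    return value


@dataclass(frozen=True)
class RiskResult:
    brand: str
    tissue: str
    metal: str
    edi: float          # µg/kg BW/day
    thq: float          # dimensionless (printed-table numeral convention)
    tr: float | None    # lifetime cancer probability; None without a CPSo
    mode: Mode


@dataclass
class GroupRisk:
    brand: str
    tissue: str
    per_metal: list[RiskResult]
    hi: float
    flags: list[str] = field(default_factory=list)


def assess(table: ConcentrationTable, registry: ReferenceRegistry,
           mode: Mode = "published") -> list[GroupRisk]:
    """Full risk characterisation of a group-level table.

    Every metal present must have a reference dose.  The report attaches
    intake-versus-guideline flags (e.g. the Al recommended dietary
    allowance of 60 mg/day) per group.
    """
    _check_mode(mode)
    if table.level != "group":
        raise ValueError("assess expects a group-level table; summarise "
                         "sample data first")
    params = registry.exposure
    for metal in table.frame["metal"].unique():
        registry.get_rfd(metal)  # raises MissingReferenceError, naming it

    results: list[GroupRisk] = []
    for brand, tissue in table.group_keys():
        sub = table.subset(brand=brand, tissue=tissue)
        fir = params.fir_for(tissue)
        per_metal = []
        flags = []
        for rec in sub.records():
            e = edi(rec.mean, fir, params.bw)
            q = thq(rec.mean, fir, params, registry.get_rfd(rec.metal), mode)
            r = (tr(rec.mean, fir, params, registry.get_cpso(rec.metal), mode)
                 if registry.has_cpso(rec.metal) else None)
            per_metal.append(RiskResult(brand, tissue, rec.metal, e, q, r, mode))
            rda_key = f"{rec.metal}_rda_mg_day"
            if rda_key in registry.guidelines:
                intake_mg_day = e * params.bw * 1e-3
                rda = registry.guidelines[rda_key]
                rel = "exceeds" if intake_mg_day > rda else "below"
                flags.append(
                    f"{rec.metal} intake {intake_mg_day:.4g} mg/day {rel} "
                    f"RDA {rda:g} mg/day")
        hi = hazard_index(r.thq for r in per_metal)
        results.append(GroupRisk(brand, tissue, per_metal, hi, flags))
    return results


def risk_frames(group_risks: Sequence[GroupRisk]) -> dict[str, pd.DataFrame]:
    """Tidy DataFrames ('edi', 'thq', 'hi', 'tr') mirroring the published
    table layout, one row per brand × tissue × metal (HI: per group)."""
    rows = [
        {"brand": r.brand, "tissue": r.tissue, "metal": r.metal,
         "edi": r.edi, "thq": r.thq, "tr": r.tr}
        for g in group_risks for r in g.per_metal
    ]
    per_metal = pd.DataFrame(rows)
    hi = pd.DataFrame(
        [{"brand": g.brand, "tissue": g.tissue, "hi": g.hi,
          "flags": "; ".join(g.flags)} for g in group_risks])
    return {
        "edi": per_metal[["brand", "tissue", "metal", "edi"]],
        "thq": per_metal[["brand", "tissue", "metal", "thq"]],
        "hi": hi,
        "tr": per_metal.dropna(subset=["tr"])[
            ["brand", "tissue", "metal", "tr"]].reset_index(drop=True),
    }
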