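"""Permissible-limit screening and study-level exceedance percentages.

A brand × tissue × metal group is screened against an authority's maximum
residue limit for the matching tissue class (chest/thigh count as muscle,
liver as offal).  A group exceeds a rule when its mean is strictly above
the limit; a mean exactly at the limit is compliant.  Because the study
publishes only group means, exceedance is judged per group and converted
to sample percentages with the group sizes (20 birds per group in the
study design); sample-level tables are screened per individual sample.

Percentages are reported over all samples of the table covered by the
authority's rules and displayed with half-up rounding to an integer, the
convention that reproduces every published exceedance figure.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP

import pandas as pd

from .io import ConcentrationTable, GroupSummary
from .registry import LimitRule, MissingLimitError, ReferenceRegistry

log = logging.getLogger(__name__)

__all__ = [
    "tissue_class_of", "classify_group", "exceedance_report",
    "ExceedanceReport", "screen", "round_half_up",
]

_TISSUE_CLASS = {"chest": "muscle", "thigh": "muscle", "liver": "offal"}


def tissue_class_of(tissue: str) -> str:
    try:
        return _TISSUE_CLASS[tissue]
    except KeyError:
        raise ValueError(f"unknown tissue {tissue!r}") from None


def round_half_up(value: float, digits: int = 0) -> float:
    q = Decimal(1).scaleb(-digits)
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


def classify_group(summary: GroupSummary, rule: LimitRule) -> bool:
    """True iff the group mean strictly exceeds the rule's limit."""
    if summary.metal != rule.metal:
        raise ValueError(f"rule is for metal {rule.metal!r}, "
                         f"group is {summary.metal!r}")
    if tissue_class_of(summary.tissue) != rule.tissue_class:
        raise ValueError(
            f"rule applies to tissue class {rule.tissue_class!r}, group "
            f"tissue {summary.tissue!r} is {tissue_class_of(summary.tissue)!r}")
    return summary.mean > rule.limit


@dataclass
class ExceedanceReport:
    authority: str
    metal: str
    flagged_groups: list[tuple[str, str]]      # (brand, tissue)
    flagged_sample_count: int
    total_sample_count: int
    excluded_groups: list[tuple[str, str]] = field(default_factory=list)

    @property
    def percent(self) -> float:
        if self.total_sample_count == 0:
            return 0.0
        return 100.0 * self.flagged_sample_count / self.total_sample_count

    @property
    def percent_display(self) -> int:
        return int(round_half_up(self.percent))


def exceedance_report(table: ConcentrationTable, registry: ReferenceRegistry,
                      authority: str, metal: str,
                      total_sample_count: int | None = None
                      ) -> ExceedanceReport:
    """Screen every group of one metal against one authority's rules.

    ``total_sample_count`` defaults to the whole table's sample count (all
    metals' groups count distinct birds per tissue in the study design:
    the published percentages are over all 360 birds, i.e. the 18 groups
    of any single metal at n = 20).  Groups without an applicable rule are
    excluded and logged; if no group has a rule, that is an error.
    """
    sub = table.subset(metal=metal)
    if len(sub) == 0:
        raise ValueError(f"table has no rows for metal {metal!r}")
    flagged: list[tuple[str, str]] = []
    excluded: list[tuple[str, str]] = []
    flagged_n = 0
    total_n = 0

    if sub.level == "group":
        for rec in sub.records():
            try:
                rule = registry.limit_rule(authority, metal,
                                           tissue_class_of(rec.tissue))
            except MissingLimitError:
                excluded.append((rec.brand, rec.tissue))
                log.warning("no %s rule for %s in tissue class %s; group "
                            "(%s, %s) excluded", authority, metal,
                            tissue_class_of(rec.tissue), rec.brand, rec.tissue)
                continue
            total_n += rec.n
            if classify_group(rec, rule):
                flagged.append((rec.brand, rec.tissue))
                flagged_n += rec.n
    else:
        for rec in sub.records():
            try:
                rule = registry.limit_rule(authority, metal,
                                           tissue_class_of(rec.tissue))
            except MissingLimitError:
                excluded.append((rec.brand, rec.tissue))
                continue
            total_n += 1
            if rec.concentration > rule.limit:
                key = (rec.brand, rec.tissue)
                if key not in flagged:
                    flagged.append(key)
                flagged_n += 1

    if total_n == 0:
        raise MissingLimitError(
            f"authority {authority!r} has no applicable rule for any group "
            f"of metal {metal!r}")
    return ExceedanceReport(
        authority=authority, metal=metal, flagged_groups=flagged,
        flagged_sample_count=flagged_n,
        total_sample_count=(total_sample_count if total_sample_count
                            is not None else total_n),
        excluded_groups=excluded)


def screen(table: ConcentrationTable, registry: ReferenceRegistry,
           pairs: list[tuple[str, str]],
           total_sample_count: int | None = None) -> pd.DataFrame:
    """Exceedance reports for (authority, metal) pairs as one tidy frame."""
    rows = []
    for authority, metal in pairs:
        rep = exceedance_report(table, registry, authority, metal,
                                total_sample_count)
        rows.append({
            "authority": authority, "metal": metal,
            "flagged_groups": len(rep.flagged_groups),
            "flagged_samples": rep.flagged_sample_count,
            "total_samples": rep.total_sample_count,
            "percent": rep.percent,
            "percent_display": rep.percent_display,
        })
    return pd.DataFrame(rows)
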