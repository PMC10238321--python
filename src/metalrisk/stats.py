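"""Group summaries and tissue-contrast testing.

Mirrors the study's analysis: concentrations are summarised as mean ± SE
per brand × tissue × metal group, tissues are compared per brand and metal
with a one-way ANOVA, and pairwise tissue differences are marked with the
letter convention of the published tables — "a" on a tissue that differs
from chest muscle, "b" on one that differs from thigh muscle, at α = 0.05.
Tukey's HSD is the default multiple-comparison procedure; Dunnett's test
with chest as the control is available as an option.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .io import ConcentrationTable, TISSUES

log = logging.getLogger(__name__)

__all__ = [
    "summarize_groups", "one_way_anova", "tissue_contrasts",
    "AnovaResult", "TissueContrastResult", "contrast_frame",
]


@dataclass(frozen=True)
class AnovaResult:
    statistic: float
    p_value: float
    df_between: int
    df_within: int


@dataclass(frozen=True)
class TissueContrastResult:
    brand: str
    metal: str
    tissue_pair: tuple[str, str]
    statistic: float
    p_value: float
    significant: bool
    letter: str  # "a" for vs-chest contrasts, "b" for vs-thigh


def summarize_groups(samples: ConcentrationTable) -> ConcentrationTable:
    """Collapse a sample-level table to group level (mean, SE = sd/√n)."""
    if samples.level != "sample":
        raise ValueError("summarize_groups expects a sample-level table")
    g = samples.frame.groupby(["brand", "tissue", "metal"], sort=False)
    out = g["concentration_ug_g"].agg(
        n="size", mean_ug_g="mean",
        se_ug_g=lambda x: x.std(ddof=1) / np.sqrt(len(x)) if len(x) > 1 else 0.0,
    ).reset_index()
    for row in out[out["n"] == 1].itertuples(index=False):
        log.warning("group (%s, %s, %s) has a single sample; SE set to 0",
                    row.brand, row.tissue, row.metal)
    out = out[["brand", "tissue", "metal", "n", "mean_ug_g", "se_ug_g"]]
    return ConcentrationTable(out, level="group")


def _tissue_arrays(samples: ConcentrationTable, brand: str, metal: str
                   ) -> dict[str, np.ndarray]:
    sub = samples.subset(brand=str(brand), metal=metal)
    groups = {
        t: sub.frame.loc[sub.frame["tissue"] == t,
                         "concentration_ug_g"].to_numpy()
        for t in TISSUES
        if (sub.frame["tissue"] == t).any()
    }
    if len(groups) < 2:
        raise ValueError(
            f"need at least 2 tissue groups for brand {brand!r}, metal "
            f"{metal!r}; found {list(groups)}")
    for t, x in groups.items():
        if len(x) < 2:
            raise ValueError(f"tissue {t!r} has fewer than 2 samples")
    return groups


def one_way_anova(samples: ConcentrationTable, brand: str, metal: str
                  ) -> AnovaResult:
    """Classic one-way F test across the tissues of one brand × metal."""
    groups = _tissue_arrays(samples, brand, metal)
    arrays = list(groups.values())
    k = len(arrays)
    n = sum(len(a) for a in arrays)
    pooled = np.concatenate(arrays)
    if np.ptp(pooled) == 0:  # no variation anywhere: no evidence either way
        return AnovaResult(0.0, 1.0, k - 1, n - k)
    f, p = sps.f_oneway(*arrays)
    return AnovaResult(float(f), float(p), k - 1, n - k)


_PAIR_LETTER = {
    ("chest", "thigh"): "a",
    ("chest", "liver"): "a",
    ("thigh", "liver"): "b",
}


def tissue_contrasts(samples: ConcentrationTable, brand: str, metal: str,
                     alpha: float = 0.05, method: str = "tukey"
                     ) -> list[TissueContrastResult]:
    """Pairwise tissue contrasts with multiplicity-adjusted p-values.

    ``method="tukey"`` (default) tests all three pairs with Tukey's HSD;
    ``method="dunnett"`` tests thigh and liver against chest as control
    (no thigh-liver contrast, matching a many-to-one comparison).
    The published letter convention: "a" marks a significant difference
    from chest, "b" from thigh.
    """
    groups = _tissue_arrays(samples, brand, metal)
    present = [t for t in TISSUES if t in groups]
    results: list[TissueContrastResult] = []

    if method == "tukey":
        res = sps.tukey_hsd(*[groups[t] for t in present])
        for i, ti in enumerate(present):
            for j, tj in enumerate(present):
                if j <= i:
                    continue
                p = float(res.pvalue[i, j])
                stat = float(res.statistic[i, j])
                pair = (ti, tj)
                results.append(TissueContrastResult(
                    str(brand), metal, pair, stat, p, p < alpha,
                    _PAIR_LETTER[pair]))
    elif method == "dunnett":
        if "chest" not in groups:
            raise ValueError("Dunnett contrasts need chest as control")
        others = [t for t in present if t != "chest"]
        res = sps.dunnett(*[groups[t] for t in others],
                          control=groups["chest"])
        for t, stat, p in zip(others, np.atleast_1d(res.statistic),
                              np.atleast_1d(res.pvalue)):
            results.append(TissueContrastResult(
                str(brand), metal, ("chest", t), float(stat), float(p),
                float(p) < alpha, "a"))
    else:
        raise ValueError(f"method must be tukey|dunnett, got {method!r}")
    return results


def letters(contrasts: list[TissueContrastResult]) -> dict[str, str]:
    """Per-tissue significance letters as printed in the study tables."""
    out = {t: "" for t in TISSUES}
    for c in contrasts:
        if not c.significant:
            continue
        ref, other = c.tissue_pair
        out[other] = "".join(sorted(set(out[other] + c.letter)))
    return out


def contrast_frame(contrasts: list[TissueContrastResult]) -> pd.DataFrame:
    return pd.DataFrame([
        {"brand": c.brand, "metal": c.metal,
         "contrast": f"{c.tissue_pair[1]}-vs-{c.tissue_pair[0]}",
         "statistic": c.statistic, "p_value": c.p_value,
         "letter": c.letter if c.significant else ""}
        for c in contrasts
    ])
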