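#!/usr/bin/env python
"""Tissue-contrast statistics on the synthetic per-bird dataset.

The study marks tissues whose concentrations differ from chest ("a") or
thigh ("b") muscle at p < 0.05.  The raw per-bird data were never
published, so the letters cannot be reproduced exactly; this driver runs
the same procedure (one-way ANOVA + Tukey HSD) on synthetic birds drawn
to the published summaries and reports the letters that design implies.

Writes results/contrasts.csv and results/letters.csv.
"""
from pathlib import Path

import pandas as pd

from metalrisk.io import load_study_means
from metalrisk.stats import (contrast_frame, letters, one_way_anova,
                             tissue_contrasts)
from metalrisk.synthetic import design_from_groups, generate

OUT = Path(__file__).resolve().parents[1] / "results"
SEED = 1


def main() -> None:
    targets = load_study_means()
    samples = generate(design_from_groups(targets, seed=SEED))

    all_contrasts = []
    letter_rows = []
    n_sig_anova = 0
    metals = sorted(targets.frame["metal"].unique())
    brands = sorted(targets.frame["brand"].unique())
    for metal in metals:
        for brand in brands:
            res = one_way_anova(samples, brand, metal)
            n_sig_anova += res.p_value < 0.05
            cs = tissue_contrasts(samples, brand, metal)
            all_contrasts.append(contrast_frame(cs))
            lt = letters(cs)
            letter_rows.append({"brand": brand, "metal": metal,
                                "anova_p": res.p_value, **lt})

    OUT.mkdir(exist_ok=True)
    pd.concat(all_contrasts, ignore_index=True).to_csv(
        OUT / "contrasts.csv", index=False)
    lf = pd.DataFrame(letter_rows)
    lf.to_csv(OUT / "letters.csv", index=False)

    n = len(lf)
    print(f"{n} brand x metal ANOVAs on synthetic birds (seed {SEED}): "
          f"{n_sig_anova} significant at p < 0.05.")
    print(f"Liver marked 'ab' (differs from both muscles) in "
          f"{(lf['liver'] == 'ab').sum()}/{n} cases; thigh marked 'a' in "
          f"{lf['thigh'].str.contains('a').sum()}/{n}.")
    print("With published group SEs this small, almost every tissue "
          "contrast separates — consistent with the near-ubiquitous "
          "letters in the published concentration tables.")


if __name__ == "__main__":
    main()
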