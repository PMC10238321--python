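import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from metalrisk.io import ConcentrationTable
from metalrisk.stats import (letters, one_way_anova, summarize_groups,
                             tissue_contrasts)


def sample_table(groups: dict[str, list[float]], brand="1", metal="Pb"
                 ) -> ConcentrationTable:
    rows = [{"brand": brand, "tissue": t, "metal": metal,
             "sample_id": f"s{i}", "concentration_ug_g": float(v)}
            for t, values in groups.items() for i, v in enumerate(values)]
    return ConcentrationTable(pd.DataFrame(rows), "sample")


class TestSummarize:
    def test_constant_data(self):
        g = summarize_groups(sample_table({"chest": [5, 5, 5, 5]}))
        row = g.frame.iloc[0]
        assert row["mean_ug_g"] == 5 and row["se_ug_g"] == 0 and row["n"] == 4

    def test_hand_computed_se(self):
        # sd([1,2,3]) = 1, se = 1/sqrt(3)
        g = summarize_groups(sample_table({"chest": [1, 2, 3]}))
        assert g.frame.iloc[0]["mean_ug_g"] == pytest.approx(2)
        assert g.frame.iloc[0]["se_ug_g"] == pytest.approx(0.5774, abs=1e-4)

    def test_se_shrinks_as_inverse_root_n_under_replication(self):
        base = [1.0, 2.0, 4.0, 8.0, 3.0, 5.0, 2.5, 6.0, 7.0, 1.5]
        se1 = summarize_groups(sample_table({"chest": base})) \
            .frame.iloc[0]["se_ug_g"]
        se4 = summarize_groups(sample_table({"chest": base * 4})) \
            .frame.iloc[0]["se_ug_g"]
        assert se4 == pytest.approx(se1 / 2, rel=0.05)

    def test_recovers_target_within_sampling_error(self, study_means):
        """Generated samples for the lead/chest/brand-1 group summarise to
        a mean within 3 target SEs of 2.577."""
        from metalrisk.synthetic import design_from_groups, generate
        target = study_means.subset(brand="1", tissue="chest", metal="Pb")
        design = design_from_groups(target, seed=7)
        g = summarize_groups(generate(design))
        assert g.frame.iloc[0]["mean_ug_g"] == pytest.approx(
            2.577, abs=3 * 0.071)


class TestAnova:
    def test_identical_groups_give_zero_f(self):
        res = one_way_anova(sample_table({"chest": [5, 5, 5],
                                          "thigh": [5, 5, 5]}), "1", "Pb")
        assert res.statistic == 0.0
        assert res.p_value == 1.0

    def test_two_groups_f_equals_t_squared(self):
        rng = np.random.default_rng(11)
        a, b = rng.normal(5, 1, 12), rng.normal(6, 1, 9)
        res = one_way_anova(sample_table({"chest": a, "thigh": b}), "1", "Pb")
        t = sps.ttest_ind(a, b).statistic
        assert res.statistic == pytest.approx(t ** 2, rel=1e-10)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_sum_of_squares_oracle(self, seed):
        """F agrees with an explicit between/within decomposition."""
        rng = np.random.default_rng(seed)
        groups = {t: rng.normal(mu, 1.3, n) for t, mu, n in
                  [("chest", 5, 8), ("thigh", 5.5, 11), ("liver", 7, 6)]}
        res = one_way_anova(sample_table(groups), "1", "Pb")

        allv = np.concatenate(list(groups.values()))
        grand = allv.mean()
        ssb = sum(len(x) * (x.mean() - grand) ** 2 for x in groups.values())
        ssw = sum(((x - x.mean()) ** 2).sum() for x in groups.values())
        k, n = len(groups), len(allv)
        f_oracle = (ssb / (k - 1)) / (ssw / (n - k))
        assert res.statistic == pytest.approx(f_oracle, rel=1e-10)
        assert res.p_value == pytest.approx(
            sps.f.sf(f_oracle, k - 1, n - k), rel=1e-10)
        assert (res.df_between, res.df_within) == (k - 1, n - k)

    def test_p_decreases_as_f_grows(self):
        ps = [float(sps.f.sf(f, 2, 57)) for f in (0.5, 1, 2, 5, 10)]
        assert ps == sorted(ps, reverse=True)

    def test_single_group_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            one_way_anova(sample_table({"chest": [1, 2, 3]}), "1", "Pb")

    def test_type_one_error_calibrated(self):
        """With all tissue means equal, ~5% of ANOVAs reject at alpha=0.05
        (within exact binomial 99% bounds over 400 replicates)."""
        n_rep, alpha, rejections = 400, 0.05, 0
        rng = np.random.default_rng(2024)
        for _ in range(n_rep):
            groups = {t: rng.normal(10.0, 0.8, 10)
                      for t in ("chest", "thigh", "liver")}
            res = one_way_anova(sample_table(groups), "1", "Pb")
            rejections += res.p_value < alpha
        lo = sps.binom.ppf(0.005, n_rep, alpha)
        hi = sps.binom.ppf(0.995, n_rep, alpha)
        assert lo <= rejections <= hi


class TestTissueContrasts:
    def test_identical_groups_get_no_letters(self):
        cs = tissue_contrasts(sample_table(
            {"chest": [5, 5.1, 4.9], "thigh": [5, 5.1, 4.9],
             "liver": [5, 5.1, 4.9]}), "1", "Pb")
        assert letters(cs) == {"chest": "", "thigh": "", "liver": ""}

    def test_separated_liver_flagged_against_both(self):
        cs = tissue_contrasts(sample_table(
            {"chest": [0.01, 0.011, 0.009], "thigh": [0.0101, 0.0111, 0.0091],
             "liver": [100, 100.1, 99.9]}), "1", "Pb")
        lt = letters(cs)
        assert lt["liver"] == "ab"
        assert lt["thigh"] == ""

    @pytest.mark.parametrize("seed", [3, 4])
    def test_tukey_p_matches_studentized_range_oracle(self, seed):
        rng = np.random.default_rng(seed)
        groups = {t: rng.normal(mu, 1.0, 7) for t, mu in
                  [("chest", 5), ("thigh", 6), ("liver", 5.2)]}
        cs = tissue_contrasts(sample_table(groups), "1", "Pb")

        k = 3
        df = sum(len(x) - 1 for x in groups.values())
        msw = sum(((x - x.mean()) ** 2).sum()
                  for x in groups.values()) / df
        for c in cs:
            a, b = (groups[t] for t in c.tissue_pair)
            q = abs(a.mean() - b.mean()) / np.sqrt(
                msw / 2 * (1 / len(a) + 1 / len(b)))
            p_oracle = float(sps.studentized_range.sf(q, k, df))
            assert c.p_value == pytest.approx(p_oracle, abs=1e-6)

    def test_dunnett_compares_against_chest_only(self):
        rng = np.random.default_rng(5)
        groups = {t: rng.normal(5, 1, 8)
                  for t in ("chest", "thigh", "liver")}
        cs = tissue_contrasts(sample_table(groups), "1", "Pb",
                              method="dunnett")
        assert {c.tissue_pair for c in cs} == {("chest", "thigh"),
                                               ("chest", "liver")}
        assert all(c.letter == "a" for c in cs)

    def test_significant_flag_is_p_below_alpha(self):
        rng = np.random.default_rng(6)
        groups = {t: rng.normal(mu, 1.0, 10) for t, mu in
                  [("chest", 5), ("thigh", 6.5), ("liver", 5.1)]}
        for alpha in (0.01, 0.05, 0.2):
            for c in tissue_contrasts(sample_table(groups), "1", "Pb",
                                      alpha=alpha):
                assert c.significant == (c.p_value < alpha)
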