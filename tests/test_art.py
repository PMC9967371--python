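"""Aligned-rank-transform ANOVA: alignment strips every other effect
exactly, F statistics match an independent statsmodels oracle, and the
companion rank/KS/Spearman tests agree with brute-force computation."""
import itertools
from math import comb

import numpy as np
import pandas as pd
import pytest
import statsmodels.formula.api as smf
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats
from statsmodels.stats.anova import anova_lm

from plvconnect import (
    align,
    art_anova,
    factorial_anova_f,
    ks_normality,
    posthoc_pairwise,
    rank_midranks,
    spearman_corr,
)
from plvconnect.exceptions import DegenerateDesignError
from tests.conftest import random_design

FACTORS = ("band", "group", "condition")
EFFECTS = (
    "band",
    "group",
    "condition",
    "band:group",
    "band:condition",
    "group:condition",
    "band:group:condition",
)


def statsmodels_table(df):
    model = smf.ols(
        "global_plv ~ C(band, Sum) * C(group, Sum) * C(condition, Sum)", df
    ).fit()
    return anova_lm(model, typ=3)


SM_ROWS = {
    "band": "C(band, Sum)",
    "group": "C(group, Sum)",
    "condition": "C(condition, Sum)",
    "band:group": "C(band, Sum):C(group, Sum)",
    "band:condition": "C(band, Sum):C(condition, Sum)",
    "group:condition": "C(group, Sum):C(condition, Sum)",
    "band:group:condition": "C(band, Sum):C(group, Sum):C(condition, Sum)",
}


class TestFactorialAnova:
    @pytest.mark.parametrize("sizes", [(8, 4), (6, 6)])
    def test_matches_statsmodels_type3_oracle(self, sizes):
        df = random_design(np.random.default_rng(7), *sizes)
        mine = factorial_anova_f(df["global_plv"].to_numpy(), df, FACTORS)
        theirs = statsmodels_table(df)
        for eff, sm_row in SM_ROWS.items():
            assert mine.loc[eff, "F"] == pytest.approx(theirs.loc[sm_row, "F"], rel=1e-8)
            assert mine.loc[eff, "p"] == pytest.approx(
                theirs.loc[sm_row, "PR(>F)"], rel=1e-8
            )

    def test_balanced_sums_of_squares_partition(self):
        df = random_design(np.random.default_rng(8), 6, 6)
        y = df["global_plv"].to_numpy()
        table = factorial_anova_f(y, df, FACTORS)
        total = float(np.sum((y - y.mean()) ** 2))
        partition = float(table["ss"].sum()) + table.attrs["sse"]
        assert partition == pytest.approx(total, rel=1e-8)

    def test_known_group_shift_recovered(self):
        rng = np.random.default_rng(9)
        df = random_design(rng, 6, 6, bands=("delta", "theta", "alpha", "beta", "gamma"))
        df["global_plv"] = rng.normal(0, 0.1, len(df)) + np.where(
            df["group"] == "HC", 2.0, 0.0
        )
        mine = factorial_anova_f(df["global_plv"].to_numpy(), df, FACTORS)
        theirs = statsmodels_table(df)
        assert mine.loc["group", "F"] > 1_000
        assert mine.loc["group", "F"] == pytest.approx(
            theirs.loc[SM_ROWS["group"], "F"], rel=1e-6
        )

    def test_study_design_denominator_df(self):
        df = random_design(
            np.random.default_rng(10), 26, 13,
            bands=("delta", "theta", "alpha", "beta", "gamma"),
        )
        table = factorial_anova_f(df["global_plv"].to_numpy(), df, FACTORS)
        assert (table["df_den"] == 370).all()
        assert list(table["df_num"]) == [4, 1, 1, 4, 4, 1, 4]

    def test_constant_response_gives_zero_f(self):
        df = random_design(np.random.default_rng(11), 4, 4)
        table = factorial_anova_f(np.full(len(df), 3.7), df, FACTORS)
        assert (table["F"] == 0).all()

    def test_zero_residual_df_rejected(self):
        rows = [
            dict(group=g, condition=c, band=b, global_plv=np.random.rand())
            for g, c, b in itertools.product("GH", "RM", "XY")
        ]
        with pytest.raises(DegenerateDesignError):
            df = pd.DataFrame(rows)
            factorial_anova_f(df["global_plv"].to_numpy(), df, FACTORS)


class TestAlignment:
    @pytest.mark.parametrize("sizes", [(8, 4), (5, 5)])
    def test_alignment_strips_all_other_effects(self, sizes):
        df = random_design(np.random.default_rng(12), *sizes)
        for effect in EFFECTS:
            aligned = align(df, effect)
            diag = factorial_anova_f(aligned, df, FACTORS)
            assert float(diag["F"].drop(effect).max()) < 1e-6

    def test_pure_group_data_aligned_up_to_constant(self):
        df = random_design(np.random.default_rng(13), 4, 4)
        y = np.where(df["group"] == "HC", 1.5, -1.5)
        df["global_plv"] = y
        aligned = align(df, "group")
        offsets = y - aligned
        assert np.allclose(offsets, offsets[0], atol=1e-9)

    def test_aligned_cell_means_depend_only_on_target_level(self):
        df = random_design(np.random.default_rng(14), 6, 3)
        df["aligned"] = align(df, "group")
        cell_means = df.groupby(["band", "group", "condition"])["aligned"].mean()
        for group, sub in cell_means.groupby(level="group"):
            assert np.allclose(sub.to_numpy(), sub.to_numpy()[0], atol=1e-9)

    def test_unknown_effect_rejected(self):
        df = random_design(np.random.default_rng(15), 3, 3)
        with pytest.raises(ValueError, match="unknown effect"):
            align(df, "subject")


class TestRankMidranks:
    def test_examples(self):
        assert list(rank_midranks([3.2, 1.1, 5.0])) == [2, 1, 3]
        assert list(rank_midranks([4.0, 4.0])) == [1.5, 1.5]

    @settings(deadline=None, derandomize=True)
    @given(st.lists(st.integers(-5, 5), min_size=1, max_size=50))
    def test_rank_sum_identity_and_monotone_invariance(self, values):
        v = np.array(values, dtype=float)
        r = rank_midranks(v)
        n = len(v)
        assert r.sum() == pytest.approx(n * (n + 1) / 2)
        assert np.array_equal(r, rank_midranks(np.exp(v / 5.0)))

    def test_nan_rejected(self):
        with pytest.raises(ValueError):
            rank_midranks([1.0, np.nan])


class TestArtAnova:
    def test_study_table_reports_370_denominator_df(self):
        df = random_design(
            np.random.default_rng(16), 26, 13,
            bands=("delta", "theta", "alpha", "beta", "gamma"),
        )
        result = art_anova(df)
        assert (result.anova["df_den"] == 370).all()
        assert set(result.anova.index) == set(EFFECTS)
        assert max(result.stripped_max_f.values()) < 1e-6

    def test_single_effect_data_reduces_to_rank_anova(self):
        """When the response carries only a Group effect (all other
        effect estimates exactly zero), ART equals a plain ANOVA on the
        ranks of the raw response."""
        rng = np.random.default_rng(17)
        df = random_design(rng, 5, 5)
        # noise with every non-Group effect removed, plus a pure Group shift
        df["global_plv"] = align(df, "group") + np.where(df["group"] == "HC", 1.0, -1.0)
        result = art_anova(df)
        plain = factorial_anova_f(
            rank_midranks(df["global_plv"].to_numpy()), df, FACTORS
        )
        assert result.anova.loc["group", "F"] == pytest.approx(
            plain.loc["group", "F"], rel=1e-8
        )

    def test_injected_interaction_detected(self):
        rng = np.random.default_rng(18)
        df = random_design(rng, 8, 8)
        bump = ((df["band"] == "delta") & (df["group"] == "HC")).to_numpy()
        df["global_plv"] = rng.normal(0, 0.5, len(df)) + 3.0 * bump
        result = art_anova(df)
        assert result.anova.loc["band:group", "p"] < 0.001


class TestPosthoc:
    def test_identical_distributions_adjusted_to_one(self):
        df = random_design(np.random.default_rng(19), 10, 10)
        df["global_plv"] = np.tile([1.0, 2.0, 3.0, 4.0], len(df) // 4)
        res = posthoc_pairwise(df, between="group", where={"band": "delta"}, family=5)
        assert res.p_adjusted == 1.0

    def test_separated_samples_match_exact_tail_probability(self):
        """Completely separated groups: two-sided p is twice the
        probability of the most extreme labelling, 2 / C(n, n1)."""
        for n_hc, n_pd in [(4, 5), (13, 26)]:
            rows = [
                dict(group="HC", condition="motor", band="delta", global_plv=10.0 + i)
                for i in range(n_hc)
            ] + [
                dict(group="PD", condition="motor", band="delta", global_plv=float(i) / 10)
                for i in range(n_pd)
            ]
            df = pd.DataFrame(rows)
            res = posthoc_pairwise(df, between="group", family=1)
            assert res.p_raw == pytest.approx(2 / comb(n_hc + n_pd, n_hc), rel=1e-9)

    def test_small_case_matches_brute_force_permutation(self):
        rng = np.random.default_rng(20)
        a, b = rng.normal(size=4), rng.normal(size=5)
        rows = [
            dict(group="HC", condition="motor", band="delta", global_plv=v) for v in a
        ] + [dict(group="PD", condition="motor", band="delta", global_plv=v) for v in b]
        res = posthoc_pairwise(pd.DataFrame(rows), between="group", family=1)
        pooled = np.concatenate([a, b])
        u_obs = stats.mannwhitneyu(a, b, alternative="two-sided").statistic
        n1 = len(a)
        count = 0
        total = 0
        for idx in itertools.combinations(range(len(pooled)), n1):
            x = pooled[list(idx)]
            y = np.delete(pooled, list(idx))
            u = stats.mannwhitneyu(x, y, alternative="two-sided").statistic
            mu = n1 * (len(pooled) - n1) / 2
            if abs(u - mu) >= abs(u_obs - mu) - 1e-12:
                count += 1
            total += 1
        assert res.p_raw == pytest.approx(count / total, rel=1e-9)

    def test_bonferroni_multiplication_rule(self):
        df = random_design(np.random.default_rng(21), 13, 13)
        res = posthoc_pairwise(df, between="group", where={"band": "delta"}, family=5)
        assert res.p_adjusted == pytest.approx(min(1.0, res.p_raw * 5))

    def test_empty_slice_rejected(self):
        df = random_design(np.random.default_rng(22), 3, 3)
        with pytest.raises(ValueError):
            posthoc_pairwise(df, between="group", where={"band": "nosuch"}, family=1)


class TestAuxiliaryTests:
    def test_ks_statistic_matches_brute_force_cdf_supremum(self):
        rng = np.random.default_rng(23)
        v = rng.normal(2.0, 3.0, 200)
        d, _ = ks_normality(v)
        s = np.sort(v)
        cdf = stats.norm.cdf(s, v.mean(), v.std(ddof=1))
        n = len(v)
        brute = max(
            np.max(np.arange(1, n + 1) / n - cdf), np.max(cdf - np.arange(n) / n)
        )
        assert d == pytest.approx(brute, abs=1e-12)

    def test_normal_sample_not_rejected(self):
        v = np.random.default_rng(24).normal(size=500)
        assert ks_normality(v)[1] > 0.05

    def test_exponential_sample_rejected(self):
        v = np.random.default_rng(25).exponential(size=500)
        assert ks_normality(v)[1] < 0.01

    def test_ks_degenerate_input_rejected(self):
        with pytest.raises(ValueError):
            ks_normality(np.ones(10))

    def test_spearman_monotone_and_antitone(self):
        x = np.linspace(-2, 2, 30)
        assert spearman_corr(x, np.exp(x))[0] == pytest.approx(1.0)
        assert spearman_corr(x, -x)[0] == pytest.approx(-1.0)

    def test_spearman_matches_rank_correlation_oracle(self):
        rng = np.random.default_rng(26)
        x, y = rng.normal(size=50), rng.normal(size=50)
        rho, _ = spearman_corr(x, y)
        brute = np.corrcoef(rank_midranks(x), rank_midranks(y))[0, 1]
        assert rho == pytest.approx(brute, abs=1e-12)

    def test_spearman_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            spearman_corr(np.zeros(5), np.zeros(6))
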