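"""Item analysis, reliability and validity statistics against
independent oracles (brute-force ANOVA, residualization, enumeration,
rank arithmetic, pingouin cross-checks)."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from oracles import anova_icc_a1_oracle, fisher_enumeration_oracle

from aphasiakit.psychometrics import (
    PsychometricsError,
    bonferroni_threshold,
    corrected_item_total,
    cronbach_alpha,
    fisher_exact_cutoff,
    icc_a1,
    item_passing_rates,
    kruskal_dunn_pooling,
    partial_corr_matrix,
    partial_pearson,
    pearson_matrix_bonferroni,
    welch_t,
)


class TestPassingRates:
    def test_binary_rate(self):
        m = pd.DataFrame({"i1": [1] * 17 + [0] * 3})
        assert item_passing_rates(m)["i1"] == pytest.approx(0.85)

    def test_half_point_rate(self):
        m = pd.DataFrame({"i1": [1.0, 0.5, 0.0, 0.5]})
        assert item_passing_rates(m)["i1"] == pytest.approx(0.5)

    def test_multi_point_normalized(self):
        m = pd.DataFrame({"i1": [4.0, 2.0, 0.0]})
        assert item_passing_rates(m, item_max=4.0)["i1"] == pytest.approx(0.5)

    def test_all_zero(self):
        m = pd.DataFrame({"i1": [0.0, 0.0]})
        assert item_passing_rates(m)["i1"] == 0.0


class TestCorrectedItemTotal:
    def test_worked_four_participant_matrix(self):
        m = pd.DataFrame(
            {"a": [1, 0, 1, 0], "b": [1, 0, 0, 0], "c": [1, 1, 1, 0]},
            dtype=float,
        )
        res = corrected_item_total(m)
        # oracle: Pearson of item a with b+c, computed by hand via cov/sd
        rest = (m["b"] + m["c"]).to_numpy()
        a = m["a"].to_numpy()
        r_manual = (
            np.sum((a - a.mean()) * (rest - rest.mean()))
            / np.sqrt(np.sum((a - a.mean()) ** 2) * np.sum((rest - rest.mean()) ** 2))
        )
        assert res.corrected_item_total["a"] == pytest.approx(r_manual)

    def test_coherent_item_approaches_one(self, rng):
        base = rng.normal(size=400)
        m = pd.DataFrame(
            {f"i{j}": base + rng.normal(scale=0.05, size=400) for j in range(8)}
        )
        res = corrected_item_total(m)
        assert (res.corrected_item_total > 0.95).all()

    def test_independent_item_near_zero(self, rng):
        n = 5000
        m = pd.DataFrame(rng.normal(size=(n, 6)), columns=[f"i{j}" for j in range(6)])
        shared = rng.normal(size=n)
        for j in range(5):
            m[f"i{j}"] += shared
        res = corrected_item_total(m)
        assert abs(res.corrected_item_total["i5"]) < 0.05
        assert res.flagged["i5"]

    def test_zero_variance_item_flagged_undefined(self):
        m = pd.DataFrame({"a": [1.0, 1.0, 1.0, 1.0], "b": [1, 0, 1, 0],
                          "c": [1, 1, 0, 0]})
        with pytest.warns(UserWarning, match="zero-variance"):
            res = corrected_item_total(m)
        assert res.undefined == ["a"]
        assert not res.flagged["a"]


class TestCronbachAlpha:
    def test_identical_items_alpha_one(self):
        col = [3.0, 1.0, 4.0, 1.0, 5.0]
        m = pd.DataFrame({f"i{j}": col for j in range(4)})
        assert cronbach_alpha(m).value == pytest.approx(1.0)

    def test_compound_symmetry_closed_form(self, rng):
        # items = latent + noise with known inter-item correlation r
        n, k, r = 5000, 6, 0.4
        lam = np.sqrt(r)
        latent = rng.normal(size=n)
        m = pd.DataFrame(
            {f"i{j}": lam * latent + np.sqrt(1 - r) * rng.normal(size=n)
             for j in range(k)}
        )
        expected = k * r / (1 + (k - 1) * r)
        assert cronbach_alpha(m).value == pytest.approx(expected, abs=0.02)

    def test_independent_items_near_zero(self, rng):
        m = pd.DataFrame(rng.normal(size=(4000, 5)))
        assert abs(cronbach_alpha(m).value) < 0.06

    def test_matches_pingouin(self, rng):
        pingouin = pytest.importorskip("pingouin")
        m = pd.DataFrame(rng.normal(size=(40, 5)) + rng.normal(size=(40, 1)))
        est = cronbach_alpha(m)
        val, ci = pingouin.cronbach_alpha(data=m)
        assert est.value == pytest.approx(val, abs=1e-10)
        assert est.ci_low == pytest.approx(ci[0], abs=0.01)
        assert est.ci_high == pytest.approx(ci[1], abs=0.01)

    def test_feldt_ci_brackets_estimate(self, rng):
        m = pd.DataFrame(rng.normal(size=(30, 4)) + 0.8 * rng.normal(size=(30, 1)))
        est = cronbach_alpha(m)
        assert est.ci_low <= est.value <= est.ci_high <= 1.0

    def test_zero_total_variance_rejected(self):
        m = pd.DataFrame({"a": [1.0] * 5, "b": [2.0] * 5})
        with pytest.raises(PsychometricsError):
            with pytest.warns(UserWarning):
                cronbach_alpha(m)




class TestICC:
    def test_identical_columns(self):
        x = pd.DataFrame({"r1": [1.0, 5, 3, 4, 2, 0], "r2": [1.0, 5, 3, 4, 2, 0]})
        assert icc_a1(x).value == pytest.approx(1.0)

    def test_constant_shift_penalized_and_matches_anova(self):
        c1 = np.array([10.0, 20, 30, 40, 50, 60])
        x = np.column_stack([c1, c1 + 5.0])
        est = icc_a1(x)
        assert est.value < 1.0
        assert est.value == pytest.approx(anova_icc_a1_oracle(x), abs=1e-12)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_anova_on_random_fixtures(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 21))
        k = int(rng.integers(2, 4))
        x = rng.normal(size=(n, k)) + rng.normal(size=(n, 1))
        assert icc_a1(x).value == pytest.approx(anova_icc_a1_oracle(x), abs=1e-12)

    def test_independent_noise_near_zero(self, rng):
        x = rng.normal(size=(500, 2))
        assert abs(icc_a1(x).value) < 0.1

    def test_matches_pingouin_icc2(self, rng):
        pingouin = pytest.importorskip("pingouin")
        n = 20
        scores = rng.normal(size=(n, 3)) + 2 * rng.normal(size=(n, 1))
        est = icc_a1(scores)
        long = pd.DataFrame(
            {
                "subject": np.repeat(np.arange(n), 3),
                "rater": np.tile(np.arange(3), n),
                "score": scores.ravel(),
            }
        )
        icc = pingouin.intraclass_corr(
            data=long, targets="subject", raters="rater", ratings="score"
        ).set_index("Type")
        row = icc.loc["ICC(A,1)"] if "ICC(A,1)" in icc.index else icc.loc["ICC2"]
        assert est.value == pytest.approx(row["ICC"], abs=1e-8)
        ci_col = "CI95%" if "CI95%" in icc.columns else "CI95"
        lo, hi = row[ci_col]  # pingouin prints the CI rounded to 2 dp
        assert est.ci_low == pytest.approx(lo, abs=0.006)
        assert est.ci_high == pytest.approx(hi, abs=0.006)

    def test_zero_between_subject_variance(self):
        x = pd.DataFrame({"r1": [1.0, 1.0, 1.0], "r2": [1.0, 1.0, 1.0]})
        with pytest.raises(PsychometricsError):
            icc_a1(x)


class TestCorrelationMatrices:
    def test_duplicated_column_r_one(self, rng):
        df = pd.DataFrame(rng.normal(size=(30, 3)), columns=["a", "b", "c"])
        df["d"] = df["a"]
        res = pearson_matrix_bonferroni(df)
        assert res.r.loc["a", "d"] == pytest.approx(1.0)
        assert np.allclose(res.r, res.r.T)

    def test_family_threshold_for_13_subtests(self):
        df = pd.DataFrame(np.random.default_rng(0).normal(size=(20, 13)))
        res = pearson_matrix_bonferroni(df)
        assert res.alpha_family == pytest.approx(0.05 / 78)
        assert round(res.alpha_family, 4) == 0.0006

    def test_familywise_error_controlled_under_null(self, rng):
        # independent columns: P(any of 78 flags) should stay near .05
        n_reps, hits = 400, 0
        for _ in range(n_reps):
            df = pd.DataFrame(rng.normal(size=(85, 13)))
            hits += bool(pearson_matrix_bonferroni(df).significant.to_numpy().any())
        assert hits / n_reps <= 0.05 + 3 * np.sqrt(0.05 * 0.95 / n_reps)

    def test_flag_count_non_increasing_in_family_size(self, rng):
        shared = rng.normal(size=(60, 1))
        df = pd.DataFrame(rng.normal(size=(60, 8)) + shared)
        res = pearson_matrix_bonferroni(df)
        counts = []
        for family in (8, 28, 78, 200):
            thresh = bonferroni_threshold(family)
            counts.append(int((res.p.to_numpy() < thresh).sum()) - df.shape[1])
        assert counts == sorted(counts, reverse=True)

    def test_pairwise_complete_counts(self, rng):
        df = pd.DataFrame(rng.normal(size=(20, 3)), columns=["a", "b", "c"])
        df.loc[:4, "b"] = np.nan
        res = pearson_matrix_bonferroni(df)
        assert res.n.loc["a", "b"] == 15
        assert res.n.loc["a", "c"] == 20


class TestPartialCorrelation:
    def test_residualization_oracle(self, rng):
        x = rng.normal(size=50)
        z = rng.normal(size=50)
        y = 0.5 * x + 0.8 * z + rng.normal(size=50)
        r_formula, _, _ = partial_pearson(x, y, z)
        # oracle: correlate least-squares residuals
        def resid(v):
            beta = np.polyfit(z, v, 1)
            return v - np.polyval(beta, z)
        r_resid = stats.pearsonr(resid(x), resid(y)).statistic
        assert r_formula == pytest.approx(r_resid, abs=1e-10)

    def test_covariate_explains_everything(self, rng):
        z = rng.normal(size=2000)
        x = z + rng.normal(scale=0.3, size=2000)
        y = z + rng.normal(scale=0.3, size=2000)
        r, _, _ = partial_pearson(x, y, z)
        assert abs(r) < 0.06

    def test_independent_covariate_leaves_r(self, rng):
        shared = rng.normal(size=3000)
        x = shared + rng.normal(size=3000)
        y = shared + rng.normal(size=3000)
        z = rng.normal(size=3000)
        raw = stats.pearsonr(x, y).statistic
        r, _, _ = partial_pearson(x, y, z)
        assert r == pytest.approx(raw, abs=0.03)

    def test_matrix_wrapper_symmetry_and_family(self, rng):
        df = pd.DataFrame(rng.normal(size=(40, 4)), columns=list("abcd"))
        cov = pd.Series(rng.normal(size=40), index=df.index)
        res = partial_corr_matrix(df, cov)
        assert np.allclose(res.r, res.r.T)
        assert res.alpha_family == pytest.approx(0.05 / 6)

    def test_collinear_covariate_rejected(self, rng):
        z = rng.normal(size=30)
        with pytest.raises(PsychometricsError):
            partial_pearson(z.copy(), rng.normal(size=30), z)


class TestWelchAndBonferroni:
    def test_identical_groups(self):
        t, df, p = welch_t([1.0, 2, 3, 4], [1.0, 2, 3, 4])
        assert t == 0.0 and p == pytest.approx(1.0)

    def test_matches_scipy_satterthwaite(self, rng):
        a, b = rng.normal(0, 1, 15), rng.normal(1, 3, 25)
        t, df, p = welch_t(a, b)
        ref = stats.ttest_ind(a, b, equal_var=False)
        assert (t, p) == pytest.approx((ref.statistic, ref.pvalue))

    @pytest.mark.parametrize(
        "family, printed", [(13, 0.0038), (26, 0.0019), (78, 0.0006)]
    )
    def test_printed_thresholds(self, family, printed):
        assert round(bonferroni_threshold(family), 4) == printed

    def test_degenerate_variance(self):
        with pytest.raises(PsychometricsError):
            welch_t([1.0, 1.0], [1.0, 1.0])




class TestFisherExact:
    def test_no_association(self):
        assert fisher_exact_cutoff([[5, 5], [5, 5]]) == pytest.approx(1.0)

    @pytest.mark.parametrize(
        "table",
        [[[10, 0], [0, 10]], [[7, 1], [2, 6]], [[3, 9], [5, 2]], [[1, 4], [6, 1]]],
    )
    def test_matches_enumeration(self, table):
        assert fisher_exact_cutoff(table) == pytest.approx(
            fisher_enumeration_oracle(table), abs=1e-12
        )

    def test_invariant_under_transposition(self):
        t = [[7, 2], [3, 8]]
        assert fisher_exact_cutoff(t) == pytest.approx(
            fisher_exact_cutoff([list(r) for r in np.transpose(t)])
        )

    def test_empty_margin_rejected(self):
        with pytest.raises(PsychometricsError):
            fisher_exact_cutoff([[0, 0], [3, 4]])


class TestKruskalDunnPooling:
    def test_identical_groups_merge_all(self):
        g = {"g1": [1.0, 2, 3, 4, 5], "g2": [1.0, 2, 3, 4, 5], "g3": [1.0, 2, 3, 4, 5]}
        res = kruskal_dunn_pooling(g)
        assert res.h == pytest.approx(0.0, abs=1e-9)
        assert sorted(map(sorted, res.merge_groups)) == [["g1", "g2", "g3"]]

    def test_separated_group_isolated(self, rng):
        g = {
            "young1": rng.normal(98, 1.5, 30).tolist(),
            "young2": rng.normal(98, 1.5, 30).tolist(),
            "old": rng.normal(80, 1.5, 30).tolist(),
        }
        res = kruskal_dunn_pooling(g)
        merged = sorted(map(sorted, res.merge_groups))
        assert ["old"] in merged
        assert ["young1", "young2"] in merged

    def test_h_matches_rank_arithmetic_oracle(self):
        g = {"a": [1.0, 3.0, 5.0], "b": [2.0, 4.0, 6.0], "c": [10.0, 11.0, 12.0]}
        res = kruskal_dunn_pooling(g)
        # oracle: H = 12/(N(N+1)) * sum n_i (Rbar_i - Rbar)^2, no ties
        pooled = sorted(sum(g.values(), []))
        ranks = {v: i + 1 for i, v in enumerate(pooled)}
        n = len(pooled)
        h = 12.0 / (n * (n + 1)) * sum(
            len(v) * (np.mean([ranks[x] for x in v]) - (n + 1) / 2) ** 2
            for v in g.values()
        )
        assert res.h == pytest.approx(h, abs=1e-9)

    def test_small_group_rejected(self):
        with pytest.raises(PsychometricsError):
            kruskal_dunn_pooling({"a": [1.0], "b": [1.0, 2.0]})
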