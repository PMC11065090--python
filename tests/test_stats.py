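import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

import shgmorph as sm
from shgmorph.stats import roc_analysis, spearman_correlations


class TestTotalEoehss:
    def test_bounds(self):
        base = dict(sample_id="s", group="aEoE", pec=20)
        zeros = sm.HistopathologyScores(**base)
        assert zeros.total_eoehss == 0.0
        threes = sm.HistopathologyScores(**base, **{f: 3 for f in sm.EOEHSS_FEATURES})
        assert threes.total_eoehss == 3.0

    def test_mean_of_assessed_features(self):
        grades = (2, 3, 1, 1, 3, 0, 0, 2)
        assert sm.total_eoehss(grades) == pytest.approx(1.5)

    def test_missing_features_reduce_denominator(self):
        assert sm.total_eoehss([3.0, np.nan, np.nan, 1.0]) == pytest.approx(2.0)
        with pytest.raises(ValueError):
            sm.total_eoehss([np.nan])

    def test_invalid_grade_rejected(self):
        with pytest.raises(ValueError):
            sm.HistopathologyScores(sample_id="s", group="aEoE", pec=1, ei=4)
        with pytest.raises(ValueError):
            sm.HistopathologyScores(sample_id="s", group="bad", pec=1)


class TestAnovaTukey:
    def test_identical_groups_null(self):
        vals = np.r_[[1.0, 2, 3, 4]]
        values = np.r_[vals, vals, vals]
        groups = np.r_[["a"] * 4, ["b"] * 4, ["c"] * 4]
        comp = sm.anova_tukey(values, groups)
        assert comp.f_statistic == pytest.approx(0.0, abs=1e-12)
        assert all(p == pytest.approx(1.0) for p in comp.pairwise_p.values())

    def test_strong_separation(self):
        rng = np.random.default_rng(0)
        values = np.r_[
            rng.normal(0, 0.01, 4), rng.normal(10, 0.01, 4), rng.normal(0, 0.01, 4)
        ]
        groups = np.r_[["a"] * 4, ["b"] * 4, ["c"] * 4]
        comp = sm.anova_tukey(values, groups)
        assert comp.pairwise_p[("a", "b")] < 1e-6
        assert comp.pairwise_p[("b", "c")] < 1e-6
        assert comp.pairwise_p[("a", "c")] > 0.05

    def test_small_group_rejected(self):
        with pytest.raises(ValueError):
            sm.anova_tukey([1.0, 2.0, 3.0], ["a", "a", "b"])

    def test_zero_variance_flagged(self):
        comp = sm.anova_tukey([1.0, 1, 2, 2], ["a", "a", "b", "b"])
        assert "zero_within_group_variance" in comp.flags

    def test_adjusted_p_at_least_unadjusted(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            a, b, c = rng.normal(0, 1, (3, 8)) + rng.normal(0, 0.5, 3)[:, None]
            comp = sm.anova_tukey(
                np.r_[a, b, c], np.r_[["a"] * 8, ["b"] * 8, ["c"] * 8]
            )
            # the unadjusted contrast t-test sharing Tukey's pooled MSE and
            # error df is never above the Tukey-adjusted p
            data = np.r_[a, b, c]
            mse = sum(((x - x.mean()) ** 2).sum() for x in (a, b, c)) / (24 - 3)
            for (g1, g2), arr1, arr2 in [(("a", "b"), a, b), (("a", "c"), a, c), (("b", "c"), b, c)]:
                t = abs(arr1.mean() - arr2.mean()) / np.sqrt(mse * 2 / 8)
                t_p = 2 * sps.t.sf(t, 24 - 3)
                assert comp.pairwise_p[(g1, g2)] >= t_p - 1e-10

    def test_matches_permutation_studentized_range(self):
        # permutation null of the maximum studentized range statistic,
        # small version of the full oracle comparison
        rng = np.random.default_rng(1)
        n, k = 11, 3
        values = rng.normal(0, 1, n * k)
        values[:n] += 1.0
        groups = np.r_[["a"] * n, ["b"] * n, ["c"] * n]
        comp = sm.anova_tukey(values, groups)
        p_perm = _permutation_tukey_p(values, n, k, ("a", "b"), rng, n_perm=4000)
        assert comp.pairwise_p[("a", "b")] == pytest.approx(p_perm, abs=0.04)


def _permutation_tukey_p(values, n, k, contrast, rng, n_perm=4000):
    """P(max studentized range >= observed q of the contrast) by permutation."""
    values = np.asarray(values, float)
    groups = np.repeat(np.arange(k), n)
    means = np.array([values[groups == g].mean() for g in range(k)])
    sse = sum(((values[groups == g] - means[g]) ** 2).sum() for g in range(k))
    mse = sse / (len(values) - k)
    idx = {"a": 0, "b": 1, "c": 2}
    q_obs = abs(means[idx[contrast[0]]] - means[idx[contrast[1]]]) / np.sqrt(mse / n)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(values)
        m = perm.reshape(k, n).mean(axis=1)
        sse_p = ((perm.reshape(k, n) - m[:, None]) ** 2).sum()
        q_max = (m.max() - m.min()) / np.sqrt(sse_p / (len(values) - k) / n)
        count += q_max >= q_obs
    return count / n_perm


class TestSpearman:
    @staticmethod
    def _corr_frames(x, y):
        mx = pd.DataFrame({"sample_id": np.arange(len(x)), "m": x})
        hy = pd.DataFrame({"sample_id": np.arange(len(x)), "s": y})
        return spearman_correlations(mx, hy, metric_cols=["m"], score_cols=["s"])

    def test_monotone_extremes(self):
        x = np.arange(10.0)
        up = self._corr_frames(x, np.exp(x))
        down = self._corr_frames(x, -np.exp(x))
        assert up.r.iloc[0] == pytest.approx(1.0)
        assert down.r.iloc[0] == pytest.approx(-1.0)

    def test_ties_equal_rank_pearson(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            x = rng.integers(0, 4, 15).astype(float)
            y = rng.integers(0, 6, 15).astype(float)
            if np.all(x == x[0]) or np.all(y == y[0]):
                continue
            got = self._corr_frames(x, y).r.iloc[0]
            expected = np.corrcoef(sps.rankdata(x), sps.rankdata(y))[0, 1]
            assert got == pytest.approx(expected, abs=1e-12)

    def test_invariance_under_monotone_transform(self):
        rng = np.random.default_rng(3)
        x = rng.normal(0, 1, 20)
        y = rng.normal(0, 1, 20)
        r1 = self._corr_frames(x, y).r.iloc[0]
        r2 = self._corr_frames(np.exp(2 * x), y**3).r.iloc[0]
        # monotone transform of x only; y**3 is monotone as well
        assert r1 == pytest.approx(r2, abs=1e-12)

    def test_constant_vector_flagged(self):
        out = self._corr_frames(np.ones(8), np.arange(8.0))
        assert np.isnan(out.r.iloc[0])
        assert "constant_input" in out["flags"].iloc[0]

    def test_permutation_p_close_to_t_approximation(self):
        rng = np.random.default_rng(4)
        x = rng.normal(0, 1, 11)
        y = 0.8 * x + rng.normal(0, 0.6, 11)
        mx = pd.DataFrame({"sample_id": np.arange(11), "m": x})
        hy = pd.DataFrame({"sample_id": np.arange(11), "s": y})
        p_t = spearman_correlations(mx, hy, metric_cols=["m"], score_cols=["s"]).p.iloc[0]
        p_perm = spearman_correlations(
            mx, hy, metric_cols=["m"], score_cols=["s"], method="permutation", seed=0
        ).p.iloc[0]
        assert p_perm == pytest.approx(p_t, abs=0.05)


class TestRoc:
    def test_perfect_separation(self):
        rep = roc_analysis([1, 2, 3, 10, 11, 12], [0, 0, 0, 1, 1, 1])
        assert rep.auc == 1.0
        assert rep.sensitivity_pct == 100.0
        assert rep.specificity_pct == 100.0
        assert 3 < rep.threshold < 10  # midpoint between classes

    def test_null_auc_near_half(self):
        rng = np.random.default_rng(0)
        v = rng.normal(0, 1, 500)
        y = rng.random(500) < 0.5
        rep = roc_analysis(v, y)
        assert rep.auc == pytest.approx(0.5, abs=0.05)

    def test_auc_equals_mann_whitney(self):
        rng = np.random.default_rng(1)
        for _ in range(100):
            n1, n0 = rng.integers(5, 20, 2)
            pos = rng.normal(0.5, 1, n1)
            neg = rng.normal(0, 1, n0)
            rep = roc_analysis(np.r_[pos, neg], np.r_[np.ones(n1, bool), np.zeros(n0, bool)])
            u = sum((p > n) for p in pos for n in neg)
            assert rep.auc == pytest.approx(u / (n1 * n0), abs=1e-12)

    def test_label_flip_mirrors_auc(self):
        rng = np.random.default_rng(2)
        v = rng.normal(0, 1, 40)
        y = rng.random(40) < 0.5
        a1 = roc_analysis(v, y).auc
        a2 = roc_analysis(v, ~y).auc
        assert a1 + a2 == pytest.approx(1.0, abs=1e-12)

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(3)
        v = rng.normal(0, 1, 30)
        y = rng.random(30) < 0.5
        assert roc_analysis(v, y).auc == pytest.approx(roc_analysis(np.exp(v), y).auc, abs=1e-12)

    def test_max_specificity_rule(self):
        v = [1, 2, 3, 4, 2.5, 5, 6, 7]
        y = [0, 0, 0, 0, 1, 1, 1, 1]
        rep = roc_analysis(v, y, threshold_rule="max_specificity")
        assert rep.specificity_pct == 100.0
        assert rep.sensitivity_pct == 75.0

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_analysis([1.0, 2.0], [True, True])


class TestCohortAnalysis:
    def _tables(self, rng):
        n = 33
        groups = np.r_[["aEoE"] * 11, ["iEoE"] * 11, ["nonEoE"] * 11]
        sev = np.r_[rng.normal(2, 0.7, 11), rng.normal(0.3, 0.5, 11), rng.normal(0, 0.5, 11)]
        results = pd.DataFrame(
            {
                "sample_id": [f"s{i}" for i in range(n)],
                "group": groups,
                "mean_pore_area_um2": 32 + 8 * sev + rng.normal(0, 2, n),
                "pore_density_per_mm2": 14000 - 2000 * sev + rng.normal(0, 500, n),
                "mean_fiber_width_um": 2.04 + 0.04 * sev + rng.normal(0, 0.02, n),
            }
        )
        histo = pd.DataFrame({"sample_id": results.sample_id, "group": groups,
                              "pec": np.maximum(0, (sev * 30 + rng.normal(0, 5, n))).astype(int)})
        for f in sm.EOEHSS_FEATURES:
            histo[f] = np.clip(np.round(sev + rng.normal(0, 0.4, n)), 0, 3).astype(int)
        return results, histo

    def test_report_structure_and_signs(self):
        results, histo = self._tables(np.random.default_rng(0))
        rep = sm.run_cohort_analysis(results, histo)
        by_metric = {c.metric: c for c in rep.comparisons}
        assert by_metric["mean_pore_area_um2"].pairwise_p[("aEoE", "iEoE")] < 0.005
        corr = rep.correlations.set_index(["metric", "score"])
        assert corr.loc[("mean_pore_area_um2", "pec"), "r"] > 0
        assert corr.loc[("pore_density_per_mm2", "pec"), "r"] < 0
        assert {r.contrast for r in rep.rocs} == {"aEoE_vs_iEoE", "aEoE_vs_nonEoE"}

    def test_unjoinable_ids_raise(self):
        results, histo = self._tables(np.random.default_rng(1))
        with pytest.raises(ValueError, match="unjoinable"):
            sm.run_cohort_analysis(results, histo.iloc[:-2])
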