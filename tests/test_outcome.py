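"""Survival, composition and concordance statistics."""

import numpy as np
import pandas as pd
import pytest

from conftest import km_oracle, logrank_oracle
from graftstates import (
    CompositionTable,
    arcsin_moderated_ttest,
    composition_ttests,
    kaplan_meier,
    log2fc_concordance,
    logrank_test,
    survival_by_score,
)
from graftstates.dge import DEResult
from graftstates.outcome import apply_horizon


class TestKaplanMeier:
    def test_no_events_is_flat_one(self):
        km = kaplan_meier([1.0, 2.0, 3.0], [0, 0, 0])
        assert (km["survival"] == 1.0).all()

    def test_all_events_no_censoring(self):
        km = kaplan_meier([1.0, 2.0, 3.0], [1, 1, 1])
        np.testing.assert_allclose(km["survival"], [2 / 3, 1 / 3, 0.0])

    def test_all_censored_with_at_risk_decreasing(self):
        km = kaplan_meier([5.0, 5.0, 5.0], [0, 0, 0])
        assert (km["survival"] == 1.0).all()
        assert km["at_risk"].iloc[0] == 3

    def test_horizon_truncation(self):
        times, events = apply_horizon([10.0, 40.0, 50.0], [1, 1, 0], 36.0)
        np.testing.assert_allclose(times, [10.0, 36.0, 36.0])
        np.testing.assert_array_equal(events, [1, 0, 0])

    @pytest.mark.parametrize("seed", range(25))
    def test_matches_hand_product_limit_small_instances(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(1, 11))
        times = rng.integers(1, 6, size=n).astype(float)
        events = rng.integers(0, 2, size=n)
        km = kaplan_meier(times, events)
        oracle = dict(km_oracle(times, events))
        for _, row in km.iterrows():
            assert row["survival"] == pytest.approx(oracle[row["time"]])

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            kaplan_meier([], [])


class TestLogrank:
    def test_identical_groups_null(self):
        t = [1.0, 2.0, 3.0]
        e = [1, 0, 1]
        stat, p = logrank_test(t, e, t, e)
        assert stat == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_zero_events_defined_null(self):
        stat, p = logrank_test([1.0, 2.0], [0, 0], [3.0], [0])
        assert (stat, p) == (0.0, 1.0)

    def test_single_event_time_matches_hand_computation(self):
        ta, ea = [1.0], [1]
        tb, eb = [2.0], [0]
        stat, p = logrank_test(ta, ea, tb, eb)
        stat_o, p_o = logrank_oracle(ta, ea, tb, eb)
        assert stat == pytest.approx(stat_o)
        assert p == pytest.approx(p_o)

    @pytest.mark.parametrize("seed", range(15))
    def test_matches_hand_logrank_random_instances(self, seed):
        rng = np.random.default_rng(300 + seed)
        na, nb = int(rng.integers(3, 12)), int(rng.integers(3, 12))
        ta = rng.integers(1, 8, na).astype(float)
        tb = rng.integers(1, 8, nb).astype(float)
        ea, eb = rng.integers(0, 2, na), rng.integers(0, 2, nb)
        if ea.sum() + eb.sum() == 0:
            ea[0] = 1
        stat, p = logrank_test(ta, ea, tb, eb)
        stat_o, p_o = logrank_oracle(ta, ea, tb, eb)
        assert stat == pytest.approx(stat_o, rel=1e-9)
        assert p == pytest.approx(p_o, rel=1e-9)

    def test_invariant_to_monotone_time_transform(self):
        rng = np.random.default_rng(4)
        ta, tb = rng.exponential(10, 20), rng.exponential(6, 20)
        ea, eb = rng.integers(0, 2, 20), rng.integers(0, 2, 20)
        s1 = logrank_test(ta, ea, tb, eb)
        s2 = logrank_test(np.sqrt(ta), ea, np.sqrt(tb), eb)
        assert s1[0] == pytest.approx(s2[0], rel=1e-9)


class TestCompositionTests:
    def test_hand_pooled_t(self):
        table = CompositionTable(
            pd.DataFrame(
                {"x": [0.1, 0.2, 0.3, 0.4, 0.5, 0.6],
                 "y": [0.9, 0.8, 0.7, 0.6, 0.5, 0.4]},
                index=[f"s{i}" for i in range(6)],
            )
        )
        groups = pd.Series(["a"] * 3 + ["b"] * 3, index=table.proportions.index)
        out = composition_ttests(table, groups)
        xa, xb = np.array([0.1, 0.2, 0.3]), np.array([0.4, 0.5, 0.6])
        sp2 = (xa.var(ddof=1) * 2 + xb.var(ddof=1) * 2) / 4
        t_hand = (xa.mean() - xb.mean()) / np.sqrt(sp2 * (2 / 3))
        assert out.loc["x", "t"] == pytest.approx(t_hand)

    def test_degenerate_type_is_null(self):
        table = CompositionTable(
            pd.DataFrame({"x": [0.5] * 4, "y": [0.5] * 4},
                         index=[f"s{i}" for i in range(4)])
        )
        groups = pd.Series(["a", "a", "b", "b"], index=table.proportions.index)
        out = composition_ttests(table, groups)
        assert (out["p"] == 1.0).all()
        assert out["degenerate"].all()

    def test_row_sum_validation(self):
        with pytest.raises(ValueError, match="sum to 1"):
            CompositionTable(pd.DataFrame({"x": [0.5], "y": [0.4]}))


class TestModeratedT:
    @staticmethod
    def _table(rng, n_samples=10, n_types=8):
        raw = rng.dirichlet(np.ones(n_types), size=n_samples)
        return CompositionTable(
            pd.DataFrame(raw, index=[f"s{i}" for i in range(n_samples)],
                         columns=[f"t{j}" for j in range(n_types)])
        )

    def test_transform_endpoints(self):
        assert np.arcsin(np.sqrt(0.0)) == 0.0
        assert np.arcsin(np.sqrt(1.0)) == pytest.approx(np.pi / 2)

    def test_no_shrinkage_equals_ordinary_t(self, rng):
        table = self._table(rng)
        groups = pd.Series(["a"] * 5 + ["b"] * 5, index=table.proportions.index)
        out = arcsin_moderated_ttest(table, groups, prior_df=0)
        y = np.arcsin(np.sqrt(table.proportions.to_numpy()))
        from scipy import stats

        t_ref, p_ref = stats.ttest_ind(y[:5], y[5:], equal_var=True)
        np.testing.assert_allclose(out["t"], t_ref, atol=1e-10)
        np.testing.assert_allclose(out["p"], p_ref, atol=1e-10)

    def test_infinite_prior_uses_prior_variance_only(self, rng):
        table = self._table(rng)
        groups = pd.Series(["a"] * 5 + ["b"] * 5, index=table.proportions.index)
        out = arcsin_moderated_ttest(table, groups, prior_df=np.inf)
        assert out["s2_posterior"].nunique() == 1

    def test_out_of_range_proportions_rejected(self):
        table = CompositionTable(
            pd.DataFrame({"x": [0.5, 0.5], "y": [0.5, 0.5]}, index=["a", "b"])
        )
        table.proportions.iloc[0, 0] = 1.2
        table.proportions.iloc[0, 1] = -0.2
        groups = pd.Series(["a", "b"], index=table.proportions.index)
        with pytest.raises(ValueError):
            arcsin_moderated_ttest(table, groups)

    def test_null_type_i_error_calibrated(self):
        """Equal-group Dirichlet proportions: rejections at alpha=0.05
        stay near nominal across replicates."""
        hits = trials = 0
        for rep in range(200):
            rng = np.random.default_rng(1000 + rep)
            table = self._table(rng, n_samples=12, n_types=6)
            groups = pd.Series(["a"] * 6 + ["b"] * 6,
                               index=table.proportions.index)
            out = arcsin_moderated_ttest(table, groups)
            hits += int((out["p"] < 0.05).sum())
            trials += len(out)
        rate = hits / trials
        assert 0.02 <= rate <= 0.08


class TestSurvivalByScore:
    def test_single_set_fdr_equals_p(self):
        from conftest import make_cohort  # noqa: F401  (fixture import side)
        from graftstates.simulate import default_config, simulate_bulk_cohort
        from graftstates import score_samples

        config = default_config(11)
        sets = [("PT Injury 2", [f"gene{i:04d}" for i in range(20)])]
        cohort, _ = simulate_bulk_cohort(config, sets)
        scores = score_samples(cohort, sets)
        res = survival_by_score(cohort, scores, letters=False)
        row = res.tests.iloc[0]
        if row["tested"]:
            assert row["fdr"] == pytest.approx(row["p"])

    def test_full_population_median_crossed_with_diagnosis(self):
        from graftstates.simulate import default_config, simulate_bulk_cohort
        from graftstates import score_samples

        config = default_config(3)
        sets = [("PT Injury 2", [f"gene{i:04d}" for i in range(20)])]
        cohort, _ = simulate_bulk_cohort(config, sets)
        scores = score_samples(cohort, sets)
        res = survival_by_score(cohort, scores)
        row = res.tests.iloc[0]
        # within-diagnosis strata need not split in half: the median is
        # computed over the full cohort
        first = cohort.first_biopsies()
        n_tcmr = int((first["diagnosis"] == "TCMR").sum())
        assert row["n_above"] + row["n_below"] == n_tcmr
        assert ("PT Injury 2", "NR", "below") in res.km_curves
        assert set(res.letters["PT Injury 2"]) <= {
            f"{d}:{s}" for d in ("TCMR", "NR") for s in ("above", "below")
        }


class TestConcordance:
    @staticmethod
    def _de(log2fc: pd.Series) -> DEResult:
        table = pd.DataFrame(
            {"log2fc": log2fc, "p": 0.5, "padj": 0.5, "frac_a": 0.5,
             "frac_b": 0.5, "direction": np.sign(log2fc)},
        )
        return DEResult(table=table)

    def test_self_and_sign_flip(self, rng):
        fc = pd.Series(rng.normal(0, 2, 600),
                       index=[f"g{i}" for i in range(600)])
        de = self._de(fc)
        assert log2fc_concordance(de, de).rho == pytest.approx(1.0)
        assert log2fc_concordance(de, self._de(-fc)).rho == pytest.approx(-1.0)

    def test_independent_null_near_zero(self, rng):
        idx = [f"g{i}" for i in range(1000)]
        a = self._de(pd.Series(rng.normal(size=1000), index=idx))
        b = self._de(pd.Series(rng.normal(size=1000), index=idx))
        assert abs(log2fc_concordance(a, b).rho) < 0.1

    def test_monotone_transform_invariance(self, rng):
        idx = [f"g{i}" for i in range(400)]
        fa = pd.Series(rng.normal(size=400), index=idx)
        fb = pd.Series(rng.normal(size=400), index=idx)
        base = log2fc_concordance(self._de(fa), self._de(fb), top_n=100)
        warped = log2fc_concordance(
            self._de(fa.rank() / 10.0), self._de(np.tanh(fb)), top_n=100
        )
        # monotone transforms keep every rank, hence rho, once the same
        # genes are selected; ranks select the same top/bottom sets
        assert warped.rho == pytest.approx(base.rho, abs=1e-12)

    def test_too_few_shared_genes_rejected(self, rng):
        a = self._de(pd.Series(rng.normal(size=30),
                               index=[f"a{i}" for i in range(30)]))
        b = self._de(pd.Series(rng.normal(size=30),
                               index=[f"b{i}" for i in range(30)]))
        with pytest.raises(ValueError, match="shared genes"):
            log2fc_concordance(a, b)
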