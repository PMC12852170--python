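"""Differential-expression kernels: normalization, Wilcoxon, BH, filters."""

import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import bh_oracle, make_cohort, wilcoxon_perm_oracle
from graftstates import (
    CellCohort,
    apply_de_filters,
    benjamini_hochberg,
    lognormalize,
    wilcoxon_de,
    wilcoxon_rank_sum_p,
)


def _tiny_cohort(counts, clusters=None):
    counts = np.asarray(counts)
    n, g = counts.shape
    cells = pd.Index([f"c{i}" for i in range(n)])
    obs = pd.DataFrame(
        {
            "cluster": clusters or ["x"] * n,
            "sample": ["s"] * n,
            "group": ["g"] * n,
        },
        index=cells,
    )
    return CellCohort(
        counts=sp.csr_matrix(counts),
        genes=pd.Index([f"g{j}" for j in range(g)]),
        cells=cells,
        obs=obs,
    )


class TestLognormalize:
    def test_closed_form(self):
        cohort = _tiny_cohort([[10, 9990]])
        norm = lognormalize(cohort, scale=10_000)
        assert norm.dense()[0, 0] == pytest.approx(np.log(11))

    def test_zeros_preserved_and_depth_invariance(self):
        cohort = _tiny_cohort([[0, 5, 5], [0, 10, 10]])
        norm = lognormalize(cohort)
        vals = norm.dense()
        assert vals[0, 0] == 0.0 and vals[1, 0] == 0.0
        # doubling all counts of a cell leaves normalized values unchanged
        np.testing.assert_allclose(vals[0], vals[1])

    def test_zero_depth_cell_rejected(self):
        cohort = _tiny_cohort([[1, 1], [0, 0]])
        with pytest.raises(ValueError, match="c1"):
            lognormalize(cohort)


class TestWilcoxon:
    def test_exact_example_no_ties(self):
        # A = {3,4,5}, B = {0,0,0}: most extreme of the C(6,3)=20 splits,
        # but B's zeros tie with each other -> still p = 2/20 = 0.1
        p = wilcoxon_rank_sum_p(np.array([3.0, 4.0, 5.0]), np.array([0.0, 0.0, 0.0]))
        assert p == pytest.approx(0.1)

    def test_identical_multisets_give_p_one(self):
        x = np.array([1.0, 2.0, 3.0, 3.0])
        assert wilcoxon_rank_sum_p(x, x) == pytest.approx(1.0)

    @pytest.mark.parametrize("trial", range(40))
    def test_matches_exhaustive_permutation_small_groups(self, trial):
        rng = np.random.default_rng(500 + trial)
        n_a = int(rng.integers(1, 7))
        n_b = int(rng.integers(1, 13 - n_a - 1))
        # integer values force ties regularly
        xa = rng.integers(0, 4, size=n_a).astype(float)
        xb = rng.integers(0, 4, size=n_b).astype(float)
        assert wilcoxon_rank_sum_p(xa, xb) == pytest.approx(
            wilcoxon_perm_oracle(xa, xb), abs=1e-12
        )

    def test_de_antisymmetry(self, rng):
        cohort = make_cohort(rng, n_cells=40, n_genes=12)
        norm = lognormalize(cohort)
        a, b = cohort.cells[:18], cohort.cells[18:]
        de_ab = wilcoxon_de(norm, a, b)
        de_ba = wilcoxon_de(norm, b, a)
        np.testing.assert_allclose(
            de_ab.table["log2fc"], -de_ba.table["log2fc"], atol=1e-12
        )
        np.testing.assert_allclose(de_ab.table["p"], de_ba.table["p"], atol=1e-12)

    def test_overlapping_groups_rejected(self, rng):
        cohort = make_cohort(rng, n_cells=20, n_genes=5)
        norm = lognormalize(cohort)
        with pytest.raises(ValueError, match="overlap"):
            wilcoxon_de(norm, cohort.cells[:10], cohort.cells[5:])

    def test_all_zero_gene_is_null(self, rng):
        counts = rng.poisson(3.0, size=(30, 4))
        counts[:, 2] = 0
        cohort = _tiny_cohort(counts)
        norm = lognormalize(cohort)
        de = wilcoxon_de(norm, cohort.cells[:15], cohort.cells[15:])
        assert de.table["p"].iloc[2] == 1.0
        assert de.table["log2fc"].iloc[2] == 0.0

    def test_scale_shift_moves_log2fc(self, rng):
        """Multiplying group-A linear expression by 2^k shifts log2FC ~ k
        once means dominate the pseudocount."""
        counts = rng.poisson(40.0, size=(60, 6)) + 20
        cohort = _tiny_cohort(counts)
        norm = lognormalize(cohort)
        a, b = cohort.cells[:30], cohort.cells[30:]
        base = wilcoxon_de(norm, a, b).table["log2fc"]
        dense = np.asarray(norm.values.todense())
        dense[:30] = np.log1p(np.expm1(dense[:30]) * 4.0)  # k = 2
        norm2 = type(norm)(values=sp.csr_matrix(dense), genes=norm.genes,
                           cells=norm.cells, scale=norm.scale)
        shifted = wilcoxon_de(norm2, a, b).table["log2fc"]
        assert np.all(np.abs((shifted - base) - 2.0) < 0.15)


class TestBenjaminiHochberg:
    def test_hand_example(self):
        np.testing.assert_allclose(
            benjamini_hochberg(np.array([0.01, 0.02, 0.03])), [0.03, 0.03, 0.03]
        )

    def test_single_and_tied(self):
        assert benjamini_hochberg(np.array([0.2]))[0] == pytest.approx(0.2)
        np.testing.assert_allclose(
            benjamini_hochberg(np.full(5, 0.04)), np.full(5, 0.04)
        )

    def test_matches_oracle_on_random_vectors(self):
        rng = np.random.default_rng(77)
        for _ in range(1000):
            m = int(rng.integers(1, 25))
            p = rng.random(m)
            np.testing.assert_allclose(
                benjamini_hochberg(p), bh_oracle(p), atol=1e-12
            )

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(7)
        p = rng.random(40)
        perm = rng.permutation(40)
        np.testing.assert_allclose(
            benjamini_hochberg(p)[perm], benjamini_hochberg(p[perm]), atol=1e-15
        )

    @given(
        st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1,
                 max_size=40)
    )
    @settings(deadline=None, derandomize=True, max_examples=60)
    def test_properties_hold_for_arbitrary_p_vectors(self, p):
        p = np.asarray(p)
        adj = benjamini_hochberg(p)
        assert (adj >= p - 1e-15).all() and (adj <= 1.0).all()
        np.testing.assert_allclose(adj, bh_oracle(p), atol=1e-12)

    def test_invalid_input_rejected(self):
        with pytest.raises(ValueError):
            benjamini_hochberg(np.array([0.5, 1.5]))
        with pytest.raises(ValueError):
            benjamini_hochberg(np.array([-0.1]))


class TestFilters:
    @staticmethod
    def _result(rows):
        from graftstates import DEResult

        table = pd.DataFrame(
            rows, columns=["log2fc", "p", "padj", "frac_a", "frac_b"],
            index=pd.Index([f"g{i}" for i in range(len(rows))]),
        )
        table["direction"] = np.sign(table["log2fc"]).astype(int)
        return DEResult(table=table)

    def test_threshold_logic(self):
        de = self._result(
            [
                (1.2, 0.001, 0.01, 0.15, 0.02),  # retained, up
                (1.2, 0.001, 0.01, 0.08, 0.02),  # removed: up-group frac < 10%
                (-1.5, 0.001, 0.01, 0.02, 0.30),  # retained, down (frac in B)
                (0.8, 0.001, 0.01, 0.90, 0.90),  # removed: |log2FC| <= 1
                (1.4, 0.001, 0.20, 0.50, 0.10),  # removed: padj >= 0.05
            ]
        )
        table = apply_de_filters(de)
        assert list(table.index) == ["g2", "g0"]
        assert table.loc["g0", "direction"] == 1
        assert table.loc["g2", "direction"] == -1

    def test_extreme_thresholds(self):
        de = self._result([(1.2, 0.001, 0.01, 0.5, 0.1), (2.0, 0.001, 0.01, 0.5, 0.1)])
        assert len(apply_de_filters(de, 0.0, 1.1, 0.0)) == 2
        assert len(apply_de_filters(de, np.inf, 0.0, 1.1)) == 0

    def test_deterministic_order(self):
        de = self._result(
            [(1.5, 0.001, 0.01, 0.5, 0.1), (1.5, 0.001, 0.01, 0.5, 0.1),
             (2.0, 0.001, 0.01, 0.5, 0.1)]
        )
        assert list(apply_de_filters(de).index) == ["g2", "g0", "g1"]


class TestNullCalibration:
    def test_null_pipeline_rarely_passes_filters(self):
        """With no real signal the full DE + filter pipeline should output
        essentially nothing across replicates."""
        clean = 0
        n_rep = 10
        for rep in range(n_rep):
            rng = np.random.default_rng(900 + rep)
            cohort = make_cohort(rng, n_cells=120, n_genes=2000, clusters=("A",))
            norm = lognormalize(cohort)
            de = wilcoxon_de(norm, cohort.cells[:60], cohort.cells[60:])
            if len(apply_de_filters(de)) == 0:
                clean += 1
        assert clean >= int(0.95 * n_rep)
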