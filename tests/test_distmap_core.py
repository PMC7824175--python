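import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from topoga.distmap_core import (
    BinaryCells,
    ScoreMatrix,
    binarize_cells,
    confusion_counts,
    map_cells,
    mcc,
    top_k_bins,
)
from topoga.io_formats import BinaryAtlas, ExpressionMatrix, GeneSet


def brute_force_scores(cell_vals, atlas_vals):
    """Independent oracle: per-pair confusion counts and the MCC formula."""
    n_cells, n_bins = cell_vals.shape[1], atlas_vals.shape[1]
    out = np.zeros((n_cells, n_bins))
    for c in range(n_cells):
        for b in range(n_bins):
            tp = fp = fn = tn = 0
            for g in range(cell_vals.shape[0]):
                cv, bv = cell_vals[g, c], atlas_vals[g, b]
                if cv and bv:
                    tp += 1
                elif cv and not bv:
                    fp += 1
                elif not cv and bv:
                    fn += 1
                else:
                    tn += 1
            denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
            out[c, b] = 0.0 if denom == 0 else (tp * tn - fp * fn) / math.sqrt(denom)
    return out


class TestBinarize:
    def test_linear_quantile_threshold_on_1_to_10(self):
        # 0.23-quantile of 1..10 by linear interpolation is 3.07; strictly
        # greater values (4..10) are called expressed
        expr = ExpressionMatrix(
            gene_ids=["g"],
            cell_ids=[f"c{i}" for i in range(10)],
            values=np.arange(1.0, 11.0)[None, :],
        )
        cells = binarize_cells(expr, q=0.23)
        assert cells.values.sum() == 7
        assert np.quantile(np.arange(1.0, 11.0), 0.23) == pytest.approx(3.07)

    def test_all_zero_gene_stays_all_zero(self):
        expr = ExpressionMatrix(
            gene_ids=["g"], cell_ids=["a", "b", "c"], values=np.zeros((1, 3))
        )
        assert binarize_cells(expr).values.sum() == 0

    def test_tiny_quantile_on_positive_values_gives_all_ones(self):
        expr = ExpressionMatrix(
            gene_ids=["g"], cell_ids=["a", "b", "c"],
            values=np.array([[1.0, 2.0, 3.0]]),
        )
        cells = binarize_cells(expr, q=1e-9)
        # linear rule: threshold sits just above the minimum
        assert cells.values.sum() >= 2
        # lower rule: threshold is exactly the minimum, so the non-strict
        # comparison calls every positive value expressed
        cells_nonstrict = binarize_cells(
            expr, q=1e-9, method="lower", strict=False
        )
        assert cells_nonstrict.values.sum() == 3

    def test_missing_gene_named_in_error(self):
        expr = ExpressionMatrix(
            gene_ids=["g"], cell_ids=["a"], values=np.ones((1, 1))
        )
        with pytest.raises(KeyError, match="absent"):
            binarize_cells(expr, GeneSet(names=["absent"]))

    def test_quantile_out_of_range_rejected(self):
        expr = ExpressionMatrix(
            gene_ids=["g"], cell_ids=["a"], values=np.ones((1, 1))
        )
        with pytest.raises(ValueError):
            binarize_cells(expr, q=1.0)


class TestConfusionAndMcc:
    def test_enumerated_example(self):
        assert confusion_counts([1, 1, 0, 0], [1, 0, 1, 0]) == (1, 1, 1, 1)

    def test_identical_vectors_have_no_errors(self):
        tp, fp, fn, tn = confusion_counts([1, 0, 1], [1, 0, 1])
        assert (fp, fn) == (0, 0)
        assert mcc(tp, fp, fn, tn) == pytest.approx(1.0)

    def test_complementary_vectors(self):
        tp, fp, fn, tn = confusion_counts([1, 0], [0, 1])
        assert (tp, tn) == (0, 0)
        assert mcc(tp, fp, fn, tn) == pytest.approx(-1.0)

    def test_balanced_confusion_is_zero(self):
        assert mcc(1, 1, 1, 1) == pytest.approx(0.0)

    def test_degenerate_marginal_returns_zero(self):
        assert mcc(3, 0, 2, 0) == 0.0

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            confusion_counts([1, 0], [1, 0, 1])

    def test_mcc_symmetric_under_tp_tn_swap(self):
        for tp, fp, fn, tn in itertools.product(range(4), repeat=4):
            if tp + fp + fn + tn == 0:
                continue
            assert mcc(tp, fp, fn, tn) == pytest.approx(mcc(tn, fn, fp, tp))

    def test_complementing_one_vector_negates_mcc(self, rng):
        for _ in range(20):
            a = rng.integers(2, size=12)
            b = rng.integers(2, size=12)
            m1 = mcc(*confusion_counts(a, b))
            m2 = mcc(*confusion_counts(a, 1 - b))
            assert m1 == pytest.approx(-m2, abs=1e-12)


class TestMapCells:
    def test_cells_identical_to_bins_give_unit_diagonal(self):
        vals = np.array([[1, 0], [0, 1], [1, 1], [0, 0]], dtype=np.int8)
        cells = BinaryCells(
            gene_ids=list("abcd"), cell_ids=["c0", "c1"], values=vals
        )
        atlas = BinaryAtlas(gene_ids=list("abcd"), values=vals)
        scores = map_cells(cells, atlas)
        assert scores.values[0, 0] == pytest.approx(1.0)
        assert scores.values[1, 1] == pytest.approx(1.0)

    def test_matches_nested_loop_oracle(self, rng):
        c = rng.integers(2, size=(10, 8))
        a = rng.integers(2, size=(10, 6))
        genes = [f"g{i}" for i in range(10)]
        cells = BinaryCells(
            gene_ids=genes, cell_ids=[f"c{i}" for i in range(8)], values=c
        )
        atlas = BinaryAtlas(gene_ids=genes, values=a)
        scores = map_cells(cells, atlas)
        np.testing.assert_allclose(
            scores.values, brute_force_scores(c, a), atol=1e-12
        )

    def test_gene_order_invariance(self, rng):
        c = rng.integers(2, size=(6, 5))
        a = rng.integers(2, size=(6, 4))
        genes = [f"g{i}" for i in range(6)]
        cells = BinaryCells(
            gene_ids=genes, cell_ids=[f"c{i}" for i in range(5)], values=c
        )
        atlas = BinaryAtlas(gene_ids=genes, values=a)
        full = map_cells(cells, atlas, GeneSet(names=genes))
        shuffled = map_cells(cells, atlas, GeneSet(names=genes[::-1]))
        np.testing.assert_allclose(full.values, shuffled.values, atol=1e-15)

    def test_empty_gene_set_rejected(self):
        cells = BinaryCells(
            gene_ids=["g"], cell_ids=["c"], values=np.ones((1, 1))
        )
        atlas = BinaryAtlas(gene_ids=["g"], values=np.ones((1, 1)))
        with pytest.raises(ValueError):
            GeneSet(names=[])


class TestTopK:
    def test_tie_break_by_ascending_bin_index(self):
        scores = ScoreMatrix(values=np.array([[0.2, 0.9, 0.9, 0.1]]))
        np.testing.assert_array_equal(top_k_bins(scores, 2)[0], [1, 2])

    def test_k_equals_n_bins_is_a_permutation(self, rng):
        scores = ScoreMatrix(values=rng.uniform(-1, 1, size=(3, 7)))
        full = top_k_bins(scores, 7)
        for row in full:
            assert sorted(row) == list(range(7))

    def test_matches_full_argsort_oracle(self, rng):
        vals = rng.uniform(-1, 1, size=(20, 15))
        scores = ScoreMatrix(values=vals)
        got = top_k_bins(scores, 5)
        for i in range(20):
            oracle = sorted(range(15), key=lambda b: (-vals[i, b], b))[:5]
            assert got[i].tolist() == oracle

    def test_prefix_consistency_across_k(self, rng):
        scores = ScoreMatrix(values=rng.uniform(-1, 1, size=(4, 9)))
        prev = top_k_bins(scores, 1)
        for k in range(2, 10):
            cur = top_k_bins(scores, k)
            np.testing.assert_array_equal(cur[:, : k - 1], prev)
            prev = cur

    def test_k_out_of_range_rejected(self):
        scores = ScoreMatrix(values=np.zeros((1, 4)))
        with pytest.raises(ValueError):
            top_k_bins(scores, 0)
        with pytest.raises(ValueError):
            top_k_bins(scores, 5)


@settings(max_examples=30, deadline=None, derandomize=True)
@given(st.integers(min_value=0, max_value=2**31 - 1))
def test_map_cells_scores_bounded(seed):
    """All MCC scores stay within [-1, 1] for arbitrary binary inputs."""
    rng = np.random.default_rng(seed)
    g, nc, nb = rng.integers(1, 8), rng.integers(1, 6), rng.integers(1, 6)
    genes = [f"g{i}" for i in range(g)]
    cells = BinaryCells(
        gene_ids=genes, cell_ids=[f"c{i}" for i in range(nc)],
        values=rng.integers(2, size=(g, nc)),
    )
    atlas = BinaryAtlas(gene_ids=genes, values=rng.integers(2, size=(g, nb)))
    scores = map_cells(cells, atlas)
    assert np.all(scores.values >= -1 - 1e-12)
    assert np.all(scores.values <= 1 + 1e-12)
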