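"""Section/gene filters, depth normalisation and HVG selection."""

import numpy as np
import pytest

from histoexpr.io import ExpressionMatrix, ExpressionState
from histoexpr.preprocess import (PreprocessConfig, filter_genes,
                                  filter_sections, normalize, run_preprocess,
                                  select_hvg)


def _em(mat, names=None, state=ExpressionState.RAW_COUNTS):
    mat = np.asarray(mat)
    names = names or [f"g{i}" for i in range(mat.shape[1])]
    return ExpressionMatrix(mat, names, state=state)


class TestFilterSections:
    def test_strictly_greater_threshold(self, rng):
        big = _em(rng.integers(0, 5, size=(181, 3)))
        small = _em(rng.integers(0, 5, size=(180, 3)))
        kept = filter_sections([big, small], min_spots=180)
        assert kept == [big]

    def test_all_above_threshold_unchanged(self, rng):
        secs = [_em(rng.integers(0, 5, size=(10, 2))) for _ in range(3)]
        assert filter_sections(secs, min_spots=5) == secs

    def test_empty_result_warns_not_raises(self, rng):
        secs = [_em(rng.integers(0, 5, size=(3, 2)))]
        with pytest.warns(UserWarning):
            assert filter_sections(secs, min_spots=100) == []


class TestFilterGenes:
    def test_direct_count_example(self):
        # gene A nonzero in 3 of 5 spots, gene B in 1
        em = _em(np.array([[1, 0], [2, 0], [3, 1], [0, 0], [0, 0]]),
                 names=["A", "B"])
        kept = filter_genes([em], min_spots=2)
        assert list(kept) == [0]

    def test_threshold_one_keeps_expressed(self):
        em = _em(np.array([[1, 0], [1, 0]]))
        assert list(filter_genes([em], min_spots=1)) == [0]

    def test_all_zero_gene_dropped(self):
        em = _em(np.array([[1, 0], [2, 0]]))
        assert 1 not in filter_genes([em], min_spots=1)

    def test_pooled_across_sections(self):
        a = _em(np.array([[1, 0]]), names=["x", "y"])
        b = _em(np.array([[0, 0], [1, 0]]), names=["x", "y"])
        assert list(filter_genes([a, b], min_spots=2)) == [0]

    def test_namespace_mismatch_errors(self):
        a = _em(np.array([[1]]), names=["x"])
        b = _em(np.array([[1]]), names=["z"])
        with pytest.raises(ValueError, match="namespace"):
            filter_genes([a, b], min_spots=1)

    def test_monotone_in_threshold(self, rng):
        em = _em(rng.integers(0, 3, size=(30, 10)))
        prev = set(filter_genes([em], min_spots=1))
        for t in range(2, 10):
            cur = set(filter_genes([em], min_spots=t))
            assert cur <= prev
            prev = cur


class TestNormalize:
    def test_cpm_log_arithmetic_oracle(self):
        em = _em(np.array([[10, 0, 90]]))
        out = normalize(em, scale=1e6)
        expected = [np.log1p(1e5), 0.0, np.log1p(9e5)]
        assert np.allclose(out.values[0], expected, atol=1e-10)
        assert out.values[0, 0] == pytest.approx(11.5129, abs=1e-4)
        assert out.values[0, 2] == pytest.approx(13.7102, abs=1e-4)
        assert out.state == ExpressionState.NORMALIZED

    def test_all_zero_spot_maps_to_zero_row(self):
        out = normalize(_em(np.array([[0, 0], [1, 1]])))
        assert np.allclose(out.values[0], 0.0)

    def test_scale_one_small_counts(self):
        out = normalize(_em(np.array([[1, 1]])), scale=1.0)
        assert np.allclose(out.values, np.log(1.5))

    def test_invariant_to_depth_scaling(self):
        a = normalize(_em(np.array([[2, 4, 6]])))
        b = normalize(_em(np.array([[20, 40, 60]])))
        assert np.allclose(a.values, b.values)

    def test_rejects_already_normalized(self):
        em = _em(np.array([[1.0, 2.0]]), state=ExpressionState.NORMALIZED)
        with pytest.raises(ValueError, match="raw"):
            normalize(em)


class TestSelectHVG:
    def _norm(self, mat, names):
        return _em(mat, names, state=ExpressionState.NORMALIZED)

    def test_top_variance_ranking(self):
        # variances 5, 1, 3 (up to scale) -> n=2 keeps genes 0 and 2
        rng = np.random.default_rng(0)
        base = rng.normal(size=100)
        mat = np.abs(np.column_stack([base * np.sqrt(5), base * 1.0,
                                      base * np.sqrt(3)]))
        idx = select_hvg([self._norm(mat, ["a", "b", "c"])], n=2)
        assert list(idx) == [0, 2]

    def test_n_equal_total_identity(self, rng):
        mat = np.abs(rng.normal(size=(10, 4)))
        idx = select_hvg([self._norm(mat, list("abcd"))], n=4)
        assert list(idx) == [0, 1, 2, 3]

    def test_n_larger_warns_keeps_all(self, rng):
        mat = np.abs(rng.normal(size=(10, 3)))
        with pytest.warns(UserWarning):
            idx = select_hvg([self._norm(mat, list("abc"))], n=5)
        assert list(idx) == [0, 1, 2]

    def test_per_section_union(self):
        # section A: gene 0 most variable; section B: gene 2
        col = np.array([0.0, 3.0, 0.0, 3.0])
        flat = np.full(4, 1.0)
        a = self._norm(np.column_stack([col, flat, flat]), list("xyz"))
        b = self._norm(np.column_stack([flat, flat, col]), list("xyz"))
        assert list(select_hvg([a, b], n=1, per_section=True)) == [0, 2]
        # pooled ranking returns exactly one gene
        assert len(select_hvg([a, b], n=1)) == 1

    def test_tie_break_lexicographic(self):
        col = np.array([0.0, 2.0, 0.0, 2.0])
        mat = np.column_stack([col * 2, col, col])   # genes b, c tied
        idx = select_hvg([self._norm(mat, ["a", "c", "b"])], n=2)
        # tie between 'c' (index 1) and 'b' (index 2): 'b' wins by name
        assert list(idx) == [0, 2]


class TestPipeline:
    def test_designed_toy_keeps_expected_genes(self):
        # 5 genes: g0/g1 widely expressed and strongly variable, g2 widely
        # expressed but steady, g3 seen in a single spot (killed by the
        # presence filter despite its huge variance), g4 silent.  With
        # n_hvg = 3 the variance ranking is {g3, g0, g1}; intersecting with
        # the presence set {g0, g1, g2} keeps exactly g0 and g1 — the same
        # mechanism that leaves the final panel smaller than n_hvg.
        n = 12
        counts = np.zeros((n, 5), dtype=int)
        counts[::2, 0] = 60
        counts[1::2, 1] = 40
        counts[:, 2] = 5
        counts[0, 3] = 7
        em = _em(counts, names=["g0", "g1", "g2", "g3", "g4"])
        cfg = PreprocessConfig(min_spots_per_section=5, min_spots_per_gene=6,
                               n_hvg=3)
        processed, genes, log = run_preprocess([em], cfg)
        assert genes == ["g0", "g1"]
        assert log["after_gene_filter"]["genes"] == 3   # g0, g1, g2
        assert log["final"]["genes"] == 2

    def test_stage_counts_non_increasing(self, rng):
        secs = [_em(rng.integers(0, 4, size=(20, 8))) for _ in range(3)]
        cfg = PreprocessConfig(min_spots_per_section=10, min_spots_per_gene=5,
                               n_hvg=4)
        _, _, log = run_preprocess(secs, cfg)
        assert log["after_section_filter"]["spots"] <= log["input"]["spots"]
        assert log["after_gene_filter"]["genes"] <= log["input"]["genes"]
        assert log["final"]["genes"] <= log["after_hvg"]["genes"]

    def test_threshold_must_be_positive(self):
        with pytest.raises(ValueError, match="positive"):
            PreprocessConfig(min_spots_per_section=0)
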