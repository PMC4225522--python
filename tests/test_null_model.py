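import numpy as np
import pytest

import dtlcoev as dc
from dtlcoev.errors import DtlCoevError
from dtlcoev.null_model import BinVector

from _oracles import enumerate_null
from conftest import random_species_tree


class TestBinVector:
    def test_two_leaf_tree(self, two_taxon_tree):
        bv = dc.bin_vector(two_taxon_tree)
        assert bv.n == 6
        assert np.allclose(bv.lengths, 1.0)
        assert bv.prefix_probabilities()[0] == 1.0

    def test_three_taxon_bin_count(self, three_taxon_tree):
        assert dc.bin_vector(three_taxon_tree).n == 12

    def test_all_zero_lengths_rejected(self):
        with pytest.raises(DtlCoevError):
            BinVector([("a", "D")], np.array([0.0]))


def _nm(lengths):
    bins = [(i, "D") for i in range(len(lengths))]
    return dc.NullModel(BinVector(bins, np.asarray(lengths, float)))


class TestBaseCases:
    def test_score_zero_gives_p_one(self):
        nm = _nm([1.0, 2.0, 3.0])
        assert nm.p_value(0.0, 5, 7) == 1.0
        assert nm.p_value(-1.0, 5, 7) == 1.0

    def test_no_events_on_either_side_gives_p_one(self):
        nm = _nm([1.0, 1.0])
        assert nm.p_value(3.0, 0, 5) == 1.0
        assert nm.p_value(3.0, 5, 0) == 1.0

    def test_impossible_overlap_gives_p_zero(self):
        nm = _nm([1.0, 1.0, 1.0])
        assert nm.p_value(3.0, 2, 5) == 0.0
        assert nm.p_value(2.5, 9, 2) == 0.0

    def test_single_bin_is_indicator(self):
        nm = _nm([4.0])
        assert nm.p_value(2.0, 3, 2) == pytest.approx(1.0)
        assert nm.p_value(3.0, 3, 2) == 0.0

    def test_two_equal_bins_one_event_each(self):
        # both events land in the same bin with probability 1/2
        nm = _nm([1.0, 1.0])
        assert nm.p_value(1.0, 1, 1) == pytest.approx(0.5)


class TestOracleEquivalence:
    @pytest.mark.parametrize("seed", range(6))
    def test_small_cases_exact(self, seed):
        rng = np.random.default_rng(300 + seed)
        n_bins = int(rng.integers(2, 5))
        lengths = rng.uniform(0.2, 3.0, size=n_bins)
        nm = _nm(lengths)
        for n1 in range(1, 4):
            for n2 in range(1, 4):
                for x in range(1, min(n1, n2) + 1):
                    want = enumerate_null(lengths, n1, n2, x)
                    got = nm.p_value(float(x), n1, n2)
                    assert got == pytest.approx(want, abs=1e-12)

    def test_fractional_score_equals_ceiling(self):
        lengths = [1.0, 2.0, 0.5, 1.5]
        nm = _nm(lengths)
        assert nm.p_value(0.77, 3, 2) == pytest.approx(
            enumerate_null(lengths, 3, 2, 1), abs=1e-12
        )
        assert nm.p_value(1.0, 3, 2) == pytest.approx(
            enumerate_null(lengths, 3, 2, 1), abs=1e-12
        )


class TestProperties:
    def test_monotonic_in_score_and_event_counts(self):
        rng = np.random.default_rng(9)
        nm = _nm(rng.uniform(0.5, 2.0, size=9))
        nm.precompute(6, 6, 6)
        t = nm._table
        assert (np.diff(t, axis=0) <= 1e-12).all()   # nonincreasing in x
        assert (np.diff(t, axis=1) >= -1e-12).all()  # nondecreasing in n1
        assert (np.diff(t, axis=2) >= -1e-12).all()  # nondecreasing in n2

    def test_bin_order_is_irrelevant(self):
        rng = np.random.default_rng(10)
        lengths = rng.uniform(0.1, 2.0, size=7)
        nm1 = _nm(lengths)
        nm2 = _nm(lengths[::-1])
        for x, n1, n2 in [(1, 3, 2), (2, 4, 4), (3, 5, 3)]:
            assert nm1.p_value(x, n1, n2) == pytest.approx(
                nm2.p_value(x, n1, n2), abs=1e-12
            )

    def test_zero_length_bins_are_skipped(self):
        got = _nm([1.0, 0.0, 1.0]).p_value(1.0, 1, 1)
        want = _nm([1.0, 1.0]).p_value(1.0, 1, 1)
        assert got == pytest.approx(want, abs=1e-12)

    def test_cached_queries_are_deterministic_and_match_fresh(self):
        rng = np.random.default_rng(12)
        S = random_species_tree(rng, 6)
        nm = dc.NullModel(S)
        nm.precompute(6, 8, 8)
        queries = [(1.4, 3, 5), (2.0, 8, 8), (3.7, 6, 4)]
        cached = [nm.p_value(*q) for q in queries]
        again = [nm.p_value(*q) for q in queries]
        assert cached == again
        fresh = [dc.NullModel(S).p_value(*q) for q in queries]
        assert cached == pytest.approx(fresh, abs=1e-12)

    def test_query_beyond_cache_recomputes_transparently(self):
        nm = _nm([1.0, 1.0, 2.0])
        nm.precompute(1, 1, 1)
        assert nm.p_value(2.0, 3, 3) == pytest.approx(
            enumerate_null([1.0, 1.0, 2.0], 3, 3, 2), abs=1e-12
        )
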