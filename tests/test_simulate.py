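import numpy as np
import pytest
from scipy import stats

import dtlcoev as dc
from dtlcoev.errors import DtlCoevError

from conftest import random_species_tree


class _LowerBoundRng:
    """uniform() always returns the lower end of the interval."""

    def uniform(self, lo, hi):
        return lo


class _ScriptedRng:
    """Replays a fixed list of (kind, value) draws; kinds must match."""

    def __init__(self, script):
        self.script = list(script)

    def _next(self, kind):
        k, v = self.script.pop(0)
        assert k == kind, f"expected draw {k}, simulator asked for {kind}"
        return v

    def exponential(self, scale):
        return self._next("exp")

    def random(self):
        return self._next("ran")

    def integers(self, lo, hi):
        return self._next("int")


class TestRates:
    def test_interval_lower_corner(self):
        r = dc.sample_rates(_LowerBoundRng())
        assert r.loss == pytest.approx(0.001)
        assert r.duplication + r.transfer == pytest.approx(0.0005)
        assert r.duplication == pytest.approx(0.00035)
        assert r.transfer == pytest.approx(0.00015)

    def test_loss_rate_mean_is_interval_midpoint(self):
        rng = np.random.default_rng(0)
        draws = [dc.sample_rates(rng) for _ in range(100_000)]
        assert np.mean([r.loss for r in draws]) == pytest.approx(
            0.0014, abs=3e-6
        )

    def test_rates_nonnegative_and_activity_consistent(self):
        rng = np.random.default_rng(1)
        for _ in range(1000):
            r = dc.sample_rates(rng)
            assert min(r.duplication, r.transfer, r.loss) >= 0
            assert r.activity == r.duplication + r.transfer + r.loss


class TestPairProcess:
    def test_c_out_of_range_rejected(self, two_taxon_tree):
        with pytest.raises(DtlCoevError):
            dc.simulate_pair(
                two_taxon_tree, dc.RateSet(0.1, 0.1, 0.1), 1.5,
                np.random.default_rng(0),
            )

    def test_fully_shared_pair_is_identical(self):
        rng = np.random.default_rng(5)
        S = random_species_tree(rng, 8, height=100.0)
        for _ in range(20):
            pair = dc.simulate_pair(S, dc.RateSet(0.01, 0.01, 0.01), 1.0, rng)
            t1 = pair.tree1.to_newick() if pair.tree1 else None
            t2 = pair.tree2.to_newick() if pair.tree2 else None
            assert t1 == t2
            log1 = [(e.etype, e.branch, e.date) for e in pair.events1]
            log2 = [(e.etype, e.branch, e.date) for e in pair.events2]
            assert log1 == log2
            assert all(e.shared for e in pair.events1)

    def test_event_dates_inside_their_branch(self):
        rng = np.random.default_rng(6)
        S = random_species_tree(rng, 8, height=100.0)
        for _ in range(30):
            pair = dc.simulate_pair(S, dc.RateSet(0.01, 0.01, 0.01), 0.3, rng)
            for e in pair.events1 + pair.events2:
                assert S.ages[e.branch] < e.date < S.ages[S.parent[e.branch]]

    def test_node_ages_strictly_decrease_towards_leaves(self):
        rng = np.random.default_rng(7)
        S = random_species_tree(rng, 8, height=100.0)
        pair = dc.simulate_pair(S, dc.RateSet(0.02, 0.02, 0.02), 0.5, rng)
        for tree in (pair.tree1, pair.tree2):
            if tree is None:
                continue
            for i in range(tree.n_nodes):
                if i != tree.root:
                    assert tree.ages[tree.parent[i]] > tree.ages[i]

    def test_no_loss_means_all_species_covered(self):
        rng = np.random.default_rng(8)
        S = random_species_tree(rng, 6, height=100.0)
        all_species = {S.labels[i] for i in S.leaves}
        for _ in range(10):
            pair = dc.simulate_pair(S, dc.RateSet(0.005, 0.005, 0.0), 0.5, rng)
            for tree in (pair.tree1, pair.tree2):
                assert {tree.species[u] for u in tree.leaves} == all_species

    def test_marginal_rates_match_single_family_process(self):
        # the 2/(1+c) correction: per-tree D/T/L counts from pairs are
        # indistinguishable from the unpaired birth-death process
        rng = np.random.default_rng(9)
        S = random_species_tree(rng, 10, height=100.0)
        rates = dc.RateSet(0.004, 0.003, 0.005)
        n = 1500
        single = [
            len(dc.simulate_single(S, rates, rng)[1]) for _ in range(n)
        ]
        for c in (0.0, 0.5):
            paired = [
                len(dc.simulate_pair(S, rates, c, rng).events1)
                for _ in range(n)
            ]
            p = stats.mannwhitneyu(single, paired).pvalue
            assert p > 0.01, f"marginal mismatch at c={c}: p={p}"


class TestScriptedScenario:
    def test_one_sided_duplication_and_shared_transfer(self):
        # species tree (A:2,(B:1,C:1):1): speciations at dates 2 and 1.
        # Scripted run: a duplication at date 1.42 in family 1 only, then a
        # transfer at date 0.55 shared by both families from branch B to A.
        S = dc.parse_dated_newick("(A:2,(B:1,C:1):1);")
        rates = dc.RateSet(0.3, 0.3, 0.4)  # activity 1
        script = [
            ("exp", 0.58), ("ran", 0.1), ("int", 0), ("ran", 0.9),  # D, one-sided
            ("exp", 10.0),                                  # copy 2 speciates
            ("exp", 10.0), ("exp", 10.0),                   # copy-2 leaves
            ("exp", 10.0),                                  # pair speciates at 1
            ("exp", 10.0),                                  # C pair reaches leaves
            ("exp", 0.45), ("ran", 0.5), ("int", 0), ("ran", 0.2), ("int", 0),
            # transfer at 0.55, shared, target A
            ("exp", 10.0), ("exp", 10.0),                   # transferred + stay
            ("exp", 10.0),                                  # A pair reaches leaves
        ]
        pair = dc.simulate_pair(S, rates, 0.5, _ScriptedRng(script))
        newick1 = pair.tree1.to_newick()
        newick2 = pair.tree2.to_newick()
        strip = lambda s: __import__("re").sub(r":[0-9.eE+-]+", "", s)
        assert strip(newick1) == "(A_6,(((B_5,A_4),C_3),(B_2,C_1)));"
        assert strip(newick2) == "(A_4,((B_3,A_2),C_1));"
        ev1 = [(e.etype, S.branch_name(e.branch), round(e.date, 2), e.shared)
               for e in pair.events1]
        ev2 = [(e.etype, S.branch_name(e.branch), round(e.date, 2), e.shared)
               for e in pair.events2]
        assert ev1 == [("D", "n3", 1.42, False), ("T", "B", 0.55, True)]
        assert ev2 == [("T", "B", 0.55, True)]
        assert pair.n_shared == 1


class TestTrueEventSets:
    def test_identical_pair_gives_identical_sets_and_full_score(self):
        rng = np.random.default_rng(20)
        S = random_species_tree(rng, 8, height=100.0)
        pair = None
        while pair is None or not pair.events1:
            pair = dc.simulate_pair(S, dc.RateSet(0.01, 0.01, 0.005), 1.0, rng)
        W1, W2 = dc.true_event_sets(pair)
        assert {k: len(v) for k, v in W1.bins.items()} == {
            k: len(v) for k, v in W2.bins.items()
        }
        score = dc.coevolution_score(W1, W2, S)
        n_events = sum(1 for e in pair.events1 if e.etype in "DTL")
        assert score == pytest.approx(n_events)
        assert score == pytest.approx(pair.n_shared)

    def test_eventless_pair_scores_zero_with_p_one(self):
        rng = np.random.default_rng(21)
        S = random_species_tree(rng, 5, height=100.0)
        pair = dc.simulate_pair(S, dc.RateSet(0.0, 0.0, 0.0), 0.5, rng)
        W1, W2 = dc.true_event_sets(pair)
        assert len(W1) == len(W2) == 0
        res = dc.detect(S, event_sets=(W1, W2))
        assert res.score == 0.0
        assert res.p_value == 1.0
        assert not res.significant


class TestYule:
    def test_leaf_count_height_and_labels(self):
        rng = np.random.default_rng(30)
        S = dc.yule_tree(37, 500.0, rng)
        assert len(S.leaves) == 37
        assert S.height == pytest.approx(500.0)
        assert all("_" not in S.labels[i] for i in S.leaves)
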