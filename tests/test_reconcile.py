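import numpy as np
import pytest

import dtlcoev as dc
from dtlcoev.reconcile import EventCosts, scenario_cost, tally_events

from _oracles import brute_reconcile
from conftest import random_gene_tree, random_species_tree


def _compare_with_oracle(S, g, costs=EventCosts()):
    Sp = S.subdivide()
    rs = dc.reconcile(g, Sp, costs)
    best, scens = brute_reconcile(g, Sp, costs)
    assert rs.min_cost == pytest.approx(best)
    assert rs.mpr_count == len(scens)
    assert tally_events(scens) == rs.event_counts
    return rs, scens


class TestAnchors:
    def test_congruent_trees_single_mpr_all_speciations(self, three_taxon_tree):
        g = dc.parse_gene_tree("((A_1,B_1),C_1);", species_tree=three_taxon_tree)
        rs = dc.reconcile(g, three_taxon_tree.subdivide())
        assert rs.min_cost == 0
        assert rs.mpr_count == 1
        freqs = rs.frequencies
        s_events = {k: v for k, v in freqs.items() if k[2] == "S"}
        assert len(s_events) == 2 and all(v == 1 for v in s_events.values())

    def test_two_copies_in_one_species_is_one_duplication(self, two_taxon_tree):
        g = dc.parse_gene_tree("((A_1,A_2),B_1);", species_tree=two_taxon_tree)
        rs = dc.reconcile(g, two_taxon_tree.subdivide())
        assert rs.min_cost == 1
        assert rs.mpr_count == 1
        d_events = [k for k in rs.event_counts if k[2] == "D"]
        assert len(d_events) == 1

    def test_unmapped_leaf_rejected(self, two_taxon_tree):
        g = dc.parse_gene_tree("(A_1,Z_1);")
        with pytest.raises(dc.ReconciliationError, match="Z"):
            dc.reconcile(g, two_taxon_tree.subdivide())


class TestAgainstBruteForce:
    @pytest.mark.parametrize("seed", range(12))
    def test_random_small_instances(self, seed):
        rng = np.random.default_rng(1000 + seed)
        S = random_species_tree(rng, int(rng.integers(2, 5)))
        g = random_gene_tree(rng, S, int(rng.integers(2, 6)))
        _compare_with_oracle(S, g)

    @pytest.mark.parametrize("seed", range(4))
    def test_non_unit_costs(self, seed):
        rng = np.random.default_rng(2000 + seed)
        S = random_species_tree(rng, 3)
        g = random_gene_tree(rng, S, 4)
        _compare_with_oracle(S, g, EventCosts(2.0, 3.0, 1.0))


class TestEnumeration:
    def test_enumeration_matches_count_and_frequencies(self):
        rng = np.random.default_rng(42)
        for _ in range(8):
            S = random_species_tree(rng, int(rng.integers(2, 5)))
            g = random_gene_tree(rng, S, int(rng.integers(2, 6)))
            Sp = S.subdivide()
            rs = dc.reconcile(g, Sp)
            scens = dc.enumerate_all_optimal(g, Sp)
            assert len(scens) == rs.mpr_count
            tot = rs.mpr_count
            tallies = tally_events(scens)
            for k, cnt in rs.event_counts.items():
                assert abs(tallies.get(k, 0) / tot - cnt / tot) < 1e-12
            for sc in scens:
                assert scenario_cost(sc) == pytest.approx(rs.min_cost)

    def test_ceiling_refusal(self, two_taxon_tree):
        rng = np.random.default_rng(3)
        g = random_gene_tree(rng, two_taxon_tree, 6)
        with pytest.raises(dc.ReconciliationError, match="ceiling"):
            dc.enumerate_all_optimal(g, two_taxon_tree.subdivide(), ceiling=0)


class TestInvariants:
    def test_terminal_event_frequencies_partition(self):
        # the first terminal event of each gene node (S/D/T/C) partitions
        # the MPR space, so its frequencies sum to 1
        rng = np.random.default_rng(77)
        for _ in range(6):
            S = random_species_tree(rng, int(rng.integers(2, 5)))
            g = random_gene_tree(rng, S, int(rng.integers(2, 6)))
            rs = dc.reconcile(g, S.subdivide())
            for u in range(g.n_nodes):
                tot = sum(
                    f for (uu, _x, ev), f in rs.frequencies.items()
                    if uu == u and ev in ("S", "D", "T", "C")
                )
                assert float(tot) == pytest.approx(1.0)

    def test_transfers_stay_within_one_slice(self):
        rng = np.random.default_rng(88)
        S = random_species_tree(rng, 4)
        g = random_gene_tree(rng, S, 5)
        Sp = S.subdivide()
        for sc in dc.enumerate_all_optimal(g, Sp, ceiling=100000):
            for e in sc:
                if e[0] in ("T", "TL"):
                    donor, receiver = e[2], e[3]
                    assert Sp.level[donor] == Sp.level[receiver]

    def test_cost_nondecreasing_in_transfer_cost(self):
        rng = np.random.default_rng(99)
        S = random_species_tree(rng, 4)
        g = random_gene_tree(rng, S, 5)
        Sp = S.subdivide()
        costs = [
            dc.reconcile(g, Sp, EventCosts(1.0, tau, 1.0)).min_cost
            for tau in (0.5, 1.0, 2.0, 4.0)
        ]
        assert costs == sorted(costs)

    def test_fast_engine_matches_exact(self):
        from dtlcoev._fast import fast_reconcile

        rng = np.random.default_rng(123)
        for _ in range(6):
            S = random_species_tree(rng, int(rng.integers(2, 6)))
            g = random_gene_tree(rng, S, int(rng.integers(2, 8)))
            Sp = S.subdivide()
            re_ = dc.reconcile(g, Sp)
            rf = fast_reconcile(g, Sp)
            assert rf.min_cost == pytest.approx(re_.min_cost)
            assert rf.mpr_count == re_.mpr_count
            fe, ff = re_.frequencies, rf.frequencies
            assert set(fe) == set(ff)
            for k in fe:
                assert float(ff[k]) == pytest.approx(float(fe[k]), abs=1e-9)
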