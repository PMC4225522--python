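"""Most-parsimonious DTL reconciliation with exact counting of scenarios.

The dynamic program maps gene-tree nodes onto the time-sliced subdivision S'
of a dated species tree.  A *state* (u, x) means: the lineage leading to gene
node u is on the branch above subdivided node x (for the species root: at the
root node).  Allowed moves and their costs (EventCosts delta, tau, lam):

=====  =====================================================  ==========
event  effect                                                 cost
=====  =====================================================  ==========
C      u leaf reaches matching species leaf x                 0
S      u speciates at real internal x; children to x's kids   0
D      u duplicates on the branch above x; both children at x delta
T      one child stays at x, the other goes to a branch of    tau
       the same time slice
SL     u passes real internal x, one descendant side is lost  lam
TL     u jumps to another branch of the slice; the stay-side  tau + lam
       child is lost on the donor branch
NE     u crosses an artificial node (slice boundary)          0
=====  =====================================================  ==========

At the species root node only S and SL apply (there is no branch above the
root, so duplications preceding the first speciation are outside the model).
Within one slice a lineage may take at most one TL between boundary
crossings, which keeps the recursion acyclic.  The gene root may start at any
state, but its first move may not be NE (otherwise reconciliations differing
only by an eventless prefix would be counted as distinct).

Counting is exact: scenario counts are Python integers and event frequencies
are ratios of big integers.  A reconciliation *contains* event (u, x, E) when
the scenario's move at that state is E; the frequency of the event is the
fraction of most-parsimonious reconciliations containing it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from fractions import Fraction

from .errors import ReconciliationError
from .trees import GeneTree, SubdividedSpeciesTree

__all__ = [
    "EventCosts",
    "ReconciliationSummary",
    "reconcile",
    "enumerate_all_optimal",
    "EVENT_TYPES",
]

EVENT_TYPES = ("S", "D", "T", "SL", "TL", "NE", "C")
_INF = math.inf
_TOL = 1e-9


@dataclass(frozen=True)
class EventCosts:
    """Per-event parsimony costs; the reference analysis uses 1/1/1."""

    duplication: float = 1.0
    transfer: float = 1.0
    loss: float = 1.0

    def __post_init__(self):
        if min(self.duplication, self.transfer, self.loss) < 0:
            raise ValueError("event costs must be nonnegative")


class ReconciliationSummary:
    """Minimal cost, exact MPR count, and per-event support frequencies.

    ``event_counts[(u, x, E)]`` is the number of most-parsimonious
    reconciliations in which gene node ``u`` undergoes event ``E`` at
    subdivided node ``x`` (for T/TL: x is the donor; for SL: x is the top of
    the branch where the lost side entered).  ``frequencies`` divides by the
    total MPR count.
    """

    def __init__(self, gene_tree, subdivided, costs, min_cost, mpr_count,
                 event_counts, engine="exact"):
        self.gene_tree = gene_tree
        self.subdivided = subdivided
        self.costs = costs
        self.min_cost = min_cost
        self.mpr_count = mpr_count
        self.event_counts = event_counts
        self.engine = engine

    @property
    def frequencies(self) -> dict:
        tot = self.mpr_count
        if isinstance(tot, int):
            return {k: Fraction(v, tot) for k, v in self.event_counts.items()}
        return {k: v / tot for k, v in self.event_counts.items()}

    def frequency_rows(self):
        """(gene_node, species_node, event_type, frequency) rows."""
        for (u, x, ev), f in sorted(self.frequencies.items()):
            yield u, x, ev, float(f)

    def write_tsv(self, path):
        with open(path, "w") as fh:
            fh.write("gene_node\tspecies_node\tevent_type\tfrequency\n")
            for u, x, ev, f in self.frequency_rows():
                fh.write(f"{u}\t{x}\t{ev}\t{f:.12g}\n")

    def __repr__(self):
        return (
            f"<ReconciliationSummary cost={self.min_cost:g} "
            f"MPRs={self.mpr_count}>"
        )


def _check_inputs(G: GeneTree, Sp: SubdividedSpeciesTree):
    missing = sorted(
        {G.species[u] for u in G.leaves if G.species[u] not in Sp.leaf_of_label}
    )
    if missing:
        raise ReconciliationError(
            "gene leaves map to species not in the species tree: "
            + ", ".join(missing)
        )


def _forward(G: GeneTree, Sp: SubdividedSpeciesTree, costs: EventCosts):
    """Bottom-up pass.

    Returns per-state tables (lists [u][x]):
      cne/nne : best cost/count over non-NE, non-TL moves
      cb/nb   : "base" = over non-TL moves (adds NE)
      cf/nf   : full = base or one TL into the slice
      cstart/nstart : root-start values (non-NE first move, TL allowed)
    """
    NG, NS = G.n_nodes, Sp.n_nodes
    delta, tau, lam = costs.duplication, costs.transfer, costs.loss
    tlc = tau + lam
    gleaf_site = [
        Sp.leaf_of_label[G.species[u]] if G.is_leaf(u) else -1
        for u in range(NG)
    ]
    cne = [[_INF] * NS for _ in range(NG)]
    nne = [[0] * NS for _ in range(NG)]
    cb = [[_INF] * NS for _ in range(NG)]
    nb = [[0] * NS for _ in range(NG)]
    cf = [[_INF] * NS for _ in range(NG)]
    nf = [[0] * NS for _ in range(NG)]

    for u in range(NG):  # nodes are in postorder
        kids = G.children[u]
        u1, u2 = kids if kids else (-1, -1)
        cfu = cf[u]
        for lev in range(Sp.n_levels):
            nodes = Sp.level_nodes[lev]
            for x in nodes:
                best, cnt = _INF, 0
                xkids = Sp.children[x]
                if not xkids:  # species leaf
                    if u1 == -1 and gleaf_site[u] == x:
                        best, cnt = 0.0, 1
                elif len(xkids) == 2:  # real internal: S, SL at node x
                    xc1, xc2 = xkids
                    if u1 != -1:
                        for a, b in ((xc1, xc2), (xc2, xc1)):
                            v = cf[u1][a] + cf[u2][b]
                            if v < best - _TOL:
                                best, cnt = v, nf[u1][a] * nf[u2][b]
                            elif v <= best + _TOL:
                                cnt += nf[u1][a] * nf[u2][b]
                    for a in (xc1, xc2):
                        v = lam + cfu[a]
                        if v < best - _TOL:
                            best, cnt = v, nf[u][a]
                        elif v <= best + _TOL:
                            cnt += nf[u][a]
                if x != Sp.root and u1 != -1:
                    # D and T on the branch above x
                    v = delta + cf[u1][x] + cf[u2][x]
                    if v < best - _TOL:
                        best, cnt = v, nf[u1][x] * nf[u2][x]
                    elif v <= best + _TOL:
                        cnt += nf[u1][x] * nf[u2][x]
                    for y in nodes:
                        if y == x or y == Sp.root:
                            continue
                        for va, ca in (
                            (tau + cf[u1][x] + cf[u2][y], nf[u1][x] * nf[u2][y]),
                            (tau + cf[u1][y] + cf[u2][x], nf[u1][y] * nf[u2][x]),
                        ):
                            if va < best - _TOL:
                                best, cnt = va, ca
                            elif va <= best + _TOL:
                                cnt += ca
                cne[u][x], nne[u][x] = best, cnt
                # base: add the NE move through an artificial node
                if len(xkids) == 1:
                    v = cfu[xkids[0]]
                    if v < best - _TOL:
                        best, cnt = v, nf[u][xkids[0]]
                    elif v <= best + _TOL:
                        cnt += nf[u][xkids[0]]
                cb[u][x], nb[u][x] = best, cnt
            # full: allow one TL within the slice
            for x in nodes:
                best, cnt = cb[u][x], nb[u][x]
                if x != Sp.root:
                    for y in nodes:
                        if y == x or y == Sp.root:
                            continue
                        v = cb[u][y] + tlc
                        if v < best - _TOL:
                            best, cnt = v, nb[u][y]
                        elif v <= best + _TOL:
                            cnt += nb[u][y]
                cf[u][x], nf[u][x] = best, cnt

    # root-start values: no NE first move, TL allowed
    r = NG - 1
    cstart = [_INF] * NS
    nstart = [0] * NS
    tlc = tau + lam
    for x in range(NS):
        best, cnt = cne[r][x], nne[r][x]
        if x != Sp.root:
            for y in Sp.partners(x):
                v = cb[r][y] + tlc
                if v < best - _TOL:
                    best, cnt = v, nb[r][y]
                elif v <= best + _TOL:
                    cnt += nb[r][y]
        cstart[x], nstart[x] = best, cnt
    return cne, nne, cb, nb, cf, nf, cstart, nstart


def reconcile(G: GeneTree, Sp: SubdividedSpeciesTree,
              costs: EventCosts = EventCosts()) -> ReconciliationSummary:
    """Compute cost, exact MPR count and event support frequencies."""
    _check_inputs(G, Sp)
    cne, nne, cb, nb, cf, nf, cstart, nstart = _forward(G, Sp, costs)
    NG, NS = G.n_nodes, Sp.n_nodes
    delta, tau, lam = costs.duplication, costs.transfer, costs.loss
    tlc = tau + lam
    opt = min(cstart)
    if not math.isfinite(opt):
        raise ReconciliationError("no valid reconciliation exists")
    total = sum(nstart[x] for x in range(NS) if cstart[x] <= opt + _TOL)

    O = [[0] * NS for _ in range(NG)]   # contexts of full states
    Ob = [[0] * NS for _ in range(NG)]  # contexts of TL-restricted states
    ev: dict[tuple, int] = {}

    def add(u, x, t, n):
        if n:
            k = (u, x, t)
            ev[k] = ev.get(k, 0) + n

    gleaf_site = [
        Sp.leaf_of_label[G.species[u]] if G.is_leaf(u) else -1
        for u in range(NG)
    ]

    def expand(u, x, ctx, target, include_ne):
        """Record first moves of value `target` from restricted state (u,x)."""
        kids = G.children[u]
        u1, u2 = kids if kids else (-1, -1)
        xkids = Sp.children[x]
        if not xkids:
            if u1 == -1 and gleaf_site[u] == x and abs(target) <= _TOL:
                add(u, x, "C", ctx)
        elif len(xkids) == 2:
            xc1, xc2 = xkids
            if u1 != -1:
                for a, b in ((xc1, xc2), (xc2, xc1)):
                    if abs(cf[u1][a] + cf[u2][b] - target) <= _TOL:
                        add(u, x, "S", ctx * nf[u1][a] * nf[u2][b])
                        O[u1][a] += ctx * nf[u2][b]
                        O[u2][b] += ctx * nf[u1][a]
            for a, lost in ((xc1, xc2), (xc2, xc1)):
                if abs(lam + cf[u][a] - target) <= _TOL:
                    add(u, lost, "SL", ctx * nf[u][a])
                    O[u][a] += ctx
        if x != Sp.root and u1 != -1:
            if abs(delta + cf[u1][x] + cf[u2][x] - target) <= _TOL:
                add(u, x, "D", ctx * nf[u1][x] * nf[u2][x])
                O[u1][x] += ctx * nf[u2][x]
                O[u2][x] += ctx * nf[u1][x]
            for y in Sp.partners(x):
                for a, b in ((u1, u2), (u2, u1)):
                    # a stays on x, b goes to y
                    if abs(tau + cf[a][x] + cf[b][y] - target) <= _TOL:
                        add(u, x, "T", ctx * nf[a][x] * nf[b][y])
                        O[a][x] += ctx * nf[b][y]
                        O[b][y] += ctx * nf[a][x]
        if include_ne and len(xkids) == 1:
            (xc,) = xkids
            if abs(cf[u][xc] - target) <= _TOL:
                add(u, x, "NE", ctx * nf[u][xc])
                O[u][xc] += ctx

    # seed from the optimal root placements
    r = NG - 1
    for x in range(NS):
        if cstart[x] <= opt + _TOL:
            expand(r, x, 1, opt, include_ne=False)
            if x != Sp.root:
                for y in Sp.partners(x):
                    if abs(cb[r][y] + tlc - opt) <= _TOL:
                        add(r, x, "TL", nb[r][y])
                        Ob[r][y] += 1

    for u in reversed(range(NG)):
        for lev in reversed(range(Sp.n_levels)):
            nodes = Sp.level_nodes[lev]
            for x in nodes:
                o = O[u][x]
                if not o:
                    continue
                if cb[u][x] <= cf[u][x] + _TOL:
                    Ob[u][x] += o
                if x != Sp.root:
                    for y in Sp.partners(x):
                        if abs(cb[u][y] + tlc - cf[u][x]) <= _TOL:
                            add(u, x, "TL", o * nb[u][y])
                            Ob[u][y] += o
            for x in nodes:
                k = Ob[u][x]
                if k:
                    expand(u, x, k, cb[u][x], include_ne=True)

    return ReconciliationSummary(G, Sp, costs, opt, total, ev, engine="exact")


# ---------------------------------------------------------------------------
# explicit enumeration of all optimal scenarios (guided by the DP tables)
# ---------------------------------------------------------------------------

def enumerate_all_optimal(G: GeneTree, Sp: SubdividedSpeciesTree,
                          costs: EventCosts = EventCosts(),
                          ceiling: int = 100_000):
    """Return every most-parsimonious scenario as an explicit event list.

    Each scenario is a tuple of event records ``(event_type, u, x, *detail)``
    (detail: receiver for T/TL, surviving child for SL).  Refuses with
    :class:`ReconciliationError` when the MPR count exceeds ``ceiling``.
    """
    _check_inputs(G, Sp)
    cne, nne, cb, nb, cf, nf, cstart, nstart = _forward(G, Sp, costs)
    NS = Sp.n_nodes
    delta, tau, lam = costs.duplication, costs.transfer, costs.loss
    tlc = tau + lam
    opt = min(cstart)
    if not math.isfinite(opt):
        raise ReconciliationError("no valid reconciliation exists")
    total = sum(nstart[x] for x in range(NS) if cstart[x] <= opt + _TOL)
    if total > ceiling:
        raise ReconciliationError(
            f"{total} optimal reconciliations exceed the ceiling {ceiling}"
        )
    gleaf_site = [
        Sp.leaf_of_label[G.species[u]] if G.is_leaf(u) else -1
        for u in range(G.n_nodes)
    ]
    memo_b: dict[tuple, list] = {}
    memo_f: dict[tuple, list] = {}

    def expand_base(u, x, include_ne=True, target=None):
        key = (u, x, include_ne, target)
        if key in memo_b:
            return memo_b[key]
        if target is None:
            target = cb[u][x] if include_ne else cne[u][x]
        out = []
        kids = G.children[u]
        u1, u2 = kids if kids else (-1, -1)
        xkids = Sp.children[x]
        if not xkids:
            if u1 == -1 and gleaf_site[u] == x and abs(target) <= _TOL:
                out.append((("C", u, x),))
        elif len(xkids) == 2:
            xc1, xc2 = xkids
            if u1 != -1:
                for a, b in ((xc1, xc2), (xc2, xc1)):
                    if abs(cf[u1][a] + cf[u2][b] - target) <= _TOL:
                        for s1 in expand_full(u1, a):
                            for s2 in expand_full(u2, b):
                                out.append((("S", u, x, a),) + s1 + s2)
            for a, lost in ((xc1, xc2), (xc2, xc1)):
                if abs(lam + cf[u][a] - target) <= _TOL:
                    for s in expand_full(u, a):
                        out.append((("SL", u, lost, a),) + s)
        if x != Sp.root and u1 != -1:
            if abs(delta + cf[u1][x] + cf[u2][x] - target) <= _TOL:
                for s1 in expand_full(u1, x):
                    for s2 in expand_full(u2, x):
                        out.append((("D", u, x),) + s1 + s2)
            for y in Sp.partners(x):
                for a, b in ((u1, u2), (u2, u1)):
                    if abs(tau + cf[a][x] + cf[b][y] - target) <= _TOL:
                        for s1 in expand_full(a, x):
                            for s2 in expand_full(b, y):
                                out.append((("T", u, x, y, b),) + s1 + s2)
        if include_ne and len(xkids) == 1:
            (xc,) = xkids
            if abs(cf[u][xc] - target) <= _TOL:
                for s in expand_full(u, xc):
                    out.append((("NE", u, x),) + s)
        memo_b[key] = out
        return out

    def expand_full(u, x):
        key = (u, x)
        if key in memo_f:
            return memo_f[key]
        out = []
        if cb[u][x] <= cf[u][x] + _TOL:
            out.extend(expand_base(u, x))
        if x != Sp.root:
            for y in Sp.partners(x):
                if abs(cb[u][y] + tlc - cf[u][x]) <= _TOL:
                    for s in expand_base(u, y):
                        out.append((("TL", u, x, y),) + s)
        memo_f[key] = out
        return out

    r = G.n_nodes - 1
    scenarios = []
    for x in range(NS):
        if cstart[x] <= opt + _TOL:
            scenarios.extend(expand_base(r, x, include_ne=False, target=opt))
            if x != Sp.root:
                for y in Sp.partners(x):
                    if abs(cb[r][y] + tlc - opt) <= _TOL:
                        for s in expand_base(r, y):
                            scenarios.append((("TL", r, x, y),) + s)
    if len(scenarios) != total:
        raise ReconciliationError(
            f"enumeration produced {len(scenarios)} scenarios but the DP "
            f"counted {total}"
        )
    return scenarios


def scenario_cost(scenario, costs: EventCosts = EventCosts()) -> float:
    """Total parsimony cost of an explicit scenario."""
    per = {"D": costs.duplication, "T": costs.transfer, "L": costs.loss,
           "SL": costs.loss, "TL": costs.transfer + costs.loss,
           "S": 0.0, "NE": 0.0, "C": 0.0}
    return sum(per[e[0]] for e in scenario)


def tally_events(scenarios):
    """Per-(u, x, type) occurrence counts over a list of scenarios.

    T/TL are tallied by donor; SL by the branch where the loss happened —
    the same keys as :class:`ReconciliationSummary.event_counts`.
    """
    out: dict[tuple, int] = {}
    for sc in scenarios:
        for e in sc:
            t, u, x = e[0], e[1], e[2]
            k = (u, x, t)
            out[k] = out.get(k, 0) + 1
    return out
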