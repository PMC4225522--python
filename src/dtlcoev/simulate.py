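"""Correlated gene-pair simulation along a dated species tree.

Two gene lineages evolve down the species tree under a birth-death process
with duplication, transfer and loss rates (events per gene per My).  A
co-evolution parameter c in [0, 1] couples the two families: while a pair of
lineages (one per family) is *paired*, D/T/L events are drawn for the pair at
the joint rate 2a/(1+c) (a = r_D + r_T + r_L) and each event occurs in one of
the two genes with probability 1 and in the other with probability c — so
each gene's marginal event rate is exactly a for every c.  Rules for paired
events:

* speciation/extant boundaries always affect both genes; like children are
  re-paired;
* duplication in both: like children re-paired; in one: the first child of
  the duplicated gene stays paired, the other copy becomes a free lineage;
* transfer in both: the receiver branch must be the same; stay-children and
  moved-children are re-paired; in one: the stay-child remains paired and
  the moved copy becomes free;
* loss in both: the pair dies; in one: the survivor becomes a free lineage.

Free (unpaired) lineages follow the ordinary single-gene process at rate a.
At c = 1 every event is shared and the two trees are identical; at c = 0 the
families evolve independently.

Lineages whose descendants all die are pruned from the returned trees but
every D/T/L event stays in the logs, with shared events carrying the same
event id in both logs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .errors import DtlCoevError
from .events import WeightedEventSet
from .trees import DatedSpeciesTree, GeneTree

__all__ = [
    "RateSet",
    "Event",
    "SimulatedPair",
    "sample_rates",
    "simulate_pair",
    "simulate_single",
    "true_event_sets",
    "yule_tree",
]

#: rate-sampling intervals (events per gene per My): the loss rate is uniform
#: on LOSS_INTERVAL; birth = loss x U(BIRTH_TO_LOSS); duplication share of
#: birth ~ U(DUP_SHARE); the transfer rate is the remainder of the birth rate.
LOSS_INTERVAL = (0.001, 0.0018)
BIRTH_TO_LOSS = (0.5, 1.1)
DUP_SHARE = (0.7, 1.0)


@dataclass(frozen=True)
class RateSet:
    """Per-family D/T/L rates; activity a is their exact sum."""

    duplication: float
    transfer: float
    loss: float

    @property
    def activity(self) -> float:
        return self.duplication + self.transfer + self.loss


def sample_rates(rng: np.random.Generator) -> RateSet:
    """Draw one family's rates from the benchmark sampling scheme."""
    r_l = rng.uniform(*LOSS_INTERVAL)
    birth = r_l * rng.uniform(*BIRTH_TO_LOSS)
    r_d = birth * rng.uniform(*DUP_SHARE)
    return RateSet(duplication=r_d, transfer=birth - r_d, loss=r_l)


@dataclass(frozen=True)
class Event:
    """One realised D/T/L event; shared events repeat the id in both logs."""

    tree: int      # 1 or 2
    etype: str     # "D", "T" or "L"
    branch: int    # species branch (bottom-node id) where the event happened
    date: float    # age of the event
    shared: bool
    eid: int


class _N:
    __slots__ = ("children", "label", "time", "dead")

    def __init__(self, time):
        self.children = []
        self.label = None
        self.time = time
        self.dead = False


@dataclass
class SimulatedPair:
    """Two correlated gene trees plus their ground-truth event logs."""

    species_tree: DatedSpeciesTree
    tree1: GeneTree | None
    tree2: GeneTree | None
    events1: list[Event]
    events2: list[Event]
    rates: RateSet
    c: float

    @property
    def n_shared(self) -> int:
        """Number of D/T/L events realised in both families."""
        ids1 = {e.eid for e in self.events1 if e.shared}
        ids2 = {e.eid for e in self.events2 if e.shared}
        return len(ids1 & ids2)


def _alive_branches(S: DatedSpeciesTree, t: float) -> list[int]:
    return [
        y for y in range(S.n_nodes)
        if y != S.root and S.ages[y] < t < S.ages[S.parent[y]]
    ]


def _gene_tree_from(root: _N | None) -> GeneTree | None:
    root = _prune(root)
    if root is None:
        return None
    children, parent, labels, species, ages = [], [], [], [], []
    order: list[_N] = []

    def post(n):
        for ch in n.children:
            post(ch)
        order.append(n)

    post(root)
    index = {id(n): i for i, n in enumerate(order)}
    for n in order:
        children.append(tuple(index[id(ch)] for ch in n.children))
        parent.append(-1)
        labels.append(n.label)
        species.append(n.label.split("_", 1)[0] if n.label else None)
        ages.append(n.time)
    for i, n in enumerate(order):
        for ch in n.children:
            parent[index[id(ch)]] = i
    return GeneTree(children, parent, labels, species, ages=ages)


def _prune(n: _N | None) -> _N | None:
    if n is None:
        return None
    if not n.children:
        return None if (n.dead or n.label is None) else n
    kept = [k for k in (_prune(ch) for ch in n.children) if k is not None]
    if not kept:
        return None
    if len(kept) == 1:
        return kept[0]
    n.children = kept
    return n


def simulate_pair(S: DatedSpeciesTree, rates: RateSet, c: float,
                  rng: np.random.Generator) -> SimulatedPair:
    """Simulate one correlated pair of gene trees (see module docstring)."""
    if not 0.0 <= c <= 1.0:
        raise DtlCoevError(f"co-evolution parameter c={c} outside [0, 1]")
    if S.is_leaf(S.root):
        raise DtlCoevError("species tree needs at least two leaves")
    a = rates.activity
    r_d, r_t = rates.duplication, rates.transfer
    logs: tuple[list[Event], list[Event]] = ([], [])
    counters = [0, 0]
    next_eid = [0]

    def log(i, etype, branch, date, shared, eid):
        logs[i].append(Event(i + 1, etype, branch, date, shared, eid))

    def new_eid():
        next_eid[0] += 1
        return next_eid[0]

    def make_leaf(i, node, x):
        counters[i] += 1
        node.label = f"{S.labels[x]}_{counters[i]}"
        node.time = 0.0

    roots = (_N(S.height), _N(S.height))
    # the process starts with the pair at the species root: speciate at once
    stack: list[tuple] = []

    def speciate_pair(n1, n2, x):
        xc1, xc2 = S.children[x]
        t = float(S.ages[x])
        kids = [(_N(t), _N(t)) for _ in range(2)]
        n1.children = [kids[0][0], kids[1][0]]
        n1.time = t
        n2.children = [kids[0][1], kids[1][1]]
        n2.time = t
        stack.append(("P", kids[0][0], kids[0][1], xc1, t))
        stack.append(("P", kids[1][0], kids[1][1], xc2, t))

    def speciate_single(i, n, x):
        xc1, xc2 = S.children[x]
        t = float(S.ages[x])
        k1, k2 = _N(t), _N(t)
        n.children = [k1, k2]
        n.time = t
        stack.append(("U", i, k1, xc1, t))
        stack.append(("U", i, k2, xc2, t))

    def draw_type() -> str:
        r = rng.random() * a
        if r < r_d:
            return "D"
        if r < r_d + r_t:
            return "T"
        return "L"

    speciate_pair(roots[0], roots[1], S.root)
    while stack:
        item = stack.pop()
        if item[0] == "P":
            _, n1, n2, x, t = item
            rate = 2.0 * a / (1.0 + c)
            tn = t - (rng.exponential(1.0 / rate) if rate > 0 else math.inf)
            bottom = float(S.ages[x])
            if tn <= bottom:
                if S.is_leaf(x):
                    make_leaf(0, n1, x)
                    make_leaf(1, n2, x)
                else:
                    speciate_pair(n1, n2, x)
                continue
            etype = draw_type()
            primary = int(rng.integers(0, 2))
            both = rng.random() < c
            nodes = (n1, n2)
            np_, no = nodes[primary], nodes[1 - primary]
            if etype == "D":
                eid = new_eid()
                if both:
                    log(0, "D", x, tn, True, eid)
                    log(1, "D", x, tn, True, eid)
                    ks = [(_N(tn), _N(tn)) for _ in range(2)]
                    n1.children = [ks[0][0], ks[1][0]]
                    n2.children = [ks[0][1], ks[1][1]]
                    n1.time = n2.time = tn
                    stack.append(("P", ks[0][0], ks[0][1], x, tn))
                    stack.append(("P", ks[1][0], ks[1][1], x, tn))
                else:
                    log(primary, "D", x, tn, False, eid)
                    k1, k2 = _N(tn), _N(tn)
                    np_.children = [k1, k2]
                    np_.time = tn
                    pair = (k1, no) if primary == 0 else (no, k1)
                    stack.append(("P", pair[0], pair[1], x, tn))
                    stack.append(("U", primary, k2, x, tn))
            elif etype == "T":
                targets = _alive_branches(S, tn)
                targets.remove(x)
                if not targets:
                    continue  # nowhere to transfer; cannot happen below the root
                y = targets[int(rng.integers(0, len(targets)))]
                eid = new_eid()
                if both:
                    log(0, "T", x, tn, True, eid)
                    log(1, "T", x, tn, True, eid)
                    s1, m1, s2, m2 = _N(tn), _N(tn), _N(tn), _N(tn)
                    n1.children = [s1, m1]
                    n2.children = [s2, m2]
                    n1.time = n2.time = tn
                    stack.append(("P", s1, s2, x, tn))
                    stack.append(("P", m1, m2, y, tn))
                else:
                    log(primary, "T", x, tn, False, eid)
                    s, m = _N(tn), _N(tn)
                    np_.children = [s, m]
                    np_.time = tn
                    pair = (s, no) if primary == 0 else (no, s)
                    stack.append(("P", pair[0], pair[1], x, tn))
                    stack.append(("U", primary, m, y, tn))
            else:  # loss
                eid = new_eid()
                if both:
                    log(0, "L", x, tn, True, eid)
                    log(1, "L", x, tn, True, eid)
                    n1.dead = n2.dead = True
                else:
                    log(primary, "L", x, tn, False, eid)
                    np_.dead = True
                    stack.append(("U", 1 - primary, no, x, tn))
        else:
            _, i, n, x, t = item
            tn = t - (rng.exponential(1.0 / a) if a > 0 else math.inf)
            bottom = float(S.ages[x])
            if tn <= bottom:
                if S.is_leaf(x):
                    make_leaf(i, n, x)
                else:
                    speciate_single(i, n, x)
                continue
            etype = draw_type()
            if etype == "D":
                log(i, "D", x, tn, False, new_eid())
                k1, k2 = _N(tn), _N(tn)
                n.children = [k1, k2]
                n.time = tn
                stack.append(("U", i, k1, x, tn))
                stack.append(("U", i, k2, x, tn))
            elif etype == "T":
                targets = _alive_branches(S, tn)
                targets.remove(x)
                if not targets:
                    continue
                y = targets[int(rng.integers(0, len(targets)))]
                log(i, "T", x, tn, False, new_eid())
                s, m = _N(tn), _N(tn)
                n.children = [s, m]
                n.time = tn
                stack.append(("U", i, s, x, tn))
                stack.append(("U", i, m, y, tn))
            else:
                log(i, "L", x, tn, False, new_eid())
                n.dead = True

    return SimulatedPair(
        species_tree=S,
        tree1=_gene_tree_from(roots[0]),
        tree2=_gene_tree_from(roots[1]),
        events1=logs[0],
        events2=logs[1],
        rates=rates,
        c=float(c),
    )


def simulate_single(S: DatedSpeciesTree, rates: RateSet,
                    rng: np.random.Generator):
    """Plain one-family birth-death simulation (calibration reference).

    Written independently of :func:`simulate_pair`; returns
    ``(GeneTree | None, [Event])``.
    """
    if S.is_leaf(S.root):
        raise DtlCoevError("species tree needs at least two leaves")
    a = rates.activity
    r_d, r_t = rates.duplication, rates.transfer
    events: list[Event] = []
    counter = [0]
    root = _N(S.height)
    xc1, xc2 = S.children[S.root]
    k1, k2 = _N(S.height), _N(S.height)
    root.children = [k1, k2]
    todo = [(k1, xc1, S.height), (k2, xc2, S.height)]
    eid = [0]
    while todo:
        n, x, t = todo.pop()
        tn = t - (rng.exponential(1.0 / a) if a > 0 else math.inf)
        if tn <= float(S.ages[x]):
            if S.is_leaf(x):
                counter[0] += 1
                n.label = f"{S.labels[x]}_{counter[0]}"
                n.time = 0.0
            else:
                c1, c2 = S.children[x]
                t0 = float(S.ages[x])
                a1, a2 = _N(t0), _N(t0)
                n.children = [a1, a2]
                n.time = t0
                todo.append((a1, c1, t0))
                todo.append((a2, c2, t0))
            continue
        r = rng.random() * a
        eid[0] += 1
        if r < r_d:
            events.append(Event(1, "D", x, tn, False, eid[0]))
            a1, a2 = _N(tn), _N(tn)
            n.children = [a1, a2]
            n.time = tn
            todo.append((a1, x, tn))
            todo.append((a2, x, tn))
        elif r < r_d + r_t:
            targets = _alive_branches(S, tn)
            targets.remove(x)
            if not targets:
                continue
            y = targets[int(rng.integers(0, len(targets)))]
            events.append(Event(1, "T", x, tn, False, eid[0]))
            s, m = _N(tn), _N(tn)
            n.children = [s, m]
            n.time = tn
            todo.append((s, x, tn))
            todo.append((m, y, tn))
        else:
            events.append(Event(1, "L", x, tn, False, eid[0]))
            n.dead = True
    return _gene_tree_from(root), events


def true_event_sets(pair: SimulatedPair):
    """Weight-1 ground-truth event sets, bypassing reconciliation."""
    out = []
    for evs in (pair.events1, pair.events2):
        W = WeightedEventSet(pair.species_tree)
        for e in evs:
            if e.etype in ("D", "T", "L"):
                W.add(e.branch, e.etype, 1.0, source=f"e{e.eid}")
        out.append(W)
    return out[0], out[1]


def yule_tree(n_leaves: int, height: float, rng: np.random.Generator,
              label_prefix: str = "s") -> DatedSpeciesTree:
    """Random pure-birth topology with n_leaves tips, rescaled to height."""
    if n_leaves < 2:
        raise DtlCoevError("need at least 2 leaves")
    split_times: list[float] = []
    t = 0.0
    for k in range(1, n_leaves):
        split_times.append(t)
        t += rng.exponential(1.0 / k)
    present = t + rng.exponential(1.0 / n_leaves)
    ages = [present - s for s in split_times]  # ages of splits, descending
    scale = height / ages[0]
    # grow the topology: each split divides a uniformly chosen active tip
    # (the first split is the root itself)
    root = {"children": [], "age": 0.0}
    active = [root]
    for agev in ages:
        idx = int(rng.integers(0, len(active)))
        nd = active[idx]
        nd["age"] = agev * scale
        c1 = {"children": [], "age": 0.0}
        c2 = {"children": [], "age": 0.0}
        nd["children"] = [c1, c2]
        active[idx] = c1
        active.append(c2)
    # make leaves
    for i, nd in enumerate(active):
        nd["age"] = 0.0
        nd["label"] = label_prefix + str(i + 1)
    children, parent, agearr, labels = [], [], [], []
    order = []

    def post(nd):
        for ch in nd["children"]:
            post(ch)
        order.append(nd)

    post(root)
    index = {id(nd): i for i, nd in enumerate(order)}
    for nd in order:
        children.append(tuple(index[id(ch)] for ch in nd["children"]))
        parent.append(-1)
        agearr.append(nd["age"])
        labels.append(nd.get("label"))
    for nd in order:
        for ch in nd["children"]:
            parent[index[id(ch)]] = index[id(nd)]
    return DatedSpeciesTree(children, parent, agearr, labels)
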