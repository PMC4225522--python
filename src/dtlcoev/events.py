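"""Weighted event sets on the original species tree.

A reconciliation summary lives on the subdivided tree and contains all seven
DTL event types.  For co-evolution detection only duplications, transfers and
losses are informative: speciations and contemporary events are dictated by
the species tree, and no-events are subdivision bookkeeping.  The projection

* drops S, C and NE events,
* keeps each SL only as an L on the branch where the lost side entered,
* splits each TL into a T and an L, both on the donor branch,
* merges transfers of the same gene node departing from the same original
  branch (receivers are deliberately not distinguished), and
* maps every subdivided branch back to its original branch ("undoes" the
  subdivision).

The result is, per (branch, event type) *bin*, a multiset of support weights
in (0, 1] — the fraction of most-parsimonious reconciliations containing the
event — each attached to the gene node it came from.
"""

from __future__ import annotations

import math
from fractions import Fraction

from .errors import EventSetError
from .reconcile import ReconciliationSummary
from .trees import DatedSpeciesTree, SubdividedSpeciesTree

__all__ = ["WeightedEventSet", "project", "read_event_set", "write_event_set"]

PROJECTED_TYPES = ("D", "T", "L")
_MERGE_TOL = 1e-6


class WeightedEventSet:
    """Multisets of event-support weights per (species branch, D/T/L).

    ``bins[(branch, type)]`` is a list of ``(weight, source_id)`` pairs;
    branch ids are node ids of the *original* species tree (the branch's
    bottom node).  Weights lie in (0, 1].
    """

    def __init__(self, species_tree: DatedSpeciesTree):
        self.species_tree = species_tree
        self.bins: dict[tuple[int, str], list[tuple[float, str]]] = {}

    def add(self, branch: int, etype: str, weight: float, source: str = ""):
        if etype not in PROJECTED_TYPES:
            raise EventSetError(f"event type must be one of D/T/L, got {etype!r}")
        if branch == self.species_tree.root or not (
            0 <= branch < self.species_tree.n_nodes
        ):
            raise EventSetError(f"not a branch of the species tree: {branch}")
        if not 0.0 < weight <= 1.0 + _MERGE_TOL:
            raise EventSetError(f"weight {weight} outside (0, 1]")
        self.bins.setdefault((branch, etype), []).append(
            (min(float(weight), 1.0), source)
        )

    def weights(self, branch: int, etype: str) -> list[float]:
        return [w for w, _ in self.bins.get((branch, etype), ())]

    def total(self) -> float:
        """Sum of all weights: the expected number of D/T/L events."""
        return float(sum(w for ws in self.bins.values() for w, _ in ws))

    def rounded_count(self) -> int:
        """The null-model event count N: total weight, rounded up."""
        return math.ceil(self.total() - 1e-12) if self.bins else 0

    def __len__(self):
        return sum(len(ws) for ws in self.bins.values())

    def __repr__(self):
        return (
            f"<WeightedEventSet {len(self)} events, "
            f"total weight {self.total():.3g}>"
        )


def project(rs: ReconciliationSummary,
            Sp: SubdividedSpeciesTree | None = None) -> WeightedEventSet:
    """Project a reconciliation summary to a weighted event set on S.

    Same-(gene node, original branch, type) frequencies are merged by
    summation — they are mutually exclusive alternatives within the MPR
    space, so their fractions add; a merged weight exceeding 1 signals a
    counting bug and raises :class:`EventSetError`.
    """
    Sp = Sp or rs.subdivided
    back = Sp.orig_branch
    merged: dict[tuple[int, int, str], float | Fraction] = {}

    def bump(u, branch, etype, w):
        k = (u, branch, etype)
        merged[k] = merged.get(k, 0) + w

    total = rs.mpr_count
    for (u, x, ev), cnt in rs.event_counts.items():
        w = Fraction(cnt, total) if isinstance(cnt, int) else cnt / total
        if ev in ("S", "C", "NE"):
            continue
        if ev == "D":
            bump(u, back[x], "D", w)
        elif ev == "T":
            bump(u, back[x], "T", w)
        elif ev == "TL":
            # a TL is a transfer plus the loss of the stay-side child, both
            # on the donor branch; its T merges with plain transfers of the
            # same gene node from the same branch (mutually exclusive
            # alternatives across MPRs)
            bump(u, back[x], "T", w)
            bump(u, back[x], "L", w)
        elif ev == "SL":
            bump(u, back[x], "L", w)
        else:  # pragma: no cover
            raise EventSetError(f"unknown event type {ev!r}")

    out = WeightedEventSet(Sp.S)
    for (u, branch, etype), w in merged.items():
        wf = float(w)
        if wf > 1.0 + _MERGE_TOL:
            raise EventSetError(
                f"merged frequency {wf} > 1 for gene node {u} on branch "
                f"{branch}: counting bug"
            )
        out.add(branch, etype, wf, source=f"g{u}")
    return out


# ---------------------------------------------------------------------------
# TSV round-trip — lets any external reconciliation method feed the scorer
# ---------------------------------------------------------------------------

def write_event_set(W: WeightedEventSet, path) -> None:
    S = W.species_tree
    with open(path, "w") as fh:
        fh.write("branch_id\tevent_type\tweight\tsource_id\n")
        for (branch, etype) in sorted(W.bins):
            for w, src in W.bins[(branch, etype)]:
                fh.write(f"{S.branch_name(branch)}\t{etype}\t{w:.12g}\t{src}\n")


def read_event_set(path, species_tree: DatedSpeciesTree) -> WeightedEventSet:
    names = species_tree.name_to_node()
    out = WeightedEventSet(species_tree)
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            if ln == 1 and line.startswith("branch_id"):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise EventSetError(f"{path}:{ln}: expected >=3 columns")
            bname, etype, wtxt = parts[0], parts[1], parts[2]
            src = parts[3] if len(parts) > 3 else ""
            if bname not in names:
                raise EventSetError(f"{path}:{ln}: unknown branch {bname!r}")
            if etype not in PROJECTED_TYPES:
                raise EventSetError(
                    f"{path}:{ln}: event type must be D/T/L, got {etype!r}"
                )
            try:
                w = float(wtxt)
            except ValueError:
                raise EventSetError(f"{path}:{ln}: bad weight {wtxt!r}") from None
            if not 0.0 < w <= 1.0:
                raise EventSetError(f"{path}:{ln}: weight {w} outside (0, 1]")
            branch = names[bname]
            if branch == species_tree.root:
                raise EventSetError(f"{path}:{ln}: {bname!r} is the root, not a branch")
            out.add(branch, etype, w, source=src)
    return out
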