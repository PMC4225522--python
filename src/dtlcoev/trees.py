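"""Dated species trees, gene trees, and the time-sliced subdivision.

A *dated* species tree is a rooted binary tree whose every node carries an
age theta (time before the present, e.g. in My); leaves sit at age 0 and ages
strictly increase towards the root.  Reconciliation with time-consistent
transfers works on the *subdivision* S' of S: on every edge that spans the age
of some internal node, an artificial degree-2 node is inserted at that age.
This partitions time into slices such that every subdivided edge lies within
exactly one slice; transfers are only allowed between contemporaneous edges,
i.e. edges of the same slice.

Trees are stored as flat arrays indexed by node id in postorder (children
before parents, root last).  A branch is identified by its bottom (child)
node; the root has no branch above it.
"""

from __future__ import annotations

import dendropy
import numpy as np

from .errors import MappingError, TreeError

__all__ = [
    "DatedSpeciesTree",
    "GeneTree",
    "SubdividedSpeciesTree",
    "parse_dated_newick",
    "parse_gene_tree",
    "read_species_map",
    "prefix_species_rule",
]

#: relative (to tree height) tolerance for ultrametricity and age ties
ULTRAMETRIC_RTOL = 1e-6


def _dendropy_parse(text: str) -> dendropy.Tree:
    try:
        return dendropy.Tree.get(
            data=text,
            schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:  # dendropy raises several parse error types
        raise TreeError(f"could not parse Newick: {exc}") from exc


def _postorder_arrays(tree: dendropy.Tree):
    """Flatten a dendropy tree into postorder arrays.

    Returns (children, parent, edge_lengths, labels, names) where labels are
    leaf taxon labels (None for internal nodes) and names are internal node
    labels when present in the Newick.
    """
    nodes = list(tree.postorder_node_iter())
    index = {id(nd): i for i, nd in enumerate(nodes)}
    children: list[tuple[int, ...]] = []
    parent = [-1] * len(nodes)
    elen: list[float | None] = []
    labels: list[str | None] = []
    names: list[str | None] = []
    for i, nd in enumerate(nodes):
        kids = tuple(index[id(ch)] for ch in nd.child_nodes())
        children.append(kids)
        for k in kids:
            parent[k] = i
        elen.append(nd.edge.length)
        if nd.is_leaf():
            if nd.taxon is None or not nd.taxon.label:
                raise TreeError("leaf without a label")
            labels.append(str(nd.taxon.label))
            names.append(None)
        else:
            labels.append(None)
            names.append(str(nd.label) if nd.label else None)
    return children, parent, elen, labels, names


class DatedSpeciesTree:
    """Rooted binary ultrametric species tree with node ages.

    Nodes are indexed in postorder; ``root == n_nodes - 1``.  ``ages`` holds
    theta (leaves exactly 0); branch ``i`` is the edge above node ``i`` and
    has duration ``ages[parent[i]] - ages[i]``.
    """

    def __init__(self, children, parent, ages, labels, names=None):
        self.children = [tuple(c) for c in children]
        self.parent = list(parent)
        self.ages = np.asarray(ages, dtype=float)
        self.labels = list(labels)
        self.names = list(names) if names is not None else [None] * len(parent)
        self.n_nodes = len(self.parent)
        self.root = self.parent.index(-1)
        self._validate()
        self.leaves = [i for i in range(self.n_nodes) if not self.children[i]]
        self.label_to_leaf = {self.labels[i]: i for i in self.leaves}

    # -- validation ----------------------------------------------------
    def _validate(self):
        seen = set()
        for i in range(self.n_nodes):
            kids = self.children[i]
            if kids and len(kids) != 2:
                raise TreeError(
                    f"species tree must be binary; node {self._name(i)} has "
                    f"{len(kids)} children"
                )
            if not kids:
                lbl = self.labels[i]
                if lbl in seen:
                    raise TreeError(f"duplicate leaf label {lbl!r}")
                seen.add(lbl)
                if self.ages[i] != 0.0:
                    raise TreeError(f"leaf {lbl!r} not at age 0")
            else:
                for k in kids:
                    if not self.ages[i] > self.ages[k]:
                        raise TreeError(
                            f"node {self._name(i)} (age {self.ages[i]:g}) not "
                            f"strictly older than child (age {self.ages[k]:g})"
                        )

    def _name(self, i: int) -> str:
        return self.branch_name(i)

    # -- accessors -----------------------------------------------------
    @property
    def height(self) -> float:
        return float(self.ages[self.root])

    def is_leaf(self, i: int) -> bool:
        return not self.children[i]

    def branches(self) -> list[int]:
        """All branch ids = every node except the root."""
        return [i for i in range((self.n_nodes)) if i != self.root]

    def branch_length(self, i: int) -> float:
        return float(self.ages[self.parent[i]] - self.ages[i])

    def branch_name(self, i: int) -> str:
        """Stable textual id of node/branch i (leaf label or internal name)."""
        if self.labels[i] is not None:
            return self.labels[i]
        if self.names[i]:
            return self.names[i]
        return f"n{i}"

    def name_to_node(self) -> dict[str, int]:
        out = {}
        for i in range(self.n_nodes):
            nm = self.branch_name(i)
            if nm in out:
                raise TreeError(f"ambiguous node name {nm!r}")
            out[nm] = i
        return out

    # -- construction --------------------------------------------------
    @classmethod
    def from_newick(cls, text: str, rtol: float = ULTRAMETRIC_RTOL) -> "DatedSpeciesTree":
        """Parse a Newick string with branch lengths into a dated tree.

        Ages are reconstructed from root-to-leaf path lengths; the tree must
        be ultrametric within ``rtol`` (relative to its height), after which
        leaves are pinned exactly at age 0 and near-equal internal ages are
        merged so that slice boundaries are exact.
        """
        tree = _dendropy_parse(text)
        children, parent, elen, labels, names = _postorder_arrays(tree)
        n = len(parent)
        root = parent.index(-1)
        for i in range(n):
            if i != root and elen[i] is None:
                raise TreeError("every non-root edge needs a branch length")
        depth = [0.0] * n
        for i in reversed(range(n)):  # preorder: root first
            if i != root:
                depth[i] = depth[parent[i]] + float(elen[i])
        height = max(depth[i] for i in range(n) if not children[i])
        if height <= 0:
            raise TreeError("tree has zero height")
        tol = rtol * height
        worst = max(
            abs(height - depth[i]) for i in range(n) if not children[i]
        )
        if worst > tol:
            raise TreeError(
                f"tree is not ultrametric: max leaf-depth deviation {worst:g} "
                f"exceeds tolerance {tol:g}"
            )
        ages = [height - d for d in depth]
        for i in range(n):
            if not children[i]:
                ages[i] = 0.0
        _snap_ages(ages, children, tol)
        return cls(children, parent, ages, labels, names)

    def to_newick(self) -> str:
        def rec(i: int) -> str:
            if not self.children[i]:
                core = self.labels[i]
            else:
                core = "(" + ",".join(rec(k) for k in self.children[i]) + ")"
                if self.names[i]:
                    core += self.names[i]
            if i == self.root:
                return core
            return f"{core}:{self.branch_length(i):.10g}"

        return rec(self.root) + ";"

    def subdivide(self) -> "SubdividedSpeciesTree":
        return SubdividedSpeciesTree(self)

    def __repr__(self):
        return (
            f"<DatedSpeciesTree {len(self.leaves)} leaves, "
            f"height {self.height:g}>"
        )


def _snap_ages(ages, children, tol):
    """Merge internal ages that agree within tol to a shared representative."""
    internal = sorted(
        (i for i in range(len(ages)) if children[i]), key=lambda i: ages[i]
    )
    group: list[int] = []
    for i in internal + [None]:
        if group and (i is None or ages[i] - ages[group[-1]] > tol):
            rep = sum(ages[j] for j in group) / len(group)
            for j in group:
                ages[j] = rep
            group = []
        if i is not None:
            group.append(i)


def parse_dated_newick(text: str, rtol: float = ULTRAMETRIC_RTOL) -> DatedSpeciesTree:
    """Functional alias for :meth:`DatedSpeciesTree.from_newick`."""
    return DatedSpeciesTree.from_newick(text, rtol=rtol)


# ---------------------------------------------------------------------------
# gene trees
# ---------------------------------------------------------------------------

def prefix_species_rule(label: str) -> str:
    """Default naming rule: species = gene label prefix up to first '_'."""
    return label.split("_", 1)[0]


def read_species_map(path) -> dict[str, str]:
    """Two-column TSV ``gene_label<TAB>species_label``."""
    out: dict[str, str] = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise MappingError(f"{path}:{ln}: expected 2 tab-separated columns")
            out[parts[0]] = parts[1]
    return out


class GeneTree:
    """Rooted binary gene tree whose leaves are assigned to species labels.

    ``species[i]`` is the species label for leaf node ``i`` (None for
    internal nodes).  ``ages`` is optional (used by the simulator to carry
    event dates); reconciliation only uses the topology.
    """

    def __init__(self, children, parent, labels, species, ages=None):
        self.children = [tuple(c) for c in children]
        self.parent = list(parent)
        self.labels = list(labels)
        self.species = list(species)
        self.ages = None if ages is None else np.asarray(ages, dtype=float)
        self.n_nodes = len(self.parent)
        self.root = self.parent.index(-1)
        self.leaves = [i for i in range(self.n_nodes) if not self.children[i]]
        self._validate()

    def _validate(self):
        if self.n_nodes == 0:
            raise TreeError("empty gene tree")
        seen = set()
        for i in range(self.n_nodes):
            kids = self.children[i]
            if kids and len(kids) != 2:
                raise TreeError(
                    f"gene tree must be binary; node {i} has {len(kids)} children"
                )
            if not kids:
                if self.labels[i] in seen:
                    raise TreeError(f"duplicate gene leaf label {self.labels[i]!r}")
                seen.add(self.labels[i])
                if self.species[i] is None:
                    raise MappingError(f"leaf {self.labels[i]!r} has no species")

    def is_leaf(self, i: int) -> bool:
        return not self.children[i]

    @property
    def n_leaves(self) -> int:
        return len(self.leaves)

    @classmethod
    def from_newick(
        cls,
        text: str,
        species_map: dict[str, str] | None = None,
        naming_rule=prefix_species_rule,
        species_tree: DatedSpeciesTree | None = None,
    ) -> "GeneTree":
        """Parse a gene tree; resolve each leaf to a species label.

        An explicit ``species_map`` takes precedence over the naming rule.
        If ``species_tree`` is given, every resolved species must be one of
        its leaves; offending leaf labels are reported together.
        """
        tree = _dendropy_parse(text)
        children, parent, elen, labels, _names = _postorder_arrays(tree)
        species: list[str | None] = []
        for i, lbl in enumerate(labels):
            if children[i]:
                species.append(None)
            elif species_map is not None and lbl in species_map:
                species.append(species_map[lbl])
            else:
                species.append(naming_rule(lbl))
        gt = cls(children, parent, labels, species)
        if species_tree is not None:
            gt.check_against(species_tree)
        return gt

    def check_against(self, species_tree: DatedSpeciesTree) -> None:
        known = set(species_tree.label_to_leaf)
        bad = sorted(
            {
                self.species[i]
                for i in self.leaves
                if self.species[i] not in known
            }
        )
        if bad:
            raise MappingError(
                "gene leaves map to species absent from the species tree: "
                + ", ".join(map(str, bad))
            )

    def to_newick(self) -> str:
        def rec(i: int) -> str:
            if not self.children[i]:
                core = self.labels[i]
            else:
                core = "(" + ",".join(rec(k) for k in self.children[i]) + ")"
            if i == self.root:
                return core
            if self.ages is not None:
                ln = self.ages[self.parent[i]] - self.ages[i]
                return f"{core}:{ln:.10g}"
            return core

        return rec(self.root) + ";"

    def __repr__(self):
        return f"<GeneTree {self.n_leaves} leaves>"


def parse_gene_tree(text, species_map=None, naming_rule=prefix_species_rule,
                    species_tree=None) -> GeneTree:
    """Functional alias for :meth:`GeneTree.from_newick`."""
    return GeneTree.from_newick(
        text, species_map=species_map, naming_rule=naming_rule,
        species_tree=species_tree,
    )


# ---------------------------------------------------------------------------
# subdivision
# ---------------------------------------------------------------------------

class SubdividedSpeciesTree:
    """The time-sliced subdivision S' of a dated species tree.

    The first ``S.n_nodes`` node ids coincide with the nodes of S; artificial
    degree-2 nodes are appended after them.  Every node age equals one of the
    boundary ``levels`` (ascending, levels[0] == 0, last == root age); the
    branch above node ``x`` spans the slice ``level[x]`` (between
    ``levels[level[x]]`` and ``levels[level[x]+1]``).  ``orig_branch[x]`` is
    the branch of S (identified by its bottom node) containing the branch
    above ``x`` (-1 for the root): the back-map used to "undo" the
    subdivision.
    """

    def __init__(self, S: DatedSpeciesTree):
        self.S = S
        internal_ages = sorted({float(S.ages[i]) for i in range(S.n_nodes)
                                if S.children[i]})
        if internal_ages and internal_ages[0] <= 0.0:
            raise TreeError("internal node at age 0 creates a degenerate slice")
        self.levels = [0.0] + internal_ages
        level_of = {a: k for k, a in enumerate(self.levels)}

        children = [list(S.children[i]) for i in range(S.n_nodes)]
        parent = list(S.parent)
        ages = [float(a) for a in S.ages]
        orig_branch = [i if i != S.root else -1 for i in range(S.n_nodes)]
        is_artificial = [False] * S.n_nodes

        for y in S.branches():
            p = S.parent[y]
            lo, hi = float(S.ages[y]), float(S.ages[p])
            inner = [a for a in internal_ages if lo < a < hi]
            below = y  # current bottom of the partially subdivided edge
            for a in inner:  # ascending: insert from bottom up
                w = len(parent)
                ages.append(a)
                children.append([below])
                orig_branch.append(y)
                is_artificial.append(True)
                parent.append(parent[below])
                # splice w between below and its current parent
                pp = parent[below]
                children[pp][children[pp].index(below)] = w
                parent[below] = w
                below = w

        self.children = [tuple(c) for c in children]
        self.parent = parent
        self.ages = np.asarray(ages)
        self.orig_branch = orig_branch
        self.is_artificial = is_artificial
        self.n_nodes = len(parent)
        self.root = S.root
        # node ages are exact copies of level values (ages were snapped when
        # the dated tree was built), so the dict lookup is exact
        self.level = [level_of[a] for a in ages]
        self.n_levels = len(self.levels)
        self.level_nodes: list[list[int]] = [[] for _ in range(self.n_levels)]
        for x in range(self.n_nodes):
            self.level_nodes[self.level[x]].append(x)
        self.leaf_of_label = {S.labels[i]: i for i in S.leaves}

    def is_leaf(self, x: int) -> bool:
        return not self.children[x]

    def is_real_internal(self, x: int) -> bool:
        return len(self.children[x]) == 2

    def partners(self, x: int) -> list[int]:
        """Contemporaneous branches: same slice as the branch above x."""
        if x == self.root:
            return []
        return [y for y in self.level_nodes[self.level[x]]
                if y != x and y != self.root]

    def branch_duration(self, x: int) -> float:
        return float(self.ages[self.parent[x]] - self.ages[x])

    def collapse(self) -> DatedSpeciesTree:
        """Remove artificial nodes; recovers the original tree exactly."""
        keep = [x for x in range(self.n_nodes) if not self.is_artificial[x]]
        remap = {x: i for i, x in enumerate(keep)}
        children, parent, ages, labels, names = [], [], [], [], []
        for x in keep:
            kids = []
            for k in self.children[x]:
                while self.is_artificial[k]:
                    (k,) = self.children[k]
                kids.append(remap[k])
            children.append(tuple(kids))
            p = self.parent[x]
            while p != -1 and self.is_artificial[p]:
                p = self.parent[p]
            parent.append(remap[p] if p != -1 else -1)
            ages.append(float(self.ages[x]))
            labels.append(self.S.labels[x])
            names.append(self.S.names[x])
        return DatedSpeciesTree(children, parent, ages, labels, names)

    def __repr__(self):
        n_art = sum(self.is_artificial)
        return (
            f"<SubdividedSpeciesTree {self.S.n_nodes}+{n_art} nodes, "
            f"{self.n_levels - 1 if self.n_levels > 1 else 1} slices>"
        )
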