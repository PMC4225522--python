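"""Exact p-values under the random-bin-placement null model.

Under the null hypothesis of independent evolution, the N1 events of one
family and the N2 events of the other are thrown independently into the
bins B = (branch, event type) — three bins per branch of S, with placement
probability proportional to branch duration.  The p-value of a score X is

    f(X; N1, N2, N) = P(sum over bins of min(count1, count2) >= X),

computed by conditioning on the counts (j, k) landing in the last bin,
which are Binomial(n_i, pi_n) with pi_n = l_n / (l_1 + ... + l_n):

    f(x; n1, n2, n) = sum_{j,k} BPr(j; pi_n, n1) BPr(k; pi_n, n2)
                      * f(x - min(j,k); n1 - j, n2 - k, n - 1),

with f = 1 for x <= 0, f = 0 for x > min(n1, n2), and
f(x; n1, n2, 1) = I(x <= min(n1, n2)).  Grouping (j, k) by m = min(j, k)
recovers the three-term form of the recursion; the kernel evaluates it with
suffix-sum tables so one bin step costs O(x n1 n2 (n1 + n2)).

The number of events in common is an integer, so for a real-valued score
f(x) = f(ceil(x)) and the whole table lives on an integer lattice.  The
function depends on the species tree only; one table serves every gene pair,
so the model caches the table at the largest (x, n1, n2) seen and answers
further queries by lookup.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from numba import njit

from .errors import DtlCoevError
from .events import PROJECTED_TYPES
from .trees import DatedSpeciesTree

__all__ = ["BinVector", "bin_vector", "NullModel", "p_value"]

log = logging.getLogger(__name__)


@dataclass
class BinVector:
    """Ordered (branch, event type) bins with their placement lengths."""

    bins: list
    lengths: np.ndarray

    def __post_init__(self):
        self.lengths = np.asarray(self.lengths, dtype=float)
        if len(self.bins) != self.lengths.size:
            raise DtlCoevError("bins and lengths differ in size")
        if np.any(self.lengths < 0):
            raise DtlCoevError("negative bin length")
        if self.lengths.sum() <= 0:
            raise DtlCoevError("all bin lengths are zero")

    @property
    def n(self) -> int:
        return len(self.bins)

    def prefix_probabilities(self) -> np.ndarray:
        """pi_n = l_n / (l_1 + ... + l_n); 0 where the prefix sum is 0."""
        csum = np.cumsum(self.lengths)
        with np.errstate(invalid="ignore", divide="ignore"):
            pis = np.where(csum > 0, self.lengths / np.maximum(csum, 1e-300), 0.0)
        return pis


def bin_vector(S: DatedSpeciesTree) -> BinVector:
    """All (branch, D/T/L) bins of S in node order; lengths = durations."""
    if S.n_nodes < 2:
        raise DtlCoevError("species tree has no branches")
    bins, lengths = [], []
    for b in S.branches():
        for etype in PROJECTED_TYPES:
            bins.append((b, etype))
            lengths.append(S.branch_length(b))
    return BinVector(bins, np.array(lengths))


@njit(cache=True)
def _null_table(pis, xmax, n1max, n2max):  # pragma: no cover - numba
    X, A, B = xmax, n1max, n2max
    f = np.empty((X + 1, A + 1, B + 1))
    for x in range(X + 1):
        for a in range(A + 1):
            for b in range(B + 1):
                m = a if a < b else b
                f[x, a, b] = 1.0 if x <= m else 0.0
    nbins = pis.size
    maxn = max(A, B)
    C = np.zeros((maxn + 1, maxn + 1))
    for n in range(maxn + 1):
        C[n, 0] = 1.0
        for k in range(1, n + 1):
            C[n, k] = C[n - 1, k - 1] + (C[n - 1, k] if k < n else 0.0)
    B1 = np.zeros((A + 1, A + 1))
    B2 = np.zeros((B + 1, B + 1))
    S1 = np.zeros((X + 1, A + 2, A + 1, B + 1))
    S2 = np.zeros((X + 1, B + 2, B + 1, A + 1))
    fn = np.empty_like(f)
    for n in range(1, nbins):
        p = pis[n]
        if p <= 0.0:
            continue
        q = 1.0 - p
        for a in range(A + 1):
            for j in range(A + 1):
                B1[a, j] = C[a, j] * p ** j * q ** (a - j) if j <= a else 0.0
        for b in range(B + 1):
            for k in range(B + 1):
                B2[b, k] = C[b, k] * p ** k * q ** (b - k) if k <= b else 0.0
        for x in range(X + 1):
            for a in range(A + 1):
                for bp in range(B + 1):
                    acc = 0.0
                    for m in range(a, -1, -1):
                        acc += B1[a, m] * f[x, a - m, bp]
                        S1[x, m, a, bp] = acc
            for b in range(B + 1):
                for ap in range(A + 1):
                    acc = 0.0
                    for m in range(b, -1, -1):
                        acc += B2[b, m] * f[x, ap, b - m]
                        S2[x, m, b, ap] = acc
        for x in range(X + 1):
            for a in range(A + 1):
                for b in range(B + 1):
                    if x == 0:
                        fn[x, a, b] = 1.0
                        continue
                    mm = a if a < b else b
                    s = 0.0
                    for m in range(mm + 1):
                        xp = x - m
                        if xp < 0:
                            xp = 0
                        # j = m, k >= m
                        s += B1[a, m] * S2[xp, m, b, a - m]
                        # k = m, j > m
                        s += B2[b, m] * S1[xp, m + 1, a, b - m]
                    fn[x, a, b] = s
        f[:, :, :] = fn
    return f


class NullModel:
    """Reusable evaluator of f(x; n1, n2, N) for one species tree."""

    def __init__(self, source):
        if isinstance(source, DatedSpeciesTree):
            self.bins = bin_vector(source)
        elif isinstance(source, BinVector):
            self.bins = source
        else:
            raise TypeError("NullModel needs a DatedSpeciesTree or BinVector")
        self._pis = self.bins.prefix_probabilities()
        self._table: np.ndarray | None = None

    def precompute(self, max_x: int, max_n1: int, max_n2: int) -> None:
        """Fill the f-table once for a whole batch of gene pairs."""
        self._table = _null_table(
            self._pis, int(max(max_x, 1)), int(max(max_n1, 1)),
            int(max(max_n2, 1)),
        )

    def p_value(self, score: float, n1: int, n2: int) -> float:
        """P(common events >= score) for N1=n1, N2=n2 random placements."""
        if n1 < 0 or n2 < 0:
            raise DtlCoevError("event counts must be nonnegative")
        x = math.ceil(score - 1e-9)
        if x <= 0 or min(n1, n2) == 0:
            return 1.0
        if x > min(n1, n2):
            return 0.0
        t = self._table
        if t is None or x >= t.shape[0] or n1 >= t.shape[1] or n2 >= t.shape[2]:
            if t is not None:
                log.info(
                    "null-model query (x=%d, n1=%d, n2=%d) beyond the cached "
                    "table %s; recomputing", x, n1, n2, t.shape,
                )
            self.precompute(
                max(x, 0 if t is None else t.shape[0] - 1),
                max(n1, 0 if t is None else t.shape[1] - 1),
                max(n2, 0 if t is None else t.shape[2] - 1),
            )
            t = self._table
        return float(min(max(t[x, n1, n2], 0.0), 1.0))


def p_value(score: float, n1: int, n2: int, bins: BinVector) -> float:
    """One-shot p-value (builds a throwaway table; prefer NullModel)."""
    return NullModel(bins).p_value(score, n1, n2)
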