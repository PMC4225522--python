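"""The co-evolution score.

Each weight in a (branch, type) bin is read as the probability that the
event really occurred, independently of all other events.  The number of
actual events in a bin then follows a Poisson-binomial distribution, built
by the recursion

    P(X_i = x) = p_i P(X_{i-1} = x-1) + (1 - p_i) P(X_{i-1} = x),

with P(X_0 = x) = I(x = 0).  For two gene families the expected number of
events in common in one bin is

    E[min(X, Y)] = sum_x sum_y min(x, y) P(X = x) P(Y = y),

and the co-evolution score is this expectation summed over every branch of
the species tree and every event type D/T/L.
"""

from __future__ import annotations

import numpy as np

from .errors import EventSetError
from .events import WeightedEventSet
from .trees import DatedSpeciesTree

__all__ = ["count_distribution", "expected_common", "coevolution_score"]

_DRIFT = 1e-9


def count_distribution(weights) -> np.ndarray:
    """Poisson-binomial pmf of the number of events, given their weights.

    Returns an array of length ``len(weights) + 1``; entry x is
    P(exactly x of the candidate events occurred).
    """
    ws = [float(w) for w in weights]
    for w in ws:
        if not 0.0 <= w <= 1.0:
            raise EventSetError(f"weight {w} outside [0, 1]")
    p = np.zeros(len(ws) + 1)
    p[0] = 1.0
    for i, w in enumerate(ws, start=1):
        p[1:i + 1] = w * p[0:i] + (1.0 - w) * p[1:i + 1]
        p[0] *= 1.0 - w
    s = p.sum()
    if abs(s - 1.0) > _DRIFT:  # numerically benign, but keep bins exact
        p /= s
    return p


def expected_common(dx: np.ndarray, dy: np.ndarray) -> float:
    """E[min(X, Y)] for independent X ~ dx, Y ~ dy."""
    dx = np.asarray(dx, dtype=float)
    dy = np.asarray(dy, dtype=float)
    x = np.arange(dx.size)[:, None]
    y = np.arange(dy.size)[None, :]
    return float((np.minimum(x, y) * dx[:, None] * dy[None, :]).sum())


def coevolution_score(
    W1: WeightedEventSet,
    W2: WeightedEventSet,
    S: DatedSpeciesTree | None = None,
    return_contributions: bool = False,
):
    """Sum of per-bin expected common event counts over all (branch, type).

    Bins that are empty on either side contribute 0.  With
    ``return_contributions`` the per-bin breakdown is returned alongside.
    """
    S = S or W1.species_tree
    for W in (W1, W2):
        if W.species_tree.n_nodes != S.n_nodes:
            raise EventSetError("event sets refer to different species trees")
        for branch, _ in W.bins:
            if branch == S.root or not 0 <= branch < S.n_nodes:
                raise EventSetError(f"branch {branch} is not a branch of S")
    score = 0.0
    contrib: dict[tuple[int, str], float] = {}
    for key in W1.bins.keys() & W2.bins.keys():
        c = expected_common(
            count_distribution(W1.weights(*key)),
            count_distribution(W2.weights(*key)),
        )
        if c:
            contrib[key] = c
        score += c
    if return_contributions:
        return score, contrib
    return score
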