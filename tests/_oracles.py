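"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's dynamic programs: scenarios are
enumerated by plain recursion with a cost budget, distributions by
exhaustive 2^n expansion, and null placements by enumerating or sampling
every assignment of events to bins.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


def brute_scenarios(G, Sp, costs, budget):
    """All valid DTL scenarios of integer cost <= budget (plain recursion)."""
    delta = int(costs.duplication)
    tau = int(costs.transfer)
    lam = int(costs.loss)
    tlc = tau + lam
    leaf_site = {u: Sp.leaf_of_label[G.species[u]] for u in G.leaves}
    memo = {}

    def scen(u, x, allow_tl, allow_ne, bud):
        key = (u, x, allow_tl, allow_ne, bud)
        if key in memo:
            return memo[key]
        out = []
        kids = G.children[u]
        xkids = Sp.children[x]
        if not xkids:
            if not kids and leaf_site[u] == x:
                out.append((0, (("C", u, x),)))
        elif len(xkids) == 2:
            xc1, xc2 = xkids
            if kids:
                u1, u2 = kids
                for a, b in ((xc1, xc2), (xc2, xc1)):
                    for c1, e1 in scen(u1, a, True, True, bud):
                        for c2, e2 in scen(u2, b, True, True, bud - c1):
                            out.append((c1 + c2, (("S", u, x, a),) + e1 + e2))
            for a, lost in ((xc1, xc2), (xc2, xc1)):
                if lam <= bud:
                    for c1, e1 in scen(u, a, True, True, bud - lam):
                        out.append((lam + c1, (("SL", u, lost, a),) + e1))
        if x != Sp.root and kids:
            u1, u2 = kids
            if delta <= bud:
                for c1, e1 in scen(u1, x, True, True, bud - delta):
                    for c2, e2 in scen(u2, x, True, True, bud - delta - c1):
                        out.append(
                            (delta + c1 + c2, (("D", u, x),) + e1 + e2)
                        )
            for y in Sp.partners(x):
                if tau <= bud:
                    for a, b in ((u1, u2), (u2, u1)):
                        for c1, e1 in scen(a, x, True, True, bud - tau):
                            for c2, e2 in scen(
                                b, y, True, True, bud - tau - c1
                            ):
                                out.append(
                                    (tau + c1 + c2,
                                     (("T", u, x, y, b),) + e1 + e2)
                                )
        if allow_ne and len(xkids) == 1:
            for c1, e1 in scen(u, xkids[0], True, True, bud):
                out.append((c1, (("NE", u, x),) + e1))
        if allow_tl and x != Sp.root and tlc <= bud:
            for y in Sp.partners(x):
                for c1, e1 in scen(u, y, False, True, bud - tlc):
                    out.append((tlc + c1, (("TL", u, x, y),) + e1))
        memo[key] = out
        return out

    r = G.n_nodes - 1
    found = []
    for x in range(Sp.n_nodes):
        found.extend(scen(r, x, True, False, budget))
    return found


def brute_reconcile(G, Sp, costs, max_budget=30):
    """(min cost, list of optimal scenarios) by iterative budget deepening."""
    for bud in range(max_budget + 1):
        scens = brute_scenarios(G, Sp, costs, bud)
        if scens:
            best = min(c for c, _ in scens)
            return best, [e for c, e in scens if c == best]
    raise AssertionError("no scenario within budget")


def brute_poisson_binomial(weights):
    """2^n expansion of the distribution of the number of occurring events."""
    n = len(weights)
    dist = np.zeros(n + 1)
    for mask in range(2 ** n):
        pr = 1.0
        k = 0
        for i, w in enumerate(weights):
            if mask >> i & 1:
                pr *= w
                k += 1
            else:
                pr *= 1.0 - w
        dist[k] += pr
    return dist


def enumerate_null(lengths, n1, n2, x):
    """P(common >= x) by enumerating every placement of labelled events."""
    lengths = np.asarray(lengths, float)
    p = lengths / lengths.sum()
    N = len(lengths)
    prob = 0.0
    for a in itertools.product(range(N), repeat=n1):
        pa = math.prod(p[i] for i in a)
        ca = np.bincount(a, minlength=N)
        for b in itertools.product(range(N), repeat=n2):
            pb = math.prod(p[i] for i in b)
            cb = np.bincount(b, minlength=N)
            if np.minimum(ca, cb).sum() >= x:
                prob += pa * pb
    return prob


def montecarlo_null(lengths, n1, n2, x, n_draws, rng):
    """Monte-Carlo estimate (mean, standard error) of P(common >= x)."""
    lengths = np.asarray(lengths, float)
    p = lengths / lengths.sum()
    hits = 0
    chunk = 100_000
    left = n_draws
    while left > 0:
        m = min(chunk, left)
        c1 = rng.multinomial(n1, p, size=m)
        c2 = rng.multinomial(n2, p, size=m)
        common = np.minimum(c1, c2).sum(axis=1)
        hits += int((common >= x).sum())
        left -= m
    phat = hits / n_draws
    se = math.sqrt(max(phat * (1 - phat), 1e-12) / n_draws)
    return phat, se
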