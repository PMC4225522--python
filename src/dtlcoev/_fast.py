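"""Array/numba implementation of the reconciliation DP.

Same model and recursion as :mod:`dtlcoev.reconcile` (the reference engine),
with scenario counts carried in float64 instead of big integers: counts are
exact below 2**53 and the reported frequencies are ratios, so benchmark-size
instances lose nothing.  Agreement of the two engines is covered by tests.
"""

from __future__ import annotations

import numpy as np
from numba import njit

from .errors import ReconciliationError
from .reconcile import EventCosts, ReconciliationSummary
from .trees import GeneTree, SubdividedSpeciesTree

__all__ = ["fast_reconcile"]

_TOL = 1e-9
_TYPE_CODES = ("S", "D", "T", "SL", "TL", "NE", "C")


def _pack_species(Sp: SubdividedSpeciesTree):
    pack = getattr(Sp, "_fast_pack", None)
    if pack is not None:
        return pack
    NS = Sp.n_nodes
    child1 = np.full(NS, -1, dtype=np.int64)
    child2 = np.full(NS, -1, dtype=np.int64)
    for x in range(NS):
        kids = Sp.children[x]
        if len(kids) >= 1:
            child1[x] = kids[0]
        if len(kids) == 2:
            child2[x] = kids[1]
    level = np.array(Sp.level, dtype=np.int64)
    nlev = Sp.n_levels
    lev_ptr = np.zeros(nlev + 1, dtype=np.int64)
    lev_nodes = np.empty(NS, dtype=np.int64)
    pos = 0
    for l in range(nlev):
        lev_ptr[l] = pos
        for x in Sp.level_nodes[l]:
            lev_nodes[pos] = x
            pos += 1
    lev_ptr[nlev] = pos
    pack = (child1, child2, level, lev_ptr, lev_nodes, Sp.root)
    Sp._fast_pack = pack
    return pack


def _pack_gene(G: GeneTree, Sp: SubdividedSpeciesTree):
    NG = G.n_nodes
    gc1 = np.full(NG, -1, dtype=np.int64)
    gc2 = np.full(NG, -1, dtype=np.int64)
    gsite = np.full(NG, -1, dtype=np.int64)
    for u in range(NG):
        kids = G.children[u]
        if kids:
            gc1[u], gc2[u] = kids
        else:
            sp = G.species[u]
            if sp not in Sp.leaf_of_label:
                raise ReconciliationError(
                    f"gene leaf {G.labels[u]!r} maps to unknown species {sp!r}"
                )
            gsite[u] = Sp.leaf_of_label[sp]
    return gc1, gc2, gsite


@njit(cache=True)
def _forward_kernel(gc1, gc2, gsite, child1, child2, level, lev_ptr,
                    lev_nodes, root, delta, tau, lam):  # pragma: no cover
    NG = gc1.size
    NS = child1.size
    nlev = lev_ptr.size - 1
    INF = 1e300
    tlc = tau + lam
    cne = np.full((NG, NS), INF)
    nne = np.zeros((NG, NS))
    cb = np.full((NG, NS), INF)
    nb = np.zeros((NG, NS))
    cf = np.full((NG, NS), INF)
    nf = np.zeros((NG, NS))
    for u in range(NG):
        u1 = gc1[u]
        u2 = gc2[u]
        for l in range(nlev):
            for ii in range(lev_ptr[l], lev_ptr[l + 1]):
                x = lev_nodes[ii]
                best = INF
                cnt = 0.0
                xc1 = child1[x]
                xc2 = child2[x]
                if xc1 == -1:  # species leaf
                    if u1 == -1 and gsite[u] == x:
                        best = 0.0
                        cnt = 1.0
                elif xc2 != -1:  # real internal
                    if u1 != -1:
                        v = cf[u1, xc1] + cf[u2, xc2]
                        c = nf[u1, xc1] * nf[u2, xc2]
                        if v < best - _TOL:
                            best = v
                            cnt = c
                        elif v <= best + _TOL:
                            cnt += c
                        v = cf[u1, xc2] + cf[u2, xc1]
                        c = nf[u1, xc2] * nf[u2, xc1]
                        if v < best - _TOL:
                            best = v
                            cnt = c
                        elif v <= best + _TOL:
                            cnt += c
                    for t in range(2):
                        xa = xc1 if t == 0 else xc2
                        v = lam + cf[u, xa]
                        c = nf[u, xa]
                        if v < best - _TOL:
                            best = v
                            cnt = c
                        elif v <= best + _TOL:
                            cnt += c
                if x != root and u1 != -1:
                    v = delta + cf[u1, x] + cf[u2, x]
                    c = nf[u1, x] * nf[u2, x]
                    if v < best - _TOL:
                        best = v
                        cnt = c
                    elif v <= best + _TOL:
                        cnt += c
                    for jj in range(lev_ptr[l], lev_ptr[l + 1]):
                        y = lev_nodes[jj]
                        if y == x or y == root:
                            continue
                        v = tau + cf[u1, x] + cf[u2, y]
                        c = nf[u1, x] * nf[u2, y]
                        if v < best - _TOL:
                            best = v
                            cnt = c
                        elif v <= best + _TOL:
                            cnt += c
                        v = tau + cf[u1, y] + cf[u2, x]
                        c = nf[u1, y] * nf[u2, x]
                        if v < best - _TOL:
                            best = v
                            cnt = c
                        elif v <= best + _TOL:
                            cnt += c
                cne[u, x] = best
                nne[u, x] = cnt
                if xc1 != -1 and xc2 == -1:  # artificial: NE move
                    v = cf[u, xc1]
                    c = nf[u, xc1]
                    if v < best - _TOL:
                        best = v
                        cnt = c
                    elif v <= best + _TOL:
                        cnt += c
                cb[u, x] = best
                nb[u, x] = cnt
            for ii in range(lev_ptr[l], lev_ptr[l + 1]):
                x = lev_nodes[ii]
                best = cb[u, x]
                cnt = nb[u, x]
                if x != root:
                    for jj in range(lev_ptr[l], lev_ptr[l + 1]):
                        y = lev_nodes[jj]
                        if y == x or y == root:
                            continue
                        v = cb[u, y] + tlc
                        c = nb[u, y]
                        if v < best - _TOL:
                            best = v
                            cnt = c
                        elif v <= best + _TOL:
                            cnt += c
                cf[u, x] = best
                nf[u, x] = cnt
    r = NG - 1
    cstart = np.full(NS, INF)
    nstart = np.zeros(NS)
    for x in range(NS):
        best = cne[r, x]
        cnt = nne[r, x]
        if x != root:
            l = level[x]
            for jj in range(lev_ptr[l], lev_ptr[l + 1]):
                y = lev_nodes[jj]
                if y == x or y == root:
                    continue
                v = cb[r, y] + tlc
                c = nb[r, y]
                if v < best - _TOL:
                    best = v
                    cnt = c
                elif v <= best + _TOL:
                    cnt += c
        cstart[x] = best
        nstart[x] = cnt
    return cne, nne, cb, nb, cf, nf, cstart, nstart


@njit(cache=True)
def _expand_kernel(u, x, ctx, target, include_ne, gc1, gc2, gsite, child1,
                   child2, level, lev_ptr, lev_nodes, root, delta, tau, lam,
                   cf, nf, O, evc):  # pragma: no cover - numba
    u1 = gc1[u]
    u2 = gc2[u]
    xc1 = child1[x]
    xc2 = child2[x]
    if xc1 == -1:
        if u1 == -1 and gsite[u] == x and abs(target) <= _TOL:
            evc[u, x, 6] += ctx  # C
    elif xc2 != -1:
        if u1 != -1:
            for t in range(2):
                a = xc1 if t == 0 else xc2
                b = xc2 if t == 0 else xc1
                if abs(cf[u1, a] + cf[u2, b] - target) <= _TOL:
                    evc[u, x, 0] += ctx * nf[u1, a] * nf[u2, b]  # S
                    O[u1, a] += ctx * nf[u2, b]
                    O[u2, b] += ctx * nf[u1, a]
        for t in range(2):
            a = xc1 if t == 0 else xc2
            lost = xc2 if t == 0 else xc1
            if abs(lam + cf[u, a] - target) <= _TOL:
                evc[u, lost, 3] += ctx * nf[u, a]  # SL
                O[u, a] += ctx
    if x != root and u1 != -1:
        if abs(delta + cf[u1, x] + cf[u2, x] - target) <= _TOL:
            evc[u, x, 1] += ctx * nf[u1, x] * nf[u2, x]  # D
            O[u1, x] += ctx * nf[u2, x]
            O[u2, x] += ctx * nf[u1, x]
        l = level[x]
        for jj in range(lev_ptr[l], lev_ptr[l + 1]):
            y = lev_nodes[jj]
            if y == x or y == root:
                continue
            for t in range(2):
                a = u1 if t == 0 else u2   # stays on x
                b = u2 if t == 0 else u1   # moves to y
                if abs(tau + cf[a, x] + cf[b, y] - target) <= _TOL:
                    evc[u, x, 2] += ctx * nf[a, x] * nf[b, y]  # T
                    O[a, x] += ctx * nf[b, y]
                    O[b, y] += ctx * nf[a, x]
    if include_ne and xc1 != -1 and xc2 == -1:
        if abs(cf[u, xc1] - target) <= _TOL:
            evc[u, x, 5] += ctx * nf[u, xc1]  # NE
            O[u, xc1] += ctx


@njit(cache=True)
def _backward_kernel(gc1, gc2, gsite, child1, child2, level, lev_ptr,
                     lev_nodes, root, delta, tau, lam, cne, nne, cb, nb, cf,
                     nf, cstart, nstart, opt):  # pragma: no cover - numba
    NG = gc1.size
    NS = child1.size
    nlev = lev_ptr.size - 1
    tlc = tau + lam
    O = np.zeros((NG, NS))
    Ob = np.zeros((NG, NS))
    evc = np.zeros((NG, NS, 7))
    r = NG - 1
    for x in range(NS):
        if cstart[x] <= opt + _TOL:
            _expand_kernel(r, x, 1.0, opt, False, gc1, gc2, gsite, child1,
                           child2, level, lev_ptr, lev_nodes, root, delta,
                           tau, lam, cf, nf, O, evc)
            if x != root:
                l = level[x]
                for jj in range(lev_ptr[l], lev_ptr[l + 1]):
                    y = lev_nodes[jj]
                    if y == x or y == root:
                        continue
                    if abs(cb[r, y] + tlc - opt) <= _TOL:
                        evc[r, x, 4] += nb[r, y]  # TL
                        Ob[r, y] += 1.0
    for u in range(NG - 1, -1, -1):
        for l in range(nlev - 1, -1, -1):
            for ii in range(lev_ptr[l], lev_ptr[l + 1]):
                x = lev_nodes[ii]
                o = O[u, x]
                if o <= 0.0:
                    continue
                if cb[u, x] <= cf[u, x] + _TOL:
                    Ob[u, x] += o
                if x != root:
                    for jj in range(lev_ptr[l], lev_ptr[l + 1]):
                        y = lev_nodes[jj]
                        if y == x or y == root:
                            continue
                        if abs(cb[u, y] + tlc - cf[u, x]) <= _TOL:
                            evc[u, x, 4] += o * nb[u, y]  # TL
                            Ob[u, y] += o
            for ii in range(lev_ptr[l], lev_ptr[l + 1]):
                x = lev_nodes[ii]
                k = Ob[u, x]
                if k > 0.0:
                    _expand_kernel(u, x, k, cb[u, x], True, gc1, gc2, gsite,
                                   child1, child2, level, lev_ptr, lev_nodes,
                                   root, delta, tau, lam, cf, nf, O, evc)
    return evc


def fast_reconcile(G: GeneTree, Sp: SubdividedSpeciesTree,
                   costs: EventCosts = EventCosts()) -> ReconciliationSummary:
    """Numba counterpart of :func:`dtlcoev.reconcile.reconcile`."""
    child1, child2, level, lev_ptr, lev_nodes, root = _pack_species(Sp)
    gc1, gc2, gsite = _pack_gene(G, Sp)
    delta, tau, lam = costs.duplication, costs.transfer, costs.loss
    out = _forward_kernel(gc1, gc2, gsite, child1, child2, level, lev_ptr,
                          lev_nodes, root, delta, tau, lam)
    cne, nne, cb, nb, cf, nf, cstart, nstart = out
    opt = float(cstart.min())
    if opt >= 1e299:
        raise ReconciliationError("no valid reconciliation exists")
    total = float(nstart[cstart <= opt + _TOL].sum())
    evc = _backward_kernel(gc1, gc2, gsite, child1, child2, level, lev_ptr,
                           lev_nodes, root, delta, tau, lam, cne, nne, cb,
                           nb, cf, nf, cstart, nstart, opt)
    counts: dict[tuple, float] = {}
    for u, x, t in zip(*np.nonzero(evc)):
        counts[(int(u), int(x), _TYPE_CODES[t])] = float(evc[u, x, t])
    if total < 2**53 and abs(total - round(total)) < 0.5:
        total_out: int | float = int(round(total))
        counts = {
            k: int(round(v)) if v < 2**53 else v for k, v in counts.items()
        }
    else:
        total_out = total
    return ReconciliationSummary(G, Sp, costs, opt, total_out, counts,
                                 engine="fast")
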