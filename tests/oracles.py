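"""Independent brute-force oracles used to certify the fast
implementations.  These deliberately share no code with the package's
algorithms: clustering is an all-pairs window test plus transitive
closure, segment detection an all-pairs maximal-run scan, and the REML
oracle a dense grid followed by derivative-free polish.
"""

import numpy as np
from scipy.optimize import minimize

from ibdscan.ibd_io import GeneticMap, PhasedHaplotypes


def pair_ibd_at(hi, hj, cm, span, focal, L, T):
    """Does one haplotype pair satisfy the L/T window relation at the
    focal position?  Runs use agreeing-marker endpoints, extended to the
    chromosome ends when no mismatch bounds them."""
    start_cm, end_cm = span
    neq = hi != hj
    mism = np.nonzero(neq)[0]
    cms = cm[mism]
    if np.any(np.abs(cms - focal) <= 1e-9):
        return False
    left = mism[cms < focal]
    right = mism[cms > focal]
    lo = left[-1] + 1 if left.size else 0
    hi_idx = right[0] - 1 if right.size else cm.size - 1
    if lo > hi_idx:
        return False
    s = start_cm if not left.size else cm[lo]
    e = end_cm if not right.size else cm[hi_idx]
    left_req = max(focal - T, start_cm)
    right_req = min(focal + T, end_cm)
    return (s <= left_req + 1e-9 and e >= right_req - 1e-9
            and e - s >= L - 1e-9)


def brute_force_clusters(haps: PhasedHaplotypes, gmap: GeneticMap,
                         focal: float, L: float, T: float,
                         chrom: str = "1") -> np.ndarray:
    """Partition of haplotypes by testing every pair against the window
    relation and taking connected components via BFS."""
    sub = haps.restrict(chrom)
    H = sub.haplotypes
    cm = np.asarray(gmap.interpolate(chrom, sub.variants["pos"].to_numpy()))
    span = gmap.span_cM(chrom)
    n = H.shape[0]
    adj = [[] for _ in range(n)]
    for i in range(n):
        for j in range(i + 1, n):
            if pair_ibd_at(H[i], H[j], cm, span, focal, L, T):
                adj[i].append(j)
                adj[j].append(i)
    labels = -np.ones(n, dtype=np.int64)
    nxt = 0
    for s in range(n):
        if labels[s] >= 0:
            continue
        stack = [s]
        labels[s] = nxt
        while stack:
            u = stack.pop()
            for v in adj[u]:
                if labels[v] < 0:
                    labels[v] = nxt
                    stack.append(v)
        nxt += 1
    return labels


def brute_force_segments(haps: PhasedHaplotypes, gmap: GeneticMap,
                         min_output_cM: float, min_mac: int = 1,
                         min_markers: int = 1):
    """All-pairs maximal identical runs on MAC-filtered markers, kept at
    the output length/marker thresholds.  Returns a set of
    (hap_i, hap_j, start_bp, end_bp) tuples."""
    out = set()
    for chrom in haps.chromosomes:
        sub = haps.restrict(chrom)
        H = sub.haplotypes
        mac = np.minimum((H > 0).sum(axis=0), (H == 0).sum(axis=0))
        keep = np.nonzero(mac >= min_mac)[0]
        if keep.size == 0:
            continue
        Hf = H[:, keep]
        pos = sub.variants["pos"].to_numpy()[keep]
        cm = np.asarray(gmap.interpolate(chrom, pos))
        n, m = Hf.shape
        for i in range(n):
            for j in range(i + 1, n):
                eq = Hf[i] == Hf[j]
                k = 0
                while k < m:
                    if not eq[k]:
                        k += 1
                        continue
                    k2 = k
                    while k2 + 1 < m and eq[k2 + 1]:
                        k2 += 1
                    length = cm[k2] - cm[k]
                    if (length >= min_output_cM - 1e-9
                            and k2 - k + 1 >= min_markers):
                        out.add((i, j, int(pos[k]), int(pos[k2])))
                    k = k2 + 1
    return out


def grid_polish_reml(model, include_local: bool) -> float:
    """Dense grid over the variance ratios followed by Nelder-Mead
    polish (log-scale), including the boundary lines; returns the
    maximal restricted log-likelihood."""
    grid = np.concatenate([[0.0], np.exp(np.linspace(-9.0, 5.0, 30))])
    best, arg = -np.inf, (0.0, 0.0)
    for ga in grid:
        for gq in (grid if include_local else [0.0]):
            ll, _, _ = model._profiled(np.array([ga, gq]), False)
            if ll > best:
                best, arg = ll, (ga, gq)

    if include_local:
        def neg(u):
            return -model._profiled(np.exp(u), False)[0]
        x0 = np.log(np.maximum(arg, 1e-9))
    else:
        def neg(u):
            return -model._profiled(np.array([np.exp(u[0]), 0.0]), False)[0]
        x0 = np.log(np.maximum([arg[0]], 1e-9))
    res = minimize(neg, x0, method="Nelder-Mead",
                   options={"xatol": 1e-12, "fatol": 1e-13, "maxiter": 4000})
    best = max(best, -res.fun)
    # polish the boundary lines too, in case the optimum is constrained
    if include_local:
        def neg_a(u):
            return -model._profiled(np.array([np.exp(u[0]), 0.0]), False)[0]
        ra = minimize(neg_a, [np.log(max(arg[0], 1e-9))], method="Nelder-Mead",
                      options={"xatol": 1e-12, "fatol": 1e-13, "maxiter": 2000})
        def neg_q(u):
            return -model._profiled(np.array([0.0, np.exp(u[0])]), False)[0]
        rq = minimize(neg_q, [np.log(max(arg[1], 1e-9))], method="Nelder-Mead",
                      options={"xatol": 1e-12, "fatol": 1e-13, "maxiter": 2000})
        best = max(best, -ra.fun, -rq.fun)
    return best
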