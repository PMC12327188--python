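"""Multi-individual IBD clustering and pairwise IBD segment detection.

Clustering assigns, at a focal genomic position, a group identifier to
each haplotype such that haplotypes in the same group are identical by
descent there.  Two haplotypes are related when they carry the same
allele sequence over a contiguous marker interval that covers the focal
position, extends at least T cM on each side of it, and spans at least
L cM in total; the clusters are the transitive closure (connected
components) of this relation.  The implementation sorts haplotypes with
a positional Burrows-Wheeler transform so that only haplotypes that are
identical across the trimming window need exact pairwise examination,
which keeps the scan near-linear in sample size.

The pairwise detector recovers maximal identical-allele runs between
haplotype pairs (seed-and-extend semantics on minor-allele-count
filtered markers) for use in kinship estimation.  With error-free phased
input a seed always extends to the maximal identical run, so segments
are maximal runs passing the length and marker-count filters.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator, Sequence

import numpy as np
import pandas as pd

from .ibd_io import ClusterField, GeneticMap, PhasedHaplotypes, SEGMENT_COLUMNS

__all__ = [
    "ClusteringParams",
    "PairwiseDetectorParams",
    "SEQUENCE_PRESET",
    "ARRAY_PRESET",
    "cluster_at_position",
    "cluster_field_scan",
    "detect_pairwise_segments",
]

_TOL = 1e-9


@dataclass(frozen=True)
class ClusteringParams:
    """Haplotype length threshold L and trimming threshold T, in cM.

    L is the minimum total span of the shared allele sequence; T is how
    far it must extend on each side of the focal position.  T <= L/2 so
    the two side requirements never exceed the total-length requirement
    (the boundary case T = L/2 makes them coincide and is admissible).
    """

    length_cM: float = 2.0
    trim_cM: float = 0.5

    def __post_init__(self) -> None:
        if self.length_cM <= 0 or self.trim_cM <= 0:
            raise ValueError("L and T must be positive")
        if self.trim_cM > self.length_cM / 2:
            raise ValueError(f"require T <= L/2, got T={self.trim_cM}, L={self.length_cM}")


@dataclass(frozen=True)
class PairwiseDetectorParams:
    min_seed_cM: float = 0.5
    min_extend_cM: float = 0.2
    min_output_cM: float = 2.0
    min_minor_allele_count: int = 100
    min_seed_markers: int = 1

    def __post_init__(self) -> None:
        for name in ("min_seed_cM", "min_extend_cM", "min_output_cM"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


# hap-ibd parameter choices for sequence vs SNP-array input
SEQUENCE_PRESET = PairwiseDetectorParams(
    min_seed_cM=0.5, min_extend_cM=0.2, min_output_cM=2.0,
    min_minor_allele_count=100, min_seed_markers=1)
ARRAY_PRESET = PairwiseDetectorParams(
    min_seed_cM=1.0, min_extend_cM=0.1, min_output_cM=3.0,
    min_minor_allele_count=1, min_seed_markers=50)


# ---------------------------------------------------------------------------
# PBWT
# ---------------------------------------------------------------------------

def _pbwt_sweep(H: np.ndarray, stops: Sequence[int]) -> Iterator[tuple[int, np.ndarray, np.ndarray]]:
    """Forward PBWT over the marker axis, yielding (m, order, div) at each
    requested marker index m (after processing marker m, 0-based).

    ``div[k]`` is the smallest marker index j such that haplotypes
    order[k-1] and order[k] carry identical alleles at markers j..m;
    div[0] is the sentinel m+1.
    """
    n_hap, n_mark = H.shape
    order = np.arange(n_hap)
    div = np.zeros(n_hap, dtype=np.int64)
    stops = sorted(set(stops))
    si = 0
    for m in range(n_mark):
        if si >= len(stops):
            break
        a = H[order, m]
        new_order = np.empty_like(order)
        new_div = np.empty_like(div)
        pos = 0
        for v in np.unique(a):
            vpos = np.nonzero(a == v)[0]
            # segment maxima of div over (previous same-allele index, this index]
            bounds = np.r_[0, vpos[:-1] + 1]
            seg = np.maximum.reduceat(div[:vpos[-1] + 1], bounds)
            seg[0] = m + 1  # first element of a bucket matches nothing above it
            k = vpos.size
            new_order[pos:pos + k] = order[vpos]
            new_div[pos:pos + k] = seg
            pos += k
        order, div = new_order, new_div
        while si < len(stops) and stops[si] == m:
            yield m, order.copy(), div.copy()
            si += 1


# ---------------------------------------------------------------------------
# Pairwise qualification within an IBS block
# ---------------------------------------------------------------------------

def _pair_qualifies(xi: np.ndarray, xj: np.ndarray, cmw: np.ndarray,
                    focal: float, left_req: float, right_req: float,
                    length_cM: float, s_floor: float, e_ceil: float) -> bool:
    """Exact L/T window test for one haplotype pair over the local marker
    window.  ``s_floor``/``e_ceil`` are the run-extent values to use when
    no mismatch bounds the run inside the window (chromosome start/end or
    the window edge, which is conservative-exact; see module tests)."""
    neq = xi != xj
    if not neq.any():
        s, e = s_floor, e_ceil
    else:
        mism = np.nonzero(neq)[0]
        cms = cmw[mism]
        if np.any(np.abs(cms - focal) <= _TOL):
            return False  # mismatch at the focal marker itself
        left = mism[cms < focal]
        right = mism[cms > focal]
        lo = left[-1] + 1 if left.size else 0
        hi = right[0] - 1 if right.size else cmw.size - 1
        if lo > hi:
            return False  # no agreeing marker interval covering the focal point
        s = cmw[lo] if left.size else s_floor
        e = cmw[hi] if right.size else e_ceil
    return (s <= left_req + _TOL and e >= right_req - _TOL
            and e - s >= length_cM - _TOL)


class _UnionFind:
    def __init__(self, n: int) -> None:
        self.parent = np.arange(n)

    def find(self, x: int) -> int:
        p = self.parent
        while p[x] != x:
            p[x] = p[p[x]]
            x = p[x]
        return x

    def union(self, a: int, b: int) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[rb] = ra


def _cluster_labels_at(H: np.ndarray, cm: np.ndarray, span: tuple[float, float],
                       params: ClusteringParams, focal: float,
                       state: tuple[np.ndarray, np.ndarray] | None,
                       idx_left: int) -> np.ndarray:
    """Partition labels for one focal position on one chromosome.

    ``state`` is the PBWT (order, div) at the last marker inside the
    right trimming requirement, or None when no marker precedes it (all
    haplotypes are then vacuously one IBS block and the exact pairwise
    window test decides everything).
    """
    n_hap, n_mark = H.shape
    start_cm, end_cm = span
    L, T = params.length_cM, params.trim_cM
    left_req = max(focal - T, start_cm)
    right_req = min(focal + T, end_cm)

    # marker window of radius L plus one bracketing marker on each side
    wlo = int(np.searchsorted(cm, focal - L, side="left"))
    whi = int(np.searchsorted(cm, focal + L, side="right"))
    wlo = max(wlo - 1, 0)
    whi = min(whi + 1, n_mark)
    cmw = cm[wlo:whi]
    s_floor = start_cm if wlo == 0 else (cmw[0] if cmw.size else start_cm)
    e_ceil = end_cm if whi == n_mark else (cmw[-1] if cmw.size else end_cm)

    if state is None:
        blocks = [np.arange(n_hap)]
    else:
        order, div = state
        breaks = np.nonzero(div > idx_left)[0]
        blocks = [order[s:e] for s, e in
                  zip(np.r_[0, breaks], np.r_[breaks, n_hap]) if e - s >= 2]

    uf = _UnionFind(n_hap)
    for block in blocks:
        Xw = H[np.ix_(block, np.arange(wlo, whi))]
        for a in range(len(block)):
            for b in range(a + 1, len(block)):
                if uf.find(block[a]) == uf.find(block[b]):
                    continue
                if _pair_qualifies(Xw[a], Xw[b], cmw, focal,
                                   left_req, right_req, L, s_floor, e_ceil):
                    uf.union(block[a], block[b])

    roots = np.array([uf.find(i) for i in range(n_hap)])
    _, labels = np.unique(roots, return_inverse=True)
    return labels


def _chrom_data(haps: PhasedHaplotypes, gmap: GeneticMap, chrom: str):
    sub = haps.restrict(chrom)
    cm = np.asarray(gmap.interpolate(chrom, sub.variants["pos"].to_numpy()))
    return sub.haplotypes, cm, gmap.span_cM(chrom)


def cluster_at_position(haps: PhasedHaplotypes, gmap: GeneticMap,
                        params: ClusteringParams, focal_cM: float,
                        chrom: str | None = None) -> ClusterField:
    """Multi-individual IBD clusters at one focal position."""
    if chrom is None:
        chroms = haps.chromosomes
        if len(chroms) != 1:
            raise ValueError("chrom must be given for multi-chromosome data")
        chrom = chroms[0]
    H, cm, span = _chrom_data(haps, gmap, chrom)
    if not (span[0] - _TOL <= focal_cM <= span[1] + _TOL):
        raise ValueError(f"focal position {focal_cM} cM outside chromosome "
                         f"{chrom!r} span {span}")
    # The block pre-filter requires agreement only at markers strictly
    # inside the trimming interval; boundary markers (ties in cM) are
    # left to the exact pairwise test so the partition matches the
    # brute-force relation even on flat map stretches.
    right_req = min(focal_cM + params.trim_cM, span[1])
    left_req = max(focal_cM - params.trim_cM, span[0])
    m_right = int(np.searchsorted(cm, right_req - _TOL, side="left")) - 1
    idx_left = int(np.searchsorted(cm, left_req + _TOL, side="right"))
    if m_right < 0 or idx_left > m_right:
        state = None
    else:
        state = next(_pbwt_sweep(H, [m_right]))[1:]
    labels = _cluster_labels_at(H, cm, span, params, focal_cM, state, idx_left)
    return ClusterField(chrom=chrom,
                        position_bp=int(round(gmap.inverse(chrom, focal_cM))),
                        position_cM=float(focal_cM), labels=labels)


def grid_positions(span: tuple[float, float], spacing_cM: float) -> np.ndarray:
    """Test grid from chromosome start to end at the given spacing."""
    start, end = span
    n = int(np.floor((end - start) / spacing_cM + _TOL)) + 1
    return start + spacing_cM * np.arange(n)


def cluster_field_scan(haps: PhasedHaplotypes, gmap: GeneticMap,
                       params: ClusteringParams, spacing_cM: float,
                       chroms: Sequence[str] | None = None) -> list[ClusterField]:
    """Cluster fields on a regular cM grid over each chromosome.

    A single forward PBWT sweep per chromosome provides the sorted state
    at every grid point, so the scan costs one pass over the markers plus
    the per-position block work.
    """
    if spacing_cM <= 0:
        raise ValueError("spacing_cM must be positive")
    fields: list[ClusterField] = []
    for chrom in (chroms or haps.chromosomes):
        H, cm, span = _chrom_data(haps, gmap, chrom)
        focals = grid_positions(span, spacing_cM)
        stop_of: dict[float, int] = {}
        for f in focals:
            r = min(f + params.trim_cM, span[1])
            stop_of[f] = int(np.searchsorted(cm, r - _TOL, side="left")) - 1
        needed = sorted({m for m in stop_of.values() if m >= 0})
        states = {m: (order, div)
                  for m, order, div in _pbwt_sweep(H, needed)}
        for f in focals:
            left_req = max(f - params.trim_cM, span[0])
            idx_left = int(np.searchsorted(cm, left_req + _TOL, side="right"))
            m_right = stop_of[f]
            state = states.get(m_right) if m_right >= 0 and idx_left <= m_right else None
            labels = _cluster_labels_at(H, cm, span, params, f, state, idx_left)
            fields.append(ClusterField(
                chrom=chrom, position_bp=int(round(gmap.inverse(chrom, f))),
                position_cM=float(f), labels=labels))
    return fields


# ---------------------------------------------------------------------------
# Pairwise segment detection
# ---------------------------------------------------------------------------

def _maximal_run(hi: np.ndarray, hj: np.ndarray, lo: int, hi_idx: int) -> tuple[int, int]:
    """Extend the agreeing interval [lo, hi_idx) of a haplotype pair to
    the maximal identical run containing it; returns marker index bounds
    (inclusive, exclusive)."""
    left_mism = np.nonzero(hi[:lo] != hj[:lo])[0]
    left = int(left_mism[-1]) + 1 if left_mism.size else 0
    right_mism = np.nonzero(hi[hi_idx:] != hj[hi_idx:])[0]
    right = hi_idx + int(right_mism[0]) if right_mism.size else hi.size
    return left, right


def detect_pairwise_segments(haps: PhasedHaplotypes, gmap: GeneticMap,
                             params: PairwiseDetectorParams) -> pd.DataFrame:
    """Maximal identical-allele runs between haplotype pairs, on markers
    passing the minor-allele-count filter, retained when the run spans at
    least ``min_output_cM`` (and ``min_seed_cM``) and contains at least
    ``min_seed_markers`` markers.

    Candidate pairs are haplotypes identical across a tiling window of
    half the output threshold — any qualifying run fully covers at least
    one such window — then extended exactly and deduplicated.
    """
    records = []
    for chrom in haps.chromosomes:
        sub = haps.restrict(chrom)
        mac = np.minimum(sub.haplotypes.sum(axis=0),
                         (1 - (sub.haplotypes > 0)).sum(axis=0))
        keep = np.nonzero(mac >= params.min_minor_allele_count)[0]
        if keep.size == 0:
            continue
        H = np.ascontiguousarray(sub.haplotypes[:, keep])
        pos = sub.variants["pos"].to_numpy()[keep]
        cm = np.asarray(gmap.interpolate(chrom, pos))
        span = gmap.span_cM(chrom)

        width = params.min_output_cM / 2.0
        edges = np.arange(span[0], span[1] + width, width)
        seen: set[tuple[int, int, int]] = set()
        for w0, w1 in zip(edges[:-1], edges[1:]):
            a = int(np.searchsorted(cm, w0, side="left"))
            b = int(np.searchsorted(cm, w1, side="left"))
            if b <= a:
                continue
            _, inv = np.unique(H[:, a:b], axis=0, return_inverse=True)
            counts = np.bincount(inv)
            for g in np.nonzero(counts >= 2)[0]:
                members = np.nonzero(inv == g)[0]
                for x in range(len(members)):
                    for y in range(x + 1, len(members)):
                        i, j = int(members[x]), int(members[y])
                        left, right = _maximal_run(H[i], H[j], a, b)
                        key = (i, j, left)
                        if key in seen:
                            continue
                        seen.add(key)
                        length = cm[right - 1] - cm[left]
                        n_markers = right - left
                        if (length >= params.min_output_cM - _TOL
                                and length >= params.min_seed_cM - _TOL
                                and n_markers >= params.min_seed_markers):
                            records.append((
                                haps.samples[i // 2], i % 2 + 1,
                                haps.samples[j // 2], j % 2 + 1,
                                chrom, int(pos[left]), int(pos[right - 1]),
                                float(length)))
    df = pd.DataFrame(records, columns=SEGMENT_COLUMNS)
    return df.drop_duplicates(ignore_index=True)
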