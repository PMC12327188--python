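"""Local and global IBD relatedness matrices and their block structure.

The local IBD matrix at position l is Phi_l = 2 A_l A_l', where the
allocation matrix A_l records the proportion (0, 1/2 or 1) of each
individual's two haplotypes assigned to each multi-individual IBD
cluster.  The global matrix Psi holds twice the kinship coefficient for
pairs at or above a sparsity threshold (0.044, i.e. closer than
third-degree relatives) and zero otherwise.  Both are kept sparse; the
variance matrix Psi*sa2 + Phi*sq2 + I*se2 is block-diagonal under the
connected components of their combined sparsity graph, which is what
makes the REML likelihood cheap to evaluate.
"""

from __future__ import annotations

import logging
import warnings
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.linalg
import scipy.sparse as sp
from scipy.sparse.csgraph import connected_components

from .ibd_io import ClusterField, GeneticMap, KINSHIP_COLUMNS

__all__ = [
    "allocation_matrix",
    "local_ibd_matrix",
    "region_ibd_matrix",
    "global_ibd_matrix",
    "kinship_from_segments",
    "block_partition",
    "ensure_psd",
    "KINSHIP_SPARSITY_THRESHOLD",
]

logger = logging.getLogger(__name__)

#: kinship below this (beyond third-degree relatives) is zeroed in Psi
KINSHIP_SPARSITY_THRESHOLD = 0.044


def allocation_matrix(field: ClusterField, n_individuals: int,
                      drop_singletons: bool = True) -> sp.csr_matrix:
    """N x K allocation matrix: entry (i, k) is the fraction of
    individual i's two haplotypes assigned to cluster k.

    Columns for singleton clusters carry no between-individual sharing
    and may be dropped; this changes no off-diagonal entry of Phi (the
    diagonal is forced to 1 downstream either way).
    """
    labels = field.labels
    if labels.size != 2 * n_individuals:
        raise ValueError(f"cluster field has {labels.size} haplotypes, "
                         f"expected {2 * n_individuals}")
    uniq, inv = np.unique(labels, return_inverse=True)
    if drop_singletons:
        counts = np.bincount(inv)
        keep = counts >= 2
        remap = -np.ones(uniq.size, dtype=np.int64)
        remap[keep] = np.arange(int(keep.sum()))
        col = remap[inv]
        mask = col >= 0
        rows = np.repeat(np.arange(n_individuals), 2)[mask]
        cols = col[mask]
        k = int(keep.sum())
    else:
        rows = np.repeat(np.arange(n_individuals), 2)
        cols = inv
        k = uniq.size
    data = np.full(rows.size, 0.5)
    A = sp.coo_matrix((data, (rows, cols)), shape=(n_individuals, k))
    A.sum_duplicates()
    return A.tocsr()


def local_ibd_matrix(A: sp.spmatrix) -> sp.csr_matrix:
    """Phi = 2 A A' with the diagonal set to exactly 1."""
    phi = (2.0 * (A @ A.T)).tocsr()
    row_sums = np.asarray(abs(A).sum(axis=1)).ravel()
    if A.shape[1] and np.any(row_sums > 1 + 1e-9):
        raise ValueError("allocation matrix row exceeds one full genome copy")
    phi.setdiag(1.0)
    phi.eliminate_zeros()
    return phi


def phi_from_field(field: ClusterField, n_individuals: int) -> sp.csr_matrix:
    """Convenience: local IBD matrix straight from a cluster field."""
    return local_ibd_matrix(allocation_matrix(field, n_individuals))


def region_ibd_matrix(fields: Sequence[ClusterField], n_individuals: int) -> sp.csr_matrix:
    """Region matrix: elementwise mean of per-position local matrices
    (typically the region's start and end positions)."""
    if not fields:
        raise ValueError("need at least one cluster field")
    mats = [phi_from_field(f, n_individuals) for f in fields]
    avg = mats[0].copy().astype(float)
    for m in mats[1:]:
        if m.shape != avg.shape:
            raise ValueError("inconsistent sample count across fields")
        avg = avg + m
    avg = (avg / len(mats)).tocsr()
    avg.setdiag(1.0)
    return avg


def global_ibd_matrix(kinship: pd.DataFrame, samples: Sequence[str],
                      threshold: float = KINSHIP_SPARSITY_THRESHOLD) -> sp.csr_matrix:
    """Psi: twice the kinship coefficient, zeroed below ``threshold``,
    unit diagonal."""
    n = len(samples)
    index = {s: i for i, s in enumerate(samples)}
    rows, cols, vals = [], [], []
    for s1, s2, k in kinship[KINSHIP_COLUMNS].itertuples(index=False):
        if k > 0.5:
            raise ValueError(f"kinship {k} > 0.5 for pair ({s1}, {s2})")
        if k < threshold:
            continue
        i, j = index[str(s1)], index[str(s2)]
        rows += [i, j]
        cols += [j, i]
        vals += [2.0 * k, 2.0 * k]
    psi = sp.coo_matrix((vals, (rows, cols)), shape=(n, n)).tocsr()
    psi.setdiag(1.0)
    return psi


# ---------------------------------------------------------------------------
# Kinship from haplotype-resolved segments
# ---------------------------------------------------------------------------

def _interval_union(iv: list[tuple[float, float]]) -> list[tuple[float, float]]:
    if not iv:
        return []
    iv = sorted(iv)
    out = [list(iv[0])]
    for s, e in iv[1:]:
        if s <= out[-1][1]:
            out[-1][1] = max(out[-1][1], e)
        else:
            out.append([s, e])
    return [(s, e) for s, e in out]


def _interval_measure(iv: list[tuple[float, float]]) -> float:
    return sum(e - s for s, e in iv)


def _interval_intersect(a: list[tuple[float, float]],
                        b: list[tuple[float, float]]) -> list[tuple[float, float]]:
    out = []
    i = j = 0
    while i < len(a) and j < len(b):
        s = max(a[i][0], b[j][0])
        e = min(a[i][1], b[j][1])
        if s < e:
            out.append((s, e))
        if a[i][1] < b[j][1]:
            i += 1
        else:
            j += 1
    return out


def kinship_from_segments(segments: pd.DataFrame, gmap: GeneticMap) -> pd.DataFrame:
    """Kinship coefficients from haplotype-resolved IBD segments.

    For each individual pair, p1 is the genome proportion where exactly
    one haplotype combination is IBD (IBD1) and p2 the proportion where
    both of one individual's haplotypes are IBD with both of the
    other's, in either pairing (IBD2); kinship = p1/4 + p2/2.
    Overlapping duplicate segments are merged before measuring.
    """
    genome_cM = sum(gmap.span_cM(c)[1] - gmap.span_cM(c)[0]
                    for c in gmap.chromosomes)
    if genome_cM <= 0:
        raise ValueError("genetic map has zero total length")

    # (sample_pair) -> chrom -> combo (h1, h2) -> interval list in cM
    pairs: dict[tuple[str, str], dict[str, dict[tuple[int, int], list]]] = {}
    for rec in segments.itertuples(index=False):
        s1, h1, s2, h2 = rec.sample1, int(rec.hap1), rec.sample2, int(rec.hap2)
        if s1 == s2:
            continue
        if s2 < s1:
            s1, s2, h1, h2 = s2, s1, h2, h1
        c0 = float(gmap.interpolate(rec.chrom, rec.start_bp))
        c1 = float(gmap.interpolate(rec.chrom, rec.end_bp))
        if c1 < c0:
            raise ValueError("negative-length segment")
        combo = (h1 - 1, h2 - 1)
        pairs.setdefault((s1, s2), {}).setdefault(rec.chrom, {}).setdefault(
            combo, []).append((c0, c1))

    records = []
    for (s1, s2), by_chrom in pairs.items():
        ibd1_len = 0.0
        ibd2_len = 0.0
        for combos in by_chrom.values():
            u = {c: _interval_union(v) for c, v in combos.items()}
            any_cov = _interval_union([iv for v in u.values() for iv in v])
            pair_a = _interval_intersect(u.get((0, 0), []), u.get((1, 1), []))
            pair_b = _interval_intersect(u.get((0, 1), []), u.get((1, 0), []))
            ibd2 = _interval_union(pair_a + pair_b)
            m2 = _interval_measure(ibd2)
            ibd2_len += m2
            ibd1_len += _interval_measure(any_cov) - m2
        p1 = ibd1_len / genome_cM
        p2 = ibd2_len / genome_cM
        records.append((s1, s2, p1 / 4.0 + p2 / 2.0))
    return pd.DataFrame(records, columns=KINSHIP_COLUMNS)


# ---------------------------------------------------------------------------
# Block structure and PSD repair
# ---------------------------------------------------------------------------

def block_partition(*matrices: sp.spmatrix) -> list[np.ndarray]:
    """Connected components of the union sparsity graph of the given
    symmetric matrices; permuting by these blocks renders any linear
    combination (plus a diagonal) block-diagonal."""
    mats = [m for m in matrices if m is not None]
    if not mats:
        raise ValueError("need at least one matrix")
    n = mats[0].shape[0]
    pattern = sp.csr_matrix((n, n))
    for m in mats:
        if m.shape != (n, n):
            raise ValueError("matrix dimensions disagree")
        pattern = pattern + (sp.csr_matrix(abs(m)) != 0).astype(np.int8)
    n_comp, labels = connected_components(pattern, directed=False)
    order = np.argsort(labels, kind="stable")
    bounds = np.searchsorted(labels[order], np.arange(n_comp + 1))
    return [order[bounds[k]:bounds[k + 1]] for k in range(n_comp)]


def ensure_psd(mat: sp.csr_matrix, blocks: list[np.ndarray] | None = None,
               jitters: tuple[float, ...] = (1e-8, 1e-6)) -> sp.csr_matrix:
    """Verify each diagonal block factorizes; where a Cholesky fails, add
    the smallest diagonal jitter from ``jitters`` that repairs it.

    Thresholding small kinship values to zero can leave Psi slightly
    indefinite; the likelihood code requires a factorizable covariance.
    """
    if blocks is None:
        blocks = block_partition(mat)
    mat = mat.tolil(copy=True)
    for block in blocks:
        if block.size == 1:
            continue
        dense = mat[np.ix_(block, block)].toarray()
        for jitter in (0.0,) + tuple(jitters):
            try:
                scipy.linalg.cholesky(dense + jitter * np.eye(block.size), lower=True)
                if jitter:
                    logger.info("added diagonal jitter %g to a %d-individual block",
                                jitter, block.size)
                    for i in block:
                        mat[i, i] += jitter
                break
            except scipy.linalg.LinAlgError:
                continue
        else:
            warnings.warn("block remained non-PSD after maximal jitter; "
                          "likelihood evaluation may fail", RuntimeWarning)
    return mat.tocsr()
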