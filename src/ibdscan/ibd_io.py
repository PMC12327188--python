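"""Readers, writers and genetic-map interpolation.

Formats handled here are the ones an IBD mapping analysis touches in
practice: phased VCF (v4.x, ``GT`` with ``|`` separators), PLINK-style
4-column and deCODE-style 3-column genetic maps, hap-ibd segment TSVs,
IBDkin kinship TSVs, and the package's own per-position haplotype
cluster table (TSV).  Coordinates are 1-based inclusive base pairs, as
in VCF; genetic positions are centimorgans.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp

__all__ = [
    "GeneticMap",
    "PhasedHaplotypes",
    "ClusterField",
    "read_phased_vcf",
    "write_phased_vcf",
    "read_plink_map",
    "read_decode_map",
    "write_plink_map",
    "read_cluster_field",
    "write_cluster_field",
    "read_ibd_segments",
    "read_kinship",
    "write_sparse_matrix",
    "read_sparse_matrix",
    "SEGMENT_COLUMNS",
    "KINSHIP_COLUMNS",
]

SEGMENT_COLUMNS = [
    "sample1", "hap1", "sample2", "hap2",
    "chrom", "start_bp", "end_bp", "length_cM",
]
KINSHIP_COLUMNS = ["sample1", "sample2", "kinship"]


class FormatError(ValueError):
    """A file does not satisfy the format contract it was read as."""


# ---------------------------------------------------------------------------
# Genetic map
# ---------------------------------------------------------------------------

@dataclass
class GeneticMap:
    """Piecewise-linear bp <-> cM map, one strictly increasing track per
    chromosome.  Queries beyond the map endpoints are clamped to the
    endpoint cM value (constant extrapolation), which keeps genetic
    positions non-negative at chromosome ends.
    """

    positions_bp: Mapping[str, np.ndarray]
    positions_cM: Mapping[str, np.ndarray]

    def __post_init__(self) -> None:
        bps, cms = {}, {}
        for chrom in self.positions_bp:
            bp = np.asarray(self.positions_bp[chrom], dtype=np.int64)
            cm = np.asarray(self.positions_cM[chrom], dtype=np.float64)
            if bp.shape != cm.shape or bp.ndim != 1 or bp.size == 0:
                raise FormatError(f"map for {chrom!r}: bp/cM shape mismatch")
            if np.any(bp < 1):
                raise FormatError(f"map for {chrom!r}: bp positions must be >= 1")
            if np.any(np.diff(bp) <= 0):
                raise FormatError(f"map for {chrom!r}: bp not strictly increasing")
            if np.any(np.diff(cm) < 0) or np.any(cm < 0):
                raise FormatError(f"map for {chrom!r}: cM must be non-negative and non-decreasing")
            bps[chrom], cms[chrom] = bp, cm
        self.positions_bp, self.positions_cM = bps, cms

    @classmethod
    def from_arrays(cls, chrom: str, bp: Sequence[int], cm: Sequence[float]) -> "GeneticMap":
        return cls({chrom: np.asarray(bp, dtype=np.int64)},
                   {chrom: np.asarray(cm, dtype=np.float64)})

    @classmethod
    def uniform(cls, chrom_lengths_cM: Mapping[str, float],
                cm_per_mb: float = 1.0) -> "GeneticMap":
        """Uniform-rate map (default 1 cM/Mb), anchored at bp 1 = 0 cM."""
        bp, cm = {}, {}
        for chrom, length in chrom_lengths_cM.items():
            end_bp = int(round(length / cm_per_mb * 1e6)) + 1
            bp[chrom] = np.array([1, end_bp], dtype=np.int64)
            cm[chrom] = np.array([0.0, length], dtype=np.float64)
        return cls(bp, cm)

    @property
    def chromosomes(self) -> list[str]:
        return list(self.positions_bp)

    def _require(self, chrom: str) -> None:
        if chrom not in self.positions_bp:
            raise KeyError(f"chromosome {chrom!r} not in genetic map "
                           f"(have {sorted(self.positions_bp)})")

    def interpolate(self, chrom: str, position_bp) -> np.ndarray | float:
        """bp -> cM, piecewise linear, clamped beyond the map span."""
        self._require(chrom)
        out = np.interp(np.asarray(position_bp, dtype=np.float64),
                        self.positions_bp[chrom], self.positions_cM[chrom])
        return float(out) if np.isscalar(position_bp) else out

    def inverse(self, chrom: str, position_cM) -> np.ndarray | float:
        """cM -> bp (nearest consistent bp; flat map stretches resolve to
        their left edge)."""
        self._require(chrom)
        out = np.interp(np.asarray(position_cM, dtype=np.float64),
                        self.positions_cM[chrom], self.positions_bp[chrom])
        return float(out) if np.isscalar(position_cM) else out

    def span_cM(self, chrom: str) -> tuple[float, float]:
        self._require(chrom)
        cm = self.positions_cM[chrom]
        return float(cm[0]), float(cm[-1])


def interpolate_cM(gmap: GeneticMap, chrom: str, position_bp) -> float | np.ndarray:
    """Functional alias for :meth:`GeneticMap.interpolate`."""
    return gmap.interpolate(chrom, position_bp)


def read_plink_map(path) -> GeneticMap:
    """PLINK 4-column map: chrom, id, cM, bp (whitespace separated)."""
    df = pd.read_csv(path, sep=r"\s+", header=None,
                     names=["chrom", "id", "cM", "bp"], comment="#",
                     dtype={"chrom": str})
    return _map_from_frame(df)


def read_decode_map(path) -> GeneticMap:
    """deCODE-style 3-column map: chrom, bp, cM.  A header line is
    detected and skipped."""
    first = Path(path).read_text().splitlines()
    skip = 1 if first and not first[0].split()[1].replace(".", "").isdigit() else 0
    df = pd.read_csv(path, sep=r"\s+", header=None, skiprows=skip,
                     names=["chrom", "bp", "cM"], dtype={"chrom": str})
    return _map_from_frame(df)


def _map_from_frame(df: pd.DataFrame) -> GeneticMap:
    bp, cm = {}, {}
    for chrom, grp in df.groupby("chrom", sort=False):
        grp = grp.sort_values("bp")
        bp[str(chrom)] = grp["bp"].to_numpy(dtype=np.int64)
        cm[str(chrom)] = grp["cM"].to_numpy(dtype=np.float64)
    return GeneticMap(bp, cm)


def write_plink_map(gmap: GeneticMap, path) -> None:
    with open(path, "w") as fh:
        for chrom in gmap.chromosomes:
            for b, c in zip(gmap.positions_bp[chrom], gmap.positions_cM[chrom]):
                fh.write(f"{chrom}\t.\t{c:.6f}\t{b}\n")


# ---------------------------------------------------------------------------
# Phased haplotypes
# ---------------------------------------------------------------------------

@dataclass
class PhasedHaplotypes:
    """Complete, phased haplotype alleles for N samples at M markers.

    ``haplotypes`` has shape (2N, M) over allele indices; haplotype h of
    sample i is row ``2*i + h``.  ``variants`` is a DataFrame with columns
    chrom, pos, ref, alt, sorted by position within chromosome.
    """

    samples: list[str]
    variants: pd.DataFrame
    haplotypes: np.ndarray

    def __post_init__(self) -> None:
        self.haplotypes = np.asarray(self.haplotypes)
        if self.haplotypes.shape != (2 * len(self.samples), len(self.variants)):
            raise ValueError(
                f"haplotype matrix shape {self.haplotypes.shape} does not match "
                f"2x{len(self.samples)} samples x {len(self.variants)} variants")
        for chrom, grp in self.variants.groupby("chrom", sort=False):
            if np.any(np.diff(grp["pos"].to_numpy()) < 0):
                raise ValueError(f"variants not sorted by position on {chrom!r}")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_markers(self) -> int:
        return len(self.variants)

    @property
    def chromosomes(self) -> list[str]:
        return list(dict.fromkeys(self.variants["chrom"]))

    def marker_cM(self, gmap: GeneticMap) -> np.ndarray:
        """cM coordinate of every marker under ``gmap``."""
        out = np.empty(self.n_markers)
        pos = self.variants["pos"].to_numpy()
        for chrom, idx in self._chrom_slices().items():
            out[idx] = gmap.interpolate(chrom, pos[idx])
        return out

    def _chrom_slices(self) -> dict[str, slice]:
        chroms = self.variants["chrom"].to_numpy()
        slices: dict[str, slice] = {}
        start = 0
        for i in range(1, len(chroms) + 1):
            if i == len(chroms) or chroms[i] != chroms[start]:
                slices[chroms[start]] = slice(start, i)
                start = i
        return slices

    def restrict(self, chrom: str) -> "PhasedHaplotypes":
        sl = self._chrom_slices().get(chrom)
        if sl is None:
            raise KeyError(f"chromosome {chrom!r} not present")
        return PhasedHaplotypes(self.samples,
                                self.variants.iloc[sl].reset_index(drop=True),
                                self.haplotypes[:, sl])

    def subset_markers(self, index: np.ndarray) -> "PhasedHaplotypes":
        return PhasedHaplotypes(self.samples,
                                self.variants.iloc[index].reset_index(drop=True),
                                self.haplotypes[:, index])

    def minor_allele_frequency(self) -> np.ndarray:
        """Per-marker MAF (biallelic; frequency of the rarer allele)."""
        freq = self.haplotypes.mean(axis=0)
        return np.minimum(freq, 1.0 - freq)

    def dosage(self, marker_index) -> np.ndarray:
        """Minor-allele copy number (0/1/2) per sample at the marker(s)."""
        h = self.haplotypes[:, marker_index]
        freq = h.mean(axis=0)
        alt_is_minor = freq <= 0.5
        counts = h.reshape(self.n_samples, 2, -1).sum(axis=1)
        return np.where(alt_is_minor, counts, 2 - counts).squeeze()


def _parse_region(region: str) -> tuple[str, int | None, int | None]:
    if ":" not in region:
        return region, None, None
    chrom, _, rng = region.partition(":")
    start, _, end = rng.partition("-")
    return chrom, int(start), int(end)


def read_phased_vcf(path, region: str | None = None) -> PhasedHaplotypes:
    """Read a fully phased VCF into a haplotype matrix.

    Any unphased or missing genotype is a hard error naming the offending
    record; an empty region query yields a 2N x 0 matrix.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=False)
    samples = list(vcf.samples)
    want = _parse_region(region) if region is not None else None

    rows, chroms, poss, refs, alts = [], [], [], [], []
    for var in vcf:
        if want is not None:
            chrom, start, end = want
            if var.CHROM != chrom:
                continue
            if start is not None and not (start <= var.POS <= end):
                continue
        gts = np.asarray(var.genotype.array())
        alleles, phased = gts[:, :-1], gts[:, -1]
        if np.any(alleles < 0):
            raise FormatError(
                f"missing genotype at {var.CHROM}:{var.POS} in {path}")
        if not np.all(phased):
            raise FormatError(
                f"unphased genotype at {var.CHROM}:{var.POS} in {path}")
        rows.append(alleles.astype(np.int8).reshape(-1))
        chroms.append(var.CHROM)
        poss.append(var.POS)
        refs.append(var.REF)
        alts.append(var.ALT[0] if var.ALT else ".")
    vcf.close()

    variants = pd.DataFrame({"chrom": chroms, "pos": poss, "ref": refs, "alt": alts})
    hmat = (np.stack(rows, axis=1) if rows
            else np.empty((2 * len(samples), 0), dtype=np.int8))
    return PhasedHaplotypes(samples, variants, hmat)


def write_phased_vcf(haps: PhasedHaplotypes, path) -> None:
    """Write a minimal phased VCF v4.2 (uncompressed text)."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom in haps.chromosomes:
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(haps.samples) + "\n")
        H = haps.haplotypes
        for m, row in enumerate(haps.variants.itertuples(index=False)):
            gts = "\t".join(f"{H[2 * i, m]}|{H[2 * i + 1, m]}"
                            for i in range(haps.n_samples))
            fh.write(f"{row.chrom}\t{row.pos}\t.\t{row.ref}\t{row.alt}"
                     f"\t.\tPASS\t.\tGT\t{gts}\n")


# ---------------------------------------------------------------------------
# Cluster fields
# ---------------------------------------------------------------------------

@dataclass
class ClusterField:
    """Assignment of each of 2N haplotypes to an IBD cluster at one
    genomic position.  Labels are arbitrary; only the partition they
    induce is meaningful, so equality compares canonical relabelings.
    """

    chrom: str
    position_bp: int
    position_cM: float
    labels: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.int64)
        if self.labels.ndim != 1 or self.labels.size % 2:
            raise ValueError("labels must be a flat vector of 2N identifiers")
        if np.any(self.labels < 0):
            raise ValueError("cluster identifiers must be non-negative")

    @property
    def n_haplotypes(self) -> int:
        return self.labels.size

    def canonical(self) -> np.ndarray:
        """Relabel clusters by order of first appearance."""
        _, canon = np.unique(self.labels, return_inverse=True)
        first = {}
        out = np.empty_like(self.labels)
        nxt = 0
        for i, lab in enumerate(canon):
            if lab not in first:
                first[lab] = nxt
                nxt += 1
            out[i] = first[lab]
        return out

    def same_partition(self, other: "ClusterField") -> bool:
        return (self.n_haplotypes == other.n_haplotypes
                and np.array_equal(self.canonical(), other.canonical()))

    def __eq__(self, other: object) -> bool:  # partition equality
        if not isinstance(other, ClusterField):
            return NotImplemented
        return (self.chrom == other.chrom
                and self.position_bp == other.position_bp
                and np.isclose(self.position_cM, other.position_cM)
                and self.same_partition(other))


def write_cluster_field(fields: Iterable[ClusterField], path,
                        samples: Sequence[str] | None = None) -> None:
    """One row per position: CHROM, POS, CM, then 2N identifiers in
    sample order (hap 0, hap 1 per sample)."""
    fields = list(fields)
    with open(path, "w") as fh:
        if samples is not None:
            cols = [f"{s}.{h}" for s in samples for h in (0, 1)]
        else:
            n = fields[0].n_haplotypes if fields else 0
            cols = [f"H{i}" for i in range(n)]
        fh.write("CHROM\tPOS\tCM\t" + "\t".join(cols) + "\n")
        for f in fields:
            labs = "\t".join(map(str, f.labels))
            fh.write(f"{f.chrom}\t{f.position_bp}\t{f.position_cM:.6f}\t{labs}\n")


def read_cluster_field(path) -> list[ClusterField]:
    fields: list[ClusterField] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        n_hap = len(header) - 3
        if n_hap <= 0 or n_hap % 2:
            raise FormatError(f"{path}: header implies {n_hap} haplotype columns")
        for lineno, line in enumerate(fh, start=2):
            parts = line.rstrip("\n").split("\t")
            if len(parts) - 3 != n_hap:
                raise FormatError(
                    f"{path}:{lineno}: expected {n_hap} identifiers, "
                    f"got {len(parts) - 3}")
            fields.append(ClusterField(
                chrom=parts[0], position_bp=int(parts[1]),
                position_cM=float(parts[2]),
                labels=np.array(parts[3:], dtype=np.int64)))
    return fields


def convert_ibd_cluster_output(path) -> list[ClusterField]:
    """Converter stub for genuine ibd-cluster output.

    Accepts the same layout as our internal TSV modulo the header marker;
    the upstream tool's exact columns should be confirmed against its
    documentation before relying on this for real data.
    """
    return read_cluster_field(path)


# ---------------------------------------------------------------------------
# Segments and kinship
# ---------------------------------------------------------------------------

def read_ibd_segments(path, gmap: GeneticMap | None = None) -> pd.DataFrame:
    """hap-ibd style segment TSV: sample1, hap1 (1/2), sample2, hap2,
    chrom, start_bp, end_bp[, length_cM].  length_cM is recomputed from
    the map when absent."""
    try:
        df = pd.read_csv(path, sep="\t", header=None, dtype={4: str})
    except pd.errors.EmptyDataError:
        return pd.DataFrame(columns=SEGMENT_COLUMNS)
    if df.shape[1] == 7:
        if gmap is None:
            raise FormatError(f"{path}: no length column and no map supplied")
        df.columns = SEGMENT_COLUMNS[:7]
        df["length_cM"] = [
            gmap.interpolate(c, e) - gmap.interpolate(c, s)
            for c, s, e in zip(df["chrom"], df["start_bp"], df["end_bp"])]
    elif df.shape[1] == 8:
        df.columns = SEGMENT_COLUMNS
    else:
        raise FormatError(f"{path}: expected 7 or 8 columns, got {df.shape[1]}")
    if np.any(df["start_bp"].to_numpy() >= df["end_bp"].to_numpy()):
        raise FormatError(f"{path}: segment with start_bp >= end_bp")
    if np.any(df["length_cM"].to_numpy() < 0):
        raise FormatError(f"{path}: negative-length segment")
    return df


def write_ibd_segments(segments: pd.DataFrame, path) -> None:
    segments[SEGMENT_COLUMNS].to_csv(path, sep="\t", header=False, index=False)


def read_kinship(path) -> pd.DataFrame:
    """IBDkin-style kinship TSV.  Accepts either a headered file with
    ID1/ID2/.../KINSHIP columns or a plain 3-column (sample1, sample2,
    kinship) table.  Self-pairs are rejected; kinship must lie in
    [0, 0.5]."""
    try:
        probe = pd.read_csv(path, sep="\t", nrows=1)
    except pd.errors.EmptyDataError:
        return pd.DataFrame(columns=KINSHIP_COLUMNS)
    cols_upper = [str(c).upper() for c in probe.columns]
    if "KINSHIP" in cols_upper:
        df = pd.read_csv(path, sep="\t")
        df.columns = [str(c).upper() for c in df.columns]
        df = df.rename(columns={"ID1": "sample1", "ID2": "sample2",
                                "KINSHIP": "kinship"})
        df = df[KINSHIP_COLUMNS]
    else:
        df = pd.read_csv(path, sep="\t", header=None)
        if df.shape[1] < 3:
            raise FormatError(f"{path}: expected >= 3 columns")
        df = df.iloc[:, [0, 1, df.shape[1] - 1]]
        df.columns = KINSHIP_COLUMNS
    df["sample1"] = df["sample1"].astype(str)
    df["sample2"] = df["sample2"].astype(str)
    if np.any(df["sample1"].to_numpy() == df["sample2"].to_numpy()):
        raise FormatError(f"{path}: self-pair in kinship table")
    k = df["kinship"].to_numpy(dtype=float)
    if np.any(k < 0) or np.any(k > 0.5):
        raise FormatError(f"{path}: kinship outside [0, 0.5]")
    return df.reset_index(drop=True)


def write_kinship(kin: pd.DataFrame, path) -> None:
    kin[KINSHIP_COLUMNS].to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Sparse matrix coordinate text
# ---------------------------------------------------------------------------

def write_sparse_matrix(mat: sp.spmatrix, path, metadata: dict | None = None) -> None:
    """Upper-triangle coordinate text (i, j, value) with a JSON sidecar
    recording N and any position metadata."""
    coo = sp.triu(sp.coo_matrix(mat))
    with open(path, "w") as fh:
        for i, j, v in zip(coo.row, coo.col, coo.data):
            fh.write(f"{i}\t{j}\t{v:.10g}\n")
    side = {"n": mat.shape[0]}
    side.update(metadata or {})
    Path(str(path) + ".json").write_text(json.dumps(side))


def read_sparse_matrix(path) -> tuple[sp.csr_matrix, dict]:
    meta = json.loads(Path(str(path) + ".json").read_text())
    n = int(meta["n"])
    rows, cols, vals = [], [], []
    with open(path) as fh:
        for line in fh:
            i, j, v = line.split()
            rows.append(int(i)); cols.append(int(j)); vals.append(float(v))
    upper = sp.coo_matrix((vals, (rows, cols)), shape=(n, n))
    full = upper + sp.triu(upper, k=1).T
    return full.tocsr(), meta
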