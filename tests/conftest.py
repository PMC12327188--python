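"""Shared fixtures: tiny text-format files and structured synthetic data
built programmatically at test time."""

import numpy as np
import pytest
import scipy.sparse as sp

from ibdscan.ibd_io import GeneticMap, PhasedHaplotypes
from ibdscan.relatedness import global_ibd_matrix, phi_from_field
from ibdscan.simdata import (StructuredSpec, generate_structured_fixture,
                             simulate_phenotypes)

PHASED_VCF = """\
##fileformat=VCFv4.2
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##contig=<ID=1>
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tA\tB
1\t100\t.\tA\tC\t.\tPASS\t.\tGT\t0|1\t1|1
1\t250\t.\tG\tT\t.\tPASS\t.\tGT\t0|0\t0|1
1\t400\t.\tT\tA\t.\tPASS\t.\tGT\t1|0\t0|0
"""

MISSING_VCF = PHASED_VCF.replace("1\t250\t.\tG\tT\t.\tPASS\t.\tGT\t0|0\t0|1",
                                 "1\t250\t.\tG\tT\t.\tPASS\t.\tGT\t./.\t0|1")
UNPHASED_VCF = PHASED_VCF.replace("0|1\t1|1", "0/1\t1|1")


@pytest.fixture
def tiny_vcf(tmp_path):
    path = tmp_path / "tiny.vcf"
    path.write_text(PHASED_VCF)
    return path


@pytest.fixture
def missing_vcf(tmp_path):
    path = tmp_path / "missing.vcf"
    path.write_text(MISSING_VCF)
    return path


@pytest.fixture
def unphased_vcf(tmp_path):
    path = tmp_path / "unphased.vcf"
    path.write_text(UNPHASED_VCF)
    return path


@pytest.fixture
def simple_map():
    return GeneticMap.from_arrays("1", [100, 300], [0.0, 2.0])


def random_haplotypes(n_hap, n_markers, length_cM=10.0, seed=0,
                      n_founders=None):
    """Haplotypes drawn from a small founder pool so that long shared
    runs exist, plus random mosaic switches; uniform map over
    ``length_cM``."""
    rng = np.random.default_rng(seed)
    n_founders = n_founders or max(2, n_hap // 4)
    founders = rng.integers(0, 2, size=(n_founders, n_markers)).astype(np.int8)
    H = np.empty((n_hap, n_markers), dtype=np.int8)
    for h in range(n_hap):
        # mosaic of founder chunks: switch points at random markers
        n_switch = rng.poisson(3)
        cuts = np.sort(rng.choice(n_markers - 1, size=n_switch, replace=False)) + 1 \
            if n_switch else np.array([], dtype=int)
        bounds = np.r_[0, cuts, n_markers]
        for lo, hi in zip(bounds[:-1], bounds[1:]):
            H[h, lo:hi] = founders[rng.integers(n_founders), lo:hi]
    pos = np.sort(rng.choice(
        np.arange(1, int(length_cM * 1e6)), size=n_markers, replace=False))
    import pandas as pd
    haps = PhasedHaplotypes(
        samples=[f"S{i:03d}" for i in range(n_hap // 2)],
        variants=pd.DataFrame({"chrom": "1", "pos": pos,
                               "ref": "A", "alt": "C"}),
        haplotypes=H)
    gmap = GeneticMap.uniform({"1": length_cM})
    return haps, gmap


@pytest.fixture
def mosaic_haps():
    return random_haplotypes(20, 400, length_cM=10.0, seed=3)


@pytest.fixture
def structured_world():
    """N=120 fixture with known Psi/Phi ground truth and one null trait."""
    n = 120
    fields, kin = generate_structured_fixture(
        n, StructuredSpec(cluster_sizes={2: 10, 3: 4, 4: 2},
                          related_fraction=0.1), seed=11)
    samples = [f"S{i:05d}" for i in range(n)]
    psi = global_ibd_matrix(kin, samples)
    phi = phi_from_field(fields[0], n)
    y = simulate_phenotypes(psi, None, 1, seed=12)[0]
    return {"n": n, "fields": fields, "kinship": kin, "samples": samples,
            "psi": psi, "phi": phi, "y": y}


@pytest.fixture
def identity_psi():
    def make(n):
        return sp.identity(n, format="csr")
    return make
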