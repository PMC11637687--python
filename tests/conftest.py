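import numpy as np
import pandas as pd
import pytest

from barrierscan.core_io import MISSING, GenotypeMatrix


def make_matrix(dosage, pos=None, chrom="chr1", qual=100.0, samples=None,
                haplotypes=None, depth=None, gq=None):
    """Small GenotypeMatrix from a dosage array (sites x samples)."""
    dosage = np.asarray(dosage, dtype=np.int8)
    S, n = dosage.shape
    if pos is None:
        pos = np.arange(1, S + 1) * 100
    if samples is None:
        samples = [f"s{i}" for i in range(n)]
    sites = pd.DataFrame(
        {
            "chrom": [chrom] * S,
            "pos": np.asarray(pos),
            "ref": ["A"] * S,
            "alt": ["T"] * S,
            "qual": np.full(S, qual, dtype=float),
        }
    )
    return GenotypeMatrix(sites, list(samples), dosage, haplotypes, depth, gq)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def tiny_vcf(tmp_path):
    """Three-site, two-sample VCF exercising phase, missingness and dosage."""
    text = """##fileformat=VCFv4.2
##contig=<ID=chr1>
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Depth">
##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="GQ">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ta\tb
chr1\t100\t.\tA\tT\t60\t.\t.\tGT:DP:GQ\t0/0:30:99\t0/1:25:80
chr1\t200\t.\tC\tG\t55\t.\t.\tGT:DP:GQ\t1/1:20:90\t./.:.:.
chr1\t300\t.\tG\tA\t50\t.\t.\tGT:DP:GQ\t0/1:35:99\t1/1:33:95
"""
    path = tmp_path / "tiny.vcf"
    path.write_text(text)
    return path
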