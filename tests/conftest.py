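import numpy as np
import pytest
from hypothesis import settings

from bsakit.variant_io import BulkSnp

settings.register_profile("ci", derandomize=True, max_examples=200)
settings.load_profile("ci")

VCF_FIXTURE = """\
##fileformat=VCFv4.2
##contig=<ID=Chr01,length=2000000>
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tbulk_a\tbulk_b\tp_high\tp_low
Chr01\t1000\t.\tA\tT\t.\t.\t.\tGT:AD\t./.:12,8\t./.:7,13\t1/1:0,9\t0/0:11,0
Chr01\t2000\t.\tG\tA,C\t.\t.\t.\tGT:AD\t./.:5,5,5\t./.:5,5,5\t./.:.\t./.:.
Chr01\t3000\t.\tAT\tA\t.\t.\t.\tGT:AD\t./.:10,10\t./.:10,10\t./.:.\t./.:.
"""

VCF_MISSING_AD = """\
##fileformat=VCFv4.2
##contig=<ID=Chr01,length=2000000>
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tbulk_a\tbulk_b
Chr01\t1000\t.\tA\tT\t.\t.\t.\tGT:AD\t./.:.\t./.:7,13
Chr01\t2000\t.\tC\tG\t.\t.\t.\tGT:AD\t./.:9,9\t./.:8,8
"""


@pytest.fixture
def fixture_vcf(tmp_path):
    """Three-record VCF: one clean biallelic SNP, one triallelic, one indel."""
    path = tmp_path / "fixture.vcf"
    path.write_text(VCF_FIXTURE)
    return path


@pytest.fixture
def missing_ad_vcf(tmp_path):
    path = tmp_path / "missing_ad.vcf"
    path.write_text(VCF_MISSING_AD)
    return path


def make_null_sites(seed, n_snps=2000, depth=30, p=0.5, spacing=25_000, chrom="Chr01"):
    """Exchangeable null: both bulks binomial(depth, p) at every site."""
    rng = np.random.default_rng(seed)
    a_alt = rng.binomial(depth, p, size=n_snps)
    b_alt = rng.binomial(depth, p, size=n_snps)
    return [
        BulkSnp(chrom, int((i + 1) * spacing), "A", "T",
                int(depth - a_alt[i]), int(a_alt[i]),
                int(depth - b_alt[i]), int(b_alt[i]))
        for i in range(n_snps)
    ]


def make_random_sites(rng, n=100, chrom="Chr01", spacing=10_000, max_depth=60):
    """Random depth-positive sites for property tests."""
    out = []
    for i in range(n):
        depths = rng.integers(1, max_depth, size=4)
        out.append(
            BulkSnp(chrom, int((i + 1) * spacing), "A", "T",
                    int(depths[0]), int(depths[1]), int(depths[2]), int(depths[3]))
        )
    return out
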