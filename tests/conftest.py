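import numpy as np
import pytest
from hypothesis import settings

from panelmap import genomeio

settings.register_profile("deterministic", derandomize=True, max_examples=50)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def small_genome():
    """Deterministic 2 x 20 kb random genome with no planted features."""
    rng = np.random.default_rng(1234)
    bases = np.array(list("ACGT"))
    names = ["chr1", "chr2"]
    seqs = {n: "".join(bases[rng.integers(0, 4, 20_000)]) for n in names}
    return genomeio.GenomeSequence(chrom_names=names, sequences=seqs)


@pytest.fixture()
def write_text(tmp_path):
    def _write(name, text):
        p = tmp_path / name
        p.write_text(text)
        return p

    return _write


SMALL_VCF = """\
##fileformat=VCFv4.2
##contig=<ID=chr1,length=20000>
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1\tS2\tS3
chr1\t101\t.\tA\tG\t.\tPASS\t.\tGT:AD\t0/0:10,0\t0/1:10,5\t1/1:0,9
chr1\t201\t.\tC\tCT\t.\tPASS\t.\tGT:AD\t0/0:7,0\t0/0:8,0\t0/1:4,4
chr1\t301\t.\tG\tT\t.\tPASS\t.\tGT:AD\t./.:.,.\t0/1:6,6\t0/0:12,0
chr1\t401\t.\tT\tA,C\t.\tPASS\t.\tGT:AD\t0/1:5,5,0\t0/2:6,0,6\t0/0:9,0,0
"""


@pytest.fixture()
def small_vcf(write_text):
    return write_text("small.vcf", SMALL_VCF)


SMALL_GFF = """\
##gff-version 3
chr1\tsrc\tgene\t1\t60\t.\t+\t.\tID=gplus
chr1\tsrc\tmRNA\t1\t60\t.\t+\t.\tID=gplus.t1;Parent=gplus
chr1\tsrc\tCDS\t31\t39\t.\t+\t0\tParent=gplus.t1
chr1\tsrc\tCDS\t11\t19\t.\t+\t0\tParent=gplus.t1
chr1\tsrc\tgene\t100\t160\t.\t-\t.\tID=gminus
chr1\tsrc\tmRNA\t100\t160\t.\t-\t.\tID=gminus.t1;Parent=gminus
chr1\tsrc\tCDS\t120\t139\t.\t-\t0\tParent=gminus.t1
"""


@pytest.fixture()
def small_gff(write_text):
    return write_text("small.gff3", SMALL_GFF)
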