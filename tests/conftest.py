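import numpy as np
import pytest

from gbstx import AlleleCountMatrix, GenotypeMatrix, MISSING


@pytest.fixture
def rng():
    return np.random.default_rng(20260926)


@pytest.fixture
def small_genotypes():
    """4 loci x 5 samples with a het, a hom-alt and some missing calls."""
    data = np.array(
        [
            [0, 0, 1, 2, 0],
            [0, 0, 0, 0, 0],
            [1, 1, MISSING, MISSING, 1],
            [2, 2, 2, 1, 0],
        ],
        dtype=np.int16,
    )
    return GenotypeMatrix([f"c{i}:100" for i in range(4)], [f"s{j}" for j in range(5)], data)


def random_genotype_matrix(rng, n_loci=30, n_samples=12, missing_rate=0.2):
    data = rng.integers(0, 3, size=(n_loci, n_samples)).astype(np.int16)
    data[rng.random(data.shape) < missing_rate] = MISSING
    return GenotypeMatrix(
        [f"c{i}:1" for i in range(n_loci)], [f"s{j}" for j in range(n_samples)], data
    )


VCF_HEADER = """\
##fileformat=VCFv4.2
##contig=<ID=ctg1,length=10000>
##contig=<ID=ctg2,length=10000>
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">
##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1\tS2\tS3
"""


@pytest.fixture
def write_vcf(tmp_path):
    """Write a VCF with the standard 3-sample header plus given data lines."""

    def _write(lines, name="test.vcf"):
        path = tmp_path / name
        path.write_text(VCF_HEADER + "".join(line + "\n" for line in lines))
        return str(path)

    return _write
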