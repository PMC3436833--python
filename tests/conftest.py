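import numpy as np
import pytest

from wfkat import GenotypeMatrix, simulate_genotypes

# matrix used in several hand-computed examples
TOY_VALUES = np.array([[0, 1], [1, 2], [0, 0]])


@pytest.fixture
def toy_genotypes() -> GenotypeMatrix:
    return GenotypeMatrix(TOY_VALUES.copy(), coding="minor")


@pytest.fixture(scope="session")
def tg_like_panel() -> GenotypeMatrix:
    """A small TG-like panel: common + rare variants, HWE, fixed seed."""
    return simulate_genotypes(
        300, ((10, (0.32, 0.43)), (60, (0.005, 0.0086))), seed=42)


def write_matrix_fixture(path, values, snp_ids=None, missing=(), sep="\t"):
    """Write a genotype matrix in the plain text dialect; ``missing`` lists
    (row, col) cells to emit as NA."""
    lines = []
    if snp_ids is not None:
        lines.append(sep.join(snp_ids))
    for i, row in enumerate(values):
        cells = ["NA" if (i, j) in missing else str(int(v))
                 for j, v in enumerate(row)]
        lines.append(sep.join(cells))
    path.write_text("\n".join(lines) + "\n")


def write_vcf_fixture(path, values, snp_ids=None):
    """Write a minimal VCF whose ALT-allele counts equal ``values``."""
    n, p = values.shape
    samples = [f"ind{i + 1}" for i in range(n)]
    ids = snp_ids or [f"rs{j + 1}" for j in range(p)]
    gt = {0: "0/0", 1: "0/1", 2: "1/1"}
    lines = [
        "##fileformat=VCFv4.2",
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        "##contig=<ID=1>",
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
        + "\t".join(samples),
    ]
    for j in range(p):
        calls = "\t".join(gt[int(values[i, j])] for i in range(n))
        lines.append(f"1\t{100 + j}\t{ids[j]}\tA\tG\t.\tPASS\t.\tGT\t{calls}")
    path.write_text("\n".join(lines) + "\n")
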