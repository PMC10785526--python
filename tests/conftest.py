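import numpy as np
import pytest

from metaclust.metagene_core import FeatureMatrix


def write_sam(path, chrom_lengths, records):
    """records: iterable of (qname, flag, chrom, pos_1based, cigar)."""
    lines = ["@HD\tVN:1.6\n"]
    for chrom, length in chrom_lengths.items():
        lines.append(f"@SQ\tSN:{chrom}\tLN:{length}\n")
    for qname, flag, chrom, pos, cigar in records:
        lines.append(f"{qname}\t{flag}\t{chrom}\t{pos}\t60\t{cigar}\t*\t0\t0\t*\t*\n")
    path.write_text("".join(lines))
    return path


def make_matrix(rows, ids=None):
    rows = np.asarray(rows, dtype=float)
    if ids is None:
        ids = [f"f{i}" for i in range(rows.shape[0])]
    return FeatureMatrix(ids=list(ids), rows=rows, L=rows.shape[1])


@pytest.fixture
def toy_sam(tmp_path):
    """Three simple reads on two chromosomes."""
    return write_sam(
        tmp_path / "toy.sam",
        {"chrI": 30, "chrII": 20},
        [
            ("r1", 0, "chrI", 5, "4M"),
            ("r2", 0, "chrI", 6, "4M"),
            ("r3", 0, "chrII", 1, "10M"),
        ],
    )


@pytest.fixture
def toy_gff(tmp_path):
    text = (
        "##gff-version 3\n"
        "chrI\tsrc\tCDS\t5\t10\t.\t+\t0\tID=gene1\n"
        "chrI\tsrc\tCDS\t12\t20\t.\t-\t0\tID=gene2\n"
        "chrII\tsrc\tCDS\t2\t9\t.\t+\t0\tID=gene3\n"
        "chrII\tsrc\tgene\t1\t15\t.\t+\t0\tID=gene4\n"
    )
    path = tmp_path / "toy.gff3"
    path.write_text(text)
    return path
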