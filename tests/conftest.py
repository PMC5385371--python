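import numpy as np
import pandas as pd
import pytest

from vbcode.barcode_codec import BarcodeMatrix
from vbcode.synthetic_panel import CrossSimConfig, SyntheticPanel


VCF_HEADER = """\
##fileformat=VCFv4.2
##contig=<ID=chr01,length=1000000>
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{samples}
"""


def make_vcf(path, rows, samples=("S1", "S2")):
    """Write a minimal multi-sample VCF; rows are (chrom,pos,ref,alt,gts)."""
    lines = [VCF_HEADER.format(samples="\t".join(samples))]
    for chrom, pos, ref, alt, gts in rows:
        gt_cols = "\t".join(gts)
        lines.append(f"{chrom}\t{pos}\t.\t{ref}\t{alt}\t.\tPASS\t.\tGT\t{gt_cols}\n")
    path.write_text("".join(lines))
    return path


@pytest.fixture
def tiny_vcf(tmp_path):
    return make_vcf(
        tmp_path / "tiny.vcf",
        [
            ("chr01", 1000, "A" * 13, "A", ("1/1", "0/0")),
            ("chr01", 2000, "G", "T", ("0/1", "1/1")),
            ("chr01", 3000, "C", "CAAAA,CAA", ("1/2", "0/2")),
        ],
    )


@pytest.fixture(scope="session")
def small_panel():
    """A small but structured synthetic panel shared across tests."""
    config = CrossSimConfig(
        n_founders=5,
        n_chromosomes=1,
        chrom_len=600_000,
        n_dvb_per_chrom=4,
        seed=11,
    )
    return SyntheticPanel.simulate_founders(config)


def barcode_matrix_from_codes(codes_by_cultivar, marker_ids=None):
    """Build a BarcodeMatrix directly from code strings (test helper)."""
    first = next(iter(codes_by_cultivar.values()))
    n = len(first)
    markers = marker_ids or [f"chr01_{1000 * (i + 1)}" for i in range(n)]
    data = pd.DataFrame.from_dict(
        {c: list(s) for c, s in codes_by_cultivar.items()},
        orient="index",
        columns=markers,
    )
    pos = {m: (m.rpartition("_")[0], int(m.rpartition("_")[2])) for m in markers}
    return BarcodeMatrix(data, marker_pos=pos)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
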