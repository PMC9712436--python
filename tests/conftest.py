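import numpy as np
import pytest

from digenic.cohort import VariantKey


def write_vcf_text(path, variants, dosage_rows, contig="chrS"):
    """Write a plain VCF 4.2 from per-variant dosage rows.

    ``variants``: list of VariantKey; ``dosage_rows``: matching list of
    arrays with per-sample alt dosage (0/1/2) or -1 for missing.
    """
    gt = {-1: "./.", 0: "0/0", 1: "0/1", 2: "1/1"}
    n = len(dosage_rows[0])
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##contig=<ID={contig},length=1000000>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(f"S{i}" for i in range(n))
            + "\n"
        )
        for key, row in zip(variants, dosage_rows):
            gts = "\t".join(gt[int(d)] for d in row)
            fh.write(
                f"{key.chrom}\t{key.pos}\t.\t{key.ref}\t{key.alt}\t.\tPASS\t.\tGT\t{gts}\n"
            )
    return str(path)


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def toy_variants():
    return (
        VariantKey("chrS", 100, "A", "T"),
        VariantKey("chrS", 200, "G", "C"),
    )
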