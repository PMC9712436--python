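"""Synthetic diploid cohorts with known two-locus truth.

Generates per-sample genotypes for one variant pair from the
penetrance-adjusted two-locus HWE distribution, optionally masks
genotypes at random, and writes a plain VCF 4.2 (GT-only) plus a JSON
truth sidecar recording the generating parameters and realized counts.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from digenic.cohort import VariantKey
from digenic.hwe import GENOTYPE_LABELS, AlleleFreqPair, GenotypeCounts9, hwe_genotype_freqs9
from digenic.power import apply_penetrance


@dataclass(frozen=True)
class SyntheticCohortSpec:
    """Parameters of a synthetic two-variant cohort."""

    n: int
    q1: float
    q2: float
    penetrance: float = 0.0
    missing_rate: float = 0.0
    seed: int = 0
    var1: VariantKey = VariantKey("chrS", 1000, "A", "T")
    var2: VariantKey = VariantKey("chrS", 2000, "G", "C")

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("cohort size must be >= 1")
        for name in ("q1", "q2", "penetrance"):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name}={value} outside [0, 1]")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError(f"missing_rate={self.missing_rate} outside [0, 1)")
        if self.var1 == self.var2:
            raise ValueError("the two variants must be distinct")


@dataclass
class SyntheticCohort:
    """Realized cohort: per-sample dosages at both sites plus truth."""

    spec: SyntheticCohortSpec
    dosage1: np.ndarray  # per-sample alt dosage at variant 1; -1 = missing
    dosage2: np.ndarray
    true_counts: GenotypeCounts9  # pre-missingness realized 9-class counts

    @property
    def n(self) -> int:
        return self.spec.n

    def realized_counts(self) -> GenotypeCounts9:
        """Counts over samples genotyped at both sites (post-missingness)."""
        keep = (self.dosage1 >= 0) & (self.dosage2 >= 0)
        idx = 3 * self.dosage1[keep].astype(np.int64) + self.dosage2[keep]
        return GenotypeCounts9(np.bincount(idx, minlength=9))

    def truth_record(self) -> dict:
        realized = self.realized_counts()
        return {
            "N": self.spec.n,
            "q1": self.spec.q1,
            "q2": self.spec.q2,
            "penetrance": self.spec.penetrance,
            "missing_rate": self.spec.missing_rate,
            "seed": self.spec.seed,
            "var1": str(self.spec.var1),
            "var2": str(self.spec.var2),
            "true_counts": dict(zip(GENOTYPE_LABELS, map(int, self.true_counts.counts))),
            "realized_counts": dict(zip(GENOTYPE_LABELS, map(int, realized.counts))),
            "realized_cocarriers": int(realized.counts[[4, 5, 7, 8]].sum()),
            "n_missing_either": int(((self.dosage1 < 0) | (self.dosage2 < 0)).sum()),
        }


def generate_cohort(spec: SyntheticCohortSpec) -> SyntheticCohort:
    """Draw a cohort from the penetrance-adjusted two-locus distribution.

    Each sample's genotype class is drawn independently; missingness is
    then applied independently per genotype call.  Deterministic given
    ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    population = apply_penetrance(
        hwe_genotype_freqs9(AlleleFreqPair(spec.q1, spec.q2)), spec.penetrance
    )
    classes = rng.choice(9, size=spec.n, p=population.probs)
    true_counts = GenotypeCounts9(np.bincount(classes, minlength=9))
    dosage1 = (classes // 3).astype(np.int8)
    dosage2 = (classes % 3).astype(np.int8)
    if spec.missing_rate > 0:
        dosage1[rng.random(spec.n) < spec.missing_rate] = -1
        dosage2[rng.random(spec.n) < spec.missing_rate] = -1
    return SyntheticCohort(spec, dosage1, dosage2, true_counts)


_GT_STRINGS = {-1: "./.", 0: "0/0", 1: "0/1", 2: "1/1"}


def _vcf_record(key: VariantKey, dosages: np.ndarray) -> str:
    gts = "\t".join(_GT_STRINGS[int(d)] for d in dosages)
    return f"{key.chrom}\t{key.pos}\t.\t{key.ref}\t{key.alt}\t.\tPASS\t.\tGT\t{gts}\n"


def write_vcf(cohort: SyntheticCohort, path) -> None:
    """Write the cohort as VCF 4.2 with a JSON truth sidecar.

    Samples are named S000001..  Missing genotypes appear as ``./.``.  The
    sidecar is written next to the VCF with suffix ``.truth.json``.
    """
    path = Path(path)
    spec = cohort.spec
    contigs = {spec.var1.chrom, spec.var2.chrom}
    samples = "\t".join(f"S{i + 1:06d}" for i in range(spec.n))
    records = sorted(
        [(spec.var1, cohort.dosage1), (spec.var2, cohort.dosage2)],
        key=lambda item: (item[0].chrom, item[0].pos),
    )
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=digenic-synth\n")
        for contig in sorted(contigs):
            fh.write(f"##contig=<ID={contig},length=1000000>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + samples + "\n"
        )
        for key, dosages in records:
            fh.write(_vcf_record(key, dosages))
    sidecar = path.with_suffix(path.suffix + ".truth.json")
    with open(sidecar, "w") as fh:
        json.dump(cohort.truth_record(), fh, indent=2)
        fh.write("\n")
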