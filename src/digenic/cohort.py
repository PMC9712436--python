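"""Carrier counting and pair screening from multi-sample VCFs.

Carrier status is defined per requested alternate allele: an individual
is a carrier when their genotype contains at least one copy of that
allele, regardless of phase.  Genotypes containing other alternate
alleles of a multi-allelic record, but not the requested one, count as
non-carriers for the pair.  Individuals missing a genotype at either
site of a pair are excluded from that pair's N (pairwise exclusion).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from cyvcf2 import VCF

from digenic.hwe import GenotypeCounts9
from digenic.gof import (
    DigenicTestResult,
    TestConfig,
    adjust_pvalues,
    digenic_test,
)

logger = logging.getLogger(__name__)

MISSING = -1  # dosage sentinel for a missing genotype


@dataclass(frozen=True)
class VariantKey:
    """A biallelic variant identified by site and requested alternate allele."""

    chrom: str
    pos: int
    ref: str
    alt: str

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"position must be >= 1, got {self.pos}")
        if not self.ref or not self.alt:
            raise ValueError("ref and alt alleles must be non-empty")
        if self.ref == self.alt:
            raise ValueError(f"ref and alt are identical ({self.ref})")

    @classmethod
    def parse(cls, text: str) -> "VariantKey":
        """Parse a ``chrom:pos:ref:alt`` string."""
        parts = text.strip().split(":")
        if len(parts) != 4:
            raise ValueError(f"cannot parse variant {text!r}; want chrom:pos:ref:alt")
        return cls(parts[0], int(parts[1]), parts[2], parts[3])

    def __str__(self) -> str:
        return f"{self.chrom}:{self.pos}:{self.ref}:{self.alt}"


@dataclass
class PairObservation:
    """Nine-class genotype counts for one variant pair over a cohort."""

    var1: VariantKey
    var2: VariantKey
    counts: GenotypeCounts9
    n_missing: int
    zygosity_breakdown: dict[str, int] = field(default_factory=dict)

    @property
    def pair_id(self) -> str:
        return f"{self.var1}|{self.var2}"

    def zygosity_summary(self) -> str:
        """Compact Het/Hom co-carrier summary, e.g. ``Het/Het(3);Hom/Het``."""
        parts = []
        for key in ("Het/Het", "Het/Hom", "Hom/Het", "Hom/Hom"):
            count = self.zygosity_breakdown.get(key, 0)
            if count == 1:
                parts.append(key)
            elif count > 1:
                parts.append(f"{key}({count})")
        return ";".join(parts) if parts else "none"


def _dosages_from_record(variant, alt_index: int) -> np.ndarray:
    """Per-sample count of the requested alt allele (0/1/2, MISSING if no call)."""
    genotypes = variant.genotype.array()  # (n_samples, ploidy+1); last col = phase
    alleles = genotypes[:, :-1]
    dosages = (alleles == alt_index).sum(axis=1).astype(np.int8)
    dosages[(alleles < 0).any(axis=1)] = MISSING
    return dosages


def extract_genotypes(vcf_path: str, variant: VariantKey) -> np.ndarray:
    """Per-sample alt-allele dosage for one variant.

    Returns an array over the VCF's samples with values 0 (non-carrier),
    1 (heterozygous), 2 (homozygous alternate) or -1 (missing).  The
    record is matched on chromosome, position, ref and the requested alt
    allele; for multi-allelic records only the requested alt counts.
    """
    vcf = VCF(vcf_path)
    try:
        nearest: list[str] = []
        for record in vcf:
            if record.CHROM == variant.chrom and record.POS == variant.pos:
                if record.REF == variant.ref and variant.alt in record.ALT:
                    alt_index = record.ALT.index(variant.alt) + 1
                    return _dosages_from_record(record, alt_index)
                nearest.append(f"{record.CHROM}:{record.POS}:{record.REF}:{','.join(record.ALT)}")
            elif record.CHROM == variant.chrom and abs(record.POS - variant.pos) <= 1000:
                nearest.append(f"{record.CHROM}:{record.POS}:{record.REF}:{','.join(record.ALT)}")
    finally:
        vcf.close()
    hint = f"; nearby records: {', '.join(nearest[:5])}" if nearest else ""
    raise LookupError(f"variant {variant} not found in {vcf_path}{hint}")


_ZYGOSITY = {1: "Het", 2: "Hom"}


def count_pair(vcf_path: str, var1: VariantKey, var2: VariantKey) -> PairObservation:
    """Count the nine two-locus genotype classes for a pair of variants.

    Only samples genotyped at both sites contribute; the zygosity
    breakdown tallies Het/Hom combinations among the co-carriers.
    """
    if var1 == var2:
        raise ValueError(f"a pair must be two distinct variants, got {var1} twice")
    d1 = extract_genotypes(vcf_path, var1)
    d2 = extract_genotypes(vcf_path, var2)
    missing = (d1 == MISSING) | (d2 == MISSING)
    kept1 = d1[~missing].astype(np.int64)
    kept2 = d2[~missing].astype(np.int64)
    counts = np.bincount(3 * kept1 + kept2, minlength=9)
    zygosity: dict[str, int] = {}
    cocarrier = (kept1 > 0) & (kept2 > 0)
    for a, b in zip(kept1[cocarrier], kept2[cocarrier]):
        key = f"{_ZYGOSITY[a]}/{_ZYGOSITY[b]}"
        zygosity[key] = zygosity.get(key, 0) + 1
    return PairObservation(
        var1=var1,
        var2=var2,
        counts=GenotypeCounts9(counts),
        n_missing=int(missing.sum()),
        zygosity_breakdown=zygosity,
    )


def read_pair_list(path: str) -> list[tuple[VariantKey, VariantKey, str]]:
    """Read a pair list TSV: chrom1 pos1 ref1 alt1 chrom2 pos2 ref2 alt2 [label].

    Lines starting with '#' are headers/comments.
    """
    pairs = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 8:
                raise ValueError(
                    f"{path}:{lineno}: expected >= 8 tab-separated columns, "
                    f"got {len(fields)}"
                )
            try:
                var1 = VariantKey(fields[0], int(fields[1]), fields[2], fields[3])
                var2 = VariantKey(fields[4], int(fields[5]), fields[6], fields[7])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from exc
            label = fields[8] if len(fields) > 8 else f"{var1}|{var2}"
            pairs.append((var1, var2, label))
    return pairs


def screen_pairs(
    vcf_path: str,
    pairs: list[tuple[VariantKey, VariantKey, str]],
    config: TestConfig = TestConfig(),
) -> list[DigenicTestResult]:
    """Count and test every pair; adjust p-values; sort by p.

    Failures on individual pairs are logged and reported as untestable
    results rather than aborting the batch.
    """
    if not pairs:
        raise ValueError("pair list is empty")
    results: list[DigenicTestResult] = []
    for var1, var2, label in pairs:
        try:
            observation = count_pair(vcf_path, var1, var2)
            result = digenic_test(observation.counts, config, pair_id=label)
            result.zygosity = observation.zygosity_summary()
        except (LookupError, ValueError) as exc:
            logger.warning("pair %s failed: %s", label, exc)
            result = DigenicTestResult(
                pair_id=label,
                q1_hat=float("nan"),
                q2_hat=float("nan"),
                n=0,
                observed_cocarriers=0,
                expected_cocarriers=0,
                testable=False,
                reason=str(exc),
            )
        results.append(result)
    results = adjust_pvalues(results, config.multiple_testing)
    results.sort(key=lambda r: (not r.testable, r.p_value if r.p_value is not None else 2.0))
    n_testable = sum(r.testable for r in results)
    logger.info("screened %d pairs, %d testable", len(results), n_testable)
    return results
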