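"""Two-locus Hardy-Weinberg genotype model.

Genotypes are labelled with the A/a (variant 1) and B/b (variant 2)
convention, lowercase being the alternate allele.  The nine two-locus
genotype classes are ordered so that ``index = 3 * dosage1 + dosage2``,
where dosage is the number of alternate alleles carried at the locus
(0, 1 or 2):

    AABB AABb AAbb AaBB AaBb Aabb aaBB aaBb aabb

Linkage equilibrium between the two loci is assumed throughout: two-locus
class frequencies are products of per-locus HWE proportions.  Pairs of
variants in strong LD (e.g. nearby sites on one chromosome) violate this
assumption and should not be tested with this model.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

#: Two-locus genotype class labels, in canonical order.
GENOTYPE_LABELS: tuple[str, ...] = (
    "AABB", "AABb", "AAbb",
    "AaBB", "AaBb", "Aabb",
    "aaBB", "aaBb", "aabb",
)

#: Indices of classes carrying >=1 alternate allele at both loci (co-carriers).
COCARRIER_IDX = np.array([4, 5, 7, 8])
#: Carrier at variant 1 only (AaBB, aaBB).
CARRIER1_ONLY_IDX = np.array([3, 6])
#: Carrier at variant 2 only (AABb, AAbb).
CARRIER2_ONLY_IDX = np.array([1, 2])
#: Reference homozygote at both loci (AABB).
NONCARRIER_IDX = np.array([0])


def _check_freq(q: float, name: str = "q") -> float:
    q = float(q)
    if not 0.0 <= q <= 1.0:
        raise ValueError(f"allele frequency {name}={q} outside [0, 1]")
    return q


@dataclass(frozen=True)
class AlleleFreqPair:
    """Alternate-allele frequencies of the two variants of a pair.

    Reference-allele frequencies are implied: ``p1 = 1 - q1``,
    ``p2 = 1 - q2``.
    """

    q1: float
    q2: float

    def __post_init__(self) -> None:
        _check_freq(self.q1, "q1")
        _check_freq(self.q2, "q2")


@dataclass(frozen=True)
class GenotypeFreqs9:
    """Probability mass over the nine two-locus genotype classes."""

    probs: np.ndarray

    def __post_init__(self) -> None:
        probs = np.asarray(self.probs, dtype=float)
        if probs.shape != (9,):
            raise ValueError(f"expected 9 genotype frequencies, got shape {probs.shape}")
        if np.any(probs < 0):
            raise ValueError("genotype frequencies must be non-negative")
        if abs(probs.sum() - 1.0) > 1e-12:
            raise ValueError(f"genotype frequencies sum to {probs.sum()!r}, not 1")
        object.__setattr__(self, "probs", probs)

    def __getitem__(self, label: str) -> float:
        return float(self.probs[GENOTYPE_LABELS.index(label)])


@dataclass(frozen=True)
class GenotypeCounts9:
    """Individual counts over the nine two-locus genotype classes."""

    counts: np.ndarray

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts)
        if counts.shape != (9,):
            raise ValueError(f"expected 9 genotype counts, got shape {counts.shape}")
        if np.any(counts < 0) or not np.all(counts == np.floor(counts)):
            raise ValueError("genotype counts must be non-negative integers")
        object.__setattr__(self, "counts", counts.astype(np.int64))

    @property
    def n(self) -> int:
        """Cohort size (number of genotyped individuals)."""
        return int(self.counts.sum())

    def __getitem__(self, label: str) -> int:
        return int(self.counts[GENOTYPE_LABELS.index(label)])


@dataclass(frozen=True)
class CollapsedCounts4:
    """Counts over the four collapsed genotype categories.

    Categories: co-carriers (Aa/aa + Bb/bb), single carriers of variant 1
    (Aa/aa + BB), single carriers of variant 2 (AA + Bb/bb), and
    non-carriers (AA + BB).  Entries may be expected counts, hence reals.
    """

    cocarriers: float
    carriers1_only: float
    carriers2_only: float
    noncarriers: float

    def __post_init__(self) -> None:
        for name in ("cocarriers", "carriers1_only", "carriers2_only", "noncarriers"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @property
    def total(self) -> float:
        return self.cocarriers + self.carriers1_only + self.carriers2_only + self.noncarriers

    def as_array(self) -> np.ndarray:
        return np.array(
            [self.cocarriers, self.carriers1_only, self.carriers2_only, self.noncarriers]
        )


def carrier_frequency(q: float) -> float:
    """Probability that an individual carries >=1 alternate allele.

    Under HWE with alternate-allele frequency ``q`` this is
    ``2(1-q)q + q^2 = 1 - (1-q)^2``.
    """
    q = _check_freq(q)
    return 2.0 * (1.0 - q) * q + q * q


def _single_locus_hwe(q: float) -> np.ndarray:
    """HWE proportions (hom-ref, het, hom-alt) for one biallelic locus."""
    p = 1.0 - q
    return np.array([p * p, 2.0 * p * q, q * q])


def hwe_genotype_freqs9(freqs: AlleleFreqPair) -> GenotypeFreqs9:
    """Two-locus genotype class frequencies under HWE and linkage equilibrium.

    ``freq(g1, g2) = HWE(g1; q1) * HWE(g2; q2)`` laid out in canonical order.
    """
    outer = np.outer(_single_locus_hwe(freqs.q1), _single_locus_hwe(freqs.q2))
    probs = outer.ravel()
    # guard against accumulated rounding before the sum-to-1 invariant check
    probs = probs / probs.sum()
    return GenotypeFreqs9(probs)


def expected_collapsed_counts(freqs: AlleleFreqPair, n: float) -> CollapsedCounts4:
    """Expected individuals per collapsed category for a cohort of size ``n``.

    Products of the two independent carrier probabilities times ``n``; the
    four entries sum to ``n`` analytically.
    """
    if n <= 0:
        raise ValueError(f"cohort size must be positive, got {n}")
    c1 = carrier_frequency(freqs.q1)
    c2 = carrier_frequency(freqs.q2)
    return CollapsedCounts4(
        cocarriers=c1 * c2 * n,
        carriers1_only=c1 * (1.0 - c2) * n,
        carriers2_only=(1.0 - c1) * c2 * n,
        noncarriers=(1.0 - c1) * (1.0 - c2) * n,
    )


def collapse(counts: GenotypeCounts9) -> CollapsedCounts4:
    """Collapse nine-class counts into the four test categories."""
    c = counts.counts
    return CollapsedCounts4(
        cocarriers=float(c[COCARRIER_IDX].sum()),
        carriers1_only=float(c[CARRIER1_ONLY_IDX].sum()),
        carriers2_only=float(c[CARRIER2_ONLY_IDX].sum()),
        noncarriers=float(c[NONCARRIER_IDX].sum()),
    )


def collapse_freqs(freqs: GenotypeFreqs9) -> np.ndarray:
    """Collapse nine-class probabilities into the four category masses."""
    p = freqs.probs
    return np.array(
        [
            p[COCARRIER_IDX].sum(),
            p[CARRIER1_ONLY_IDX].sum(),
            p[CARRIER2_ONLY_IDX].sum(),
            p[NONCARRIER_IDX].sum(),
        ]
    )
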