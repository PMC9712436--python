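"""Chi-squared goodness-of-fit test for co-carrier depletion.

Observed genotype category counts are compared with the counts expected
under the two-locus HWE model at allele frequencies estimated from the
same cohort.  The collapsed test compares the four categories
(co-carriers, single carriers of each variant, non-carriers) with 1
degree of freedom; the full test compares all nine two-locus genotype
classes with 6 degrees of freedom.  The degrees of freedom equal
cells - 1 - 2 estimated allele frequencies in each mode.

A pair is only testable when the expected number of co-carriers reaches
a minimum (default 5 individuals); below that the chi-squared
approximation is unreliable and the result is flagged instead of tested.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from digenic.hwe import (
    GENOTYPE_LABELS,
    AlleleFreqPair,
    CollapsedCounts4,
    GenotypeCounts9,
    collapse,
    expected_collapsed_counts,
    hwe_genotype_freqs9,
)

COLLAPSED_LABELS = ("cocarriers", "carriers1_only", "carriers2_only", "noncarriers")

_ADJUST_METHODS = ("none", "benjamini-hochberg", "bonferroni")


@dataclass(frozen=True)
class TestConfig:
    """Configuration of the depletion test.

    mode
        ``"collapsed"`` for the 4-category / 1 df test, ``"full"`` for the
        9-class / 6 df test.
    min_expected_cocarriers
        Minimum expected co-carrier count for a pair to be testable.
    require_all_expected
        Stricter option: require every expected category (not only the
        co-carriers) to reach the minimum.  Off by default.
    multiple_testing
        Adjustment applied across a batch of pairs.
    """

    mode: str = "collapsed"
    min_expected_cocarriers: float = 5.0
    alpha: float = 0.05
    multiple_testing: str = "none"
    require_all_expected: bool = False

    def __post_init__(self) -> None:
        if self.mode not in ("collapsed", "full"):
            raise ValueError(f"mode must be 'collapsed' or 'full', got {self.mode!r}")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError(f"alpha must be in (0, 1), got {self.alpha}")
        if self.min_expected_cocarriers < 0:
            raise ValueError("min_expected_cocarriers must be >= 0")
        if self.multiple_testing not in _ADJUST_METHODS:
            raise ValueError(
                f"unknown multiple_testing method {self.multiple_testing!r}; "
                f"choose from {_ADJUST_METHODS}"
            )


@dataclass
class DigenicTestResult:
    """Outcome of the depletion test for one variant pair."""

    pair_id: str
    q1_hat: float
    q2_hat: float
    n: int
    observed_cocarriers: float
    expected_cocarriers: float
    chi2_statistic: float | None = None
    df: int | None = None
    p_value: float | None = None
    testable: bool = True
    reason: str | None = None
    adjusted_p: float | None = None
    imputed: bool = False
    zygosity: str | None = None

    @property
    def difference(self) -> float:
        """Observed minus expected co-carriers; negative means depletion."""
        return self.observed_cocarriers - self.expected_cocarriers

    @property
    def depleted(self) -> bool:
        return self.difference < 0

    def significant(self, alpha: float = 0.05, adjusted: bool = False) -> bool:
        p = self.adjusted_p if adjusted else self.p_value
        return self.testable and p is not None and p < alpha


def chi2_gof(
    observed: Sequence[float],
    expected: Sequence[float],
    df: int,
    labels: Sequence[str] | None = None,
) -> tuple[float, float]:
    """Pearson chi-squared goodness-of-fit statistic and upper-tail p-value.

    No continuity correction is applied.  ``df`` is supplied by the caller
    (1 for the collapsed table, 6 for the nine-class table).
    """
    obs = np.asarray(observed, dtype=float)
    exp = np.asarray(expected, dtype=float)
    if obs.shape != exp.shape:
        raise ValueError(
            f"observed has {obs.size} categories but expected has {exp.size}"
        )
    zero = np.flatnonzero(exp <= 0)
    if zero.size:
        names = (
            ", ".join(str(labels[i]) for i in zero)
            if labels is not None
            else ", ".join(f"category {i}" for i in zero)
        )
        raise ValueError(f"expected count is zero for: {names}")
    if not math.isclose(obs.sum(), exp.sum(), rel_tol=1e-6, abs_tol=1e-6):
        raise ValueError(
            f"observed total {obs.sum()} does not match expected total {exp.sum()}"
        )
    statistic = float(((obs - exp) ** 2 / exp).sum())
    p_value = float(stats.chi2.sf(statistic, df))
    return statistic, p_value


def estimate_freqs_from_counts(observed9: GenotypeCounts9) -> AlleleFreqPair:
    """Allele frequencies by allele counting over the nine-class table.

    Each heterozygote contributes one alternate allele and each alternate
    homozygote two, out of 2N alleles per locus.
    """
    n = observed9.n
    if n == 0:
        raise ValueError("cannot estimate allele frequencies from an empty cohort")
    c = observed9.counts.reshape(3, 3)
    dosage = np.array([0.0, 1.0, 2.0])
    q1 = float(dosage @ c.sum(axis=1)) / (2.0 * n)
    q2 = float(dosage @ c.sum(axis=0)) / (2.0 * n)
    return AlleleFreqPair(q1, q2)


def digenic_test(
    observed9: GenotypeCounts9,
    config: TestConfig = TestConfig(),
    pair_id: str = "",
) -> DigenicTestResult:
    """Depletion test from a full nine-class observed table.

    Allele frequencies are estimated from the observed table itself, the
    expected table is rebuilt under HWE at those frequencies for the same
    N, and observed vs expected are compared with a Pearson chi-squared
    test (collapsed: 4 categories, 1 df; full: 9 classes, 6 df).
    """
    n = observed9.n
    if n == 0:
        raise ValueError("cohort is empty (N = 0)")
    freqs = estimate_freqs_from_counts(observed9)
    expected4 = expected_collapsed_counts(freqs, n)
    observed4 = collapse(observed9)
    result = DigenicTestResult(
        pair_id=pair_id,
        q1_hat=freqs.q1,
        q2_hat=freqs.q2,
        n=n,
        observed_cocarriers=observed4.cocarriers,
        expected_cocarriers=expected4.cocarriers,
    )
    if freqs.q1 in (0.0, 1.0) or freqs.q2 in (0.0, 1.0):
        result.testable = False
        result.reason = "monomorphic variant"
        return result
    if expected4.cocarriers < config.min_expected_cocarriers:
        result.testable = False
        result.reason = (
            f"expected co-carriers {expected4.cocarriers:.4g} below minimum "
            f"{config.min_expected_cocarriers:g}"
        )
        return result
    if config.mode == "collapsed":
        exp = expected4.as_array()
        obs = observed4.as_array()
        labels: Sequence[str] = COLLAPSED_LABELS
        df = 1
    else:
        exp = hwe_genotype_freqs9(freqs).probs * n
        obs = observed9.counts.astype(float)
        labels = GENOTYPE_LABELS
        df = 6
    if config.require_all_expected and np.any(exp < config.min_expected_cocarriers):
        result.testable = False
        result.reason = "an expected category is below the minimum count"
        return result
    result.chi2_statistic, result.p_value = chi2_gof(obs, exp, df, labels=labels)
    result.df = df
    return result


def test_from_summary(
    q1: float,
    q2: float,
    n: float,
    observed_cocarriers: float,
    config: TestConfig = TestConfig(),
    pair_id: str = "",
) -> DigenicTestResult:
    """Depletion test from summary data only (frequencies + co-carrier count).

    Entry point for report-style inputs where only the allele frequencies,
    the cohort size and the observed co-carrier count are known.  The three
    non-co-carrier observed cells are imputed: the table starts at its HWE
    expectation and the co-carrier deficit (or excess) is redistributed to
    the two single-carrier cells proportionally to their expected sizes.
    This is an approximation — a depleted co-carrier is still a single
    carrier at each locus — and results carry ``imputed=True``.
    """
    if not (0.0 < q1 < 1.0 and 0.0 < q2 < 1.0):
        raise ValueError("q1 and q2 must be strictly between 0 and 1")
    if n <= 0:
        raise ValueError(f"cohort size must be positive, got {n}")
    if not 0.0 <= observed_cocarriers <= n:
        raise ValueError(
            f"observed co-carriers {observed_cocarriers} outside [0, N={n}]"
        )
    expected4 = expected_collapsed_counts(AlleleFreqPair(q1, q2), n)
    deficit = expected4.cocarriers - observed_cocarriers
    single_total = expected4.carriers1_only + expected4.carriers2_only
    observed4 = CollapsedCounts4(
        cocarriers=observed_cocarriers,
        carriers1_only=expected4.carriers1_only
        + deficit * expected4.carriers1_only / single_total,
        carriers2_only=expected4.carriers2_only
        + deficit * expected4.carriers2_only / single_total,
        noncarriers=expected4.noncarriers,
    )
    result = DigenicTestResult(
        pair_id=pair_id,
        q1_hat=q1,
        q2_hat=q2,
        n=int(n),
        observed_cocarriers=observed_cocarriers,
        expected_cocarriers=expected4.cocarriers,
        imputed=True,
    )
    if expected4.cocarriers < config.min_expected_cocarriers:
        result.testable = False
        result.reason = (
            f"expected co-carriers {expected4.cocarriers:.4g} below minimum "
            f"{config.min_expected_cocarriers:g}"
        )
        return result
    result.chi2_statistic, result.p_value = chi2_gof(
        observed4.as_array(), expected4.as_array(), df=1, labels=COLLAPSED_LABELS
    )
    result.df = 1
    return result


def adjust_pvalues(
    results: Iterable[DigenicTestResult], method: str = "benjamini-hochberg"
) -> list[DigenicTestResult]:
    """Fill ``adjusted_p`` across a batch of results.

    Only testable results enter the adjustment; untestable ones keep
    ``adjusted_p=None``.  Input results are not mutated.
    """
    if method not in _ADJUST_METHODS:
        raise ValueError(f"unknown method {method!r}; choose from {_ADJUST_METHODS}")
    results = [replace(r) for r in results]
    testable = [r for r in results if r.testable and r.p_value is not None]
    if not testable:
        return results
    pvals = np.array([r.p_value for r in testable])
    m = pvals.size
    if method == "none":
        adjusted = pvals
    elif method == "bonferroni":
        adjusted = np.minimum(pvals * m, 1.0)
    else:  # benjamini-hochberg step-up
        order = np.argsort(pvals)
        ranked = pvals[order] * m / np.arange(1, m + 1)
        ranked = np.minimum.accumulate(ranked[::-1])[::-1]
        adjusted = np.empty(m)
        adjusted[order] = np.minimum(ranked, 1.0)
    for r, adj in zip(testable, adjusted):
        r.adjusted_p = float(adj)
    return results


# ---------------------------------------------------------------------------
# result writers

_TSV_COLUMNS = (
    "pair",
    "freq1",
    "freq2",
    "N",
    "zygosity",
    "obs",
    "exp",
    "diff",
    "p_value",
    "adjusted_p",
    "significant",
    "testable",
    "note",
)


def _fmt(value: float | None, digits: int = 4) -> str:
    if value is None:
        return "NA"
    return f"{value:.{digits}f}"


def results_to_rows(
    results: Sequence[DigenicTestResult], alpha: float = 0.05
) -> list[dict[str, str]]:
    rows = []
    for r in results:
        rows.append(
            {
                "pair": r.pair_id or "NA",
                "freq1": _fmt(r.q1_hat, 6),
                "freq2": _fmt(r.q2_hat, 6),
                "N": str(r.n),
                "zygosity": r.zygosity or "NA",
                "obs": _fmt(r.observed_cocarriers),
                "exp": _fmt(r.expected_cocarriers),
                "diff": _fmt(r.difference),
                "p_value": _fmt(r.p_value),
                "adjusted_p": _fmt(r.adjusted_p),
                "significant": "*" if r.significant(alpha) else "",
                "testable": "yes" if r.testable else "no",
                "note": r.reason or ("imputed" if r.imputed else ""),
            }
        )
    return rows


def write_results_tsv(
    results: Sequence[DigenicTestResult], path, alpha: float = 0.05
) -> None:
    """Write a report table: one row per pair, significance starred at alpha."""
    rows = results_to_rows(results, alpha=alpha)
    with open(path, "w") as fh:
        fh.write("\t".join(_TSV_COLUMNS) + "\n")
        for row in rows:
            fh.write("\t".join(row[c] for c in _TSV_COLUMNS) + "\n")


def write_results_json(
    results: Sequence[DigenicTestResult], path, alpha: float = 0.05
) -> None:
    payload = []
    for r in results:
        payload.append(
            {
                "pair": r.pair_id,
                "q1_hat": r.q1_hat,
                "q2_hat": r.q2_hat,
                "N": r.n,
                "observed_cocarriers": r.observed_cocarriers,
                "expected_cocarriers": r.expected_cocarriers,
                "difference": r.difference,
                "chi2_statistic": r.chi2_statistic,
                "df": r.df,
                "p_value": r.p_value,
                "adjusted_p": r.adjusted_p,
                "significant": r.significant(alpha),
                "testable": r.testable,
                "reason": r.reason,
                "imputed": r.imputed,
                "zygosity": r.zygosity,
            }
        )
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)
        fh.write("\n")
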