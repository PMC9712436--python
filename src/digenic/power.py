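"""Monte-Carlo power analysis for the co-carrier depletion test.

One replicate: build the two-locus HWE genotype distribution, deplete the
four co-carrier classes by the penetrance (the fraction of co-carriers
assumed to develop disease and therefore be absent from a healthy
cohort), renormalize, draw one multinomial cohort of size N, re-estimate
the allele frequencies from the draw, rebuild HWE expected counts at the
estimated frequencies, and run the chi-squared test.  Power is the
fraction of replicates significant at alpha.

The pre-sampling population is treated as infinite (exact adjusted class
frequencies); the only sampling noise is the single multinomial draw.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd

from digenic.hwe import (
    COCARRIER_IDX,
    GENOTYPE_LABELS,
    AlleleFreqPair,
    GenotypeCounts9,
    GenotypeFreqs9,
    collapse,
    expected_collapsed_counts,
    hwe_genotype_freqs9,
)
from digenic.gof import COLLAPSED_LABELS, chi2_gof, estimate_freqs_from_counts


@dataclass(frozen=True)
class PowerScenario:
    """One simulation setting.

    ``min_expected_cocarriers`` defaults to 0 here (no testability filter)
    so that raw power curves are reproduced; replicates whose expected
    co-carrier count falls below a positive threshold are counted as
    non-significant and tallied separately.
    """

    q1: float
    q2: float
    penetrance: float
    n: int
    iterations: int = 1000
    alpha: float = 0.05
    mode: str = "collapsed"
    seed: int = 0
    min_expected_cocarriers: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.penetrance <= 1.0:
            raise ValueError(f"penetrance must be in [0, 1], got {self.penetrance}")
        if self.iterations < 1:
            raise ValueError("iterations must be >= 1")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError(f"alpha must be in (0, 1), got {self.alpha}")
        if self.n < 1:
            raise ValueError("sample size must be >= 1")
        if self.mode not in ("collapsed", "full"):
            raise ValueError(f"mode must be 'collapsed' or 'full', got {self.mode!r}")


@dataclass(frozen=True)
class PowerEstimate:
    """Estimated power with its Monte-Carlo uncertainty."""

    scenario: PowerScenario
    power: float
    mc_stderr: float
    replicates_untestable: int

    def as_dict(self) -> dict:
        s = self.scenario
        return {
            "q1": s.q1,
            "q2": s.q2,
            "penetrance": s.penetrance,
            "N": s.n,
            "mode": s.mode,
            "iterations": s.iterations,
            "alpha": s.alpha,
            "seed": s.seed,
            "power": self.power,
            "mc_stderr": self.mc_stderr,
            "untestable": self.replicates_untestable,
        }


def apply_penetrance(freqs: GenotypeFreqs9, penetrance: float) -> GenotypeFreqs9:
    """Deplete co-carrier classes by the penetrance and renormalize.

    The four co-carrier classes (AaBb, Aabb, aaBb, aabb) are multiplied by
    ``1 - penetrance``; the five single-carrier and non-carrier classes are
    left untouched; all nine are then divided by their sum so the
    distribution totals 1 again.
    """
    if not 0.0 <= penetrance <= 1.0:
        raise ValueError(f"penetrance must be in [0, 1], got {penetrance}")
    probs = freqs.probs.copy()
    probs[COCARRIER_IDX] *= 1.0 - penetrance
    return GenotypeFreqs9(probs / probs.sum())


def sample_cohort(
    freqs: GenotypeFreqs9, n: int, rng: np.random.Generator
) -> GenotypeCounts9:
    """One multinomial draw of ``n`` individuals over the nine classes."""
    if n < 1:
        raise ValueError("sample size must be >= 1")
    return GenotypeCounts9(rng.multinomial(n, freqs.probs))


def estimate_allele_freqs(counts: GenotypeCounts9) -> AlleleFreqPair:
    """Allele-counting frequency estimate from a sampled cohort."""
    return estimate_freqs_from_counts(counts)


def run_replicate(
    scenario: PowerScenario, rng: np.random.Generator
) -> tuple[float | None, bool]:
    """One simulation replicate; returns ``(p_value, testable)``.

    ``p_value`` is None when the replicate is untestable (monomorphic draw
    or expected co-carriers under the scenario's minimum).
    """
    population = apply_penetrance(
        hwe_genotype_freqs9(AlleleFreqPair(scenario.q1, scenario.q2)),
        scenario.penetrance,
    )
    cohort = sample_cohort(population, scenario.n, rng)
    freqs_hat = estimate_allele_freqs(cohort)
    if freqs_hat.q1 in (0.0, 1.0) or freqs_hat.q2 in (0.0, 1.0):
        return None, False
    expected4 = expected_collapsed_counts(freqs_hat, scenario.n)
    if expected4.cocarriers < scenario.min_expected_cocarriers:
        return None, False
    if scenario.mode == "collapsed":
        observed = collapse(cohort).as_array()
        expected = expected4.as_array()
        df = 1
        labels = COLLAPSED_LABELS
    else:
        observed = cohort.counts.astype(float)
        expected = hwe_genotype_freqs9(freqs_hat).probs * scenario.n
        df = 6
        labels = GENOTYPE_LABELS
    _, p_value = chi2_gof(observed, expected, df, labels=labels)
    return p_value, True


def estimate_power(scenario: PowerScenario) -> PowerEstimate:
    """Run the scenario's replicates and report the rejection rate.

    Untestable replicates count as non-significant (dropping them would
    bias power upward at rare frequencies) and are tallied separately.
    Per-replicate RNG substreams are derived deterministically from the
    scenario seed.
    """
    streams = np.random.SeedSequence(scenario.seed).spawn(scenario.iterations)
    significant = 0
    untestable = 0
    for stream in streams:
        p_value, testable = run_replicate(scenario, np.random.default_rng(stream))
        if not testable:
            untestable += 1
        elif p_value < scenario.alpha:
            significant += 1
    power = significant / scenario.iterations
    stderr = float(np.sqrt(power * (1.0 - power) / scenario.iterations))
    return PowerEstimate(scenario, power, stderr, untestable)


def power_grid(
    q_values,
    penetrance_values,
    n_values,
    iterations: int = 1000,
    alpha: float = 0.05,
    mode: str = "collapsed",
    seed: int = 0,
    min_expected_cocarriers: float = 0.0,
) -> pd.DataFrame:
    """Estimate power over the Cartesian grid of settings.

    Both variants of each scenario share the same allele frequency (one
    frequency axis).  Each scenario gets a deterministic per-scenario seed
    derived from the base seed and its grid position.  Returns a
    long-format table, one row per scenario.
    """
    q_values = list(q_values)
    penetrance_values = list(penetrance_values)
    n_values = list(n_values)
    if not (q_values and penetrance_values and n_values):
        raise ValueError("all grid axes must be non-empty")
    rows = []
    combos = itertools.product(n_values, q_values, penetrance_values)
    for index, (n, q, penetrance) in enumerate(combos):
        scenario_seed = int(
            np.random.SeedSequence(entropy=(seed, index)).generate_state(1)[0]
        )
        scenario = PowerScenario(
            q1=q,
            q2=q,
            penetrance=penetrance,
            n=n,
            iterations=iterations,
            alpha=alpha,
            mode=mode,
            seed=scenario_seed,
            min_expected_cocarriers=min_expected_cocarriers,
        )
        rows.append(estimate_power(scenario).as_dict())
    return pd.DataFrame(rows)


def plot_power_curves(table: pd.DataFrame, path) -> None:
    """Power-vs-penetrance curves, one panel per N, 80% reference line."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    n_values = sorted(table["N"].unique())
    fig, axes = plt.subplots(
        1, len(n_values), figsize=(4 * len(n_values), 3.5), sharey=True, squeeze=False
    )
    for ax, n in zip(axes[0], n_values):
        sub = table[table["N"] == n]
        for q, group in sub.groupby("q1"):
            group = group.sort_values("penetrance")
            ax.plot(group["penetrance"], group["power"], marker="o", label=f"q={q:g}")
        ax.axhline(0.8, color="red", linestyle="--", linewidth=1)
        ax.set_title(f"N = {n:,}")
        ax.set_xlabel("penetrance")
        ax.set_ylim(-0.02, 1.02)
    axes[0][0].set_ylabel("power")
    axes[0][-1].legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
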