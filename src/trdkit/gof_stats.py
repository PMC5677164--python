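"""Goodness-of-fit and deviation tests for genotype counts.

Pearson chi-square tests against Mendelian, allele-frequency and
model-derived genotype expectations, with the conventions used throughout
the analysis: no continuity correction; classes with zero expected
frequency (e.g. under a lethality model) are excluded from both the
statistic and the degrees of freedom; degrees of freedom default to
(number of nonzero classes - 1) but may be overridden; expected counts
below 5 trigger a warning, not an error.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .genetics_core import GenotypeDistribution

#: Significance thresholds and their star codes, most stringent last.
STAR_THRESHOLDS: tuple[tuple[float, str], ...] = (
    (0.05, "*"),
    (0.01, "**"),
    (0.005, "***"),
    (0.0001, "****"),
)


def star_code(p: float) -> str:
    """Star-code a p-value (0.05 *, 0.01 **, 0.005 ***, 0.0001 ****)."""
    stars = ""
    for threshold, code in STAR_THRESHOLDS:
        if p < threshold:
            stars = code
    return stars


@dataclass
class GofResult:
    """A Pearson chi-square goodness-of-fit result."""

    chi2: float
    df: int
    p: float
    expectation_label: str
    observed: np.ndarray
    expected: np.ndarray  # expected *counts*
    small_expected: bool = False

    @property
    def stars(self) -> str:
        return star_code(self.p)

    def __post_init__(self) -> None:
        if self.chi2 < 0 or self.df < 1 or not 0.0 <= self.p <= 1.0:
            raise ValueError("invalid goodness-of-fit result")


def chi2_gof(
    observed: Sequence[float],
    expected,
    df_override: int | None = None,
    expectation_label: str = "custom",
) -> GofResult:
    """Pearson chi-square test of observed counts against expected
    frequencies.

    ``expected`` is a frequency vector (or GenotypeDistribution) over the
    same classes as ``observed``.  Classes with zero expected frequency are
    dropped from the statistic and the remaining frequencies renormalised;
    an observation in such a class is an error (an impossible class was
    observed).  df defaults to (number of retained classes - 1).
    """
    obs = np.asarray(observed, dtype=float)
    exp_freq = (
        expected.freqs
        if isinstance(expected, GenotypeDistribution)
        else np.asarray(expected, dtype=float)
    )
    if obs.shape != exp_freq.shape:
        raise ValueError("observed and expected must have the same length")
    if np.any(obs < 0) or np.any(exp_freq < 0):
        raise ValueError("counts and frequencies must be non-negative")
    n = obs.sum()
    if n <= 0:
        raise ValueError("no observations")
    nonzero = exp_freq > 0
    if np.any(obs[~nonzero] > 0):
        raise ValueError("impossible class observed (expected frequency is zero)")
    obs_used = obs[nonzero]
    freq_used = exp_freq[nonzero] / exp_freq[nonzero].sum()
    exp_counts = n * freq_used
    small = bool(np.any(exp_counts < 5))
    if small:
        warnings.warn(
            "some expected counts are below 5; the chi-square approximation "
            "may be poor",
            stacklevel=2,
        )
    chi2 = float(((obs_used - exp_counts) ** 2 / exp_counts).sum())
    df = int(df_override) if df_override is not None else len(obs_used) - 1
    if df < 1:
        raise ValueError("degrees of freedom must be at least 1")
    p = float(stats.chi2.sf(chi2, df))
    return GofResult(
        chi2=chi2,
        df=df,
        p=p,
        expectation_label=expectation_label,
        observed=obs,
        expected=n * np.where(nonzero, exp_freq / exp_freq[nonzero].sum(), 0.0),
        small_expected=small,
    )


def allele_freq_test(genotype_counts: Sequence[float]) -> GofResult:
    """Test allele counts (2N alleles from N individuals) against the
    Mendelian 0.5 : 0.5 expectation, 1 d.f."""
    arr = np.asarray(genotype_counts, dtype=float)
    if arr.shape != (3,):
        raise ValueError("expected genotype counts (GG, GN, NN)")
    alleles = np.array([2 * arr[0] + arr[1], 2 * arr[2] + arr[1]])
    return chi2_gof(alleles, np.array([0.5, 0.5]), expectation_label="mendelian")


def homozygote_deficit_test(
    progeny_counts: Sequence[float], target_class: str = "NN", selfed: bool = True
) -> tuple[float, GofResult]:
    """Deviation of a focal-locus homozygote class from its Mendelian 0.25
    share in selfed progeny, plus the chi-square against 1:2:1.

    Used to map distortion by selfing heterozygous parents: only a locus
    heterozygous in the parent can reveal distortion in its progeny.
    Returns (signed deviation = observed fraction - 0.25, GofResult).
    """
    if not selfed:
        raise ValueError("homozygote-deficit test applies to selfed progeny only")
    arr = np.asarray(progeny_counts, dtype=float)
    if arr.shape != (3,):
        raise ValueError("expected genotype counts (GG, GN, NN)")
    idx = {"GG": 0, "NN": 2}.get(target_class)
    if idx is None:
        raise ValueError("target_class must be a homozygote, 'GG' or 'NN'")
    result = chi2_gof(
        arr, np.array([0.25, 0.5, 0.25]), expectation_label="mendelian"
    )
    deviation = float(arr[idx] / arr.sum() - 0.25)
    return deviation, result


def heterogeneity_test(transmitted_counts: Sequence[Sequence[float]]) -> GofResult:
    """R x 2 contingency chi-square of transmitted-allele counts (G, N per
    cross) across crosses: tests whether transmission ratios differ among
    crosses, without reference to any Mendelian expectation."""
    table = np.asarray(transmitted_counts, dtype=float)
    if table.ndim != 2 or table.shape[0] < 2 or table.shape[1] != 2:
        raise ValueError("need a (>=2 crosses) x 2 table of (G, N) counts")
    chi2, p, df, expected = stats.chi2_contingency(table, correction=False)
    return GofResult(
        chi2=float(chi2),
        df=int(df),
        p=float(p),
        expectation_label="homogeneity",
        observed=table,
        expected=expected,
    )


def results_table(
    results: Sequence[GofResult],
    labels: Sequence[str] | None = None,
    bonferroni: bool = False,
) -> pd.DataFrame:
    """One row per test with chi2, df, p and star coding; optional
    Bonferroni-adjusted column (the per-test reporting itself is
    uncorrected, matching standard practice for per-cross tables)."""
    rows = []
    m = len(results)
    for i, r in enumerate(results):
        row = {
            "test": labels[i] if labels is not None else r.expectation_label,
            "chi2": r.chi2,
            "df": r.df,
            "p": r.p,
            "stars": r.stars,
        }
        if bonferroni:
            row["p_bonferroni"] = min(1.0, r.p * m)
        rows.append(row)
    return pd.DataFrame(rows)
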