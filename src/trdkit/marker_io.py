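"""Marker-level genotype handling.

Focal-locus genotypes are not scored directly: each locus is inferred from
a pair of flanking codominant markers (e.g. M8/M24 around *hms1*,
M51/MgSTS193 around *hms2*).  When the two flanking genotypes agree, the
interval between them is almost certainly non-recombinant and the shared
genotype is taken as the locus genotype; individuals with a crossover
between the flanking markers are excluded from transmission counts.  The
residual error of this scheme — a double crossover producing concordant
flanks with a different genotype in between — has probability
r_left * r_right per gamete under no interference.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import pandas as pd
from statsmodels.stats.proportion import proportion_confint

from .genetics_core import GENOTYPES, normalize_genotype

#: Sentinel returned when flanking markers disagree.
RECOMBINANT = "recombinant"

#: Default mapping from raw marker codes to internal genotypes; None = missing.
DEFAULT_CODE_MAP: dict[str, str | None] = {
    "AA": "GG",
    "AB": "GN",
    "BA": "GN",
    "BB": "NN",
    "NA": None,
    "": None,
}


@dataclass
class MarkerGenotypeRecord:
    """Per-individual marker genotypes plus inferred locus calls.

    ``inferred`` maps locus name to a genotype, :data:`RECOMBINANT`, or
    None (missing data at either flank).
    """

    individual_id: str
    markers: dict[str, str | None]
    inferred: dict[str, str | None] = field(default_factory=dict)


def _parse_genotype(code: str | None, code_map: Mapping[str, str | None]) -> str | None:
    if code is None or (isinstance(code, float) and pd.isna(code)):
        return None
    key = str(code).strip()
    if key in code_map:
        mapped = code_map[key]
        return None if mapped is None else normalize_genotype(mapped)
    # already in internal coding?
    try:
        return normalize_genotype(key)
    except ValueError:
        raise ValueError(f"invalid genotype code: {code!r}") from None


def infer_locus_genotype(
    flank_left: str | None,
    flank_right: str | None,
    code_map: Mapping[str, str | None] = DEFAULT_CODE_MAP,
) -> str | None:
    """Locus genotype from two flanking-marker genotypes.

    Returns the shared genotype when the flanks agree, None when either is
    missing, and :data:`RECOMBINANT` when they disagree (a crossover
    occurred between the flanks, so the focal genotype is unknown).
    Symmetric in its two arguments.
    """
    left = _parse_genotype(flank_left, code_map)
    right = _parse_genotype(flank_right, code_map)
    if left is None or right is None:
        return None
    return left if left == right else RECOMBINANT


def infer_loci(
    table: pd.DataFrame,
    loci: Mapping[str, tuple[str, str]],
    code_map: Mapping[str, str | None] = DEFAULT_CODE_MAP,
    id_column: str = "individual_id",
) -> pd.DataFrame:
    """Add an inferred-genotype column per locus to a marker table.

    ``loci`` maps locus name -> (left marker column, right marker column).
    """
    out = table.copy()
    for locus, (left, right) in loci.items():
        out[locus] = [
            infer_locus_genotype(l, r, code_map)
            for l, r in zip(table[left], table[right])
        ]
    return out


def filter_recombinants(
    table: pd.DataFrame, loci: Sequence[str]
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Drop individuals called recombinant at any requested locus.

    Returns the retained rows (genotype calls untouched) and a per-locus
    count of exclusions.  Rows with missing calls are retained; they carry
    no crossover evidence.
    """
    report = {
        locus: int((table[locus] == RECOMBINANT).sum()) for locus in loci
    }
    mask = ~pd.DataFrame(
        {locus: table[locus] == RECOMBINANT for locus in loci}
    ).any(axis=1)
    retained = table[mask].copy()
    if retained.empty and len(table):
        warnings.warn("all individuals were recombinant; no records retained",
                      stacklevel=2)
    return retained, report


def double_crossover_error_rate(r_left: float, r_right: float) -> float:
    """Probability that a gamete recombines in both flanking intervals,
    producing concordant flanks that miscall the focal locus.

    Under no interference this is the product of the two recombination
    fractions; each must lie in [0, 0.5].
    """
    for name, r in (("r_left", r_left), ("r_right", r_right)):
        if not 0.0 <= r <= 0.5:
            raise ValueError(f"{name} must be a recombination fraction in [0, 0.5]")
    return float(r_left) * float(r_right)


def proportion_with_ci(
    k: int, n: int, confidence: float = 0.95
) -> tuple[float, float, float]:
    """Proportion k/n with an exact (Clopper–Pearson) binomial confidence
    interval: (proportion, lower, upper)."""
    if n <= 0:
        raise ValueError("n must be positive")
    if not 0 <= k <= n:
        raise ValueError("k must satisfy 0 <= k <= n")
    lower, upper = proportion_confint(k, n, alpha=1 - confidence, method="beta")
    return k / n, float(lower), float(upper)


def read_marker_table(source, sep: str = ",") -> pd.DataFrame:
    """Read a delimited marker table: one row per individual, one column per
    marker, plus an individual_id column."""
    return pd.read_csv(source, sep=sep, dtype=str)
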