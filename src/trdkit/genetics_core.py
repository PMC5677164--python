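"""Diallelic two-locus genotype and gamete algebra.

The package analyses transmission at two unlinked diallelic loci — the
*hms1*–*hms2* hybrid sterility system of the yellow monkeyflowers
*Mimulus guttatus* and *M. nasutus*.  Throughout, allele ``G`` denotes the
*M. guttatus* allele and ``N`` the *M. nasutus* allele; the same two-symbol
algebra is reused for within-species crosses (e.g. IM62 vs. IM767 alleles)
through a configurable label map.

Conventions
-----------
* Single-locus diploid genotypes are the unordered strings ``GG``, ``GN``,
  ``NN`` (``NG`` normalises to ``GN``).
* A two-locus genotype pairs the *hms1* and *hms2* genotypes; there are 9,
  listed in canonical (hms1-major) order in :data:`TWO_LOCUS_GENOTYPES`.
* A gamete class pairs one allele per locus; the 4 classes are listed in
  canonical order (G;G, G;N, N;G, N;N) in :data:`GAMETE_CLASSES`.  The
  incompatible class in hybrids is G;N (G at *hms1* with N at *hms2*).
* All frequency vectors use these canonical orders, are non-negative and
  sum to 1 within 1e-9.  Internal arithmetic is full precision; rounding to
  a table's printed precision happens only via :func:`round_for_report`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from decimal import ROUND_HALF_EVEN, Decimal
from typing import Iterable, Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd

ALLELES: tuple[str, str] = ("G", "N")
GENOTYPES: tuple[str, str, str] = ("GG", "GN", "NN")
LOCI: tuple[str, str] = ("hms1", "hms2")

_SUM_TOL = 1e-9


class EmptySampleError(ValueError):
    """Raised when an operation receives an all-zero count vector."""


def normalize_genotype(genotype: str) -> str:
    """Return the unordered genotype in canonical form (``NG`` -> ``GN``)."""
    g = genotype.strip()
    if len(g) != 2 or any(a not in ALLELES for a in g):
        raise ValueError(f"invalid genotype code: {genotype!r}")
    return "".join(sorted(g))  # G sorts before N


class GameteClass(NamedTuple):
    """One haploid two-locus allelic combination (one allele per locus)."""

    hms1: str
    hms2: str

    @property
    def label(self) -> str:
        return f"{self.hms1};{self.hms2}"

    @classmethod
    def from_label(cls, label: str) -> "GameteClass":
        a, b = (s.strip() for s in label.split(";"))
        if a not in ALLELES or b not in ALLELES:
            raise ValueError(f"invalid gamete label: {label!r}")
        return cls(a, b)


GAMETE_CLASSES: tuple[GameteClass, ...] = (
    GameteClass("G", "G"),
    GameteClass("G", "N"),
    GameteClass("N", "G"),
    GameteClass("N", "N"),
)
GAMETE_LABELS: tuple[str, ...] = tuple(g.label for g in GAMETE_CLASSES)
#: Index of the hybrid-incompatible gamete class (G at hms1, N at hms2).
INCOMPATIBLE_GAMETE_INDEX = GAMETE_CLASSES.index(GameteClass("G", "N"))


class TwoLocusGenotype(NamedTuple):
    """Unordered diploid genotypes at *hms1* and *hms2*."""

    hms1: str
    hms2: str

    @property
    def label(self) -> str:
        return f"{self.hms1}; {self.hms2}"

    @classmethod
    def from_label(cls, label: str) -> "TwoLocusGenotype":
        a, b = (s.strip() for s in label.split(";"))
        return cls(normalize_genotype(a), normalize_genotype(b))

    def genotype_at(self, locus: str) -> str:
        if locus not in LOCI:
            raise ValueError(f"unknown locus: {locus!r}")
        return self.hms1 if locus == "hms1" else self.hms2


TWO_LOCUS_GENOTYPES: tuple[TwoLocusGenotype, ...] = tuple(
    TwoLocusGenotype(a, b) for a in GENOTYPES for b in GENOTYPES
)
GENOTYPE_LABELS: tuple[str, ...] = tuple(g.label for g in TWO_LOCUS_GENOTYPES)
_GENOTYPE_INDEX: dict[TwoLocusGenotype, int] = {
    g: i for i, g in enumerate(TWO_LOCUS_GENOTYPES)
}


def _validated_freqs(freqs, size: int, what: str) -> np.ndarray:
    arr = np.asarray(freqs, dtype=float)
    if arr.shape != (size,):
        raise ValueError(f"{what} must have {size} entries, got shape {arr.shape}")
    if np.any(arr < -_SUM_TOL):
        raise ValueError(f"{what} has negative entries")
    arr = np.clip(arr, 0.0, None)
    total = arr.sum()
    if abs(total - 1.0) > _SUM_TOL:
        raise ValueError(f"{what} must sum to 1 (got {total!r})")
    return arr


@dataclass(frozen=True)
class GametePool:
    """Frequency vector over the 4 gamete classes for one parent and sex.

    ``n`` optionally records the number of progeny the pool was estimated
    from, for downstream goodness-of-fit tests.
    """

    freqs: np.ndarray
    sex: str | None = None
    n: int | None = None

    def __post_init__(self) -> None:
        if self.sex is not None and self.sex not in ("male", "female"):
            raise ValueError(f"sex must be 'male' or 'female', got {self.sex!r}")
        object.__setattr__(
            self, "freqs", _validated_freqs(self.freqs, 4, "gamete pool")
        )

    def allele_freq(self, locus: str) -> float:
        """Frequency of the G allele at ``locus`` in this pool."""
        if locus not in LOCI:
            raise ValueError(f"unknown locus: {locus!r}")
        mask = [getattr(g, locus) == "G" for g in GAMETE_CLASSES]
        return float(self.freqs[mask].sum())

    def as_series(self) -> pd.Series:
        return pd.Series(self.freqs, index=list(GAMETE_LABELS), name=self.sex)


@dataclass(frozen=True)
class GenotypeDistribution:
    """Frequency vector over the 9 two-locus progeny genotype classes."""

    freqs: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "freqs", _validated_freqs(self.freqs, 9, "genotype distribution")
        )

    def __getitem__(self, genotype: TwoLocusGenotype | str) -> float:
        if isinstance(genotype, str):
            genotype = TwoLocusGenotype.from_label(genotype)
        return float(self.freqs[_GENOTYPE_INDEX[genotype]])

    def marginal(self, locus: str) -> np.ndarray:
        """Single-locus genotype distribution (GG, GN, NN) at ``locus``."""
        out = np.zeros(3)
        for g, f in zip(TWO_LOCUS_GENOTYPES, self.freqs):
            out[GENOTYPES.index(g.genotype_at(locus))] += f
        return out

    def as_series(self) -> pd.Series:
        return pd.Series(self.freqs, index=list(GENOTYPE_LABELS))


# ---------------------------------------------------------------------------
# Null expectations
# ---------------------------------------------------------------------------

def allele_freq_from_genotypes(counts: Sequence[float]) -> tuple[float, float]:
    """Allele frequencies (G, N) from single-locus genotype counts (GG, GN, NN).

    freq_G = (2 n_GG + n_GN) / 2N, where N is the number of individuals.
    """
    arr = np.asarray(counts, dtype=float)
    if arr.shape != (3,):
        raise ValueError("expected counts for (GG, GN, NN)")
    if np.any(arr < 0):
        raise ValueError("counts must be non-negative")
    total = arr.sum()
    if total == 0:
        raise EmptySampleError("empty sample: all genotype counts are zero")
    freq_g = (2 * arr[0] + arr[1]) / (2 * total)
    return float(freq_g), float(1.0 - freq_g)


def random_union_expectation(freq_g: float) -> np.ndarray:
    """Single-locus genotype distribution (GG, GN, NN) from random union of
    gametes at G-allele frequency ``freq_g`` (i.e. Hardy–Weinberg
    proportions p^2 : 2pq : q^2)."""
    if not 0.0 <= freq_g <= 1.0:
        raise ValueError(f"allele frequency must be in [0, 1], got {freq_g}")
    p, q = freq_g, 1.0 - freq_g
    return np.array([p * p, 2 * p * q, q * q])


def mendelian_gamete_pool(
    parent: TwoLocusGenotype, sex: str | None = None
) -> GametePool:
    """Gamete-class frequencies under independent assortment and fair meiosis.

    Each homozygous locus contributes its allele with probability 1, each
    heterozygous locus contributes either allele with probability 1/2; the
    two loci (on different chromosomes) assort independently.
    """
    margins = []
    for locus in LOCI:
        geno = normalize_genotype(parent.genotype_at(locus))
        margins.append(
            np.array([geno.count("G") / 2.0, geno.count("N") / 2.0])
        )
    freqs = np.outer(margins[0], margins[1]).ravel()
    return GametePool(freqs, sex=sex)


def mendelian_f2_distribution() -> GenotypeDistribution:
    """Two-locus F2 expectation under Mendelian segregation: 1:2:1 at each
    locus, loci independent (double homozygotes 1/16, single-het 1/8,
    double het 1/4)."""
    return two_locus_expectation_from_allele_freqs(0.5, 0.5)


def two_locus_expectation_from_allele_freqs(
    p1: float, p2: float
) -> GenotypeDistribution:
    """Two-locus genotype distribution from the random union of gametes with
    G-allele frequencies ``p1`` at *hms1* and ``p2`` at *hms2*, assuming
    independent assortment (product of the single-locus random-union
    distributions)."""
    d1 = random_union_expectation(p1)
    d2 = random_union_expectation(p2)
    return GenotypeDistribution(np.outer(d1, d2).ravel())


# Map from (maternal gamete index, paternal gamete index) to the index of
# the resulting unordered two-locus genotype.
_UNION_INDEX = np.empty((4, 4), dtype=int)
for _i, _gm in enumerate(GAMETE_CLASSES):
    for _j, _gp in enumerate(GAMETE_CLASSES):
        _geno = TwoLocusGenotype(
            normalize_genotype(_gm.hms1 + _gp.hms1),
            normalize_genotype(_gm.hms2 + _gp.hms2),
        )
        _UNION_INDEX[_i, _j] = _GENOTYPE_INDEX[_geno]


def union_of_pools(
    female: GametePool | np.ndarray, male: GametePool | np.ndarray
) -> GenotypeDistribution:
    """Progeny genotype distribution from the random union of a maternal and
    a paternal gamete pool, collapsed to unordered genotypes.

    This is the shared kernel behind both model-based progeny expectations
    and expectations built from empirically measured pools.
    """
    f = female.freqs if isinstance(female, GametePool) else np.asarray(female, float)
    m = male.freqs if isinstance(male, GametePool) else np.asarray(male, float)
    joint = np.outer(f, m)
    out = np.zeros(9)
    np.add.at(out, _UNION_INDEX.ravel(), joint.ravel())
    return GenotypeDistribution(out)


# ---------------------------------------------------------------------------
# Presentation rounding
# ---------------------------------------------------------------------------

def round_for_report(values, ndigits: int):
    """Round to a table's printed precision using banker's (half-even)
    decimal rounding, after quantising away binary floating-point noise.

    Returns a float for scalar input, an ndarray otherwise.  Internal
    computations never round; this is presentation-layer only.
    """

    def _one(x: float) -> float:
        d = Decimal(float(x)).quantize(Decimal("1e-12"), rounding=ROUND_HALF_EVEN)
        return float(d.quantize(Decimal(1).scaleb(-ndigits), rounding=ROUND_HALF_EVEN))

    if np.isscalar(values):
        return _one(values)
    arr = np.asarray(values, dtype=float)
    return np.array([_one(x) for x in arr.ravel()]).reshape(arr.shape)


# ---------------------------------------------------------------------------
# Allele label maps (within-species crosses)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AlleleLabelMap:
    """Maps external allele labels onto the internal G/N algebra.

    For within-species crosses the mathematics is unchanged — only labels
    differ (e.g. IM62 plays the role of G, IM767 of N).
    """

    g_label: str = "G"
    n_label: str = "N"

    def encode(self, allele: str) -> str:
        if allele == self.g_label:
            return "G"
        if allele == self.n_label:
            return "N"
        raise ValueError(f"unknown allele label: {allele!r}")

    def decode(self, allele: str) -> str:
        return {"G": self.g_label, "N": self.n_label}[allele]

    def encode_genotype(self, a1: str, a2: str) -> str:
        return normalize_genotype(self.encode(a1) + self.encode(a2))


# ---------------------------------------------------------------------------
# Genotype-count table I/O
# ---------------------------------------------------------------------------

LONG_COLUMNS = ("cross_id", "genotype_hms1", "genotype_hms2", "count")


def counts_to_long(counts_by_cross: Mapping[str, Mapping[str, float]]) -> pd.DataFrame:
    """Build a long-format table (cross_id, genotype_hms1, genotype_hms2,
    count) from per-cross mappings of two-locus genotype label -> count."""
    rows = []
    for cross_id, counts in counts_by_cross.items():
        for label, count in counts.items():
            g = TwoLocusGenotype.from_label(label)
            rows.append((cross_id, g.hms1, g.hms2, count))
    return pd.DataFrame(rows, columns=list(LONG_COLUMNS))


def long_to_wide(df: pd.DataFrame) -> pd.DataFrame:
    """Pivot a long-format genotype count table to one row per cross with the
    9 canonical genotype columns."""
    df = df.copy()
    df["genotype"] = [
        TwoLocusGenotype(normalize_genotype(a), normalize_genotype(b)).label
        for a, b in zip(df["genotype_hms1"], df["genotype_hms2"])
    ]
    wide = (
        df.pivot_table(
            index="cross_id", columns="genotype", values="count", aggfunc="sum"
        )
        .reindex(columns=list(GENOTYPE_LABELS))
        .fillna(0.0)
    )
    wide.columns.name = None
    return wide


def wide_to_long(wide: pd.DataFrame) -> pd.DataFrame:
    records = {
        str(cross_id): {c: row[c] for c in GENOTYPE_LABELS}
        for cross_id, row in wide.iterrows()
    }
    return counts_to_long(records)


def read_genotype_counts(source, fmt: str = "long", sep: str = ",") -> pd.DataFrame:
    """Read a genotype-count table from delimited text.

    ``fmt='long'`` expects columns cross_id, genotype_hms1, genotype_hms2,
    count; ``fmt='wide'`` expects cross_id plus the 9 canonical two-locus
    genotype columns.  Either way a long-format DataFrame is returned.
    """
    df = pd.read_csv(source, sep=sep)
    if fmt == "long":
        missing = set(LONG_COLUMNS) - set(df.columns)
        if missing:
            raise ValueError(f"long-format table missing columns: {sorted(missing)}")
        return df[list(LONG_COLUMNS)]
    if fmt == "wide":
        if "cross_id" not in df.columns:
            raise ValueError("wide-format table must have a cross_id column")
        return wide_to_long(df.set_index("cross_id"))
    raise ValueError(f"unknown table format: {fmt!r}")


def write_genotype_counts(
    df: pd.DataFrame, target, fmt: str = "long", sep: str = ","
) -> None:
    """Write a long-format genotype-count table as delimited text, in either
    dialect accepted by :func:`read_genotype_counts`."""
    if fmt == "long":
        df[list(LONG_COLUMNS)].to_csv(target, sep=sep, index=False)
    elif fmt == "wide":
        long_to_wide(df).reset_index().to_csv(target, sep=sep, index=False)
    else:
        raise ValueError(f"unknown table format: {fmt!r}")
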