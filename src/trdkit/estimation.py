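"""Inverting observed cross data into gamete pools and model expectations.

A backcross of a multiply heterozygous parent to a homozygous recurrent
parent reveals, in every progeny genotype, exactly which gamete the
heterozygous parent transmitted: subtracting the recurrent parent's known
gamete leaves the transmitted one.  This module estimates two-locus gamete
pools from backcross progeny counts, averages them across crosses, builds
F2 genotype expectations from measured pools, renormalises expectations
under zygotic lethality, and fits transmission-model parameters by maximum
likelihood on multinomial progeny counts.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize

from .genetics_core import (
    GAMETE_CLASSES,
    GAMETE_LABELS,
    GENOTYPE_LABELS,
    LOCI,
    TWO_LOCUS_GENOTYPES,
    GameteClass,
    GametePool,
    GenotypeDistribution,
    TwoLocusGenotype,
    normalize_genotype,
    union_of_pools,
)
from .transmission_model import TransmissionModel, _progeny_probs, progeny_distribution


class NonParentalGenotypeError(ValueError):
    """Progeny genotype inconsistent with the recurrent parent's gamete
    (flags a genotyping error or contamination)."""


class NotSegregatingError(ValueError):
    """The requested locus is homozygous in the heterozygous-parent line."""


#: Recurrent-parent lines and the gamete each one contributes.
RECURRENT_GAMETES: dict[str, GameteClass] = {
    "G": GameteClass("G", "G"),
    "N": GameteClass("N", "N"),
}


def _counts_series(counts) -> pd.Series:
    if isinstance(counts, pd.Series):
        s = counts.copy()
        s.index = [TwoLocusGenotype.from_label(str(i)).label for i in s.index]
        s = s.reindex(list(GENOTYPE_LABELS)).fillna(0.0)
    else:
        s = pd.Series(0.0, index=list(GENOTYPE_LABELS))
        for label, c in dict(counts).items():
            s[TwoLocusGenotype.from_label(label).label] += c
    if (s < 0).any():
        raise ValueError("progeny counts must be non-negative")
    return s.astype(float)


@dataclass
class ProgenyTable:
    """Counts over the 9 two-locus progeny genotype classes for one cross."""

    counts: pd.Series
    label: str | None = None

    def __post_init__(self) -> None:
        self.counts = _counts_series(self.counts)

    @property
    def n(self) -> int:
        return int(round(self.counts.sum()))

    def freqs(self) -> np.ndarray:
        if self.n == 0:
            raise ValueError("empty progeny table")
        return self.counts.to_numpy() / self.counts.sum()


@dataclass
class BackcrossRecord:
    """One backcross: a (partly) heterozygous IL parent crossed to a
    homozygous recurrent line, with the scored progeny counts."""

    il_genotype: TwoLocusGenotype
    il_sex: str  # sex of the IL parent in this cross
    recurrent: str  # "G" or "N" recurrent line
    progeny: ProgenyTable
    label: str | None = None

    def __post_init__(self) -> None:
        if self.il_sex not in ("male", "female"):
            raise ValueError("il_sex must be 'male' or 'female'")
        if self.recurrent not in RECURRENT_GAMETES:
            raise ValueError("recurrent parent must be 'G' or 'N'")

    @property
    def recurrent_genotype(self) -> TwoLocusGenotype:
        g = RECURRENT_GAMETES[self.recurrent]
        return TwoLocusGenotype(g.hms1 * 2, g.hms2 * 2)

    def parents(self) -> tuple[TwoLocusGenotype, TwoLocusGenotype]:
        """(mother, father) genotypes of the cross."""
        if self.il_sex == "female":
            return self.il_genotype, self.recurrent_genotype
        return self.recurrent_genotype, self.il_genotype


def transmitted_gamete(
    progeny: TwoLocusGenotype, recurrent_gamete: GameteClass
) -> GameteClass:
    """The gamete the heterozygous parent contributed to ``progeny``, found
    by subtracting the recurrent parent's known gamete allele-by-allele."""
    alleles = []
    for locus in LOCI:
        geno = normalize_genotype(progeny.genotype_at(locus))
        rec = getattr(recurrent_gamete, locus)
        if rec not in geno:
            raise NonParentalGenotypeError(
                f"non-parental genotype {progeny.label!r}: no {rec} allele at "
                f"{locus} to attribute to the recurrent parent"
            )
        alleles.append(geno.replace(rec, "", 1))
    return GameteClass(*alleles)


def estimate_gamete_freqs(record: BackcrossRecord) -> GametePool:
    """Relative frequencies of the gamete classes transmitted by the IL
    parent, from backcross progeny counts.  The pool's ``n`` preserves the
    number of scored progeny for downstream tests."""
    for locus in LOCI:
        if record.il_genotype.genotype_at(locus) not in ("GN",):
            # only fully doubly heterozygous parents give all 4 classes, but
            # single-het parents are still estimable over their segregating
            # classes; no error here — zero classes simply stay zero.
            pass
    rec_gamete = RECURRENT_GAMETES[record.recurrent]
    gamete_counts = np.zeros(4)
    for label, count in record.progeny.counts.items():
        if count == 0:
            continue
        gam = transmitted_gamete(TwoLocusGenotype.from_label(label), rec_gamete)
        gamete_counts[GAMETE_CLASSES.index(gam)] += count
    total = gamete_counts.sum()
    if total == 0:
        raise ValueError("no usable progeny in backcross record")
    return GametePool(gamete_counts / total, sex=record.il_sex, n=int(round(total)))


def average_pools(
    pools: Sequence[GametePool], weighting: str = "unweighted"
) -> GametePool:
    """Average gamete pools across crosses of the same sex.

    The default is the plain arithmetic mean of the per-cross frequency
    vectors; ``weighting='count'`` weights by each pool's progeny count.
    """
    if not pools:
        raise ValueError("need at least one pool")
    sexes = {p.sex for p in pools}
    if len(sexes) > 1:
        raise ValueError(f"cannot average pools of mixed sexes: {sorted(map(str, sexes))}")
    mat = np.vstack([p.freqs for p in pools])
    if weighting == "unweighted":
        mean = mat.mean(axis=0)
        n = None
    elif weighting == "count":
        ns = np.array([p.n for p in pools], dtype=float)
        if np.any(np.isnan(ns)) or None in [p.n for p in pools]:
            raise ValueError("count weighting requires every pool to carry n")
        mean = (mat * ns[:, None]).sum(axis=0) / ns.sum()
        n = int(ns.sum())
    else:
        raise ValueError(f"unknown weighting: {weighting!r}")
    return GametePool(mean / mean.sum(), sex=pools[0].sex, n=n)


def f2_expectation_from_pools(
    female: GametePool, male: GametePool
) -> GenotypeDistribution:
    """Expected F2 (selfed-progeny) genotype distribution from empirically
    measured maternal and paternal gamete pools — the same union kernel as
    the model expectation, with measured pools in place of model pools."""
    return union_of_pools(female, male)


def lethality_renormalize(
    expected, lethal_classes: Iterable[TwoLocusGenotype | str]
) -> GenotypeDistribution:
    """Zero out lethal genotype classes and renormalise the survivors.

    ``expected`` may be a GenotypeDistribution or a raw 9-vector in
    canonical order (printed table columns need not sum exactly to 1; the
    survivors are divided by the surviving mass either way, which preserves
    all pairwise ratios among surviving classes).
    """
    freqs = (
        expected.freqs.copy()
        if isinstance(expected, GenotypeDistribution)
        else np.asarray(expected, dtype=float).copy()
    )
    if freqs.shape != (9,):
        raise ValueError("expected a 9-class genotype frequency vector")
    lethal = {
        g if isinstance(g, TwoLocusGenotype) else TwoLocusGenotype.from_label(g)
        for g in lethal_classes
    }
    for i, genotype in enumerate(TWO_LOCUS_GENOTYPES):
        if genotype in lethal:
            freqs[i] = 0.0
    mass = freqs.sum()
    if mass <= 0.0:
        raise ValueError("all genotype classes lethal")
    return GenotypeDistribution(freqs / mass)


def allele_transmission_fraction(record: BackcrossRecord, locus: str) -> float:
    """Fraction of progeny that received the G allele at ``locus`` from the
    heterozygous IL parent."""
    if record.il_genotype.genotype_at(locus) != "GN":
        raise NotSegregatingError(
            f"IL parent is not segregating at {locus} "
            f"({record.il_genotype.genotype_at(locus)})"
        )
    pool = estimate_gamete_freqs(record)
    return pool.allele_freq(locus)


def undertransmission(observed_minor_freq: float, expected: float = 0.5) -> float:
    """Percent undertransmission of an allele relative to its expectation:
    100 * (expected - observed) / expected.  Negative values indicate
    overtransmission; the result is returned signed."""
    if expected <= 0:
        raise ValueError("expected frequency must be positive")
    return 100.0 * (expected - observed_minor_freq) / expected


# ---------------------------------------------------------------------------
# Maximum-likelihood model fitting
# ---------------------------------------------------------------------------

@dataclass
class CrossObservation:
    """Observed progeny counts for one cross with known parents, the unit of
    data for likelihood fitting."""

    mother: TwoLocusGenotype
    father: TwoLocusGenotype
    counts: pd.Series
    background: str | None = None
    label: str | None = None

    def __post_init__(self) -> None:
        self.counts = _counts_series(self.counts)

    @classmethod
    def from_backcross(cls, record: BackcrossRecord, background: str | None = None):
        mother, father = record.parents()
        return cls(mother, father, record.progeny.counts, background, record.label)


@dataclass
class FitResult:
    model: TransmissionModel
    params: dict[str, float]
    loglik: float


FREE_PARAMS = ("s_male", "s_female", "k_drive")


def _loglik(
    model: TransmissionModel, observations: Sequence[CrossObservation]
) -> float:
    return _loglik_fast(
        model,
        [(o.mother, o.father, o.background, o.counts.to_numpy()) for o in observations],
    )


def _loglik_fast(model: TransmissionModel, prepared) -> float:
    total = 0.0
    for mother, father, background, counts in prepared:
        probs = _progeny_probs(mother, father, model, background)
        nz = counts > 0
        if np.any(probs[nz] <= 0):
            return -np.inf
        total += float(counts[nz] @ np.log(probs[nz]))
    return total


def _check_identifiable(
    free_params: Sequence[str], observations: Sequence[CrossObservation]
) -> None:
    # a parameter is identifiable only if some cross produces gametes it acts on
    needs = {
        "s_male": lambda o: o.father.hms1 in ("GG", "GN") and o.father.hms2 in ("GN", "NN"),
        "s_female": lambda o: o.mother.hms1 in ("GG", "GN") and o.mother.hms2 in ("GN", "NN"),
        "k_drive": lambda o: o.mother.hms1 == "GN" or o.father.hms1 == "GN",
    }
    unidentifiable = [
        p
        for p in free_params
        if not any(needs[p](o) for o in observations)
    ]
    if unidentifiable:
        raise ValueError(
            "parameters not identifiable from the supplied crosses: "
            + ", ".join(unidentifiable)
        )


def fit_model_ml(
    observations: Sequence[CrossObservation],
    free_params: Sequence[str] = FREE_PARAMS,
    base_model: TransmissionModel | None = None,
    grid_step: float = 0.05,
) -> FitResult:
    """Fit transmission-model parameters by maximising the multinomial
    log-likelihood of the observed progeny counts.

    A coarse grid over [0, 1] for each free parameter locates the basin;
    Nelder–Mead refinement then polishes the optimum.  Deterministic given
    the data and settings.  ``k_drive`` is fitted as a single scalar.
    """
    if not observations:
        raise ValueError("need at least one cross observation")
    unknown = set(free_params) - set(FREE_PARAMS)
    if unknown:
        raise ValueError(f"unknown free parameters: {sorted(unknown)}")
    _check_identifiable(free_params, observations)
    base = base_model if base_model is not None else TransmissionModel()

    def build(values: Sequence[float]) -> TransmissionModel:
        kwargs = dict(zip(free_params, np.clip(values, 0.0, 1.0)))
        return replace(base, **{k: float(v) for k, v in kwargs.items()})

    prepared = [
        (o.mother, o.father, o.background, o.counts.to_numpy())
        for o in observations
    ]

    def negloglik(values) -> float:
        return -_loglik_fast(build(values), prepared)

    grid = np.arange(0.0, 1.0 + 1e-12, grid_step)
    best_point, best_nll = None, np.inf
    mesh = np.meshgrid(*[grid] * len(free_params), indexing="ij")
    points = np.stack([m.ravel() for m in mesh], axis=-1)
    for point in points:
        nll = negloglik(point)
        if nll < best_nll:
            best_nll, best_point = nll, point
    res = optimize.minimize(
        negloglik,
        best_point,
        method="Nelder-Mead",
        options={"xatol": 1e-5, "fatol": 1e-8, "maxiter": 2000},
    )
    values = np.clip(res.x, 0.0, 1.0)
    if res.fun > best_nll:  # refinement should never lose to the grid
        values = best_point
        res_fun = best_nll
    else:
        res_fun = res.fun
    params = {p: float(v) for p, v in zip(free_params, values)}
    return FitResult(model=build(values), params=params, loglik=-float(res_fun))


# ---------------------------------------------------------------------------
# Table-2-style expectation report
# ---------------------------------------------------------------------------

def expectation_table(columns: Mapping[str, GenotypeDistribution | np.ndarray]) -> pd.DataFrame:
    """Assemble named expectation columns (e.g. Mendelian, allele-frequency,
    backcross-derived, lethality-renormalised) into one genotype-by-column
    table in canonical row order."""
    data = {}
    for name, dist in columns.items():
        freqs = dist.freqs if isinstance(dist, GenotypeDistribution) else np.asarray(dist)
        data[name] = freqs
    return pd.DataFrame(data, index=list(GENOTYPE_LABELS))
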