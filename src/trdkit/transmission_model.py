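"""Selection-modified gamete pools and progeny genotype distributions.

Three transmission-ratio-distortion mechanisms act on an otherwise
Mendelian cross, in this fixed order:

1. *Drive reweighting* — if the parent is heterozygous at *hms1*, its
   gametes carry the G allele with probability ``k_drive`` instead of 1/2
   (``k_drive`` may depend on the parent's *hms2* genotype, since
   overtransmission of G at *hms1* is strongest when *hms2* is homozygous
   N).
2. *Gametic selection* — the incompatible G;N gamete class (G at *hms1*
   with N at *hms2*) survives with probability ``1 - s_sex``, sex-specific
   (pollen vs. ovules).  Total surviving mass is the predicted gamete
   viability; survivors are renormalised.
3. *Zygotic lethality* — after the union of the two parental pools, progeny
   genotype classes matching a lethal rule (e.g. *hms1* GG against an
   *M. nasutus*-like genetic background) die with the rule's penetrance and
   the survivors are renormalised.

Drive is modelled as acting at gamete formation and the incompatibility on
gamete survival; the order of the two stages is not identifiable from
transmission data alone and is fixed here by convention.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping

import numpy as np
import yaml

from .genetics_core import (
    GAMETE_CLASSES,
    GENOTYPE_LABELS,
    INCOMPATIBLE_GAMETE_INDEX,
    LOCI,
    TWO_LOCUS_GENOTYPES,
    GametePool,
    GenotypeDistribution,
    TwoLocusGenotype,
    mendelian_gamete_pool,
    union_of_pools,
)


class CrossInfeasibleError(RuntimeError):
    """A requested cross cannot produce progeny under the model (a parent is
    fully sterile, or every progeny class is lethal)."""


def _check_unit(name: str, value: float) -> float:
    v = float(value)
    if not 0.0 <= v <= 1.0:
        raise ValueError(f"{name} must be in [0, 1], got {value}")
    return v


@dataclass(frozen=True)
class LethalRule:
    """Zygotic lethality predicate over progeny genotype and genetic
    background.

    ``hms1``/``hms2`` restrict the rule to a single-locus genotype (None =
    any); ``background`` restricts it to a cross-level background flag
    (e.g. "N" for an *M. nasutus*-like background; None = any).  The
    background is an annotation of the cross, not inferred from the scored
    genotypes, because the lethality depends on unmapped unlinked loci.
    """

    hms1: str | None = None
    hms2: str | None = None
    background: str | None = None
    penetrance: float = 1.0

    def __post_init__(self) -> None:
        _check_unit("penetrance", self.penetrance)

    def matches(self, genotype: TwoLocusGenotype, background: str | None) -> bool:
        if self.hms1 is not None and genotype.hms1 != self.hms1:
            return False
        if self.hms2 is not None and genotype.hms2 != self.hms2:
            return False
        if self.background is not None and background != self.background:
            return False
        return True


@dataclass(frozen=True)
class TransmissionModel:
    """Parameters of the three distortion mechanisms.

    s_male, s_female
        Penetrance of gametic inviability for the G;N class through pollen
        and ovules respectively (0 = fully viable, 1 = fully inviable).
    k_drive
        Transmission probability of the G allele at *hms1* from a
        heterozygote (0.5 = fair meiosis).  Either a scalar or a mapping
        from the parent's *hms2* genotype ("GG"/"GN"/"NN") to a value;
        unlisted genotypes default to 0.5.
    lethal_rules
        Zygotic lethality predicates applied to progeny.
    baseline_viability
        Genotype-independent gamete viability multiplier (affects predicted
        pollen viability, not transmitted frequencies).

    The null model (s = 0, k = 0.5, no rules) reproduces Mendelian
    expectations exactly.
    """

    s_male: float = 0.0
    s_female: float = 0.0
    k_drive: float | Mapping[str, float] = 0.5
    lethal_rules: tuple[LethalRule, ...] = ()
    baseline_viability: float = 1.0

    def __post_init__(self) -> None:
        _check_unit("s_male", self.s_male)
        _check_unit("s_female", self.s_female)
        _check_unit("baseline_viability", self.baseline_viability)
        if isinstance(self.k_drive, Mapping):
            for g, k in self.k_drive.items():
                _check_unit(f"k_drive[{g}]", k)
            object.__setattr__(self, "k_drive", dict(self.k_drive))
        else:
            _check_unit("k_drive", self.k_drive)
        object.__setattr__(self, "lethal_rules", tuple(self.lethal_rules))

    def drive_coefficient(self, parent_hms2: str) -> float:
        if isinstance(self.k_drive, Mapping):
            return float(self.k_drive.get(parent_hms2, 0.5))
        return float(self.k_drive)

    def selection_coefficient(self, sex: str) -> float:
        if sex == "male":
            return self.s_male
        if sex == "female":
            return self.s_female
        raise ValueError(f"sex must be 'male' or 'female', got {sex!r}")


#: The null model: fair meiosis, no gametic selection, no lethality.
MENDELIAN_MODEL = TransmissionModel()


@dataclass(frozen=True)
class ViabilityPrediction:
    """Predicted fraction of surviving gametes and the surviving pool
    (None when the parent is fully sterile)."""

    viability: float
    surviving_pool: GametePool | None

    @property
    def sterile(self) -> bool:
        return self.surviving_pool is None


def selected_gamete_pool(
    parent: TwoLocusGenotype, sex: str, model: TransmissionModel
) -> ViabilityPrediction:
    """Gamete pool of ``parent`` after drive reweighting and gametic
    selection, with the predicted gamete viability.

    Starting from the Mendelian pool, the *hms1* margin of a heterozygote is
    reweighted to (k, 1-k); the G;N class is then multiplied by
    ``1 - s_sex``; viability is the total surviving mass (times the
    baseline viability) and the surviving pool is renormalised.
    """
    pool = mendelian_gamete_pool(parent, sex=sex).freqs.copy()
    if parent.hms1 == "GN":
        k = model.drive_coefficient(parent.hms2)
        for i, gc in enumerate(GAMETE_CLASSES):
            pool[i] *= 2 * k if gc.hms1 == "G" else 2 * (1 - k)
    pool[INCOMPATIBLE_GAMETE_INDEX] *= 1.0 - model.selection_coefficient(sex)
    mass = pool.sum()
    viability = float(mass * model.baseline_viability)
    if mass <= 0.0:
        return ViabilityPrediction(0.0, None)
    return ViabilityPrediction(viability, GametePool(pool / mass, sex=sex))


def _lethal_survival(
    model: TransmissionModel, background: str | None
) -> np.ndarray:
    """Per-genotype zygotic survival probabilities under the model's lethal
    rules in the given background."""
    survival = np.ones(9)
    for i, genotype in enumerate(TWO_LOCUS_GENOTYPES):
        for rule in model.lethal_rules:
            if rule.matches(genotype, background):
                survival[i] *= 1.0 - rule.penetrance
    return survival


def _selected_pool_raw(
    parent: TwoLocusGenotype, sex: str, model: TransmissionModel
) -> np.ndarray | None:
    """Unvalidated surviving-pool vector (None if sterile); hot path for
    likelihood evaluation."""
    g1 = parent.hms1.count("G") / 2.0
    g2 = parent.hms2.count("G") / 2.0
    if parent.hms1 == "GN":
        g1 = model.drive_coefficient(parent.hms2)
    pool = np.array(
        [g1 * g2, g1 * (1 - g2), (1 - g1) * g2, (1 - g1) * (1 - g2)]
    )
    pool[INCOMPATIBLE_GAMETE_INDEX] *= 1.0 - model.selection_coefficient(sex)
    mass = pool.sum()
    if mass <= 0.0:
        return None
    return pool / mass


def _progeny_probs(
    mother: TwoLocusGenotype,
    father: TwoLocusGenotype,
    model: TransmissionModel,
    background: str | None = None,
) -> np.ndarray:
    """Progeny class probabilities as a bare ndarray; raises
    CrossInfeasibleError exactly as :func:`progeny_distribution`."""
    from .genetics_core import _UNION_INDEX  # shared collapse map

    fm = _selected_pool_raw(mother, "female", model)
    fp = _selected_pool_raw(father, "male", model)
    if fm is None or fp is None:
        which = "mother" if fm is None else "father"
        raise CrossInfeasibleError(f"cross infeasible: {which} is fully sterile")
    out = np.zeros(9)
    np.add.at(out, _UNION_INDEX.ravel(), np.outer(fm, fp).ravel())
    if model.lethal_rules:
        out *= _lethal_survival(model, background)
        mass = out.sum()
        if mass <= 0.0:
            raise CrossInfeasibleError("cross infeasible: all progeny classes lethal")
        out /= mass
    return out


def progeny_distribution(
    mother: TwoLocusGenotype,
    father: TwoLocusGenotype,
    model: TransmissionModel = MENDELIAN_MODEL,
    background: str | None = None,
) -> GenotypeDistribution:
    """Expected progeny genotype distribution of a cross under the model.

    The mother's and father's selected gamete pools are united at random
    (outer product over the 4x4 ordered gamete combinations, collapsed to
    unordered genotypes); zygotic lethality is then applied and the
    survivors renormalised.
    """
    vm = selected_gamete_pool(mother, "female", model)
    vp = selected_gamete_pool(father, "male", model)
    if vm.sterile or vp.sterile:
        which = "mother" if vm.sterile else "father"
        raise CrossInfeasibleError(f"cross infeasible: {which} is fully sterile")
    dist = union_of_pools(vm.surviving_pool, vp.surviving_pool)
    survival = _lethal_survival(model, background)
    if np.all(survival == 1.0):
        return dist
    surviving = dist.freqs * survival
    mass = surviving.sum()
    if mass <= 0.0:
        raise CrossInfeasibleError("cross infeasible: all progeny classes lethal")
    return GenotypeDistribution(surviving / mass)


def ils_feasible_genotypes(
    model: TransmissionModel, background: str | None = None
) -> frozenset[TwoLocusGenotype]:
    """Two-locus genotype classes recoverable (nonzero expected frequency)
    from selfing a doubly heterozygous parent under the model in the given
    background."""
    het = TwoLocusGenotype("GN", "GN")
    dist = progeny_distribution(het, het, model, background=background)
    return frozenset(
        g for g, f in zip(TWO_LOCUS_GENOTYPES, dist.freqs) if f > 0.0
    )


def predict_transmission_from_viability(
    parent: TwoLocusGenotype, observed_viability: float
) -> dict[str, float]:
    """Transmitted G-allele frequencies predicted from an observed gamete
    (pollen) viability, attributing sterility to the incompatible G;N class.

    Assumes equal transmission of G and N into gametes (Mendelian pool).
    The observed sterility ``1 - viability`` is charged to the G;N class
    first, up to that class's Mendelian share; any residual sterility is
    divided equally among the remaining gamete classes.  Returns the
    G-allele frequency of the surviving pool at each locus heterozygous in
    the parent.
    """
    if not 0.0 < observed_viability <= 1.0:
        raise ValueError("observed viability must be in (0, 1]")
    het_loci = [locus for locus in LOCI if parent.genotype_at(locus) == "GN"]
    if not het_loci:
        raise ValueError("parent must be heterozygous at at least one locus")
    pool = mendelian_gamete_pool(parent).freqs.copy()
    sterility = 1.0 - observed_viability
    attributable = pool[INCOMPATIBLE_GAMETE_INDEX]
    if attributable == 0.0 and sterility > 0.0:
        warnings.warn(
            "parent produces no G;N gametes; observed sterility cannot be "
            "attributed to the incompatible class and is spread equally",
            stacklevel=2,
        )
    killed = min(sterility, attributable)
    pool[INCOMPATIBLE_GAMETE_INDEX] -= killed
    residual = sterility - killed
    if residual > 0.0:
        survivors = pool > 0.0
        pool[survivors] -= residual / survivors.sum()
        if np.any(pool < 0.0):
            raise ValueError(
                "observed sterility exceeds what the gamete pool can absorb"
            )
    surviving = GametePool(pool / pool.sum())
    return {locus: surviving.allele_freq(locus) for locus in het_loci}


# ---------------------------------------------------------------------------
# Config serialisation
# ---------------------------------------------------------------------------

def model_to_dict(model: TransmissionModel) -> dict:
    return {
        "s_male": model.s_male,
        "s_female": model.s_female,
        "k_drive": dict(model.k_drive)
        if isinstance(model.k_drive, Mapping)
        else model.k_drive,
        "baseline_viability": model.baseline_viability,
        "lethal_rules": [
            {
                "hms1": r.hms1,
                "hms2": r.hms2,
                "background": r.background,
                "penetrance": r.penetrance,
            }
            for r in model.lethal_rules
        ],
    }


def model_from_dict(data: Mapping) -> TransmissionModel:
    rules = tuple(LethalRule(**r) for r in data.get("lethal_rules", []))
    return TransmissionModel(
        s_male=data.get("s_male", 0.0),
        s_female=data.get("s_female", 0.0),
        k_drive=data.get("k_drive", 0.5),
        lethal_rules=rules,
        baseline_viability=data.get("baseline_viability", 1.0),
    )


def save_model(model: TransmissionModel, path) -> None:
    """Write the model to a YAML config file (schema: the keys of
    :func:`model_to_dict`)."""
    with open(path, "w") as fh:
        yaml.safe_dump(model_to_dict(model), fh, sort_keys=False)


def load_model(path) -> TransmissionModel:
    with open(path) as fh:
        return model_from_dict(yaml.safe_load(fh))
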