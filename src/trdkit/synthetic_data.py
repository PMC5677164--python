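"""Crossing-experiment simulator and packaged study fixtures.

Two jobs live here.  First, machine-readable copies of the study's printed
summary tables (single- and two-locus genotype frequencies in the large
interspecific F2, per-cross allelic transmission in the IL backcrosses,
two-locus gamete-class transmission of doubly heterozygous ILs, and pollen
viabilities), with integer counts reconstructed from printed frequencies
times sample sizes.  Second, a multinomial cross simulator that generates
progeny tables with the statistical structure the analysis assumes —
sex-specific gametic selection against the G;N class, drive at *hms1*,
background-dependent zygotic lethality — so every estimation and testing
stage can be exercised without any external data.

Randomness: one top-level seed; each cross draws from a substream derived
by stable hashing of its label, so adding a cross never perturbs the
others.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .genetics_core import (
    GAMETE_LABELS,
    GENOTYPE_LABELS,
    GENOTYPES,
    TwoLocusGenotype,
    mendelian_f2_distribution,
)
from .estimation import BackcrossRecord, ProgenyTable
from .transmission_model import (
    CrossInfeasibleError,
    LethalRule,
    TransmissionModel,
    model_to_dict,
    progeny_distribution,
    selected_gamete_pool,
)

# ---------------------------------------------------------------------------
# Printed study tables (fixtures)
# ---------------------------------------------------------------------------
# Counts are reconstructed as round(freq * N), repaired on the largest class
# when rounding breaks the sum; reconstructed values are flagged so tests
# can use one-count tolerances.

#: Interspecific F2: single-locus observed frequencies, N = 5487.
TABLE_F2_SINGLE_LOCUS: dict = {
    "N": 5487,
    "hms1": {"genotype_freqs": (0.22, 0.55, 0.23), "allele_freqs": (0.49, 0.51)},
    "hms2": {"genotype_freqs": (0.38, 0.48, 0.14), "allele_freqs": (0.62, 0.38)},
}

#: Two-locus genotype frequency columns for the F2 and the IL F2s, in
#: canonical genotype order.  The IL-G backcross-derived column's GG;NN
#: entry is stored as 0.020 (the printed 0.200 is inconsistent with the
#: column's unit sum and with the product of the printed pools).
TABLE_TWO_LOCUS_COLUMNS: dict[str, tuple] = {
    "f2_allele_freq_expected": (0.093, 0.115, 0.035, 0.191, 0.236, 0.073,
                                0.098, 0.121, 0.037),
    "f2_observed": (0.099, 0.100, 0.022, 0.208, 0.268, 0.071, 0.070, 0.117, 0.047),
    "ilg_observed": (0.066, 0.114, 0.006, 0.174, 0.234, 0.054, 0.102, 0.180, 0.072),
    "ilg_backcross_expected": (0.107, 0.106, 0.020, 0.176, 0.249, 0.078,
                               0.072, 0.133, 0.061),
    "iln_observed": (0.0, 0.0, 0.0, 0.185, 0.300, 0.075, 0.085, 0.225, 0.130),
    "iln_backcross_expected": (0.119, 0.069, 0.090, 0.193, 0.249, 0.058,
                               0.077, 0.151, 0.074),
    "iln_backcross_lethal_expected": (0.0, 0.0, 0.0, 0.241, 0.310, 0.073,
                                      0.096, 0.188, 0.092),
}
TABLE_TWO_LOCUS_N: dict[str, int] = {"f2": 5487, "ilg": 167, "iln": 200}

#: Per-cross allelic transmission in the IL backcrosses: the %G transmitted
#: by the heterozygous IL parent at each segregating locus.  mother/father
#: are "IL-G"/"IL-N" (the IL) or "G"/"N" (the recurrent line); n is None
#: where the cross failed ("no seeds") or the IL genotype could not be made.
TABLE_BACKCROSS_TRANSMISSION: tuple[dict, ...] = (
    {"mother": "IL-G", "father": "G", "genotype": "GN; GG", "n": 101, "hms1_pG": 0.56, "hms2_pG": None},
    {"mother": "IL-G", "father": "G", "genotype": "GN; NN", "n": 171, "hms1_pG": 0.60, "hms2_pG": None},
    {"mother": "IL-G", "father": "G", "genotype": "GG; GN", "n": 163, "hms1_pG": None, "hms2_pG": 0.53},
    {"mother": "IL-G", "father": "G", "genotype": "NN; GN", "n": 158, "hms1_pG": None, "hms2_pG": 0.47},
    {"mother": "IL-G", "father": "G", "genotype": "GN; GN", "n": 293, "hms1_pG": 0.46, "hms2_pG": 0.54},
    {"mother": "IL-G", "father": "N", "genotype": "GN; GG", "n": 189, "hms1_pG": 0.55, "hms2_pG": None},
    {"mother": "IL-G", "father": "N", "genotype": "GN; NN", "n": 119, "hms1_pG": 0.64, "hms2_pG": None},
    {"mother": "IL-G", "father": "N", "genotype": "GG; GN", "n": 49, "hms1_pG": None, "hms2_pG": 0.53},
    {"mother": "IL-G", "father": "N", "genotype": "NN; GN", "n": 132, "hms1_pG": None, "hms2_pG": 0.50},
    {"mother": "IL-G", "father": "N", "genotype": "GN; GN", "n": 232, "hms1_pG": 0.52, "hms2_pG": 0.54},
    {"mother": "G", "father": "IL-G", "genotype": "GN; GG", "n": 382, "hms1_pG": 0.55, "hms2_pG": None},
    {"mother": "G", "father": "IL-G", "genotype": "GN; NN", "n": None, "hms1_pG": None, "hms2_pG": None},
    {"mother": "G", "father": "IL-G", "genotype": "GG; GN", "n": 120, "hms1_pG": None, "hms2_pG": 0.86},
    {"mother": "G", "father": "IL-G", "genotype": "NN; GN", "n": 187, "hms1_pG": None, "hms2_pG": 0.50},
    {"mother": "G", "father": "IL-G", "genotype": "GN; GN", "n": 298, "hms1_pG": 0.37, "hms2_pG": 0.67},
    {"mother": "N", "father": "IL-G", "genotype": "GN; GG", "n": 636, "hms1_pG": 0.62, "hms2_pG": None},
    {"mother": "N", "father": "IL-G", "genotype": "GN; NN", "n": None, "hms1_pG": None, "hms2_pG": None},
    {"mother": "N", "father": "IL-G", "genotype": "GG; GN", "n": 158, "hms1_pG": None, "hms2_pG": 0.90},
    {"mother": "N", "father": "IL-G", "genotype": "NN; GN", "n": 187, "hms1_pG": None, "hms2_pG": 0.52},
    {"mother": "N", "father": "IL-G", "genotype": "GN; GN", "n": 450, "hms1_pG": 0.53, "hms2_pG": 0.64},
    {"mother": "IL-N", "father": "G", "genotype": "GN; GG", "n": 266, "hms1_pG": 0.44, "hms2_pG": None},
    {"mother": "IL-N", "father": "G", "genotype": "GN; NN", "n": 593, "hms1_pG": 0.48, "hms2_pG": None},
    {"mother": "IL-N", "father": "G", "genotype": "GG; GN", "n": None, "hms1_pG": None, "hms2_pG": None},
    {"mother": "IL-N", "father": "G", "genotype": "NN; GN", "n": 325, "hms1_pG": None, "hms2_pG": 0.55},
    {"mother": "IL-N", "father": "G", "genotype": "GN; GN", "n": 354, "hms1_pG": 0.42, "hms2_pG": 0.59},
    {"mother": "IL-N", "father": "N", "genotype": "GN; GG", "n": 211, "hms1_pG": 0.48, "hms2_pG": None},
    {"mother": "IL-N", "father": "N", "genotype": "GN; NN", "n": 317, "hms1_pG": 0.52, "hms2_pG": None},
    {"mother": "IL-N", "father": "N", "genotype": "GG; GN", "n": None, "hms1_pG": None, "hms2_pG": None},
    {"mother": "IL-N", "father": "N", "genotype": "NN; GN", "n": 43, "hms1_pG": None, "hms2_pG": 0.54},
    {"mother": "IL-N", "father": "N", "genotype": "GN; GN", "n": 320, "hms1_pG": 0.58, "hms2_pG": 0.66},
    {"mother": "G", "father": "IL-N", "genotype": "GN; GG", "n": 113, "hms1_pG": 0.46, "hms2_pG": None},
    {"mother": "G", "father": "IL-N", "genotype": "GN; NN", "n": 85, "hms1_pG": 0.71, "hms2_pG": None},
    {"mother": "G", "father": "IL-N", "genotype": "GG; GN", "n": None, "hms1_pG": None, "hms2_pG": None},
    {"mother": "G", "father": "IL-N", "genotype": "NN; GN", "n": 250, "hms1_pG": None, "hms2_pG": 0.53},
    {"mother": "G", "father": "IL-N", "genotype": "GN; GN", "n": 104, "hms1_pG": 0.37, "hms2_pG": 0.64},
    {"mother": "N", "father": "IL-N", "genotype": "GN; GG", "n": 177, "hms1_pG": 0.51, "hms2_pG": None},
    {"mother": "N", "father": "IL-N", "genotype": "GN; NN", "n": 194, "hms1_pG": 0.72, "hms2_pG": None},
    {"mother": "N", "father": "IL-N", "genotype": "GG; GN", "n": None, "hms1_pG": None, "hms2_pG": None},
    {"mother": "N", "father": "IL-N", "genotype": "NN; GN", "n": 188, "hms1_pG": None, "hms2_pG": 0.57},
    {"mother": "N", "father": "IL-N", "genotype": "GN; GN", "n": 212, "hms1_pG": 0.42, "hms2_pG": 0.61},
)

#: Two-locus gamete-class transmission of doubly heterozygous ILs, by cross,
#: frequencies in canonical gamete order (G;G, G;N, N;G, N;N), plus the
#: printed per-sex unweighted averages.
TABLE_GAMETE_TRANSMISSION: tuple[dict, ...] = (
    {"mother": "IL-G", "father": "G", "n": 293, "freqs": (0.31, 0.20, 0.24, 0.25)},
    {"mother": "IL-G", "father": "N", "n": 232, "freqs": (0.28, 0.24, 0.25, 0.22)},
    {"mother": "IL-N", "father": "G", "n": 354, "freqs": (0.30, 0.13, 0.30, 0.28)},
    {"mother": "IL-N", "father": "N", "n": 320, "freqs": (0.43, 0.15, 0.22, 0.19)},
    {"mother": "G", "father": "IL-G", "n": 298, "freqs": (0.32, 0.05, 0.35, 0.28)},
    {"mother": "N", "father": "IL-G", "n": 450, "freqs": (0.40, 0.13, 0.24, 0.23)},
    {"mother": "G", "father": "IL-N", "n": 104, "freqs": (0.34, 0.03, 0.30, 0.34)},
    {"mother": "N", "father": "IL-N", "n": 212, "freqs": (0.32, 0.10, 0.30, 0.29)},
)
TABLE_GAMETE_TRANSMISSION_AVERAGES: dict[str, tuple] = {
    "female": (0.33, 0.18, 0.25, 0.24),
    "male": (0.34, 0.08, 0.30, 0.28),
}

#: Pollen viability by IL genotype: mean proportion viable grains per flower
#: (100 grains scored per flower, 2 flowers per plant), with SE and the
#: number of plants scored.
TABLE_POLLEN_VIABILITY: tuple[dict, ...] = (
    {"background": "IL-G", "genotype": "GG; GN", "n": 5, "viability": 0.64, "se": 0.04},
    {"background": "IL-G", "genotype": "NN; GN", "n": 16, "viability": 0.79, "se": 0.04},
    {"background": "IL-G", "genotype": "GN; GN", "n": 16, "viability": 0.67, "se": 0.06},
    {"background": "IL-G", "genotype": "GN; GG", "n": 12, "viability": 0.71, "se": 0.06},
    {"background": "IL-G", "genotype": "GN; NN", "n": 3, "viability": 0.18, "se": 0.17},
    {"background": "IL-N", "genotype": "NN; GN", "n": 15, "viability": 0.88, "se": 0.02},
    {"background": "IL-N", "genotype": "GN; GN", "n": 14, "viability": 0.81, "se": 0.03},
    {"background": "IL-N", "genotype": "GN; GG", "n": 13, "viability": 0.85, "se": 0.02},
    {"background": "IL-N", "genotype": "GN; NN", "n": 18, "viability": 0.09, "se": 0.01},
)

#: Introgression-line heterozygosity proportions near hms2 (MgSTS45):
#: (heterozygous individuals, individuals genotyped) for the backcross
#: populations with M. guttatus and M. nasutus recurrent parents.
INTROGRESSION_HETEROZYGOSITY: dict[str, tuple[int, int]] = {
    "G_background": (5, 175),
    "N_background": (18, 181),
}

#: Study design constants: per-cross progeny sample sizes and the F2 size.
DESIGN_N_RANGE: tuple[int, int] = (33, 215)
DESIGN_N_MEAN: int = 136
DESIGN_F2_N: int = 5487
POLLEN_GRAINS_PER_FLOWER: int = 100
FLOWERS_PER_PLANT: int = 2


def reconstruct_counts(freqs: Sequence[float], n: int) -> np.ndarray:
    """Integer counts from printed frequencies times N, rounding to the
    nearest integer and repairing any sum mismatch on the largest class."""
    arr = np.asarray(freqs, dtype=float)
    counts = np.rint(arr * n).astype(int)
    counts[np.argmax(counts)] += n - counts.sum()
    if counts.min() < 0:
        raise ValueError("count reconstruction produced a negative count")
    return counts


def make_fixture_tables() -> dict[str, pd.DataFrame]:
    """Machine-readable copies of the printed study tables, with
    reconstructed integer counts flagged ``reconstructed=True`` and the
    reconstruction residual (count repair applied to the largest class)
    recorded per row."""
    tables: dict[str, pd.DataFrame] = {}

    rows = []
    for locus in ("hms1", "hms2"):
        info = TABLE_F2_SINGLE_LOCUS[locus]
        n = TABLE_F2_SINGLE_LOCUS["N"]
        counts = reconstruct_counts(info["genotype_freqs"], n)
        residual = int(n - np.rint(np.asarray(info["genotype_freqs"]) * n).sum())
        for geno, freq, count in zip(GENOTYPES, info["genotype_freqs"], counts):
            rows.append(
                {"locus": locus, "genotype": geno, "freq": freq, "count": int(count),
                 "N": n, "reconstructed": True, "residual": residual}
            )
    tables["f2_single_locus"] = pd.DataFrame(rows)

    two_locus = pd.DataFrame(TABLE_TWO_LOCUS_COLUMNS, index=list(GENOTYPE_LABELS))
    two_locus.insert(0, "mendelian", mendelian_f2_distribution().freqs)
    tables["f2_two_locus"] = two_locus

    rows = []
    for col, n in (("f2_observed", TABLE_TWO_LOCUS_N["f2"]),
                   ("ilg_observed", TABLE_TWO_LOCUS_N["ilg"]),
                   ("iln_observed", TABLE_TWO_LOCUS_N["iln"])):
        freqs = TABLE_TWO_LOCUS_COLUMNS[col]
        counts = reconstruct_counts(freqs, n)
        residual = int(n - np.rint(np.asarray(freqs) * n).sum())
        for label, freq, count in zip(GENOTYPE_LABELS, freqs, counts):
            rows.append({"population": col.replace("_observed", ""),
                         "genotype": label, "freq": freq, "count": int(count),
                         "N": n, "reconstructed": True, "residual": residual})
    tables["two_locus_observed_counts"] = pd.DataFrame(rows)

    tables["backcross_transmission"] = pd.DataFrame(TABLE_BACKCROSS_TRANSMISSION)

    rows = []
    for rec in TABLE_GAMETE_TRANSMISSION:
        counts = reconstruct_counts(rec["freqs"], rec["n"])
        residual = int(rec["n"] - np.rint(np.asarray(rec["freqs"]) * rec["n"]).sum())
        row = {"mother": rec["mother"], "father": rec["father"], "N": rec["n"],
               "reconstructed": True, "residual": residual}
        for label, freq, count in zip(GAMETE_LABELS, rec["freqs"], counts):
            row[f"freq_{label}"] = freq
            row[f"count_{label}"] = int(count)
        rows.append(row)
    tables["gamete_transmission"] = pd.DataFrame(rows)

    tables["pollen_viability"] = pd.DataFrame(TABLE_POLLEN_VIABILITY)
    return tables


def gamete_transmission_records() -> list[BackcrossRecord]:
    """Backcross records for the doubly heterozygous IL crosses, with the
    9-class progeny counts implied by the reconstructed gamete counts and
    the recurrent parent's gamete."""
    from .estimation import RECURRENT_GAMETES
    from .genetics_core import GAMETE_CLASSES, normalize_genotype

    records = []
    for rec in TABLE_GAMETE_TRANSMISSION:
        il_is_mother = rec["mother"].startswith("IL")
        recurrent = rec["father"] if il_is_mother else rec["mother"]
        rec_gamete = RECURRENT_GAMETES[recurrent]
        counts = reconstruct_counts(rec["freqs"], rec["n"])
        progeny: dict[str, int] = {}
        for gamete, count in zip(GAMETE_CLASSES, counts):
            genotype = TwoLocusGenotype(
                normalize_genotype(gamete.hms1 + rec_gamete.hms1),
                normalize_genotype(gamete.hms2 + rec_gamete.hms2),
            )
            progeny[genotype.label] = progeny.get(genotype.label, 0) + int(count)
        records.append(
            BackcrossRecord(
                il_genotype=TwoLocusGenotype("GN", "GN"),
                il_sex="female" if il_is_mother else "male",
                recurrent=recurrent,
                progeny=ProgenyTable(progeny),
                label=f"{rec['mother']} x {rec['father']}",
            )
        )
    return records


# ---------------------------------------------------------------------------
# Simulator
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CrossSpec:
    """One cross in a design: parental genotypes, a progeny-background flag
    for lethality rules, and the number of progeny to sample."""

    label: str
    mother: TwoLocusGenotype
    father: TwoLocusGenotype
    n: int
    background: str | None = None

    def __post_init__(self) -> None:
        if self.n <= 0:
            raise ValueError("progeny sample size must be positive")


@dataclass(frozen=True)
class CrossDesign:
    crosses: tuple[CrossSpec, ...]

    def __post_init__(self) -> None:
        labels = [c.label for c in self.crosses]
        if len(set(labels)) != len(labels):
            raise ValueError("cross labels must be unique")


@dataclass(frozen=True)
class SimulationConfig:
    model: TransmissionModel
    design: CrossDesign
    seed: int = 0
    pollen_sample_size: int = POLLEN_GRAINS_PER_FLOWER


def _cross_rng(seed: int, label: str | None) -> np.random.Generator:
    """Substream for one cross: stable hash of the label mixed with the
    top-level seed, so adding crosses never perturbs existing ones."""
    key = zlib.crc32((label or "").encode("utf-8"))
    return np.random.default_rng([int(seed) & 0x7FFFFFFF, key])


def simulate_cross(
    mother: TwoLocusGenotype,
    father: TwoLocusGenotype,
    model: TransmissionModel,
    n: int,
    seed: int = 0,
    background: str | None = None,
    label: str | None = None,
) -> ProgenyTable:
    """Multinomial sample of ``n`` progeny from the model's expected
    genotype distribution for this cross.  Raises
    :class:`CrossInfeasibleError` for crosses a fully sterile parent makes
    impossible (the simulated analogue of a failed cross)."""
    dist = progeny_distribution(mother, father, model, background=background)
    rng = _cross_rng(seed, label)
    counts = rng.multinomial(n, dist.freqs)
    return ProgenyTable(
        pd.Series(counts.astype(float), index=list(GENOTYPE_LABELS)), label=label
    )


#: IL genotypes used in the backcross experiment (the doubly heterozygous
#: self's segregating classes that are heterozygous at hms1 and/or hms2).
IL_GENOTYPES: tuple[str, ...] = ("GN; GG", "GN; NN", "GG; GN", "NN; GN", "GN; GN")

_RECURRENT_GENOTYPES = {"G": TwoLocusGenotype("GG", "GG"),
                        "N": TwoLocusGenotype("NN", "NN")}


def paper_design(
    n_per_cross: int = DESIGN_N_MEAN,
    f2_n: int = DESIGN_F2_N,
    il_f2_n: tuple[int, int] = (167, 200),
) -> CrossDesign:
    """The study's crossing layout: 9 viable IL genotypes (5 on the
    *M. guttatus* background, 4 on the *M. nasutus* background — the
    GG; GN IL cannot be made against the N background) each backcrossed to
    both recurrent lines in both directions (36 crosses), the two doubly
    heterozygous IL selfs, and one large interspecific F2.

    Background flags: crosses within one species' background keep that
    background; any cross between backgrounds (or the interspecific F2)
    yields F1-like progeny, where the background-dependent lethality is not
    expressed.
    """
    crosses: list[CrossSpec] = []
    for il_bg in ("G", "N"):
        for geno_label in IL_GENOTYPES:
            if il_bg == "N" and geno_label == "GG; GN":
                continue  # unrecoverable against the N background
            il = TwoLocusGenotype.from_label(geno_label)
            for recurrent in ("G", "N"):
                background = il_bg if recurrent == il_bg else "F1"
                rec_geno = _RECURRENT_GENOTYPES[recurrent]
                for il_sex in ("female", "male"):
                    mother, father = (il, rec_geno) if il_sex == "female" else (rec_geno, il)
                    label = (
                        f"IL-{il_bg}[{geno_label}]"
                        f"{'x' if il_sex == 'female' else '<-'}{recurrent}"
                        f"/{il_sex}"
                    )
                    crosses.append(
                        CrossSpec(label, mother, father, n_per_cross, background)
                    )
    het = TwoLocusGenotype("GN", "GN")
    crosses.append(CrossSpec("IL-G F2 self", het, het, il_f2_n[0], "G"))
    crosses.append(CrossSpec("IL-N F2 self", het, het, il_f2_n[1], "N"))
    crosses.append(CrossSpec("species F2", het, het, f2_n, "F1"))
    return CrossDesign(tuple(crosses))


def simulate_paper_design(config: SimulationConfig) -> dict:
    """Simulate every cross in the design; infeasible crosses (a fully
    sterile parent under the model) are reported rather than generated.

    Returns {"tables": {label: ProgenyTable}, "infeasible": [labels],
    "manifest": {...}}.
    """
    tables: dict[str, ProgenyTable] = {}
    infeasible: list[str] = []
    for cross in config.design.crosses:
        try:
            tables[cross.label] = simulate_cross(
                cross.mother,
                cross.father,
                config.model,
                cross.n,
                seed=config.seed,
                background=cross.background,
                label=cross.label,
            )
        except CrossInfeasibleError:
            infeasible.append(cross.label)
    manifest = {
        "seed": config.seed,
        "model": model_to_dict(config.model),
        "n_crosses": len(config.design.crosses),
        "infeasible": infeasible,
    }
    return {"tables": tables, "infeasible": infeasible, "manifest": manifest}


def simulate_pollen_viability(
    genotype: TwoLocusGenotype,
    model: TransmissionModel,
    n_flowers: int = FLOWERS_PER_PLANT,
    seed: int = 0,
    pollen_sample_size: int = POLLEN_GRAINS_PER_FLOWER,
) -> dict:
    """Binomially sampled per-flower viable-grain proportions around the
    model's predicted pollen viability; returns the mean, the standard
    error over flowers, and the per-flower values."""
    prediction = selected_gamete_pool(genotype, "male", model)
    rng = _cross_rng(seed, f"pollen:{genotype.label}")
    per_flower = (
        rng.binomial(pollen_sample_size, prediction.viability, size=n_flowers)
        / pollen_sample_size
    )
    se = float(per_flower.std(ddof=1) / np.sqrt(n_flowers)) if n_flowers > 1 else np.nan
    return {
        "viability_mean": float(per_flower.mean()),
        "viability_se": se,
        "per_flower": per_flower,
        "predicted": prediction.viability,
    }
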