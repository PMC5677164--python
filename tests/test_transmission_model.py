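"""Selection-modified gamete pools and progeny distributions."""

import itertools

import numpy as np
import pytest
from hypothesis import given, strategies as st

from trdkit.genetics_core import (
    GENOTYPES,
    TWO_LOCUS_GENOTYPES,
    TwoLocusGenotype,
    mendelian_f2_distribution,
)
from trdkit.transmission_model import (
    CrossInfeasibleError,
    LethalRule,
    MENDELIAN_MODEL,
    TransmissionModel,
    _progeny_probs,
    ils_feasible_genotypes,
    load_model,
    model_from_dict,
    model_to_dict,
    predict_transmission_from_viability,
    progeny_distribution,
    save_model,
    selected_gamete_pool,
)

HET = TwoLocusGenotype("GN", "GN")


def enumerate_progeny(mother, father, model=MENDELIAN_MODEL, background=None):
    """Independent oracle: explicit enumeration of the two alleles each
    parent carries per locus, gamete-by-gamete, with drive/selection weights
    applied per gamete and lethality per zygote."""
    out = {g: 0.0 for g in TWO_LOCUS_GENOTYPES}

    def gametes(parent, sex):
        weighted = []
        for a1 in parent.hms1:
            for a2 in parent.hms2:
                w = 0.25
                if parent.hms1 == "GN":
                    k = model.drive_coefficient(parent.hms2)
                    w = (k if a1 == "G" else 1 - k) * 0.5
                if a1 == "G" and a2 == "N":
                    w *= 1 - model.selection_coefficient(sex)
                weighted.append(((a1, a2), w))
        total = sum(w for _, w in weighted)
        return [(g, w / total) for g, w in weighted]

    for (gm, wm) in gametes(mother, "female"):
        for (gp, wp) in gametes(father, "male"):
            genotype = TwoLocusGenotype(
                "".join(sorted(gm[0] + gp[0])), "".join(sorted(gm[1] + gp[1]))
            )
            out[genotype] += wm * wp
    for rule in model.lethal_rules:
        for g in list(out):
            if rule.matches(g, background):
                out[g] *= 1 - rule.penetrance
    total = sum(out.values())
    return {g: v / total for g, v in out.items()}


def test_selected_pool_full_male_selection():
    pred = selected_gamete_pool(HET, "male", TransmissionModel(s_male=1.0))
    assert pred.viability == pytest.approx(0.75)
    assert np.allclose(pred.surviving_pool.freqs, [1 / 3, 0, 1 / 3, 1 / 3])


def test_selected_pool_partial_selection_matches_worked_example():
    # a parent fixed G at hms1, heterozygous at hms2, with 64% pollen
    # viability transmits G at hms2 to ~78% of its progeny
    pred = selected_gamete_pool(
        TwoLocusGenotype("GG", "GN"), "male", TransmissionModel(s_male=0.72)
    )
    assert pred.viability == pytest.approx(0.64)
    assert pred.surviving_pool.allele_freq("hms2") == pytest.approx(0.5 / 0.64)


def test_selected_pool_null_model_is_mendelian():
    for genotype in TWO_LOCUS_GENOTYPES:
        pred = selected_gamete_pool(genotype, "male", MENDELIAN_MODEL)
        assert pred.viability == pytest.approx(1.0)
        assert pred.surviving_pool.freqs.sum() == pytest.approx(1.0)


def test_drive_symmetry_at_half():
    model = TransmissionModel(k_drive=0.5)
    for sex in ("male", "female"):
        pred = selected_gamete_pool(HET, sex, model)
        assert pred.surviving_pool.allele_freq("hms1") == pytest.approx(0.5)


def test_drive_conditioned_on_hms2_genotype():
    model = TransmissionModel(k_drive={"NN": 0.9})
    strong = selected_gamete_pool(TwoLocusGenotype("GN", "NN"), "female", model)
    neutral = selected_gamete_pool(TwoLocusGenotype("GN", "GG"), "female", model)
    assert strong.surviving_pool.allele_freq("hms1") == pytest.approx(0.9)
    assert neutral.surviving_pool.allele_freq("hms1") == pytest.approx(0.5)


def test_stronger_male_selection_reduces_n_alleles_at_hms2():
    freqs = []
    for s in (0.0, 0.3, 0.6, 0.9):
        dist = progeny_distribution(
            TwoLocusGenotype("NN", "NN"), HET, TransmissionModel(s_male=s)
        )
        # frequency of N alleles at hms2 among offspring
        marg = dist.marginal("hms2")
        freqs.append(marg[2] + 0.5 * marg[1])
    assert all(a > b for a, b in zip(freqs, freqs[1:]))


def test_null_progeny_distribution_is_mendelian_f2():
    dist = progeny_distribution(HET, HET, MENDELIAN_MODEL)
    assert np.allclose(dist.freqs, mendelian_f2_distribution().freqs)


def test_full_selection_self_matches_enumeration():
    model = TransmissionModel(s_male=1.0, s_female=1.0)
    dist = progeny_distribution(HET, HET, model)
    oracle = enumerate_progeny(HET, HET, model)
    for genotype in TWO_LOCUS_GENOTYPES:
        assert dist[genotype] == pytest.approx(oracle[genotype], abs=1e-12)


def test_lethality_removes_and_renormalises():
    model = TransmissionModel(lethal_rules=(LethalRule(hms1="GG"),))
    dist = progeny_distribution(HET, HET, model)
    assert dist["GG; GG"] == 0.0 and dist["GG; GN"] == 0.0 and dist["GG; NN"] == 0.0
    # survivors scaled up by the removed quarter
    assert dist["GN; GN"] == pytest.approx(0.25 / 0.75)


@given(
    s_male=st.floats(0, 1), s_female=st.floats(0, 1),
    k=st.floats(0.05, 0.95),
    mi=st.integers(0, 8), fi=st.integers(0, 8),
)
def test_progeny_distribution_matches_enumeration_oracle(s_male, s_female, k, mi, fi):
    model = TransmissionModel(s_male=s_male, s_female=s_female, k_drive=k)
    mother, father = TWO_LOCUS_GENOTYPES[mi], TWO_LOCUS_GENOTYPES[fi]
    try:
        dist = progeny_distribution(mother, father, model)
    except CrossInfeasibleError:
        return
    oracle = enumerate_progeny(mother, father, model)
    for genotype in TWO_LOCUS_GENOTYPES:
        assert dist[genotype] == pytest.approx(oracle[genotype], abs=1e-9)
    # the fast likelihood path agrees with the validated path
    assert np.allclose(_progeny_probs(mother, father, model), dist.freqs)


def test_sterile_parent_raises():
    # all gametes are G;N and all are killed: fully sterile father
    model = TransmissionModel(s_male=1.0, k_drive=1.0)
    with pytest.raises(CrossInfeasibleError):
        progeny_distribution(
            TwoLocusGenotype("NN", "NN"), TwoLocusGenotype("GN", "NN"), model
        )


def test_ils_feasible_genotypes():
    assert len(ils_feasible_genotypes(MENDELIAN_MODEL)) == 9
    lethal = TransmissionModel(
        lethal_rules=(LethalRule(hms1="GG", background="N"),)
    )
    against_n = ils_feasible_genotypes(lethal, background="N")
    assert len(against_n) == 6
    assert all(g.hms1 != "GG" for g in against_n)
    assert len(ils_feasible_genotypes(lethal, background="G")) == 9


@pytest.mark.parametrize(
    "genotype, viability, expected",
    [
        (("GG", "GN"), 0.64, {"hms2": 0.5 / 0.64}),
        (("GN", "GN"), 0.67, {"hms1": 1 / 3, "hms2": 2 / 3}),
        (("GN", "GN"), 1.0, {"hms1": 0.5, "hms2": 0.5}),
    ],
)
def test_predict_transmission_from_viability(genotype, viability, expected):
    result = predict_transmission_from_viability(
        TwoLocusGenotype(*genotype), viability
    )
    assert set(result) == set(expected)
    for locus, freq in expected.items():
        assert result[locus] == pytest.approx(freq, abs=1e-6)


def test_predict_transmission_warns_when_nothing_attributable():
    # NN; GN parent makes no G;N gametes, so sterility cannot be charged to
    # the incompatible class
    with pytest.warns(UserWarning):
        predict_transmission_from_viability(TwoLocusGenotype("NN", "GN"), 0.8)


def test_predict_transmission_requires_heterozygosity():
    with pytest.raises(ValueError):
        predict_transmission_from_viability(TwoLocusGenotype("GG", "NN"), 0.8)


def test_model_config_roundtrip(tmp_path):
    model = TransmissionModel(
        s_male=0.9,
        s_female=0.3,
        k_drive={"NN": 0.65},
        lethal_rules=(LethalRule(hms1="GG", background="N", penetrance=1.0),),
        baseline_viability=0.85,
    )
    path = tmp_path / "model.yaml"
    save_model(model, path)
    assert load_model(path) == model
    assert model_from_dict(model_to_dict(model)) == model


def test_parameter_domain_validation():
    with pytest.raises(ValueError):
        TransmissionModel(s_male=1.5)
    with pytest.raises(ValueError):
        TransmissionModel(k_drive={"NN": -0.1})
    with pytest.raises(ValueError):
        LethalRule(penetrance=2.0)
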