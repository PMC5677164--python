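"""Cross simulator and packaged study fixtures."""

import io

import numpy as np
import pandas as pd
import pytest

from trdkit.estimation import estimate_gamete_freqs
from trdkit.genetics_core import (
    GENOTYPE_LABELS,
    TwoLocusGenotype,
    mendelian_f2_distribution,
    read_genotype_counts,
    counts_to_long,
    write_genotype_counts,
    long_to_wide,
)
from trdkit.synthetic_data import (
    CrossDesign,
    CrossSpec,
    SimulationConfig,
    TABLE_GAMETE_TRANSMISSION,
    TABLE_TWO_LOCUS_COLUMNS,
    gamete_transmission_records,
    make_fixture_tables,
    paper_design,
    reconstruct_counts,
    simulate_cross,
    simulate_paper_design,
    simulate_pollen_viability,
)
from trdkit.transmission_model import (
    LethalRule,
    MENDELIAN_MODEL,
    TransmissionModel,
    selected_gamete_pool,
)

HET = TwoLocusGenotype("GN", "GN")


def test_simulate_cross_law_of_large_numbers():
    table = simulate_cross(HET, HET, MENDELIAN_MODEL, 100000, seed=1, label="lln")
    freqs = table.freqs()
    assert np.allclose(freqs, mendelian_f2_distribution().freqs, atol=0.01)


def test_simulate_cross_impossible_class_never_appears():
    model = TransmissionModel(s_male=1.0)
    for seed in range(5):
        table = simulate_cross(
            TwoLocusGenotype("NN", "NN"), HET, model, 2000, seed=seed, label="imp"
        )
        # the paternal G;N gamete is dead, so GN; NN progeny cannot occur
        assert table.counts["GN; NN"] == 0


def test_simulate_cross_determinism_and_substreams():
    a = simulate_cross(HET, HET, MENDELIAN_MODEL, 500, seed=9, label="x")
    b = simulate_cross(HET, HET, MENDELIAN_MODEL, 500, seed=9, label="x")
    c = simulate_cross(HET, HET, MENDELIAN_MODEL, 500, seed=9, label="y")
    assert a.counts.equals(b.counts)
    assert not a.counts.equals(c.counts)


def test_estimation_recovers_generating_pool():
    model = TransmissionModel(s_female=0.6, k_drive=0.65)
    pool = selected_gamete_pool(HET, "female", model).surviving_pool
    # simulate the maternal backcross and re-estimate the transmitted pool
    table = simulate_cross(
        HET, TwoLocusGenotype("NN", "NN"), model, 100000, seed=4, label="recov"
    )
    from trdkit.estimation import BackcrossRecord, ProgenyTable

    record = BackcrossRecord(HET, "female", "N", ProgenyTable(table.counts))
    estimated = estimate_gamete_freqs(record)
    assert np.allclose(estimated.freqs, pool.freqs, atol=0.01)


def test_paper_design_layout():
    design = paper_design()
    labels = [c.label for c in design.crosses]
    assert len(labels) == len(set(labels))
    # 36 backcrosses + two IL selfs + the species F2
    assert len(design.crosses) == 39
    ns = [c.n for c in design.crosses]
    assert ns.count(5487) == 1


def test_simulate_paper_design_null_model_transmission():
    design = paper_design(n_per_cross=500)
    result = simulate_paper_design(
        SimulationConfig(MENDELIAN_MODEL, design, seed=12)
    )
    assert result["infeasible"] == []
    assert len(result["tables"]) == 39
    # transmission near 0.5 everywhere under the null
    from trdkit.estimation import BackcrossRecord, ProgenyTable, allele_transmission_fraction

    for cross in design.crosses:
        if "[GN; GN]" not in cross.label or "F2" in cross.label:
            continue
        il_sex = "female" if cross.mother == HET else "male"
        recurrent = "G" if TwoLocusGenotype("GG", "GG") in (cross.mother, cross.father) else "N"
        record = BackcrossRecord(
            HET, il_sex, recurrent, ProgenyTable(result["tables"][cross.label].counts)
        )
        frac = allele_transmission_fraction(record, "hms1")
        assert abs(frac - 0.5) < 0.08  # ~3.6 SD at n = 500


def test_simulate_paper_design_qualitative_distortion():
    # sex-specific gametic selection + hms2-NN-conditioned drive reproduce
    # the observed directional pattern: N undertransmitted at hms2 through
    # pollen, G overtransmitted at hms1 by GN; NN ILs
    model = TransmissionModel(
        s_male=0.9, s_female=0.3, k_drive={"NN": 0.65},
        lethal_rules=(LethalRule(hms1="GG", background="N"),),
    )
    design = paper_design(n_per_cross=2000)
    result = simulate_paper_design(SimulationConfig(model, design, seed=2))
    from trdkit.estimation import BackcrossRecord, ProgenyTable, allele_transmission_fraction

    tables = result["tables"]
    # paternal doubly heterozygous IL-G to the G line
    rec = BackcrossRecord(
        HET, "male", "G", ProgenyTable(tables["IL-G[GN; GN]<-G/male"].counts)
    )
    assert allele_transmission_fraction(rec, "hms2") > 0.6
    # GN; NN IL transmits G at hms1 in excess through either sex
    gn_nn = TwoLocusGenotype("GN", "NN")
    rec = BackcrossRecord(
        gn_nn, "female", "G",
        ProgenyTable(tables["IL-G[GN; NN]xG/female"].counts),
    )
    assert allele_transmission_fraction(rec, "hms1") > 0.55


def test_iln_self_lethality_blocks_hms1_gg():
    model = TransmissionModel(
        lethal_rules=(LethalRule(hms1="GG", background="N"),)
    )
    for seed in range(3):
        table = simulate_cross(
            HET, HET, model, 200, seed=seed, background="N", label="iln-self"
        )
        for label in ("GG; GG", "GG; GN", "GG; NN"):
            assert table.counts[label] == 0


def test_simulate_pollen_viability():
    null = simulate_pollen_viability(HET, MENDELIAN_MODEL, seed=3)
    assert null["predicted"] == 1.0
    assert null["viability_mean"] == 1.0
    again = simulate_pollen_viability(HET, MENDELIAN_MODEL, seed=3)
    assert np.array_equal(null["per_flower"], again["per_flower"])
    # strong drive toward G plus complete pollen killing of G;N drives
    # viability of a GN; NN parent far below the 50% gametic expectation
    model = TransmissionModel(s_male=1.0, k_drive={"NN": 0.88})
    low = simulate_pollen_viability(
        TwoLocusGenotype("GN", "NN"), model, n_flowers=2, seed=3
    )
    assert low["predicted"] == pytest.approx(0.12)
    assert low["viability_mean"] < 0.5


def test_reconstruct_counts():
    counts = reconstruct_counts((0.31, 0.20, 0.24, 0.25), 293)
    assert list(counts) == [91, 59, 70, 73]
    assert counts.sum() == 293
    f2 = reconstruct_counts((0.22, 0.55, 0.23), 5487)
    assert f2.sum() == 5487


def test_make_fixture_tables_consistency():
    tables = make_fixture_tables()
    two_locus = tables["f2_two_locus"]
    assert list(two_locus.index) == list(GENOTYPE_LABELS)
    assert two_locus["mendelian"].sum() == pytest.approx(1.0)
    observed = tables["two_locus_observed_counts"]
    for pop, group in observed.groupby("population"):
        assert group["count"].sum() == group["N"].iloc[0]
    assert tables["pollen_viability"]["viability"].between(0, 1).all()
    gametes = tables["gamete_transmission"]
    count_cols = [c for c in gametes.columns if c.startswith("count_")]
    assert (gametes[count_cols].sum(axis=1) == gametes["N"]).all()


def test_fixture_counts_roundtrip_through_reader():
    tables = make_fixture_tables()
    observed = tables["two_locus_observed_counts"]
    counts = {
        pop: dict(zip(group["genotype"], group["count"]))
        for pop, group in observed.groupby("population")
    }
    long = counts_to_long(counts)
    buf = io.StringIO()
    write_genotype_counts(long, buf, fmt="long")
    buf.seek(0)
    reread = read_genotype_counts(buf, fmt="long")
    assert long_to_wide(reread).equals(long_to_wide(long))


def test_gamete_transmission_records_match_printed_freqs():
    records = gamete_transmission_records()
    assert len(records) == len(TABLE_GAMETE_TRANSMISSION)
    for record, printed in zip(records, TABLE_GAMETE_TRANSMISSION):
        pool = estimate_gamete_freqs(record)
        assert pool.n == printed["n"]
        # slack: one count unit per class, plus the sum-repair residual when
        # the printed frequencies do not sum exactly to 1
        residual = abs(printed["n"] - round(sum(printed["freqs"]) * printed["n"]))
        atol = (1.0 + residual) / printed["n"] + 5e-3
        assert np.allclose(pool.freqs, printed["freqs"], atol=atol)


def test_cross_spec_validation():
    with pytest.raises(ValueError):
        CrossSpec("bad", HET, HET, 0)
    with pytest.raises(ValueError):
        CrossDesign((CrossSpec("a", HET, HET, 10), CrossSpec("a", HET, HET, 10)))
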