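# trdkit

Two-locus transmission-ratio-distortion (TRD) analysis for gametic hybrid
incompatibility systems.

## The problem

Crosses between the yellow monkeyflowers *Mimulus guttatus* and
*M. nasutus* segregate a two-locus hybrid sterility system, *hms1*
(chromosome 6) and *hms2* (chromosome 13): gametes carrying the
*M. guttatus* allele (G) at *hms1* together with the *M. nasutus* allele
(N) at *hms2* tend to be inviable. Progeny genotype ratios in such crosses
deviate from Mendelian expectations for at least three distinct reasons —
sex-specific gametic selection against the incompatible G;N gamete class,
overtransmission (drive) of G alleles at *hms1*, and background-dependent
zygotic lethality of *hms1* GG homozygotes. `trdkit` provides the model,
estimation and testing machinery to pull these mechanisms apart from
backcross and F2 genotype counts, for anyone analysing transmission
distortion at a pair of unlinked diallelic loci.

## The model

Write a parent's gamete output as a frequency vector over the four gamete
classes (G;G, G;N, N;G, N;N). Starting from the Mendelian pool (independent
assortment, fair meiosis), the model applies, in order:

1. **drive** — a heterozygote at *hms1* transmits G with probability *k*
   instead of ½ (*k* may depend on the parent's *hms2* genotype);
2. **gametic selection** — the G;N class survives with probability
   1 − *s*, with separate *s*♂ (pollen) and *s*♀ (ovules); the total
   surviving mass is the predicted gamete (pollen) viability;
3. **zygotic lethality** — after the random union of the two parental
   pools, progeny classes matching a lethal rule (e.g. *hms1* GG against an
   *M. nasutus*-like background) die with penetrance ℓ and the survivors
   are renormalised.

With *s* = 0, *k* = ½ and no lethal rules the model reduces exactly to
Mendelian segregation. Backcrosses to a homozygous recurrent parent reveal
the transmitted gamete of the heterozygous parent directly, so gamete pools
are estimated by counting; model parameters are fitted by maximising the
multinomial likelihood of progeny counts. Goodness-of-fit uses Pearson χ²
with the conventions of this literature (no continuity correction; classes
with zero expected frequency excluded from statistic and d.f.).

## Worked example

Predict and then re-estimate the pollen output of a doubly heterozygous
introgression line under strong pollen-side incompatibility (*s*♂ = 0.9)
with drive conditional on an *hms2*-NN background:

```python
import numpy as np
import trdkit as t
from trdkit.estimation import BackcrossRecord, ProgenyTable, estimate_gamete_freqs
from trdkit.gof_stats import chi2_gof

model = t.TransmissionModel(s_male=0.9, s_female=0.3, k_drive={"NN": 0.65})
het = t.TwoLocusGenotype("GN", "GN")

pred = t.selected_gamete_pool(het, "male", model)
# predicted pollen viability: 0.775
# surviving pool: {'G;G': 0.323, 'G;N': 0.032, 'N;G': 0.323, 'N;N': 0.323}

table = t.simulate_cross(t.TwoLocusGenotype("GG", "GG"), het, model,
                         n=298, seed=42, label="G x IL")
rec = BackcrossRecord(het, "male", "G", ProgenyTable(table.counts))
pool = estimate_gamete_freqs(rec)
# estimated pool: {'G;G': 0.31, 'G;N': 0.03, 'N;G': 0.34, 'N;N': 0.33}, n = 298

res = chi2_gof(pool.freqs * pool.n, np.full(4, 0.25))
# chi2 = 77.46, df = 3, p = 1.07e-16 ****
```

Reading the numbers: a quarter of this parent's gametes are the
incompatible G;N class and 90% of those die, so predicted pollen viability
is 1 − 0.9 × 0.25 ≈ 0.78, and the surviving pool is
strongly depleted for G;N (0.032 expected, 0.03 estimated from 298
simulated backcross progeny). The χ² test rejects equal transmission of
the four gamete classes overwhelmingly. The estimated pool puts the
transmitted G allele at 34% at *hms1* and 64% at *hms2* — undertransmission
of G at *hms1* and of N at *hms2*, the joint signature of a gametic
incompatibility acting through pollen.

A command-line interface mirrors the library for shell use
(`trdkit simulate | estimate | expect | gof | markers`); see
`trdkit --help`.

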