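# Methods

## Model

`trdkit` models transmission at two unlinked diallelic loci, *hms1* and
*hms2*, with alleles G (*M. guttatus*) and N (*M. nasutus*). All vectors
use fixed canonical orders: gamete classes (G;G, G;N, N;G, N;N) and the
nine two-locus genotypes in hms1-major order (GG;GG … NN;NN). The G;N
class — G at *hms1* with N at *hms2* — is the hybrid-incompatible gamete
type.

A cross is modelled in three stages:

1. **Drive reweighting.** A parent heterozygous at *hms1* transmits G with
   probability `k_drive` (default 0.5 = fair meiosis). `k_drive` may be a
   mapping from the parent's *hms2* genotype to a value, because
   overtransmission of G at *hms1* is strongest when the parent is
   homozygous N at *hms2*; unlisted genotypes fall back to 0.5.
2. **Gametic selection.** The G;N class is multiplied by `1 − s_sex`, with
   independent `s_male` (pollen) and `s_female` (ovules), both in [0, 1].
   The remaining total mass is the predicted gamete viability (times an
   optional genotype-independent `baseline_viability`, default 1.0, which
   models residual pollen inviability unrelated to the incompatibility);
   the surviving pool is renormalised.
3. **Zygotic lethality.** Progeny genotype frequencies are the outer
   product of the two parental surviving pools collapsed to unordered
   genotypes. Each `LethalRule` (single-locus genotype pattern + background
   flag + penetrance) multiplies matching classes by `1 − penetrance`;
   survivors are renormalised.

Drive is placed before selection because the former is modelled as acting
at gamete formation and the latter on gamete survival; the order is not
identifiable from transmission data, so it is fixed by convention.

The background flag ("G", "N", "F1", …) is a cross-level annotation, not
inferred from the scored genotypes: the lethality of *hms1*-GG homozygotes
depends on unmapped loci unlinked to either scored locus, so only the
experimenter's knowledge of the cross can supply it.

Assumptions: independent assortment (the loci sit on different
chromosomes; linked-loci segregation is out of scope), random union of
surviving gametes, no maternal effects beyond the sex-specific selection
coefficients, and multinomial sampling of progeny.

## Estimation

In a backcross to a homozygous recurrent line, subtracting the recurrent
parent's known gamete from each progeny genotype identifies the gamete
transmitted by the heterozygous parent; pools are estimated as the
relative frequencies of these transmitted classes, carrying the progeny
count `n` for downstream tests. Cross-level pools are averaged per sex;
the default is the unweighted arithmetic mean across crosses (the
convention of the source tables, verified arithmetically), with
count-weighted averaging behind a flag.

Model fitting maximises the multinomial log-likelihood of progeny counts
over any subset of {`s_male`, `s_female`, `k_drive`} (scalar `k`). A
coarse grid (default step 0.05 over [0, 1] per parameter) locates the
basin and Nelder–Mead polishes it; the likelihood of these small discrete
models is smooth and unimodal in practice, so a finer grid adds cost
without benefit (pass `grid_step=0.01` to tighten it). An identifiability
check rejects parameter subsets no supplied cross can inform (e.g.
`s_male` with no father that produces G;N gametes).

## Goodness of fit

Pearson χ² = Σ(O−E)²/E with no continuity correction. Classes with zero
expected frequency (lethality models) are excluded from the statistic and
the degrees of freedom — nine classes give 8 d.f., six surviving classes
give 5 d.f. — and an observation in such a class is an error, not a large
statistic. `df_override` reproduces published conventions where they
differ from class counting. Expected counts below 5 trigger a warning
only; several historical cells are that small. Allele-frequency tests use
2N transmitted alleles against 0.5:0.5 at 1 d.f. Heterogeneity of
transmission across crosses uses an R×2 contingency χ² (scipy, no
correction), standing in for factorial ANOVA, which is out of scope. Star
coding follows the 0.05/0.01/0.005/0.0001 thresholds. No multiple-testing
correction is applied by default, matching per-cross reporting; a
Bonferroni column is opt-in.

## Presentation rounding

Internal arithmetic is full precision. `round_for_report` quantises away
binary floating-point noise (12 decimals) and then applies half-even
(banker's) decimal rounding, which is the convention that reproduces the
source tables' printed averages exactly (e.g. 0.345 → 0.34, 0.235 → 0.24).

## Viability-based transmission prediction

`predict_transmission_from_viability` inverts an observed pollen viability
into predicted transmitted allele frequencies: observed sterility is
charged to the G;N class first, up to its Mendelian share; any residual is
split equally over the remaining classes. The residual is computed from
the observed viability itself (e.g. viability 0.67 with a 0.25 G;N share
leaves 0.08 residual, giving 33.3% G at *hms1* and 66.7% at *hms2*). When
the parent produces no G;N gametes at all, sterility cannot be attributed
and a warning is emitted.

## Synthetic data

The simulator draws multinomial progeny from the model's expected
distribution. Defaults mirror the study conditions: 136 progeny per
backcross (the study's mean; its range was 33–215), an F2 of 5487, IL F2
selfs of 167 and 200, and pollen viability scored as 100 grains per flower
on 2 flowers. The full design is 36 backcrosses (nine viable doubly- or
singly-heterozygous IL genotypes × two recurrent lines × two cross
directions; the GG;GN IL cannot exist against the N background under the
lethal rule), two IL selfs, and the species F2. Crosses made infeasible by
the model (a fully sterile parent) are reported, not generated — the
simulated analogue of failed crosses.

Randomness: one top-level seed; each cross uses a substream keyed by
CRC-32 of its label, so adding or removing a cross never perturbs the
others, and identical (config, seed) gives byte-identical output.

Packaged fixtures reproduce the study's printed summary tables with
integer counts reconstructed as round(freq × N), repaired on the largest
class when rounding breaks the sum and flagged `reconstructed=True`;
tests that use them allow one count unit per class plus the repair
residual. Known print artefacts: one backcross-expectation cell is stored
as 0.020 where 0.200 was printed (the column's unit sum and the product of
the printed pools both give 0.020), and the lethality-renormalised column
is reproduced to 3 decimals except one cell that differs by 0.001 from
rounding of the unrounded originals.

What the generator does *not* emulate: marker-level fragment data and
genotyping error, recombination between the focal loci and their flanking
markers (recombinant filtering is exercised on synthetic marker tables,
not on simulated meioses), segregating lethality penetrance in F1-like
backgrounds, and variation in per-cross sample size. Passing tests
therefore demonstrate correctness of the estimation and testing machinery
under the model's assumptions, not robustness to genotyping artefacts in
real data.

## Numerical choices and problem sizes

Frequency vectors are validated to sum to 1 within 1e-9 with no negative
entries. Law-of-large-numbers checks use 10⁵ draws at tolerance 0.01;
type-I-error calibration uses 2000 Mendelian multinomial replicates at
N = 136 and accepts rejection rates in [0.035, 0.065] at α = 0.05;
parameter-recovery tests simulate 2000 progeny per cross and require
s-parameters within ±0.05 and k within ±0.03 — sizes chosen so the whole
suite runs in seconds while keeping Monte-Carlo noise well inside the
asserted tolerances.

## Known limitations

- `k_drive` is fitted as a scalar; fitting a per-*hms2*-genotype drive
  table is possible in principle but not implemented.
- Interval estimation is limited to what the likelihood surface provides;
  no profile or Bayesian intervals.
- The lethality background flag is binary per cross; partially penetrant,
  segregating backgrounds (as in a real F2) must be approximated by a
  penetrance value.
- Exact multinomial tests are not provided; χ² with small-count warnings
  is the only GOF machinery.
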