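# Methods

## The analysis in one paragraph

`glycoproteomap` correlates two omics layers measured on the same plasma
samples: a protein layer (relative abundances, e.g. aptamer fluorescence
units) and a total-plasma N-glycome layer quantified as 36 HILIC-UPLC peak
percentages. Glycan information enters as 113 traits derived from the peak
percentages. Both layers are inverse-normal scaled per feature, every
protein × trait pair is tested by Pearson correlation in a discovery cohort
under Bonferroni control, and discovered pairs are confirmed in an
independent replication cohort by nominal significance (p < 0.05) with a
consistent correlation sign. The output is a record per pair plus a
glycan × protein matrix holding sign(r)·r² for replicated pairs.

## Oxford notation and the grammar

Labels are parsed against the grammar

```
F? A<d> ( (3|6) )? F<d>? B? ( (3|6) )? G<d>? ( S( <links> )<d> | S<d> )?   |   M<d>
```

with the constraints sialic ≤ galactoses ≤ antennae, antennary fucoses ≤
antennae, |linkage list| = sialic count, and mannoses ≥ 5 for high-mannose
labels. Decisions where the notation itself is ambiguous:

* A leading `F` is a core fucose; `F<d>` after the antenna count is
  antennary fucose. Every label in the shipped annotation follows this
  convention.
* The arm qualifier `(6)`/`(3)` may appear before or after `B`
  (`A2(6)BG1` is the canonical placement) and names the core-mannose arm
  carrying a single galactose.
* A bare `S1` stores an *unspecified* sialic linkage (some peaks do not
  chromatographically resolve the α2-3/α2-6 variants); it satisfies only
  linkage-agnostic predicates, never `contains 3` or `contains 6`.
* Hybrid glycans are not representable and are rejected loudly; the
  shipped 36-peak assignment contains none.

## Peak annotation and the dominant-structure rule

HILIC peaks co-elute structures (e.g. GP29 = `A3F1G3S(3,3,3)3 +
A3F1G3S(3,3,6)3`). Trait membership is decided by each peak's *dominant*
(first-listed) structure; this is deterministic, recorded in the annotation
table, and switchable to an "any co-eluting structure" policy. The
annotation ships as TSV configuration (`data/peak_annotation.tsv`), not
code, so an alternative assignment can be swapped in.

The shipped assignment is a representative total-plasma table: the peaks
that the analysis fixes by name (GP3 `A2(6)BG1`, GP8 `A2G2`, GP11 `FA2BG2`,
GP14, GP16, GP18 `M9`, GP19, GP21, GP22, GP24, GP29, GP30, GP32, GP36) sit
at those positions, and the remaining peaks are filled with standard plasma
N-glycome structures chosen so that (a) all structural invariants hold,
(b) the neutral (asialylated-dominant) peaks are exactly
GP1–GP11 + GP18, which makes the neutral-subglycome trait numbering
consistent (GP8 is the 8th neutral peak → trait PGP65, GP18 the 12th →
PGP69), and (c) every structural class referenced by a derived trait is
populated. Users working with a laboratory's actual assignment should
replace the TSV.

## The 113-trait catalog

* **PGP1–PGP36** — primary traits: each peak's % of total integrated area.
* **PGP37–PGP44** — sialylation sub-fractions of the core-fucosylated
  digalactosylated family, split by bisecting GlcNAc.
* **PGP45–PGP57** — fucosylated mono-/disialylated group percentages,
  bisection incidences and their ratios.
* **PGP58–PGP69** — the 12 neutral peaks re-expressed as % of the neutral
  sub-glycome (GPn traits).
* **PGP70–PGP79** — neutral sub-glycome derived traits (galactosylation
  classes, fucosylation and bisection incidences, one ratio).
* **PGP80–PGP91** — total-glycome sub-fractions (sialylation per
  galactosylation class, bisection and core-fucosylation incidences,
  linkage-specific sialylation groups).
* **PGP92–PGP113** — total-glycome group percentages by fucosylation type,
  sialylation degree (0–4), galactosylation degree (0–4), antennarity,
  high-mannose and bisecting GlcNAc, plus ratio and antennary-fucosylation
  traits.

Group percentages over each classification (sialylation degree,
galactosylation degree + high-mannose, antennarity + high-mannose) partition
the 36 peaks, so they sum to 100 per sample — a conservation law the test
suite enforces. Zero denominators (a sample with no mass in a sub-fraction's
reference class) yield *missing*, never an exception or an infinity;
downstream association uses pairwise-complete observations. The catalog
serializes to versioned JSON; only about 30 of the 77 derived traits are
individually fixed by the analyses this package supports, the rest following
the systematic scheme above.

## Inverse-normal transform

Blom scores: a value with (average, tie-shared) rank r among n non-missing
observations maps to Φ⁻¹((r − 3/8)/(n + 1/4)). The offset is a parameter;
3/8 is the common omics convention. Constant features and features with
fewer than three observations cannot be ranked meaningfully and are dropped
with a report. The transform is applied **per cohort**, matching the
independence of discovery and replication. No covariate residualization is
applied by default — the analysis deliberately probes the diversity created
by age, sex and disease state rather than removing it.

## Association testing

Pearson r on scaled values with the exact t reference
(t = r√(n−2)/√(1−r²), df = n−2, two-sided); with one predictor on
rank-normal data this is equivalent to the simple linear-model t-test.
Discovery significance is α/(n_proteins × n_glycans) with strict `<`; for
the full published design (1116 × 113, α = 0.05) this is 3.96 × 10⁻⁷.
Replication requires p < 0.05 (strict) and sign(r_rep) = sign(r_disc); an
exactly zero replication correlation has no sign and cannot replicate.
Pairs with fewer than three complete replication observations are flagged
untestable (`not_replicated` with a note). `consistency_report` tabulates
(r_disc, r_rep) sorted by |r_disc| and the sign-concordance fraction, and
the pipeline's `--swap-roles` flag runs the same analysis with the cohorts
exchanged (the reverse-replication design used when the second cohort is
larger for a particular trait).

## Synthetic cohorts

Per sample, protein abundances are log-normal, aᵢ ~ exp(μᵢ + σᵢZ); the raw
peak vector is Σᵢ aᵢφᵢ over assayed plus background proteins, with each φᵢ a
composition on the 36-peak simplex; enzyme-type links multiply designated
peak masses by aᵢ^γ; every peak is then degraded by multiplicative
log-normal noise with coefficient of variation `glycan_noise_cv` and the
vector is closed to percentages. The protein readout is log aᵢ plus Gaussian
noise — a monotone proxy for relative-quantification assays (no saturation
is modelled; rank-based scaling downstream removes scale anyway). Cohorts
default to 344 discovery / 46 replication samples, drawn independently from
identical population parameters under distinct child seeds; output is
bit-reproducible for a fixed config.

Two stock configurations:

* `null_config` — every protein shares one baseline profile, so the closed
  composition is independent of all abundances and every protein-trait
  correlation is null. Used for family-wise-error calibration.
* `planted_source_config` — PROT1's profile is a point mass on its link
  peaks (default GP22). The defaults (`link_strength` 0.2, `link_log_sd`
  0.8, `glycan_noise_cv` 0.15, readout noise 0.2) were fixed once by
  measuring the induced correlation between PROT1's scaled readout and the
  scaled GP22 percentage at n = 20 000, targeting a population |r| of 0.5 —
  the middle of the effect-size range the design is meant to detect
  (published replicated effects span roughly |r| 0.3–0.7).

`expected_signatures` propagates planted links to trait-level expectations:
positive on every non-ratio trait whose numerator peaks overlap the link
peaks; negative on traits whose numerator is disjoint and carries at least
`contribution_threshold` (default 5%) of mean glycome mass — compositional
complements must fall when the planted contribution rises.

What the generator does **not** emulate: chromatographic drift and
integration error shapes, assay saturation, batch and plate structure, twin
relatedness in the replication cohort, population stratification, or
realistic inter-protein abundance correlation. Passing recovery tests
therefore demonstrate the statistical machinery under the stated generative
model, not robustness to those real-data features.

## Problem sizes and numerical choices

The calibration and recovery studies use simulation sizes chosen to give
stable Monte-Carlo estimates: 200 null runs at 50 proteins × 113 traits for
family-wise error (binomial 95% band around the nominal 5%), and 100
planted-link runs at 20 proteins for recovery (expected power ≈ 0.93: near-1
discovery power at r ≈ 0.5, n = 344, α = 2.2 × 10⁻⁵, times ≈ 0.95
replication power at n = 46). The permutation cross-check of the t-based
p-value uses n = 30 vectors and 10⁴ permutations, where the permutation
null and the t reference coincide and the comparison isolates Monte-Carlo
error. Trait-engine results are verified against a brute-force re-derivation
at 10⁻⁹ relative tolerance on 1000 random Dirichlet profiles.

TSV output uses 6 significant digits (`--full-precision` for more); missing
values are empty cells; all percent traits live on the 0–100 scale and
ratios are dimensionless.

## Known limitations

* The published headline pair counts from the original cohorts cannot be
  reproduced because those cohort data are not public; the pipeline reports
  the analogous counts for whatever data it is given.
* The 36-peak structure assignment is representative configuration, not a
  transcription of any single laboratory's assignment table.
* Replication treats samples as independent; familial relatedness in a
  twin-registry replication cohort is not modelled.
* Aptamer cross-reactivity and protein-isoform ambiguity are out of scope;
  protein identifiers are pass-through strings.
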