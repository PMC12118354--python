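# Methods

## Scope and model

`standmix` computes leaf-level nutrient-cycling diagnostics for tree stands
and compares two-species mixtures against monocultures. The core quantities
are concentration-based: green and senescent leaf N and P concentrations
(GLNC, GLPC, SLNC, SLPC; g kg⁻¹), the mass-loss-corrected resorption
efficiencies NRE and PRE, their ratio RRE with the limitation trichotomy
(N-limited above 100 %, P-limited below, co-limited at exactly 100 %), leaf
trait indices (SLA, LDMC, LD), and signed mixture-effect percentages
Δ = (mix − mono)/mono × 100. No nutrient-pool (mass-per-area) or litterfall
flux accounting is attempted; the analysis lives entirely in concentrations,
as the underlying field methodology does.

Numerical conventions worth stating:

* **MLCF.** The mass-loss correction factor multiplies the senescent/green
  concentration ratio; the angiosperm default is 0.784 and it is applied
  identically to N and P. It is configurable for non-angiosperm material.
  An immediate consequence: leaves whose senescent concentration equals
  their green concentration have NuRE = (1 − 0.784) × 100 = 21.6 %.
* **Units in LD.** Leaf thickness is measured in mm but LD is reported in
  g cm⁻³, so thickness is divided by 10 inside LD = DW/(LT × LA).
* **Negative NuRE** (apparent accretion during senescence) is returned
  unclipped; tabulations flag it and set the limitation label to
  "indeterminate", since the trichotomy is defined for resorbing leaves.
* **Co-limitation** uses exact equality RRE = 100. No tolerance band is
  introduced; with continuous data the boundary has measure zero and a band
  would manufacture a category the definition does not contain.
* **NuRE aggregation.** The default computes NuRE per tree from that tree's
  own green/senescent pair (the two samples come from the same individual,
  so the pairing carries information) and averages afterwards;
  `resorption_table(level="stand")` offers the ratio-of-cell-means
  alternative. On noise-free data the two coincide exactly.
* **Δ percentages** are stored signed; the monoculture is always the
  denominator, so the quantity is deliberately not antisymmetric. The
  report renderer prints magnitude plus "higher/lower". Cell means default
  to grand means over trees; plot-level means are available through the
  `replicate_unit` switch.

## Synthetic-study generator

The generator emulates a five-stand design: monocultures RP, AD, AS and
mixtures RPAD, RPAS; 3 plots per stand (15 total); 5 trees per species per
plot, so monoculture plots carry 5 trees and mixture plots 10. Stand
densities are stored as metadata only — they play no computational role.

**Ground truth and calibration.** Every species × stand cell has true mean
GLNC/GLPC and true NRE/PRE; true senescent means are defined by the
algebraic inversion SLNC = GLNC(1 − NRE/100)/MLCF, so the generating model
and the analysis formula agree exactly. The default mixture effects are a
table of percentage changes of true cell means. Because concentrations and
efficiencies are algebraically linked, an effect triple
(Δgreen, Δsenescent, ΔNuRE) pins down the monoculture senescent/green
ratio: rM = ΔE/((1+ΔE) − (1+ΔS)/(1+ΔG)). The default parameterisation
solves these constraints exactly, which makes every configured effect
reproducible to machine precision from the truth table. Two anchors remain
genuinely free and are chosen as field-plausible synthetic stand-ins (the
underlying field data are not public): the monoculture green-leaf levels
(RP 28/1.6, AD 16/1.2, AS 18/1.3 g kg⁻¹ N/P — the legume N-rich) and RP's
monoculture RRE (90 %, i.e. P-limited, as expected for an N₂-fixer on
calcareous loess). One derived consequence: RP's RPAD effect table fixes
ΔPRE = +10.73 % and ΔRRE = −12.05 % jointly, which implies
ΔNRE = −2.61 %.

**Noise model.** Green concentrations are multiplicative lognormal around
the (plot-adjusted) cell mean with a mean-exact parameterisation
(σ² = ln(1+cv²), μ = ln m − σ²/2), guaranteeing positivity and
unbiasedness; the default CV is 0.10 for both green and senescent noise, a
typical within-stand foliar CV. Senescent values derive from each tree's
own green draw times the cell's true retention ratio times independent
lognormal noise — hence per-tree NuRE is exactly unbiased for the cell
truth, and with CVs at 0 it is exact tree by tree. Structure (AH, DBH, CA)
and morphology (FW, LT, LA, and LDMC ∈ (0,1], with DW = FW × LDMC so dry
mass can never exceed fresh mass) are zero-truncated normals drawn by
rejection. Soil texture is a Dirichlet composition scaled to 100 (closure
exact by construction); other soil properties are truncated normals at
calcareous-loess levels. An optional plot-level lognormal intercept
(`plot_sd`, default 0) induces within-plot correlation; the default assumes
none because the field variance partitioning is unknown.

**RNG discipline.** Each plot and each tree gets its own stream keyed by
(seed, stand index, plot index[, species index, tree index]) through
`numpy.random.SeedSequence`, so identical seeds reproduce datasets
bit-for-bit and enlarging the design never perturbs earlier draws. This
also yields a useful monotonicity: raising a cell's true NRE (same seed)
lowers every generated senescent N value.

**What the generator does not emulate.** Structure and morphology are
independent of the nutrient truth (no crown-area–concentration coupling),
soil is independent of stand type, and there is no spatial layout, no
litter-decomposition dynamics and no explicit rhizobial N fixation. Passing
tests therefore demonstrate that the computation chain recovers known
truth under a realistic sampling design and noise level — not that any
particular ecological mechanism holds in real stands.

## Statistical battery

* Gating follows field practice: Shapiro–Wilk per group and Levene across
  groups at α = 0.05; on failure all groups are natural-log transformed and
  re-tested; if they still fail the analysis proceeds with a recorded
  warning. Non-positive values make the log impossible and raise (the
  pipeline then falls back to raw data with a warning rather than silently
  offsetting).
* One-way ANOVA uses the classical decomposition; Tukey HSD uses the
  studentized-range distribution with the Tukey–Kramer adjustment for
  unequal n (via scipy). The compact letter display is the
  insert-and-absorb algorithm: significant pairs never share a letter and
  non-significant pairs always share at least one; letters order by group
  mean. Student's t defaults to the pooled equal-variance form (homogeneity
  having been pre-checked); Welch is available.
* Two-way ANOVA (stand × species) uses the orthogonal balanced
  decomposition when cell counts are equal — the synthetic default is
  balanced, where all sum-of-squares types coincide — and Type II sums of
  squares via statsmodels otherwise (no interaction-before-main-effect
  ambiguity for factorial questions). The full field design is incomplete
  (no species occupies every stand), so factorial analyses run on complete
  species-pair layouts: each mixture against the two corresponding
  monocultures, coded mono/mixed × species.
* Pearson matrices are pairwise-complete with stars at 0.05/0.01/0.001 and
  **no multiple-testing correction** — the convention of the reporting
  style being mirrored; readers should treat isolated single stars
  accordingly.
* Random-forest importance: a regression forest (defaults 500 trees,
  mtry = ⌊p/3⌋, minimum leaf 5, all exposed in config) on Z-scored inputs;
  importance is the per-tree out-of-bag permutation increase in MSE,
  averaged over trees and expressed as a percentage of the mean OOB MSE.
  OOB sets are recovered by replaying each tree's bootstrap draw from its
  recorded random state; permutations come from a seed-derived stream, so
  the whole table is deterministic under a fixed seed. Negative values are
  reported as-is.
* The replicate unit is a config switch (tree or plot mean), defaulting to
  tree; the unit used is recorded in the output tables.

## Pipeline and provenance

`run_analysis` executes: cell summaries (mean ± SE at the replicate unit);
within-species across-stand comparisons (Tukey letters for the species
present in three stands, t-tests for those in two; lowercase letters) and
across-species within-stand comparisons (uppercase letters); two-way ANOVAs
per response on the species-pair layouts; the Δ table; correlation
matrices, forests and regression panels per species and pooled ("all
species" pools trees across the five stands with species kept as a column).
Stage failures are collected with stage names into the provenance rather
than aborting unrelated stages. Outputs are plain CSVs plus
`provenance.json` (seed, config, versions, checksums); a config + seed
reproduces the bundle byte-identically.

## Validation strategy and problem sizes

The suite checks exact algebra (resorption inversion to 1e-9 over a 10⁴
grid, Δ reconstruction to 1e-12), oracle agreement (hand sum-of-squares
decompositions, t² = F, letter displays against a brute-force pairwise
partition check for 2–5 groups), distributional behaviour (two-way
interaction type-I error 0.05 ± 0.02 over 1000 simulated null studies), and
recovery of injected truth (NuRE and mixture-effect bias within Monte-Carlo
error over 100–150 replicate studies; limitation labels exact in all
noise-free runs; the informative predictor tops the %IncMSE ranking in
≥ 95/100 seeded runs). These sizes give Monte-Carlo standard errors a few
times smaller than the tested tolerances while keeping the full suite fast
on a single core.

One coverage property is worth flagging rather than testing: at the default
noise (CV 10 %, 15 trees per cell) a single study estimates a large
mixture effect like +44 % with an SD of ≈ 5.3 percentage points, so any
fixed ±5-point window captures only about two-thirds of single-study
estimates. Point reproduction of effect sizes is therefore assessed on
replicate averages (unbiasedness), not on single runs.

## Known limitations

* The truth-table anchors are synthetic stand-ins, not measured values;
  only the *relative* mixture effects are calibrated quantities.
* Compact letter displays are not unique in pathological non-transitive
  significance patterns; the insert-and-absorb guarantees stated above are
  the contract, not a specific lettering.
* The correlation/importance stages inherit whatever confounding the input
  data carry; in the synthetic default, soil and structure are independent
  of the nutrient truth, so their importances are genuinely null.
* No mixed-effects modelling: plot-level correlation, if enabled in the
  generator, is handled only by switching the replicate unit to plots.
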