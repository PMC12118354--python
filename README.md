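# standmix

Nutrient-cycling diagnostics for mixed versus monoculture tree plantations.

Mixing a dinitrogen-fixing tree (here *Robinia pseudoacacia*, RP) with
non-fixing species (*Amygdalus davidiana*, AD; *Armeniaca sibirica*, AS) can
change how much nitrogen and phosphorus each species keeps in its leaves and
how much it withdraws before leaf fall. `standmix` packages the standard
computation chain ecologists use to ask that question, plus a calibrated
synthetic-study generator so the whole pipeline can be validated against
known ground truth. It is aimed at plant-stoichiometry and restoration
ecologists working with per-tree leaf and per-plot topsoil tables.

## The quantities

For green/senescent leaf nutrient concentrations (g kg⁻¹), the mass-loss-
corrected **nutrient resorption efficiency** is

    NuRE = (1 − NuC_senescent / NuC_green × MLCF) × 100   [%]

with MLCF = 0.784, the angiosperm mass-loss correction factor (senescing
leaves lose dry mass, which would otherwise inflate apparent resorption).
NRE and PRE are NuRE for N and P. The **relative resorption efficiency**

    RRE = NRE / PRE × 100   [%]

diagnoses growth limitation: RRE > 100 % → N-limited, < 100 % → P-limited,
= 100 % → co-limited. Mixture effects are signed percentage changes of a
species' mixed-stand mean against its monoculture,

    Δ = (mix − mono) / mono × 100   [%],

applied to concentrations and efficiencies alike. Leaf trait indices follow
the usual definitions: SLA = LA/DW (cm² g⁻¹), LDMC = DW/FW (g g⁻¹),
LD = DW/(LT × LA) (g cm⁻³, thickness converted mm → cm).

The statistical battery mirrors field practice at α = 0.05: Shapiro–Wilk and
Levene gating with a natural-log fallback, one-way ANOVA + Tukey HSD with
compact letters, pooled Student's t, two-way factorial ANOVA
(stand × species), Pearson correlation matrices starred at 0.05/0.01/0.001,
simple linear regressions, and random-forest variable importance as the
percentage increase in out-of-bag MSE (%IncMSE).

## Worked example

Simulate one study (five stand types — RP/AD/AS monocultures plus the RPAD
and RPAS mixtures; 3 plots each, 5 trees per species per plot), analyse it,
and summarise:

```
$ standmix simulate --seed 42 --out demo/data
wrote dataset (seed=42, design=454125d9c2ae0f51) to demo/data
$ standmix analyze --in demo/data --seed 42 --out demo/report
wrote report bundle to demo/report
$ standmix report --in demo/report
Mixture effects (percent change vs. monoculture):
  AD GLNC: 46.16% higher in RPAD than AD
  AD SLNC: 85.04% higher in RPAD than AD
  AD NRE: 29.62% lower in RPAD than AD
  AS GLNC: 29.28% higher in RPAS than AS
  RP GLPC: 17.33% higher in RPAD than RP
  ...
```

Reading: in this simulated study the non-fixer *A. davidiana* carries ~46 %
more green-leaf N and drops ~85 % N-richer litter when grown with the
N-fixer, and correspondingly resorbs ~30 % less N before abscission — the
classic signature of relaxed N limitation in the mixture. The report
directory holds the full machine-readable tables (`metrics.csv`,
`tukey.csv`, `anova.csv`, `ttests.csv`, `deltas.csv`, `correlations.csv`,
`regressions.csv`, `importance.csv`) plus `provenance.json` with the seed,
config and file checksums; the same run reproduces byte-identically.

The same pipeline runs on real data: any directory with `trees.csv` and
`soil.csv` in the documented schema (see `standmix/dataset.py`) works with
`standmix analyze --in <dir>`.

From Python:

```python
import standmix as sm

dataset, truth = sm.generate_study(sm.default_design(), seed=42)
bundle = sm.run_analysis(sm.RunConfig(seed=42), dataset=dataset)
print(bundle.deltas.head())
```

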