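# settlescan

Spatial-epidemiological analysis of diarrheal risk and housing deprivation in
informal settlements, built around cross-sectional georeferenced household
surveys of the kind collected in rapidly urbanizing African cities.

Diarrheal disease burden in informal settlements is usually attributed to
water, sanitation and hygiene (WASH) access, but dwelling conditions — what a
house is built from, whether cooking happens indoors, whether water flows
every day — may mediate contamination pathways of their own. `settlescan`
implements the full analysis chain for testing that hypothesis on a two-site
household survey, plus a synthetic survey generator so the whole pipeline is
testable end to end without any field data.

## What it computes

**Sample-size design.** Minimum individuals for a prevalence survey, with
design effect, and its conversion to households:

```
n0 = Z²_{1-α/2} · P(1-P) · D_eff / e²
households = ceil( n0 / (p_target · hh_size) / valid_rate )
```

**Deprivation binaries.** From raw survey answers: inadequate building
materials (any of wall/roof/floor non-durable), overcrowding (> 3 persons
per room), and at-least-basic water / sanitation / hygiene service per the
WHO/UNICEF JMP ladders. The material partition and ladder lookup ship as
editable CSV tables.

**Risk regression.** Individual-level multiple logistic regressions,
stratified (general population and under-fives): bivariate pre-selection at
p < 0.1, variance-inflation-factor exclusion at VIF > 5 (plus a rarity guard
for near-universal exposures), then adjusted odds ratios aOR = exp(β) with
95% Wald CIs. A variable is significant only if its CI excludes 1 **and**
the model's likelihood-ratio test has p < 0.05.

**Spatial clusters.** Per site: local transverse-Mercator projection,
16-nearest-neighbor weights, and the local join count — for each household
with an event (a diarrheal case, or a dwelling deprivation), the number of
its k neighbors with the same event — with conditional-permutation pseudo
p-values `(M+1)/(nperm+1)` (the focal value held fixed, the remaining values
reassigned at random).

**Synthetic surveys.** A two-site generator (≈266 + 301 households,
household size 1 + Poisson(3.5), spatially clustered deprivation fields,
logistic outcomes with configurable effect sizes, 90% valid-response rate)
whose defaults emulate the study conditions the pipeline targets.

## Worked example

```bash
python analysis/01_simulate_survey.py --seed 1
python analysis/03_risk_regression.py
python analysis/04_spatial_clusters.py --seed 1
```

prints (abridged):

```
seed 1: 567 households, 2477 individuals
2477 individual rows, 2234 complete cases (243 dropped)
prevalence: general 15.5%, under-5 21.3%

general: n=2234, LLR p=2.4e-14
  indoor_cooking             aOR 0.61 (0.48-0.77) ****
  inadequate_materials       aOR 1.81 (1.41-2.31) ****
  water_constant             aOR 0.59 (0.46-0.74) ****
  excluded basic_water [dropped_screen] degenerate: minority class 1.9% < 2%

centraltown: 301 households, median 16-NN neighbor distance 18 m
  no_constant_water       53 significant / 134 event households
lagoonside: 266 households, median 16-NN neighbor distance 35 m
  no_constant_water       15 significant / 80 event households
```

Read: about 15% of individuals reported diarrhea in the past two weeks;
living in a dwelling with inadequate materials nearly doubles the adjusted
odds of diarrhea (the generator's built-in aOR is 1.79, recovered as 1.81),
indoor cooking and constant water access are protective, and the
near-universal basic-water variable is excluded by the degeneracy guard
before modelling. The cluster stage flags the households whose local join
count is improbably high under spatial randomness — here concentrated where
the generator placed its deprivation cores. Stars: `*` p<0.1, `**` p<0.05,
`***` p<0.01, `****` p<0.001. The same chain is available as a CLI
(`settlescan simulate | samplesize | regress | clusters | run | report`) and
as one call, `settlescan.pipeline.run_pipeline`, which writes a bundle with
a manifest (seed, config snapshot, digests) making every number traceable.

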