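# Methods

## Study design emulated

The pipeline targets a cross-sectional georeferenced household survey in two
informal settlements of contrasting urban fabric: a low-density lagoon-side
village with comparatively good services, and a dense central settlement
with widespread deprivation. The survey unit is the household; the analysis
unit is the individual, who inherits all dwelling covariates from their
household. The outcome is self-reported diarrhea (three or more loose stools
per day) in the two weeks preceding the survey.

## Sample size

Minimum individuals follow the normal-approximation prevalence formula with
a design effect, `n0 = Z²_{1-α/2} P(1-P) D_eff / e²`, then convert to
households by dividing by the target-population share (under-fives), the
mean household size, and the expected valid-response rate. Defaults: α=0.05,
P=0.15, D_eff=1.5, e=0.05, share 0.15, household size 4.5, valid rate 0.90
→ n0 ≈ 293.9 and 484 households. Z is computed from the normal quantile so
α is general; a `z_value` override reproduces the conventionally printed
1.96 (both give 484). Rounding: fractional values are carried through the
chain with a single final ceiling. The per-step-ceiling variant is available
by flag and is more conservative — it yields 485 at the defaults, because
ceil(435.4)=436 and ceil(436/0.9)=485.

## Deprivation and WASH binaries

* `inadequate_materials`: true if any of wall, roof or floor is made of a
  non-durable material. The material vocabulary and its durable/non-durable
  partition ship as `settlescan/data/materials.csv` (finished brick,
  concrete, metal sheet, tiles, cement = durable; planks, thatch, earth,
  tarpaulin, unfinished surfaces = non-durable) and can be edited without
  touching code, since field vocabularies vary.
* `overcrowded`: strictly more than three members per room.
* `basic_water` / `basic_sanitation` / `basic_hygiene`: the facility code's
  rung on the WHO/UNICEF JMP service ladder is "basic" or higher
  (`settlescan/data/jmp_ladders.csv`). The encoding is a faithful generic
  JMP ladder; a study with different observed facility codes edits the
  table. Basic hygiene requires water *and* soap at the handwashing
  facility.
* Constant water availability over the past month is a direct survey answer,
  kept separate from the ladder (a basic source does not imply continuous
  service).

Missing answers are explicit (`pandas.NA`); flags derived from a missing
input are missing, never imputed. Complete-case filtering on the eight
analysis variables (outcome + seven covariates) is the only row-dropping
step, and reports its count.

## Risk regression

Per stratum (general population; under-fives only):

1. **Bivariate screen** — one-predictor logistic fit per candidate; keep if
   the Wald p-value is below 0.1. Constant candidates, and binaries whose
   minority class is below 2%, are dropped with a "degenerate" note: a
   near-universal exposure (e.g. basic water at 99% coverage) carries almost
   no information and destabilizes the joint fit, and a pure VIF pass need
   not catch it.
2. **VIF exclusion** — variance inflation factors `1/(1-R²_j)` over the kept
   set; while any VIF exceeds 5, drop the single worst variable and
   recompute (a single-pass mode exists). Exact collinearity reports +inf.
3. **Joint fit** — maximum-likelihood logistic regression (Newton, relative
   log-likelihood tolerance 1e-8, 100 iterations max) of the outcome on the
   kept variables. Adjusted odds ratios exp(β) with 95% Wald CIs
   exp(β ± 1.96·se); per-variable p-values are Wald (the star scale `*`<0.1,
   `**`<0.05, `***`<0.01, `****`<0.001 uses them). A variable is
   *significant* only when its CI excludes 1 and the model-level
   likelihood-ratio test against the intercept-only model has p < 0.05.

Degenerate fits are never silent: a constant outcome or perfect separation
raises; rank deficiency or quasi-separation returns `converged=False` with a
diagnostic note, and screening converts these into documented exclusions.

No household-level clustering correction (random effects, GEE, robust SEs)
is applied even though siblings share covariates — this matches the analysis
design the pipeline reproduces and is a known limitation: household-shared
outcomes would make the nominal CIs somewhat anticonservative.

## Spatial cluster detection

* **Projection**: spherical transverse Mercator centered on each site's
  centroid, sphere radius 6378137 m (so 0.001° of latitude ≈ 111.32 m).
  Closed-form forward and inverse; over a settlement-scale extent (≤5 km)
  the pairwise-distance distortion is well below 0.1%.
* **Weights**: exact k nearest neighbors (k=16 by default, a bandwidth
  suited to small dense settlements), Euclidean distance, no self-neighbors,
  distance ties broken by ascending observation index so the structure is
  deterministic. Sites with n ≤ k are rejected rather than silently
  reduced. The median over all (focal, neighbor) distances is reported as a
  density diagnostic; at the default generator it lands near 35 m in the
  sparse site and 18 m in the dense one.
* **Local join count**: for each household i with the event (x_i = 1),
  `bb_i = Σ_{j∈N(i)} x_j` — the number of its k neighbors that also have
  the event. Non-event households carry no statistic.
* **Inference**: conditional permutation. The focal value is held fixed and
  the remaining n-1 observed values are reassigned uniformly at random to
  the other locations; with M the number of the `nperm=999` permutations
  whose neighbor count is ≥ the observed bb_i (ties count, so bb_i = 0 gives
  pseudo-p = 1), `pseudo_p = (M+1)/(nperm+1) ∈ [1/(nperm+1), 1]`. Under this
  scheme the neighbor count is exactly Hypergeometric(n-1, events-1, k),
  which the tests use as a closed-form oracle. Significance at α=0.05 by
  default (an optional Benjamini–Hochberg mode exists but is off, matching
  the uncorrected per-site reading of settlement maps). The permutation test
  on a discrete count is conservative: under spatial randomness it flags
  fewer than the nominal 5% of event households.
* **Event layers** (household level, since dwellings are what is mapped):
  any-member diarrhea, under-5 diarrhea, lack of at least one basic WASH
  service, lack of constant water, lack of indoor cooking, inadequate
  materials. Inference is within-site; constant layers are skipped as
  inference-free.

A note on the null: permuting the attribute values among locations with the
focal fixed is the standard conditional construction for local statistics
and is equivalent in distribution to randomly permuting the point positions
under a fixed attribute multiset.

## Synthetic data generator

The generator is first-class, tested code; its defaults *are* the study
conditions the pipeline targets:

* two sites of 266 and 301 households; extents (540×420 m and 250×190 m)
  chosen so the 16-NN median neighbor distances land near 36 m and 17 m;
* layouts: Thomas cluster process (uniform parents, isotropic Gaussian
  offsets, rejection at the boundary) to mimic built-fabric clumping;
  uniform available;
* deprivation fields: independent Bernoulli draws from a distance-to-core
  kernel `p(s) = p_base + (p_core − p_base)·max_c exp(−d²/2σ²)`, cores
  uniform in the site. Chosen over a latent Gaussian random field for
  transparency and O(n·cores) cost; both produce the clustered binary maps
  the cluster stage must detect. Site A's base rates are consistently lower
  than site B's (the sparse site is wealthier and better served); lack of a
  basic water source is rare (1%) everywhere while lack of *constant* water
  is common (~25–35% base), reproducing the divergence between source
  access and service continuity;
* raw fields are then written consistently with the drawn binaries (one
  non-durable surface for an inadequate dwelling; facility codes sampled
  from the matching ladder rungs; the smallest room count consistent with
  the drawn crowding state — households of ≤3 members cannot be overcrowded,
  so there the realized flag follows the raw fields);
* demographics: household size 1 + Poisson(3.5) (mean 4.5, ≥1 guaranteed);
  under-5 share 0.15 by default (the design assumption; 0.11, an observed
  value, is a config away); female share 0.53;
* outcome: individual-level Bernoulli with logit link over the seven
  household covariates plus under-5 status, so true adjusted odds ratios
  equal exp(β) by construction. Default β are the study-scale effects
  (aOR 0.55 indoor cooking, 1.79 inadequate materials, 0.68 constant water,
  0.60 basic hygiene, 1.20 basic sanitation, 1.51 education, 1.51 wealth,
  1.9 under-5). The intercept is calibrated by solving
  `mean(expit(β0 + η_i)) = 0.15` over the realized linear predictors
  (Brent's method), so overall prevalence matches the design prevalence;
* missingness: each household is independently invalid with probability
  0.10; one of the eight required variables is masked (an invalid materials
  answer blanks all three surfaces; an invalid outcome masks every member).

What the generator does **not** emulate: within-household outcome
correlation beyond shared covariates, seasonality, street-network random
walk sampling, measurement/recall error, and correlation *between*
deprivation fields beyond co-located cores. Passing tests therefore
demonstrate the pipeline's correctness and calibration under the stated
model, not the epidemiology of any real settlement.

## Numerical and testing choices

* Logistic fits: statsmodels Newton MLE behind the module surface; the 2×2
  single-predictor identity (MLE odds ratio = cross-product ratio) is the
  test oracle, swept exhaustively over small tables.
* Permutation engine: per focal household, `nperm` uniform k-subsets of the
  remaining values via random-key argpartition; one `numpy` Generator seeded
  from the run seed drives all layers in order, so outputs are reproducible
  byte-for-byte.
* Calibration tests run at reduced but representative sizes — 50 seeds of a
  600-household single-site design for odds-ratio recovery, 20 seeds of a
  500-point CSR field for type-I error, 20 seeds of a single 50 m core for
  detection power, 200 datasets of n=1500 for CI coverage — sizes at which
  the binomial error of the asserted proportions is well inside the asserted
  bounds.
* Geometry: shapely for polygons and containment; GeoJSON via plain JSON
  documents (RFC 7946), coordinates to 7 decimals (~1 cm).

## Known limitations

* Wald CIs and p-values only; profile-likelihood CIs are out of scope.
* No correction for household clustering of individuals (see above).
* The JMP ladder lookup is generic; studies must adapt the code tables.
* The LJC stage tests each layer and site separately without multiplicity
  correction by default (the optional FDR mode addresses this when desired).
* Join-count inference conditions on the observed event count per site;
  cross-site or bivariate co-location statistics are not implemented.
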