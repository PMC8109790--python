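# Methods

## The diagnostic problem

Cranberry fertilization is conventionally guided by comparing tissue
nutrient concentrations with fixed regional sufficiency ranges. Those
ranges are averages across cultivars, sites, climates and management
regimes, so the comparison silently assumes every other growth factor is
near optimum. `crancoda` implements the alternative: treat the tissue
test as a *composition*, find high-yielding reference specimens that
share the diagnosed bed's factor combination, and read the nutrient
imbalance off the log-ratio geometry between the two.

## Compositional representation

A tissue test reports ten nutrients (N, P, K, Mg, Ca, B, Cu, Zn, Mn, Fe,
g kg⁻¹ dry weight). These are parts of a whole: the dry-weight
measurement unit of 1000 g kg⁻¹. A filling value

    Fv = 1000 − Σ nutrients

completes the composition, so every specimen lives on the 11-part
simplex. All geometry is done in log-ratio coordinates:

- **clr**: clrᵢ = ln(xᵢ / g(x)), with g(x) the geometric mean of all 11
  parts; clr vectors sum to zero.
- **ilr** under a sequential binary partition (SBP): for a contrast of
  r parts against s parts, ilr = √(rs/(r+s)) · ln(G_r/G_s), with G the
  group geometric means. The default SBP first separates the ten
  nutrients from Fv, then macronutrients {N,P,K,Mg,Ca} from
  micronutrients {B,Cu,Zn,Mn,Fe}, then cascades left-to-right inside
  each group in the fixed part order. Because any valid SBP is an
  orthonormal basis, distances are invariant to this choice; only the
  coordinate values depend on it. The cascade is a deterministic
  convention, fixed so coordinates are reproducible.
- **Aitchison distance** ε: the Euclidean norm of the clr difference
  over all 11 parts. Computing it over the *full* composition,
  including Fv, is the convention that reproduces the worked reference
  distances (0.66, 0.99 exactly; 1.65 vs a published 1.64, i.e. one
  unit in the last printed digit) from their printed rows.
- **Perturbation vector** p = X ⊖ x*: component-wise ratio of diagnosed
  over reference concentrations. Ratios > 1 read as relative excess,
  < 1 as relative shortage; nutrients are ranked by |ln ratio|
  descending. Raw ratios are the default report; a re-closed variant
  (ratios summing to the part count) is available because the formal
  simplex perturbation is defined up to closure. A ratio within
  |ln ratio| ≤ 0.01 (configurable) is tagged balanced — below any
  agronomically meaningful contrast.

Zero or missing concentrations are rejected, not imputed: log-ratio
math is undefined at zero, and silent replacement rules would leak into
every downstream distance.

## Classification and the reference bank

Bed-years are labelled high- or low-yielding about a cutoff (default
40 t ha⁻¹, above the ~30 t ha⁻¹ regional average; *high* requires
strictly exceeding it). A random forest (500 trees, √p features per
split, fixed seed — stability preferred over tuning) relates the label
to the survey features; categorical features are one-hot encoded.
Metrics come from seeded stratified k-fold cross-validation with
k ∈ {5, 10, 20} (default 10): AUC and CA = (TN+TP)/n are computed from
*out-of-fold* predictions only, and the same out-of-fold predictions
define the confusion quadrants. Using refit predictions instead would
optimistically inflate the true-negative bank; we never do. Probability
ties at 0.5 resolve to "imbalanced". Records are canonically sorted by
key before fold assignment so metrics are invariant to input order.

The reference bank consists of the true negatives — high-yielding and
predicted balanced. False negatives (low-yielding but predicted
balanced) may be flagged in as additional benchmarks when the TN set is
small; false positives and true positives never enter, since
high tissue levels from luxury consumption or contamination at low
yield are exactly what the confusion-matrix screen removes.

Diagnosis is then:

- **local** — nearest bank specimen in Aitchison distance (ties break
  to the higher yield, then key order), by default restricted to the
  same cultivar when the bank has it (the report records the filter
  used); the neighbour's yield is the *attainable yield*;
- **regional** — the bank-average composition (arithmetic mean of raw
  concentrations, re-closed; a geometric-mean variant is kept behind a
  flag because published average rows do not always state their
  convention), with no attainable yield since the average is a
  statistical construct;
- **quartile ranges** — Q1/Q3 of raw bank concentrations
  (linear-interpolation quantiles), the compatibility intervals
  analogous to published sufficiency ranges.

## Carryover modelling

Reserves stored in year *t* affect yield in year *t+1*. The panel pairs
each bed-year with its consecutive successor (gap years form no rows;
an exclusion list drops damaged site-years before pairing). Six nested
random-forest regressions predict Y_{t+1} from C_t (entered as ilr
coordinates under the default SBP — raw-concentration mode is retained
behind a flag), F_t (seven seasonal doses), Y_t, and soil tests.
Folds are grouped by bed so years of the same bed never straddle a
split. Next-year classification about the cutoff yields a predictive TN
bank; predictive diagnosis is mechanically identical to local diagnosis
against that bank.

## The synthetic survey generator

The survey data behind the published analysis are not deposited, so the
generator emulates their statistical structure; every downstream stage
is exercised against it.

- **Design**: 10 sites × 20 beds × 5 consecutive years = 1000 bed-year
  records by default; regions Quebec/Wisconsin (3:1), cultivar mix
  dominated by 'Stevens' (70%), conventional/organic 85/15.
- **Tissue**: log-normal around a region×cultivar optimum anchored at
  the across-region true-negative average (N 10.6, P 1.1, K 5.4,
  Mg 2.0, Ca 8.9, B 0.052, Cu 0.004, Zn 0.021, Mn 0.355, Fe 0.117
  g kg⁻¹), jittered per region×cultivar (0.03/0.10 log units
  macro/micro). Bed-year variation: 0.08 log units for macronutrients,
  0.35 for micronutrients — micronutrients are deliberately far more
  variable, reproducing the dominant feature of real tissue surveys.
- **Yield**: Y = yield_max · m · exp(−(ε/τ)²) + carryover + noise, with
  yield_max per site uniform on 45–65 t ha⁻¹, m a bounded [0.8, 1.2]
  climate/soil modifier (a smooth function of summer temperature, pH
  displacement from 4.75 and Mehlich-3 K), ε the Aitchison distance of
  the tissue composition from the local optimum, τ = 1 distance unit,
  and Gaussian noise of 3 t ha⁻¹. The Gaussian decay is a smoothness
  choice with a single interpretable scale; it puts the average yield
  near 30 t ha⁻¹ with roughly a fifth of bed-years above the 40 t ha⁻¹
  cutoff, matching the field situation the cutoff was designed for.
- **Carryover**: from the second year on, yield gains
  β_store · z(prior N+K dose) and loses β_dep · z(prior yield)
  (β_store = 2, β_dep = 3 t ha⁻¹ per SD), standardized with *fixed*
  constants (dose 90 ± 45 kg ha⁻¹, yield 30 ± 10 t ha⁻¹) rather than
  dataset moments so the planted effect is closed-form checkable.
  Years are otherwise conditionally independent.
- **Covariates**: site-level soil tests (log-normal around field-typical
  values), Dirichlet texture closing to 100%, bulk density at three
  depths, three soil-series labels, monthly May–October temperature and
  precipitation around a seasonal baseline.

Generated records carry a non-serialized latent block (optimum,
potential, carryover term, noise draw) so `plant_defect` can multiply
one nutrient by exp(δ), re-close, and re-evaluate the yield under the
identical draw; records read back from CSV have no latent block and
cannot be re-planted.

What the generator does **not** emulate: real Quebec/Wisconsin climate
normals or soil-series chemistry, cultivar pedigree effects, within-bed
temporal autocorrelation of tissue tests, spatial correlation between
beds, and any direct effect of current composition on next-year yield
beyond the dose/yield carryover terms. Passing tests therefore show
that the pipeline recovers structure *of this kind* when present; they
do not certify accuracy numbers on the real survey, which is why
survey-scale published accuracies are checked as orderings and bounds,
not values.

## Experiment sizes and numerical choices

- Property suites run on 1000 random compositions (log-uniform over
  field-plausible concentration ranges) and 10 random SBPs; isometry
  and clr-sum tolerances are 1e-9, metric symmetry 1e-12.
- The planted-defect recovery experiment plants a single ±0.5 log-unit
  defect on each of 200 otherwise-balanced beds and diagnoses against
  the TN-average (regional) reference of a bank built end-to-end
  (classifier → quadrants → bank, false negatives flagged in). The
  regional reference is the right oracle here: a planted defect is a
  deviation from the population standard, whereas any single
  nearest-neighbour reference carries micronutrient sampling noise of
  the same order as the defect (0.35 vs 0.5 log units by design), which
  caps single-neighbour top-1 identification well below the population
  rate.
- The permutation-null experiment (20 label permutations, 5-fold CV)
  and the paired-seed carryover ordering (10 seeds, variants 1/3/6,
  5-fold grouped CV) use k = 5, the smallest of the supported fold
  counts, which leaves the comparisons paired while keeping forest
  refits modest.
- Report JSON prints distances at 2 decimal places (matching the
  published tables) with full precision in a `raw` block.

## Known limitations

- The classifier's out-of-fold TN bank on the default synthetic survey
  is small (tens of specimens): with 500-tree forests on n = 1000, the
  learned probability of exceeding the cutoff rarely clears 0.5 for the
  minority high-yield class. The bank-building API is unaffected; real
  surveys with stronger feature–yield coupling yield proportionally
  larger banks.
- Next-year R² on the default synthetic panel is far below published
  survey values because the generator makes next-year tissue shocks
  unpredictable by design; only the variant orderings are meaningful.
- The regional-average worked distances published alongside the
  local ones (0.82/1.77) do not recompute from the published rounded
  average row under either averaging convention; they are not asserted
  anywhere.
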