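# Methods

This note documents the models, parameter choices and numerical conventions
behind `trialmorb`, and what the synthetic-data tests do and do not show
about real data.

## Drug-defined comorbidity ascertainment

A comorbidity rule is a set of *include* ATC prefixes and optional *exclude*
prefixes. A medication record matches a rule when its ATC code
string-extends at least one include prefix and no exclude prefix; ATC is
hierarchical, so a 4-character prefix such as `A02B` denotes a drug class.
Prefix extension is the matching semantic throughout (the granularity is a
package choice; rule tables can pin codes down to the 7-character substance
level where needed). Exclude prefixes express drug-level carve-outs — the
shipped table removes amitriptyline (`N06AA09`) from the affective-disorders
definition because it is widely used for chronic pain.

The shipped default table defines 21 comorbidities with representative
drug-class prefixes and a conflict map for 22 index conditions (an index
condition suppresses any comorbidity judged to be the same disease, e.g.
asthma and COPD trials suppress asthma/COPD). **Both tables are
reconstructions**: curated, package-shipped CSVs that a user can replace
with their own definitions; they are not a redistribution of any proprietary
code list. The per-person comorbidity count is the number of distinct
flagged comorbidities after suppression, so it ranges over 0–21 (0–20 or
fewer under suppression) and never includes the index condition.

Exposure windows: trial concomitant medications count when started on or
before the randomisation date; records with a missing start date are
dropped (pre-randomisation exposure cannot be confirmed) and counted in the
log. Community prescriptions count when dated inside the observation year
(calendar 2011 by default, matching the primary-care extraction period the
pipeline emulates). Drug names are mapped to ATC codes through a lookup
table (a small fixture of common representative drugs ships with the
package); unresolved names become `UNKNOWN` and contribute to nothing.

## Aggregation and standardisation

Counts are aggregated into per-(condition, age-band, sex) distributions
over counts 0..`K_max` with `K_max = 12`; larger counts pool into the top
cell. Default age bands are 18–39 then 10-year bands to 80+ (the bands are
configurable; nothing in the method depends on this choice). Disclosure
control merges any non-zero cell below a threshold (default 5) into the
adjacent lower cell, scanning from the top; a violating zero-count cell
absorbs the nearest non-zero cell above it. Merging stops when all non-zero
cells meet the threshold or one cell remains. Merged distributions shift
mass downward by at most the threshold per merge — a conservative,
documented distortion that vanishes at realistic cell sizes.

Direct standardisation weights each community stratum by the pooled trial
age–sex composition for that condition:
`p_k = Σ_s w_s · n_{s,k} / N_s`, with the invariants that weights sum to 1,
the output sums to 1, homogeneous strata pass through unchanged, and the
standardised mean equals the weighted average of stratum means.

## Uncertainty quantification

**Dirichlet resampling.** For one observed count distribution the
proportion vector is drawn from `Dirichlet(n_k + α)` — the conjugate
posterior under a symmetric prior — with `α = 1` by default so empty cells
keep support. Community uncertainty is propagated per stratum: each of the
1000 draws samples every stratum independently and weight-averages them, so
strata with few patients contribute more uncertainty. Note the finite-sample
effect of the prior: each stratum's mean is pulled toward the uniform mean
(6 for 13 cells) by a factor `13α/(n_s + 13α)`. At realistic stratum sizes
(thousands) this is negligible; at small test sizes it is visible, which is
why the null-coverage validation below uses a near-zero `α`.

**Poisson random-effects meta-analysis.** For indications with several
trials, each trial's exported total count `y_i` over `n_i` participants is
modelled as `y_i ~ Poisson(n_i λ_i)` with `log λ_i ~ Normal(μ, τ²)` —
equivalent to person-level Poisson counts, but requiring only aggregates.
Priors are weakly informative and configurable: `μ ~ Normal(0, 10)`,
`τ ~ HalfNormal(1)`. The population mean count is reported as `exp(μ)` per
draw (a population-median interpretation across trials); a predictive-trial
alternative `exp(μ + τz)` sits behind a flag because either reading is
defensible. The posterior is sampled with an affine-invariant ensemble
sampler (emcee) over `(μ, log τ, log λ_1..T)` using differential-evolution
moves, which mix far better than stretch moves once the dimension passes
~10. Defaults: 1200 burn-in and 500 retained steps across ≥48 walkers,
thinned to 1000 evenly spaced draws. Bulk ESS for `μ` and `log τ` and the
mean acceptance fraction are always reported; an ESS below 100 raises a
`RuntimeWarning` rather than failing silently. A test cross-checks the
posterior against an independent Gibbs-sampler implementation (JAGS via
rjags) on a fixed dataset.

Posterior mean-count draws map to count distributions via the Poisson PMF
over 0..12; mass above 12 is kept as an explicit tail and never
renormalised. The single-trial route uses Dirichlet resampling of the
trial's own count distribution instead (a random-effects model is undefined
for one trial, and the code directs callers accordingly).

## Comparison statistics

Three pre-specified statistics are computed **per paired draw** (not as
ratios of summaries — the two orderings differ in the second decimal):
the community:trial ratio of mean counts; the ratio of the proportions with
count ≥ 2 (the usual high-multimorbidity threshold of three conditions
overall, counting the index condition); and the proportion of community
patients strictly above the trial median count. The trial median is the
smallest k whose CDF reaches 0.5 (ties resolve downward), taken from the
trial side's point count distribution. Points are means over the 1000
draws; intervals are 2.5th/97.5th *nearest-rank* percentiles (rank
`⌈p·n/100⌉`, no interpolation). Reports round to 2 decimals; internal
values keep full precision.

The published summary table for 22 index conditions ships as package data
and anchors internal-consistency checks: for asthma, hypertension,
migraine, psoriasis and psoriatic arthropathy the published trial
"% with count ≥ 2" cell (point and both interval bounds) is exactly the
Poisson plug-in transform `1 − e^{−λ}(1+λ)` of the published mean count to
2 dp, and the published osteoarthritis ratio equals the ratio of its
published means. The type 2 diabetes (printed 0.27 vs plug-in ≈ 0.19) and
osteoporosis (0.60 vs ≈ 0.61) cells do **not** satisfy the plug-in identity
— those were evidently averaged over draws rather than transformed at the
point estimate — so the checks document rather than force agreement there.

## Synthetic-data generator

The generator produces trial and community cohorts whose true comorbidity
flags are known, emulating the study design the pipeline targets:

- A person's comorbidity count is Poisson with a rate varying
  multiplicatively by age band and sex (defaults rise from 0.55 at 18–39 to
  1.8 at 80+, male 1.1× female), normalised so the marginal mean equals the
  configured mean. The age–sex structure of the emulated populations is not
  publicly documented, so these gradients are invented defaults — they exist
  to give standardisation a signal, not to be demographically accurate.
- Per-trial means are `exp(Normal(μ, τ))` — heterogeneity on the log scale,
  mirroring the inference model. Community means are fixed.
- Flags are drawn uniformly from the comorbidities *definable* for the
  index condition, and each flag is backed by one medication whose ATC code
  matches that comorbidity's rule and no other (representative codes are
  derived from the rule table and verified unambiguous), so
  classify(materialise(truth)) == truth exactly. A configurable fraction of
  records carries a resolvable drug name instead of a code.
- Decoys (on by default) exercise every filter: medications matching no
  rule, out-of-window community prescriptions and post-randomisation or
  undated trial medications whose codes *do* match rules.

`study_config()` seeds per-condition means from the published estimates
(community means 1.35–3.61; trial means roughly half), with defaults of 5
trials × 500 participants and 5000 community patients per condition —
deliberately smaller than the emulated study (116 trials, 2.3 M community
patients) so tests and examples run in seconds to minutes; test problem
sizes are stated in each test.

What passing synthetic tests shows: the coding, windowing, aggregation,
standardisation, resampling and comparison machinery is internally correct
and recovers known ground truth. What it cannot show: that the shipped rule
table matches any particular study's proprietary definitions, or that real
prescribing data are as clean as generated records (no misspelt drug names,
no multi-indication drugs beyond the encoded exclusions, no date errors).

## Validation design choices

- **Null coverage.** The end-to-end no-difference check feeds the *same*
  generated cohort down both arms (community: stratified, standardised
  Dirichlet; trial: pooled single-trial Dirichlet) with `α = 0.01` and
  decoys off. With an independent community sample the third statistic
  would compare a narrow community interval against a trial-estimated null
  whose own sampling error exceeds that interval's width — a coin flip even
  for a correct implementation — and with `α = 1` the prior pull at test
  scale is of the same order as the interval width. Matched cohorts and a
  negligible prior make the null check exact, isolating pipeline
  correctness from prior shrinkage and trial sampling noise.
- **Parameter recovery.** The main recovery run uses 20 generated trials of
  500 participants (μ = log 1.5, τ = 0.3) passed through the full coding
  path; interval calibration uses 50 replicates of 8 trials × 200 drawn
  directly from the random-effects core, sized so 50 refits stay cheap.
- **Degenerate inputs.** Zero-heterogeneity trials, single-participant
  trials, vanishing prevalence, empty medication lists, all-zero cells with
  `α = 0`, inverted date windows and out-of-band ages are all exercised and
  raise the documented errors.

## Known limitations

- Drug-name → ATC mapping ships as a small fixture; production use needs a
  full RxNorm/BNF-scale lookup, supplied by the user in the same CSV shape.
- Disclosure merging biases merged distributions downward by construction;
  the merge log records every affected cell.
- The uniform Dirichlet prior is informative at very small cell sizes (see
  above); set `prior_alpha` accordingly when strata are tiny.
- Dose, duration and adherence are out of scope: exposure is binary
  (any qualifying drug in the window).
- The trial median is a point (not a per-draw) quantity, matching the
  reported statistic's definition; median uncertainty is not propagated.
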