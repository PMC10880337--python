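# Methods

## Pipeline

The screen is a new-user-style cohort comparison on prescription claims.
Stages, each a module under `src/ledd_screen/`:

1. **claims_io** — typed loading of the patient, prescription and drug
   tables; rows with a missing prescription period, daily dose or single
   dose are flagged, never silently dropped.  Exclusions run in a fixed
   order (diagnosis age >= 40; at least one PD-drug or antihistamine
   prescription; no invalid prescription rows — patient-level, since one
   unusable row makes the patient's dose history untrustworthy) and are
   reconciled in an attrition log.
2. **exposure** — prescriptions of one drug merge into episodes when the
   gap from the running coverage end to the next start is < 31 days
   (coverage-based gaps are the pharmacoepidemiology convention; a
   start-to-start rule is available via configuration).  An episode
   qualifies as exposure when its span strictly exceeds 31 days.  Exposed =
   a qualifying episode of exactly one antihistamine type; patients with a
   qualifying episode plus any second antihistamine are excluded
   (`excluded_multi_type`, dropped rather than returned to the pool);
   everyone else is unexposed.  The exposed index date is the first
   prescription of the first qualifying episode (the literal first-ever
   prescription can be selected instead); the unexposed index date
   transfers the exposed group's median diagnosis-to-index interval onto
   each unexposed patient's diagnosis date.  Per-drug screens use per-drug
   medians; the overall screen the overall median.
3. **ledd** — levodopa-equivalent conversion (`factor` rules; `adjunct`
   rules for COMT inhibitors as a fraction of concurrent levodopa; `none`
   for decarboxylase inhibitors) and time-averaged daily LEDD over the
   half-open 90-day windows `[index-90, index)` and `[index, index+90)`.
   "Three months" is fixed at 90 days — calendar months are irreproducible
   across index dates.  Prescriptions spanning a window edge contribute
   pro-rata.  The window value is cumulative LED-days divided by 90, which
   puts results on the daily-dose scale; a `cumulative` switch returns the
   raw sum.
4. **matching** — maximum-likelihood logistic propensity model on sex, age
   at diagnosis, cumulative pre-index PD-drug coverage days, and pre-index
   LEDD (separation or non-convergence falls back to an L2-penalised fit
   with a warning).  Greedy 1:3 nearest-neighbour matching without
   replacement on the probability scale, exposed processed in descending
   score order (hardest first; ties by patient id), caliper 0.25 x pooled
   score SD.  Strict mode drops exposed units that cannot fill all three
   slots, so matched controls are exactly 3x the retained exposed.
5. **screen** — the increment ratio (mean over patients of
   `100*(after-before)/before`; zero-baseline patients excluded and
   counted, the only definition-preserving choice), a Welch t-test on the
   per-patient ratio lists (Student optional; two identical constant
   samples give p=1), optional Benjamini–Hochberg adjustment (off by
   default — the screen reports raw p-values per drug), and the report
   assembly over the overall cohort, antihistamine generations, and each
   drug.  The mean-of-ratios and the ratio-of-aggregate-means are distinct
   statistics computed by distinct code paths and reported in separate
   columns; they coincide only when all baselines are equal.

All dates are integer day offsets from a study epoch, all intervals
half-open, which makes coverage arithmetic exact and the whole pipeline
bit-reproducible: a fixed seed and configuration yield a byte-identical
report.

## Synthetic cohort model

`synthetic.generate_population` emulates a national-claims extract:

* **Latent trajectory.** Each patient's levodopa-equivalent need is
  piecewise-constant over 90-day blocks and grows multiplicatively by a
  per-patient progression rate `p ~ Normal(9, 15)` percent per block
  (negative rates — dose reductions — occur; trajectories truncate at
  zero).  Blocks are anchored at the patient's *index timeframe*: the
  first antihistamine prescription for exposed patients, diagnosis + the
  nominal median interval (752 days) for unexposed.  `baseline_ledd ~
  Normal(250, 50)` mg/day is the level of the pre-index block, matching
  the scale of published screens of this design.  Because growth is
  constant (multiplicative) on each side of the index, the window-averaged
  percent change is independent of where a 90-day window sits relative to
  the block grid — this keeps the unexposed group, whose transferred index
  is not block-aligned, exactly comparable under the null.
* **Exposure and effect.** Exposure prevalence 0.08 (the cohort arithmetic
  of published screens: roughly 26k single-type users among 334k analyzable
  patients).  Exposure multiplies post-index increments by
  `1 - exposure_effect`, so the latent exposed increment ratio is
  `p*(1-effect)` in closed form.  Confounding enters as
  `confounding_strength` log-odds of exposure per SD of a latent severity
  that also sets baseline LEDD — so matching has genuine covariate work to
  do.
* **Dispensing.** PD drugs (levodopa 80%, pramipexole 12%, ropinirole 8%,
  doses divided by their LED factors) renew on a 30-day grid aligned with
  the dose blocks: dose revisions happen at renewal visits.  Treatment
  initiation is delayed after diagnosis by a bounded lognormal (median 120
  days, capped so that treatment is established at least 270 days before
  the index window — an initiation inside the pre-index window would turn
  the ratio's denominator into a coverage artifact).  Antihistamine users
  get 3–6 scripts; the first gap is short (so intended exposure always
  qualifies and latent truth groups equal recovered groups) and later
  gaps mix below/above the 31-day grace period, exercising episode
  splitting.  5% of users receive a second antihistamine
  (`excluded_multi_type` downstream); 10% of non-users receive one
  sub-threshold script.
* **Data pathologies.** 2% of prescription rows lose one of
  period/daily-dose/single-dose, clustered within a ~10% subset of
  patients (record quality clusters by provider; clustered corruption
  keeps the expected row fraction while leaving patient-level attrition
  near 10% instead of the ~70% i.i.d. corruption would cause at ~60 rows
  per patient).  1% of patients are deliberately diagnosed before age 40.

### What the generator does *not* emulate, and why

Two realism knobs exist but default to zero, because each breaks the
calibration of the *published analysis design itself* (a plain unpaired
t-test on matched data), not of this implementation:

* `severity_progression_corr` — when progression correlates with the
  severity that drives exposure and baseline LEDD, propensity matching
  selects controls whose outcomes are mutually correlated; the matched
  control mean is then overdispersed (~1.4x in our measurements) and the
  unpaired t-test anticonservative.  Real cohorts plausibly have such
  correlation; results from this design should be read with that caveat.
* `dose_noise_sd` — random per-script dose noise enters both the matching
  covariate (pre-index LEDD) and the ratio denominator, coupling selection
  to outcomes the same way.  Claims doses are in reality deterministic
  pill quantities, so the default of zero is also the more realistic
  choice.

Similarly, the diagnosis-to-first-antihistamine interval is lognormal with
median 752 days and log-SD 0.25: with a much wider spread, the
median-transfer index design leaves no common support on the pre-index
coverage covariate (unexposed coverage is hard-capped at the median
interval), making long-interval exposed patients unmatchable *in
principle* — an intrinsic limitation of the transfer design worth knowing
about when applying it to real data.

Passing tests on this generator therefore demonstrate that the pipeline
recovers known effects and does not manufacture them under its stated
assumptions; they do not certify the design against outcome-correlated
confounding, informative adherence gaps, diagnosis-code noise, death or
censoring, none of which are modelled.

## Numerical and design choices

* Episode building, classification, window aggregation and matching are
  deterministic; ties break by patient id (matching additionally prefers
  the lower score at equal distance).
* The caliper is interpreted in pooled-score-SD units (the convention of
  the standard matching software); absolute-probability units are a
  parameter away.  Distances are on the probability scale, logit on
  request.
* Degenerate inputs: empty exposed sets raise; drugs with zero qualifying
  exposed patients are reported as `skipped` rows, not errors; a t-test on
  two identical constant samples returns p=1; unknown drug codes raise an
  error naming the code.
* Problem sizes in tests and the acceptance script — 1,000-instance oracle
  sweeps, 200 null replicates at n=2,000, 20 confounded replicates at
  n=5,000 — were chosen so the binomial/KS tolerances of each check are
  meaningful at desk scale.
* Post-match balance is judged by standardised mean differences with the
  conventional 0.1 threshold; at ~350 matched exposed the SMD *estimator*
  has an SE near 0.05, so balance criteria are evaluated across replicates
  rather than demanded of every single draw.

## Known limitations

* LEDD escalation is an indirect progression surrogate; the screen cannot
  distinguish slower progression from prescribing inertia.
* The unpaired t-test ignores the matched structure; a cluster-robust or
  paired analysis would be more defensible (kept as-is for fidelity to the
  design being reproduced).
* Increment ratios are ill-defined at zero baseline and unstable at tiny
  baselines; exclusion-and-count is a convention, not a solution.
* Greedy nearest-neighbour matching is order-dependent by construction;
  optimal matching is out of scope.
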