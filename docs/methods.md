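# Methods

`slmarker` implements a three-stage procedure for discovering prognostic
immunohistochemistry (IHC) markers in oral squamous cell carcinoma (OSCC),
guided by a prior list of synthetic-lethal (SL) gene pairs, together with a
ground-truth synthetic-data generator that makes every stage testable
without patient data.

## 1. Expression screen

**Model.** Input is a linear-scale expression matrix (genes × samples) with
a cancer/control label per sample (the default study dimensions are 57
cancer and 22 control tissues) and a two-column list of candidate gene
pairs. Processing:

1. *Quantile normalization.* Each column is replaced, rank for rank, by the
   across-column mean of the sorted columns. Ties are resolved by stable
   sort position rather than tie-averaging; both choices make the operation
   exactly idempotent, and the positional rule is simpler. The operation is
   label-free, so it is never re-run inside the permutation loop (re-running
   it would be a no-op).
2. *Log ratios.* For each gene, log2(cancer intensity / mean control
   intensity). The control average is taken on the linear intensity scale
   and then logged; log base 2 throughout.
3. *Regulation calls.* A three-level call per (gene, cancer sample): up if
   the log2 ratio is ≥ log2(c), down if ≤ −log2(c), neutral otherwise, with
   the fold cutoff c = 1.5 for screening (1.4 is kept as a configurable
   relaxation for external-validation reruns). Boundaries are inclusive.
4. *Pattern fractions.* For an ordered pair (A, B), the fraction of cancer
   samples showing each of the four joint patterns (up,up), (up,down),
   (down,up), (down,down). Samples with a neutral call on either gene count
   only in the denominator, so the four fractions sum to at most 1.
5. *Permutation null.* Each rearrangement re-assigns which samples act as
   the control set (class sizes preserved), recomputes log ratios, calls and
   the pattern fraction over the new cancer set. The p-value is the
   add-one-corrected upper tail (1 + #{permuted ≥ observed}) / (n_perm + 1),
   which avoids p = 0 and is super-uniform by construction. For small
   cohorts an exhaustive mode enumerates every control-set choice and
   returns the exact tail proportion. The default tests the (up,up) and
   (down,up) patterns; all four are available. The default n_perm is 10,000.
6. *FDR.* Storey q-values per tested pattern across pairs. π0 is estimated
   with the Storey–Tibshirani smoother: π0(λ) = #{p > λ}/(m(1 − λ)) on the
   grid λ = 0.05, 0.10, …, 0.95, a natural cubic spline through those
   points evaluated at the largest grid point, clipped to (0, 1]. Below 20
   p-values the smoother is unstable and the fixed-λ = 0.5 point estimate is
   used. With π0 = 1 the q-values reduce exactly to Benjamini–Hochberg.
7. *Panel selection.* A pair enters the initial panel when
   max(f_uu, f_du) ≥ 15%. Pairs containing KRAS must reach 25% to qualify
   through their (down,up) fraction — KRAS has a low mutation rate in oral
   cancer and contributes a disproportionate number of candidate pairs, so
   its discordant route is held to a stricter bar; its (up,up) route keeps
   the ordinary threshold. An include-list lets prior-knowledge pairs enter
   regardless, flagged as such.

**Calibration note.** On null data generated at the default 10% background
call rate the joint-pattern fractions are mostly zero (the probability that
a given sample shows a specific joint pattern is (0.05)² = 0.25%), so the
permutation p-values are heavily tied at 1 and the test is conservative at
small α. This is a property of the discrete statistic, not a fault of the
permutation scheme; the super-uniformity bound P(p ≤ α) ≤ α is what the
tests assert.

## 2. IHC panel

Each stain is a protein read in one cellular compartment — nucleus (N),
cytoplasm (C) or membrane (M). Per-core intensity grades on the ordinal
scale 0 / ± / 1+ / 2+ / 3+ are coded 0, 0.5, 1, 2, 3; the linear coding
makes core averaging well defined. A patient's score per stain is the
arithmetic mean over the available cancerous cores (nominally three;
tissue loss is routine, so one or two are accepted), and percent-positive
readings are averaged the same way.

Cutoff rules are small conjunctive expressions over the aggregated grade
and percent (e.g. `<1+`, `≤1+`, `≥1+ and ≥10%`, `>0%`), parsed at panel
load time so malformed panels fail before any call is made. The call
semantics is **over iff the over-rule holds, under otherwise**; loading
additionally verifies on a score grid (grades 0–3 in steps of 0.25,
percents 0–100 in steps of 5) that the stated under- and over-rules never
both hold. The complement semantics matters for the one conjunctive rule in
the default panel, where an intermediate score (intensity passes, percent
fails) is classified under. The packaged default panel holds 29 stains over
21 proteins, 8 of which are assayed in two compartments; percent-based
rules are evaluated on the aggregated percent, and a `>0%` over-rule means
strictly positive (its `≤0%` complement means exactly zero).

Markers are single stains or ordered stain pairs with a direction pattern
(e.g. (↓,↓)): a patient is in the risk group iff every component call
matches its arrow, versus "otherwise". Pair enumeration takes all C(n,2)
unordered stain pairs minus pairs staining the same protein in two
compartments — 29 stains give 406 − 8 = 398 pairs. Patients missing any
component call are excluded marker-wise (complete case per marker).

## 3. Survival screen

Overall survival in months with a death indicator, administratively
censored at 120 months (10-year overall survival); censoring at the horizon
can only remove events, never add them. Per marker:

* the ≥5-patient rule: the risk group **and** its complement must each hold
  at least `min_subset = 5` patients, otherwise the marker is recorded as
  `skipped_small_subset` and not fitted (the symmetric guard prevents
  degenerate one-sided fits);
* a two-group log-rank test (1 df, two-sided);
* a univariate Cox proportional-hazards model on the binary indicator;
* a stage-adjusted Cox model, stage coded III–IV vs I–II.

Cox models use the Efron tie approximation via lifelines, with Newton
tolerances tightened (`precision 1e-12`, relative log-likelihood `1e-18`)
so estimates agree with an independent numerical optimizer of the partial
likelihood to well under 1e-6 even on small flat toy likelihoods. Hazard
ratios are reported with 95% Wald intervals on the log scale; model-level
evidence is the likelihood-ratio χ² against the null (or a supplied nested)
model. Constant covariates are rejected; monotone partial likelihood
(complete separation) is returned flagged `converged=False`, never
silently. Each stain is screened once with the over-pattern — the Cox model
on a binary indicator is orientation-symmetric, so screening the under
orientation would duplicate every test — and stain pairs are screened over
all four direction patterns. No multiplicity correction is applied across
the marker screen; a Benjamini–Hochberg column is emitted for reference
but plays no role in selection.

Stepwise covariate entry (for habits/age style candidates) is
forward-backward minimization of the partial-likelihood AIC with the base
covariates (marker, stage) never dropped. Note the statistical fine print:
a candidate independent of outcome still enters whenever its chance LR χ²
exceeds 2, i.e. with probability P(χ²₁ > 2) ≈ 0.157, so "no null candidate
selected" holds in roughly 84% of replicates per candidate, which is what
the tests assert.

Two-marker combinations intersect risk subsets: a marker whose pattern
subset showed *reduced* hazard contributes the complement of its subset
(so every component of a combination points at excess risk); a
`combine_protective="as-is"` switch disables the complementing. The joint
indicator is tested with the stage-adjusted Cox model under the same
subset-size rule. By default only the strongest `combine_top = 8`
significant markers are combined pairwise, mirroring the scale at which
such combination tables are practically reported.

## 4. Synthetic data generator

The generator defines the study conditions; its defaults are fixed, not
tuned.

**Expression.** Background log2 intensities are Gaussian per gene (means
uniform on [4, 10]), giving log-normal linear intensities. The noise scale
σ is derived from a configurable *background call rate* (default 10%): σ =
log2(1.5) / (z₀.₉₅ · √(1 + 1/n_control)), so an unplanted gene crosses the
1.5-fold cutoff against the averaged controls in about 10% of cancer
samples. For each planted pair, round(f · n_cancer) cancer samples receive
coordinated fold shifts of log2(1.5) + 1.0 log2-units in the pattern's
directions — large enough that noise almost never erases a planted call.
Defaults mirror the study: 57 cancer, 22 control samples.

**Cohort.** 160 patients by default. Background stain calls follow a
Gaussian-copula threshold model with configurable over-prevalence (default
0.5) and pairwise latent correlation (default 0). Each planted marker draws
a Bernoulli(prevalence) risk indicator; risk patients get exactly the risk
pattern on the marker's stains, the rest a uniformly drawn non-matching
pattern (planted markers should therefore use disjoint stains). Per-core
grades are then sampled from the set of constant grades satisfying the
intended call's rule side; because every rule is a conjunction of one-sided
thresholds, any mean of such grades still satisfies them, so core-level
noise can never flip the intended call — the generated score table always
reproduces the intended call table exactly. Survival times are exponential
with hazard = baseline · exp(Σ β_m · risk_m + β_stage · late-stage), with
baseline 0.02/month (median untreated survival ≈ 35 months), independent
exponential censoring at 0.008/month, stage drawn at (0.43, 0.16, 0.12,
0.26)-style early-heavy probabilities and a planted late-stage log-HR of
log 3.15. Demographics and habits are independent nuisance columns.

**What the generator does not emulate:** probe-level microarray structure,
batch effects, gene–gene correlation beyond the planted pairs, inter-rater
scoring disagreement, non-proportional or time-varying hazards, competing
risks, and informative censoring. Passing tests therefore demonstrate that
the pipeline recovers known truth under a clean proportional-hazards,
independent-censoring world, not that it is robust to those violations.

**Non-collapsibility.** Hazard ratios are non-collapsible: the marginal HR
of a marker in a population with an independent omitted risk factor is
attenuated below the conditional HR. Recovery checks therefore compare
like with like — the univariate-recovery scenario (planted HR 3) is run
with the stage effect switched off, while the headline scenario (planted
HR 7.5, prevalence 8%) keeps the stage effect and checks the
stage-*adjusted* estimate.

## 5. Numerical and design choices

* Every stochastic operation takes an explicit seed and flows through one
  `numpy.random.Generator`; the CLI default seed is 20210415. Generators
  are bit-reproducible given (truth, seed), and two pipeline runs with the
  same config and seed write byte-identical numeric outputs.
* Permutation p-values use the (1+b)/(N+1) estimator; exhaustive mode
  returns the exact proportion. Fraction comparisons use a 1e-12 slack to
  absorb floating-point ties.
* Pair identity: stain pairs are unordered for enumeration, but markers
  store an order so pattern arrows bind to named stains.
* Problem sizes in the test-suite simulations (replicate counts, gene
  counts, permutation counts) are chosen so each statistical check has
  conventional Monte-Carlo slack (2–3 SE) around its expected value at a
  few minutes' total runtime; the acceptance script scales the same
  computations to single-run size.

## 6. Known limitations

* The screen treats gene symbols as given; no probe-to-gene mapping or
  batch correction is attempted.
* The IHC rule language covers conjunctions of one-sided thresholds only —
  exactly what the packaged panel needs — not disjunctions or ranges.
* Stepwise AIC explores single add/drop moves; it does not enumerate all
  covariate subsets.
* Combinations are pairwise; triplets and higher are out of scope (subset
  sizes collapse quickly at realistic prevalences in any case).
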