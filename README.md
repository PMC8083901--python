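# slmarker

Synthetic-lethality-guided discovery of prognostic immunohistochemistry
(IHC) marker pairs in oral squamous cell carcinoma (OSCC).

## The problem

Single-protein IHC markers rarely stratify OSCC patients well. This package
implements a screening procedure that starts from a prior list of
synthetic-lethal (SL) gene pairs — pairs whose joint perturbation kills a
cell while either alone does not — and narrows it to a small panel of
stainable proteins whose *paired* expression patterns predict overall
survival:

1. **Expression screen.** For each candidate pair (A, B), compute the
   fraction of cancer samples showing each joint regulation pattern —
   (up,up), (up,down), (down,up), (down,down) — where up/down means a
   ≥1.5-fold change of the quantile-normalized intensity against the
   averaged non-cancerous controls, f_pat = #{samples with pattern}/n.
   Significance comes from a label-permutation null (re-assigning which
   samples act as controls; p = (1+b)/(N+1), N = 10,000 by default) with
   Storey q-values for FDR control. Pairs with max(f_uu, f_du) ≥ 15% enter
   the panel (25% for the (down,up) route of KRAS pairs).
2. **IHC panel.** A packaged 29-stain panel (21 proteins, 8 in two cellular
   compartments) with per-stain over/under cutoff rules over the ordinal
   grade scale 0/±/1+/2+/3+ (coded 0, 0.5, 1, 2, 3; per-patient score =
   mean over up to three cancerous cores). The 29 stains combine into 398
   distinct pairs (C(29,2) = 406 minus 8 same-protein pairs).
3. **Survival screen.** Per marker (a stain, or a stain pair with a
   direction pattern such as CSNK1E(C)↓-SHC1(N)↓ vs "otherwise"):
   administrative censoring at 120 months, a ≥5-patient rule on both sides
   of the split, a log-rank test, a univariate Cox proportional-hazards
   model (Efron ties) and a stage-adjusted Cox model (III–IV vs I–II),
   reporting HR with 95% Wald CI and the likelihood-ratio χ². Stepwise/AIC
   covariate entry and pairwise combinations of significant markers (with
   protective markers contributing their complement) complete the screen.

A synthetic-data generator produces expression matrices, IHC score tables
and proportional-hazards survival cohorts with known ground truth, so the
whole pipeline is testable end to end. See `docs/methods.md` for models,
assumptions and design choices.

## Worked example

The numbered scripts under `analysis/` run the full study on synthetic
data. `01_simulate_data.py` generates the inputs (57+22-sample expression
matrix with three planted co-expression pairs; a 160-patient cohort scored
on the 29-stain panel with a planted HR-7.5 under-under pair and a planted
HR-3 over-over pair); the later scripts screen them:

```
$ python analysis/02_expression_screen.py --seed 11 --n-perm 1000
screened 23 pairs; 3 pass the fraction thresholds
  SLA1-SLB1: f_uu=0.40 f_du=0.00 q_uu=0.023 q_du=1 (f_uu)
  SLA2-SLB2: f_uu=0.00 f_du=0.30 q_uu=1 q_du=0.023 (f_du)
  KRAS-SLB3: f_uu=0.00 f_du=0.35 q_uu=1 q_du=0.023 (f_du)
```

All three planted pairs — and none of the 20 background pairs — pass the
selection rule, with their planted pattern fractions (0.4, 0.3, 0.35)
recovered and q < 0.05.

```
$ python analysis/03_ihc_calls_and_pairs.py
called 160 patients on 29 stains (21 proteins)
29 stains -> 398 distinct pairs (same-protein pairs excluded)

$ python analysis/04_survival_screen.py
1621 markers screened; 1621 tested (0 skipped by the subset rule); 91 significant at p < 0.05
  BRCA1(N)↓-CDH3(C)↓: n_risk=12/160 HR=9.61 (5.04-18.32) p=6.36e-12 | adjusted HR=13.29 p=6.76e-14
  PIM1(C)↓-RAD54B(N)↑: n_risk=41/160 HR=2.32 (1.57-3.44) p=2.81e-05 | adjusted HR=1.85 p=0.00285
  ...
```

The top hit is exactly the planted HR-7.5 pair (BRCA1(N)↓-CDH3(C)↓ in this
panel ordering): 12 of 160 patients carry the under-under pattern and their
estimated hazard ratio is 9.61 (95% CI 5.04–18.32), significant after
stage adjustment. `05_combine_markers.py` then intersects the strongest
markers pairwise and reports stage-adjusted hazard ratios for the joint
risk groups.

The same stages are available as a CLI (`slmarker simulate`,
`screen-expression`, `select-panel`, `call-ihc`, `enumerate-pairs`,
`survival-screen`, `combine`, `run-all`) driven by a YAML config with flag
overrides; `run-all` writes per-stage tables, a run log and a summary, and
is byte-deterministic given a seed.

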