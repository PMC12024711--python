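# Methods

`splenopt` implements an offline (observational-data) treatment-prescription
pipeline for blunt splenic trauma. Three interventions are compared:
non-operative observation (OBS), splenic angioembolization (AE), and
splenectomy. The pipeline estimates, for every patient, what their
in-hospital mortality risk would have been under each of the three arms, and
then fits a small axis-aligned decision tree that prescribes one arm per
leaf so as to minimize the cohort's mean estimated mortality.

## 1. Counterfactual rewards (AIPW)

For patient *i* with covariates *x_i*, received treatment *T_i* and outcome
*Y_i* (death = 1), the reward for arm *t* is the augmented
inverse-propensity-weighted score

    Γ_i(t) = μ̂_t(x_i) + 1{T_i = t} · (Y_i − μ̂_t(x_i)) / ê_t(x_i),

with μ̂_t the outcome model (mortality risk under arm *t*) and ê_t the
propensity model (probability of receiving *t* given *x*). The score is an
unbiased estimate of the counterfactual mortality if **either** nuisance
model is correct (double robustness). Rewards are mortality probabilities on
the scale to be *minimized*; entries can leave [0, 1] because of the
correction term and are deliberately not clamped.

Nuisance estimation:

* Both models are **cross-fitted** with stratified k-fold (default k = 5):
  every patient's predictions come from models trained on the other folds,
  so no observation is scored by a model trained on itself.
* The default family is a random forest, mirroring common practice for
  trauma-registry risk models. Probability calibration drives the
  hyperparameters: `min_samples_leaf = 50` for the three-class propensity
  forest (leaf class fractions on a 3 % arm need large leaves) and 25 for
  the outcome forest. A logistic family is available for tests and
  diagnostics.
* The forest **outcome model is a single forest over covariates plus
  treatment-indicator features** ("S-learner"), predicted with the
  indicator set to each arm in turn. Per-arm fits would train the AE risk
  model on ~3 % of the cohort and degenerate to a near-constant; the shared
  fit borrows the dominant patient-risk structure (shock index, grade, GCS,
  age) across arms.
* Propensities are clipped into [0.01, 0.99] (configurable) before
  weighting; the count of clipped values is carried in the reward
  provenance. With this floor, no reward entry can differ from μ̂ by more
  than 100.

## 2. Policy trees

A policy tree routes a patient by binary threshold splits — `feature <
threshold` goes left, `≥` goes right, matching the clinical reading "shock
index below the cutoff" — and prescribes one arm per leaf. Fitting
minimizes

    mean_i Γ_i(π(x_i)) + cp · (number of splits)

subject to a maximum depth and at least `min_leaf` (default 20) training
patients per leaf. Leaf arms are the within-leaf reward argmin; ties prefer
the less invasive arm in the fixed order OBS < AE < SPLENECTOMY.
`prescription_strength` of a leaf is the mean reward gap between its best
and second-best arm (drives the DOT export's color intensity). A missing
value at a split follows the branch the majority of training rows took.

The optimizer is a randomized local search:

1. **Greedy grow** — recursively take the best single split (thresholds at
   midpoints of adjacent observed values; nodes over 600 rows subsample to
   48 evenly spaced candidate cuts). At nodes with two remaining levels a
   cost-gated two-step lookahead enumerates root cuts with each side
   optimized as the better of a leaf and its best split.
2. **Coordinate-descent refinement** — repeatedly revisit internal nodes,
   proposing prune-to-leaf and re-split moves. A candidate is verified by
   exactly recomputing its subtree's contribution (leaf arms re-optimized)
   and accepted only when the penalized objective strictly decreases, so
   the objective is monotone non-increasing.
3. **Restarts** — the best of `n_restarts` starts: deterministic greedy
   first, then randomized starts (random feature subsets; fully random
   trees for shallow fits).

An exhaustive enumerator (`exhaustive_policy_tree`, guarded to depth ≤ 2
and n ≤ 2,000) provides the exact optimum for verifying the local search;
it is written independently of the search code.

### Tuning

`tune` grid-searches maximum depth (default 3–8) × complexity penalty cp
(default {0, 10⁻⁴, 10⁻³, 10⁻²}), scoring each cell by the mean validation
reward its prescriptions select. Because AIPW scores are heavy-tailed on
rare arms, the raw validation minimum systematically favors noise-chasing
deep trees; selection therefore uses the **one-standard-error rule**: among
cells within one SE of the best validation value, the simplest tree wins
(fewest splits, then smallest depth, then smallest cp). The winner's
settings are refit on train + validation combined.

## 3. Pipeline protocol

Per hemodynamic stratum (SBP < 70 vs ≥ 70 mmHg by default; stratification
can be disabled):

1. 50/50 train/test split, stratified jointly on (treatment, outcome);
   singleton cells go to training with a warning.
2. The test half gets its own cross-fitted nuisances and rewards — no
   information flows from training to test.
3. The training half is split 50/50 again for tuning, and the two inner
   halves **also get independent nuisance fits**. This recursive use of the
   per-half-independence device matters: if inner train and validation
   shared one outcome-model fit, its local biases would appear in both and
   the validation value would endorse trees that chase them.
4. The tuned tree is evaluated on the test half: the held-out DR policy
   value (the headline "predicted mortality under the prescribed policy"),
   the observed test-half and full-stratum mortality, a naive plug-in value
   (outcome model only, diagnostic), the unconstrained row-wise argmin value
   (a lower bound every tree obeys), and a per-leaf table of crude observed
   death rates by arm actually received (empty cells are NA, never 0).
5. Artifacts per stratum: tree JSON + Graphviz DOT, report JSON + text,
   tuning table CSV, and a provenance block (seeds, versions, clip counts,
   leakage bookkeeping). One integer seed drives a single generator stream
   for every stage, so a run is byte-reproducible.

A stratum too small for the leaf constraint or for per-half cross-fitting
(any arm under 4·k_folds patients) is skipped with an explicit warning — at
realistic cohort sizes the SBP < 70 stratum is only ~2.5 % of patients.

## 4. Synthetic cohort generator

Real multi-center registry extracts for this question are access-restricted,
so the generator is a first-class module that emulates one:

* **Covariates.** Age, sex, SBP, heart rate, respiratory rate, GCS, BMI,
  ED intubation, AAST splenic grade 1–5, pRBC and whole-blood transfusion
  within 1 h, five comorbidity flags and seven concomitant-injury flags.
  Marginals approximate a large blunt-splenic-trauma registry (median age
  38, IQR 26–56; SBP 124, 107–141 mmHg; grade 4–5 ≈ 25 %; overall mortality
  ≈ 8 %; treatment mix ≈ 84 % OBS / 13 % splenectomy / 3 % AE). A single
  latent severity factor z couples them the way hemorrhagic shock does:
  higher z lowers SBP and GCS, raises heart rate, grade and transfusion.
* **Assignment.** Softmax of per-arm linear scores loading on grade, shock
  index and transfusion — sicker patients preferentially get splenectomy.
  Naive arm comparisons are therefore confounded by construction; this is
  deliberate and load-bearing for demonstrating the DR estimator.
* **Outcomes.** Per-arm mortality logit = shared risk index s(x) (age,
  shock index, grade, GCS, transfusion, intubation, TBI) + a per-(leaf,
  arm) offset, where "leaf" is the region of the **planted policy**: a
  depth-2 tree splitting shock index at 1.5, then splenic grade ≥ 4 on the
  stable side and early pRBC transfusion on the shocked side (observe
  low-grade stable patients; embolize high-grade stable and shocked
  untransfused patients; operate on shocked transfused patients). Because
  the offsets give the planted arm the strict minimum in every region and
  the logistic link is monotone, the planted policy equals argmin_t p_t(x)
  everywhere *by construction* — no tuning or Monte-Carlo search involved.
* **Margin sizing (power).** The per-region offsets are sized so each
  recoverable planted split's reward gain clears roughly 2.5 paired
  standard errors of the DR validation value at the inner-half sizes a
  20,000-patient cohort implies: the grade-4/5 AE benefit is ≈ 0.10
  absolute mortality, the shocked-region gaps 0.10–0.25. Smaller, subtler
  margins are perfectly realistic clinically but are statistically
  unidentifiable at these sizes with a 3 % arm — a testbed that cannot be
  passed by a correct method tests nothing.
* **Oracle columns.** True per-arm risks (p_obs, p_ae, p_splen) are stored
  with the data and excluded from every model feature list by name; they
  power ground-truth checks (`true_policy_value` Monte-Carlo integrates the
  prescribed risk over fresh covariate draws and reports a standard error).

What the generator does **not** emulate: real joint covariate
distributions beyond one severity factor, missingness (optional in SBP
only), center-level clustering, coding errors, or time-varying physiology.
Passing tests on it therefore shows the estimator and optimizer work when
their assumptions hold — not that the learned trees transfer to registry
data.

## 5. What the validation exercises show

* **Descriptive arithmetic** (treatment mix, overall and per-arm mortality,
  grade-5 shares) is exact on reconstructed count tables.
* **Optimizer exactness**: at depth ≤ 2, n = 400, the local search attains
  the exhaustive enumeration optimum in ≥ 95 % of 20 seeded replicates.
* **Planted-policy recovery**: one end-to-end pipeline run at n = 20,000
  recovers a policy agreeing with the planted optimum on ≥ 90 % of an
  independent sample with true-value regret ≤ 0.01. Recovery is
  seed-stochastic: a Poisson-level deficit of deaths among the ~150 AE
  recipients of some covariate region (probability of order 10 % per draw)
  can make AE spuriously attractive in both inner halves at once, in which
  case the run honestly reports a worse policy. Roughly five of six seeds
  recover cleanly; the acceptance script reports the median of three
  replicates.
* **Double robustness**: the DR value of the planted policy stays within
  2 SE of the Monte-Carlo truth when either the outcome model is replaced
  by confounded per-arm marginal rates (with oracle propensities) or the
  propensities are replaced by uniform 1/3 (with the oracle outcome model),
  at n = 20,000.
* **Direction of effect**: across 20 seeds at n = 20,000 (with
  runtime-reduced settings: 60-tree forests, 3 folds, depth grid 3–5, cp
  grid {10⁻³, 10⁻²}, 2 restarts), the estimated mortality under the learned
  policy falls below the observed test-half mortality in ≥ 18 seeds.
* **Within-leaf observed rates**: the per-leaf table flags the arm with the
  lowest crude observed death rate. On *randomized* synthetic assignment
  this matches the oracle-best arm in ≥ 80 % of leaves; on the default
  confounded preset it frequently does not — observation is selectively
  given to milder patients — which is precisely the bias the DR scores
  correct and a caveat that applies equally to such tables computed on real
  registries.

Problem sizes in the test-suite and acceptance script (n = 20,000 cohorts,
20 replicates/seeds, 10⁵ Monte-Carlo draws) are the package's validation
design choices; the generator and estimator accept arbitrary sizes.

## 6. Numerical conventions and degenerate inputs

* Quartiles: linear interpolation on the inclusive empirical distribution
  (numpy default), used everywhere.
* Split semantics: strictly-less goes left; thresholds at midpoints of
  adjacent observed values; a row equal to the threshold goes right.
* Arm tie-breaks: fixed order OBS < AE < SPLENECTOMY (clinical
  conservatism, deterministic output). Grid ties: smallest depth, then
  smallest cp.
* Empty cohorts raise undefined-value errors for rates (never return 0);
  an arm with fewer than 2·k_folds patients raises an estimation error
  naming the arm; `min_leaf · 2^depth > n` reduces depth to the feasible
  maximum with a recorded warning; shock index with non-positive SBP is an
  error, not infinity.
* All randomness flows from one integer seed through a single
  `numpy.random.Generator` stream per run; derived seeds stay below 2³¹.

## 7. Known limitations

* The commercial Optimal Policy Tree optimizer is proprietary; the local
  search here is validated against exhaustive enumeration only at depth ≤ 2
  and makes no equivalence claim at larger depths.
* Per-patient reward entries have no confidence intervals; bootstrap CIs
  for policy values are out of scope.
* The published cohort's tree thresholds (shock index 1.551 / 1.181) are
  artifacts of restricted data; nothing here attempts to reproduce them
  numerically.
* At a 3 % arm share, policy learning at n = 20,000 operates near its
  statistical detection limit; results at smaller n degrade quickly and the
  pipeline makes no attempt to hide that.
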