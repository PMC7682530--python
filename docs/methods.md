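# Methods

## Problem and estimand

A three-arm randomized trial yields i.i.d. triplets (Y_i, X_i, A_i): a scalar
outcome (larger is better), a p-vector of mixed continuous/categorical
baseline covariates, and an arm label A ∈ {1, 2, 3} with known randomization
probabilities P(A|X) = 1/3.  An individualized treatment rule (ITR) D maps
covariates to an arm.  Its value

    V(D) = E[ I(A = D(X)) / P(A|X) · Y ]

is the mean outcome had everyone been treated per D; the optimal rule D*
maximizes V.  The package estimates D* with five learners and evaluates any
rule with the plug-in inverse-probability-weighted (IPW) estimator of V
(divide by n, not by the weight sum; a Hájek-normalized variant is available
behind a flag), misclassification against a known truth, and the empirical
ITR effect δ(D) — the mean outcome among subjects whose observed arm agrees
with D minus the mean among those whose arm disagrees.  For a constant rule,
δ contrasts one arm against the pooled others.  δ is undefined (a distinct
error signal, not numeric zero) when either group is empty.

## Learners

**Penalized least squares (GL / HGL).**  A linear model on the basis
(1, X, A, XA): dummy-coded covariate main effects, K−1 arm dummies, and all
covariate-by-arm interaction blocks.  GL applies a group lasso at the factor
level (each covariate's dummies, the arm block, and each interaction block is
one group, penalty weight √(group size), intercept unpenalized via centering).
HGL uses the glinternet-style overlapped-group formulation: each interaction
group is augmented with copies of its two parent main-effect blocks, so a
selected interaction always implies nonzero parent main effects (strong
hierarchy) while weak-main-effect interactions remain discoverable.  The
optimizer is FISTA with gram-matrix gradients, group soft-threshold prox,
adaptive restart (the momentum sequence otherwise stalls on plateaus — the
convergence criterion additionally must hold on five consecutive iterations),
warm starts along a 50-point λ path log-spaced four decades below λ_max, and
the minimum-CV-MSE λ over 5 folds (not 1-SE).  Columns are standardized
internally and coefficients returned on the original scale.  The rule is the
per-subject argmax of the K predicted means.

**Adaptive contrast weighted learning (ACWL).**  Per-arm outcome regressions
μ̃_a (default: gradient-boosted trees, 500 trees, depth 3, learning rate 0.05,
via the histogram implementation; a linear option exists) are corrected by the
doubly-robust AIPW construction μ̂_a(X_i) = μ̃_a(X_i) + I(A_i = a)/π_a ·
(Y_i − μ̃_a(X_i)).  Sorting the K pseudo-estimates per subject gives ordering
labels l_1..l_K (ties broken by arm index) and contrasts C1 = μ̂_(K) − μ̂_(K−1),
C2 = μ̂_(K) − μ̂_(1).  The rule is a CART classifier predicting the optimal
label l_K with per-subject weight C2 (C1 is implemented; C2 is the reported
default), pruned along the cost-complexity path by weighted 5-fold CV with the
1-SE rule; minimum leaf size scales as n/400 (at least 5).  All classification
weights zero falls back to the majority label with a warning.

**Direct learning (D-learning).**  For each arm pair {a, i} (a < i), subjects
on those arms are coded A_ai = ±1 and the linear decision function f_ai
minimizes Σ (2·Y·A_ai − xᵀβ)² / P(A|X) (ordinary weighted least squares;
an l1-penalized variant with CV-chosen λ sits behind a flag but is off by
default).  Anti-symmetry f_ia = −f_ai is exact by construction.  The
multi-arm rule is argmax_a Σ_{i≠a} f_ai(x).  Under uniform randomization the
weights are constant and cancel; they are carried explicitly anyway.

**BART posterior-argmax.**  A sum-of-trees model for E(Y|X, A) with the arm
supplied as dummy inputs so trees can split on any arm contrast.  The sampler
is standard Bayesian backfitting MCMC with grow (0.25) / prune (0.25) /
change (0.5) Metropolis–Hastings proposals per tree per sweep, conjugate
normal leaf-mean draws, and an inverse-gamma error-variance draw.  Defaults
follow the conventional prior: 200 trees, depth prior base 0.95 / power 2,
leaf scale k = 2 after internally mapping Y to [−0.5, 0.5] (σ_μ = 1/(2k√m)),
σ² ~ νλ/χ²_ν with ν = 3 and λ calibrated so P(σ < sd(Y)) = 0.90, 100
cutpoints per variable on a quantile grid, minimum 5 observations per leaf,
100 burn-in sweeps, 1000 kept draws.  The ITR assigns each subject the arm
with the largest posterior mean of E(Y|X = x, A = a).  Posterior ITR-effect
summaries contrast mean predicted outcomes at the observed arms between
rule-concordant and rule-discordant subjects per draw (mean and 2.5/97.5
percentiles).  The "optimized ITR" reference assigns, within each draw, every
subject that draw's argmax arm; its per-draw value dominates any fixed rule's
per-draw value exactly, which is the dominance property we test.  The
per-draw-varying rule is non-achievable in practice and is flagged as such.

## Benchmark simulation settings

Six data-generating processes share Y = m(X) + 0.5·Δ_A(X) + ε, ε ~ N(0, 1),
m(X) = 1 + 0.5·X4 + 0.3·X5, arms uniform on {1, 2, 3}, and five independent
covariates (U(−1, 1), except setting 5: X1 discrete uniform {1..5} treated as
categorical, X2 Bernoulli(0.5)).  The interaction functions cover tree-type
(1, 6), linear (2), nonlinear (3, 4 — setting 3 with a between-covariate
product), and discrete-covariate (5) structure; in setting 6 arm 1 is optimal
for every subject (Δ1 ≥ 2 > Δ3 = 0 > Δ2).  The true optimal arm is
argmax_a Δ_a(X) with ties to the smallest arm index (ties have probability
zero except at the discrete point masses of setting 5).  The evaluation test
set is drawn once per setting from a dedicated seed stream and reused across
replicates — the zero across-replicate SDs reported for the trivial setting
are only consistent with a fixed test set.  A Monte-Carlo oracle of the
population value E[m(X) + 0.5·Δ_{D(X)}(X)] provides a diagnostic that does
not depend on any finite trial sample (e.g. the all-arm-1 rule in setting 6
has value 1 + 0.5·(0.25 + 2) = 2.125).

## Synthetic donor cohort

The donor generator emulates the structure of a two-year three-arm
inter-donation-interval trial in male donors (arm 1 = 12-week, 2 = 10-week,
3 = 8-week).  It is a negative-binomial-attendance / per-attendance
Bernoulli-deferral process: 19 baseline covariates (11 continuous, 8
categorical with fixed level lists) drawn independently on realistic scales;
attendances ~ NegBin with per-arm means (3.9, 4.8, 5.8) and dispersion 30,
chosen so per-arm mean units collected (≈ 3.7 / 4.5 / 5.3) and the all-8-week
fixed-rule donation effect (≈ +1.2 units) sit at the levels reported for
trials of this design; each attendance is a low-hemoglobin deferral with
logistic probability (intercept −4.3, frequency slope 1.2 → per-arm deferral
rates ≈ 0.013 / 0.024 / 0.043, all-8-week effect ≈ +0.027) depending on
standardized baseline hemoglobin (−0.9) and prior donations (+0.25);
non-deferred attendances yield one unit with probability 0.97.  By
construction G ≤ attendances and R̃ ≤ attendances on every draw.  With the
default, quantitative-only interactions, shorter intervals are better for
collection and worse for deferral for *every* donor, so the true
benefit-optimal rule is all-8-week and the true deferral-optimal rule is
all-12-week.  A nonnegative `qualitative_strength` adds a hemoglobin-by-
frequency term of opposite sign that reverses the utility-optimal arm for
low-hemoglobin donors, generating genuine heterogeneity under
U = G − b·R̃.  The deferral-rate target is analyzed as arcsin(√(1−R))
(variance-stabilizing, strictly decreasing in R, so maximizing it minimizes
the deferral rate); R at zero attendances is set to 0 with a logged warning
(real analyses exclude zero-attendance donors; the generator may produce
them).  What the generator does *not* emulate: the joint (correlated)
covariate distribution of a real donor register, donor return behavior after
deferral, and any seasonal or site structure — passing tests therefore show
method correctness under a controlled truth, not performance on real
registry data.

## Orchestration and reproducibility

The simulation harness derives replicate r's seed as master + r and reuses
the per-setting fixed test set, so identical configurations reproduce
identical reports; method failures are tallied and excluded from that
method's summary rather than aborting the study.  The application harness
draws repeated 4:1 train/validation splits of a cohort; per target (donation;
deferral via the transform; utility at each b in {1..5}) it reports
validation-set assignment proportions and ITR effects on G, R, R̃ and U, with
across-split SDs that measure repeatability of the splitting only.  CV tuning
is nested inside each split's training part.  The identity
δ_U = δ_G − b·δ_R̃ holds exactly for any rule and split and is tested
exactly.  Reports serialize to tidy CSV and JSON.

## Problem sizes in the shipped checks

The acceptance checks replicate the benchmark study at desk scale: the
closed-form learners run at the full n_train = 20,000 with 5–10 replicates;
the MCMC learner runs 2–3 replicates, at n_train = 20,000 (200 trees) for the
hard nonlinear setting whose reference level genuinely requires the full sample,
and at n_train = 8,000 (100 trees, 300 kept draws) for the tree-type and
discrete settings where the decision boundary is recovered comfortably below
full scale.  These sizes are the package's own desk-scale choices; the
corresponding tolerance bands are stated in the tests themselves.

## Known limitations

* The HGL selection indicator reports the latent (overlapped) interaction
  group; an interaction's *effective* coefficients are sums of latent copies
  and can in principle cancel (measure-zero event).
* The BART sampler is single-threaded pure numpy; it is intended for
  method-comparison studies at 10³–2×10⁴ observations, not for very wide
  covariate spaces.
* The weighted classification step of ACWL uses CART only; no alternative
  classifiers are provided.
* Inference on δ is limited to across-split variability; no bootstrap SDs.
* The BART rule object predicts only for the evaluation table it was built
  with (trees are not retained after sampling).
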