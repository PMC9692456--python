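# Methods

`frailmark` implements a chemometric workflow for small two-group biomarker
panels: a cohort of older adults split into a physical frailty & sarcopenia
group (PF&S, n = 22 by default) and controls (n = 27), each subject carrying
clinical covariates and 10 serum marker concentrations. This note documents
the statistical models, the defaults and why they were chosen, the synthetic
data the tests run on, and the numerical conventions that make results
reproducible bit-for-bit.

## Univariate stage

Continuous variables pass through a normality gate before the two-group
test. The gate is a Kolmogorov–Smirnov test with location and scale
estimated from the sample, which invalidates the classical KS null; we use
the Lilliefors correction, tabulating the null distribution of the KS
distance D by Monte Carlo (10,000 seeded draws per sample size, cached).
The Monte-Carlo p-value is (1 + #{D_null ≥ D}) / (B + 1). If *both* groups
are normal at α = 0.05, the comparison is a pooled-variance Student t-test
with df = n₁+n₂−2; otherwise a two-sided Mann–Whitney U — exact by
enumeration when n₁+n₂ ≤ 20 without ties, tie-corrected normal
approximation otherwise. Categorical 2×2 comparisons use Pearson's χ²
without continuity correction. The pooled-t and uncorrected-χ² variants are
deliberate: they are the only variants that reproduce closed-form p-values
from the published summary statistics (Welch and Yates do not).

Requiring normality in *both* groups for the t-test is the conservative
reading of a "use t when normal, else Mann–Whitney" rule. No multiplicity
correction is applied at this stage (none is standard in this kind of
exploratory panel comparison); per-marker p-values are interpreted
marker-wise.

## Correlation and clustering

Marker–marker association is examined separately per group with Pearson
correlation; the p-value uses t = r√(n−2)/√(1−r²) on df = n−2. The 10×10
matrix is clustered with Ward's minimum-variance method on the signed
dissimilarity d = 1 − r, so positively co-varying markers cluster together
and anticorrelated markers are maximally distant (clustering on |r| or r²
would instead group by association strength; the signed choice matches how
correlation heatmaps of co-regulated panels are usually read).

Ward is implemented with the Lance–Williams recurrence on *squared* input
dissimilarities:

    d²(ij,k) = [(nᵢ+nₖ)d²(i,k) + (nⱼ+nₖ)d²(j,k) − nₖ d²(i,j)] / (nᵢ+nⱼ+nₖ)

Each merge joins the pair with the smallest current criterion value; ties
break toward the lowest (cluster-id) pair, so dendrograms are deterministic.
The recorded merge height is the criterion value itself, which for
Euclidean input equals twice the increase in total within-cluster sum of
squares (scipy's `ward` heights are the square root of the same quantity;
the test suite checks both equivalences, plus an exhaustive-search oracle on
5-item instances). Heights are non-decreasing by the Ward monotonicity
property.

## PLS and PLS-DA

The core regression is PLS1 fitted by NIPALS with X-deflation only: weight
vectors are unit-norm, scores t = X_d w, loadings p = X_dᵀt/tᵀt, response
coefficients q_a = yᵀt/tᵀt. The projection matrix is R = W(PᵀW)⁻¹, so that
for new (preprocessed) data the scores are T = XR and predictions ŷ = Tq;
the composite coefficient vector is b = Rq. Both identities are asserted to
1e−8 on every fitted model, and NIPALS at A = rank(X) reproduces ordinary
least squares (tested against an independent normal-equations solve).
Components are nested, so a single fit at A_max yields the whole complexity
path — the cross-validation loops exploit this. A weight vector with norm
below 1e−12 stops extraction early with a warning (degenerate collinear
input).

Markers enter the model as log concentrations (serum panels are
right-skewed and strictly positive) and are autoscaled — centered and
scaled to unit variance with statistics from the training rows only. The
log transform can be disabled (`DCVConfig.log_transform`).

Classification uses a 0/1 dummy response (PF&S = 1). Because predictions
are real-valued, assignment applies one-dimensional linear discriminant
analysis to ŷ with equal priors and pooled variance, which reduces to the
midpoint threshold between the class means of the training predictions.
Equal priors were chosen over class-proportional ones because the 22/27
imbalance is mild and per-class accuracies should be comparable; the
positive class is a parameter. The canonical variate is ŷ shifted so the
threshold maps to zero and oriented so the PF&S training mean is negative
(the convention used when plotting the discriminant axis). "Variable
weights" reported for a PLS-DA model are the composite coefficients b on
the autoscaled inputs — sign positive means the marker pushes the
prediction toward PF&S. (Raw weights W or loadings P are alternative
definitions; b is the only one that includes the response regression and is
directly interpretable as a linear rule.)

## Kernel PLS

KPLS replaces X by an implicit feature map through the kernel
k(x,x′) = exp(−‖x−x′‖²/(2σ²)). The training kernel is double-centered,
K_c = (I − 11ᵀ/n) K (I − 11ᵀ/n); new samples are centered with training
means. Components are extracted in dual form (t ∝ K_d y_d, normalized, then
kernel and response deflated by the score projector), and predictions use
the dual coefficients B = U(TᵀK_cU)⁻¹Tᵀy. Two limits anchor correctness:
with the linear kernel, KPLS predictions equal linear PLS exactly; as
σ → ∞ the Gaussian kernel linearizes and predictions converge to linear
PLS. A constant response yields zero extractable components and the model
predicts the mean.

The kernel width is not fixed a priori: the inner cross-validation loop
selects σ from a 7-point log grid spanning a factor of 10 around the median
pairwise Euclidean distance of the (autoscaled, log-transformed) training
fold — the standard median heuristic, computed per fold so selection never
sees held-out data.

Regression quality is reported as Q² = 1 − PRESS/TSS computed from
*outer-loop held-out* predictions, pooled per repetition. Q² can be
negative; summaries floor it at zero for display but the raw value is kept.

## Repeated double cross-validation

Model complexity must not be chosen on the same data that estimates
performance. DCV nests two loops: 10 outer folds ("cancellation groups")
emulate an external test set; within each outer-training block, 8 inner
folds select complexity — the number of latent variables for PLS-DA
(maximizing inner balanced accuracy, ties toward the smallest A), or (σ, A)
for KPLS (minimizing inner RMSE, ties toward smaller A then smaller σ). The
selected model is refit on the whole outer-training block and predicts the
held-out fold. The entire procedure is repeated (default 50 times) with
reshuffled partitions, giving distributions for accuracy, Q², selected
complexity, per-sample canonical-variate scores, and coefficients.

Partitions are stratified: each class is dealt, in seeded shuffled order,
to the currently smallest fold, keeping fold sizes within 1 of each other
and per-fold class counts within 1 of proportionality (49 subjects in 10
folds gives nine of 5 and one of 4). A partition that still produces a
single-class fold is re-drawn (logged, at most 100 attempts). Seeding uses
one master seed spawning one independent stream per repetition, so any
repetition is individually reproducible.

Overall accuracy is pooled over all outer-loop samples of a repetition;
per-class accuracies are also emitted (both flavors are common in reports).
Confidence intervals are percentile intervals across repetitions.

## Variable significance

Which markers "significantly contribute" is decided from the stability of
the composite coefficients across all repetitions × outer folds. The naive
rule — percentile interval of the raw coefficient samples excludes zero —
is badly anticonservative here: outer-fold coefficients are delete-d
jackknife replicates of the full-data coefficient, and since outer-training
sets overlap by ~(k−2)/k, their raw spread understates the sampling
variance roughly k-fold (measured null false-positive rate ≈ 0.44 at a
nominal 0.05). We therefore use the delete-d jackknife variance,
(k−1)/k · Σᵢ(bᵢ − b̄)², additionally subtracting the Monte-Carlo component
contributed by partition reshuffling (estimated from the between-repetition
variance of per-repetition mean coefficients, and floored at 20% of the raw
spread so the variance can never collapse). Significance is a two-sided
normal interval at α = 0.05 around the mean coefficient. Measured on null
cohorts this rule has a per-variable false-positive rate ≈ 0.04, and it
recovers a planted 5-of-10 informative panel. The direction label ("higher
in PF&S" / "higher in controls") is the sign of the median coefficient. A
permutation-based alternative would be exactly calibrated but costs a full
DCV per permutation; the permutation test of the *overall accuracy* is
provided separately (`permutation_test_accuracy`).

The reduced model is a complete, independent DCV re-run restricted to the
selected markers — selection bias from re-using the full-model folds is
avoided, though the selection itself was made on the same cohort (an
unavoidable limitation at n = 49, and the reason reduced-model accuracy
should be read as descriptive, not confirmatory).

## Synthetic cohort generator

No subject-level data are distributed with the package; every test runs on
generated cohorts. The generator emulates the study design: group sizes
22/27; covariates drawn from per-group normal marginals matching the
published summary table (e.g. BMI 29.9±4.4 vs 26.6±2.2 kg/m², SPPB 7.8±1.6
vs 11.3±0.9 rounded and clipped to 0–12, aLM 16.3±3.6 vs 20.3±4.0 kg); sex
Bernoulli with the published female fractions (18/22, 17/27). Markers are
multivariate normal on the log scale — Cholesky factor of a per-group
correlation matrix, PF&S group shifted by a signed per-marker effect in
log-SD units, then exponentiated. Default effect directions follow the
reported group differences (TNF-α, ICAM-1, TIMP-1 higher in PF&S; IL1-β,
IL6, GFAP lower; Activin A, Serpin E1, GDF15, FGF21 null) with magnitudes
0.4–1.1 log-SD set so the per-marker tests at n = 22/27 land in the
reported significance bands. Default correlation matrices encode only the
two cluster memberships visible in the published per-group heatmaps
(constant within-block r = 0.45): {FGF21, Activin A} vs the rest in PF&S;
the inflammatory trio vs the remodeling/mitochondrial block in controls.
Log-scale locations are typical serum concentration scales with log-SD 0.5
throughout. Covariates are independent of markers by default; an optional
`sppb_marker_link` couples SPPB negatively to the latent marker profile for
regression-recovery studies.

What the generator does **not** emulate: the study's actual concentration
distributions (unpublished), assay-specific noise and detection limits,
covariate–marker confounding (age, BMI and medication effects on cytokines),
and any negative marker–marker correlations. Passing tests therefore show
that the *pipeline* behaves correctly under the study's design and
plausible effect sizes — not that it would reproduce the study's numeric
results on the real sera.

## Problem sizes and numerical conventions

- Simulation anchors use scaled-down repetition counts chosen as a
  compromise between Monte-Carlo stability and runtime: 10 repetitions for
  accuracy-calibration runs, 20 for variable-selection runs (the analysis
  default is 50).
- Chance-level band for null classification: mean outer accuracy in
  [0.40, 0.60] over 20 seeded cohorts; strong-separation anchor: ≥ 0.90
  with five markers shifted 3 log-SD.
- All tolerances for algebraic identities are 1e−8; kernel-linearization
  uses 1e−3 at σ = 10⁶.
- The Lilliefors null table uses a fixed internal seed; it is a constant of
  the package, not user randomness.
- Dendrograms, partitions and NIPALS are fully deterministic given seeds;
  `run_full_analysis` twice with one master seed serializes byte-identically.

## Known limitations

- The significance rule's jackknife variance is approximate for a
  non-smooth estimator (complexity selection changes A across folds); its
  measured calibration is slightly conservative (~0.04 at nominal 0.05).
- Exact Mann–Whitney switches to the tie-corrected normal approximation in
  the presence of ties even at small n.
- KPLS model selection is limited to the Gaussian width and component
  count; no other kernels are offered (the linear kernel exists for
  equivalence testing).
- With n = 49 and 10 predictors, outer-loop accuracy estimates carry large
  Monte-Carlo and sampling variability; repetition SDs quantify only the
  former.
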