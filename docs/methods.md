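# Methods

This note documents the models, numerical choices and limitations of
`terroirpls`. Nothing here states an empirical result that the test suite
or `scripts/acceptance.py` does not itself compute.

## Study structure and data model

The package is built around a nested multi-year survey design: 7 vineyards
(AM, BA, BM, CS, FA, MN, PM) grouped into 3 macrozones (Lake Garda: BA,
CS; Valpolicella: BM, FA, MN; Soave: AM, PM), sampled over 3 vintages
(2006–2008), 3 developmental stages (véraison to full maturity) and 3
replicate pools — 189 samples in the full layout, 63 in the single-stage
GC-MS-like layout. The macrozone is a fixed function of the vineyard; the
map is total and hard-coded.

Feature tables are sample × feature intensity matrices with a processing
state that only moves forward (raw → normalized → logged →
centered/autoscaled); class responses are dummy-coded in first-appearance
order so component signs are reproducible; constraint blocks are centered
dummy codes of the nuisance factor with **all** levels kept. The resulting
rank deficiency (rank c−1 for c levels) is deliberate — levels are treated
symmetrically — and harmless because every downstream projector uses a
pseudo-inverse (cutoff 1e-12 × largest singular value).

## Preprocessing

*Median fold change (MFC) normalization* removes per-sample dilution: the
reference profile is the per-feature median over the table's samples, and
each sample is divided by the median of its feature-wise ratios to that
reference (over features positive in both). The choice of the median
profile as reference follows common untargeted-metabolomics practice; no
designated reference sample is used. MFC with a *fixed* reference is
exactly idempotent and exactly removes scalar dilution; when the reference
is re-estimated from an already-normalized table the factors are close to
but not identically 1 — the stored-reference form is therefore what
cross-validation uses.

*Log transform* is the natural log of (x + ε), ε = 1 raw-intensity unit by
default (configurable). Any log base differs only by a constant factor
absorbed by centering or autoscaling, so the base is not a modelling
choice. *Autoscaling* uses the sample (n−1) standard deviation.

All preprocessing parameters (MFC reference, means, standard deviations)
are estimated on training rows only inside cross-validation and applied
unchanged to held-out rows, avoiding leakage.

## NIPALS engine and the orthogonal constraint

PCA is computed by SVD. PLS2-DA uses the NIPALS iteration per component
(u → w = Xᵀu/uᵀu → normalize → t = Xw → c = Yᵀt/tᵀt → u = Yc/cᵀc), with
convergence declared when the score changes by less than 1e-10 relative,
and a hard error after 500 iterations. Y is centered, never scaled, inside
the fit. Each component is sign-flipped so the largest-magnitude weight
entry is positive.

NIPALS (rather than SIMPLS or a kernel formulation) is used because the
constrained variant needs an injection point inside the weight update: for
oCPLS2-DA, w is replaced by Qw with Q the projector onto the null space of
A₀ᵀ, A₀ = XᵀZ computed from the *currently deflated* X — deflation changes
the forbidden span, so A₀ is recomputed at every component, making
tᵀZ = 0 exact for all components, not just the first. An empty constraint
gives Q = I and the code path is bitwise that of PLS2-DA. If the projected
weight vanishes (class structure entirely inside the forbidden span) the
fit aborts with a "confounded" error rather than returning a degenerate
component.

One numerical refinement: the NIPALS inner loop is a power iteration on
the (projected) cross-covariance, and its convergence rate degrades when
trailing components have nearly degenerate singular values — at A = 4 with
a 3-class response the residual Y structure is essentially noise and the
plain iteration can exceed any reasonable iteration cap. The loop is
therefore *initialized* at its own fixed point, the dominant singular
direction of the (projected) XᵀY block (an inexpensive SVD of a p × N
matrix), after which the contractual iteration converges in a few steps.
This changes no fixed point, only the starting value.

An alternative constraint strategy — pre-projecting X itself onto the
orthocomplement of Z — is exposed as `project_out_constraint` for
comparison. It is a different estimator (it removes nuisance variance from
the loadings too) and is not the default.

## Post-transformation

A fitted A-component model of N classes generically spreads class
discrimination over all A score directions. The post-transformation builds
an orthogonal G from the SVD of M = YcᵀT: right singular vectors with
nonzero singular value (relative cutoff 1e-10) span the predictive block,
ordered by decreasing singular value; the null-space vectors span the
orthogonal block, reordered by decreasing rotated-score variance.
n_predictive = rank(M) ≤ N−1. The weight matrix is rotated (W·G) and the
score rotation follows from it. Because G is orthogonal and acts inside
the fitted score space, fitted and new-sample predictions are exactly
invariant, and ‖T‖² is conserved across the split. When A < N−1 there is
nothing to split and the function warns and keeps all components
predictive.

## OPLS-DA

Orthogonal filtering peels `n_orth` components of Y-uncorrelated
structured variation from X before fitting min(N−1, rank) predictive
components. Per component the provisional loading p is projected off an
orthonormal basis of col(XᵀYc); for a two-class (rank-1) response this is
exactly the classical w_o = p − (wᵀp/wᵀw)w, and for any N it guarantees
T_oᵀYc = 0 exactly. For two classes, OPLS with k orthogonal + 1 predictive
component predicts identically to PLS with k+1 components (the classical
rotation equivalence); for N > 2 the multi-column response makes this an
approximation, so the exact equivalence is only asserted for N = 2.

The terroir-feature battery fits one OPLS-DA per candidate classification,
chooses n_orth at the first maximum of 7-fold Q², and flags a model
reliable only when Q² > 0.5 **and** the permutation test passes.
Classifications with an empty or single class are reported not-estimable
and the battery continues.

## Validation

"Full" N-fold cross-validation partitions samples so each is held out
exactly once. Folds are assigned deterministically: samples ordered by
(class, stable index) and dealt round-robin — a stratified venetian-blinds
scheme; a seed shuffles only within class. Q² = 1 − PRESS/SS, with PRESS
accumulated over every sample once and SS computed against training-fold
response means. The direct (non-cumulative) Q² of the full A-component
model is reported, since per-component cumulative Q² is never needed by
the protocol.

The permutation test shuffles only the class labels (constraint labels
stay attached to their samples), recomputes the 7-fold Q² per permutation,
and uses p = (1 + #{Q²_perm ≥ Q²_obs})/(n_perm + 1), so p is never 0. Note
the attainability constraint this implies: with n_perm = 19 the smallest
possible p is 0.05, which cannot pass a strict p < 0.05 rule — defaults
are 400 permutations (200 exposed in configuration, reflecting the two
values quoted in practice for this protocol).

Component selection takes the smallest A with Q²(A) ≥ Q²(A+1) (first local
maximum) under the constraint that the selected model passes the
permutation test; failing that, the next local maximum is tried, and if
none passes the model is explicitly rejected. A strictly increasing Q²
sequence selects max_A with an "accepted_at_max" status.

## Split-plot ANOVA

Sampling across years is randomized only within a year, so year and
replicate are whole-plot factors and producer the subplot factor:
y = μ + year + replicate + wholeplot_error(year×replicate) + producer +
residual. Year and replicate are tested against the year×replicate
stratum, producer against the residual. Sums of squares are the sequential
decomposition, which on the balanced 3×3×7 design equals the cell-means
decomposition. No year×producer interaction is included by default (the
screening model names only the three factors); a flag adds it, tested
against the residual. Designs with a single replicate level have no
whole-plot error stratum and are rejected with a clear error. The
per-feature screen reports raw p-value fractions at the chosen α (default
0.05); Benjamini–Hochberg adjustment is available behind a flag but off by
default because the screen reports raw significance fractions.

## Markers

Correlation loadings place each feature at its Pearson correlations with
the predictive scores (p(corr)) and each class-response column at its
correlations with the same scores (q(corr)). A feature becomes a marker
when |p(corr)| exceeds the threshold on at least one predictive component;
it is assigned to the class with the largest |q(corr)| on that component
and flagged negative when feature and class point opposite ways. The
default threshold is 0.5 and is configurable; 0.75 is the conventional
"strong correlation" cutoff for the terroir-feature models and is the
battery's reference value. Group aggregation uses the mean (not the sum)
of member features per vineyard × vintage so group size does not inflate
the summary.

## Synthetic study generator

Intensities follow a log-normal model: on the natural-log scale, baseline
(N(7, 1), i.e. median raw intensity ≈ 1100 a.u.) plus a monotone stage
trend with random sign (sd 0.5), vintage effects (sd 0.75), macrozone
effects (sd 0.25), vineyard-within-macrozone effects (sd 0.20) and
replicate noise (sd 0.35 ≈ 35 % CV, a realistic untargeted-LC-MS
replicate spread). Effects are drawn once per (feature, level); the share
of features carrying each effect is 0.60 (stage), 0.67 (vintage), 0.50
(macrozone) and 0.69 (vineyard) — the vintage/producer shares mirror the
proportions a univariate screen of such a survey is expected to flag. The
defaults put the vintage effect at three times the macrozone effect: the
confounded regime in which unsupervised projections cluster by vintage
(the generator's own property test checks this via silhouette comparison)
while site structure remains recoverable after constraint. Per-sample
dilution factors are log-uniform in [0.5, 2] so MFC normalization has
something to remove. Three small disjoint marker groups (6 features each)
are planted elevated in one macrozone apiece to exercise the aggregation
path.

Every drawn effect is stored in a truth record; recovery tests query the
truth rather than re-deriving it. Same seed ⇒ bitwise-identical output.

What the generator does **not** emulate: realistic metabolite correlation
networks (features are conditionally independent given the design),
missing values, chromatographic drift, heteroscedastic detector noise, and
class-dependent dilution. Passing tests therefore demonstrate the
correctness and calibration of the algorithms under the declared variance
structure, not performance on any real instrument's quirks.

## Problem sizes used in checks

The automated checks run the full 189 × 551 layout for the constrained
model and the headline accuracy comparison (10 seeds), 200 independent
21 × 6 null datasets with 49 permutations each for permutation-null
calibration, 1000 null features for ANOVA type-I error, and 20 random
datasets for the reduction-to-PLS-DA identity. These sizes keep the whole
suite in the low minutes on one CPU while leaving the statistical
assertions well-powered.

## Known limitations

- Only one constraint block is supported (multiple nuisance factors can be
  column-concatenated by the caller); continuous-covariate constraints are
  accepted (any centered Z) but untested beyond the dummy-coded case.
- The split-plot ANOVA targets balanced or near-balanced designs; strongly
  unbalanced data would need a mixed-model (REML) treatment that is out of
  scope.
- Q² is the direct 1 − PRESS/SS of the full model, not a per-component
  cumulative variant.
- The OPLS↔PLS prediction equivalence is exact only for two-class
  responses.
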