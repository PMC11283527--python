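# Methods

## Synthetic embedding model

Each extractor profile generates a samples × features table from a
class-conditional Gaussian model: all features are independent with
standard deviation `noise_sd` (default 1), and the first `n_informative`
columns add per-class mean offsets. Offsets are the vertices of a regular
4-simplex rotated by a seeded random orthonormal frame into the informative
subspace and scaled so the pairwise distance between class mean vectors is
`effect_size · noise_sd` (default effect size 3 — strong but not trivially
separable signal). When `n_informative < K−1` the simplex cannot be
embedded exactly; the projection is rescaled so the *mean* pairwise
distance matches.

Defaults mirror the benchmark's shape: four extractor profiles of
dimensions 4096 / 2048 / 1280 / 2048, 1466 samples in four imbalanced
classes (478 / 438 / 376 / 174 — a configuration default chosen once as a
plausible imbalance; the source dataset's per-class counts were never
published), 64 informative columns, and a 70/15/15 stratified split.

What the generator does *not* emulate: feature correlations within and
across CNN channels, heavy-tailed activation distributions, label noise,
and class-dependent covariance. Passing tests therefore demonstrate that
the pipeline's machinery is correct and that the selector can recover a
planted independent-Gaussian signal; they do not certify performance on
real dermoscopic embeddings.

The stratified split shuffles each class with a seeded generator and
allocates counts by largest-remainder rounding (ties to the earlier
partition), guaranteeing per-class proportions within one sample, exact
conservation of rows, and determinism given the seed.

## Grey-wolf wrapper selection

Positions are continuous per-feature values initialized uniformly on
[−1, 1], symmetric around the logistic transfer's 0.5 point so the initial
selection probability is unbiased at threshold 0.5. Each iteration computes
the exploration coefficient `a` (linear `a₀(1 − t/T)` for the classical
variant, quadratic `a₀(1 − t²/T²)` for the modified one, which dominates
the linear schedule at every interior iteration), then moves every wolf
toward the three current best by the standard update with per-dimension
independent uniform draws (r₁ then r₂ per leader, leaders in
alpha/beta/delta order — the contract the oracle tests replay).

Control defaults per variant: population 10, T = 100; classical — a₀ = 2,
exploitation rate 0.5, stopping ε = 1e−6; modified — a₀ = 1.5,
exploitation rate 0.3, ε = 4e−7. The exploitation rate ρ maps to the
binarization threshold θ = 1 − ρ applied to the logistic transfer with a
strict inequality (ties excluded); θ = 0.7 under the modified variant is
what drives its much smaller selected subsets. The run stops early once
the best fitness improves by less than ε over 10 consecutive iterations.
If an entire population binarizes to empty masks the threshold is
degenerate and the run aborts with a dedicated error; a single empty-mask
candidate simply receives worst fitness.

**Fitness.** The selection objective is a nearest-centroid class-separation
margin: z-score the selected columns on train statistics, compute class
centroids on train, and average over validation samples the difference
(distance to the nearest wrong-class centroid − distance to the own-class
centroid). It is fast enough for thousands of wrapper evaluations, zero
for indistinguishable classes, and grows with genuine class separation.
The fitness is a pluggable callable, so a wrapper-accuracy objective can
be substituted without touching the optimizer.

## Classifier battery and metrics

The six families map to sklearn estimators behind a train-fitted
`StandardScaler`: polynomial-kernel SVMs of degree 1/2/3 (coef0 = 1,
C = 1), single-hidden-layer networks of width 25 and 100 (500-iteration
budget), and a bagging ensemble of linear discriminant learners on random
half-size feature subspaces without bootstrapping (30 learners). The
ensemble vote averages predicted class probabilities; with one learner on
the full subspace it reduces exactly to a single discriminant fit. Widths
and degrees are exposed as hyperparameters.

Metrics are computed one-vs-rest per class from the test-split confusion
matrix and macro-averaged (unweighted class mean; micro pooling is
available). Per class the complementary identities ACC + ER = 1,
SV + FNR = 1 and SP + FPR = 1 hold exactly and survive macro averaging.
A ratio with a zero denominator contributes 0 and is flagged on the
result rather than propagating NaN into the decision matrix.

## CRITIC and RAPS

CRITIC min-max normalizes every criterion column with a single orientation,
takes the population standard deviation σ_j of each normalized column and
Pearson correlations ρ between columns, forms the information index
c_j = σ_j Σ_k (1 − ρ_jk) and normalizes to weights. If all criteria are
perfectly correlated the index sum is zero and weights fall back to
uniform by symmetry. The packaged reference weights reproduce exactly from
the published information indices; recomputing CRITIC from the published
decision matrix yields close but not identical weights, consistent with
the source's intermediate rounding.

RAPS ratio-normalizes (benefit x/max, cost min/x), weights, and decomposes
the ideal vector into benefit/cost magnitudes Q_k, Q_h — the legs of a
right triangle with perimeter P = Q_k + Q_h + √(Q_k² + Q_h²). Each
alternative's row yields magnitudes U_ik, U_ih and perimeter P_i, and the
score is PS_i = P_i / P, which is 1 exactly for an ideal-attaining row and
bounded by 1 whenever the ideal dominates the matrix. Ranking is by
descending PS with ties broken by input order (stable), so ranks are
always a permutation of 1..n.

Two deliberate orientation choices: the ranking index is P_i / P (the
published worked rows are only consistent with this orientation, not with
the inverse), and NPV is treated as a *cost* criterion to match the
published benefit/cost split, with the conventional benefit orientation a
one-line config change. An explicit ideal row can be injected into the
normalization; the packaged best-value row differs from the matrix's own
column extremes (its ER ideal is below any model's ER), and with an
explicit ideal the ideal vector q equals the weight vector, since the
ideal normalizes to 1 in every column.

## Pipeline

The grid enumerates models profile-outer, feature-map-middle (gwo1, gwo2,
original), classifier-inner — the published A1–A51 layout; with the default
per-profile classifier sets this is 3 × (4+4+5+4) = 51 models. Selection
runs once per (profile, variant) and is shared by that profile's
classifiers; classifiers fit on the train split and are scored on the test
split. Cost-metric zeros (possible when a classifier is perfect on strongly
separated synthetic data) are floored at 1e−6 before ranking so ratio
normalization stays defined while keeping such models best on that
criterion. All stage seeds derive deterministically from the global seed.

Reduction percentages are integer-rounded 100·(1 − selected/original).

## Problem sizes in tests

The suite exercises the optimizer on a 50-feature / 5-informative test bed
(205 samples) with the full 100-iteration budget over 20 seeds for the
recovery property, and end-to-end grids at 12–51 models on 160–230 samples
with 32–64 features and shortened (8–15 iteration) selector budgets —
sizes chosen so the complete suite runs in well under a minute while still
exercising every stage at full fidelity.

## Known limitations

- The selection fitness is a proxy margin, not the downstream classifier's
  accuracy; selected subsets are classifier-agnostic by design.
- The published full ranking reproduces broadly (rank correlation ≈ 0.93,
  identical best model) but not row-for-row, because the source's printed
  intermediates are rounded to 3 decimal places.
- CRITIC weights recomputed from the decision matrix differ from the
  published weight vector (see above); analyses that need the published
  weights should pass them explicitly, as the replay tooling does.
- Synthetic data is independent-Gaussian; see the generator section for
  what that does and does not establish.
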