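# dermbench

Benchmarking pipeline for dermoscopic skin-lesion classifiers: grey-wolf
wrapper feature selection, a multi-classifier evaluation battery, and
CRITIC-weighted RAPS multicriteria ranking that picks the best model.

## The problem

Automated skin-cancer classification studies routinely train dozens of
model variants — different deep feature extractors, with or without feature
selection, different classifiers — and then face a selection problem: which
model is *best* when nine evaluation metrics partly disagree? `dermbench`
implements that whole benchmarking loop as a tested, reproducible pipeline
for a four-class lesion problem (basal cell carcinoma, melanoma, pigmented
benign keratosis, vascular lesions):

1. **Embeddings.** Class-conditional Gaussian feature tables emulate the
   outputs of four CNN feature extractors (4096 / 2048 / 1280 / 2048
   dimensions, 1466 samples, 70/15/15 stratified split). A known informative
   subset of columns carries class-separating mean offsets, so selector
   recovery can be scored against ground truth; precomputed feature tables
   load from CSV through the same interface.
2. **Feature selection.** A binary grey wolf optimizer (GWO): wolves hold
   continuous per-feature positions and move toward the three fittest pack
   members (alpha, beta, delta) under a decaying exploration coefficient

   `A = 2·a·r₁ − a, C = 2·r₂, D_L = |C·X_L − X|, X⁺ = mean_L(X_L − A·D_L)`

   with either the classical linear decay `a = a₀(1 − t/T)` ("GWO1",
   a₀ = 2) or a modified quadratic decay `a = a₀(1 − t²/T²)` ("GWO2",
   a₀ = 1.5) that stays high longer. Positions binarize through a logistic
   transfer with a strict threshold θ = 1 − exploitation rate (0.5 / 0.7),
   so GWO2 reduces features far more aggressively. Fitness is a
   nearest-centroid class-separation margin on a held-out validation split.
   Exposed both functionally and as a scikit-learn `SelectorMixin`
   transformer (`GWOFeatureSelector`) that drops into sklearn pipelines.
3. **Classification.** Six families: linear / quadratic / cubic-kernel
   SVMs, medium (25-unit) and wide (100-unit) neural networks, and an
   ensemble subspace discriminant. Nine metrics from the multiclass
   confusion matrix, macro-averaged one-vs-rest: ACC, SV (sensitivity),
   SP (specificity), PR (precision), ER, FPR, FNR, NPV, F1S.
4. **Ranking.** The 51-model grid (3 feature maps × per-extractor
   classifier sets) forms a decision matrix. CRITIC derives objective
   criterion weights `w_j = c_j / Σc` from `c_j = σ_j Σ_k (1 − ρ_jk)`;
   RAPS scores each model by the perimeter of a right triangle whose legs
   are the Euclidean magnitudes of its weighted benefit and cost
   components, relative to the ideal's perimeter:
   `P = Q_k + Q_h + √(Q_k² + Q_h²)`, `PS_i = P_i / P ∈ (0, 1]`.

## Worked example

The package ships the published 51-model benchmark decision matrix, its
CRITIC weights and the explicit ideal row as delimited-text fixtures.
Ranking it takes milliseconds:

```python
from dermbench.fixtures import (
    load_decision_matrix, load_reference_critic, load_ideal_row,
)
from dermbench.mcdm import rank_models

matrix = load_decision_matrix()
_, w = load_reference_critic()
res = rank_models(matrix, weights=w, ideal_row=load_ideal_row())
print(f"ideal magnitudes: Qk={res.Qk:.5f}  Qh={res.Qh:.5f}  P={res.P:.5f}")
print(res.to_dataframe().sort_values("rank").head(5).to_string(index=False))
```

```
ideal magnitudes: Qk=0.18347  Qh=0.30244  P=0.83966
alternative      Uik      Uih       Pi       PS  rank
         A2 0.183438 0.275312 0.789575 0.940355     1
        A10 0.182329 0.262611 0.764640 0.910659     2
         A1 0.181429 0.263343 0.764563 0.910567     3
         A9 0.181982 0.260807 0.760811 0.906098     4
         A4 0.181934 0.260621 0.760397 0.905605     5
```

`Qk` and `Qh` are the benefit- and cost-side magnitudes of the ideal
solution (the legs of the reference triangle), `P` its perimeter. Each
model's `PS` is its own perimeter over `P`; A2 — the wide neural network on
GWO1-selected AlexNet-style features — attains PS ≈ 0.940 and rank 1,
agreeing with the published ranking.

The same stages run from the shell:

```sh
dermbench report --out ranking.csv              # replay the published ranking
dermbench simulate --dimension 1280 --out f.csv # synthetic feature table
dermbench select --features f.csv --variant gwo2 --out mask.csv
dermbench benchmark --seed 0 --out-dir run/     # full 51-model synthetic grid
dermbench rank --matrix run/decision_matrix.csv --out run/ranking.csv
```

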