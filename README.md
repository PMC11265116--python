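# mvselect

Interpretable multiview learning with structured-sparse feature selection.

`mvselect` is for studies that measure two or more data modalities — *views*
— on the same samples (gene expression and DNA methylation, CpG sites and
clinical markers, any aligned multi-omics design) and need to answer two
questions at once: **what low-dimensional structure is shared across the
views**, and **which features in each view carry it**.

## The model

Views `X⁽¹⁾ … X⁽ᴰ⁾` (each `n × p⁽ᵈ⁾`, features standardized) are assumed to
be generated from one shared latent code `Z ∈ ℝⁿˣᴷ` through per-view decoder
networks `G_d` (small multilayer perceptrons; `Z` itself is a free
optimization variable, there is no encoder). Stage 1 solves

```
min_{Z, G_1…G_D}  Σ_d ‖X⁽ᵈ⁾ − G_d(Z)‖₂,₁ + λ⁽ᵈ⁾ ‖G_d(Z)‖₂,₁
```

where `‖M‖₂,₁ = Σ_j ‖M·ⱼ‖₂` is the column-wise ℓ2,1 norm. The penalty drives
whole reconstructed columns toward zero, so features that are not needed to
reconstruct a view from the shared code fade out; features are ranked by the
ℓ2 norm of their reconstructed column and the top `r` per view are selected.
When a prior feature–feature network is available (e.g. protein–protein
interactions), the penalty becomes `λ⁽ᵈ⁾‖G_d(Z) 𝓛⁽ᵈ⁾‖₂,₁` with `𝓛⁽ᵈ⁾` the
network's normalized graph Laplacian, encouraging connected features to be
selected together.

Stage 2 refits fresh decoders `R_d` and a new code `Z′` on the selected
features only, minimizing plain Frobenius reconstruction error subject to
`‖z′_i‖₂ = 1` for every sample (the unit-row constraint removes the scale
indeterminacy of jointly optimized codes and decoders). Stage 3 infers codes
for new samples by optimizing `Z′_test` against the frozen stage-2 decoders.
Downstream, an SVM (classification) or k-means (clustering) runs on the
codes.

## Worked example

Simulate the built-in two-view nonlinear benchmark (10% of features are
signals driven by a shared angle parameter; two classes occupy different
angle blocks), then run the full three-stage pipeline:

```python
import dataclasses
from mvselect.pipeline import RunConfig, run_three_stage, simulate_preset

train, _, truth = simulate_preset("setting1", seed=100)   # 350 x 500 per view
test, _, _ = simulate_preset("setting1", seed=102)
cfg = RunConfig(latent_dim=4, top=0.1, lambdas=0.5, seed=11)
res = run_three_stage(train, test=test, truth=truth, config=cfg)
print(f"test error: {res.error:.2f}%")
for d, m in enumerate(res.per_view_metrics):
    pct = m.as_percent()
    print(f"view {d+1}: TPR {pct['tpr']:.1f}  FPR {pct['fpr']:.2f}")
```

```
test error: 1.71%
view 1: TPR 98.0  FPR 0.22
view 2: TPR 100.0  FPR 0.00
```

Selection recovered 49–50 of the 50 planted signal features per view, and
the SVM on the 4-dimensional latent codes misclassified 1.71% of the test
samples — the planted class structure survives a 250-fold compression of
the feature space.

The same flow is available from the shell:

```
mvselect simulate setting1 --seed 100 --out data/
mvselect run --views data/view1.csv --views data/view2.csv \
    --labels data/labels.csv --top 0.1 --seed 11 --out run/
mvselect benchmark lattice-setting1 --laplacian --replicates 5 --seed 0
```

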