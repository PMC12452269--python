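# ianam — imaging-assisted neural additive Cox model for G–E interactions

`ianam` estimates gene–environment (G–E) interaction effects on censored
survival outcomes with a **neural additive model** (NAM) under a Cox
partial-likelihood loss, and sharpens that estimate by **borrowing strength
from histopathology imaging features** through a joint, agreement-penalized
fit. It is aimed at biostatisticians analysing cancer cohorts where gene
expression, clinical/demographic covariates, and slide-derived imaging
features are measured on the same patients — and at methodologists who want
a fully scriptable simulation bench for penalized additive survival
networks.

## The model

For subject *i* with environmental variables `d_i ∈ R^q`, gene expressions
`z_i ∈ R^r`, and imaging features `x_i ∈ R^p`, two parallel Cox models are
specified through additive predictors

    f1_i = Σ_j β_j B_j(z_ij) + Σ_{k,j} γ_kj Γ_kj(d_ik · z_ij) + Σ_k α_k A_k(d_ik)
    f2_i = Σ_j' θ_j' U_j'(x_ij') + Σ_{k,j'} μ_kj' V_kj'(d_ik · x_ij') + Σ_k η_k T_k(d_ik)

where every `B, Γ, A, U, V, T` is an *r-net*: a small one-input ReLU network
with a residual skip (`g(u) = u + net(u)`), so the linear effect is always
representable and a zeroed network is exactly the identity. The scalar
coefficients (β, γ, α, …) form a *sparse layer*: a zero coefficient excises
its variable.

Estimation minimizes

    Q = −L1(f1) − L2(f2) + R(ψ1; λ1) + R(ψ2; λ2)
        + λ3 Σ_{j,j'} c_jj' Σ_i [B_j(z_ij, d_i) − U_j'(x_ij', d_i)]²

with `L` the mean Breslow log partial likelihoods, `R` a **sparse-group
minimax concave penalty (MCP)**: for each gene the group
`b_j = (β_j, γ_1j, …, γ_qj)` is penalized through its norm (dropping the
gene *and all its interactions* together — the "main effects, interactions"
heredity) plus elementwise MCP on the interaction entries. The last term is
the **agreement penalty**: `c_jj'` is the absolute Spearman correlation
between gene *j* and imaging feature *j'*, thresholded at its 0.9 quantile,
and the penalty pulls the paired total effects toward each other, letting
the imaging model assist the G–E model. Optimization is proximal gradient
descent; the closed-form group-MCP proximal map produces exact zeros, which
define the selected variables. Tuning uses a BIC-style criterion.

## Worked example

```python
import ianam as ia

# a small banded-coupling scenario with ELU-shaped effects, ~40% censoring
design = ia.SimDesign(n=100, r=40, p=20, q=4, seed=101)
train, test, truth = ia.make_dataset(design)

pcfg = ia.PenaltyConfig(lam1=0.06, lam2=0.06, lam3=2e-4)
fcfg = ia.FitConfig(max_epochs=120, pretrain_epochs=60, learning_rate=0.05,
                    coef_learning_rate=0.3, optimizer="adam",
                    layer_sizes=(1, 8, 1), mode="joint", seed=0)
result = ia.fit_joint(train, pcfg, fcfg)

mains, inters = ia.selected_sets(result)
report = ia.tp_fp(mains, inters, truth)
wt = test.standardized()
ci = ia.c_index(result.gem.linear_predictor(wt.d, wt.z), test.y, test.delta)
print(f"selected {len(mains)} genes ({report.tp_main} true), "
      f"{len(inters)} interactions ({report.tp_inter} true), "
      f"test C-index {ci:.3f}")
```

Output:

```
selected 15 genes (9 true), 23 interactions (12 true), test C-index 0.768
```

Nine of the 15 planted gene main effects and twelve of the 25 planted
interactions are recovered at this very small n = 100, and the fitted risk
score orders the independent test subjects with concordance 0.768 (0.5
would be random; the oracle score using the true effects reaches 0.961 on
this draw). Larger samples sharpen both numbers quickly — see the
scaled-down study in `tests/test_acceptance.py`.

The same pipeline is scriptable from the shell:

```
ianam simulate --seed 1 --outdir sim --config design.yaml
ianam fit --datadir sim/train --outdir fit --mode joint --lambda3 2e-4
ianam evaluate --datadir sim/test --modeldir fit --truth sim/truth.json
ianam replicate --config study.yaml --n-replicates 10 --outdir rep
```

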