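# Methods

## Model

`ianam` fits two additive Cox models on the same right-censored outcome:
a gene–environment (G–E) model over `(z, d)` and an imaging–environment
model over `(x, d)`. Each scalar input — every gene, every environmental
variable, and every gene×environment (or imaging×environment) product —
feeds its own *r-net*, a one-input/one-output fully connected ReLU network
with a residual skip connection, multiplied by a scalar sparse-layer
coefficient. The residual skip has two roles: the linear effect is always
representable (a zeroed network is exactly the identity), and the model
class degenerates gracefully to linear Cox regression, which anchors both a
unit test (coefficient recovery against an established Cox solver) and the
linear simulation scenario.

The log partial likelihood uses the Breslow convention for ties: the risk
set of subject *i* is `{i' : Y_i' ≥ Y_i}`, so tied failures share one risk
set that includes each other. It is computed by a single sort plus a
cumulative log-sum-exp; the predictor is centred first (location
invariance) so the exponentials stay in range.

## Penalties

Selection uses the minimax concave penalty (MCP)
`ρ_a(t; λ) = ∫_0^{|t|} (λ − s/a)_+ ds` with scale `a = 3`. Gene *j*'s
coefficients form the group `b_j = (β_j, γ_1j, …, γ_qj)`; the penalty is
MCP on `‖b_j‖₂` at level `√(q+1)·λ1` plus elementwise MCP at level `λ1` on
the interaction entries only. Zeroing the group removes the gene and all
its interactions at once, which enforces the "main effects, interactions"
heredity; the surviving groups then have their individual interactions
examined by the elementwise term. The group-level multiplier `√(q+1)`
(root group size, the standard group-penalty scaling) is a deliberate
reading of an ambiguous constant and is exposed as `group_scale`.
Environmental coefficients `α, η` are never penalized.

The agreement penalty couples the models coordinate-wise:
`λ3 Σ_{j,j'} c_jj' Σ_i [B_j(z_ij, d_i) − U_j'(x_ij', d_i)]²`, where `B_j`
and `U_j'` are the *total* effects (main + interactions) of gene *j* and
imaging feature *j'*. The weights `c_jj'` are absolute Spearman
correlations thresholded at their 0.9 empirical quantile (computed once on
the training data and frozen), so roughly 10% of pairs are active. Ranks
use average-tie handling; a constant column gets correlation 0 with a
warning. Note the agreement term sums over samples and active pairs while
the likelihood terms are per-sample means, so useful `λ3` values scale
like `1/(n × active pairs per gene)`; at the problem sizes used here this
means `λ3` in the 1e-6 – 1e-4 range.

## Optimization

Proximal gradient descent: a full-batch gradient step on the smooth part
(both likelihoods plus the agreement term) for *all* parameters, followed
by the closed-form composite prox of the sparse-group MCP applied to each
group — elementwise firm thresholding of the interaction entries, then
group-norm firm thresholding of the result. The prox uses the effective
threshold `λ · step`, and exact zeros produced by the prox are the
selection; nothing is thresholded post hoc. Gradients of the batched
sub-networks are computed by an explicit backward pass (einsum-based); the
implementation is NumPy throughout and is validated against finite
differences.

Two optimizers are provided. The default plain gradient descent supports
backtracking line search (halving the step until the full objective does
not increase), which guarantees a monotone objective trace and is what the
descent property test exercises. The `adam` option applies adaptive-moment
steps **to the network weights only**, while the sparse layers keep plain
gradient steps with their own `coef_learning_rate`: adaptive rescaling
would let arbitrarily small persistent gradients (e.g. from the agreement
term) climb past a fixed prox threshold, destroying the selection
semantics. The coefficient gradient is elementwise-clipped to ±1 as a
divergence guard. The prox, not the optimizer, defines selection.

Two further choices matter in practice and were adopted after their
effect was measured on synthetic data:

- **Zero-initialized final layers.** Each r-net's last layer starts at
  zero, so every sub-net begins exactly at the identity. Randomly
  initialized output layers distort each feature before any training and
  let noise features correlate spuriously with the risk; with the
  zero-start, early dynamics coincide with a linear Cox fit and networks
  grow only where the likelihood asks for curvature. Hidden layers use
  fan-in-scaled Gaussian initialization.
- **Decoupled pretraining (`pretrain_epochs`).** With `λ3 > 0`, the first
  phase runs both models with the coupling off, then switches it on. The
  agreement gradient is meaningless while both effect estimates are still
  near their initialization; coupling half-trained models transfers noise
  rather than signal.

Tuning minimizes `BIC = 2n(npll₁ + npll₂) + log(n)·df` with `df` the
number of nonzero sparse-layer coefficients across both models, over a
user grid with warm starts along descending `λ1`. The BIC constant is a
documented choice isolated in one function.

## Synthetic data

The generator reproduces the simulation design the package is benchmarked
on: `d ~ N(0, Σ_q(0.3))` and `z ~ N(0, Σ_r(0.5))` with AR(1) correlation
`[Σ_h]_ij = ρ^|i−j|`; imaging features `x = H* z + ε` (or
`tanh(H* z) + ε`) with `ε ~ 0.05·N(0, Σ_p(0.3))` and four structures for
the `p×r` coupling matrix `H*` — banded (1 on the diagonal, 0.3 on the
first off-diagonals), diagonal, random 5% off-diagonal entries
`~ U(0.3, 0.6)`, and the elementwise-tanh nonlinear map. Survival times
are exponential with hazard `exp(−2 + f_i)`; censoring times are
exponential with the rate calibrated analytically (each subject's censoring
probability is `κ/(κ + rate_i)`; monotone root finding matches the mean to
the 40% target).

Default signal: 15 gene main effects and 25 interactions placed so that
every interaction's gene carries a main effect (heredity by construction;
a `heredity_violation` count relocates interactions for sensitivity runs).
Effect shapes: `0.8·ELU`, `1.5·sin`, tanh with (0.6, 1.0, 0.4)
main/interaction/environment coefficients, and a linear setting with
`U(0.5, 1)` coefficients drawn fresh per replicate. Main-effect genes are
evenly spaced over the *imaging-covered* block `0..min(r, p)−1`: all four
coupling structures tie imaging feature *j'* to genes near *j' = j*, so
genes beyond *p* have no imaging correlate and would be structurally
immune to the assisted-learning mechanism the package exists to study;
placing signal there would benchmark the coupling against targets it
cannot reach. Interactions are assigned round-robin over environmental
indices among the signal genes.

What the generator does *not* emulate: real expression marginals
(log-scale skew, zero inflation), batch effects, informative censoring,
and imaging features that aggregate many genes nonlinearly. Passing tests
demonstrate correct mechanics and the direction of the assisted-learning
effect under the stated Gaussian designs, not performance on real cohorts.

## Evaluation

Selection quality is TP/FP against the planted positions, for gene main
effects (a gene counts as selected when its group survives; a strict
`β_j ≠ 0` variant is available) and interactions separately. Predictive
quality is Harrell's C-index, computed by exhaustive comparable-pair
logic (`δ_i = 1, Y_i < Y_j`; ties in score count ½; tied event times are
incomparable) on an independent test draw of the same size as training
(in-sample evaluation is available behind a flag). The
`effect_agreement` diagnostic reports the mean Spearman correlation
between paired gene/imaging total-effect vectors over the active weight
pairs — the quantity the agreement penalty targets.

Covariates are standardized to mean 0 and variance 1 before fitting
(penalties are then comparable across coordinates); an evaluation set is
standardized with its own column statistics, which at the sample sizes
used here differs negligibly from reusing the training statistics under
the simulated designs.

## Problem sizes used in the shipped studies

- Toy assisted-learning study: `(r, p, q, n) = (40, 20, 4, 100)`, banded
  coupling, ELU effects, 40 replicates; joint fit `λ1 = λ2 = 0.06,
  λ3 = 2e-4`, 120 epochs with 60 decoupled, `(1, 8, 1)` sub-nets. The
  coupling raises mean test concordance and mean paired-effect correlation
  over the `λ3 = 0` ablation. The concordance gain is small at this sample
  size (~+0.01 on average, against a replicate-to-replicate SD of ~0.03),
  which is why the study uses 40 replicates; the paired-effect correlation
  gain (~+0.06) is unambiguous in every replicate batch.
- Scaled-down simulation study: `(r, p, q, n) = (100, 70, 4, 500)`,
  10 replicates, `λ1 = λ2 = 0.06, λ3 = 4e-6`, 400 epochs (150 decoupled
  for the joint fit). These dimensions keep a replicate affordable on a
  single CPU while preserving the high-dimensional character
  (r + q + qr = 504 sub-nets); penalty levels were fixed by a small pilot
  sweep instead of per-replicate BIC tuning, a degenerate single-point
  grid.
- `λ1/λ2/λ3` defaults are scenario-bound, not universal: the agreement
  level in particular must be rescaled with `n` and the number of active
  pairs (see above).

## Known limitations

- Plain proximal GD needs many epochs at useful learning rates; the adam
  hybrid converges far faster but abandons the monotone-descent guarantee.
- MCP's flat region means a noise coefficient that drifts past `a·λ`
  feels no further shrinkage; very large `coef_learning_rate` values make
  such escapes likely (hence the default 0.3 and the clip).
- The BIC constant and the exact epoch schedule are pragmatic choices;
  both are isolated (one function, two config fields) for easy revision.
- No inference (standard errors, selection p-values) is provided; the
  selections are point estimates.
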