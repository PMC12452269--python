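"""Penalized estimation of the joint gene/imaging additive Cox models.

The smooth part of the objective is the sum of the two negative log
partial likelihoods (Breslow ties) plus the lam3-weighted agreement term;
the nonsmooth part is the sparse-group MCP on each model's sparse-layer
coefficients.  Estimation is proximal gradient descent: a full-batch
gradient step on every parameter (network weights and sparse coefficients)
followed by the closed-form group-MCP proximal map on the gene-group
coefficient vectors.  Environmental coefficients take gradient steps but
are never proximal-shrunk.  Exact zeros produced by the prox define the
selected variable sets; the group structure makes the selection respect the
"main effects, interactions" heredity.

Tuning follows a BIC-style criterion, 2n * (sum of negative log partial
likelihoods) + log(n) * df with df the number of nonzero sparse-layer
coefficients across the fitted models.
"""

from __future__ import annotations

import copy
import dataclasses
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .model import (
    DEFAULT_LAYER_SIZES,
    GEModel,
    ImagingModel,
    SurvivalDataset,
    _AdditiveInteractionModel,
)
from .penalty import (
    AgreementWeights,
    PenaltyConfig,
    agreement_value,
    sparse_group_penalty,
    spearman_weights,
)
from . import penalty as _penalty_mod

__all__ = [
    "FitConfig",
    "FitResult",
    "cox_npll",
    "cox_npll_grad",
    "joint_objective",
    "prox_mcp",
    "prox_group_mcp",
    "fit_joint",
    "select_tuning",
]


# ---------------------------------------------------------------------------
# Cox partial likelihood
# ---------------------------------------------------------------------------

def _cox_core(f: np.ndarray, y: np.ndarray, delta: np.ndarray):
    """Value and gradient of the negative mean log partial likelihood.

    Risk set of subject i is {i': Y_i' >= Y_i}; tied event times share the
    same risk set (Breslow).  Computed by one sort plus cumulative
    log-sum-exp / cumulative sums, O(n log n).
    """
    f = np.asarray(f, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    delta = np.asarray(delta).ravel().astype(int)
    n = f.size
    if y.size != n or delta.size != n:
        raise ValueError("f, y, delta must have equal length")
    if n == 0:
        raise ValueError("empty data")
    if delta.sum() == 0:
        warnings.warn("all observations censored; partial likelihood is 0",
                      stacklevel=3)
        return 0.0, np.zeros(n)

    order = np.argsort(y, kind="stable")
    # centring f leaves the value and gradient unchanged (location
    # invariance) but keeps exp() in range
    ys, fs, ds = y[order], f[order] - f.mean(), delta[order]

    # log S_i = logsumexp over the suffix starting at the FIRST index of the
    # tie run of y_i (suffix in ascending order == risk set).
    rev = fs[::-1]
    lse_rev = np.logaddexp.accumulate(rev)
    lse = lse_rev[::-1]  # lse[i] = logsumexp(fs[i:])
    first = np.searchsorted(ys, ys, side="left")
    last = np.searchsorted(ys, ys, side="right") - 1
    log_s = lse[first]

    npll = -np.sum(ds * (fs - log_s)) / n

    # grad_k = -(1/n) [ delta_k - exp(f_k) * sum_{events i: Y_i <= Y_k} 1/S_i ]
    inv_s = np.where(ds == 1, np.exp(-log_s), 0.0)
    cum_inv = np.cumsum(inv_s)
    grad_s = -(ds - np.exp(fs) * cum_inv[last]) / n
    grad = np.empty(n)
    grad[order] = grad_s
    return float(npll), grad


def cox_npll(f, y, delta) -> float:
    """Negative mean Breslow log partial likelihood at fixed predictor f.

    Returns -(1/n) sum_i delta_i [f_i - log sum_{Y_i' >= Y_i} exp f_i'].
    All-censored data give 0 with a warning.
    """
    return _cox_core(f, y, delta)[0]


def cox_npll_grad(f, y, delta) -> np.ndarray:
    """Gradient of :func:`cox_npll` with respect to f."""
    return _cox_core(f, y, delta)[1]


# ---------------------------------------------------------------------------
# Proximal maps
# ---------------------------------------------------------------------------

def prox_mcp(v, t: float, lam: float, a: float = 3.0):
    """Proximal map of MCP (firm thresholding), step size t.

    argmin_u (1/(2t))(u - v)^2 + rho_a(u; lam):
    0 for |v| <= t*lam; sign(v)(|v| - t*lam)/(1 - t/a) for t*lam < |v| <=
    a*lam; v beyond.  Requires a > t for a well-posed (convex) subproblem.
    """
    if not 0 < t < a:
        raise ValueError(f"need 0 < t < a, got t={t}, a={a}")
    if lam < 0:
        raise ValueError("lam must be nonnegative")
    v = np.asarray(v, dtype=float)
    av = np.abs(v)
    shrunk = np.sign(v) * (av - t * lam) / (1.0 - t / a)
    out = np.where(av <= t * lam, 0.0, np.where(av <= a * lam, shrunk, v))
    return float(out) if out.ndim == 0 else out


def prox_group_mcp(
    b: np.ndarray, t: float, lam_group: float, lam_elem: float, a: float = 3.0
) -> np.ndarray:
    """Composite sparse-group MCP prox on one group (beta_j, gamma_.j).

    (i) elementwise MCP prox on the q interaction entries (the leading
    main-effect entry passes through); (ii) group MCP prox on the norm of
    the result, scaling the whole vector (exact zero when the norm prox is
    zero — gene and all its interactions dropped together).
    """
    b = np.asarray(b, dtype=float)
    if b.ndim != 1 or b.size == 0:
        raise ValueError("b must be a nonempty 1-D group vector")
    out = b.copy()
    if b.size > 1:
        out[1:] = prox_mcp(b[1:], t, lam_elem, a)
    norm = float(np.linalg.norm(out))
    if norm == 0.0:
        return out
    s = prox_mcp(norm, t, lam_group, a)
    return out * (s / norm)


def _prox_groups_batch(
    groups: np.ndarray, t: float, lam_group: float, lam_elem: float, a: float
) -> np.ndarray:
    """Vectorized :func:`prox_group_mcp` over the (r, q+1) group matrix."""
    out = groups.copy()
    out[:, 1:] = prox_mcp(groups[:, 1:], t, lam_elem, a)
    norms = np.linalg.norm(out, axis=1)
    shrunk = prox_mcp(norms, t, lam_group, a)
    scale = np.divide(shrunk, norms, out=np.zeros_like(norms), where=norms > 0)
    return out * scale[:, None]


# ---------------------------------------------------------------------------
# Objective
# ---------------------------------------------------------------------------

def _group_scale(pcfg: PenaltyConfig, q: int) -> float:
    return pcfg.group_scale if pcfg.group_scale is not None else float(
        np.sqrt(q + 1)
    )


def _model_penalty(model, lam: float, pcfg: PenaltyConfig, flavor: str) -> float:
    if flavor == "none" or lam == 0:
        return 0.0
    if flavor == "sparse_group":
        return sparse_group_penalty(
            model.groups, lam, pcfg.a, _group_scale(pcfg, model.q)
        )
    if flavor == "mcp_elementwise":
        return float(np.sum(_penalty_mod.mcp_value(model.groups, lam, pcfg.a)))
    raise ValueError(f"unknown penalty flavor {flavor!r}")


def joint_objective(
    gem: GEModel | None,
    im: ImagingModel | None,
    data: SurvivalDataset,
    weights: AgreementWeights | None,
    pcfg: PenaltyConfig,
    mode: str = "joint",
    penalty_flavor: str = "sparse_group",
) -> float:
    """Full objective: npll(s) + sparse-group terms + lam3 * agreement."""
    total = 0.0
    b_eff = u_eff = None
    if mode in ("joint", "ge_only"):
        out1 = gem.subnet_outputs(data.d, data.z)
        b_eff = gem.feature_effects_from_outputs(out1)
        f1 = b_eff.sum(axis=1) + gem.e_effects_from_outputs(out1).sum(axis=1)
        total += cox_npll(f1, data.y, data.delta)
        total += _model_penalty(gem, pcfg.lam1, pcfg, penalty_flavor)
    if mode in ("joint", "imaging_only"):
        out2 = im.subnet_outputs(data.d, data.x)
        u_eff = im.feature_effects_from_outputs(out2)
        f2 = u_eff.sum(axis=1) + im.e_effects_from_outputs(out2).sum(axis=1)
        total += cox_npll(f2, data.y, data.delta)
        total += _model_penalty(im, pcfg.lam2, pcfg, penalty_flavor)
    if mode == "joint" and pcfg.lam3 > 0 and weights is not None:
        total += pcfg.lam3 * agreement_value(b_eff, u_eff, weights.c)
    return float(total)


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------

@dataclass
class FitConfig:
    """Optimizer and model-architecture settings for :func:`fit_joint`."""

    learning_rate: float = 0.1
    max_epochs: int = 300
    tol: float = 1e-6
    seed: int = 0
    mode: str = "joint"  # joint | ge_only | imaging_only
    penalty_flavor: str = "sparse_group"  # sparse_group | mcp_elementwise | none
    layer_sizes: tuple[int, ...] = DEFAULT_LAYER_SIZES
    coef_init: float = 0.1
    standardize: bool = True
    backtracking: bool = True
    train_nets: bool = True  # False: sub-nets frozen at zero (linear limit)
    pretrain_epochs: int = 0  # decoupled (lam3 = 0) epochs before coupling
    optimizer: str = "gd"  # gd | adam
    coef_learning_rate: float | None = None  # sparse-layer step; learning_rate if None
    trace_every: int = 1  # adam only: objective evaluated every k epochs
    adam_beta1: float = 0.9
    adam_beta2: float = 0.999

    def __post_init__(self):
        if self.learning_rate <= 0 or self.max_epochs <= 0:
            raise ValueError("learning rate and epoch count must be positive")
        if self.mode not in ("joint", "ge_only", "imaging_only"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.penalty_flavor not in ("sparse_group", "mcp_elementwise", "none"):
            raise ValueError(f"unknown penalty flavor {self.penalty_flavor!r}")
        if self.optimizer not in ("gd", "adam"):
            raise ValueError(f"unknown optimizer {self.optimizer!r}")


@dataclass
class FitResult:
    """Fitted models, tuning values, objective trace, and selections."""

    gem: GEModel | None
    im: ImagingModel | None
    lambdas: tuple[float, float, float]
    objective_trace: list[float]
    selected_main: list[int]
    selected_inter: list[tuple[int, int]]
    selected_main_imaging: list[int]
    selected_inter_imaging: list[tuple[int, int]]
    criterion: float | None = None
    n_epochs: int = 0
    converged: bool = False
    config: FitConfig | None = None
    standardizer: dict | None = None

    def selection_table(self) -> pd.DataFrame:
        """Selected variables as a (name, type, coefficient) table."""
        rows = []
        if self.gem is not None:
            for j in self.selected_main:
                rows.append((f"G{j}", "main_G", self.gem.beta[j]))
            for (k, j) in self.selected_inter:
                rows.append((f"E{k}xG{j}", "interaction", self.gem.gamma[k, j]))
            for k in range(self.gem.q):
                rows.append((f"E{k}", "main_E", self.gem.alpha[k]))
        return pd.DataFrame(rows, columns=["variable", "type", "coefficient"])


class _ModelState:
    """Flat view of one additive model's parameters for the optimizer."""

    def __init__(self, model: _AdditiveInteractionModel):
        self.model = model

    def params(self) -> list[np.ndarray]:
        m = self.model
        return (
            [w for w in m.nets.weights]
            + [b for b in m.nets.biases]
            + [m.main_coef, m.inter_coef, m.e_coef]
        )

    def set_params(self, ps: list[np.ndarray]) -> None:
        m = self.model
        nl = m.nets.n_layers
        m.nets.weights = [p for p in ps[:nl]]
        m.nets.biases = [p for p in ps[nl : 2 * nl]]
        m.main_coef, m.inter_coef, m.e_coef = ps[2 * nl], ps[2 * nl + 1], ps[2 * nl + 2]


def _smooth_loss_and_grads(
    gem, im, data, c, lam3, mode, design1, design2
):
    """Value of the smooth objective part and gradients for all parameters.

    Returns (smooth_value, grads1, grads2) with grads ordered like
    ``_ModelState.params``.
    """
    n = data.n
    smooth = 0.0
    grads1 = grads2 = None
    b_eff = u_eff = None
    cache1 = cache2 = None
    out1 = out2 = None

    if mode in ("joint", "ge_only"):
        out1, cache1 = gem.nets.forward(design1, want_cache=True)
        out1 = out1  # (n, m1)
        b_eff = gem.feature_effects_from_outputs(out1)
        e1 = gem.e_effects_from_outputs(out1)
        f1 = b_eff.sum(axis=1) + e1.sum(axis=1)
        v1, g_f1 = _cox_core(f1, data.y, data.delta)
        smooth += v1
    if mode in ("joint", "imaging_only"):
        out2, cache2 = im.nets.forward(design2, want_cache=True)
        u_eff = im.feature_effects_from_outputs(out2)
        e2 = im.e_effects_from_outputs(out2)
        f2 = u_eff.sum(axis=1) + e2.sum(axis=1)
        v2, g_f2 = _cox_core(f2, data.y, data.delta)
        smooth += v2

    # agreement term and its gradient wrt the per-feature effect matrices
    d_b = d_u = None
    if mode == "joint" and lam3 > 0 and c is not None:
        jj, kk = np.nonzero(c)
        if jj.size:
            diff = b_eff[:, jj] - u_eff[:, kk]
            w = c[jj, kk]
            smooth += lam3 * float(np.sum(w * np.sum(diff * diff, axis=0)))
            row_w = c.sum(axis=1)  # (r,)
            col_w = c.sum(axis=0)  # (p,)
            d_b = 2.0 * lam3 * (b_eff * row_w - u_eff @ c.T)
            d_u = 2.0 * lam3 * (u_eff * col_w - b_eff @ c)

    def model_grads(model, out, cache, g_f, d_eff, design):
        """Gradients for one model given dL/df (n,) and dL/d(effects) (n,r)."""
        nf, q = model.n_feat, model.q
        # upstream gradient on each per-feature total effect column
        g_eff = np.tile(g_f[:, None], (1, nf))
        if d_eff is not None:
            g_eff = g_eff + d_eff
        # sparse-coefficient gradients
        o_main = out[:, :nf]
        o_int = out[:, nf : nf + q * nf].reshape(-1, nf, q)
        o_e = out[:, nf + q * nf :]
        g_main_coef = np.sum(g_eff * o_main, axis=0)
        g_inter_coef = np.einsum("nj,njk->kj", g_eff, o_int, optimize=True)
        g_e_coef = np.sum(g_f[:, None] * o_e, axis=0)
        # upstream gradient on sub-net outputs
        g_out = np.empty_like(out)
        g_out[:, :nf] = g_eff * model.main_coef
        g_out[:, nf : nf + q * nf] = (
            g_eff[:, :, None] * model.inter_coef.T[None, :, :]
        ).reshape(out.shape[0], nf * q)
        g_out[:, nf + q * nf :] = g_f[:, None] * model.e_coef
        gw, gb = model.nets.backward(g_out, cache)
        return gw + gb + [g_main_coef, g_inter_coef, g_e_coef]

    if mode in ("joint", "ge_only"):
        grads1 = model_grads(gem, out1, cache1, g_f1, d_b, design1)
    if mode in ("joint", "imaging_only"):
        grads2 = model_grads(im, out2, cache2, g_f2, d_u, design2)
    return smooth, grads1, grads2


def _nonsmooth_value(gem, im, pcfg, mode, flavor):
    val = 0.0
    if mode in ("joint", "ge_only"):
        val += _model_penalty(gem, pcfg.lam1, pcfg, flavor)
    if mode in ("joint", "imaging_only"):
        val += _model_penalty(im, pcfg.lam2, pcfg, flavor)
    return val


def _apply_prox(model, t, lam, pcfg, flavor):
    """Prox step on the sparse layer (E coefficients untouched)."""
    if flavor == "none" or lam == 0:
        return
    if flavor == "sparse_group":
        g = _prox_groups_batch(
            model.groups, t, _group_scale(pcfg, model.q) * lam, lam, pcfg.a
        )
        model.set_groups(g)
    elif flavor == "mcp_elementwise":
        g = model.groups
        model.set_groups(prox_mcp(g, t, lam, pcfg.a))


def _selections(model) -> tuple[list[int], list[tuple[int, int]]]:
    if model is None:
        return [], []
    groups = model.groups
    main = [j for j in range(model.n_feat) if np.any(groups[j] != 0)]
    kk, jj = np.nonzero(model.inter_coef)
    inter = list(zip(kk.tolist(), jj.tolist()))
    return main, inter


def fit_joint(
    data: SurvivalDataset,
    pcfg: PenaltyConfig,
    fcfg: FitConfig,
    weights: AgreementWeights | None = None,
    init: tuple[GEModel | None, ImagingModel | None] | None = None,
) -> FitResult:
    """Proximal-gradient fit of the joint (or single-model) objective.

    Each epoch takes a full-batch gradient step on all parameters of the
    smooth part, then applies the group-MCP proximal map (step-scaled
    thresholds lam * step) to the sparse layers.  With backtracking the step
    is halved until the full objective does not increase, giving monotone
    descent; the Adam variant trades monotonicity for speed.
    """
    if fcfg.mode in ("joint", "imaging_only") and data.x is None:
        raise ValueError(f"mode {fcfg.mode!r} requires imaging features")
    work = data.standardized() if fcfg.standardize else data
    if fcfg.mode == "joint" and pcfg.lam3 > 0 and weights is None:
        weights = spearman_weights(work.z, work.x, pcfg.corr_quantile)
    c = weights.c if (weights is not None and fcfg.mode == "joint") else None

    rng = np.random.default_rng(fcfg.seed)
    gem = im = None
    if init is not None:
        # deep-copy so warm starts never mutate the caller's models
        g0, i0 = init
        gem = copy.deepcopy(g0)
        im = copy.deepcopy(i0)
    net_rng = rng if fcfg.train_nets else None  # frozen nets start (and stay) zero
    if fcfg.mode in ("joint", "ge_only") and gem is None:
        gem = GEModel(work.q, work.r, fcfg.layer_sizes, rng=net_rng,
                      coef_init=fcfg.coef_init)
    if fcfg.mode in ("joint", "imaging_only") and im is None:
        im = ImagingModel(work.q, work.p, fcfg.layer_sizes, rng=net_rng,
                          coef_init=fcfg.coef_init)

    design1 = gem.design_matrix(work.d, work.z) if gem is not None else None
    design2 = im.design_matrix(work.d, work.x) if im is not None else None

    states = []
    if fcfg.mode in ("joint", "ge_only"):
        states.append((_ModelState(gem), pcfg.lam1))
    if fcfg.mode in ("joint", "imaging_only"):
        states.append((_ModelState(im), pcfg.lam2))

    lam3_full = pcfg.lam3 if fcfg.mode == "joint" else 0.0
    pretrain = fcfg.pretrain_epochs if lam3_full > 0 else 0

    def objective(lam3_now: float) -> float:
        p_now = pcfg if lam3_now == pcfg.lam3 else dataclasses.replace(pcfg, lam3=lam3_now)
        return joint_objective(
            gem, im, work, weights, p_now, fcfg.mode, fcfg.penalty_flavor
        )

    trace = [objective(0.0 if pretrain > 0 else lam3_full)]
    step0 = fcfg.learning_rate
    converged = False
    # Adam state
    adam_m: dict[int, list[np.ndarray]] = {}
    adam_v: dict[int, list[np.ndarray]] = {}
    adam_t = 0

    epoch = 0
    for epoch in range(1, fcfg.max_epochs + 1):
        in_pretrain = epoch <= pretrain
        lam3 = 0.0 if in_pretrain else lam3_full
        if epoch == pretrain + 1 and pretrain > 0:
            trace.append(objective(lam3_full))  # rebase at the coupled objective
        smooth, grads1, grads2 = _smooth_loss_and_grads(
            gem, im, work, c if lam3 > 0 else None, lam3, fcfg.mode,
            design1, design2,
        )
        if not np.isfinite(smooth):
            raise FloatingPointError("objective diverged (non-finite loss)")
        all_grads = [g for g in (grads1, grads2) if g is not None]
        if not fcfg.train_nets:
            for (state, _), grads in zip(states, all_grads):
                nl = state.model.nets.n_layers
                for gi in range(2 * nl):
                    grads[gi] = np.zeros_like(grads[gi])

        if fcfg.optimizer == "adam":
            # adaptive-moment steps for the network weights only; the sparse
            # layers take plain gradient steps so the MCP prox threshold
            # keeps its meaning (the prox, not the optimizer, selects)
            coef_lr = fcfg.coef_learning_rate or step0
            if not 0 < coef_lr < pcfg.a:
                raise ValueError("coef_learning_rate must lie in (0, a)")
            adam_t += 1
            b1, b2 = fcfg.adam_beta1, fcfg.adam_beta2
            for si, grads in enumerate(all_grads):
                if si not in adam_m:
                    adam_m[si] = [np.zeros_like(g) for g in grads]
                    adam_v[si] = [np.zeros_like(g) for g in grads]
                state, lam = states[si]
                nl = state.model.nets.n_layers
                old = state.params()
                new = []
                for pi, (p, g) in enumerate(zip(old, grads)):
                    if pi < 2 * nl:
                        adam_m[si][pi] = b1 * adam_m[si][pi] + (1 - b1) * g
                        adam_v[si][pi] = b2 * adam_v[si][pi] + (1 - b2) * g * g
                        mhat = adam_m[si][pi] / (1 - b1**adam_t)
                        vhat = adam_v[si][pi] / (1 - b2**adam_t)
                        new.append(p - step0 * mhat / (np.sqrt(vhat) + 1e-8))
                    else:
                        # elementwise clip keeps a strong coupling gradient
                        # from destabilizing the un-normalized coefficient step
                        new.append(p - coef_lr * np.clip(g, -1.0, 1.0))
                state.set_params(new)
                _apply_prox(state.model, coef_lr, lam, pcfg,
                            fcfg.penalty_flavor)
            if (
                epoch % fcfg.trace_every
                and epoch != fcfg.max_epochs
                and epoch != pretrain
            ):
                continue  # objective evaluated every trace_every epochs
            q_new = objective(lam3)
        else:
            old_params = [[p.copy() for p in s.params()] for s, _ in states]
            step = step0
            q_prev = trace[-1]
            for _halving in range(30):
                for (state, lam), olds, grads in zip(states, old_params, all_grads):
                    state.set_params([p - step * g for p, g in zip(olds, grads)])
                    _apply_prox(state.model, step, lam, pcfg, fcfg.penalty_flavor)
                q_new = objective(lam3)
                if not fcfg.backtracking or q_new <= q_prev + 1e-12:
                    break
                step *= 0.5
            else:
                # no decreasing step found: restore and stop
                for (state, _), olds in zip(states, old_params):
                    state.set_params(olds)
                q_new = q_prev
                converged = True

        trace.append(float(q_new))
        if not np.isfinite(q_new):
            raise FloatingPointError("objective diverged (non-finite loss)")
        rel = abs(trace[-2] - trace[-1]) / (abs(trace[-2]) + 1e-12)
        if converged or rel < fcfg.tol:
            if in_pretrain:
                # decoupled phase converged early; move on to coupling
                pretrain = epoch
                converged = False
                continue
            converged = True
            break

    main1, inter1 = _selections(gem)
    main2, inter2 = _selections(im)
    return FitResult(
        gem=gem,
        im=im,
        lambdas=(pcfg.lam1, pcfg.lam2, pcfg.lam3),
        objective_trace=trace,
        selected_main=main1,
        selected_inter=inter1,
        selected_main_imaging=main2,
        selected_inter_imaging=inter2,
        n_epochs=epoch,
        converged=converged,
        config=fcfg,
    )


def _bic(result: FitResult, data: SurvivalDataset, fcfg: FitConfig) -> float:
    """2n * sum(npll) + log(n) * (# nonzero sparse-layer coefficients)."""
    work = data.standardized() if fcfg.standardize else data
    n = work.n
    total_npll = 0.0
    df = 0
    if result.gem is not None:
        f1 = result.gem.linear_predictor(work.d, work.z)
        total_npll += cox_npll(f1, work.y, work.delta)
        df += int(np.count_nonzero(result.gem.psi))
    if result.im is not None:
        f2 = result.im.linear_predictor(work.d, work.x)
        total_npll += cox_npll(f2, work.y, work.delta)
        df += int(np.count_nonzero(result.im.psi))
    return float(2.0 * n * total_npll + np.log(n) * df)


def select_tuning(
    data: SurvivalDataset,
    grids: dict[str, Sequence[float]],
    fcfg: FitConfig,
    pcfg_base: PenaltyConfig | None = None,
) -> tuple[tuple[float, float, float], FitResult]:
    """Grid search over (lam1, lam2, lam3) minimizing the BIC criterion.

    ``grids`` maps 'lam1' / 'lam2' / 'lam3' to value sequences (missing
    keys default to [0]).  lam1 is swept descending with warm starts.
    """
    base = pcfg_base or PenaltyConfig()
    lam1s = sorted(grids.get("lam1", [0.0]), reverse=True)
    lam2s = list(grids.get("lam2", [0.0]))
    lam3s = list(grids.get("lam3", [0.0]))
    if not lam1s or not lam2s or not lam3s:
        raise ValueError("tuning grids must be nonempty")

    weights = None
    if fcfg.mode == "joint" and any(l3 > 0 for l3 in lam3s):
        work = data.standardized() if fcfg.standardize else data
        weights = spearman_weights(work.z, work.x, base.corr_quantile)

    best: tuple[float, tuple, FitResult] | None = None
    for lam3 in lam3s:
        for lam2 in lam2s:
            warm: tuple | None = None
            for lam1 in lam1s:
                pcfg = PenaltyConfig(
                    lam1=lam1, lam2=lam2, lam3=lam3, a=base.a,
                    corr_quantile=base.corr_quantile,
                    group_scale=base.group_scale,
                )
                res = fit_joint(data, pcfg, fcfg, weights=weights, init=warm)
                warm = (res.gem, res.im)
                crit = _bic(res, data, fcfg)
                res.criterion = crit
                if best is None or crit < best[0] - 1e-12 or (
                    abs(crit - best[0]) <= 1e-12
                    and _df_of(res) < _df_of(best[2])
                ):
                    best = (crit, (lam1, lam2, lam3), res)
    return best[1], best[2]


def _df_of(res: FitResult) -> int:
    df = 0
    if res.gem is not None:
        df += int(np.count_nonzero(res.gem.psi))
    if res.im is not None:
        df += int(np.count_nonzero(res.im.psi))
    return df
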