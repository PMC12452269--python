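"""Synthetic data generator for the simulation designs.

A replicate draws AR(1)-correlated Gaussian environmental variables
d ~ N(0, Sigma_q(0.3)) and gene expressions z ~ N(0, Sigma_r(0.5)), couples
imaging features to genes through one of four structures for the p x r
matrix H* (banded, diagonal, random 5% off-diagonal, or an elementwise-tanh
nonlinear map), and generates survival times from a constant-baseline Cox
hazard h_i = exp(-2 + f_i) with f_i built from 15 main gene effects, 25
gene-environment interaction effects placed to respect the "main effects,
interactions" heredity, and effects on all environmental variables.  Four
effect shapes are available (ELU, sine, tanh, linear).  Censoring times are
exponential with the rate calibrated so that the expected censored fraction
matches a target (~40% by default).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
from scipy.optimize import brentq

from .model import SurvivalDataset

__all__ = [
    "SimDesign",
    "SimTruth",
    "ar_cov",
    "gen_covariates",
    "make_H",
    "gen_imaging",
    "gen_effects",
    "gen_survival",
    "calibrate_censoring",
    "make_dataset",
    "elu",
]

H_STRUCTURES = ("banded", "diagonal", "random5pct", "nonlinear_tanh")
EXAMPLES = ("elu", "sin", "tanh", "linear")


@dataclass
class SimDesign:
    """Full specification of one simulation scenario."""

    n: int = 500
    r: int = 300
    p: int = 200
    q: int = 4
    h_structure: str = "banded"
    example: str = "elu"
    n_main: int = 15
    n_inter: int = 25
    censor_target: float = 0.4
    rho_e: float = 0.3
    rho_g: float = 0.5
    rho_eps: float = 0.3
    noise_scale: float = 0.05
    baseline_loglevel: float = -2.0
    heredity_violation: int = 0  # interactions moved off the main-effect genes
    seed: int | None = None

    def __post_init__(self):
        if min(self.n, self.r, self.p, self.q) < 1:
            raise ValueError("dimensions must be positive")
        if self.h_structure not in H_STRUCTURES:
            raise ValueError(f"h_structure must be one of {H_STRUCTURES}")
        if self.example not in EXAMPLES:
            raise ValueError(f"example must be one of {EXAMPLES}")
        if not 0 <= self.censor_target < 1:
            raise ValueError("censor_target must lie in [0, 1)")
        if self.n_main > self.r:
            raise ValueError("n_main cannot exceed r")
        if self.n_inter > self.n_main * self.q and self.heredity_violation == 0:
            raise ValueError("too many interactions for the main-effect genes")


@dataclass
class SimTruth:
    """Ground truth attached to a simulated replicate."""

    phi_main: np.ndarray               # gene indices with main effects
    phi_inter: list[tuple[int, int]]   # (E index k, gene index j) pairs
    H: np.ndarray                      # p x r coupling matrix
    example: str
    kappa: float                       # calibrated censoring rate
    linear_coefs: dict | None = None   # example-4 coefficients


def elu(x):
    """ELU(x) = x for x >= 0, exp(x) - 1 for x < 0."""
    x = np.asarray(x, dtype=float)
    out = np.where(x >= 0, x, np.expm1(np.minimum(x, 0.0)))
    return float(out) if out.ndim == 0 else out


def ar_cov(h: int, rho: float) -> np.ndarray:
    """AR(1) correlation matrix [Sigma]_{ij} = rho^|i-j| (h x h, SPD)."""
    if h < 1:
        raise ValueError("dimension must be positive")
    if not -1 < rho < 1:
        raise ValueError("|rho| must be below 1")
    idx = np.arange(h)
    return rho ** np.abs(idx[:, None] - idx[None, :])


def _mvn_ar(rng: np.random.Generator, n: int, h: int, rho: float) -> np.ndarray:
    chol = np.linalg.cholesky(ar_cov(h, rho))
    return rng.standard_normal((n, h)) @ chol.T


def gen_covariates(
    design: SimDesign, rng: np.random.Generator | int | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Draw (d, z): AR-correlated Gaussian E and gene matrices."""
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    d = _mvn_ar(rng, design.n, design.q, design.rho_e)
    z = _mvn_ar(rng, design.n, design.r, design.rho_g)
    return d, z


def make_H(
    design: SimDesign, rng: np.random.Generator | int | None = None
) -> np.ndarray:
    """The p x r gene-to-imaging coupling matrix H*.

    banded / nonlinear_tanh: 1 on the diagonal, 0.3 on the first
    off-diagonals; diagonal: identity pattern; random5pct: identity plus a
    random 5% of off-diagonal entries ~ Uniform(0.3, 0.6).
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    p, r = design.p, design.r
    h = np.zeros((p, r))
    ii = np.arange(min(p, r))
    h[ii, ii] = 1.0
    if design.h_structure in ("banded", "nonlinear_tanh"):
        jj = np.arange(min(p - 1, r))
        h[jj + 1, jj] = 0.3
        kk = np.arange(min(p, r - 1))
        h[kk, kk + 1] = 0.3
    elif design.h_structure == "random5pct":
        off = np.argwhere(~np.eye(p, r, dtype=bool))
        n_pick = int(round(0.05 * off.shape[0]))
        pick = off[rng.choice(off.shape[0], size=n_pick, replace=False)]
        h[pick[:, 0], pick[:, 1]] = rng.uniform(0.3, 0.6, size=n_pick)
    return h


def gen_imaging(
    z: np.ndarray,
    H: np.ndarray,
    design: SimDesign,
    rng: np.random.Generator | int | None = None,
) -> np.ndarray:
    """Imaging features x = H z + eps, or tanh(H z) + eps for the nonlinear
    structure, with eps ~ noise_scale * N(0, Sigma_p(rho_eps))."""
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    signal = z @ H.T
    if design.h_structure == "nonlinear_tanh":
        signal = np.tanh(signal)
    eps = design.noise_scale * _mvn_ar(rng, z.shape[0], design.p, design.rho_eps)
    return signal + eps


def gen_effects(
    design: SimDesign, rng: np.random.Generator | int | None = None
) -> tuple[np.ndarray, list[tuple[int, int]], Callable, dict | None]:
    """Signal positions and the true linear-predictor builder.

    Main-effect genes are evenly spaced over 0..r-1; interactions are
    assigned round-robin over E indices among the main-effect genes so the
    heredity holds by construction (unless ``heredity_violation`` moves some
    pairs to non-main genes for sensitivity runs).  Returns
    (phi_main, phi_inter, f(d, z), linear_coefs-or-None).
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    # signal genes are placed (evenly spaced) within the imaging-covered
    # block j < min(r, p): the coupling structures tie imaging feature j'
    # to genes near j' = j, so only covered genes have imaging correlates —
    # the premise of the assisted-learning design
    upper = min(design.r, design.p)
    phi_main = np.unique(
        np.round(np.linspace(0, upper - 1, design.n_main)).astype(int)
    )
    if phi_main.size < design.n_main:
        raise ValueError(
            "imaging-covered gene range too small for distinct main-effect "
            "positions"
        )
    phi_inter: list[tuple[int, int]] = []
    for t in range(design.n_inter):
        j = int(phi_main[t % design.n_main])
        k = (t // design.n_main) % design.q
        phi_inter.append((k, j))
    if design.heredity_violation > 0:
        non_main = np.setdiff1d(np.arange(design.r), phi_main)
        nv = min(design.heredity_violation, len(phi_inter), non_main.size)
        repl = rng.choice(non_main, size=nv, replace=False)
        for t in range(nv):
            k, _ = phi_inter[t]
            phi_inter[t] = (k, int(repl[t]))
    if len(set(phi_inter)) != len(phi_inter):
        raise ValueError("interaction positions collide; reduce n_inter")

    kk = np.array([k for k, _ in phi_inter])
    jj = np.array([j for _, j in phi_inter])
    coefs = None
    if design.example == "linear":
        coefs = {
            "beta": rng.uniform(0.5, 1.0, size=phi_main.size),
            "gamma": rng.uniform(0.5, 1.0, size=len(phi_inter)),
            "alpha": rng.uniform(0.5, 1.0, size=design.q),
        }

    def f(d: np.ndarray, z: np.ndarray) -> np.ndarray:
        zm = z[:, phi_main]
        zi = d[:, kk] * z[:, jj]
        if design.example == "elu":
            return 0.8 * (
                elu(zm).sum(axis=1) + elu(zi).sum(axis=1) + elu(d).sum(axis=1)
            )
        if design.example == "sin":
            return 1.5 * (
                np.sin(zm).sum(axis=1)
                + np.sin(zi).sum(axis=1)
                + np.sin(d).sum(axis=1)
            )
        if design.example == "tanh":
            return (
                0.6 * np.tanh(zm).sum(axis=1)
                + 1.0 * np.tanh(zi).sum(axis=1)
                + 0.4 * np.tanh(d).sum(axis=1)
            )
        # linear
        return zm @ coefs["beta"] + zi @ coefs["gamma"] + d @ coefs["alpha"]

    return phi_main, phi_inter, f, coefs


def calibrate_censoring(
    f: np.ndarray,
    baseline_loglevel: float = -2.0,
    target_fraction: float = 0.4,
) -> float:
    """Exponential censoring rate kappa hitting the target censored fraction.

    With event rates h_i = exp(baseline_loglevel + f_i) and C ~ Exp(kappa),
    P(censored | i) = kappa / (kappa + h_i); kappa solves the mean of these
    equal to the target by monotone root finding (analytic, no simulation).
    """
    if not 0 <= target_fraction < 1:
        raise ValueError("target fraction must lie in [0, 1)")
    if target_fraction == 0:
        return 0.0
    rates = np.exp(baseline_loglevel + np.asarray(f, dtype=float))

    def cens_frac(kappa: float) -> float:
        return float(np.mean(kappa / (kappa + rates)))

    # at hi the censored fraction is >= target (with equality for
    # homogeneous rates), so pad the bracket slightly for the root finder
    hi = float(rates.max()) * target_fraction / (1.0 - target_fraction) * 1.01
    return float(brentq(lambda k: cens_frac(k) - target_fraction, 0.0, hi,
                        xtol=1e-12, rtol=1e-10))


def gen_survival(
    f: np.ndarray,
    kappa: float,
    baseline_loglevel: float = -2.0,
    rng: np.random.Generator | int | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Draw (T, C, Y, delta) under the constant hazard exp(loglevel + f).

    T_i ~ Exponential(rate exp(loglevel + f_i)); C_i ~ Exponential(kappa)
    (infinite when kappa = 0); Y = min(T, C), delta = I(T <= C).
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    f = np.asarray(f, dtype=float)
    rates = np.exp(baseline_loglevel + f)
    t = rng.exponential(1.0 / rates)
    if kappa > 0:
        c = rng.exponential(1.0 / kappa, size=f.size)
    else:
        c = np.full(f.size, np.inf)
    y = np.minimum(t, c)
    delta = (t <= c).astype(int)
    return t, c, y, delta


def make_dataset(
    design: SimDesign,
) -> tuple[SurvivalDataset, SurvivalDataset, SimTruth]:
    """Independent train/test draws from one design plus the ground truth.

    H*, the signal positions, and (for the linear example) the effect
    coefficients are drawn once per replicate and shared by both splits;
    the censoring rate is calibrated on the training linear predictor.
    """
    rng = np.random.default_rng(design.seed)
    H = make_H(design, rng)
    phi_main, phi_inter, f_build, coefs = gen_effects(design, rng)

    def draw(kappa: float | None):
        d, z = gen_covariates(design, rng)
        x = gen_imaging(z, H, design, rng)
        f = f_build(d, z)
        if kappa is None:
            kappa = calibrate_censoring(
                f, design.baseline_loglevel, design.censor_target
            )
        _, _, y, delta = gen_survival(f, kappa, design.baseline_loglevel, rng)
        return SurvivalDataset(d=d, z=z, x=x, y=y, delta=delta), kappa

    train, kappa = draw(None)
    test, _ = draw(kappa)
    truth = SimTruth(
        phi_main=phi_main,
        phi_inter=phi_inter,
        H=H,
        example=design.example,
        kappa=kappa,
        linear_coefs=coefs,
    )
    return train, test, truth
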