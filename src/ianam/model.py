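"""Neural additive architecture for gene-environment survival modelling.

The building block is the *r-net*: a one-input/one-output fully connected
network with ReLU activations and a residual (identity) skip connection,

    g(u) = u + g_L( sigma( g_{L-1}( ... sigma(g_1(u)) ... ) ) ),

so that with all hidden weights at zero the net is exactly the identity and
the purely linear effect is always representable.  Each gene, environmental
variable, and gene-environment product gets its own r-net, scaled by a
scalar *sparse-layer* coefficient; a zero coefficient excises the variable.

Two parallel additive Cox models are defined over the same environmental
variables: one driven by gene expressions (:class:`GEModel`) and one driven
by imaging features (:class:`ImagingModel`).  Their linear predictors are

    f1_i = sum_j beta_j B_j(z_ij) + sum_{k,j} gamma_kj G_kj(d_ik z_ij)
           + sum_k alpha_k A_k(d_ik)

and the mirror image with (z, beta, gamma, alpha) replaced by
(x, theta, mu, eta).

All sub-nets of a model share one layer-size signature and are evaluated in
a single batched einsum pass over an n x (r + q*r + q) design built from the
data columns and their elementwise products; gradients are computed by an
explicit backward pass (see :meth:`BatchedRNets.backward`).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = [
    "RNet",
    "BatchedRNets",
    "GEModel",
    "ImagingModel",
    "SurvivalDataset",
    "rnet_forward",
    "ge_linear_predictor",
    "gene_effect",
    "imaging_linear_predictor",
    "image_effect",
]

DEFAULT_LAYER_SIZES = (1, 16, 16, 1)


def _check_layer_sizes(layer_sizes: Sequence[int]) -> tuple[int, ...]:
    ls = tuple(int(s) for s in layer_sizes)
    if len(ls) < 2 or ls[0] != 1 or ls[-1] != 1 or any(s < 1 for s in ls):
        raise ValueError(
            f"layer sizes must start and end at 1 with positive widths, got {ls}"
        )
    return ls


@dataclass
class RNet:
    """A single residual one-input/one-output ReLU network.

    ``weights[l]`` has shape (p_{l+1}, p_l) and ``biases[l]`` has length
    p_{l+1}.  The activation sits between layers, not after the last one.
    """

    layer_sizes: tuple[int, ...]
    weights: list[np.ndarray]
    biases: list[np.ndarray]

    @classmethod
    def zeros(cls, layer_sizes: Sequence[int] = DEFAULT_LAYER_SIZES) -> "RNet":
        ls = _check_layer_sizes(layer_sizes)
        ws = [np.zeros((ls[l + 1], ls[l])) for l in range(len(ls) - 1)]
        bs = [np.zeros(ls[l + 1]) for l in range(len(ls) - 1)]
        return cls(ls, ws, bs)

    @classmethod
    def random(
        cls,
        rng: np.random.Generator,
        layer_sizes: Sequence[int] = DEFAULT_LAYER_SIZES,
    ) -> "RNet":
        ls = _check_layer_sizes(layer_sizes)
        ws = [
            rng.standard_normal((ls[l + 1], ls[l])) * np.sqrt(2.0 / ls[l])
            for l in range(len(ls) - 1)
        ]
        bs = [np.zeros(ls[l + 1]) for l in range(len(ls) - 1)]
        return cls(ls, ws, bs)

    def forward(self, u):
        """Evaluate the net at a scalar or an array of scalars."""
        u = np.asarray(u, dtype=float)
        a = u.reshape(-1, 1)
        n_layers = len(self.weights)
        for l, (w, b) in enumerate(zip(self.weights, self.biases)):
            if w.shape != (self.layer_sizes[l + 1], self.layer_sizes[l]):
                raise ValueError(
                    f"layer {l} weight shape {w.shape} inconsistent with "
                    f"layer sizes {self.layer_sizes}"
                )
            a = a @ w.T + b
            if l < n_layers - 1:
                a = np.maximum(a, 0.0)
        out = u + a.reshape(u.shape)
        return out if out.ndim else float(out)


def rnet_forward(net: RNet, u):
    """Residual-net evaluation; elementwise over a batch of scalars."""
    return net.forward(u)


class BatchedRNets:
    """``m`` r-nets with a common layer signature, evaluated in one pass.

    ``weights[l]`` has shape (m, p_{l+1}, p_l); ``biases[l]`` shape
    (m, p_{l+1}).  ``forward`` maps an (n, m) input column-block to (n, m)
    outputs; ``backward`` pushes an upstream (n, m) gradient back to
    per-layer parameter gradients.
    """

    def __init__(
        self,
        m: int,
        layer_sizes: Sequence[int] = DEFAULT_LAYER_SIZES,
        rng: np.random.Generator | None = None,
    ):
        self.m = int(m)
        self.layer_sizes = _check_layer_sizes(layer_sizes)
        ls = self.layer_sizes
        self.weights: list[np.ndarray] = []
        self.biases: list[np.ndarray] = []
        for l in range(len(ls) - 1):
            if rng is None or l == len(ls) - 2:
                # zero final layer: every sub-net starts exactly at the
                # identity (residual path) and grows only when trained
                w = np.zeros((self.m, ls[l + 1], ls[l]))
            else:
                w = rng.standard_normal((self.m, ls[l + 1], ls[l])) * np.sqrt(
                    2.0 / ls[l]
                )
            self.weights.append(w)
            self.biases.append(np.zeros((self.m, ls[l + 1])))

    @property
    def n_layers(self) -> int:
        return len(self.weights)

    def forward(self, u: np.ndarray, want_cache: bool = False):
        """Evaluate all m nets on their own column of ``u`` (n, m)."""
        u = np.asarray(u, dtype=float)
        if u.ndim != 2 or u.shape[1] != self.m:
            raise ValueError(f"expected (n, {self.m}) input, got {u.shape}")
        a = u[:, :, None]  # (n, m, p)
        cache = [a] if want_cache else None
        for l in range(self.n_layers):
            z = np.einsum("nmi,moi->nmo", a, self.weights[l], optimize=True) + self.biases[l]
            a = np.maximum(z, 0.0) if l < self.n_layers - 1 else z
            if want_cache:
                cache.append(a)
        out = u + a[:, :, 0]
        if want_cache:
            return out, cache
        return out

    def backward(self, grad_out: np.ndarray, cache: list[np.ndarray]):
        """Parameter gradients given d(loss)/d(output), shape (n, m).

        Returns (grads_w, grads_b) matching ``weights``/``biases`` shapes.
        The residual path contributes nothing to parameter gradients.
        """
        grads_w = [None] * self.n_layers
        grads_b = [None] * self.n_layers
        da = grad_out[:, :, None]  # gradient wrt post-activation of layer l
        for l in range(self.n_layers - 1, -1, -1):
            a_in = cache[l]
            if l < self.n_layers - 1:
                dz = da * (cache[l + 1] > 0)
            else:
                dz = da
            grads_w[l] = np.einsum("nmo,nmi->moi", dz, a_in, optimize=True)
            grads_b[l] = dz.sum(axis=0)
            if l > 0:
                da = np.einsum("nmo,moi->nmi", dz, self.weights[l], optimize=True)
        return grads_w, grads_b

    def subnet(self, idx: int) -> RNet:
        """Extract sub-net ``idx`` as a standalone :class:`RNet`."""
        return RNet(
            self.layer_sizes,
            [w[idx].copy() for w in self.weights],
            [b[idx].copy() for b in self.biases],
        )

    def zero_(self) -> "BatchedRNets":
        for w in self.weights:
            w[:] = 0.0
        for b in self.biases:
            b[:] = 0.0
        return self


class _AdditiveInteractionModel:
    """Shared machinery of the gene- and imaging-driven additive models.

    ``n_feat`` main features plus ``q`` environmental variables gives
    ``n_feat + q*n_feat + q`` sub-nets, laid out column-wise as
    [mains (n_feat), interactions j-major (q*n_feat), E (q)].  The group
    vector of feature j is (main_coef_j, inter_coef_{1..q,j}).
    """

    def __init__(
        self,
        q: int,
        n_feat: int,
        layer_sizes: Sequence[int] = DEFAULT_LAYER_SIZES,
        rng: np.random.Generator | None = None,
        coef_init: float = 0.1,
    ):
        if q < 1 or n_feat < 1:
            raise ValueError("q and the feature count must be positive")
        self.q = int(q)
        self.n_feat = int(n_feat)
        self.nets = BatchedRNets(
            self.n_feat + self.q * self.n_feat + self.q, layer_sizes, rng
        )
        self.main_coef = np.full(self.n_feat, float(coef_init))
        self.inter_coef = np.full((self.q, self.n_feat), float(coef_init))
        self.e_coef = np.full(self.q, float(coef_init))

    # --- column layout -------------------------------------------------
    @property
    def n_subnets(self) -> int:
        return self.n_feat + self.q * self.n_feat + self.q

    def _inter_col(self, k: int, j: int) -> int:
        return self.n_feat + j * self.q + k

    def _e_col(self, k: int) -> int:
        return self.n_feat + self.q * self.n_feat + k

    def design_matrix(self, d: np.ndarray, v: np.ndarray) -> np.ndarray:
        """Stack [v, d*v products (j-major), d] into the (n, m) input block."""
        d = np.asarray(d, dtype=float)
        v = np.asarray(v, dtype=float)
        if d.ndim != 2 or v.ndim != 2 or d.shape[0] != v.shape[0]:
            raise ValueError("d and the feature matrix must share n rows")
        if d.shape[1] != self.q or v.shape[1] != self.n_feat:
            raise ValueError(
                f"expected q={self.q}, features={self.n_feat}; "
                f"got d {d.shape}, features {v.shape}"
            )
        n = d.shape[0]
        prods = (v[:, :, None] * d[:, None, :]).reshape(n, self.n_feat * self.q)
        return np.concatenate([v, prods, d], axis=1)

    # --- effects -------------------------------------------------------
    def subnet_outputs(self, d, v, want_cache: bool = False):
        return self.nets.forward(self.design_matrix(d, v), want_cache=want_cache)

    def feature_effects_from_outputs(self, outputs: np.ndarray) -> np.ndarray:
        """(n, n_feat) matrix of per-feature total effects (main + inter)."""
        n = outputs.shape[0]
        mains = outputs[:, : self.n_feat] * self.main_coef
        inter = outputs[:, self.n_feat : self.n_feat + self.q * self.n_feat]
        inter = inter.reshape(n, self.n_feat, self.q)
        return mains + np.einsum("njk,kj->nj", inter, self.inter_coef, optimize=True)

    def e_effects_from_outputs(self, outputs: np.ndarray) -> np.ndarray:
        return outputs[:, self.n_feat + self.q * self.n_feat :] * self.e_coef

    def feature_effects(self, d, v) -> np.ndarray:
        return self.feature_effects_from_outputs(self.subnet_outputs(d, v))

    def linear_predictor(self, d, v) -> np.ndarray:
        out = self.subnet_outputs(d, v)
        return self.feature_effects_from_outputs(out).sum(
            axis=1
        ) + self.e_effects_from_outputs(out).sum(axis=1)

    def feature_effect(self, j: int, d, v) -> np.ndarray:
        if not 0 <= j < self.n_feat:
            raise IndexError(f"feature index {j} out of range [0, {self.n_feat})")
        return self.feature_effects(d, v)[:, j]

    # --- sparse-layer views --------------------------------------------
    @property
    def groups(self) -> np.ndarray:
        """(n_feat, q+1) array; row j is (main_coef_j, inter_coef_{.,j})."""
        return np.concatenate(
            [self.main_coef[:, None], self.inter_coef.T], axis=1
        )

    def set_groups(self, g: np.ndarray) -> None:
        g = np.asarray(g, dtype=float)
        if g.shape != (self.n_feat, self.q + 1):
            raise ValueError(f"expected {(self.n_feat, self.q + 1)}, got {g.shape}")
        self.main_coef = g[:, 0].copy()
        self.inter_coef = g[:, 1:].T.copy()

    @property
    def psi(self) -> np.ndarray:
        """Full sparse vector: groups row-wise, then the E coefficients."""
        return np.concatenate([self.groups.ravel(), self.e_coef])

    # --- serialization -------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "kind": type(self).__name__,
            "q": self.q,
            "n_feat": self.n_feat,
            "layer_sizes": list(self.nets.layer_sizes),
            "weights": [w.tolist() for w in self.nets.weights],
            "biases": [b.tolist() for b in self.nets.biases],
            "main_coef": self.main_coef.tolist(),
            "inter_coef": self.inter_coef.tolist(),
            "e_coef": self.e_coef.tolist(),
        }

    @classmethod
    def from_dict(cls, dct: dict) -> "_AdditiveInteractionModel":
        model = cls(dct["q"], dct["n_feat"], layer_sizes=dct["layer_sizes"])
        model.nets.weights = [np.asarray(w, dtype=float) for w in dct["weights"]]
        model.nets.biases = [np.asarray(b, dtype=float) for b in dct["biases"]]
        model.main_coef = np.asarray(dct["main_coef"], dtype=float)
        model.inter_coef = np.asarray(dct["inter_coef"], dtype=float)
        model.e_coef = np.asarray(dct["e_coef"], dtype=float)
        return model

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh)

    @classmethod
    def load(cls, path) -> "_AdditiveInteractionModel":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


class GEModel(_AdditiveInteractionModel):
    """Additive Cox model over gene expressions z and E variables d.

    Sparse-layer coefficients: ``beta`` (gene mains), ``gamma`` (q x r
    interactions), ``alpha`` (E mains, never penalized).
    """

    def __init__(self, q, r, layer_sizes=DEFAULT_LAYER_SIZES, rng=None, coef_init=0.1):
        super().__init__(q, r, layer_sizes=layer_sizes, rng=rng, coef_init=coef_init)

    @property
    def r(self) -> int:
        return self.n_feat

    @property
    def beta(self) -> np.ndarray:
        return self.main_coef

    @beta.setter
    def beta(self, v):
        self.main_coef = np.asarray(v, dtype=float)

    @property
    def gamma(self) -> np.ndarray:
        return self.inter_coef

    @gamma.setter
    def gamma(self, v):
        self.inter_coef = np.asarray(v, dtype=float)

    @property
    def alpha(self) -> np.ndarray:
        return self.e_coef

    @alpha.setter
    def alpha(self, v):
        self.e_coef = np.asarray(v, dtype=float)

    @classmethod
    def from_dict(cls, dct: dict) -> "GEModel":
        model = cls(dct["q"], dct["n_feat"], layer_sizes=dct["layer_sizes"])
        model.nets.weights = [np.asarray(w, dtype=float) for w in dct["weights"]]
        model.nets.biases = [np.asarray(b, dtype=float) for b in dct["biases"]]
        model.main_coef = np.asarray(dct["main_coef"], dtype=float)
        model.inter_coef = np.asarray(dct["inter_coef"], dtype=float)
        model.e_coef = np.asarray(dct["e_coef"], dtype=float)
        return model


class ImagingModel(_AdditiveInteractionModel):
    """Mirror of :class:`GEModel` over p imaging features x.

    Coefficients: ``theta`` (imaging mains), ``mu`` (q x p interactions),
    ``eta`` (E mains).
    """

    def __init__(self, q, p, layer_sizes=DEFAULT_LAYER_SIZES, rng=None, coef_init=0.1):
        super().__init__(q, p, layer_sizes=layer_sizes, rng=rng, coef_init=coef_init)

    @property
    def p(self) -> int:
        return self.n_feat

    @property
    def theta(self) -> np.ndarray:
        return self.main_coef

    @theta.setter
    def theta(self, v):
        self.main_coef = np.asarray(v, dtype=float)

    @property
    def mu(self) -> np.ndarray:
        return self.inter_coef

    @mu.setter
    def mu(self, v):
        self.inter_coef = np.asarray(v, dtype=float)

    @property
    def eta(self) -> np.ndarray:
        return self.e_coef

    @eta.setter
    def eta(self, v):
        self.e_coef = np.asarray(v, dtype=float)

    @classmethod
    def from_dict(cls, dct: dict) -> "ImagingModel":
        model = cls(dct["q"], dct["n_feat"], layer_sizes=dct["layer_sizes"])
        model.nets.weights = [np.asarray(w, dtype=float) for w in dct["weights"]]
        model.nets.biases = [np.asarray(b, dtype=float) for b in dct["biases"]]
        model.main_coef = np.asarray(dct["main_coef"], dtype=float)
        model.inter_coef = np.asarray(dct["inter_coef"], dtype=float)
        model.e_coef = np.asarray(dct["e_coef"], dtype=float)
        return model


def ge_linear_predictor(m: GEModel, d, z) -> np.ndarray:
    """f1_i: additive Cox predictor from genes, E variables, interactions."""
    return m.linear_predictor(d, z)


def gene_effect(m: GEModel, j: int, d, z) -> np.ndarray:
    """Total (main + interaction) effect of gene j, per sample."""
    return m.feature_effect(j, d, z)


def imaging_linear_predictor(m: ImagingModel, d, x) -> np.ndarray:
    """f2_i: additive Cox predictor from imaging features and E variables."""
    return m.linear_predictor(d, x)


def image_effect(m: ImagingModel, jp: int, d, x) -> np.ndarray:
    """Total (main + interaction) effect of imaging feature j', per sample."""
    return m.feature_effect(jp, d, x)


@dataclass
class SurvivalDataset:
    """Right-censored survival data with E, gene, and optional imaging blocks.

    ``y`` holds observed times min(T, C); ``delta`` is 1 for an observed
    event (T <= C) and 0 for censoring.
    """

    d: np.ndarray
    z: np.ndarray
    y: np.ndarray
    delta: np.ndarray
    x: np.ndarray | None = None

    def __post_init__(self):
        self.d = np.atleast_2d(np.asarray(self.d, dtype=float))
        self.z = np.atleast_2d(np.asarray(self.z, dtype=float))
        self.y = np.asarray(self.y, dtype=float).ravel()
        self.delta = np.asarray(self.delta).ravel().astype(int)
        if self.x is not None:
            self.x = np.atleast_2d(np.asarray(self.x, dtype=float))
        n = self.d.shape[0]
        parts = [self.z.shape[0], self.y.shape[0], self.delta.shape[0]]
        if self.x is not None:
            parts.append(self.x.shape[0])
        if any(m != n for m in parts):
            raise ValueError("all dataset components must share the same n")
        for name, arr in (("d", self.d), ("z", self.z), ("x", self.x),
                          ("y", self.y)):
            if arr is not None and not np.all(np.isfinite(arr)):
                raise ValueError(f"non-finite values in {name}")
        if np.any(self.y < 0):
            raise ValueError("observed times must be nonnegative")
        if not np.isin(self.delta, [0, 1]).all():
            raise ValueError("event indicators must be 0/1")

    @property
    def n(self) -> int:
        return self.d.shape[0]

    @property
    def q(self) -> int:
        return self.d.shape[1]

    @property
    def r(self) -> int:
        return self.z.shape[1]

    @property
    def p(self) -> int | None:
        return None if self.x is None else self.x.shape[1]

    def standardized(self) -> "SurvivalDataset":
        """Columns of d, z (and x) rescaled to mean 0, variance 1.

        Constant columns are left centred at 0 (scale 1) with a warning.
        """

        def _std(a):
            mu = a.mean(axis=0)
            sd = a.std(axis=0)
            if np.any(sd == 0):
                warnings.warn("constant column(s) left unscaled", stacklevel=2)
            sd = np.where(sd == 0, 1.0, sd)
            return (a - mu) / sd

        return SurvivalDataset(
            d=_std(self.d),
            z=_std(self.z),
            x=None if self.x is None else _std(self.x),
            y=self.y.copy(),
            delta=self.delta.copy(),
        )

    def subset(self, idx) -> "SurvivalDataset":
        return SurvivalDataset(
            d=self.d[idx],
            z=self.z[idx],
            x=None if self.x is None else self.x[idx],
            y=self.y[idx],
            delta=self.delta[idx],
        )
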