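"""Penalties: MCP, the heredity-enforcing sparse-group penalty, and the
Spearman-weighted agreement penalty coupling the two additive models.

The minimax concave penalty (MCP) with scale a > 1 is

    rho_a(t; lam) = integral_0^|t| (lam - s/a)_+ ds
                  = lam|t| - t^2/(2a)   for |t| <= a*lam,
                    a*lam^2/2           otherwise.

Genes are penalized in groups b_j = (beta_j, gamma_1j, ..., gamma_qj): an
MCP on the group norm (selecting the gene together with all its
interactions — the "main effects, interactions" heredity) plus elementwise
MCP on the interaction entries only.  Environmental coefficients are never
penalized.

The agreement penalty ties the total effect of gene j to the total effect
of imaging feature j' for pairs whose absolute Spearman correlation exceeds
a data-driven cutoff (the 0.9 quantile of all absolute correlations by
default), enabling the imaging model to assist the gene model.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

__all__ = [
    "PenaltyConfig",
    "AgreementWeights",
    "mcp_value",
    "sparse_group_penalty",
    "spearman_weights",
    "agreement_penalty",
    "agreement_value",
]


@dataclass
class PenaltyConfig:
    """Penalty levels and shape constants for the joint objective."""

    lam1: float = 0.0        # sparse-group level, gene model
    lam2: float = 0.0        # sparse-group level, imaging model
    lam3: float = 0.0        # agreement level
    a: float = 3.0           # MCP concavity scale
    corr_quantile: float = 0.9  # cutoff quantile for agreement weights
    group_scale: float | None = None  # group-level multiplier; sqrt(q+1) if None

    def __post_init__(self):
        if self.a <= 1:
            raise ValueError("MCP scale a must exceed 1")
        if min(self.lam1, self.lam2, self.lam3) < 0:
            raise ValueError("penalty levels must be nonnegative")
        if not 0 < self.corr_quantile < 1:
            raise ValueError("corr_quantile must lie in (0, 1)")


def mcp_value(t, lam: float, a: float = 3.0):
    """MCP rho_a(t; lam); symmetric, nondecreasing in |t|, capped at a*lam^2/2."""
    if lam < 0:
        raise ValueError("lam must be nonnegative")
    if a <= 0:
        raise ValueError("a must be positive")
    t = np.asarray(t, dtype=float)
    at = np.abs(t)
    val = np.where(at <= a * lam, lam * at - t * t / (2.0 * a), a * lam * lam / 2.0)
    return float(val) if val.ndim == 0 else val


def sparse_group_penalty(
    groups: np.ndarray,
    lam: float,
    a: float = 3.0,
    group_scale: float | None = None,
) -> float:
    """Sparse-group MCP over gene groups.

    ``groups`` is (r, q+1) with row j = (main coefficient, q interaction
    coefficients).  Value:

        sum_j [ rho_a(||b_j||_2; group_scale*lam, a)
                + sum_{k} rho_a(gamma_kj; lam, a) ]

    The main-effect entry is skipped by the inner elementwise term, and E
    coefficients are outside ``groups`` entirely.
    """
    groups = np.asarray(groups, dtype=float)
    if groups.ndim != 2:
        raise ValueError("groups must be a 2-D (r, q+1) array")
    if group_scale is None:
        group_scale = float(np.sqrt(groups.shape[1]))
    norms = np.linalg.norm(groups, axis=1)
    group_term = np.sum(mcp_value(norms, group_scale * lam, a))
    elem_term = np.sum(mcp_value(groups[:, 1:], lam, a))
    return float(group_term + elem_term)


@dataclass
class AgreementWeights:
    """Thresholded absolute Spearman correlations c_{j,j'} (r x p)."""

    c: np.ndarray
    cutoff: float
    corr: np.ndarray | None = None

    def __post_init__(self):
        self.c = np.asarray(self.c, dtype=float)
        if np.any(self.c < 0) or np.any(self.c > 1):
            raise ValueError("weights must lie in [0, 1]")

    @property
    def pairs(self) -> tuple[np.ndarray, np.ndarray]:
        """Indices (genes, imaging features) of the nonzero weights."""
        return np.nonzero(self.c)

    def to_table(self) -> pd.DataFrame:
        jj, kk = self.pairs
        return pd.DataFrame(
            {"gene": jj, "imaging_feature": kk, "weight": self.c[jj, kk]}
        )

    def save(self, path) -> None:
        self.to_table().to_csv(path, sep="\t", index=False)


def _rank_standardize(a: np.ndarray) -> np.ndarray:
    """Column-wise average ranks, centred and scaled; constant columns -> 0."""
    n = a.shape[0]
    ranks = np.apply_along_axis(rankdata, 0, a)
    ranks = ranks - ranks.mean(axis=0)
    sd = ranks.std(axis=0)
    const = sd == 0
    if np.any(const):
        warnings.warn(
            f"{int(const.sum())} constant column(s); their correlations set to 0",
            stacklevel=3,
        )
    sd = np.where(const, 1.0, sd)
    out = ranks / (sd * np.sqrt(n))
    out[:, const] = 0.0
    return out


def spearman_weights(
    z: np.ndarray, x: np.ndarray, quantile: float = 0.9
) -> AgreementWeights:
    """Agreement weights from the gene/imaging Spearman cross-correlations.

    c_{j,j'} = |corr_{j,j'}| * I(|corr_{j,j'}| > cutoff) with the cutoff at
    the given empirical quantile of all |corr| values, so roughly a
    (1 - quantile) fraction of the pairs is retained.
    """
    z = np.asarray(z, dtype=float)
    x = np.asarray(x, dtype=float)
    if z.ndim != 2 or x.ndim != 2 or z.shape[0] != x.shape[0]:
        raise ValueError("z and x must be 2-D with the same number of rows")
    if z.shape[0] < 3:
        raise ValueError("need at least 3 samples for rank correlations")
    if not 0 < quantile < 1:
        raise ValueError("quantile must lie in (0, 1)")
    corr = _rank_standardize(z).T @ _rank_standardize(x)
    corr = np.clip(corr, -1.0, 1.0)
    cutoff = float(np.quantile(np.abs(corr), quantile))
    c = np.where(np.abs(corr) > cutoff, np.abs(corr), 0.0)
    return AgreementWeights(c=c, cutoff=cutoff, corr=corr)


def agreement_value(
    gene_effects: np.ndarray, image_effects: np.ndarray, c: np.ndarray
) -> float:
    """sum_{j,j'} c_{j,j'} ||gene_effect_j - image_effect_j'||^2.

    Only pairs with positive weight are visited; inputs are the (n, r) and
    (n, p) per-feature total-effect matrices.
    """
    c = np.asarray(c, dtype=float)
    if c.shape != (gene_effects.shape[1], image_effects.shape[1]):
        raise ValueError(
            f"weight matrix shape {c.shape} does not match effect matrices"
        )
    jj, kk = np.nonzero(c)
    if jj.size == 0:
        return 0.0
    diff = gene_effects[:, jj] - image_effects[:, kk]
    return float(np.sum(c[jj, kk] * np.sum(diff * diff, axis=0)))


def agreement_penalty(gem, im, w: AgreementWeights, d, z, x) -> float:
    """Weighted squared disagreement between paired gene/imaging effects.

    Returned *without* the lam3 factor; the objective multiplies it in.
    """
    return agreement_value(gem.feature_effects(d, z), im.feature_effects(d, x), w.c)
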