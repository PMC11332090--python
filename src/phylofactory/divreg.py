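"""Tip diversification rates and phylogenetic logistic regression.

Tip rates come either from :func:`equal_splits_rates` — the inverse
equal-splits statistic, a desk-scale speciation-rate proxy computed from
root-path branch lengths with geometrically decaying weights — or from
an externally computed per-species rate file via :func:`read_tip_rates`.

:func:`fit_phylo_logistic` regresses a binary response (invasive or
not) on a tip-level predictor under a logit link while modelling
phylogenetic dependence among observations, in the spirit of the
Ives-Garland mean-reverting binary-trait estimator: generalized
estimating equations with a working correlation exp(-alpha * d_ij),
where d_ij is patristic distance on the height-normalized tree and
alpha is estimated from a Gaussian pseudo-likelihood of the Pearson
residuals.  Large alpha means correlations die off quickly
(phylogeny-free limit); small alpha means strong inherited correlation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import linalg, stats
from scipy.optimize import minimize_scalar

from ._arrays import TreeArrays
from .traits import TraitVector
from .treeio import Phylogeny

__all__ = [
    "TipRates",
    "PhyloGlmFit",
    "PerfectSeparationError",
    "equal_splits_rates",
    "read_tip_rates",
    "fit_phylo_logistic",
]

logger = logging.getLogger(__name__)


class PerfectSeparationError(ValueError):
    """The predictor perfectly separates the binary response."""


@dataclass(frozen=True)
class TipRates:
    """Per-species diversification rates (per lineage per unit time)."""

    rates: dict[str, float]
    source: str = "equal-splits"

    def __post_init__(self):
        bad = {k: v for k, v in self.rates.items() if not v > 0}
        if bad:
            raise ValueError(f"non-positive rates: {dict(list(bad.items())[:5])}")

    def aligned(self, labels) -> np.ndarray:
        missing = [lab for lab in labels if lab not in self.rates]
        if missing:
            raise KeyError(f"rates missing species: {sorted(missing)[:10]}")
        return np.asarray([self.rates[lab] for lab in labels], dtype=float)


@dataclass(frozen=True)
class PhyloGlmFit:
    beta: float
    intercept: float
    se_beta: float
    z: float
    p_value: float
    alpha_phy: float
    converged: bool
    n: int
    standardized: bool
    n_iter: int = 0


def equal_splits_rates(tree: Phylogeny) -> TipRates:
    """Inverse equal-splits statistic per tip.

    For tip i with root-path edge lengths l_1 (pendant) ... l_N,
    ES_i = sum_j l_j / 2^(j-1) and rate_i = 1 / ES_i.  The root stem,
    if any, carries no split and is excluded.
    """
    arrays = TreeArrays(tree)
    rates: dict[str, float] = {}
    for row, node in enumerate(arrays.tip_nodes):
        es = 0.0
        weight = 1.0
        i = int(node)
        while arrays.parent[i] >= 0:
            es += arrays.blen[i] * weight
            weight *= 0.5
            i = int(arrays.parent[i])
        if es <= 0:
            raise ValueError(
                f"tip {arrays.tip_labels[row]!r} has a zero-length root path; "
                "equal-splits rate undefined"
            )
        rates[arrays.tip_labels[row]] = 1.0 / es
    return TipRates(rates=rates, source="equal-splits")


def read_tip_rates(path, tree: Phylogeny | None = None) -> TipRates:
    """Read a ``species,rate`` CSV of externally computed tip rates.

    Rates must be positive and species unique; when a tree is supplied,
    species absent from it are dropped with a logged warning.
    """
    df = pd.read_csv(path, comment="#")
    required = {"species", "rate"}
    if not required.issubset(df.columns):
        raise ValueError(f"rates file needs columns {sorted(required)}; got {list(df.columns)}")
    dupes = df["species"][df["species"].duplicated()].unique()
    if len(dupes):
        raise ValueError(f"duplicate species in rates file: {sorted(dupes)[:5]}")
    if not (df["rate"] > 0).all():
        bad = df.loc[~(df["rate"] > 0), "species"].tolist()
        raise ValueError(f"non-positive rates for: {bad[:5]}")
    rates = dict(zip(df["species"].astype(str), df["rate"].astype(float)))
    if tree is not None:
        tips = set(tree.tip_labels)
        unknown = sorted(set(rates) - tips)
        if unknown:
            logger.warning("dropping %d rate rows for species not in tree: %s%s",
                           len(unknown), unknown[:5], "..." if len(unknown) > 5 else "")
            rates = {k: v for k, v in rates.items() if k in tips}
    return TipRates(rates=rates, source=str(path))


# ---------------------------------------------------------------------
# phylogenetic logistic regression


def _gee_logistic(X, y, chol_R, beta0, max_iter=50, tol=1e-9):
    """Fisher-scoring GEE for a logit link with fixed working correlation.

    Returns (beta, cov_beta, converged, n_iter).  cov is the model-based
    (bread-only) covariance (U' R^-1 U)^-1 with U = A^(1/2) X.
    """
    beta = beta0.copy()
    converged = False
    it = 0
    M = None
    for it in range(1, max_iter + 1):
        eta = np.clip(X @ beta, -30, 30)
        mu = 1.0 / (1.0 + np.exp(-eta))
        a = np.clip(mu * (1.0 - mu), 1e-10, None)
        sa = np.sqrt(a)
        U = sa[:, None] * X
        r = (y - mu) / sa
        RiU = linalg.cho_solve(chol_R, U)
        M = U.T @ RiU
        g = RiU.T @ r
        try:
            step = linalg.solve(M, g, assume_a="pos")
        except linalg.LinAlgError:
            break
        beta = beta + step
        if np.max(np.abs(step)) < tol:
            converged = True
            break
    cov = linalg.inv(M) if M is not None else np.full((X.shape[1],) * 2, np.nan)
    return beta, cov, converged, it


def fit_phylo_logistic(
    tree: Phylogeny,
    y: TraitVector,
    x: TipRates,
    standardize: bool = True,
    alpha_bounds: tuple[float, float] = (1e-2, 1e3),
    nugget: float = 0.05,
) -> PhyloGlmFit:
    """Fit P(y=1) = logit^-1(b0 + b1 * x) with phylogenetically
    correlated observations.

    The working correlation is (1 - nugget) * exp(-alpha * d_ij) off the
    diagonal, with d the patristic distance after rescaling the tree to
    unit height; alpha is chosen to minimize the Gaussian
    pseudo-likelihood of the Pearson residuals and reported as
    ``alpha_phy``.  The nugget bounds pairwise working correlation away
    from 1: dated trees carry effectively zero-length cherries whose
    contrast would otherwise receive unbounded weight and degenerate the
    estimating equations for a binary response.  The predictor is
    z-scored by default (slope on the standardized scale); pass
    ``standardize=False`` for the raw scale.
    """
    if not 0.0 < nugget < 1.0:
        raise ValueError("nugget must lie in (0, 1)")
    labels = tree.tip_labels
    yv = y.aligned(tree).astype(float)
    xv = x.aligned(labels)
    n = len(labels)
    if n < 4:
        raise ValueError("too few species for regression")
    if yv.min() == yv.max():
        raise ValueError("response invariant; regression undefined")
    lo1, hi0 = xv[yv == 1].min(), xv[yv == 0].max()
    lo0, hi1 = xv[yv == 0].min(), xv[yv == 1].max()
    if lo1 > hi0 or lo0 > hi1:
        raise PerfectSeparationError(
            "predictor perfectly separates the response; coefficients diverge"
        )
    if standardize:
        sd = xv.std(ddof=1)
        if sd == 0:
            raise ValueError("predictor is constant")
        xs = (xv - xv.mean()) / sd
    else:
        xs = xv.astype(float)
    X = np.column_stack([np.ones(n), xs])

    arrays = TreeArrays(tree)
    D = arrays.patristic_matrix()
    height = arrays.tip_depth.max()
    if height <= 0:
        raise ValueError("tree has zero height")
    D = D / height

    # independence start for beta
    beta0, _, _, _ = _gee_logistic(
        X, yv, linalg.cho_factor(np.eye(n)), np.zeros(2), max_iter=25
    )

    def solve_at(log_alpha: float):
        alpha = float(np.exp(log_alpha))
        R = (1.0 - nugget) * np.exp(-alpha * D)
        R[np.diag_indices_from(R)] = 1.0
        chol = linalg.cho_factor(R)
        beta, cov, conv, it = _gee_logistic(X, yv, chol, beta0)
        eta = np.clip(X @ beta, -30, 30)
        mu = 1.0 / (1.0 + np.exp(-eta))
        a = np.clip(mu * (1.0 - mu), 1e-10, None)
        r = (yv - mu) / np.sqrt(a)
        logdet = 2.0 * np.sum(np.log(np.diag(chol[0])))
        quad = r @ linalg.cho_solve(chol, r)
        return quad + logdet, (alpha, beta, cov, conv, it)

    res = minimize_scalar(
        lambda la: solve_at(la)[0],
        bounds=(np.log(alpha_bounds[0]), np.log(alpha_bounds[1])),
        method="bounded",
        options={"xatol": 1e-3},
    )
    _, (alpha, beta, cov, conv, it) = solve_at(res.x)
    se = float(np.sqrt(cov[1, 1]))
    if not np.isfinite(se) or se <= 0:
        return PhyloGlmFit(
            beta=float(beta[1]), intercept=float(beta[0]), se_beta=np.nan, z=np.nan,
            p_value=np.nan, alpha_phy=alpha, converged=False, n=n,
            standardized=standardize, n_iter=it,
        )
    z = float(beta[1] / se)
    p = float(2.0 * stats.norm.sf(abs(z)))
    return PhyloGlmFit(
        beta=float(beta[1]), intercept=float(beta[0]), se_beta=se, z=z, p_value=p,
        alpha_phy=float(alpha), converged=bool(conv and res.success), n=n,
        standardized=standardize, n_iter=it,
    )
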