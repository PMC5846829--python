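"""Univariate SNP–phenotype association tests.

Each phenotype is regressed on the allele count with ordinary least squares
(intercept included, no covariates); the slope's two-sided p-value comes
from the t distribution with N - 2 degrees of freedom. For simple
regression the t statistic equals ``r * sqrt((N-2) / (1-r^2))`` where r is
the genotype–phenotype sample correlation, which is what the vectorized
implementation computes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .simulate import SimulatedDataset

__all__ = ["AssocResult", "univariate_pvalues", "batch_pvalues"]


@dataclass
class AssocResult:
    """Per-phenotype association results for one SNP.

    ``pvalues`` and ``tstats`` have length m; ``df`` is N - 2.
    """

    pvalues: np.ndarray
    tstats: np.ndarray
    df: int


def _corr_tstats(g: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """t statistics and p-values from sample correlations, last axis = subjects.

    ``g``: (..., N) genotype, ``y``: (..., N, m) phenotypes. Perfectly
    (anti)correlated phenotypes get |t| = inf, p = 0.
    """
    n = g.shape[-1]
    gc = g - g.mean(axis=-1, keepdims=True)
    yc = y - y.mean(axis=-2, keepdims=True)
    gss = np.einsum("...n,...n->...", gc, gc)
    if np.any(gss == 0.0):
        raise ValueError("monomorphic variant: genotype vector is constant")
    yss = np.einsum("...nm,...nm->...m", yc, yc)
    cross = np.einsum("...n,...nm->...m", gc, yc)
    with np.errstate(divide="ignore", invalid="ignore"):
        r = cross / np.sqrt(gss[..., None] * yss)
        r = np.clip(np.nan_to_num(r), -1.0, 1.0)
        t = r * np.sqrt((n - 2) / (1.0 - r * r))
    t = np.where(np.abs(r) >= 1.0, np.sign(r) * np.inf, t)
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    return t, p


def univariate_pvalues(data: SimulatedDataset) -> AssocResult:
    """OLS slope tests of every phenotype on the allele count.

    Raises on a monomorphic variant (constant genotype vector): with no
    genotypic variance there is no association test, and the combination
    tests receive no p-values.
    """
    g = np.asarray(data.genotypes, dtype=float)
    y = np.asarray(data.phenotypes, dtype=float)
    n = g.shape[0]
    if n < 3:
        raise ValueError("need at least 3 subjects for a slope test")
    t, p = _corr_tstats(g, y)
    return AssocResult(pvalues=p, tstats=t, df=n - 2)


def batch_pvalues(G: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """P-values for a batch of replicates at once.

    ``G`` has shape (B, N) and ``Y`` shape (B, N, m); returns a (B, m) array
    of two-sided p-values. Agrees with :func:`univariate_pvalues` applied
    row-wise to machine precision.
    """
    G = np.asarray(G, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if G.shape[1] < 3:
        raise ValueError("need at least 3 subjects for a slope test")
    _, p = _corr_tstats(G, Y)
    return p
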