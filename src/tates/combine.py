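"""Weighted-selection combination tests for multivariate SNP association.

Given ``m`` univariate association p-values for one SNP (one per phenotype),
each test here weights the p-values, selects the smallest weighted value and
reports it as the combined p-value for the joint null hypothesis that the SNP
is associated with none of the phenotypes:

* ``minp_bonf``  — Bonferroni: every p-value is weighted with ``m``.
* ``minp_ns``    — Nyholt/Šidák: weight is the effective number of phenotypes
  ``M_eff`` derived from the eigenvalue spectrum of their correlation matrix.
* ``simes``      — the p-values are sorted ascendingly and the j-th smallest
  is weighted with ``m/j``.
* ``tates``      — the extended Simes test: ``m`` and ``j`` are replaced by
  effective counts ``m_e`` and ``m_ej`` computed from eigenvalues of leading
  submatrices of the p-value correlation matrix, reordered to follow the
  ascending sort of the p-values.

All weights are >= 1, so weighted p-values are >= the raw ones; any weighted
value exceeding 1 is truncated to 1 before selection.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "CombinationResult",
    "validate_pvalues",
    "validate_correlation",
    "sort_ascending",
    "simes",
    "minp_bonf",
    "nyholt_meff",
    "minp_ns",
    "pval_correlation_map",
    "register_pvalue_map",
    "tates_effective_counts",
    "tates",
]

SYMMETRY_TOL = 1e-10
PSD_TOL = -1e-8


@dataclass
class CombinationResult:
    """Outcome of one combination test on one SNP.

    Attributes
    ----------
    method : str
        One of ``tates``, ``simes``, ``minp_bonf``, ``minp_ns``.
    combined_p : float
        The selected (smallest) weighted p-value, truncated to [0, 1].
    selected_index : int
        1-based rank ``j`` (in the ascending sort) of the selected value.
    weights : numpy.ndarray
        Weight applied to each sorted p-value, all >= 1.
    effective_counts : numpy.ndarray or None
        For ``tates``: ``m_ej`` for j = 1..m. For ``minp_ns``: the single
        value ``M_eff``. ``None`` otherwise.
    """

    method: str
    combined_p: float
    selected_index: int
    weights: np.ndarray
    effective_counts: np.ndarray | None = None


def validate_pvalues(p) -> np.ndarray:
    """Coerce to a 1-d float array of probabilities and check bounds."""
    arr = np.asarray(p, dtype=float)
    if arr.ndim != 1:
        raise ValueError("p-value vector must be one-dimensional")
    if arr.size == 0:
        raise ValueError("no p-values")
    if not np.all(np.isfinite(arr)):
        raise ValueError("p-values must be finite (no missing entries)")
    if np.any(arr < 0.0) or np.any(arr > 1.0):
        raise ValueError("p-values must lie in [0, 1]")
    return arr


def validate_correlation(R) -> np.ndarray:
    """Validate a correlation matrix: symmetric, unit diagonal, PSD.

    Symmetry is required within 1e-10; eigenvalues may undershoot zero by at
    most 1e-8 (numerical noise); off-diagonals must lie in [-1, 1].
    """
    mat = np.asarray(R, dtype=float)
    if mat.ndim != 2 or mat.shape[0] != mat.shape[1]:
        raise ValueError("correlation matrix must be square")
    if not np.all(np.isfinite(mat)):
        raise ValueError("invalid correlation matrix: non-finite entries")
    if np.max(np.abs(mat - mat.T)) > SYMMETRY_TOL:
        raise ValueError("invalid correlation matrix: not symmetric")
    if np.max(np.abs(np.diag(mat) - 1.0)) > SYMMETRY_TOL:
        raise ValueError("invalid correlation matrix: diagonal must be 1")
    if np.any(np.abs(mat) > 1.0 + SYMMETRY_TOL):
        raise ValueError("invalid correlation matrix: entries outside [-1, 1]")
    if np.min(np.linalg.eigvalsh(mat)) < PSD_TOL:
        raise ValueError("invalid correlation matrix: not positive semidefinite")
    return mat


def _clipped_eigvals(mat: np.ndarray) -> np.ndarray:
    """Eigenvalues of a symmetric PSD matrix, descending, negatives clipped.

    Eigenvalues below -1e-8 raise; values in [-1e-8, 0) are treated as 0.
    """
    lam = np.linalg.eigvalsh(mat)[::-1]
    if lam[-1] < PSD_TOL:
        raise ValueError("invalid correlation matrix: not positive semidefinite")
    return np.clip(lam, 0.0, None)


def sort_ascending(p) -> tuple[np.ndarray, np.ndarray]:
    """Sort p-values ascendingly, returning the sorted vector and permutation.

    The permutation maps sorted positions to original phenotype indices; ties
    are broken by original index (stable sort).
    """
    arr = validate_pvalues(p)
    perm = np.argsort(arr, kind="stable")
    return arr[perm], perm


def simes(p) -> CombinationResult:
    """Simes combination: min over j of (m/j) * p_(j) on sorted p-values."""
    sorted_p, _ = sort_ascending(p)
    m = sorted_p.size
    weights = m / np.arange(1, m + 1)
    weighted = np.minimum(weights * sorted_p, 1.0)
    j = int(np.argmin(weighted))
    return CombinationResult("simes", float(weighted[j]), j + 1, weights)


def minp_bonf(p) -> CombinationResult:
    """Bonferroni minP: m times the smallest p-value, truncated at 1."""
    sorted_p, _ = sort_ascending(p)
    m = sorted_p.size
    weights = np.full(m, float(m))
    combined = min(1.0, m * sorted_p[0])
    return CombinationResult("minp_bonf", float(combined), 1, weights)


def nyholt_meff(R) -> float:
    """Effective number of independent phenotypes from the eigenvalue spectrum.

    Uses the variance-of-eigenvalues form
    ``M_eff = 1 + (m - 1) * (1 - Var(lambda) / m)`` with the sample variance
    (denominator ``m - 1``). Equals ``m`` for the identity matrix and
    decreases towards 1 as off-diagonal correlation grows.
    """
    mat = validate_correlation(R)
    m = mat.shape[0]
    if m == 1:
        return 1.0
    lam = _clipped_eigvals(mat)
    var = float(np.var(lam, ddof=1))
    return 1.0 + (m - 1) * (1.0 - var / m)


def minp_ns(p, R, style: str = "mult") -> CombinationResult:
    """Effective-number-of-tests minP.

    The smallest p-value is corrected by ``M_eff`` (from :func:`nyholt_meff`)
    instead of ``m``; since ``M_eff <= m`` this is never stricter than
    :func:`minp_bonf`.

    Parameters
    ----------
    style : {"mult", "sidak"}
        ``"mult"``: ``min(1, M_eff * min(p))`` — the weighted form (default).
        ``"sidak"``: ``1 - (1 - min(p)) ** M_eff``.
    """
    sorted_p, _ = sort_ascending(p)
    mat = validate_correlation(R)
    if mat.shape[0] != sorted_p.size:
        raise ValueError(
            f"dimension mismatch: {sorted_p.size} p-values vs "
            f"{mat.shape[0]}x{mat.shape[0]} correlation matrix"
        )
    meff = nyholt_meff(mat)
    pmin = sorted_p[0]
    if style == "mult":
        combined = min(1.0, meff * pmin)
    elif style == "sidak":
        combined = 1.0 - (1.0 - pmin) ** meff
    else:
        raise ValueError(f"unknown minP_NS style: {style!r}")
    weights = np.full(sorted_p.size, meff)
    return CombinationResult(
        "minp_ns", float(combined), 1, weights, np.array([meff])
    )


_PVALUE_MAPS: dict = {}


def register_pvalue_map(name: str, fn) -> None:
    """Register a mapping from phenotypic to p-value correlations.

    ``fn`` receives a validated correlation matrix and must return another
    valid correlation matrix of the same dimension (e.g. the polynomial
    approximation used in the original TATES software).
    """
    _PVALUE_MAPS[name] = fn


register_pvalue_map("identity", lambda mat: mat)

#: Sixth-order polynomial approximating the correlation between two
#: two-sided test p-values from the correlation r of the underlying traits
#: (the approximation used by the GATES/TATES software). Even in r, so it
#: is applied to |r|; perfect correlations map to exactly 1.
_POLY_COEF = (0.2982, -0.0127, 0.0588, 0.0099, 0.6281, -0.0009, 0.0)


def _polynomial_map(mat: np.ndarray) -> np.ndarray:
    out = np.polyval(_POLY_COEF, np.abs(mat))
    out[np.abs(mat) >= 1.0 - 1e-12] = 1.0
    np.fill_diagonal(out, 1.0)
    return out


register_pvalue_map("tates_polynomial", _polynomial_map)

DEFAULT_PVALUE_MAP = "tates_polynomial"


def pval_correlation_map(R_pheno, mapping: str = DEFAULT_PVALUE_MAP) -> np.ndarray:
    """Approximate the correlation matrix of the m p-values.

    The default ``"tates_polynomial"`` mapping shrinks each phenotypic
    correlation through the polynomial approximation of the correlation
    between two-sided p-values; ``"identity"`` uses the phenotypic
    correlations directly. Further mappings can be added with
    :func:`register_pvalue_map`.
    """
    mat = validate_correlation(R_pheno)
    try:
        fn = _PVALUE_MAPS[mapping]
    except KeyError:
        raise ValueError(f"unknown p-value correlation map: {mapping!r}") from None
    return validate_correlation(fn(mat))


def tates_effective_counts(R_p, perm) -> np.ndarray:
    """Effective numbers of p-values ``m_ej`` for j = 1..m.

    ``m_ej = j - sum_i I(lambda_i > 1)(lambda_i - 1)`` where the lambda_i are
    eigenvalues of the leading j x j submatrix of ``R_p`` after reordering
    rows and columns by ``perm`` (phenotypes ordered by ascending p-value).
    ``m_ej`` is not guaranteed monotone in j.
    """
    mat = validate_correlation(R_p)
    perm = np.asarray(perm, dtype=int)
    m = mat.shape[0]
    if perm.shape != (m,) or sorted(perm.tolist()) != list(range(m)):
        raise ValueError("perm must be a permutation of 0..m-1")
    reordered = mat[np.ix_(perm, perm)]
    counts = np.empty(m)
    for j in range(1, m + 1):
        lam = _clipped_eigvals(reordered[:j, :j])
        excess = lam[lam > 1.0] - 1.0
        counts[j - 1] = j - excess.sum()
    return counts


def tates(p, R_pheno, mapping: str = DEFAULT_PVALUE_MAP) -> CombinationResult:
    """Trait-based Association Test using Extended Simes.

    The j-th smallest p-value is weighted with ``m_e / m_ej`` (effective
    counts from :func:`tates_effective_counts`); the smallest weighted value
    is the combined p-value. With an identity correlation matrix this reduces
    exactly to :func:`simes`.
    """
    sorted_p, perm = sort_ascending(p)
    R_p = pval_correlation_map(R_pheno, mapping)
    if R_p.shape[0] != sorted_p.size:
        raise ValueError(
            f"dimension mismatch: {sorted_p.size} p-values vs "
            f"{R_p.shape[0]}x{R_p.shape[0]} correlation matrix"
        )
    counts = tates_effective_counts(R_p, perm)
    me = counts[-1]
    weights = me / counts
    if np.any(weights < 1.0 - 1e-12):
        raise AssertionError("TATES weights must all be >= 1")
    weighted = np.minimum(weights * sorted_p, 1.0)
    j = int(np.argmin(weighted))
    return CombinationResult(
        "tates", float(weighted[j]), j + 1, weights, counts
    )
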