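"""Null-hypothesis data generation: genotypes and correlated phenotypes.

Each replicate of the simulation study draws, for N subjects, a single
unassociated diallelic variant (allele counts 0/1/2 under Hardy–Weinberg
equilibrium at a given MAF) and m phenotypes from a zero-mean multivariate
normal with unit variances and a prescribed correlation matrix. Genotypes
and phenotypes are drawn independently, so the global null holds by
construction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .combine import validate_correlation

__all__ = [
    "ScenarioSpec",
    "SimulatedDataset",
    "compound_symmetric",
    "trivariate_replication_matrix",
    "simulate_genotypes",
    "simulate_phenotypes",
    "simulate_null_dataset",
]


def compound_symmetric(m: int, r: float) -> np.ndarray:
    """Compound-symmetric (exchangeable) correlation matrix.

    Unit diagonal, all off-diagonals equal to ``r``. Positive semidefinite
    iff ``r`` lies in ``(-1/(m-1), 1]``; values outside raise.
    """
    if m < 1:
        raise ValueError("m must be >= 1")
    if m == 1:
        return np.ones((1, 1))
    lo = -1.0 / (m - 1)
    if not (lo < r <= 1.0):
        raise ValueError(
            f"compound symmetry with m={m} requires r in ({lo:.4g}, 1]"
        )
    mat = np.full((m, m), float(r))
    np.fill_diagonal(mat, 1.0)
    return mat


def trivariate_replication_matrix() -> np.ndarray:
    """The 3x3 trivariate correlation matrix from the replication scenarios.

    Pairwise correlations r12 = 0.81, r13 = 0.95, r23 = 0.78.
    """
    return np.array(
        [
            [1.00, 0.81, 0.95],
            [0.81, 1.00, 0.78],
            [0.95, 0.78, 1.00],
        ]
    )


def simulate_genotypes(n: int, maf: float, rng: np.random.Generator) -> np.ndarray:
    """Draw n allele counts under Hardy–Weinberg equilibrium.

    Counts are i.i.d. Binomial(2, maf), i.e. genotype frequencies
    ((1-maf)^2, 2 maf (1-maf), maf^2) for counts (0, 1, 2).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not (0.0 < maf <= 0.5):
        raise ValueError("maf must lie in (0, 0.5]")
    return rng.binomial(2, maf, size=n)


def _corr_factor(R: np.ndarray) -> np.ndarray:
    """Factor L with R = L L^T, tolerating singular (PSD) matrices."""
    try:
        return np.linalg.cholesky(R)
    except np.linalg.LinAlgError:
        lam, vec = np.linalg.eigh(R)
        return vec * np.sqrt(np.clip(lam, 0.0, None))


def simulate_phenotypes(n: int, R, rng: np.random.Generator) -> np.ndarray:
    """Draw n i.i.d. rows from MVN(0, R) with unit variances."""
    mat = validate_correlation(R)
    L = _corr_factor(mat)
    z = rng.standard_normal((n, mat.shape[0]))
    return z @ L.T


@dataclass
class ScenarioSpec:
    """One cell of the simulation study.

    Parameters
    ----------
    m : int
        Number of phenotypes (>= 1).
    corr : float or array-like
        A single r for a compound-symmetric structure, or a full m x m
        correlation matrix.
    n_subjects : int
        Sample size per replicate (default 2000).
    maf : float
        Minor allele frequency of the simulated variant, in (0, 0.5].
    nsim : int
        Number of Monte-Carlo replicates.
    alpha : float
        Nominal significance level for rejection counting.
    seed : int
        Seed for the scenario's random stream.
    """

    m: int
    corr: object
    n_subjects: int = 2000
    maf: float = 0.5
    nsim: int = 10_000
    alpha: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.m < 1:
            raise ValueError("m must be >= 1")
        if self.n_subjects < 3:
            raise ValueError("n_subjects must be >= 3")
        if not (0.0 < self.maf <= 0.5):
            raise ValueError("maf must lie in (0, 0.5]")
        if self.nsim < 1:
            raise ValueError("nsim must be >= 1")
        if not (0.0 < self.alpha < 1.0):
            raise ValueError("alpha must lie in (0, 1)")
        self.correlation_matrix()  # fail fast on an invalid structure

    def correlation_matrix(self) -> np.ndarray:
        """Resolve ``corr`` to a validated m x m correlation matrix."""
        if np.isscalar(self.corr):
            return compound_symmetric(self.m, float(self.corr))
        mat = validate_correlation(self.corr)
        if mat.shape[0] != self.m:
            raise ValueError(
                f"correlation matrix is {mat.shape[0]}x{mat.shape[0]} "
                f"but m={self.m}"
            )
        return mat


@dataclass
class SimulatedDataset:
    """Genotype vector (length N, values 0/1/2) and N x m phenotype matrix."""

    genotypes: np.ndarray
    phenotypes: np.ndarray

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes)
        self.phenotypes = np.asarray(self.phenotypes, dtype=float)
        if self.phenotypes.ndim != 2:
            raise ValueError("phenotypes must be an N x m matrix")
        if self.genotypes.shape[0] != self.phenotypes.shape[0]:
            raise ValueError("genotype and phenotype lengths differ")
        if not np.isin(self.genotypes, (0, 1, 2)).all():
            raise ValueError("genotypes must be allele counts in {0, 1, 2}")
        if not np.all(np.isfinite(self.phenotypes)):
            raise ValueError("phenotypes contain missing values")


def simulate_null_dataset(
    spec: ScenarioSpec, rng: np.random.Generator | None = None
) -> SimulatedDataset:
    """Draw one null dataset for a scenario.

    Genotypes are drawn first, then phenotypes, from the same stream (the
    documented split order), so a given seed reproduces the dataset exactly.
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    g = simulate_genotypes(spec.n_subjects, spec.maf, rng)
    y = simulate_phenotypes(spec.n_subjects, spec.correlation_matrix(), rng)
    return SimulatedDataset(g, y)
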