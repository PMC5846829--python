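"""Type-I-error simulation study for the four combination tests.

Each scenario simulates ``nsim`` independent null datasets (unassociated
variant, correlated multivariate-normal phenotypes), computes the m
univariate regression p-values per replicate, applies TATES, Simes,
Bonferroni minP and effective-number minP, and reports the fraction of
combined p-values below the nominal alpha. A 95% confidence interval for an
unbiased rate uses the binomial normal approximation
``alpha +/- 1.96 * sqrt(alpha * (1 - alpha) / nsim)``.

The replicate loop is vectorized in fixed-size batches, each drawing from
its own spawned substream of the scenario seed, so results for a given seed
do not change when ``nsim`` grows (earlier batches are a prefix).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .assoc import batch_pvalues
from .combine import (
    DEFAULT_PVALUE_MAP,
    minp_ns,
    nyholt_meff,
    pval_correlation_map,
    tates,
    tates_effective_counts,
)
from .simulate import ScenarioSpec, _corr_factor

__all__ = [
    "METHODS",
    "ScenarioSummary",
    "GridSummary",
    "PValueDistribution",
    "ci95",
    "classify_rate",
    "run_scenario",
    "run_grid",
    "default_grid_specs",
    "grid_table",
    "rejection_rates",
    "pvalue_distribution",
]

METHODS = ("tates", "simes", "minp_bonf", "minp_ns")

#: Reference replicate counts for the two-level CI flags (narrow, wide).
FLAG_NSIM_REFS = (100_000, 10_000)


def ci95(p: float, nsim: int) -> tuple[float, float]:
    """Normal-approximation 95% CI for an empirical rate around ``p``.

    ``SE = sqrt(p * (1 - p) / nsim)``; the interval is
    ``(p - 1.96 SE, p + 1.96 SE)``. ``p`` must lie strictly in (0, 1).
    """
    if not (0.0 < p < 1.0):
        raise ValueError("p must lie strictly in (0, 1)")
    if nsim < 1:
        raise ValueError("nsim must be >= 1")
    se = math.sqrt(p * (1.0 - p) / nsim)
    return p - 1.96 * se, p + 1.96 * se


def classify_rate(
    rate: float, alpha: float, nsim_refs: tuple[int, int] = FLAG_NSIM_REFS
) -> str:
    """Two-level CI membership flag for an empirical rejection rate.

    ``outside_10k`` if outside the wide CI (second reference nsim),
    ``outside_100k`` if outside only the narrow CI, else ``inside``.
    """
    narrow = ci95(alpha, nsim_refs[0])
    wide = ci95(alpha, nsim_refs[1])
    if not (wide[0] <= rate <= wide[1]):
        return "outside_10k"
    if not (narrow[0] <= rate <= narrow[1]):
        return "outside_100k"
    return "inside"


class _TatesWeightCache:
    """Per-permutation TATES weight vectors for a fixed correlation matrix.

    For an exchangeable (compound-symmetric) matrix every principal
    submatrix reached by a permutation is compound symmetric with the same
    r, so one weight vector serves all replicates. Otherwise weights are
    computed per distinct permutation and memoized.
    """

    def __init__(self, R_p: np.ndarray):
        self.R_p = R_p
        self.m = R_p.shape[0]
        off = R_p[~np.eye(self.m, dtype=bool)]
        if off.size == 0 or np.ptp(off) < 1e-12:
            self.fixed = self._weights(np.arange(self.m))
        else:
            self.fixed = None
            self._cache: dict[tuple, np.ndarray] = {}

    def _weights(self, perm: np.ndarray) -> np.ndarray:
        counts = tates_effective_counts(self.R_p, perm)
        return counts[-1] / counts

    def for_orders(self, orders: np.ndarray) -> np.ndarray:
        """Weight matrix (B, m) matching a (B, m) array of sort permutations."""
        if self.fixed is not None:
            return np.broadcast_to(self.fixed, orders.shape)
        uniq, inverse = np.unique(orders, axis=0, return_inverse=True)
        table = np.empty_like(uniq, dtype=float)
        for k, perm in enumerate(uniq):
            key = tuple(perm.tolist())
            if key not in self._cache:
                self._cache[key] = self._weights(perm)
            table[k] = self._cache[key]
        return table[inverse]


def _combine_batch(
    P: np.ndarray,
    meff: float,
    ns_style: str,
    wcache: _TatesWeightCache,
) -> np.ndarray:
    """Apply all four tests to a (B, m) batch of p-value vectors.

    Returns a (B, 4) array in METHODS order. Matches the scalar functions in
    :mod:`tates.combine` exactly.
    """
    B, m = P.shape
    order = np.argsort(P, axis=1, kind="stable")
    Ps = np.take_along_axis(P, order, axis=1)
    j = np.arange(1, m + 1)
    simes_c = np.minimum((m / j) * Ps, 1.0).min(axis=1)
    bonf_c = np.minimum(m * Ps[:, 0], 1.0)
    if ns_style == "mult":
        ns_c = np.minimum(meff * Ps[:, 0], 1.0)
    elif ns_style == "sidak":
        ns_c = 1.0 - (1.0 - Ps[:, 0]) ** meff
    else:
        raise ValueError(f"unknown minP_NS style: {ns_style!r}")
    W = wcache.for_orders(order)
    tates_c = np.minimum(W * Ps, 1.0).min(axis=1)
    return np.column_stack([tates_c, simes_c, bonf_c, ns_c])


def _combine_batch_sample_corr(
    P: np.ndarray, Y: np.ndarray, ns_style: str, pmap: str
) -> np.ndarray:
    """Sensitivity-mode combiner using each replicate's estimated correlations."""
    out = np.empty((P.shape[0], 4))
    m = P.shape[1]
    j = np.arange(1, m + 1)
    for i in range(P.shape[0]):
        Rhat = np.corrcoef(Y[i].T) if m > 1 else np.ones((1, 1))
        Ps = np.sort(P[i], kind="stable")
        out[i, 0] = tates(P[i], Rhat, mapping=pmap).combined_p
        out[i, 1] = np.minimum((m / j) * Ps, 1.0).min()
        out[i, 2] = min(1.0, m * Ps[0])
        out[i, 3] = minp_ns(P[i], Rhat, style=ns_style).combined_p
    return out


@dataclass
class ScenarioSummary:
    """Empirical Type I error of every method for one scenario.

    ``flags`` classifies each rate against the two reference CIs (see
    :func:`classify_rate`); ``ci_low``/``ci_high`` are the CI at the
    scenario's own nsim. ``pvalues`` holds the per-replicate combined
    p-values (columns in METHODS order) when the run kept them.
    """

    spec: ScenarioSpec
    rate_by_method: dict[str, float]
    ci_low: float
    ci_high: float
    flags: dict[str, str]
    pvalues: pd.DataFrame | None = None


@dataclass
class GridSummary:
    """Per-method aggregate over a list of scenarios (Table-style rows)."""

    mean: float
    sd: float
    largest_overshoot: float
    largest_undershoot: float
    sum_abs_dev: float


def run_scenario(
    spec: ScenarioSpec,
    *,
    ns_style: str = "mult",
    pmap: str = DEFAULT_PVALUE_MAP,
    batch_size: int = 500,
    keep_pvalues: bool = False,
    use_sample_corr: bool = False,
    nsim_refs: tuple[int, int] = FLAG_NSIM_REFS,
) -> ScenarioSummary:
    """Simulate one scenario end to end and estimate Type I error.

    For every replicate: draw a null dataset, regress each phenotype on the
    allele count, combine the m p-values with all four tests using the
    scenario's true correlation matrix (or, with ``use_sample_corr``, each
    replicate's estimated matrix), and count combined p-values strictly
    below ``spec.alpha``.
    """
    R = spec.correlation_matrix()
    R_p = pval_correlation_map(R, pmap)
    meff = nyholt_meff(R)
    L = _corr_factor(R)
    wcache = _TatesWeightCache(R_p)
    m, N = spec.m, spec.n_subjects

    n_batches = -(-spec.nsim // batch_size)
    children = np.random.SeedSequence(spec.seed).spawn(n_batches)
    combined = np.empty((spec.nsim, len(METHODS)))
    done = 0
    for child in children:
        rng = np.random.default_rng(child)
        # always draw a full batch so a partial final batch consumes the
        # stream identically and larger nsim extends (never rewrites) runs
        G = rng.binomial(2, spec.maf, size=(batch_size, N)).astype(float)
        # monomorphic draws carry no association test; redraw those rows
        while True:
            bad = np.ptp(G, axis=1) == 0
            if not bad.any():
                break
            G[bad] = rng.binomial(2, spec.maf, size=(int(bad.sum()), N))
        Y = rng.standard_normal((batch_size, N, m)) @ L.T
        B = min(batch_size, spec.nsim - done)
        P = batch_pvalues(G[:B], Y[:B])
        if use_sample_corr:
            combined[done : done + B] = _combine_batch_sample_corr(
                P, Y[:B], ns_style, pmap
            )
        else:
            combined[done : done + B] = _combine_batch(P, meff, ns_style, wcache)
        done += B

    rates = {
        method: float(np.mean(combined[:, k] < spec.alpha))
        for k, method in enumerate(METHODS)
    }
    low, high = ci95(spec.alpha, spec.nsim)
    flags = {
        method: classify_rate(rate, spec.alpha, nsim_refs)
        for method, rate in rates.items()
    }
    pvals = (
        pd.DataFrame(combined, columns=list(METHODS)) if keep_pvalues else None
    )
    return ScenarioSummary(spec, rates, low, high, flags, pvals)


def rejection_rates(summary: ScenarioSummary, alpha: float) -> dict[str, float]:
    """Re-count rejections of a kept-p-value run at another threshold."""
    if summary.pvalues is None:
        raise ValueError("scenario was run without keep_pvalues=True")
    return {
        method: float(np.mean(summary.pvalues[method].to_numpy() < alpha))
        for method in METHODS
    }


def default_grid_specs(
    nsim: int = 10_000,
    *,
    n_subjects: int = 2000,
    maf: float = 0.5,
    alpha: float = 0.05,
    seed: int = 0,
    ms: tuple[int, ...] = (2, 4, 8, 16),
    rs: tuple[float, ...] = (0.1, 0.3, 0.5, 0.7, 0.9),
) -> list[ScenarioSpec]:
    """The 20-cell study grid: m in {2,4,8,16} x compound-symmetric r.

    Per-scenario seeds are derived deterministically from ``seed``.
    """
    states = np.random.SeedSequence(seed).generate_state(len(ms) * len(rs))
    specs = []
    for k, (m, r) in enumerate((m, r) for m in ms for r in rs):
        specs.append(
            ScenarioSpec(
                m=m,
                corr=r,
                n_subjects=n_subjects,
                maf=maf,
                nsim=nsim,
                alpha=alpha,
                seed=int(states[k]) & 0x7FFFFFFF,
            )
        )
    return specs


def run_grid(
    specs: list[ScenarioSpec], **kwargs
) -> tuple[list[ScenarioSummary], dict[str, GridSummary]]:
    """Run every scenario and aggregate per-method summary statistics.

    Aggregates (over scenarios, per method): mean and SD of the rates,
    largest overshoot ``max(0, max rate - alpha)``, largest undershoot
    ``max(0, alpha - min rate)``, and the sum of absolute deviations from
    alpha. With a single scenario the SD is 0 by convention.
    """
    if not specs:
        raise ValueError("no scenarios supplied")
    summaries = [run_scenario(spec, **kwargs) for spec in specs]
    grid: dict[str, GridSummary] = {}
    for method in METHODS:
        rates = np.array([s.rate_by_method[method] for s in summaries])
        alphas = np.array([s.spec.alpha for s in summaries])
        dev = rates - alphas
        grid[method] = GridSummary(
            mean=float(rates.mean()),
            sd=float(rates.std(ddof=1)) if len(rates) > 1 else 0.0,
            largest_overshoot=max(0.0, float(dev.max())),
            largest_undershoot=max(0.0, -float(dev.min())),
            sum_abs_dev=float(np.abs(dev).sum()),
        )
    return summaries, grid


def grid_table(
    summaries: list[ScenarioSummary], grid: dict[str, GridSummary]
) -> pd.DataFrame:
    """Long-format table of the grid: one row per scenario plus summary rows.

    Columns: ``m``, ``r``, one rate column per method, one ``<method>_flag``
    overlay column per method, and ``outside_actual_ci`` listing the methods
    whose rate falls outside the CI at the scenario's own nsim.
    """
    rows = []
    for s in summaries:
        r_label = (
            float(s.spec.corr) if np.isscalar(s.spec.corr) else "matrix"
        )
        row: dict = {"m": s.spec.m, "r": r_label}
        outside = []
        for method in METHODS:
            rate = s.rate_by_method[method]
            row[method] = rate
            row[f"{method}_flag"] = s.flags[method]
            if not (s.ci_low <= rate <= s.ci_high):
                outside.append(method)
        row["outside_actual_ci"] = ",".join(outside)
        rows.append(row)
    for stat in ("mean", "largest_overshoot", "largest_undershoot",
                 "sum_abs_dev"):
        row = {"m": "", "r": stat}
        for method in METHODS:
            row[method] = getattr(grid[method], stat)
            row[f"{method}_flag"] = ""
        row["outside_actual_ci"] = ""
        rows.append(row)
    return pd.DataFrame(rows)


@dataclass
class PValueDistribution:
    """Histogram and uniformity diagnostics of combined null p-values."""

    spec: ScenarioSpec
    bin_edges: np.ndarray
    counts: pd.DataFrame  # one column per method, one row per bin
    ks_distance: dict[str, float]
    pvalues: pd.DataFrame  # the n_keep x methods values the stats refer to


def pvalue_distribution(
    spec: ScenarioSpec, n_keep: int = 10_000, bins: int = 20, **kwargs
) -> PValueDistribution:
    """Distribution of the combined null p-values of every method.

    Runs the scenario, keeps the first ``n_keep`` combined p-values per
    method, bins them into equal-width bins on [0, 1] and computes each
    method's Kolmogorov–Smirnov distance from Uniform(0, 1). Under the null
    the univariate p-values are uniform but weighted-selection combination
    p-values are not (except in the degenerate m = 1 case).
    """
    if n_keep > spec.nsim:
        raise ValueError("n_keep cannot exceed nsim")
    summary = run_scenario(spec, keep_pvalues=True, **kwargs)
    kept = summary.pvalues.iloc[:n_keep]
    edges = np.linspace(0.0, 1.0, bins + 1)
    counts = {}
    ks = {}
    for method in METHODS:
        vals = kept[method].to_numpy()
        counts[method], _ = np.histogram(vals, bins=edges)
        ks[method] = float(stats.kstest(vals, "uniform").statistic)
    return PValueDistribution(
        spec, edges, pd.DataFrame(counts), ks, kept.reset_index(drop=True)
    )
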