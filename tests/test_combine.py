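"""Unit and property tests for the four combination tests."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from tates import combine
from tates.simulate import compound_symmetric


# ---------------------------------------------------------------------------
# independent brute-force oracle (plain loops, no shared code paths)
# ---------------------------------------------------------------------------

def naive_combined(method, pvals, R=None, mapping="identity", style="mult"):
    """Minimal literal implementation of each min-over-j formula."""
    pairs = sorted(enumerate(pvals), key=lambda t: (t[1], t[0]))
    perm = [i for i, _ in pairs]
    sp = [v for _, v in pairs]
    m = len(sp)
    if method == "minp_bonf":
        return min(1.0, m * sp[0])
    if method == "simes":
        return min(min(1.0, (m / (j + 1)) * sp[j]) for j in range(m))
    if method == "minp_ns":
        lam = sorted(np.linalg.eigvalsh(np.asarray(R, float)), reverse=True)
        mean = sum(lam) / m
        var = sum((x - mean) ** 2 for x in lam) / (m - 1) if m > 1 else 0.0
        meff = 1.0 + (m - 1) * (1.0 - var / m)
        if style == "mult":
            return min(1.0, meff * sp[0])
        return 1.0 - (1.0 - sp[0]) ** meff
    if method == "tates":
        Rp = np.asarray(R, float).copy()
        if mapping == "tates_polynomial":
            a = np.abs(Rp)
            Rp = (0.2982 * a**6 - 0.0127 * a**5 + 0.0588 * a**4
                  + 0.0099 * a**3 + 0.6281 * a**2 - 0.0009 * a)
            Rp[a >= 1 - 1e-12] = 1.0
            np.fill_diagonal(Rp, 1.0)
        sub_full = Rp[np.ix_(perm, perm)]
        mej = []
        for j in range(1, m + 1):
            lam = np.linalg.eigvalsh(sub_full[:j, :j])
            mej.append(j - sum(x - 1 for x in lam if x > 1))
        me = mej[-1]
        return min(
            min(1.0, (me / mej[j]) * sp[j]) for j in range(m)
        )
    raise ValueError(method)


def random_psd_corr(rng, m):
    A = rng.standard_normal((m, m + 2))
    S = A @ A.T
    d = np.sqrt(np.diag(S))
    R = S / np.outer(d, d)
    return (R + R.T) / 2.0


# ---------------------------------------------------------------------------
# worked examples
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "p, expected_sorted, expected_perm",
    [
        ([0.04, 0.01, 0.9], [0.01, 0.04, 0.9], [1, 0, 2]),
        ([0.05, 0.05], [0.05, 0.05], [0, 1]),
        ([0.7], [0.7], [0]),
    ],
)
def test_sort_ascending(p, expected_sorted, expected_perm):
    sp, perm = combine.sort_ascending(p)
    np.testing.assert_array_equal(sp, expected_sorted)
    np.testing.assert_array_equal(perm, expected_perm)


def test_sort_empty_rejected():
    with pytest.raises(ValueError, match="no p-values"):
        combine.sort_ascending([])


@pytest.mark.parametrize(
    "p, expected",
    [([0.01, 0.04, 0.9], 0.03), ([0.5], 0.5), ([0.05, 0.05], 0.05)],
)
def test_simes_examples(p, expected):
    res = combine.simes(p)
    assert res.combined_p == pytest.approx(expected, abs=1e-15)


@pytest.mark.parametrize(
    "p, expected",
    [([0.01, 0.04], 0.02), ([0.5], 0.5), ([0.9, 0.95], 1.0)],
)
def test_minp_bonf_examples(p, expected):
    res = combine.minp_bonf(p)
    assert res.combined_p == pytest.approx(expected, abs=1e-15)
    assert res.selected_index == 1


@pytest.mark.parametrize(
    "R, expected",
    [
        (np.eye(4), 4.0),
        ([[1.0, 1.0], [1.0, 1.0]], 1.0),
        ([[1.0, 0.5], [0.5, 1.0]], 1.75),
    ],
)
def test_nyholt_meff(R, expected):
    assert combine.nyholt_meff(R) == pytest.approx(expected, abs=1e-12)


def test_nyholt_meff_decreases_with_correlation():
    vals = [combine.nyholt_meff(compound_symmetric(5, r))
            for r in (0.0, 0.2, 0.5, 0.8)]
    assert all(a > b for a, b in zip(vals, vals[1:]))
    assert vals[0] == pytest.approx(5.0)


def test_nyholt_rejects_non_psd():
    bad = np.array([[1.0, 0.9, -0.9], [0.9, 1.0, 0.9], [-0.9, 0.9, 1.0]])
    with pytest.raises(ValueError, match="positive semidefinite"):
        combine.nyholt_meff(bad)


@pytest.mark.parametrize(
    "p, R, style, expected",
    [
        ([0.01, 0.04], np.eye(2), "mult", 0.02),
        ([0.01, 0.04], [[1.0, 1.0], [1.0, 1.0]], "mult", 0.01),
        ([0.02, 0.5], [[1.0, 0.5], [0.5, 1.0]], "mult", 0.035),
    ],
)
def test_minp_ns_examples(p, R, style, expected):
    res = combine.minp_ns(p, R, style=style)
    assert res.combined_p == pytest.approx(expected, abs=1e-12)


def test_minp_ns_dimension_mismatch():
    with pytest.raises(ValueError, match="dimension mismatch"):
        combine.minp_ns([0.1, 0.2, 0.3], np.eye(2))


@pytest.mark.parametrize(
    "R, perm, expected",
    [
        (np.eye(3), [0, 1, 2], [1.0, 2.0, 3.0]),
        ([[1.0, 1.0], [1.0, 1.0]], [0, 1], [1.0, 1.0]),
        ([[1.0, 0.5], [0.5, 1.0]], [0, 1], [1.0, 1.5]),
    ],
)
def test_tates_effective_counts(R, perm, expected):
    got = combine.tates_effective_counts(R, perm)
    np.testing.assert_allclose(got, expected, atol=1e-12)


@pytest.mark.parametrize(
    "p, R, mapping, expected",
    [
        ([0.01, 0.04, 0.9], np.eye(3), "identity", 0.03),
        ([0.02, 0.5], [[1.0, 1.0], [1.0, 1.0]], "identity", 0.02),
        ([0.02, 0.5], [[1.0, 0.5], [0.5, 1.0]], "identity", 0.03),
    ],
)
def test_tates_examples(p, R, mapping, expected):
    res = combine.tates(p, R, mapping=mapping)
    assert res.combined_p == pytest.approx(expected, abs=1e-12)


def test_tates_largest_sorted_pvalue_has_unit_weight(rng):
    R = random_psd_corr(rng, 5)
    res = combine.tates(rng.uniform(size=5), R)
    assert res.weights[-1] == pytest.approx(1.0)
    assert np.all(res.weights >= 1.0 - 1e-12)


# ---------------------------------------------------------------------------
# p-value correlation maps
# ---------------------------------------------------------------------------

def test_pval_map_identity_fixes_matrix():
    R = compound_symmetric(3, 0.5)
    np.testing.assert_array_equal(
        combine.pval_correlation_map(R, "identity"), R
    )
    np.testing.assert_array_equal(
        combine.pval_correlation_map(np.eye(4), "identity"), np.eye(4)
    )


def test_pval_map_polynomial_properties():
    # fixes independence and perfect correlation; shrinks moderate r;
    # even in the sign of r; output is a valid correlation matrix
    out = combine.pval_correlation_map(np.eye(3), "tates_polynomial")
    np.testing.assert_allclose(out, np.eye(3), atol=1e-15)
    perfect = combine.pval_correlation_map(
        [[1.0, 1.0], [1.0, 1.0]], "tates_polynomial"
    )
    assert perfect[0, 1] == 1.0
    pos = combine.pval_correlation_map(
        compound_symmetric(2, 0.6), "tates_polynomial"
    )
    neg = combine.pval_correlation_map(
        compound_symmetric(2, -0.6), "tates_polynomial"
    )
    assert 0.0 < pos[0, 1] < 0.6
    assert neg[0, 1] == pytest.approx(pos[0, 1])


def test_pval_map_unknown_name():
    with pytest.raises(ValueError, match="unknown p-value correlation map"):
        combine.pval_correlation_map(np.eye(2), "nope")


def test_register_pvalue_map_roundtrip():
    combine.register_pvalue_map("halve_offdiag", lambda m: np.eye(len(m)) + (m - np.eye(len(m))) / 2)
    out = combine.pval_correlation_map(compound_symmetric(2, 0.8), "halve_offdiag")
    assert out[0, 1] == pytest.approx(0.4)


# ---------------------------------------------------------------------------
# validation errors
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("bad", [[0.1, 1.2], [-0.01], [0.2, np.nan]])
def test_invalid_pvalues_rejected(bad):
    with pytest.raises(ValueError):
        combine.validate_pvalues(bad)


@pytest.mark.parametrize(
    "bad",
    [
        [[1.0, 0.5], [0.4, 1.0]],          # asymmetric
        [[1.0, 0.5], [0.5, 0.9]],          # diagonal != 1
        [[1.0, 1.5], [1.5, 1.0]],          # off-diagonal outside [-1, 1]
    ],
)
def test_invalid_correlation_rejected(bad):
    with pytest.raises(ValueError, match="correlation matrix"):
        combine.validate_correlation(bad)


def test_degenerate_pvalues_propagate():
    assert combine.simes([0.0, 0.3]).combined_p == 0.0
    assert combine.minp_bonf([1.0, 1.0]).combined_p == 1.0
    assert combine.tates([0.0, 1.0], np.eye(2)).combined_p == 0.0


# ---------------------------------------------------------------------------
# properties
# ---------------------------------------------------------------------------

pvec = st.lists(
    st.floats(min_value=0.0, max_value=1.0, allow_nan=False),
    min_size=1, max_size=6,
)


@given(pvec, st.integers(0, 2**31 - 1))
def test_all_methods_bounded_and_weighted_geq_raw(p, seed):
    rng = np.random.default_rng(seed)
    R = random_psd_corr(rng, len(p))
    sp, _ = combine.sort_ascending(p)
    for res in (
        combine.simes(p),
        combine.minp_bonf(p),
        combine.minp_ns(p, R),
        combine.tates(p, R),
    ):
        assert 0.0 <= res.combined_p <= 1.0
        assert np.all(res.weights >= 1.0 - 1e-12)
        weighted = np.minimum(res.weights * sp, 1.0)
        # capping at 1 may pull a weighted value below the raw one only
        # when the raw value itself exceeds 1, which cannot happen
        assert np.all(weighted >= sp - 1e-15)


@given(st.floats(min_value=0.0, max_value=1.0, allow_nan=False))
def test_m1_identity_reduction(p):
    R = np.eye(1)
    for res in (
        combine.simes([p]),
        combine.minp_bonf([p]),
        combine.minp_ns([p], R),
        combine.tates([p], R),
    ):
        assert res.combined_p == pytest.approx(p, abs=1e-15)


@given(pvec)
def test_identity_correlation_reductions(p):
    R = np.eye(len(p))
    assert combine.tates(p, R).combined_p == combine.simes(p).combined_p
    assert (
        combine.minp_ns(p, R, style="mult").combined_p
        == combine.minp_bonf(p).combined_p
    )


@given(pvec, st.integers(0, 2**31 - 1))
def test_simes_and_ns_never_stricter_than_bonferroni(p, seed):
    rng = np.random.default_rng(seed)
    R = random_psd_corr(rng, len(p))
    bonf = combine.minp_bonf(p).combined_p
    assert combine.simes(p).combined_p <= bonf + 1e-15
    assert combine.minp_ns(p, R).combined_p <= bonf + 1e-15


@given(pvec, st.data())
def test_monotone_in_each_pvalue(p, data):
    idx = data.draw(st.integers(0, len(p) - 1))
    shrink = data.draw(st.floats(min_value=0.0, max_value=1.0))
    rng = np.random.default_rng(7)
    R = random_psd_corr(rng, len(p))
    q = list(p)
    q[idx] = p[idx] * shrink
    for fn in (
        combine.simes,
        combine.minp_bonf,
        lambda v: combine.minp_ns(v, R),
    ):
        assert fn(q).combined_p <= fn(p).combined_p + 1e-12


@given(pvec, st.data())
def test_tates_monotone_under_exchangeable_correlation(p, data):
    # with an exchangeable matrix the weight vector does not depend on the
    # sort permutation, so shrinking any p-value cannot raise the combined p
    idx = data.draw(st.integers(0, len(p) - 1))
    shrink = data.draw(st.floats(min_value=0.0, max_value=1.0))
    R = compound_symmetric(len(p), 0.6 if len(p) > 1 else 0.0)
    q = list(p)
    q[idx] = p[idx] * shrink
    assert (
        combine.tates(q, R).combined_p
        <= combine.tates(p, R).combined_p + 1e-12
    )


@pytest.mark.parametrize("m", [2, 3, 4])
@pytest.mark.parametrize("mapping", ["identity", "tates_polynomial"])
def test_oracle_equivalence_small_m(m, mapping, rng):
    for _ in range(25):
        p = rng.uniform(size=m)
        R = random_psd_corr(rng, m)
        assert combine.simes(p).combined_p == pytest.approx(
            naive_combined("simes", p), abs=1e-12
        )
        assert combine.minp_bonf(p).combined_p == pytest.approx(
            naive_combined("minp_bonf", p), abs=1e-12
        )
        for style in ("mult", "sidak"):
            assert combine.minp_ns(p, R, style=style).combined_p == pytest.approx(
                naive_combined("minp_ns", p, R, style=style), abs=1e-12
            )
        assert combine.tates(p, R, mapping=mapping).combined_p == pytest.approx(
            naive_combined("tates", p, R, mapping=mapping), abs=1e-12
        )


def test_simes_exact_size_under_independence(rng):
    # Simes' theorem: size exactly alpha for independent uniforms
    m, nsim, alpha = 5, 200_000, 0.05
    P = rng.uniform(size=(nsim, m))
    Ps = np.sort(P, axis=1)
    combined = ((m / np.arange(1, m + 1)) * Ps).min(axis=1)
    rate = (combined < alpha).mean()
    se = np.sqrt(alpha * (1 - alpha) / nsim)
    assert abs(rate - alpha) < 3 * se
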