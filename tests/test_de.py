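"""Normalisation, dispersion, NB exact test and BH adjustment."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from fibromir import de


def _frame(array, prefix="s"):
    array = np.asarray(array)
    return pd.DataFrame(
        array,
        index=[f"m{i}" for i in range(array.shape[0])],
        columns=[f"{prefix}{j}" for j in range(array.shape[1])],
    )


# ---------------------------------------------------------------- size factors
def test_size_factors_identical_columns():
    counts = _frame([[5, 5], [9, 9], [2, 2]])
    f = de.size_factors(counts)
    assert f.iloc[0] == pytest.approx(f.iloc[1])


def test_size_factors_proportional_columns():
    counts = _frame([[5, 15], [9, 27], [2, 6]])
    f = de.size_factors(counts)
    assert f.iloc[1] / f.iloc[0] == pytest.approx(3.0)


def test_size_factors_hand_example():
    """[[2, 4], [6, 12]] -> factors (1/sqrt(2), sqrt(2))."""
    f = de.size_factors(_frame([[2, 4], [6, 12]]))
    assert f.to_numpy() == pytest.approx([1 / np.sqrt(2), np.sqrt(2)])


def test_size_factors_column_equivariance(rng):
    """Scaling one column by c scales its factor by c relative to the others."""
    counts = _frame(rng.poisson(50, size=(40, 4)) + 1)
    base = de.size_factors(counts)
    scaled = counts.copy()
    scaled.iloc[:, 2] = (scaled.iloc[:, 2] * 5).astype(int)
    after = de.size_factors(scaled)
    # factors are defined up to the geometric-mean reference: compare ratios
    assert after.iloc[2] / after.iloc[0] == pytest.approx(5 * base.iloc[2] / base.iloc[0])
    assert after.iloc[1] / after.iloc[0] == pytest.approx(base.iloc[1] / base.iloc[0])


def test_size_factors_need_positive_row():
    counts = _frame([[0, 4], [6, 0]])
    with pytest.raises(ValueError):
        de.size_factors(counts)


# ----------------------------------------------------------------- dispersion
def test_dispersion_constant_counts_hits_floor():
    counts = _frame(np.full((3, 6), 7.0))
    groups = pd.Series(["A"] * 3 + ["B"] * 3, index=counts.columns)
    alpha = de.estimate_dispersion(counts, groups, floor=1e-8)
    assert (alpha == 1e-8).all()


def test_dispersion_poisson_counts_near_zero(rng):
    counts = _frame(rng.poisson(100, size=(300, 200)).astype(float))
    groups = pd.Series(["A"] * 100 + ["B"] * 100, index=counts.columns)
    alpha = de.estimate_dispersion(counts, groups)
    assert np.median(alpha) < 0.01


def test_dispersion_recovers_planted_alpha(rng):
    size = 1 / 0.2
    mu = 200.0
    counts = _frame(rng.negative_binomial(size, size / (size + mu), size=(300, 100)).astype(float))
    groups = pd.Series(["A"] * 50 + ["B"] * 50, index=counts.columns)
    alpha = de.estimate_dispersion(counts, groups)
    assert 0.1 <= np.median(alpha) <= 0.3


def test_dispersion_single_sample_group_rejected():
    counts = _frame([[1, 2, 3]])
    groups = pd.Series(["A", "A", "B"], index=counts.columns)
    with pytest.raises(ValueError):
        de.estimate_dispersion(counts, groups)


# ----------------------------------------------------------------- exact test
def brute_force_exact(k_a, k_b, mu_a, mu_b, alpha_a, alpha_b):
    """Independent plain-Python enumeration of the conditional two-sided test."""

    def pmf(k, mu, alpha):
        if alpha < 1e-12:
            return stats.poisson.pmf(k, mu)
        size = 1.0 / alpha
        return stats.nbinom.pmf(k, size, size / (size + mu))

    K = k_a + k_b
    if K == 0:
        return 1.0
    probs = [pmf(a, mu_a, alpha_a) * pmf(K - a, mu_b, alpha_b) for a in range(K + 1)]
    obs = probs[k_a]
    return min(1.0, sum(p for p in probs if p <= obs * (1 + 1e-7)) / sum(probs))


def test_exact_test_symmetric_split_is_one():
    assert de.nb_exact_test(10, 10, 10.0, 10.0, 0.1) == pytest.approx(1.0)


def test_exact_test_zero_total_convention():
    assert de.nb_exact_test(0, 0, 5.0, 5.0, 0.1) == 1.0


def test_exact_test_binomial_limit():
    """alpha -> 0, equal means, K = 4, observed (0, 4): two-sided tail 2/16."""
    assert de.nb_exact_test(0, 4, 2.0, 2.0, 0.0) == pytest.approx(0.125, rel=1e-9)


def test_exact_test_matches_brute_force(rng):
    """Random small instances agree with the enumeration oracle to 1e-12."""
    for _ in range(200):
        K = int(rng.integers(1, 51))
        k_a = int(rng.integers(0, K + 1))
        mu_a = float(np.exp(rng.uniform(-1, 3)))
        mu_b = float(np.exp(rng.uniform(-1, 3)))
        alpha = float(rng.uniform(0, 0.5))
        got = de.nb_exact_test(k_a, K - k_a, mu_a, mu_b, alpha, alpha)
        want = brute_force_exact(k_a, K - k_a, mu_a, mu_b, alpha, alpha)
        assert got == pytest.approx(want, rel=1e-12)


def test_exact_test_rejects_bad_input():
    with pytest.raises(ValueError):
        de.nb_exact_test(-1, 2, 1.0, 1.0, 0.1)
    with pytest.raises(ValueError):
        de.nb_exact_test(1, 2, 1.0, 1.0, -0.1)


# -------------------------------------------------------------------------- BH
def test_bh_examples():
    assert de.adjust_bh([0.03]) == pytest.approx([0.03])
    assert de.adjust_bh([0.01, 0.02, 0.03]) == pytest.approx([0.03, 0.03, 0.03])
    assert de.adjust_bh([1.0, 1.0, 1.0]) == pytest.approx([1.0, 1.0, 1.0])


def test_bh_step_up_oracle(rng):
    """Matches a direct implementation of the step-up definition."""
    p = rng.uniform(size=37)
    m = len(p)
    order = np.argsort(p)
    stepped = np.minimum(1, p[order] * m / np.arange(1, m + 1))
    stepped = np.minimum.accumulate(stepped[::-1])[::-1]
    expected = np.empty(m)
    expected[order] = stepped
    assert de.adjust_bh(p) == pytest.approx(expected)


def test_bh_monotone_and_bounded(rng):
    p = rng.uniform(size=100)
    padj = de.adjust_bh(p)
    assert (padj >= p - 1e-12).all() and (padj <= 1.0).all()
    order = np.argsort(p)
    assert (np.diff(padj[order]) >= -1e-12).all()


def test_bh_rejects_out_of_range():
    with pytest.raises(ValueError):
        de.adjust_bh([0.5, 1.5])


# --------------------------------------------------------- full DE model fit
def test_all_zero_row_convention(rng):
    counts = _frame(rng.poisson(30, size=(10, 6)))
    counts.iloc[3] = 0
    groups = pd.Series(["A"] * 3 + ["B"] * 3, index=counts.columns)
    res = de.differential_expression(counts, groups)
    assert res.results.iloc[3]["pvalue"] == 1.0
    assert res.results.iloc[3]["log2FoldChange"] == 0.0


def test_row_permutation_invariance(rng):
    counts = _frame(rng.poisson(40, size=(30, 8)))
    groups = pd.Series(["A"] * 4 + ["B"] * 4, index=counts.columns)
    res = de.differential_expression(counts, groups)
    perm = rng.permutation(counts.index)
    res_perm = de.differential_expression(counts.loc[perm], groups)
    pd.testing.assert_frame_equal(res.results.loc[perm], res_perm.results)


def test_planted_fold_change_recovered(rng):
    """Planted 4-fold miRNAs: median recovered log2FC within +/-0.3 of 2."""
    n_mir, n_planted, shift = 200, 20, 4.0
    mu = rng.uniform(50, 500, size=n_mir)
    size = 1 / 0.05
    mu_mat = np.tile(mu[:, None], (1, 10)).astype(float)
    mu_mat[:n_planted, 5:] *= shift  # a minority of miRNAs is 4-fold up in group B
    counts = _frame(rng.negative_binomial(size, size / (size + mu_mat)))
    groups = pd.Series(["A"] * 5 + ["B"] * 5, index=counts.columns)
    res = de.differential_expression(counts, groups, reference="A")
    median_lfc = res.results.iloc[:n_planted]["log2FoldChange"].median()
    assert median_lfc == pytest.approx(2.0, abs=0.3)
    # and the planted miRNAs dominate the significant set
    sig = res.significant(0.05, 1.0)
    assert len(sig) >= 15
    assert sig.index.str.replace("m", "").astype(int).max() < n_planted


def test_contrast_orientation_and_summary(small_cohort):
    _, counts, _, truth = small_cohort
    model = de.DifferentialExpression(counts, truth.group, reference="control")
    res = model.fit()
    assert res.group_a == "control" and res.group_b == "DMD"
    text = res.summary()
    assert "DMD vs control" in text and "miRNAs tested" in text
    with pytest.raises(ValueError):
        de.DifferentialExpression(counts, truth.group, reference="nope")
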