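"""Likelihood-model tests: closed forms, exact oracles, Monte Carlo, LRT."""

import itertools

import numpy as np
import pytest
from scipy.linalg import expm

from crisprtrace.models import (
    ALPHA_BOUNDS,
    BranchDeletionData,
    DeletionDataset,
    alpha_bias_correction,
    bdm_branch_loglik,
    estimate_params,
    focal_conditioned_geometric_fit,
    geometric_pmf,
    group_loglik,
    idm_branch_loglik,
    lrt,
    unobserved_correction,
)
from crisprtrace.phylo import Phylogeny


# ----------------------------------------------------------------------
# Independent oracle: CTMC over ALL 2^N subsets, built from the model
# rules by direct enumeration (positions re-indexed after each deletion).
# ----------------------------------------------------------------------

def full_space_prob(t, N, target_deleted, rho, alpha):
    states = list(itertools.product([0, 1], repeat=N))
    idx = {s: i for i, s in enumerate(states)}
    Q = np.zeros((len(states), len(states)))
    p = 1 / alpha
    for s in states:
        present = [i for i in range(N) if s[i]]
        m = len(present)
        for j in range(m):
            for k in range(1, m - j + 1):
                rate = rho * (1 - p) ** (k - 1) * p
                tgt = list(s)
                for q_ in present[j:j + k]:
                    tgt[q_] = 0
                Q[idx[s], idx[tuple(tgt)]] += rate
    np.fill_diagonal(Q, 0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    P = expm(Q * t)
    full = tuple([1] * N)
    tgt = tuple(0 if (i + 1) in target_deleted else 1 for i in range(N))
    return P[idx[full], idx[tgt]]


def mc_branch_deletions(t, N, rho, alpha, n_rep, rng):
    """Simulate the branch process directly; returns deleted frozensets."""
    out = []
    p = 1 / alpha
    for _ in range(n_rep):
        present = list(range(1, N + 1))
        time = 0.0
        while present:
            rate = rho * len(present)
            time += rng.exponential(1 / rate)
            if time > t:
                break
            i = rng.integers(len(present))
            L = rng.geometric(p)
            if i + L <= len(present):
                del present[i:i + L]
        out.append(frozenset(range(1, N + 1)) - frozenset(present))
    return out


def test_geometric_pmf_head_and_normalisation():
    assert geometric_pmf(1, 2.7) == pytest.approx(1 / 2.7)
    assert round(100 * geometric_pmf(1, 2.7)) == 37
    assert geometric_pmf(1, 1.0) == 1.0
    assert geometric_pmf(5, 1.0) == 0.0
    ks = np.arange(1, 10_001)
    for alpha in (1.0, 2.7, 10.0):
        assert geometric_pmf(ks, alpha).sum() == pytest.approx(1.0, abs=1e-8)
    with pytest.raises(ValueError):
        geometric_pmf(1, 0.5)


def test_idm_closed_forms():
    assert idm_branch_loglik(0.0, 5, 0, 1.0) == 0.0
    # rho*t = ln 2: every spacer deleted or kept with probability 1/2
    t = np.log(2)
    assert idm_branch_loglik(t, 3, 1, 1.0) == pytest.approx(np.log(0.125))
    with pytest.raises(ValueError):
        idm_branch_loglik(-1.0, 3, 1, 1.0)
    with pytest.raises(ValueError):
        idm_branch_loglik(1.0, 3, 4, 1.0)


def test_bdm_equals_idm_at_alpha_one():
    rng = np.random.default_rng(0)
    for _ in range(25):
        N = int(rng.integers(1, 12))
        k = int(rng.integers(0, N + 1))
        deleted = tuple(sorted(rng.choice(np.arange(1, N + 1), k, replace=False)))
        t, rho = float(rng.uniform(0.01, 3)), float(rng.uniform(0.01, 3))
        d = BranchDeletionData("b", t, N, deleted)
        assert bdm_branch_loglik(d, rho, 1.0) == pytest.approx(
            idm_branch_loglik(t, N, k, rho), rel=1e-12
        )


def test_bdm_matches_full_space_oracle():
    rng = np.random.default_rng(1)
    for _ in range(40):
        N = int(rng.integers(1, 8))
        k = int(rng.integers(0, N + 1))
        deleted = tuple(sorted(rng.choice(np.arange(1, N + 1), k, replace=False)))
        t = float(rng.uniform(0.05, 2))
        rho = float(rng.uniform(0.05, 2))
        alpha = float(rng.uniform(1, 6))
        d = BranchDeletionData("b", t, N, deleted)
        expected = full_space_prob(t, N, set(deleted), rho, alpha)
        assert np.exp(bdm_branch_loglik(d, rho, alpha)) == pytest.approx(
            expected, abs=1e-10
        )


def test_bdm_single_spacer_closed_form():
    # with one spacer only length-1 events survive the boundary rule
    d = BranchDeletionData("b", 1.3, 1, (1,))
    assert np.exp(bdm_branch_loglik(d, 0.5, 3.0)) == pytest.approx(
        1 - np.exp(-0.5 / 3.0 * 1.3), rel=1e-12
    )


@pytest.mark.parametrize("N,alpha", [(6, 2.5), (8, 1.7), (8, 4.0)])
def test_bdm_normalisation_over_all_outcomes(N, alpha):
    t, rho = 0.7, 0.8
    total = 0.0
    for r in range(N + 1):
        for deleted in itertools.combinations(range(1, N + 1), r):
            d = BranchDeletionData("b", t, N, deleted)
            total += np.exp(bdm_branch_loglik(d, rho, alpha))
    assert total == pytest.approx(1.0, abs=1e-8)


def test_bdm_matches_monte_carlo():
    """Exact branch probabilities agree with simulation within 3 SE."""
    rng = np.random.default_rng(7)
    t, N, rho, alpha = 0.6, 7, 0.5, 3.0
    n_rep = 100_000
    draws = mc_branch_deletions(t, N, rho, alpha, n_rep, rng)
    from collections import Counter

    freq = Counter(draws)
    for outcome in [frozenset(), frozenset({3}), frozenset({3, 4}),
                    frozenset({1, 2}), frozenset({5, 6, 7}),
                    frozenset({2, 5})]:
        p_hat = freq[outcome] / n_rep
        d = BranchDeletionData("b", t, N, tuple(sorted(outcome)))
        p = np.exp(bdm_branch_loglik(d, rho, alpha))
        se = np.sqrt(p * (1 - p) / n_rep)
        assert abs(p_hat - p) < 3 * se + 1e-12, (outcome, p_hat, p)


def test_bdm_interior_marginal_rate_is_rho_alpha():
    """P(middle spacer deleted) ~ rho*alpha*t for small t, interior position."""
    rho, alpha, t, N = 0.5, 3.0, 0.01, 40
    rng = np.random.default_rng(3)
    n_rep = 30_000
    hits = 0
    for _ in range(n_rep):
        present = list(range(1, N + 1))
        time = rng.exponential(1 / (rho * N))
        while time <= t:
            i = rng.integers(len(present))
            L = rng.geometric(1 / alpha)
            if i + L <= len(present):
                del present[i:i + L]
            if not present:
                break
            time += rng.exponential(1 / (rho * len(present)))
        if 20 not in present:
            hits += 1
    p_hat = hits / n_rep
    p_expected = rho * alpha * t
    se = np.sqrt(p_expected * (1 - p_expected) / n_rep)
    assert abs(p_hat - p_expected) < 3 * se + 0.05 * p_expected


def test_unobserved_correction_recursion_and_monotonicity(cherry_tree):
    # two leaf children at distance t with rho*t = ln 2: q = 1/4
    t = np.log(2) / 1.0
    tree = Phylogeny([-1, 0, 0], [0.0, t, t], ["R", "a0", "a1"])
    assert unobserved_correction(tree, "R", 1.0) == pytest.approx(0.75)
    assert unobserved_correction(tree, "a0", 1.0) == 1.0
    factors = [unobserved_correction(tree, "R", r) for r in (0.1, 0.5, 1, 2, 5)]
    assert all(a >= b for a, b in zip(factors, factors[1:]))
    with pytest.raises(KeyError):
        unobserved_correction(tree, "missing", 1.0)


def test_group_loglik_additive_and_monotone(cherry_tree):
    b1 = BranchDeletionData("a0", 0.5, 5, (2,))
    b2 = BranchDeletionData("a1", 0.5, 5, ())
    ds1 = DeletionDataset(cherry_tree, [b1], {}, 5.0)
    ds2 = DeletionDataset(cherry_tree, [b2], {}, 5.0)
    both = DeletionDataset(cherry_tree, [b1, b2], {}, 5.0)
    ll = group_loglik(both, 0.4, 2.0, corrections=False)
    assert ll == pytest.approx(
        group_loglik(ds1, 0.4, 2.0, corrections=False)
        + group_loglik(ds2, 0.4, 2.0, corrections=False)
    )
    # with no deletions, likelihood decreases as rho grows
    lls = [group_loglik(ds2, r, 1.0, corrections=False) for r in (0.1, 1, 10)]
    assert lls[0] > lls[1] > lls[2]
    with pytest.raises(ValueError):
        DeletionDataset(cherry_tree, [], {}, 5.0)


def test_alpha_bias_correction_limits():
    assert alpha_bias_correction(1.0, 5) == 1.0
    a = alpha_bias_correction(3.0, 10**6)
    assert abs(a - 3.0) / 3.0 < 1e-4
    # corrected value exceeds the raw MLE for small samples (upward shift)
    assert alpha_bias_correction(3.0, 10) > 3.0


def test_alpha_bias_correction_reduces_bias():
    """The geometric success-probability MLE p = 1/alpha is biased high
    for small samples; the first-order correction shrinks that bias."""
    rng = np.random.default_rng(5)
    alpha_true = 3.0
    p_true = 1 / alpha_true
    raw_p, corr_p = [], []
    for _ in range(2000):
        sample = rng.geometric(p_true, size=20)
        a_hat = max(float(np.mean(sample)), 1.0)
        raw_p.append(1 / a_hat)
        corr_p.append(1 / alpha_bias_correction(a_hat, 20))
    bias_raw = abs(np.mean(raw_p) - p_true)
    bias_corr = abs(np.mean(corr_p) - p_true)
    assert bias_corr < bias_raw / 2


def test_estimate_params_bounds_and_zero_deletions(cherry_tree):
    ds = DeletionDataset(
        cherry_tree,
        [BranchDeletionData("a0", 0.5, 5, ()),
         BranchDeletionData("a1", 0.5, 5, ())],
        {},
        5.0,
    )
    fit = estimate_params(ds, "BDM", corrections=False)
    assert fit.at_bound and fit.alpha == 1.0
    with pytest.raises(ValueError):
        estimate_params(ds, "XXX")


def test_lrt_nested_identity(cherry_tree):
    """Data with single scattered deletions: BDM optimum at alpha = 1."""
    ds = DeletionDataset(
        cherry_tree,
        [BranchDeletionData("a0", 0.5, 9, (2, 5, 8)),
         BranchDeletionData("a1", 0.5, 9, ())],
        {},
        9.0,
    )
    res = lrt(ds, corrections=False)
    assert res.bdm.alpha == pytest.approx(1.0, abs=0.05)
    assert 0 < res.lambda_lr <= 1.0
    assert res.pvalue > 0.4
    assert res.chosen_model == "IDM"


def test_lrt_detects_blocks(cherry_tree):
    """Repeated multi-spacer adjacent blocks on short branches favor BDM."""
    branches = [
        BranchDeletionData("a0", 0.1, 12, (3, 4, 5)),
        BranchDeletionData("a1", 0.1, 12, (7, 8, 9, 10)),
    ]
    ds = DeletionDataset(cherry_tree, branches, {}, 12.0)
    res = lrt(ds, corrections=False)
    assert res.bdm.alpha > 1.5
    assert res.pvalue < 0.05
    assert res.chosen_model == "BDM"


def test_focal_fit_all_singletons_and_recovery():
    alpha, _, _ = focal_conditioned_geometric_fit([1] * 10)
    assert alpha == 1.0
    # size-biased geometric draws: P(L=k) ~ k (1-p)^(k-1) p, mean 2a-1
    rng = np.random.default_rng(11)
    a_true = 3.0
    ks = np.arange(1, 200)
    w = ks * (1 - 1 / a_true) ** (ks - 1) / a_true
    w /= w.sum()
    est = []
    for _ in range(30):
        sample = rng.choice(ks, size=200, p=w)
        a_hat, ks_stat, ks_p = focal_conditioned_geometric_fit(sample.tolist())
        est.append(a_hat)
    assert abs(np.median(est) - a_true) / a_true < 0.2
    # the size-biased mean is 2 alpha - 1 (sanity of the conditional law)
    assert np.mean(rng.choice(ks, size=200_000, p=w)) == pytest.approx(
        2 * a_true - 1, rel=0.02
    )
    with pytest.raises(ValueError):
        focal_conditioned_geometric_fit([1, 2])


def test_focal_fit_with_boundaries():
    """Boundary-limited starts reweight short blocks correctly."""
    a_hat, stat, p = focal_conditioned_geometric_fit(
        [1, 1, 2, 1, 3, 1, 2, 1],
        focal_positions=[1] * 8,
        array_lengths=[10] * 8,
    )
    assert 1.0 <= a_hat < ALPHA_BOUNDS[1]
    assert 0 <= stat <= 1 and 0 <= p <= 1
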