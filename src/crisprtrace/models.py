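"""Likelihoods, parameter estimation and the block-deletion LRT.

Two deletion models act on an array of N spacers present at the parent
node of a branch of length t:

* IDM (independent deletion model): each spacer is deleted independently
  at rate rho_I.
* BDM (block deletion model): each present spacer position initiates
  deletion events at rate rho_B; an event at current position i with
  drawn length L ~ geometric(mean alpha) jointly removes the L adjacent
  currently-present spacers starting at i.  Events whose length would
  run past the current end of the array are ignored entirely.  Earlier
  deletions close gaps, so later events act on the shortened array.
  alpha = 1 recovers the IDM exactly.

The branch likelihood L_B(b, N_b, K_b, rho, alpha) is the probability
that exactly the spacer set K_b (given by parent-array positions) is gone
after time t_b.  Because the process is monotone (spacers are only ever
removed), every trajectory ending at the observed outcome stays within
the states "surviving spacers all present, some subset of K_b present".
The likelihood is therefore computed EXACTLY on a continuous-time Markov
chain over the 2^|K_b| subsets of K_b — regardless of N_b.  The
generator of this chain is graded by subset size with eigenvalues that
depend only on the current array length, which yields a closed-form
expansion  P(t) = sum_m gamma_m exp(-rho R_m t)  whose coefficients are
computed by one sweep over subsets (no matrix exponential needed; a dense
``expm`` evaluation of the same chain is kept as a numerical fallback).

The group likelihood is the product of branch likelihoods; an optional
correction conditions each spacer on being observed in at least one
sampled descendant of its acquisition node, compensating the downward
rate bias from unobservable extinct spacers.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from functools import cached_property, lru_cache
from typing import Sequence

import numpy as np
from scipy import optimize, sparse, stats
from scipy.linalg import expm
from scipy.sparse.linalg import expm_multiply as sparse_expm_multiply

from .phylo import Phylogeny

logger = logging.getLogger(__name__)

RHO_BOUNDS = (1e-6, 1e6)
ALPHA_BOUNDS = (1.0, 1e3)

# exact spectral computation is used up to this many deleted spacers per
# branch; above it, maximal deleted runs are combined multiplicatively
_EXACT_MAX_DELETED = 12


# ----------------------------------------------------------------------
# Elementary distributions
# ----------------------------------------------------------------------

def geometric_pmf(k: int | np.ndarray, alpha: float) -> float | np.ndarray:
    """P(L = k) for the block length, L ~ geometric with mean alpha >= 1."""
    if alpha < 1:
        raise ValueError("alpha must be >= 1")
    k = np.asarray(k)
    if np.any(k < 1):
        raise ValueError("block lengths are >= 1")
    p = 1.0 / alpha
    out = (1 - p) ** (k - 1) * p
    return float(out) if out.ndim == 0 else out


def _executed_rate_factor(m: int, alpha: float) -> float:
    """sum_{j=1..m} P(L <= m-j+1): executed-event rate per unit rho.

    Events are ignored when their length overruns the current array of
    length m, so only this fraction of initiations changes the state.
    """
    if m <= 0:
        return 0.0
    beta = 1.0 - 1.0 / alpha
    if beta == 0.0:
        return float(m)
    return m - beta * (1.0 - beta**m) / (1.0 - beta)


def idm_branch_loglik(t: float, N: int, k: int, rho_I: float) -> float:
    """Log-probability that a specific set of k of N spacers is deleted."""
    if t < 0:
        raise ValueError("negative branch length")
    if not 0 <= k <= N:
        raise ValueError("need 0 <= k <= N")
    if N == 0:
        return 0.0
    log_s = -rho_I * t  # per-spacer log survival
    log_d = np.log1p(-np.exp(log_s)) if log_s < 0 else -np.inf
    if k == 0:
        return (N) * log_s
    return k * log_d + (N - k) * log_s


# ----------------------------------------------------------------------
# Branch data containers
# ----------------------------------------------------------------------

@dataclass(frozen=True)
class BranchDeletionData:
    """Deletions on one branch: parent-array size and deleted positions."""

    branch_id: str
    t: float
    N: int
    deleted: tuple[int, ...]  # 1-based positions in the parent array, sorted

    def __post_init__(self) -> None:
        if self.t < 0:
            raise ValueError("negative branch length")
        d = tuple(sorted(self.deleted))
        object.__setattr__(self, "deleted", d)
        if d and (d[0] < 1 or d[-1] > self.N):
            raise ValueError("deleted positions outside 1..N")
        if len(set(d)) != len(d):
            raise ValueError("duplicate deleted positions")

    @cached_property
    def runs(self) -> tuple[int, ...]:
        """Lengths of maximal runs of consecutive deleted positions."""
        out = []
        prev = None
        for p in self.deleted:
            if prev is not None and p == prev + 1:
                out[-1] += 1
            else:
                out.append(1)
            prev = p
        return tuple(out)


@dataclass
class DeletionDataset:
    """All branch deletion records of one group plus acquisition nodes."""

    tree: Phylogeny
    branches: list[BranchDeletionData]
    acquisition_nodes: dict[str, str] = field(default_factory=dict)
    mean_array_length: float = float("nan")

    def __post_init__(self) -> None:
        if not self.branches:
            raise ValueError("empty deletion dataset")

    @property
    def n_deleted_spacers(self) -> int:
        return sum(len(b.deleted) for b in self.branches)

    @property
    def n_deletion_events(self) -> int:
        """Number of maximal deleted blocks (geometric sample size proxy)."""
        return sum(len(b.runs) for b in self.branches)

    def observed_block_lengths(self) -> list[int]:
        return [r for b in self.branches for r in b.runs]


# ----------------------------------------------------------------------
# Exact BDM branch likelihood
# ----------------------------------------------------------------------

@lru_cache(maxsize=100_000)
def _structure(runs: tuple[int, ...]) -> tuple:
    """Transition table of the subset chain for a given run decomposition.

    Bits are assigned to deleted positions left to right.  Returns, per
    subset-size level b (number of still-present deleted spacers), arrays
    (src_mask, dst_mask, block_length) of all transitions out of level b.
    """
    k = sum(runs)
    run_of = np.repeat(np.arange(len(runs)), runs)
    by_level: dict[int, list[tuple[int, int, int]]] = {}
    for mask in range(1 << k):
        present = [i for i in range(k) if mask >> i & 1]
        if not present:
            continue
        b = len(present)
        trans = by_level.setdefault(b, [])
        # present bits of one run are adjacent in the shortened array
        blocks: list[list[int]] = []
        for i in present:
            if blocks and run_of[i] == run_of[blocks[-1][-1]]:
                blocks[-1].append(i)
            else:
                blocks.append([i])
        for block in blocks:
            s = len(block)
            for a in range(s):
                for l in range(1, s - a + 1):
                    cleared = 0
                    for i in block[a:a + l]:
                        cleared |= 1 << i
                    trans.append((mask, mask & ~cleared, l))
    out = {}
    for b, tr in by_level.items():
        arr = np.array(tr, dtype=np.int64).reshape(-1, 3)
        out[b] = (arr[:, 0], arr[:, 1], arr[:, 2])
    return (k, out)


@lru_cache(maxsize=200_000)
def _gamma_coefficients(
    n_surv: int, runs: tuple[int, ...], alpha: float
) -> tuple[np.ndarray, np.ndarray]:
    """Spectral coefficients of P(all K deleted at time t).

    Returns (gamma, R) of length k+1 such that the branch probability is
    sum_b gamma[b] * exp(-rho * R[b] * t), with R[b] the executed-event
    rate factor of an array holding n_surv survivors plus b of the
    deleted spacers.  gamma depends on alpha only, not on rho or t.
    """
    k, by_level = _structure(runs)
    p = 1.0 / alpha
    w = (1 - p) ** np.arange(k) * p  # P(L = l), l = 1..k
    R = np.array([_executed_rate_factor(n_surv + b, alpha) for b in range(k + 1)])
    popcount = np.array([bin(m).count("1") for m in range(1 << k)], dtype=np.int64)
    coeff = np.zeros((1 << k, k + 1))
    start = (1 << k) - 1
    coeff[start, k] = 1.0
    for b in range(k, 0, -1):
        if b < k:
            # homogeneous terms enforce p_S(0) = 0 for every reached state
            lvl = np.flatnonzero(popcount == b)
            coeff[lvl, b] = -coeff[lvl].sum(axis=1)
        src, dst, ell = by_level[b]
        denom = R[popcount[dst], None] - R[None, :]  # (n_trans, k+1)
        denom[np.arange(len(dst)), popcount[dst]] = 1.0  # guarded 0/0
        contrib = (w[ell - 1][:, None] * coeff[src]) / denom
        np.add.at(coeff, dst, contrib)
    coeff[0, 0] = -coeff[0, 1:].sum()
    return coeff[0], R


def _bdm_prob_expm(t: float, N: int, data: BranchDeletionData,
                   rho: float, alpha: float) -> float:
    """Matrix-exponential evaluation of the same subset chain.

    Rows are conservative only up to the absorbed mass (events that hit a
    survivor leave the tracked space and never return), so the entry
    (full, empty) of exp(Qt) is exactly the branch probability.  Small
    chains use a dense exponential; larger ones propagate a single
    indicator column through ``expm_multiply``.
    """
    runs = data.runs
    k = len(data.deleted)
    _, by_level = _structure(runs)
    n_states = 1 << k
    p = 1.0 / alpha
    popcount = np.array([bin(m).count("1") for m in range(n_states)])
    diag = -rho * np.array(
        [_executed_rate_factor(N - k + b, alpha) for b in popcount]
    )
    srcs = np.concatenate([by_level[b][0] for b in range(1, k + 1)])
    dsts = np.concatenate([by_level[b][1] for b in range(1, k + 1)])
    ells = np.concatenate([by_level[b][2] for b in range(1, k + 1)])
    rates = rho * (1 - p) ** (ells - 1) * p
    if k <= 6:
        Q = np.zeros((n_states, n_states))
        np.add.at(Q, (srcs, dsts), rates)
        Q[np.arange(n_states), np.arange(n_states)] = diag
        P = expm(Q * t)
        return float(P[n_states - 1, 0])
    rows = np.concatenate([dsts, np.arange(n_states)])
    cols = np.concatenate([srcs, np.arange(n_states)])
    vals = np.concatenate([rates, diag])
    QT = sparse.csc_matrix((vals, (rows, cols)), shape=(n_states, n_states))
    v = np.zeros(n_states)
    v[n_states - 1] = 1.0
    out = sparse_expm_multiply(QT * t, v)
    return float(out[0])


def bdm_branch_loglik(
    data: BranchDeletionData, rho_B: float, alpha: float
) -> float:
    """Exact log-likelihood of the observed deletions on one branch."""
    if alpha < 1:
        raise ValueError("alpha must be >= 1")
    if rho_B <= 0:
        raise ValueError("rho must be positive")
    t, N, k = data.t, data.N, len(data.deleted)
    if N == 0:
        return 0.0
    if k == 0:
        return -rho_B * _executed_rate_factor(N, alpha) * t
    if t == 0:
        return -np.inf
    if k > _EXACT_MAX_DELETED:
        return _bdm_loglik_factorized(data, rho_B, alpha)
    gamma, R = _gamma_coefficients(N - k, data.runs, alpha)
    terms = gamma * np.exp(-rho_B * R * t)
    prob = float(terms.sum())
    biggest = float(np.max(np.abs(terms)))
    if not np.isfinite(prob) or prob <= 0.0 or biggest > 1e10 * prob:
        # cancellation in the spectral sum: re-evaluate via expm
        if biggest < 1e-250:
            return -np.inf  # genuinely negligible probability
        prob = _bdm_prob_expm(t, N, data, rho_B, alpha)
        if prob <= 0.0:
            logger.debug("BDM branch likelihood underflowed; returning -inf")
            return -np.inf
    return float(np.log(prob))


def _bdm_loglik_factorized(
    data: BranchDeletionData, rho_B: float, alpha: float
) -> float:
    """Approximate likelihood for branches with very many deleted spacers.

    Maximal deleted runs are treated as approximately independent:
    log L ~ (1 - m) * log P(no deletion) + sum_r log P(only run r deleted),
    each run term computed exactly.  Used only above the exact-size cap.
    """
    t, N = data.t, data.N
    runs = data.runs
    log_p0 = -rho_B * _executed_rate_factor(N, alpha) * t
    pieces: list[tuple[int, ...]] = []
    pos = 0
    for r in data.runs:
        run_positions = list(data.deleted[pos:pos + r])
        pos += r
        # overlong runs are halved recursively; the product over the halves
        # misses only the events spanning the split point
        stack = [run_positions]
        while stack:
            seg = stack.pop()
            if len(seg) > _EXACT_MAX_DELETED:
                mid = len(seg) // 2
                stack.extend([seg[:mid], seg[mid:]])
            else:
                pieces.append(tuple(seg))
    total = (1 - len(pieces)) * log_p0
    for piece in pieces:
        sub = BranchDeletionData(data.branch_id, t, N, piece)
        total += bdm_branch_loglik(sub, rho_B, alpha)
    return total


# ----------------------------------------------------------------------
# Unobserved-spacer correction and group likelihood
# ----------------------------------------------------------------------

def bdm_mean_per_spacer_rate(rho: float, alpha: float, n: float) -> float:
    """Average realised deletion rate per spacer in an array of length n.

    Averages the positional coverage rate over all positions, accounting
    for the boundary rule (events longer than the remaining array are
    ignored): rho * sum_m T(m) / n with T(m) = sum_{k<=m} k P(L=k).
    Approaches rho * alpha for alpha << n and rho for alpha = 1.
    """
    n_int = max(int(round(n)), 1)
    beta = 1.0 - 1.0 / alpha
    if beta == 0.0:
        return rho
    m = np.arange(1, n_int + 1)
    T = alpha - beta**m * (m + alpha)
    return float(rho * T.sum() / n_int)


def _correction_rate(rho: float, alpha: float, n: float) -> float:
    """Effective single-spacer rate used inside the extinction recursion.

    Block deletions make spacer survivals strongly positively correlated,
    so multiplying marginal per-spacer extinction factors can understate
    the joint observation probability without bound (the conditional
    likelihood would become improper).  The recursion therefore uses the
    joint-consistent rate rho * R(n) / n, which reproduces the array-wide
    no-deletion probability exactly and equals rho in the independent
    model, where the per-spacer conditioning itself is exact.
    """
    n_int = max(int(round(n)), 1)
    return rho * _executed_rate_factor(n_int, alpha) / n_int


def _extinction_probs(tree: Phylogeny, rho_eff: float) -> np.ndarray:
    """q[v] = P(a spacer present at node v survives in no sampled leaf)."""
    q = np.zeros(tree.n_nodes)
    for v in tree.postorder():
        if tree.is_leaf(v):
            q[v] = 0.0
            continue
        prod = 1.0
        for c in tree.children[v]:
            s = np.exp(-rho_eff * tree.length[c])
            prod *= (1.0 - s) + s * q[c]
        q[v] = prod
    return q


def unobserved_correction(
    tree: Phylogeny, node_name: str, rho_eff: float
) -> float:
    """P(spacer acquired at this node is observed in >= 1 descendant leaf)."""
    if rho_eff <= 0:
        raise ValueError("rho_eff must be positive")
    v = tree.index_of(node_name)
    q = _extinction_probs(tree, rho_eff)
    return float(1.0 - q[v])


def group_loglik(
    dataset: DeletionDataset,
    rho: float,
    alpha: float,
    corrections: bool = True,
) -> float:
    """Group log-likelihood: sum over branches, optionally conditioned on
    every spacer surviving in at least one descendant of its acquisition
    node (per-spacer factor 1 - q, with an IDM-style rate set to the
    boundary-aware mean per-spacer deletion rate of the BDM)."""
    total = sum(bdm_branch_loglik(b, rho, alpha) for b in dataset.branches)
    if corrections and dataset.acquisition_nodes:
        n_bar = dataset.mean_array_length
        if not np.isfinite(n_bar) or n_bar <= 0:
            n_bar = float(np.mean([b.N for b in dataset.branches]))
        q = _extinction_probs(dataset.tree, _correction_rate(rho, alpha, n_bar))
        for node_name in dataset.acquisition_nodes.values():
            qv = q[dataset.tree.index_of(node_name)]
            if qv >= 1.0:
                return -np.inf
            total -= np.log1p(-qv)
    return float(total)


# ----------------------------------------------------------------------
# Parameter estimation
# ----------------------------------------------------------------------

@dataclass
class ModelParams:
    """Fitted deletion-model parameters for one group."""

    model: str  # "IDM" or "BDM"
    rho: float
    alpha: float
    alpha_corrected: float
    loglik: float
    n_events: int
    mean_array_length: float
    se_rho: float | None = None
    se_alpha: float | None = None
    at_bound: bool = False

    @property
    def per_spacer_rate(self) -> float:
        """Approximate deletion rate per spacer, rho * alpha."""
        return self.rho * self.alpha_corrected

    @property
    def theta(self) -> float:
        """Ad hoc insertion-rate estimate theta = n_bar * rho * alpha.

        Derived from the balance heuristic that an insertion rate of
        n * (per-spacer deletion rate) sustains a mean array length n;
        high variance, interpret with extreme caution.
        """
        return self.mean_array_length * self.per_spacer_rate

    def to_dict(self) -> dict:
        return {
            "model": self.model,
            "rho": self.rho,
            "alpha": self.alpha,
            "alpha_corrected": self.alpha_corrected,
            "per_spacer_rate": self.per_spacer_rate,
            "theta": self.theta,
            "mean_array_length": self.mean_array_length,
            "loglik": self.loglik,
            "n_events": self.n_events,
            "se_rho": self.se_rho,
            "se_alpha": self.se_alpha,
            "at_bound": self.at_bound,
        }


def alpha_bias_correction(alpha_hat: float, n_events: int) -> float:
    """First-order bias correction of the geometric-mean MLE.

    The MLE of the geometric success probability p = 1/alpha is biased for
    small samples; p_tilde = p_hat - p_hat (1 - p_hat) / n removes the
    leading term.  The corrected mean 1/p_tilde is clamped to >= 1 and the
    correction vanishes as n grows.
    """
    if alpha_hat < 1 or n_events < 1:
        raise ValueError("need alpha >= 1 and n_events >= 1")
    p_hat = 1.0 / alpha_hat
    p_tilde = p_hat - p_hat * (1.0 - p_hat) / n_events
    if p_tilde <= 0:
        return ALPHA_BOUNDS[1]
    return max(1.0, 1.0 / p_tilde)


def _profile_rho(
    dataset: DeletionDataset, alpha: float, corrections: bool
) -> tuple[float, float]:
    """Maximise the group log-likelihood over rho at fixed alpha."""
    lo, hi = np.log(RHO_BOUNDS[0]), np.log(RHO_BOUNDS[1])

    def neg(u: float) -> float:
        ll = group_loglik(dataset, float(np.exp(u)), alpha, corrections)
        return -ll if np.isfinite(ll) else 1e12

    res = optimize.minimize_scalar(
        neg, bounds=(lo, hi), method="bounded",
        options={"xatol": 1e-5},
    )
    return float(np.exp(res.x)), float(-res.fun)


def estimate_params(
    dataset: DeletionDataset,
    model: str = "BDM",
    corrections: bool = True,
    compute_se: bool = False,
) -> ModelParams:
    """Maximum-likelihood (rho, alpha) for the chosen deletion model.

    The BDM is fitted by a bounded profile-likelihood search over alpha
    with an inner 1-D search over rho (the spectral coefficients are
    cached per alpha, so the inner search is cheap).  The reported alpha
    receives the small-sample bias correction; the uncorrected MLE and
    its log-likelihood are kept for use inside the LRT.
    """
    if model not in ("IDM", "BDM"):
        raise ValueError("model must be IDM or BDM")
    n_events = dataset.n_deletion_events
    n_bar = dataset.mean_array_length
    if dataset.n_deleted_spacers == 0:
        logger.warning("no deletions in dataset; rate estimate is at the "
                       "lower bound")
        rho, ll = _profile_rho(dataset, 1.0, corrections)
        return ModelParams(model, RHO_BOUNDS[0], 1.0, 1.0, ll, 0, n_bar,
                           at_bound=True)
    if model == "IDM":
        rho, ll = _profile_rho(dataset, 1.0, corrections)
        se = _standard_errors(dataset, rho, 1.0, corrections) if compute_se else (None, None)
        return ModelParams("IDM", rho, 1.0, 1.0, ll, n_events, n_bar,
                           se_rho=se[0], se_alpha=None,
                           at_bound=not RHO_BOUNDS[0] * 2 < rho < RHO_BOUNDS[1] / 2)

    lo, hi = 0.0, np.log(ALPHA_BOUNDS[1])

    def neg_profile(u: float) -> float:
        return -_profile_rho(dataset, float(np.exp(u)), corrections)[1]

    res = optimize.minimize_scalar(
        neg_profile, bounds=(lo, hi), method="bounded",
        options={"xatol": 1e-3},
    )
    alpha_hat = float(np.exp(res.x))
    rho_hat, ll = _profile_rho(dataset, alpha_hat, corrections)
    # the boundary alpha = 1 must never be beaten by numerical wiggle
    rho_at_1, ll_at_1 = _profile_rho(dataset, 1.0, corrections)
    if ll_at_1 >= ll:
        alpha_hat, rho_hat, ll = 1.0, rho_at_1, ll_at_1
    if not np.isfinite(ll):
        raise RuntimeError("BDM optimisation failed to find a finite optimum")
    alpha_corr = alpha_bias_correction(alpha_hat, n_events)
    se = (_standard_errors(dataset, rho_hat, alpha_hat, corrections)
          if compute_se else (None, None))
    return ModelParams(
        "BDM", rho_hat, alpha_hat, alpha_corr, ll, n_events, n_bar,
        se_rho=se[0], se_alpha=se[1],
        at_bound=not (RHO_BOUNDS[0] * 2 < rho_hat < RHO_BOUNDS[1] / 2
                      and alpha_hat < ALPHA_BOUNDS[1] / 2),
    )


def _standard_errors(
    dataset: DeletionDataset, rho: float, alpha: float, corrections: bool
) -> tuple[float | None, float | None]:
    """Asymptotic SEs from a finite-difference observed information."""

    def ll(params: np.ndarray) -> float:
        return group_loglik(dataset, float(params[0]), max(float(params[1]), 1.0),
                            corrections)

    x0 = np.array([rho, alpha])
    h = np.maximum(1e-4 * np.abs(x0), 1e-8)
    dim = 2 if alpha > 1.0 else 1
    H = np.zeros((dim, dim))
    for i in range(dim):
        for j in range(i, dim):
            ei = np.zeros(2); ei[i] = h[i]
            ej = np.zeros(2); ej[j] = h[j]
            H[i, j] = H[j, i] = (
                ll(x0 + ei + ej) - ll(x0 + ei - ej)
                - ll(x0 - ei + ej) + ll(x0 - ei - ej)
            ) / (4 * h[i] * h[j])
    try:
        cov = np.linalg.inv(-H)
        if np.any(np.diag(cov) <= 0):
            return None, None
        ses = np.sqrt(np.diag(cov))
        return float(ses[0]), (float(ses[1]) if dim == 2 else None)
    except np.linalg.LinAlgError:
        return None, None


# ----------------------------------------------------------------------
# Likelihood ratio test
# ----------------------------------------------------------------------

@dataclass
class LRTResult:
    """IDM (alpha = 1) against BDM (alpha >= 1), boundary-aware null."""

    lambda_lr: float
    statistic: float  # -2 log lambda
    pvalue: float
    reject_idm: bool
    level: float
    idm: ModelParams
    bdm: ModelParams

    @property
    def chosen_model(self) -> str:
        return "BDM" if self.reject_idm else "IDM"

    def to_dict(self) -> dict:
        return {
            "lambda": self.lambda_lr,
            "statistic": self.statistic,
            "pvalue": self.pvalue,
            "chosen": self.chosen_model,
            "level": self.level,
        }


def lrt(
    dataset: DeletionDataset,
    corrections: bool = True,
    level: float = 0.05,
    null: str = "mixture",
) -> LRTResult:
    """Likelihood ratio test of independent vs blockwise deletions.

    The statistic compares sup-likelihoods (uncorrected MLEs; the alpha
    bias correction is applied only to the reported estimate).  Because
    alpha = 1 sits on the boundary of the alternative, the default null
    distribution is the mixture (chi2_0 + chi2_1) / 2; a plain chi2_1 is
    available via ``null="chi2"``.
    """
    idm = estimate_params(dataset, "IDM", corrections)
    bdm = estimate_params(dataset, "BDM", corrections)
    stat = max(0.0, 2.0 * (bdm.loglik - idm.loglik))
    lam = float(np.exp(-0.5 * stat))
    if null == "mixture":
        pvalue = 1.0 if stat == 0.0 else 0.5 * float(stats.chi2.sf(stat, df=1))
    elif null == "chi2":
        pvalue = float(stats.chi2.sf(stat, df=1))
    else:
        raise ValueError("null must be 'mixture' or 'chi2'")
    return LRTResult(lam, stat, pvalue, pvalue < level, level, idm, bdm)


# ----------------------------------------------------------------------
# Focal-spacer conditioned geometric fit
# ----------------------------------------------------------------------

def focal_conditioned_geometric_fit(
    block_lengths: Sequence[int],
    focal_positions: Sequence[int] | None = None,
    array_lengths: Sequence[int] | None = None,
) -> tuple[float, float, float]:
    """Fit alpha to deletion-block lengths that all cover one focal spacer.

    A block of length k can cover the focal spacer from k different start
    positions (fewer near the array boundaries), so observed lengths are
    size-biased:  P(L = k | covers focal) ~ w(k) P(L = k)  with w(k) the
    number of admissible starts.  Without boundary information w(k) = k,
    the classic size-biased geometric whose mean is 2 alpha - 1.

    Returns (alpha_hat, KS statistic, KS p-value) of the fitted
    conditional law.
    """
    lengths = np.asarray(block_lengths, dtype=int)
    if len(lengths) < 5:
        raise ValueError("need at least 5 observed block lengths")
    if np.any(lengths < 1):
        raise ValueError("block lengths are >= 1")
    n_obs = len(lengths)
    if focal_positions is None:
        max_k = max(int(lengths.max()) * 5, 200)
        weights = np.broadcast_to(
            np.arange(1, max_k + 1, dtype=float), (n_obs, max_k)
        )
    else:
        if array_lengths is None or len(focal_positions) != n_obs or len(
            array_lengths
        ) != n_obs:
            raise ValueError("focal_positions and array_lengths must match "
                             "block_lengths in length")
        max_k = int(max(array_lengths))
        weights = np.zeros((n_obs, max_k))
        for i, (f, n) in enumerate(zip(focal_positions, array_lengths)):
            for k in range(1, max_k + 1):
                lo = max(1, f - k + 1)
                hi = min(f, n - k + 1)
                weights[i, k - 1] = max(0, hi - lo + 1)
    ks = np.arange(1, weights.shape[1] + 1)

    def neg_ll(u: float) -> float:
        alpha = 1.0 + np.exp(u)
        pmf = geometric_pmf(ks, alpha)
        cond = weights * pmf
        norm = cond.sum(axis=1)
        probs = cond[np.arange(n_obs), lengths - 1] / norm
        if np.any(probs <= 0):
            return np.inf
        return -float(np.log(probs).sum())

    if np.all(lengths == 1):
        alpha_hat = 1.0
    else:
        res = optimize.minimize_scalar(
            neg_ll, bounds=(np.log(1e-6), np.log(ALPHA_BOUNDS[1])),
            method="bounded",
        )
        alpha_hat = float(1.0 + np.exp(res.x))
        if neg_ll(np.log(1e-6)) < res.fun:
            alpha_hat = 1.0
    if np.all(lengths == weights.shape[1]):
        warnings.warn("all observed block lengths equal the maximum; "
                      "the fit is degenerate")
    pmf = geometric_pmf(ks, max(alpha_hat, 1.0 + 1e-12))
    cond = weights * pmf
    cond /= cond.sum(axis=1, keepdims=True)
    model_cdf_rows = np.cumsum(cond, axis=1)
    mean_cdf = model_cdf_rows.mean(axis=0)

    def cdf(x):
        x = np.atleast_1d(x)
        idx = np.clip(np.floor(x).astype(int), 0, len(mean_cdf))
        out = np.where(idx < 1, 0.0, mean_cdf[np.clip(idx - 1, 0, len(mean_cdf) - 1)])
        return out

    ks_res = stats.kstest(lengths, cdf)
    return alpha_hat, float(ks_res.statistic), float(ks_res.pvalue)
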