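"""Guide reconstruction: joint-ML ancestral presence/absence per column.

Each alignment column is treated as an independent two-state (absent=0,
present=1) reversible Markov chain along the tree, with gain rate ``g``
(0->1) and loss rate ``l`` (1->0).  The default l/g ratio of 10 makes
multiple deletions cheaper than multiple independent acquisitions of the
same spacer, which are biologically rare.  The joint maximum-likelihood
assignment of internal states is found by max-product dynamic programming
up the tree with a backtrace down (the assignment, not per-node
marginals, is what the order-based refinement reasons about).  Selected
nodes can be constrained to a fixed state, which the refinement uses to
force spacers to be present ancestrally.

Within the tree, ties are broken toward "present", avoiding spurious
repeated insertions; at the root they are broken toward "absent", since
time reversibility makes "acquired just below the root" and "present at
the root but deleted in the sister lineage" exactly equally likely, and
polarized acquisition is the parsimonious reading of that tie.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .arrays import EventRecord, ReconstructionResult
from .msaa import MSAA
from .phylo import Phylogeny


class InfeasibleConstraintError(ValueError):
    """Fixed states cannot be realised (e.g. conflict across a zero branch)."""


@dataclass(frozen=True)
class GuideModelParams:
    """Two-state gain/loss rates and root prior.

    ``root_prior`` is over (absent, present); by default the stationary
    distribution (l, g)/(l+g).

    By default the rates are interpreted relative to the tree: they are
    rescaled so that loss_rate x (mean branch length) = ``loss_per_branch``.
    This keeps the reconstruction in the regime where ancestral presence
    is cheap to maintain, a deletion costs a moderate penalty, and an
    extra independent acquisition costs loss_rate/gain_rate times more —
    regardless of whether branch lengths are substitutions per site or
    coalescent units.  Set ``tree_scaled=False`` to use the rates as
    absolute rates per branch-length unit.

    With ``use_branch_lengths=False`` (the default) every positive branch
    contributes the same transition matrix (evaluated at the mean branch
    length); zero-length branches still forbid change.  Per-branch
    Poisson costs make long branches attract events, which fabricates
    ancestral presence near deep roots and spurious deletions in the
    sister lineages; with equal contributions the guide places events
    parsimoniously by topology and the loss/gain priority, and the
    subsequent order-based refinement supplies the timing information.
    """

    gain_rate: float = 1.0
    loss_rate: float = 10.0
    root_prior: tuple[float, float] | None = None
    tree_scaled: bool = True
    loss_per_branch: float = 0.5
    use_branch_lengths: bool = False

    def __post_init__(self) -> None:
        if self.gain_rate <= 0 or self.loss_rate <= 0:
            raise ValueError("rates must be positive")
        if self.loss_rate <= self.gain_rate:
            raise ValueError("loss rate must exceed gain rate")
        if self.loss_per_branch <= 0:
            raise ValueError("loss_per_branch must be positive")

    def prior(self) -> np.ndarray:
        if self.root_prior is not None:
            p = np.asarray(self.root_prior, dtype=float)
            if p.shape != (2,) or np.any(p < 0) or not np.isclose(p.sum(), 1.0):
                raise ValueError("root prior must be a distribution over 2 states")
            return p
        g, l = self.gain_rate, self.loss_rate
        return np.array([l, g]) / (g + l)

    def rate_scale(self, mean_branch_length: float) -> float:
        if not self.tree_scaled:
            return 1.0
        if mean_branch_length <= 0:
            return 1.0
        return self.loss_per_branch / (self.loss_rate * mean_branch_length)

    def transition_matrix(self, t: float, scale: float = 1.0) -> np.ndarray:
        """P[a, b] = P(state b at child | state a at parent) after time t."""
        if t < 0:
            raise ValueError("negative branch length")
        g, l = self.gain_rate * scale, self.loss_rate * scale
        s = g + l
        e = np.exp(-s * t)
        return np.array(
            [
                [(l + g * e) / s, (g - g * e) / s],
                [(l - l * e) / s, (g + l * e) / s],
            ]
        )


def joint_ml_ancestral_states(
    tree: Phylogeny,
    leaf_profiles: dict[str, np.ndarray],
    params: GuideModelParams,
    constraints: dict[tuple[str, int], bool] | None = None,
) -> tuple[dict[str, tuple[bool, ...]], np.ndarray]:
    """Exact joint-ML internal states for every column.

    ``leaf_profiles`` maps leaf name -> boolean presence vector over
    columns.  ``constraints`` maps (node name, column index) -> fixed
    state.  Returns (profile per node, per-column max log-likelihood).
    """
    constraints = constraints or {}
    leaves = tree.leaves
    ncols = len(next(iter(leaf_profiles.values()))) if leaf_profiles else 0
    for nm, prof in leaf_profiles.items():
        if len(prof) != ncols:
            raise ValueError(f"leaf profile length mismatch at {nm!r}")
    if set(tree.leaf_names) != set(leaf_profiles):
        raise ValueError("leaf profiles must cover exactly the tree's leaves")

    NEG = -np.inf
    mean_bl = float(np.mean(tree.length[1:])) if tree.n_nodes > 1 else 0.0
    scale = params.rate_scale(mean_bl)

    def branch_time(t: float) -> float:
        if params.use_branch_lengths or t == 0.0:
            return t
        return mean_bl

    with np.errstate(divide="ignore"):
        logP = [np.log(params.transition_matrix(branch_time(float(tree.length[i])),
                                                scale))
                for i in range(tree.n_nodes)]
        log_prior = np.log(params.prior())

    # mask[v, s, col] = 0 if state s allowed at node v else -inf
    mask = np.zeros((tree.n_nodes, 2, ncols))
    for (nm, col), state in constraints.items():
        v = tree.index_of(nm)
        mask[v, 0 if state else 1, col] = NEG
    for v in leaves:
        obs = np.asarray(leaf_profiles[tree.names[v]], dtype=bool)
        mask[v, 0, obs] = NEG
        mask[v, 1, ~obs] = NEG

    # C[v, a, col]: best log-lik of subtree at v given parent state a;
    # choice[v, a, col]: the state of v realising it.
    C = np.zeros((tree.n_nodes, 2, ncols))
    choice = np.zeros((tree.n_nodes, 2, ncols), dtype=np.int8)
    for v in tree.postorder():
        if v == tree.root:
            continue
        below = mask[v].copy()  # (2, ncols) indexed by state of v
        for c in tree.children[v]:
            below += C[c]
        for a in (0, 1):
            cand = below + logP[v][a][:, None]  # (2, ncols)
            # ties -> present
            pick = (cand[1] >= cand[0]).astype(np.int8)
            C[v, a] = np.where(pick == 1, cand[1], cand[0])
            choice[v, a] = pick

    root = tree.root
    root_cand = mask[root] + log_prior[:, None]
    for c in tree.children[root]:
        root_cand += C[c]
    # at the root, reversibility ties "acquired on one child branch" with
    # "present at root, deleted on the other"; break toward absence so a
    # polarized acquisition is preferred over a fabricated block deletion
    tol = 1e-9
    root_state = (root_cand[1] > root_cand[0] + tol).astype(np.int8)
    col_loglik = np.where(root_state == 1, root_cand[1], root_cand[0])
    if np.any(~np.isfinite(col_loglik)):
        bad = np.flatnonzero(~np.isfinite(col_loglik))
        raise InfeasibleConstraintError(
            f"constraints are unsatisfiable in columns {(bad + 1).tolist()}"
        )

    states = np.zeros((tree.n_nodes, ncols), dtype=np.int8)
    states[root] = root_state
    for v in tree.preorder():
        if v == root:
            continue
        a = states[tree.parent[v]]
        states[v] = choice[v, a, np.arange(ncols)]

    profile = {
        tree.names[v]: tuple(bool(x) for x in states[v]) for v in tree.preorder()
    }
    return profile, col_loglik


def extract_events(
    profile: dict[str, tuple[bool, ...]],
    tree: Phylogeny,
    msaa: MSAA,
) -> list[EventRecord]:
    """Per-branch acquisitions and block deletions from a presence profile.

    A 0->1 change on a branch is an acquisition (one record per column).
    1->0 changes are grouped into block records when the lost columns are
    adjacent in the parent node's array, i.e. ignoring columns absent at
    the parent.
    """
    events: list[EventRecord] = []
    labels = msaa.column_labels
    for v in tree.preorder():
        if v == tree.root:
            continue
        child, par = tree.names[v], tree.names[tree.parent[v]]
        ps, cs = profile[par], profile[child]
        for col, (a, b) in enumerate(zip(ps, cs)):
            if not a and b:
                events.append(
                    EventRecord(child, "acquisition", (labels[col],), (col + 1,))
                )
        block_cols: list[int] = []
        for col, present in enumerate(ps):
            if not present:
                continue
            if not cs[col]:
                block_cols.append(col)
            else:
                if block_cols:
                    events.append(_deletion_record(child, block_cols, labels))
                    block_cols = []
        if block_cols:
            events.append(_deletion_record(child, block_cols, labels))
    return events


def _deletion_record(child: str, cols: list[int], labels: list[str]) -> EventRecord:
    return EventRecord(
        child,
        "deletion",
        tuple(labels[c] for c in cols),
        tuple(c + 1 for c in cols),
    )


def reconstruct(
    tree: Phylogeny,
    msaa: MSAA,
    params: GuideModelParams | None = None,
    constraints: dict[tuple[str, int], bool] | None = None,
) -> tuple[ReconstructionResult, float]:
    """Run the guide reconstruction for a group and extract events."""
    params = params or GuideModelParams()
    leaf_profiles = {
        aid: msaa.presence[i] for i, aid in enumerate(msaa.array_ids)
    }
    profile, col_loglik = joint_ml_ancestral_states(
        tree, leaf_profiles, params, constraints
    )
    result = ReconstructionResult(
        node_names=[tree.names[v] for v in tree.preorder()],
        column_labels=list(msaa.column_labels),
        profile=profile,
    )
    result.events = extract_events(profile, tree, msaa)
    return result, float(col_loglik.sum())
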