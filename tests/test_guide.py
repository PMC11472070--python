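"""Joint-ML ancestral reconstruction vs brute-force enumeration."""

import itertools

import numpy as np
import pytest

from crisprtrace.guide import (
    GuideModelParams,
    InfeasibleConstraintError,
    extract_events,
    joint_ml_ancestral_states,
    reconstruct,
)
from crisprtrace.msaa import align_group
from crisprtrace.phylo import Phylogeny
from tests.conftest import make_group


def brute_force_best(tree, leaf_states, params, constraints=None):
    """Enumerate all internal-state assignments; return max log-likelihood."""
    constraints = constraints or {}
    mean_bl = float(np.mean(tree.length[1:]))
    scale = params.rate_scale(mean_bl)

    def bt(t):
        if params.use_branch_lengths or t == 0.0:
            return t
        return mean_bl

    logP = {}
    for v in range(1, tree.n_nodes):
        with np.errstate(divide="ignore"):
            logP[v] = np.log(params.transition_matrix(
                bt(float(tree.length[v])), scale))
    prior = np.log(params.prior())
    internal = [v for v in range(tree.n_nodes) if not tree.is_leaf(v)]
    best = -np.inf
    for combo in itertools.product([0, 1], repeat=len(internal)):
        states = dict(zip(internal, combo))
        for v in tree.leaves:
            states[v] = leaf_states[tree.names[v]]
        ok = all(states[tree.index_of(nm)] == int(s)
                 for (nm, _), s in constraints.items())
        if not ok:
            continue
        ll = prior[states[0]]
        for v in range(1, tree.n_nodes):
            ll += logP[v][states[tree.parent[v]], states[v]]
        best = max(best, ll)
    return best


@pytest.mark.parametrize("seed", range(8))
def test_joint_ml_matches_brute_force(seed, balanced4_tree):
    rng = np.random.default_rng(seed)
    params = GuideModelParams()
    ncols = 6
    profiles = {
        nm: rng.integers(0, 2, size=ncols).astype(bool)
        for nm in balanced4_tree.leaf_names
    }
    profile, col_ll = joint_ml_ancestral_states(
        balanced4_tree, profiles, params
    )
    for col in range(ncols):
        leaf_states = {nm: int(profiles[nm][col]) for nm in profiles}
        expected = brute_force_best(balanced4_tree, leaf_states, params)
        assert col_ll[col] == pytest.approx(expected, rel=1e-9), col


def test_all_leaves_present_gives_all_internal_present(balanced4_tree):
    profiles = {nm: np.ones(3, bool) for nm in balanced4_tree.leaf_names}
    profile, _ = joint_ml_ancestral_states(
        balanced4_tree, profiles, GuideModelParams()
    )
    assert all(all(profile[nm]) for nm in profile)


def test_single_present_leaf_reconstructed_as_terminal_gain(balanced4_tree):
    profiles = {nm: np.zeros(1, bool) for nm in balanced4_tree.leaf_names}
    profiles["a2"] = np.ones(1, bool)
    profile, _ = joint_ml_ancestral_states(
        balanced4_tree, profiles, GuideModelParams()
    )
    assert profile["a2"][0]
    for nm in ("R", "U", "V", "a0", "a1", "a3"):
        assert not profile[nm][0]


def test_deletion_priority_over_double_insertion(balanced4_tree):
    """Spacer in (a0, a1, a2): one gain + one loss beats two gains."""
    profiles = {nm: np.ones(1, bool) for nm in balanced4_tree.leaf_names}
    profiles["a3"] = np.zeros(1, bool)
    profile, _ = joint_ml_ancestral_states(
        balanced4_tree, profiles, GuideModelParams()
    )
    # present at V (parent of a2, a3): deleted on a3's branch
    assert profile["V"][0] and profile["R"][0]


def test_constraints_are_respected(balanced4_tree):
    profiles = {nm: np.zeros(1, bool) for nm in balanced4_tree.leaf_names}
    profiles["a2"] = np.ones(1, bool)
    constraints = {("R", 0): True}
    profile, ll = joint_ml_ancestral_states(
        balanced4_tree, profiles, GuideModelParams(), constraints
    )
    assert profile["R"][0]
    expected = brute_force_best(
        balanced4_tree,
        {nm: int(profiles[nm][0]) for nm in profiles},
        GuideModelParams(),
        constraints,
    )
    assert ll[0] == pytest.approx(expected, rel=1e-9)


def test_conflicting_constraint_over_zero_branch_raises():
    tree = Phylogeny([-1, 0, 1, 1], [0.0, 0.0, 0.5, 0.5],
                     ["R", "M", "a", "b"])
    profiles = {"a": np.ones(1, bool), "b": np.ones(1, bool)}
    with pytest.raises(InfeasibleConstraintError):
        joint_ml_ancestral_states(
            tree, profiles, GuideModelParams(),
            {("R", 0): True, ("M", 0): False},
        )


def test_extract_events_block_grouping(cherry_tree):
    g = make_group(("1", "2", "3"), ("1", "2", "3"))
    msaa = align_group(g)
    profile = {
        "R": (True, True, True),
        "a0": (True, False, False),
        "a1": (True, True, True),
    }
    events = extract_events(profile, cherry_tree, msaa)
    dels = [e for e in events if e.event_type == "deletion"]
    assert len(dels) == 1
    assert dels[0].spacer_labels == ("2", "3")
    assert dels[0].branch_id == "a0"


def test_extract_events_nonadjacent_deletions_split(cherry_tree):
    g = make_group(("1", "2", "3", "4", "5"), ("1", "3", "5"))
    msaa = align_group(g)
    profile = {
        "R": (True,) * 5,
        "a0": (True,) * 5,
        "a1": (True, False, True, False, True),
    }
    events = extract_events(profile, cherry_tree, msaa)
    dels = [e for e in events if e.event_type == "deletion"]
    assert sorted(e.spacer_labels for e in dels) == [("2",), ("4",)]


def test_no_change_no_events(cherry_tree):
    g = make_group(("1", "2"), ("1", "2"))
    msaa = align_group(g)
    rec, ll = reconstruct(cherry_tree, msaa)
    assert rec.events == []
    assert np.isfinite(ll)


def test_guide_params_validation():
    with pytest.raises(ValueError):
        GuideModelParams(gain_rate=2.0, loss_rate=1.0)
    with pytest.raises(ValueError):
        GuideModelParams(gain_rate=0.0)
    p = GuideModelParams(root_prior=(0.7, 0.3))
    assert p.prior()[1] == 0.3
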