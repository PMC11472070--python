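import warnings

import pytest

from crisprtrace.arrays import SpacerArrayRecord, SpacerGroup
from crisprtrace.phylo import Phylogeny
from crisprtrace.simulate import SimulationConfig, simulate_group

warnings.filterwarnings("ignore", category=RuntimeWarning)


def make_group(*arrays: tuple[str, ...], group_id: str = "g") -> SpacerGroup:
    return SpacerGroup(
        group_id,
        [
            SpacerArrayRecord(group_id, f"a{i}", tuple(arr))
            for i, arr in enumerate(arrays)
        ],
    )


@pytest.fixture
def fig_group() -> SpacerGroup:
    """The two-array example group: (1,2,4,6) and (2,3,5,6)."""
    return make_group(("1", "2", "4", "6"), ("2", "3", "5", "6"))


@pytest.fixture
def cherry_tree() -> Phylogeny:
    """Two leaves a0, a1 under a root."""
    return Phylogeny([-1, 0, 0], [0.0, 0.5, 0.5], ["R", "a0", "a1"])


@pytest.fixture
def balanced4_tree() -> Phylogeny:
    """((a0,a1),(a2,a3)) with unit-ish branch lengths."""
    return Phylogeny(
        [-1, 0, 1, 1, 0, 4, 4],
        [0.0, 0.4, 0.3, 0.3, 0.4, 0.3, 0.3],
        ["R", "U", "a0", "a1", "V", "a2", "a3"],
    )


def simulated(seed: int = 0, **kwargs):
    cfg = SimulationConfig(seed=seed, **kwargs)
    return simulate_group(cfg)


@pytest.fixture
def sim_group():
    group, tree, log, arrays = simulated(seed=42, rho=0.15, alpha=2.0)
    return group, tree, log, arrays
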