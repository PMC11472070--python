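"""Forward simulation of spacer-array evolution along trees.

Arrays evolve by exact event-driven (Gillespie) simulation: new, globally
unique spacers are acquired at the leader end at total rate theta, and
deletions follow one of three variants:

* ``boundary`` (the block deletion model): each present spacer initiates
  events at rate rho_B; a drawn geometric(mean alpha) length L deletes
  the L adjacent spacers starting at the initiation position, and events
  that would run past the current trailer end are ignored entirely.
* ``uniform`` (symmetric reference): blocks may overhang both array ends
  virtually (truncated to the array), placed so that every position is
  covered at exactly rate rho_B * alpha regardless of its position; used
  as the flat-deletion-frequency reference.
* ``independent``: alpha forced to 1, i.e. single-spacer deletions.

Trees are standard coalescents (exponential waiting times at rate
C(k, 2), uniform pair merging) with branch lengths in coalescent units,
or user-supplied.  A full event log is kept; replaying it from the root
array reproduces every node's array exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np

from .arrays import SpacerArrayRecord, SpacerGroup
from .phylo import Phylogeny

Variant = Literal["boundary", "uniform", "independent"]


@dataclass(frozen=True)
class SimulationConfig:
    """Simulation conditions for one group of arrays.

    Defaults follow the turnover balance theta = n_bar * rho_B * alpha
    with a sustained mean array length n_bar of about 17.4 spacers and a
    per-spacer deletion rate of 0.3 per unit branch length — enough
    turnover on coalescent-scale trees to observe deletions without
    collapsing the arrays.
    """

    n_leaves: int = 10
    theta: float = 17.4 * 0.3
    rho: float = 0.3
    alpha: float = 1.0
    variant: Variant = "boundary"
    root_length: int | None = None  # None: draw Poisson(theta / (rho*alpha))
    burn_in: bool = False  # exact stationary root via single-lineage burn-in
    seed: int = 0

    def __post_init__(self) -> None:
        if self.theta < 0 or self.rho < 0:
            raise ValueError("rates must be >= 0")
        if self.alpha < 1:
            raise ValueError("alpha must be >= 1")
        if self.variant not in ("boundary", "uniform", "independent"):
            raise ValueError(f"unknown deletion variant {self.variant!r}")

    @property
    def effective_alpha(self) -> float:
        return 1.0 if self.variant == "independent" else self.alpha


@dataclass(frozen=True)
class SimEvent:
    branch_id: str
    time: float  # time since the start of the branch
    kind: Literal["insertion", "deletion"]
    label: int | None = None  # inserted label
    initiation: int | None = None  # 1-based position (or virtual start)
    drawn_length: int | None = None
    deleted: tuple[int, ...] = ()  # labels removed, leader to trailer


@dataclass
class EventLog:
    events: list[SimEvent] = field(default_factory=list)

    def for_branch(self, branch_id: str) -> list[SimEvent]:
        return [e for e in self.events if e.branch_id == branch_id]

    def replay(
        self, root_array: tuple[int, ...], tree: Phylogeny
    ) -> dict[str, tuple[int, ...]]:
        """Re-apply all events from the root; returns per-node arrays."""
        arrays: dict[str, tuple[int, ...]] = {tree.names[tree.root]: root_array}
        for v in tree.preorder():
            if v == tree.root:
                continue
            arr = list(arrays[tree.names[tree.parent[v]]])
            for ev in self.for_branch(tree.names[v]):
                if ev.kind == "insertion":
                    arr.insert(0, ev.label)
                else:
                    for lab in ev.deleted:
                        arr.remove(lab)
            arrays[tree.names[v]] = tuple(arr)
        return arrays


def simulate_coalescent_tree(
    n: int, rng: np.random.Generator | int
) -> Phylogeny:
    """Standard neutral coalescent genealogy of n lineages.

    While k lineages remain, an exponential waiting time with rate
    C(k, 2) passes and a uniformly random pair merges.  Branch lengths
    are in coalescent units.
    """
    if n < 2:
        raise ValueError("need at least 2 leaves")
    rng = np.random.default_rng(rng) if isinstance(rng, int) else rng
    # nodes: leaves L0..L{n-1}; internal created on merge
    heights = {f"L{i}": 0.0 for i in range(n)}
    children: dict[str, list[str]] = {}
    active = [f"L{i}" for i in range(n)]
    t = 0.0
    k = n
    idx = 0
    while k > 1:
        t += rng.exponential(1.0 / (k * (k - 1) / 2.0))
        i, j = rng.choice(k, size=2, replace=False)
        a, b = active[i], active[j]
        new = f"C{idx}"
        idx += 1
        heights[new] = t
        children[new] = [a, b]
        active = [x for x in active if x not in (a, b)] + [new]
        k -= 1
    root = active[0]
    parent: list[int] = []
    length: list[float] = []
    names: list[str] = []
    pos: dict[str, int] = {}

    def visit(name: str, par: int) -> None:
        pos[name] = len(names)
        names.append(name)
        parent.append(par)
        if par == -1:
            length.append(0.0)
        else:
            length.append(heights[names[par]] - heights[name])
        for c in children.get(name, []):
            visit(c, pos[name])

    visit(root, -1)
    return Phylogeny(parent, length, names)


class _LabelSource:
    def __init__(self, start: int = 0) -> None:
        self.next = start

    def take(self) -> int:
        lab = self.next
        self.next += 1
        return lab


def _evolve_branch(
    array: list[int],
    branch_id: str,
    t_total: float,
    config: SimulationConfig,
    rng: np.random.Generator,
    labels: _LabelSource,
    log: list[SimEvent],
) -> list[int]:
    theta, rho = config.theta, config.rho
    alpha = config.effective_alpha
    geom_p = 1.0 / alpha
    t = 0.0
    while True:
        n = len(array)
        if config.variant == "uniform":
            del_rate = rho * (n - 1 + alpha) if n else 0.0
        else:
            del_rate = rho * n
        total = theta + del_rate
        if total <= 0:
            return array
        t += rng.exponential(1.0 / total)
        if t > t_total:
            return array
        if rng.random() < theta / total:
            lab = labels.take()
            array.insert(0, lab)
            log.append(SimEvent(branch_id, t, "insertion", label=lab))
            continue
        if config.variant == "uniform":
            # length re-weighted by the number of admissible (overhanging)
            # starts, then a uniform start among them: coverage rate of
            # every position is exactly rho * alpha
            weights = np.array(
                [(1 - geom_p) ** (l - 1) * geom_p * (n + l - 1)
                 for l in range(1, n + 61)]
            )
            L = int(rng.choice(np.arange(1, n + 61), p=weights / weights.sum()))
            s = int(rng.integers(2 - L, n + 1))  # 1-based start, may overhang
            lo, hi = max(s, 1), min(s + L - 1, n)
            if lo > hi:
                continue
            removed = array[lo - 1:hi]
            del array[lo - 1:hi]
            log.append(SimEvent(branch_id, t, "deletion", initiation=s,
                                drawn_length=L, deleted=tuple(removed)))
        else:
            i = int(rng.integers(1, n + 1))
            L = int(rng.geometric(geom_p))
            if i + L - 1 > n:
                continue  # boundary rule: overlong events are ignored
            removed = array[i - 1:i + L - 1]
            del array[i - 1:i + L - 1]
            log.append(SimEvent(branch_id, t, "deletion", initiation=i,
                                drawn_length=L, deleted=tuple(removed)))


def evolve_array(
    root_array: tuple[int, ...],
    tree: Phylogeny,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
    label_start: int | None = None,
) -> tuple[dict[str, tuple[int, ...]], EventLog]:
    """Evolve a root array along a tree; returns per-node arrays + log."""
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    labels = _LabelSource(
        label_start if label_start is not None
        else (max(root_array) + 1 if root_array else 0)
    )
    log: list[SimEvent] = []
    arrays: dict[str, tuple[int, ...]] = {tree.names[tree.root]: tuple(root_array)}
    for v in tree.preorder():
        if v == tree.root:
            continue
        parent_arr = list(arrays[tree.names[tree.parent[v]]])
        out = _evolve_branch(
            parent_arr, tree.names[v], float(tree.length[v]), config, rng,
            labels, log,
        )
        arrays[tree.names[v]] = tuple(out)
    return arrays, EventLog(log)


def _stationary_root(
    config: SimulationConfig, rng: np.random.Generator, labels: _LabelSource
) -> list[int]:
    per_spacer = config.rho * config.effective_alpha
    if config.burn_in and per_spacer > 0:
        arr: list[int] = []
        _evolve_branch(arr, "burnin", 20.0 / config.rho, config, rng, labels, [])
        return arr
    if per_spacer <= 0:
        raise ValueError("stationary root length needs rho > 0 "
                         "(or pass root_length)")
    n0 = int(rng.poisson(config.theta / per_spacer))
    return [labels.take() for _ in range(n0)][::-1]


def simulate_group(
    config: SimulationConfig,
    tree: Phylogeny | None = None,
    group_id: str = "sim",
) -> tuple[SpacerGroup, Phylogeny, EventLog, dict[str, tuple[int, ...]]]:
    """Simulate a group: tree (coalescent unless given), root array, events.

    The root length is drawn from the stationary balance Poisson with
    mean theta / (rho * alpha) (exact for independent deletions, an
    approximation under blockwise deletion; ``burn_in`` simulates a
    single lineage instead).  Resamples up to 100 times while any leaf
    array ends up empty.  Labels in the root array are ordered youngest
    (leader) first.  Deterministic given the seed.
    """
    rng = np.random.default_rng(config.seed)
    for _ in range(100):
        labels = _LabelSource(0)
        tr = tree if tree is not None else simulate_coalescent_tree(
            config.n_leaves, rng
        )
        if config.root_length is not None:
            root = [labels.take() for _ in range(config.root_length)][::-1]
        else:
            root = _stationary_root(config, rng, labels)
        arrays, log = evolve_array(tuple(root), tr, config, rng,
                                   label_start=labels.next)
        leaf_arrays = {
            tr.names[v]: arrays[tr.names[v]] for v in tr.leaves
        }
        if all(len(a) > 0 for a in leaf_arrays.values()):
            records = [
                SpacerArrayRecord(group_id, name, tuple(str(x) for x in arr))
                for name, arr in sorted(leaf_arrays.items())
            ]
            group = SpacerGroup(group_id, records)
            return group, tr, log, arrays
    raise RuntimeError("simulation produced empty leaf arrays 100 times; "
                       "increase theta or shorten the tree")
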