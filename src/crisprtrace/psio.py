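"""Partial spacer insertion order (PSIO): construction, refinement, and
classification of duplicate candidates.

Because new spacers enter only at the leader end, every array is a
timeline: its leader-proximal spacers were acquired after its
trailer-proximal ones.  Pooling these total orders over all arrays of a
group yields a partial order, stored as a transitively reduced DAG whose
edge ``y -> x`` means "y was acquired after x".

The guide reconstruction ignores this order and can place a younger
spacer's acquisition on a lineage where an older spacer has not yet been
acquired.  The iterative refinement finds such contradictions and fixes
the older spacer to be present at the parent node of the offending
acquisition, recomputing the constrained joint-ML reconstruction until no
contradiction remains.  Non-oldest duplicate candidates are excluded from
the PSIO and later classified as duplication / rearrangement /
reacquisition / independent acquisition / other.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx

from .arrays import EventRecord, ReconstructionResult
from .guide import GuideModelParams
from .guide import reconstruct as _guide_reconstruct
from .msaa import MSAA, DuplicateCandidateSet
from .phylo import Phylogeny

logger = logging.getLogger(__name__)


class PSIOError(RuntimeError):
    pass


@dataclass
class PSIO:
    """Transitively reduced "acquired after" DAG over retained labels."""

    graph: nx.DiGraph  # reduced; edge y -> x: y acquired after x
    closure: nx.DiGraph  # transitive closure of the same relation
    excluded: set[str]  # non-oldest duplicate candidates

    def older_than(self, label: str) -> set[str]:
        """Labels that must have been acquired before ``label``."""
        if label not in self.closure:
            return set()
        return set(self.closure.successors(label))


def _acquisition_depths(
    recon: ReconstructionResult, tree: Phylogeny
) -> dict[str, float]:
    """Root-distance of each label's rootmost acquisition.

    Labels already present at the root get depth 0 (acquired before the
    root).
    """
    depths = tree.depths()
    root_name = tree.names[tree.root]
    out: dict[str, float] = {}
    for col, lab in enumerate(recon.column_labels):
        if recon.profile[root_name][col]:
            out[lab] = 0.0
    for ev in recon.events:
        if ev.event_type != "acquisition":
            continue
        lab = ev.spacer_labels[0]
        d = float(depths[tree.index_of(ev.branch_id)])
        out[lab] = min(out.get(lab, d), d)
    return out


def select_oldest_candidates(
    duplicates: list[DuplicateCandidateSet],
    recon: ReconstructionResult,
    tree: Phylogeny,
) -> set[str]:
    """Pick, per candidate set, the candidate acquired closest to the root.

    Ties are broken toward the trailer-proximal column.  All other
    candidates are excluded from the PSIO.
    """
    acq = _acquisition_depths(recon, tree)
    excluded: set[str] = set()
    for ds in duplicates:
        ranked = sorted(
            zip(ds.candidates, ds.columns),
            key=lambda t: (acq.get(t[0], float("inf")), -t[1]),
        )
        excluded.update(lab for lab, _ in ranked[1:])
    return excluded


def build_psio(
    msaa: MSAA,
    recon: ReconstructionResult,
    tree: Phylogeny,
) -> PSIO:
    """PSIO from the union of all per-array insertion orders.

    For each array row (leader to trailer) every label is "acquired
    after" each label to its trailer side; consecutive edges generate the
    same closure.  Non-oldest duplicate candidates are dropped before the
    union.  The MSAA's renaming guarantees acyclicity.
    """
    excluded = select_oldest_candidates(msaa.duplicates, recon, tree)
    g = nx.DiGraph()
    for lab in msaa.column_labels:
        if lab not in excluded:
            g.add_node(lab)
    for aid in msaa.array_ids:
        row = [lab for lab in msaa.row_labels(aid) if lab not in excluded]
        for younger, older in zip(row, row[1:]):
            g.add_edge(younger, older)
    if not nx.is_directed_acyclic_graph(g):
        raise PSIOError(
            "PSIO contains a cycle; the MSAA failed to rename conflicting labels"
        )
    reduced = nx.transitive_reduction(g)
    closure = nx.transitive_closure_dag(g)
    return PSIO(graph=reduced, closure=closure, excluded=excluded)


def find_contradictions(
    recon: ReconstructionResult,
    psio: PSIO,
    tree: Phylogeny,
) -> set[tuple[str, str, str]]:
    """(younger, older, conflicting branch) triples violating the order.

    The relation "y acquired after x" requires, for every reconstructed
    acquisition of y on a branch b_y, that x was acquired on b_y itself
    or root-ward of it (or was already present at the root).  When no
    acquisition of x satisfies this, every acquisition branch of x is
    reported as conflicting: x was inserted too close to the leaves.
    Acquisitions of excluded duplicate candidates are ignored on both
    sides.
    """
    col_of = {lab: i for i, lab in enumerate(recon.column_labels)}
    root_name = tree.names[tree.root]
    acq_branches: dict[str, set[int]] = {}
    for ev in recon.events:
        if ev.event_type == "acquisition":
            lab = ev.spacer_labels[0]
            if lab not in psio.excluded:
                acq_branches.setdefault(lab, set()).add(
                    tree.index_of(ev.branch_id)
                )

    def rootpath(v: int) -> set[int]:
        out = {v}
        while tree.parent[v] != -1:
            v = int(tree.parent[v])
            out.add(v)
        return out

    contradictions: set[tuple[str, str, str]] = set()
    for y, y_branches in acq_branches.items():
        for x in psio.older_than(y):
            if recon.profile[root_name][col_of[x]]:
                continue  # x predates the root
            x_branches = acq_branches.get(x)
            if not x_branches:
                continue
            for b_y in y_branches:
                if not (x_branches & rootpath(b_y)):
                    for b_x in x_branches:
                        contradictions.add((y, x, tree.names[b_x]))
    return contradictions


def refine(
    recon: ReconstructionResult,
    psio: PSIO,
    tree: Phylogeny,
    msaa: MSAA,
    params: GuideModelParams | None = None,
    guide_loglik: float = float("nan"),
) -> tuple[ReconstructionResult, float, dict[tuple[str, int], bool]]:
    """Iteratively repair the guide reconstruction until PSIO-consistent.

    Each round fixes every older spacer whose acquisition violates the
    order to be present at the parent node of its own (conflicting)
    acquisition branch, then recomputes the constrained joint-ML
    reconstruction — the spacer's insertion walks root-ward, one node per
    round, until the order is satisfied or the spacer reaches the root.
    Accumulated constraints are kept across rounds.  Returns the refined
    reconstruction, its log likelihood, and the constraints used.
    """
    params = params or GuideModelParams()
    col_of = {lab: i for i, lab in enumerate(recon.column_labels)}
    constraints: dict[tuple[str, int], bool] = {}
    current = recon
    loglik = guide_loglik
    cap = max(1, len(recon.column_labels)) * tree.n_nodes
    for _ in range(cap):
        contras = find_contradictions(current, psio, tree)
        if not contras:
            return current, loglik, constraints
        added = False
        for y, x, branch in sorted(contras):
            v = tree.index_of(branch)
            key = (tree.names[tree.parent[v]], col_of[x])
            if constraints.get(key) is not True:
                constraints[key] = True
                added = True
        if not added:
            raise PSIOError("refinement stalled: contradictions persist "
                            "with no new constraints to add")
        current, loglik = _guide_reconstruct(tree, msaa, params, constraints)
    raise PSIOError("refinement did not converge within the iteration cap")


def classify_duplicates(
    duplicates: list[DuplicateCandidateSet],
    recon: ReconstructionResult,
    tree: Phylogeny,
    psio: PSIO,
) -> list[EventRecord]:
    """Classify each non-oldest duplicate candidate's insertion event.

    For a candidate c with partner set P (the other candidates of the same
    base label), tested in order:

    * duplication — some partner coexists with c at the node where c is
      acquired, or c is inserted internally (not at the leader end);
    * rearrangement — c's acquisition shares a branch with the deletion
      of a partner;
    * reacquisition — leader-end insertion with a partner present at an
      ancestor of the acquisition branch but not on it;
    * independent_acquisition — leader-end insertion with no partner
      anywhere root-ward;
    * other — anything else (e.g. a candidate already present at the
      root).
    """
    col_of = {lab: i for i, lab in enumerate(recon.column_labels)}
    acq_events: dict[str, list[EventRecord]] = {}
    del_on_branch: dict[str, set[str]] = {}
    acq_on_branch: dict[str, set[str]] = {}
    for ev in recon.events:
        if ev.event_type == "acquisition":
            acq_events.setdefault(ev.spacer_labels[0], []).append(ev)
            acq_on_branch.setdefault(ev.branch_id, set()).add(ev.spacer_labels[0])
        elif ev.event_type == "deletion":
            del_on_branch.setdefault(ev.branch_id, set()).update(ev.spacer_labels)
    depths = tree.depths()
    out: list[EventRecord] = []
    for ds in duplicates:
        for cand, col in zip(ds.candidates, ds.columns):
            if cand not in psio.excluded:
                continue
            partners = [c for c in ds.candidates if c != cand]
            events = acq_events.get(cand)
            if not events:
                out.append(EventRecord(tree.names[tree.root], "other",
                                       (cand,), (col,)))
                continue
            ev = min(events, key=lambda e: depths[tree.index_of(e.branch_id)])
            v = tree.index_of(ev.branch_id)
            child_name = tree.names[v]
            parent_name = tree.names[tree.parent[v]]
            child_prof = recon.profile[child_name]
            parent_prof = recon.profile[parent_name]
            new_here = acq_on_branch.get(child_name, set())
            # leader-end insertion: nothing inherited from the parent sits
            # leader-ward of the candidate in the child's array
            leader_end = not any(
                child_prof[c2] and recon.column_labels[c2] not in new_here
                for c2 in range(col - 1)
            )
            partner_at_child = any(child_prof[col_of[p]] for p in partners)
            partner_deleted_here = bool(
                set(partners) & del_on_branch.get(child_name, set())
            )
            partner_at_ancestor = any(
                recon.profile[tree.names[a]][col_of[p]]
                for p in partners
                for a in [tree.parent[v]] + tree.ancestors(tree.parent[v])
            )
            if partner_at_child or not leader_end:
                etype = "duplication"
            elif partner_deleted_here:
                etype = "rearrangement"
            elif partner_at_ancestor:
                etype = "reacquisition"
            else:
                etype = "independent_acquisition"
            out.append(EventRecord(child_name, etype, (cand,), (col,)))
    return out
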