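"""End-to-end reconstruction pipeline for one group of spacer arrays.

Order of operations: align the arrays into an MSAA, run the unordered
guide reconstruction, build the PSIO, refine the reconstruction until it
respects the insertion order, classify duplicate candidates, extract
per-branch deletion data, and fit/test the deletion models.  Array
orientation can be chosen automatically by comparing the maximised model
likelihood of the forward and reversed alignments.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .arrays import EventRecord, ReconstructionResult, SpacerGroup
from .guide import GuideModelParams
from .guide import reconstruct as guide_reconstruct
from .models import (
    BranchDeletionData,
    DeletionDataset,
    LRTResult,
    ModelParams,
    estimate_params,
    lrt,
)
from .msaa import MSAA, align_group
from .phylo import Phylogeny
from .psio import PSIO, build_psio, classify_duplicates, refine

logger = logging.getLogger(__name__)


@dataclass
class GroupReconstruction:
    """Everything the pipeline derives for one group."""

    group: SpacerGroup
    tree: Phylogeny
    msaa: MSAA
    guide: ReconstructionResult
    refined: ReconstructionResult
    psio: PSIO
    loglik: float
    dataset: DeletionDataset | None
    orientation: str = "forward"
    orientation_margin: float = 0.0

    @property
    def events(self) -> list[EventRecord]:
        return self.refined.events


def _check_tree_matches(group: SpacerGroup, tree: Phylogeny) -> None:
    if set(tree.leaf_names) != set(group.array_ids):
        raise ValueError(
            "tree leaves and group array ids differ: "
            f"{sorted(set(tree.leaf_names) ^ set(group.array_ids))}"
        )


def extract_deletion_dataset(
    recon: ReconstructionResult, tree: Phylogeny
) -> DeletionDataset | None:
    """Collect (N_b, K_b) per branch plus per-spacer acquisition nodes.

    N_b is the number of alignment columns present at the parent of
    branch b; K_b holds the deleted columns as 1-based positions within
    the parent's array.  Returns None when the tree has no branches.
    """
    branches: list[BranchDeletionData] = []
    deleted_by_branch: dict[str, list[int]] = {}
    for ev in recon.events:
        if ev.event_type == "deletion":
            deleted_by_branch.setdefault(ev.branch_id, []).extend(
                c - 1 for c in ev.alignment_columns
            )
    for v in tree.preorder():
        if v == tree.root:
            continue
        child = tree.names[v]
        parent_profile = recon.profile[tree.names[tree.parent[v]]]
        parent_cols = [c for c, p in enumerate(parent_profile) if p]
        pos_of = {c: i + 1 for i, c in enumerate(parent_cols)}
        deleted = tuple(sorted(pos_of[c] for c in deleted_by_branch.get(child, [])))
        branches.append(
            BranchDeletionData(child, float(tree.length[v]), len(parent_cols),
                               deleted)
        )
    if not branches:
        return None
    # rootmost acquisition node per spacer (for the unobserved correction);
    # spacers present at the root are conditioned from the root itself
    acq: dict[str, str] = {}
    depths = tree.depths()
    root_name = tree.names[tree.root]
    for col, lab in enumerate(recon.column_labels):
        if recon.profile[root_name][col]:
            acq[lab] = root_name
    for ev in recon.events:
        if ev.event_type != "acquisition":
            continue
        lab = ev.spacer_labels[0]
        if lab not in acq or (
            depths[tree.index_of(ev.branch_id)] < depths[tree.index_of(acq[lab])]
        ):
            acq[lab] = ev.branch_id
    leaf_lengths = [
        sum(recon.profile[tree.names[v]]) for v in tree.leaves
    ]
    return DeletionDataset(
        tree=tree,
        branches=branches,
        acquisition_nodes=acq,
        mean_array_length=float(np.mean(leaf_lengths)),
    )


def reconstruct_group(
    group: SpacerGroup,
    tree: Phylogeny,
    guide_params: GuideModelParams | None = None,
) -> GroupReconstruction:
    """Align, reconstruct, and refine one group along a given tree."""
    _check_tree_matches(group, tree)
    guide_params = guide_params or GuideModelParams()
    msaa = align_group(group)
    guide, guide_ll = guide_reconstruct(tree, msaa, guide_params)
    psio = build_psio(msaa, guide, tree)
    refined, loglik, _ = refine(guide, psio, tree, msaa, guide_params,
                                guide_loglik=guide_ll)
    complex_events = classify_duplicates(msaa.duplicates, refined, tree, psio)
    refined.events = refined.events + complex_events
    dataset = extract_deletion_dataset(refined, tree)
    return GroupReconstruction(
        group=group, tree=tree, msaa=msaa, guide=guide, refined=refined,
        psio=psio, loglik=loglik, dataset=dataset,
    )


@dataclass
class GroupAnalysis:
    """Reconstruction plus fitted models and the deletion-mode test."""

    reconstruction: GroupReconstruction
    idm: ModelParams | None = None
    bdm: ModelParams | None = None
    lrt_result: LRTResult | None = None

    def summary(self) -> dict:
        rec = self.reconstruction
        out = {
            "group_id": rec.group.group_id,
            "orientation": rec.orientation,
            "orientation_margin": rec.orientation_margin,
            "n_arrays": len(rec.group.arrays),
            "n_columns": rec.msaa.n_columns,
            "n_deletion_events": rec.refined.n_deletion_events(),
            "loglik": rec.loglik,
        }
        if self.idm is not None:
            out["idm"] = self.idm.to_dict()
        if self.bdm is not None:
            out["bdm"] = self.bdm.to_dict()
        if self.lrt_result is not None:
            out["lrt"] = self.lrt_result.to_dict()
        return out


def analyze_group(
    group: SpacerGroup,
    tree: Phylogeny,
    guide_params: GuideModelParams | None = None,
    corrections: bool = True,
    orientation: str = "auto",
    orientation_margin: float = 2.0,
    run_lrt: bool = True,
) -> GroupAnalysis:
    """Full pipeline: orientation, reconstruction, estimation, LRT."""
    if orientation == "auto":
        rec = choose_orientation(group, tree, guide_params, corrections,
                                 margin=orientation_margin)
    elif orientation in ("forward", "reverse"):
        g = group if orientation == "forward" else group.reversed()
        rec = reconstruct_group(g, tree, guide_params)
        rec.orientation = orientation
    else:
        raise ValueError("orientation must be auto, forward or reverse")
    if rec.dataset is None or rec.dataset.n_deleted_spacers == 0:
        logger.info("group %s has no reconstructed deletions; skipping "
                    "estimation", group.group_id)
        return GroupAnalysis(rec)
    if not run_lrt:
        return GroupAnalysis(
            rec,
            idm=estimate_params(rec.dataset, "IDM", corrections),
            bdm=estimate_params(rec.dataset, "BDM", corrections),
        )
    res = lrt(rec.dataset, corrections)
    return GroupAnalysis(rec, idm=res.idm, bdm=res.bdm, lrt_result=res)


def _max_model_loglik(rec: GroupReconstruction, corrections: bool) -> float:
    """Maximised BDM group log-likelihood of a reconstruction."""
    if rec.dataset is None or rec.dataset.n_deleted_spacers == 0:
        return 0.0
    return estimate_params(rec.dataset, "BDM", corrections).loglik


def choose_orientation(
    group: SpacerGroup,
    tree: Phylogeny,
    guide_params: GuideModelParams | None = None,
    corrections: bool = True,
    margin: float = 2.0,
) -> GroupReconstruction:
    """Reconstruct in both orientations and keep the better-supported one.

    The forward and reversed alignments are each reconstructed and their
    maximised model likelihoods compared; the reversed orientation is
    adopted only when it wins by more than ``margin`` log-units,
    otherwise the supplied orientation is kept.  Single-spacer or
    palindromic groups give margin 0 and keep the input orientation.
    """
    fwd = reconstruct_group(group, tree, guide_params)
    rev = reconstruct_group(group.reversed(), tree, guide_params)
    ll_f = _max_model_loglik(fwd, corrections)
    ll_r = _max_model_loglik(rev, corrections)
    delta = ll_r - ll_f
    if delta > margin:
        rev.orientation = "reverse"
        rev.orientation_margin = float(delta)
        return rev
    fwd.orientation = "forward" if abs(delta) > margin else "default"
    fwd.orientation_margin = float(-delta)
    return fwd
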