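"""Positional deletion-frequency profiles and cross-group aggregation.

Deletions of spacers near the array boundaries are expected to be rarer
under a blockwise, repeat-misalignment-driven process, because boundary
repeats have fewer partners to misalign with.  Two views quantify this:

* a relative-position profile — every deleted spacer is binned by its
  position in the parent array divided by the parent array length, with
  the first (FS) and last (LS) spacers in dedicated bins;
* a boundary-proximity profile — deletion frequencies at absolute
  offsets from either boundary, normalised per exposure (the number of
  branch x position opportunities), so that a position-independent
  deletion process yields a flat profile.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .arrays import ReconstructionResult
from .phylo import Phylogeny

logger = logging.getLogger(__name__)


@dataclass
class PositionalDeletionProfile:
    """Share of all deletions falling in each relative-position bin."""

    bin_labels: list[str]  # "FS", interior bins by upper limit, "LS"
    proportions: np.ndarray
    counts: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"bin": self.bin_labels, "count": self.counts,
             "proportion": self.proportions}
        )


def _deleted_positions(
    recon: ReconstructionResult, tree: Phylogeny
) -> Iterable[tuple[int, int]]:
    """(position in parent array, parent array length) per deleted spacer."""
    for v in tree.preorder():
        if v == tree.root:
            continue
        child = tree.names[v]
        parent_profile = recon.profile[tree.names[tree.parent[v]]]
        parent_cols = [c for c, p in enumerate(parent_profile) if p]
        pos_of = {c: i + 1 for i, c in enumerate(parent_cols)}
        n = len(parent_cols)
        for ev in recon.events:
            if ev.event_type != "deletion" or ev.branch_id != child:
                continue
            for col in ev.alignment_columns:
                yield pos_of[col - 1], n


def _mean_leaf_length(recon: ReconstructionResult, tree: Phylogeny) -> float:
    return float(np.mean([
        sum(recon.profile[tree.names[v]]) for v in tree.leaves
    ]))


def deletion_position_profile(
    reconstructions: Sequence[tuple[ReconstructionResult, Phylogeny]],
    bins: int = 10,
    length_filter: tuple[float, float] | None = None,
) -> PositionalDeletionProfile:
    """Bin deleted spacers by relative position in the parent array.

    Each deleted spacer contributes at position/length; position 1 goes
    to the FS bin, position = length to the LS bin, the rest into
    ``bins`` equal-width interior bins labeled by their upper limit.
    ``length_filter=(lo, hi)`` keeps only groups whose mean leaf array
    length lies in [lo, hi].
    """
    edges = np.linspace(0.0, 1.0, bins + 1)
    labels = ["FS"] + [f"{e:.2f}" for e in edges[1:]] + ["LS"]
    counts = np.zeros(len(labels))
    for recon, tree in reconstructions:
        if length_filter is not None:
            m = _mean_leaf_length(recon, tree)
            if not length_filter[0] <= m <= length_filter[1]:
                continue
        for pos, n in _deleted_positions(recon, tree):
            if pos == 1:
                counts[0] += 1
            elif pos == n:
                counts[-1] += 1
            else:
                rel = pos / n
                b = min(int(np.searchsorted(edges, rel, side="left")), bins)
                counts[b] += 1
    total = counts.sum()
    if total == 0:
        logger.warning("no deletions found; profile is empty")
        proportions = counts
    else:
        proportions = counts / total
    return PositionalDeletionProfile(labels, proportions, counts)


@dataclass
class BoundaryProximityProfile:
    """Exposure-normalised deletion frequency near both array ends."""

    offsets: list[str]  # FS, FS+1, ..., LS-1, LS
    frequencies: np.ndarray
    exposures: np.ndarray
    hits: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"offset": self.offsets, "hits": self.hits,
             "exposure": self.exposures, "frequency": self.frequencies}
        )

    @property
    def fs_frequency(self) -> float:
        return float(self.frequencies[0])

    @property
    def ls_frequency(self) -> float:
        return float(self.frequencies[-1])


def boundary_proximity_profile(
    reconstructions: Sequence[tuple[ReconstructionResult, Phylogeny]],
    k: int = 3,
) -> BoundaryProximityProfile:
    """Deletion frequency at absolute offsets from the two boundaries.

    A position p in a parent array of length n has leader offset p-1 and
    trailer offset n-p; it is assigned to whichever boundary is closer
    (ties toward the leader), and only offsets < k are tracked.  Both
    hits and exposures (present positions on a branch) are accumulated,
    so the frequency is per opportunity and flat for a
    position-independent process.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    exposures = np.zeros(2 * k)
    hits = np.zeros(2 * k)

    def bucket(pos: int, n: int) -> int | None:
        lead, trail = pos - 1, n - pos
        if lead <= trail and lead < k:
            return lead
        if trail < lead and trail < k:
            return 2 * k - 1 - trail
        return None

    for recon, tree in reconstructions:
        for v in tree.preorder():
            if v == tree.root:
                continue
            parent_profile = recon.profile[tree.names[tree.parent[v]]]
            n = sum(parent_profile)
            for pos in range(1, n + 1):
                b = bucket(pos, n)
                if b is not None:
                    exposures[b] += 1
        for pos, n in _deleted_positions(recon, tree):
            b = bucket(pos, n)
            if b is not None:
                hits[b] += 1
    with np.errstate(invalid="ignore", divide="ignore"):
        freq = np.where(exposures > 0, hits / np.maximum(exposures, 1), np.nan)
    offsets = [f"FS+{j}" if j else "FS" for j in range(k)] + [
        f"LS-{k - 1 - j}" if j < k - 1 else "LS" for j in range(k)
    ]
    return BoundaryProximityProfile(offsets, freq, exposures, hits)


def aggregate_groups(analyses: Sequence["object"]) -> dict:
    """Summary table over per-group analyses (means/medians of estimates).

    Only groups with at least one reconstructed deletion enter the
    parameter summaries.  Also reports the LRT rejection fraction and
    duplicate-candidate classification counts.
    """
    rows = []
    rejections = []
    class_counts: dict[str, int] = {}
    total_spacers = 0
    total_candidates = 0
    for a in analyses:
        rec = a.reconstruction
        total_spacers += rec.msaa.n_columns
        for ev in rec.refined.events:
            if ev.event_type in ("duplication", "rearrangement",
                                 "reacquisition", "independent_acquisition",
                                 "other"):
                class_counts[ev.event_type] = class_counts.get(
                    ev.event_type, 0) + 1
                total_candidates += 1
        if a.bdm is None:
            continue
        rows.append({
            "group_id": rec.group.group_id,
            "alpha": a.bdm.alpha_corrected,
            "rho_B": a.bdm.rho,
            "rho_I": a.idm.rho if a.idm else np.nan,
            "per_spacer_rate": a.bdm.per_spacer_rate,
        })
        if a.lrt_result is not None:
            rejections.append(a.lrt_result.reject_idm)
    frame = pd.DataFrame(rows)
    summary: dict = {
        "n_groups": len(list(analyses)),
        "n_groups_with_deletions": len(frame),
        "total_spacers": total_spacers,
        "duplicate_candidates": total_candidates,
        "psio_compatible": total_spacers - total_candidates,
        "classes": class_counts,
    }
    if len(frame):
        for colname in ("alpha", "rho_B", "rho_I", "per_spacer_rate"):
            summary[colname] = {
                "mean": float(frame[colname].mean()),
                "median": float(frame[colname].median()),
            }
    if rejections:
        summary["lrt_rejection_fraction"] = float(np.mean(rejections))
    return summary
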