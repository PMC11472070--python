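"""Spacer sequence clustering and group formation.

Near-identical spacer DNA sequences (and their reverse complements) are
collapsed into label clusters by single-linkage merging: two clusters are
joined whenever they contain a cross-pair of sequences, in either
orientation, at Levenshtein distance <= 1.  Relabeled arrays are then
partitioned into analysis groups: connected components of the shared-label
graph, keeping only components with at least three arrays and some spacer
diversity.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import edlib

from .arrays import SpacerArrayRecord, SpacerGroup, ValidationError

logger = logging.getLogger(__name__)

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _check_dna(seq: str) -> str:
    s = seq.upper()
    if not s or set(s) - set("ACGTN"):
        raise ValidationError(f"not a DNA sequence over ACGTN: {seq!r}")
    return s


def levenshtein_distance(a: str, b: str) -> int:
    """Exact edit distance (substitution, insertion, deletion all cost 1)."""
    a, b = _check_dna(a), _check_dna(b)
    if a == b:
        return 0
    return int(edlib.align(a, b, task="distance")["editDistance"])


def canonical_orientation(seq: str) -> str:
    """The lexicographically smaller of a sequence and its reverse complement."""
    s = _check_dna(seq)
    rc = reverse_complement(s)
    return min(s, rc)


@dataclass
class SpacerCluster:
    label: str
    members: tuple[str, ...]  # canonical orientations, sorted


class _UnionFind:
    def __init__(self, n: int) -> None:
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int) -> None:
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            self.parent[max(ri, rj)] = min(ri, rj)


def _close_pair(a: str, b: str) -> bool:
    """Distance <= 1 between a and b considering both orientations of b."""
    if abs(len(a) - len(b)) > 1:
        return False
    for cand in (b, reverse_complement(b)):
        res = edlib.align(a, cand, task="distance", k=1)
        if res["editDistance"] != -1:
            return True
    return False


def cluster_spacers(
    sequences: Iterable[str],
) -> tuple[list[SpacerCluster], dict[str, str]]:
    """Single-linkage clustering of spacer sequences at edit distance <= 1.

    Returns the clusters and a mapping from every input sequence (as
    given, upper-cased) to its cluster label.  The label is the
    lexicographically smallest canonical member, so the clustering is
    invariant under input order and under reverse-complementing any
    sequence.
    """
    raw = sorted({_check_dna(s) for s in sequences})
    if not raw:
        raise ValidationError("no sequences to cluster")
    canon = sorted({canonical_orientation(s) for s in raw})
    uf = _UnionFind(len(canon))
    for i in range(len(canon)):
        for j in range(i + 1, len(canon)):
            if uf.find(i) != uf.find(j) and _close_pair(canon[i], canon[j]):
                uf.union(i, j)
    groups: dict[int, list[str]] = {}
    for i, seq in enumerate(canon):
        groups.setdefault(uf.find(i), []).append(seq)
    clusters = [
        SpacerCluster(label=min(members), members=tuple(sorted(members)))
        for members in groups.values()
    ]
    clusters.sort(key=lambda c: c.label)
    seq_to_label: dict[str, str] = {}
    canon_to_label = {m: c.label for c in clusters for m in c.members}
    for s in raw:
        seq_to_label[s] = canon_to_label[canonical_orientation(s)]
    return clusters, seq_to_label


def relabel_arrays(
    arrays: Sequence[SpacerArrayRecord], seq_to_label: Mapping[str, str]
) -> list[SpacerArrayRecord]:
    """Replace raw spacer sequences in arrays by their cluster labels."""
    return [
        SpacerArrayRecord(
            a.group_id, a.array_id, tuple(seq_to_label[s.upper()] for s in a.spacers)
        )
        for a in arrays
    ]


def form_groups(
    arrays: Sequence[SpacerArrayRecord],
    min_arrays: int = 3,
) -> tuple[list[SpacerGroup], list[tuple[str, str]]]:
    """Partition arrays into groups by transitive spacer-label overlap.

    Two arrays are connected if they share at least one label; groups are
    the connected components.  Components with fewer than ``min_arrays``
    arrays, or whose arrays are all identical (no spacer diversity), are
    dropped.  Returns (groups, dropped) where ``dropped`` lists
    (array_id, reason) pairs.
    """
    ids = [a.array_id for a in arrays]
    if len(set(ids)) != len(ids):
        raise ValidationError("duplicate array ids in input")
    n = len(arrays)
    uf = _UnionFind(n)
    label_owner: dict[str, int] = {}
    for i, arr in enumerate(arrays):
        for lab in set(arr.spacers):
            if lab in label_owner:
                uf.union(label_owner[lab], i)
            else:
                label_owner[lab] = i
    comps: dict[int, list[SpacerArrayRecord]] = {}
    for i, arr in enumerate(arrays):
        comps.setdefault(uf.find(i), []).append(arr)
    groups: list[SpacerGroup] = []
    dropped: list[tuple[str, str]] = []
    for members in comps.values():
        members.sort(key=lambda a: a.array_id)
        if len(members) < min_arrays:
            dropped.extend((a.array_id, "group too small") for a in members)
            continue
        if len({a.spacers for a in members}) == 1:
            dropped.extend((a.array_id, "no spacer diversity") for a in members)
            continue
        gid = members[0].group_id
        groups.append(SpacerGroup(gid, members))
    groups.sort(key=lambda g: g.arrays[0].array_id)
    if dropped:
        logger.info("dropped %d arrays during group formation", len(dropped))
    return groups, dropped
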