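"""Multiple spacer array alignment (MSAA) over label sequences.

Arrays are aligned on their spacer labels, never on DNA: two positions may
share a column only if their labels are equal, so the only degrees of
freedom are gaps.  Scoring is match(+1 for equal labels) / mismatch
(forbidden) / gap(0), i.e. the alignment maximises matched cells, which is
the same as minimising gap cells.

Repeated occurrences of a label (within one array, or in positions whose
orders conflict across arrays) cannot all share a column; they are split
into uniquely renamed duplicate candidates (e.g. ``3`` -> ``3A``, ``3B``)
so that every label occupies exactly one column.  Within an array,
occurrences are numbered from the trailer end, so that a single occurrence
in another array preferentially matches the trailer-proximal (oldest)
copy.

Groups of at most three arrays with short arrays are aligned exactly by
multi-dimensional dynamic programming; larger groups use progressive
pairwise alignment ordered by shared-label counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Sequence

import numpy as np

from .arrays import SpacerGroup, ValidationError

Token = tuple[str, int]  # (base label, occurrence index counted from trailer)

_EXACT_MAX_ARRAYS = 3
_EXACT_MAX_LEN = 12


@dataclass(frozen=True)
class DuplicateCandidateSet:
    """Columns holding relabeled duplicates of one base label."""

    base_label: str
    candidates: tuple[str, ...]  # renamed labels, leader-most first
    columns: tuple[int, ...]  # 1-based column of each candidate

    def __post_init__(self) -> None:
        if len(self.candidates) < 2:
            raise ValidationError("duplicate candidate set needs >= 2 candidates")


@dataclass
class MSAA:
    """Alignment result: unique label per column, boolean presence matrix."""

    array_ids: list[str]
    column_labels: list[str]
    base_labels: list[str]
    presence: np.ndarray  # bool, shape (n_arrays, n_columns)
    duplicates: list[DuplicateCandidateSet] = field(default_factory=list)

    @property
    def n_columns(self) -> int:
        return len(self.column_labels)

    @property
    def n_gap_cells(self) -> int:
        return int((~self.presence).sum())

    def row_labels(self, array_id: str) -> tuple[str, ...]:
        i = self.array_ids.index(array_id)
        return tuple(
            lab for lab, p in zip(self.column_labels, self.presence[i]) if p
        )

    def reversed(self) -> "MSAA":
        return MSAA(
            self.array_ids,
            self.column_labels[::-1],
            self.base_labels[::-1],
            self.presence[:, ::-1].copy(),
            [
                DuplicateCandidateSet(
                    d.base_label,
                    d.candidates[::-1],
                    tuple(self.n_columns - c + 1 for c in reversed(d.columns)),
                )
                for d in self.duplicates
            ],
        )


def _tokenize(spacers: Sequence[str]) -> list[Token]:
    """Label occurrences numbered from the trailer end (oldest = 0)."""
    seen: dict[str, int] = {}
    out: list[Token] = []
    for lab in reversed(spacers):
        occ = seen.get(lab, 0)
        seen[lab] = occ + 1
        out.append((lab, occ))
    return out[::-1]


# ----------------------------------------------------------------------
# Exact multi-array alignment (small groups)
# ----------------------------------------------------------------------

def _align_exact(rows: list[list[Token]]) -> list[tuple[Token, frozenset[int]]]:
    """Minimum-column alignment by DP over consumed-prefix tuples."""
    k = len(rows)
    lens = tuple(len(r) for r in rows)
    start = (0,) * k
    best: dict[tuple[int, ...], int] = {start: 0}
    back: dict[tuple[int, ...], tuple[tuple[int, ...], Token, frozenset[int]]] = {}
    # subsets ordered so ties prefer larger subsets, then lexicographic
    subsets = sorted(
        (frozenset(s) for r in range(1, k + 1) for s in combinations(range(k), r)),
        key=lambda s: (-len(s), tuple(sorted(s))),
    )
    import heapq

    heap = [(0, start)]
    while heap:
        cols, state = heapq.heappop(heap)
        if cols > best.get(state, 1 << 30):
            continue
        if state == lens:
            break
        for sub in subsets:
            if any(state[i] >= lens[i] for i in sub):
                continue
            toks = {rows[i][state[i]] for i in sub}
            if len(toks) != 1:
                continue
            nxt = tuple(
                state[i] + (1 if i in sub else 0) for i in range(k)
            )
            if cols + 1 < best.get(nxt, 1 << 30):
                best[nxt] = cols + 1
                back[nxt] = (state, next(iter(toks)), sub)
                heapq.heappush(heap, (cols + 1, nxt))
    state = lens
    cols_rev: list[tuple[Token, frozenset[int]]] = []
    while state != start:
        prev, tok, sub = back[state]
        cols_rev.append((tok, sub))
        state = prev
    return cols_rev[::-1]


# ----------------------------------------------------------------------
# Progressive pairwise alignment (general case)
# ----------------------------------------------------------------------

def _align_row_to_profile(
    columns: list[tuple[Token, set[int]]], row: list[Token], row_index: int
) -> list[tuple[Token, set[int]]]:
    """Needleman-Wunsch of one token row against the profile columns.

    Match (+1) only between equal tokens; gaps cost nothing.  Ties prefer
    the match, then consuming a profile column, keeping the traceback
    deterministic.
    """
    n, m = len(columns), len(row)
    score = np.zeros((n + 1, m + 1), dtype=np.int64)
    for i in range(1, n + 1):
        tok_i = columns[i - 1][0]
        for j in range(1, m + 1):
            s = max(score[i - 1, j], score[i, j - 1])
            if tok_i == row[j - 1]:
                s = max(s, score[i - 1, j - 1] + 1)
            score[i, j] = s
    out: list[tuple[Token, set[int]]] = []
    i, j = n, m
    while i > 0 or j > 0:
        if (
            i > 0
            and j > 0
            and columns[i - 1][0] == row[j - 1]
            and score[i, j] == score[i - 1, j - 1] + 1
        ):
            tok, members = columns[i - 1]
            out.append((tok, members | {row_index}))
            i, j = i - 1, j - 1
        elif i > 0 and score[i, j] == score[i - 1, j]:
            out.append(columns[i - 1])
            i -= 1
        else:
            out.append((row[j - 1], {row_index}))
            j -= 1
    return out[::-1]


def _guide_order(rows: dict[str, list[Token]]) -> list[str]:
    ids = sorted(rows)
    if len(ids) <= 2:
        return ids
    shared = {
        (a, b): len(set(rows[a]) & set(rows[b]))
        for i, a in enumerate(ids)
        for b in ids[i + 1:]
    }
    first = min(shared, key=lambda p: (-shared[p], tuple(sorted(p))))
    order = sorted(first)
    placed = set(rows[order[0]]) | set(rows[order[1]])
    remaining = [i for i in ids if i not in order]
    while remaining:
        nxt = min(remaining, key=lambda a: (-len(set(rows[a]) & placed), a))
        order.append(nxt)
        placed |= set(rows[nxt])
        remaining.remove(nxt)
    return order


# ----------------------------------------------------------------------
# Renaming and assembly
# ----------------------------------------------------------------------

def _suffix(i: int) -> str:
    out = ""
    i += 1
    while i:
        i, r = divmod(i - 1, 26)
        out = chr(ord("A") + r) + out
    return out


def _assemble(
    array_ids: list[str],
    columns: list[tuple[Token, set[int]]],
    universe: set[str],
) -> MSAA:
    base_labels = [tok[0] for tok, _ in columns]
    counts: dict[str, int] = {}
    for lab in base_labels:
        counts[lab] = counts.get(lab, 0) + 1
    column_labels: list[str] = []
    dup_map: dict[str, list[tuple[str, int]]] = {}
    seen: dict[str, int] = {}
    for c, lab in enumerate(base_labels):
        if counts[lab] == 1:
            column_labels.append(lab)
            continue
        k = seen.get(lab, 0)
        seen[lab] = k + 1
        new = f"{lab}{_suffix(k)}"
        while new in universe:
            new = f"{new}~"
        column_labels.append(new)
        dup_map.setdefault(lab, []).append((new, c + 1))
    presence = np.zeros((len(array_ids), len(columns)), dtype=bool)
    for c, (_, members) in enumerate(columns):
        for i in members:
            presence[i, c] = True
    duplicates = [
        DuplicateCandidateSet(
            lab,
            tuple(n for n, _ in cands),
            tuple(col for _, col in cands),
        )
        for lab, cands in sorted(dup_map.items())
    ]
    return MSAA(array_ids, column_labels, base_labels, presence, duplicates)


def align_group(group: SpacerGroup) -> MSAA:
    """Align a group's arrays into an MSAA and split duplicate candidates."""
    rows = {a.array_id: _tokenize(a.spacers) for a in group.arrays}
    ids = sorted(rows)
    universe = group.label_universe
    lens = [len(r) for r in rows.values()]
    if len(ids) <= _EXACT_MAX_ARRAYS and max(lens) <= _EXACT_MAX_LEN:
        cols = _align_exact([rows[i] for i in ids])
        columns = [(tok, {i for i in sub}) for tok, sub in cols]
    else:
        order = _guide_order(rows)
        pos = {a: ids.index(a) for a in ids}
        columns = [(tok, {pos[order[0]]}) for tok in rows[order[0]]]
        for a in order[1:]:
            columns = _align_row_to_profile(columns, rows[a], pos[a])
    return _assemble(ids, columns, universe)


def validate_msaa(msaa: MSAA, group: SpacerGroup | None = None) -> list[str]:
    """Check the MSAA invariants; returns a list of violations (empty = ok)."""
    violations: list[str] = []
    if len(set(msaa.column_labels)) != msaa.n_columns:
        dupes = {
            lab for lab in msaa.column_labels if msaa.column_labels.count(lab) > 1
        }
        violations.append(f"labels occupy multiple columns: {sorted(dupes)}")
    for c in range(msaa.n_columns):
        if not msaa.presence[:, c].any():
            violations.append(f"column {c + 1} is empty")
    if group is not None:
        by_id = {a.array_id: a for a in group.arrays}
        for i, aid in enumerate(msaa.array_ids):
            row_bases = tuple(
                base
                for base, p in zip(msaa.base_labels, msaa.presence[i])
                if p
            )
            if row_bases != by_id[aid].spacers:
                violations.append(
                    f"row {aid}: gap-stripped sequence differs from input array"
                )
    return violations
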