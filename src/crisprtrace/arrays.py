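"""Core domain types: spacer arrays, groups, and reconstructed events.

Spacer arrays are ordered sequences of label tokens.  Position 1 is the
leader-proximal (most recently acquired) spacer; the trailer end holds the
oldest spacers.  Labels are opaque strings that identify spacer clusters.
"""

from __future__ import annotations

from dataclasses import dataclass, field


class ValidationError(ValueError):
    """Raised when a record violates a structural invariant."""


_FORBIDDEN = set("\t, \n\r")


def _check_token(token: str) -> str:
    if not token or any(ch in _FORBIDDEN for ch in token):
        raise ValidationError(f"invalid spacer label {token!r}")
    return token


@dataclass(frozen=True)
class SpacerArrayRecord:
    """One CRISPR array: ordered spacer labels, leader-proximal first."""

    group_id: str
    array_id: str
    spacers: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.spacers) == 0:
            raise ValidationError(f"array {self.array_id!r}: empty spacer list")
        for tok in self.spacers:
            _check_token(tok)
        object.__setattr__(self, "spacers", tuple(self.spacers))

    def reversed(self) -> "SpacerArrayRecord":
        return SpacerArrayRecord(self.group_id, self.array_id, self.spacers[::-1])


@dataclass
class SpacerGroup:
    """A set of arrays sharing spacer labels, analysed jointly."""

    group_id: str
    arrays: list[SpacerArrayRecord]

    def __post_init__(self) -> None:
        ids = [a.array_id for a in self.arrays]
        if len(set(ids)) != len(ids):
            raise ValidationError(f"group {self.group_id!r}: duplicate array ids")

    @property
    def array_ids(self) -> list[str]:
        return [a.array_id for a in self.arrays]

    @property
    def label_universe(self) -> set[str]:
        out: set[str] = set()
        for a in self.arrays:
            out.update(a.spacers)
        return out

    def reversed(self) -> "SpacerGroup":
        return SpacerGroup(self.group_id, [a.reversed() for a in self.arrays])


EVENT_TYPES = (
    "acquisition",
    "deletion",
    "duplication",
    "rearrangement",
    "reacquisition",
    "independent_acquisition",
    "other",
)


@dataclass(frozen=True)
class EventRecord:
    """A reconstructed evolutionary event on one branch.

    ``branch_id`` names the child node of the branch.  ``alignment_columns``
    are 1-based alignment column indices, strictly increasing.  Deletion
    records list every spacer removed by one (block) deletion.
    """

    branch_id: str
    event_type: str
    spacer_labels: tuple[str, ...]
    alignment_columns: tuple[int, ...]

    def __post_init__(self) -> None:
        if self.event_type not in EVENT_TYPES:
            raise ValidationError(f"unknown event type {self.event_type!r}")
        if self.event_type == "deletion" and len(self.spacer_labels) < 1:
            raise ValidationError("deletion event with no spacers")
        cols = self.alignment_columns
        if any(c2 <= c1 for c1, c2 in zip(cols, cols[1:])):
            raise ValidationError("alignment columns must be strictly increasing")
        if any(c < 1 for c in cols):
            raise ValidationError("alignment columns are 1-based")


@dataclass
class ReconstructionResult:
    """Presence/absence profiles at every node plus per-branch events.

    ``profile`` maps node name -> boolean presence over alignment columns
    (in column order).  ``ancestral_arrays`` gives, per node, the ordered
    spacer labels implied by the profile.  ``events`` lists acquisition,
    deletion and complex events keyed by the child node of each branch.
    """

    node_names: list[str]
    column_labels: list[str]
    profile: dict[str, "tuple[bool, ...]"]
    events: list[EventRecord] = field(default_factory=list)

    @property
    def ancestral_arrays(self) -> dict[str, tuple[str, ...]]:
        return {
            n: tuple(
                lab for lab, p in zip(self.column_labels, self.profile[n]) if p
            )
            for n in self.node_names
        }

    def events_of_type(self, event_type: str) -> list[EventRecord]:
        return [e for e in self.events if e.event_type == event_type]

    def n_deletion_events(self) -> int:
        return len(self.events_of_type("deletion"))
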