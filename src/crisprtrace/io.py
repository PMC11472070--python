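"""Readers and writers for every external representation of the pipeline.

All formats are plain text: a 3-column array table (group, array,
comma-separated spacer labels, leader-proximal first), newick trees with
mandatory branch lengths, spacer FASTA for clustering, tab-separated
event/ancestral-array/profile tables, DOT for the insertion-order graph,
and a JSON run summary.  Readers reject malformed input rather than
repairing it; every writer/reader pair round-trips valid data exactly.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio import SeqIO

from .arrays import (
    EventRecord,
    ReconstructionResult,
    SpacerArrayRecord,
    SpacerGroup,
    ValidationError,
)
from .msaa import MSAA
from .phylo import Phylogeny
from .psio import PSIO


class ParseError(ValueError):
    pass


# ----------------------------------------------------------------------
# Array tables
# ----------------------------------------------------------------------

def read_array_table(path: str | Path) -> list[SpacerGroup]:
    """Read a 3-column TSV: group_id, array_id, comma-separated labels.

    Records keep file order; a duplicated array id within a group is an
    error, as is any malformed line (reported with its line number).
    """
    groups: dict[str, list[SpacerArrayRecord]] = {}
    order: list[str] = []
    with open(path, "rt") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise ParseError(
                    f"{path}:{lineno}: expected 3 tab-separated fields, "
                    f"got {len(parts)}"
                )
            gid, aid, spacer_field = parts
            if not spacer_field.strip():
                raise ParseError(f"{path}:{lineno}: empty spacer list")
            spacers = tuple(s for s in spacer_field.split(","))
            try:
                rec = SpacerArrayRecord(gid, aid, spacers)
            except ValidationError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
            if gid not in groups:
                order.append(gid)
                groups[gid] = []
            if any(r.array_id == aid for r in groups[gid]):
                raise ParseError(
                    f"{path}:{lineno}: duplicate array id {aid!r} in group "
                    f"{gid!r}"
                )
            groups[gid].append(rec)
    return [SpacerGroup(gid, groups[gid]) for gid in order]


def write_array_table(groups: Iterable[SpacerGroup], path: str | Path) -> None:
    with open(path, "wt") as fh:
        for g in groups:
            for a in g.arrays:
                fh.write(f"{g.group_id}\t{a.array_id}\t{','.join(a.spacers)}\n")


# ----------------------------------------------------------------------
# Trees
# ----------------------------------------------------------------------

def read_newick(path: str | Path) -> Phylogeny:
    """Rooted newick with branch lengths; unnamed internal nodes are named
    N0, N1, ... in preorder."""
    text = Path(path).read_text()
    return Phylogeny.from_newick(text)


def write_newick(tree: Phylogeny, path: str | Path) -> None:
    Path(path).write_text(tree.to_newick())


# ----------------------------------------------------------------------
# Spacer FASTA
# ----------------------------------------------------------------------

def read_spacer_fasta(path: str | Path) -> dict[str, str]:
    """Spacer DNA sequences keyed by FASTA header (spacer id)."""
    out: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in out:
            raise ParseError(f"duplicate spacer id {rec.id!r} in {path}")
        out[rec.id] = str(rec.seq).upper()
    if not out:
        raise ParseError(f"no sequences in {path}")
    return out


def write_label_map(seq_to_label: Mapping[str, str], path: str | Path) -> None:
    with open(path, "wt") as fh:
        fh.write("sequence\tlabel\n")
        for seq in sorted(seq_to_label):
            fh.write(f"{seq}\t{seq_to_label[seq]}\n")


# ----------------------------------------------------------------------
# MSAA
# ----------------------------------------------------------------------

def write_msaa(msaa: MSAA, path: str | Path) -> None:
    """Rows = arrays, columns = alignment columns, '-' marks a gap."""
    with open(path, "wt") as fh:
        fh.write("array_id\t" + "\t".join(msaa.column_labels) + "\n")
        for i, aid in enumerate(msaa.array_ids):
            cells = [
                lab if p else "-"
                for lab, p in zip(msaa.column_labels, msaa.presence[i])
            ]
            fh.write(aid + "\t" + "\t".join(cells) + "\n")


# ----------------------------------------------------------------------
# PSIO as DOT
# ----------------------------------------------------------------------

def export_psio_dot(psio: PSIO) -> str:
    """Deterministic DOT text; one edge per reduced 'acquired after' pair."""
    lines = ["digraph PSIO {"]
    for node in sorted(psio.graph.nodes):
        lines.append(f'  "{node}";')
    for young, old in sorted(psio.graph.edges):
        lines.append(f'  "{young}" -> "{old}";')
    lines.append("}")
    return "\n".join(lines) + "\n"


def write_psio_dot(psio: PSIO, path: str | Path) -> None:
    Path(path).write_text(export_psio_dot(psio))


# ----------------------------------------------------------------------
# Results
# ----------------------------------------------------------------------

_EVENT_HEADER = "branch_id\tevent_type\tspacer_labels\talignment_columns\n"


def write_events_tsv(events: Sequence[EventRecord], path: str | Path) -> None:
    with open(path, "wt") as fh:
        fh.write(_EVENT_HEADER)
        for ev in events:
            fh.write(
                f"{ev.branch_id}\t{ev.event_type}\t"
                f"{','.join(ev.spacer_labels)}\t"
                f"{','.join(str(c) for c in ev.alignment_columns)}\n"
            )


def read_events_tsv(path: str | Path) -> list[EventRecord]:
    out: list[EventRecord] = []
    with open(path, "rt") as fh:
        header = fh.readline()
        if header != _EVENT_HEADER:
            raise ParseError(f"{path}: unexpected events header")
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 4:
                raise ParseError(f"{path}:{lineno}: expected 4 fields")
            branch, etype, labels, cols = parts
            out.append(EventRecord(
                branch, etype,
                tuple(labels.split(",")) if labels else (),
                tuple(int(c) for c in cols.split(",")) if cols else (),
            ))
    return out


def write_ancestral_arrays_tsv(
    recon: ReconstructionResult, path: str | Path
) -> None:
    with open(path, "wt") as fh:
        fh.write("node\tspacers\n")
        for node in recon.node_names:
            arr = recon.ancestral_arrays[node]
            fh.write(f"{node}\t{','.join(arr)}\n")


def write_summary_json(summary: Mapping, path: str | Path) -> None:
    Path(path).write_text(json.dumps(summary, indent=2, sort_keys=True) + "\n")


def read_summary_json(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())


def write_results(
    analysis: "object",
    out_dir: str | Path,
    prefix: str = "group",
) -> dict[str, Path]:
    """Write events TSV, ancestral arrays TSV and the JSON summary.

    Every reconstructed event appears exactly once in the events TSV; the
    JSON carries the parameter estimates, LRT and orientation decision.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rec = analysis.reconstruction
    paths = {
        "events": out / f"{prefix}.events.tsv",
        "ancestral": out / f"{prefix}.ancestral.tsv",
        "summary": out / f"{prefix}.summary.json",
        "psio": out / f"{prefix}.psio.dot",
        "msaa": out / f"{prefix}.msaa.tsv",
    }
    write_events_tsv(rec.refined.events, paths["events"])
    write_ancestral_arrays_tsv(rec.refined, paths["ancestral"])
    write_summary_json(analysis.summary(), paths["summary"])
    write_psio_dot(rec.psio, paths["psio"])
    write_msaa(rec.msaa, paths["msaa"])
    return paths
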