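"""Fusion breakpoint localization and junction-probe construction.

The breakpoint of a composite gene is the coordinate on its nucleotide
sequence where parent-A-derived sequence ends and parent-B-derived sequence
begins.  It is inferred from the local-alignment intervals of the two
parents on the composite; because alignments fray at the junction the two
intervals may abut, leave a gap, or overlap slightly — the midpoint rule
resolves the latter two cases deterministically.

Probes centered on the breakpoint (50-nt flanks for RNA-seq reads, 8-nt
flanks for ~16-nt ribosome footprints) are the query sequences used for
junction-spanning read counting.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

from .similarity_graph import ScoringScheme, local_align

__all__ = [
    "Breakpoint",
    "JunctionProbe",
    "AmbiguousBreakpointError",
    "align_parent_to_composite",
    "infer_breakpoint",
    "make_junction_probe",
    "write_probe_fasta",
    "read_probe_fasta",
]


class AmbiguousBreakpointError(ValueError):
    """Raised when one parent interval is contained in the other."""


@dataclass(frozen=True)
class Breakpoint:
    """Inferred junction on a composite nucleotide sequence.

    The junction lies between ``position - 1`` and ``position`` (0-based).
    ``mode`` records how the parent intervals met: "abutting", "gap"
    (midpoint of the uncovered stretch) or "overlap" (midpoint of the
    doubly-covered stretch).
    """

    composite_id: str
    position: int
    parent_a_id: str
    parent_b_id: str
    interval_a: tuple[int, int]
    interval_b: tuple[int, int]
    mode: str

    def __post_init__(self) -> None:
        if self.mode not in ("abutting", "gap", "overlap"):
            raise ValueError(f"unknown breakpoint mode {self.mode!r}")


@dataclass(frozen=True)
class JunctionProbe:
    """Breakpoint-spanning probe sequence.

    ``breakpoint_offset`` is the junction position within the probe;
    ``truncated`` is set when the composite is too short on either side to
    provide the full flank.
    """

    composite_id: str
    sequence: str
    breakpoint_offset: int
    flank: int
    truncated: bool

    def __post_init__(self) -> None:
        if len(self.sequence) > 2 * self.flank:
            raise ValueError("probe longer than 2*flank")
        if self.breakpoint_offset > self.flank:
            raise ValueError("breakpoint offset exceeds flank")


def align_parent_to_composite(
    composite_nt: str,
    parent_nt: str,
    scoring: str | ScoringScheme = "nucleotide",
    min_score: int | None = None,
) -> tuple[int, int] | None:
    """Best local-alignment interval of a parent on the composite sequence,
    or None when no alignment reaches the minimum score."""
    hit = local_align(
        composite_nt, parent_nt, scoring,
        query_id="composite", subject_id="parent", min_score=min_score,
    )
    if hit is None:
        return None
    return hit.query_interval


def infer_breakpoint(
    interval_a: tuple[int, int],
    interval_b: tuple[int, int],
    composite_id: str = "composite",
    parent_a_id: str = "parentA",
    parent_b_id: str = "parentB",
) -> Breakpoint:
    """Infer the junction position from the two parent-match intervals.

    The upstream interval (smaller start) is treated as parent A.  Abutting
    intervals put the junction at the shared boundary; gapped or overlapping
    intervals use the floor-midpoint of the gap/overlap stretch, which is
    unbiased and symmetric under exchanging the parents.
    """
    if (interval_a[0] <= interval_b[0] and interval_a[1] >= interval_b[1]) or (
        interval_b[0] <= interval_a[0] and interval_b[1] >= interval_a[1]
    ):
        raise AmbiguousBreakpointError(
            f"{composite_id}: one parent interval contains the other "
            f"({interval_a} vs {interval_b})"
        )
    if interval_b[0] < interval_a[0]:
        interval_a, interval_b = interval_b, interval_a
        parent_a_id, parent_b_id = parent_b_id, parent_a_id
    end_a, start_b = interval_a[1], interval_b[0]
    if end_a == start_b:
        position, mode = end_a, "abutting"
    elif end_a < start_b:
        position, mode = (end_a + start_b) // 2, "gap"
    else:
        position, mode = (start_b + end_a) // 2, "overlap"
    return Breakpoint(
        composite_id, position, parent_a_id, parent_b_id,
        interval_a, interval_b, mode,
    )


def make_junction_probe(
    composite_nt: str, breakpoint: Breakpoint, flank: int
) -> JunctionProbe:
    """Extract the probe spanning ``flank`` nt on each side of the junction.

    The probe is clipped at the sequence boundaries (flagged ``truncated``);
    a breakpoint on the boundary itself would give a one-sided probe and is
    rejected.
    """
    p = breakpoint.position
    n = len(composite_nt)
    if not (0 < p < n):
        raise ValueError(
            f"{breakpoint.composite_id}: breakpoint {p} at/outside sequence "
            f"boundary (length {n})"
        )
    if flank < 1:
        raise ValueError("flank must be >= 1")
    start = max(0, p - flank)
    end = min(n, p + flank)
    return JunctionProbe(
        composite_id=breakpoint.composite_id,
        sequence=composite_nt[start:end],
        breakpoint_offset=p - start,
        flank=flank,
        truncated=(p - start < flank) or (end - p < flank),
    )


def write_probe_fasta(probes: Iterable[JunctionProbe], path: str | Path) -> None:
    """Probe FASTA; the header carries the junction offset and flank
    (``>fusion7|bp=50|flank=50``, bp being the offset within the probe)."""
    with open(path, "w") as fh:
        for p in probes:
            fh.write(f">{p.composite_id}|bp={p.breakpoint_offset}|flank={p.flank}\n")
            fh.write(p.sequence + "\n")


def read_probe_fasta(path: str | Path) -> list[JunctionProbe]:
    probes: list[JunctionProbe] = []
    header: str | None = None
    chunks: list[str] = []

    def _flush() -> None:
        if header is None:
            return
        fields = header.split("|")
        meta = dict(f.split("=", 1) for f in fields[1:] if "=" in f)
        seq = "".join(chunks)
        offset = int(meta["bp"])
        flank = int(meta["flank"])
        probes.append(
            JunctionProbe(
                fields[0], seq, offset, flank,
                truncated=len(seq) < 2 * flank,
            )
        )

    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line.startswith(">"):
                _flush()
                header = line[1:]
                chunks = []
            elif line:
                chunks.append(line)
    _flush()
    return probes
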