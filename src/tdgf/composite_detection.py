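"""Composite (fused) gene detection in a sequence similarity network.

A fused gene c shows up in an SSN as the middle of a *non-transitive
triplet* a-c-b: both parent relatives a and b align to c, in different
regions of c, while a and b themselves share no edge.  Genuinely fused
nodes additionally behave as *clique separators*: removing them splits
their component, separating the parent families.  Candidates whose
"parents" are in fact distant homologs of one another (one ancestral
family, not two) are filtered using the unthresholded hit list.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx

from .similarity_graph import SSN, SimilarityHit

__all__ = [
    "Triplet",
    "CompositeCandidate",
    "find_nontransitive_triplets",
    "verify_clique_separator",
    "aggregate_composites",
    "filter_distant_homology",
    "write_candidates",
]


def _overlap_fraction(iv_a: tuple[int, int], iv_b: tuple[int, int]) -> float:
    """Overlap length divided by the length of the shorter interval."""
    ov = min(iv_a[1], iv_b[1]) - max(iv_a[0], iv_b[0])
    if ov <= 0:
        return 0.0
    return ov / min(iv_a[1] - iv_a[0], iv_b[1] - iv_b[0])


@dataclass(frozen=True)
class Triplet:
    """Non-transitive triplet a-c-b with the two parent-hit intervals on c."""

    parent_a: str
    composite_c: str
    parent_b: str
    interval_a_on_c: tuple[int, int]
    interval_b_on_c: tuple[int, int]
    overlap_fraction: float

    def __post_init__(self) -> None:
        if self.parent_a >= self.parent_b:
            raise ValueError("triplet parents must be canonically ordered (a < b)")
        if not (0.0 <= self.overlap_fraction <= 1.0):
            raise ValueError("overlap fraction out of [0, 1]")


@dataclass
class CompositeCandidate:
    """A detected composite gene with its parent families.

    ``parent_families`` are disjoint node sets ordered along the composite by
    their merged hit interval; ``separator_verified`` records whether the
    composite passes the clique-separator check.  Filtered candidates carry a
    ``filtered_reason`` label.
    """

    composite_id: str
    parent_families: list[frozenset[str]]
    family_intervals: list[tuple[int, int]]
    si_threshold: float
    separator_verified: bool
    filtered_reason: str | None = None

    def __post_init__(self) -> None:
        if len(self.parent_families) < 2:
            raise ValueError("composite needs >= 2 parent families")
        seen: set[str] = set()
        for fam in self.parent_families:
            if not fam:
                raise ValueError("empty parent family")
            if seen & fam:
                raise ValueError("parent families must be disjoint")
            seen |= fam
        starts = [iv[0] for iv in self.family_intervals]
        if starts != sorted(starts):
            raise ValueError("family intervals must be ordered along the composite")


def find_nontransitive_triplets(
    ssn: SSN, max_overlap_fraction: float = 0.2
) -> list[Triplet]:
    """Enumerate non-transitive triplets of the SSN.

    For every node c and unordered pair of its neighbors (a, b) with no a-b
    edge, a triplet is reported when the two parent-hit intervals on c
    overlap by at most ``max_overlap_fraction`` of the shorter interval
    (small overlap is tolerated because local alignments fray at the
    junction).
    """
    g = ssn.graph
    out: list[Triplet] = []
    for c in sorted(g.nodes):
        neighbors = sorted(g.neighbors(c))
        for a, b in combinations(neighbors, 2):
            if g.has_edge(a, b):
                continue
            iv_a = ssn.interval_on(c, a)
            iv_b = ssn.interval_on(c, b)
            frac = _overlap_fraction(iv_a, iv_b)
            if frac <= max_overlap_fraction:
                out.append(Triplet(a, c, b, iv_a, iv_b, frac))
    return out


def verify_clique_separator(ssn: SSN, node_set: Iterable[str]) -> bool:
    """Check whether ``node_set`` is a clique separator of its component.

    True iff the set induces a clique and, within the connected component
    containing it, removing the set leaves at least two components that each
    contain a former neighbor of the set.
    """
    nodes = set(node_set)
    if not nodes:
        raise ValueError("node set must be non-empty")
    g = ssn.graph
    unknown = nodes - set(g.nodes)
    if unknown:
        raise KeyError(f"nodes not in SSN: {sorted(unknown)}")
    for u, v in combinations(sorted(nodes), 2):
        if not g.has_edge(u, v):
            return False
    # component containing the set (a separator must sit inside one component)
    comp = None
    for component in nx.connected_components(g):
        if nodes <= component:
            comp = component
            break
    if comp is None:
        return False
    neighbors = {n for v in nodes for n in g.neighbors(v)} - nodes
    sub = g.subgraph(comp - nodes)
    n_with_neighbor = sum(
        1 for component in nx.connected_components(sub) if component & neighbors
    )
    return n_with_neighbor >= 2


def aggregate_composites(ssn: SSN, triplets: Sequence[Triplet]) -> list[CompositeCandidate]:
    """Aggregate triplets into one candidate per composite node.

    The parent families of a composite c are the connected components of the
    subgraph induced on c's neighbors with c removed; each family's interval
    is the merged span of its members' hit intervals on c.  Middles whose
    neighbors all collapse into a single family (parents connected through
    other neighbors) are not composites and are dropped.
    """
    g = ssn.graph
    middles = sorted({t.composite_c for t in triplets})
    out: list[CompositeCandidate] = []
    for c in middles:
        neighbors = set(g.neighbors(c))
        sub = g.subgraph(neighbors)  # c is not its own neighbor
        families = [frozenset(comp) for comp in nx.connected_components(sub)]
        if len(families) < 2:
            continue
        spans = []
        for fam in families:
            ivs = [ssn.interval_on(c, m) for m in fam]
            spans.append((min(s for s, _ in ivs), max(e for _, e in ivs)))
        order = sorted(range(len(families)), key=lambda i: (spans[i], sorted(families[i])))
        out.append(
            CompositeCandidate(
                composite_id=c,
                parent_families=[families[i] for i in order],
                family_intervals=[spans[i] for i in order],
                si_threshold=ssn.si_threshold,
                separator_verified=verify_clique_separator(ssn, {c}),
            )
        )
    return out


def filter_distant_homology(
    candidates: Sequence[CompositeCandidate],
    unthresholded_hits: Iterable[SimilarityHit],
    floor_identity: float = 30.0,
    evalue_max: float = 1e-5,
    max_family_overlap: float = 0.2,
) -> tuple[list[CompositeCandidate], list[CompositeCandidate]]:
    """Remove false-positive composites whose parents are distant homologs.

    A candidate is removed when (i) any cross-family gene pair shares a
    pre-threshold hit with identity >= ``floor_identity`` and e-value <=
    ``evalue_max`` (the parents belong to one ancestral family), or (ii) its
    family intervals on the composite overlap by more than
    ``max_family_overlap`` of the shorter interval (the "parents" match the
    same region).  Returns (kept, removed); removed candidates carry a
    ``filtered_reason``.
    """
    pair_hits: dict[tuple[str, str], tuple[float, float]] = {}
    for h in unthresholded_hits:
        if h.query_id == h.subject_id:
            continue
        key = tuple(sorted((h.query_id, h.subject_id)))
        prev = pair_hits.get(key)
        cur = (h.percent_identity, h.e_value)
        if prev is None or cur[0] > prev[0]:
            pair_hits[key] = cur

    kept: list[CompositeCandidate] = []
    removed: list[CompositeCandidate] = []
    for cand in candidates:
        reason = None
        fams = cand.parent_families
        for fam_i, fam_j in combinations(range(len(fams)), 2):
            for x in fams[fam_i]:
                for y in fams[fam_j]:
                    hit = pair_hits.get(tuple(sorted((x, y))))
                    if hit is not None and hit[0] >= floor_identity and hit[1] <= evalue_max:
                        reason = "parent_homology"
                        break
                if reason:
                    break
            if reason:
                break
        if reason is None:
            for iv_i, iv_j in combinations(cand.family_intervals, 2):
                if _overlap_fraction(iv_i, iv_j) > max_family_overlap:
                    reason = "interval_overlap"
                    break
        if reason is None:
            kept.append(cand)
        else:
            cand.filtered_reason = reason
            removed.append(cand)
    return kept, removed


def write_candidates(candidates: Iterable[CompositeCandidate], path: str | Path) -> None:
    """TSV export of candidates (one row per composite)."""
    with open(path, "w") as fh:
        fh.write(
            "composite_id\tsi_threshold\tseparator_verified\tfiltered_reason\t"
            "families\tfamily_intervals\n"
        )
        for c in candidates:
            fams = ";".join(",".join(sorted(f)) for f in c.parent_families)
            ivs = ";".join(f"{s}-{e}" for s, e in c.family_intervals)
            fh.write(
                f"{c.composite_id}\t{c.si_threshold:g}\t{c.separator_verified}\t"
                f"{c.filtered_reason or '.'}\t{fams}\t{ivs}\n"
            )
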