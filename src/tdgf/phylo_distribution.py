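"""Phylogenetic origin mapping of fusion genes.

Junction-read evidence per species is collapsed into a fusion x species
presence/absence matrix (species without read data are *missing*, not
absent), and each fusion's origin is placed at the most recent common
ancestor (MRCA) of the species in which it is observed — a single-gain,
Dollo-style assignment.  Per-branch totals summarize how many fusions arose
on each node of the species tree.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import dendropy
import pandas as pd

__all__ = [
    "SpeciesTree",
    "PresenceMatrix",
    "OriginAssignment",
    "parse_newick",
    "write_newick",
    "build_presence_matrix",
    "assign_origin",
    "per_branch_counts",
]

PRESENT, ABSENT, MISSING = "present", "absent", "missing"


class SpeciesTree:
    """Rooted species tree with uniquely labeled tips.

    Internal nodes are addressed by their label when present, otherwise by
    the canonical identifier ``tip1|tip2|...`` (sorted descendant tips),
    which is stable under tip reordering.
    """

    def __init__(self, tree: dendropy.Tree):
        tips = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
        if len(tips) != len(set(tips)):
            raise ValueError("duplicate tip labels in species tree")
        self.tree = tree
        self.tip_labels = sorted(tips)

    @staticmethod
    def node_id(node: dendropy.Node) -> str:
        if node.is_leaf():
            return node.taxon.label
        if node.label:
            return node.label
        tips = sorted(leaf.taxon.label for leaf in node.leaf_iter())
        return "|".join(tips)

    def node_ids(self) -> list[str]:
        return [self.node_id(n) for n in self.tree.preorder_node_iter()]

    def mrca(self, tip_labels: Sequence[str]) -> dendropy.Node:
        missing = set(tip_labels) - set(self.tip_labels)
        if missing:
            raise KeyError(f"species not in tree: {sorted(missing)}")
        if len(set(tip_labels)) == 1:
            label = next(iter(tip_labels))
            return self.tree.find_node_with_taxon_label(label)
        return self.tree.mrca(taxon_labels=list(set(tip_labels)))


def parse_newick(source: str | Path) -> SpeciesTree:
    """Parse a rooted Newick tree (path or literal string); polytomies are
    allowed, duplicate tip labels are rejected."""
    text = None
    if isinstance(source, Path) or (isinstance(source, str) and not source.lstrip().startswith("(")):
        text = Path(source).read_text()
    else:
        text = str(source)
    try:
        tree = dendropy.Tree.get(
            data=text, schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except dendropy.utility.error.DataParseError as exc:
        raise ValueError(f"malformed Newick tree: {exc}") from exc
    tree.is_rooted = True
    return SpeciesTree(tree)


def write_newick(tree: SpeciesTree, path: str | Path) -> None:
    Path(path).write_text(
        tree.tree.as_string(schema="newick", suppress_rooting=True)
    )


class PresenceMatrix:
    """Fusion x species matrix with cells present / absent / missing."""

    def __init__(self, frame: pd.DataFrame):
        bad = frame.apply(lambda row: (row == MISSING).all(), axis=1)
        if bad.any():
            raise ValueError(
                f"rows with no non-missing cell: {list(frame.index[bad])}"
            )
        self.frame = frame

    @property
    def fusion_ids(self) -> list[str]:
        return list(self.frame.index)

    @property
    def species(self) -> list[str]:
        return list(self.frame.columns)

    def present_species(self, fusion_id: str) -> list[str]:
        row = self.frame.loc[fusion_id]
        return sorted(row.index[row == PRESENT])

    def to_tsv(self, path: str | Path) -> None:
        coded = self.frame.replace({PRESENT: "P", ABSENT: "A", MISSING: "M"})
        coded.to_csv(path, sep="\t", index_label="fusion_id")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "PresenceMatrix":
        frame = pd.read_csv(path, sep="\t", index_col="fusion_id")
        return cls(frame.replace({"P": PRESENT, "A": ABSENT, "M": MISSING}))


def build_presence_matrix(
    junction_counts: Iterable,
    tier: int = 1,
    all_species: Sequence[str] | None = None,
) -> PresenceMatrix:
    """Collapse per-species/tissue junction counts into presence calls.

    A fusion is *present* in a species when it is expressed at the requested
    tier in at least one tissue of that species; species with no read data
    for a fusion are *missing* and are ignored downstream.  Fusions present
    in no species carry no placement signal and are dropped with a warning.
    """
    cells: dict[str, dict[str, bool]] = {}
    species_seen: set[str] = set(all_species or [])
    for jc in junction_counts:
        species_seen.add(jc.species)
        row = cells.setdefault(jc.composite_id, {})
        expressed = jc.expressed_at.get(tier)
        if expressed is None:
            expressed = jc.count >= tier
        row[jc.species] = row.get(jc.species, False) or bool(expressed)
    columns = sorted(species_seen)
    rows = {}
    for fusion_id in sorted(cells):
        row = cells[fusion_id]
        if not any(row.values()):
            warnings.warn(
                f"fusion {fusion_id} is expressed in no species; dropped from matrix"
            )
            continue
        rows[fusion_id] = [
            (PRESENT if row[sp] else ABSENT) if sp in row else MISSING
            for sp in columns
        ]
    frame = pd.DataFrame.from_dict(rows, orient="index", columns=columns)
    return PresenceMatrix(frame)


@dataclass(frozen=True)
class OriginAssignment:
    """Single-gain origin of a fusion: the MRCA of all species where it is
    present (a single present species maps to that tip)."""

    fusion_id: str
    origin_node: str
    n_supporting_species: int


def assign_origin(tree: SpeciesTree, fusion_id: str, presence_row: Mapping[str, str]) -> OriginAssignment:
    """Place a fusion's origin at the MRCA of its present species.

    Missing species are ignored; present species must be tips of the tree.
    """
    present = sorted(sp for sp, state in presence_row.items() if state == PRESENT)
    if not present:
        raise ValueError(f"fusion {fusion_id}: no present species, cannot assign origin")
    node = tree.mrca(present)
    return OriginAssignment(fusion_id, SpeciesTree.node_id(node), len(present))


def assign_origins(tree: SpeciesTree, matrix: PresenceMatrix) -> list[OriginAssignment]:
    return [
        assign_origin(tree, fid, matrix.frame.loc[fid].to_dict())
        for fid in matrix.fusion_ids
    ]


def per_branch_counts(
    assignments: Sequence[OriginAssignment], tree: SpeciesTree
) -> dict[str, int]:
    """Number of fusions originating on each tree node (zeros included);
    totals are conserved: sum of counts == number of assignments."""
    counts = {nid: 0 for nid in tree.node_ids()}
    for a in assignments:
        if a.origin_node not in counts:
            raise KeyError(f"origin node {a.origin_node!r} not in tree")
        counts[a.origin_node] += 1
    return counts
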