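"""Sequence similarity network (SSN) construction.

An SSN is an undirected graph whose nodes are genes and whose edges record
pairwise local-alignment evidence above a percent-identity threshold.  Edges
are derived from best-reciprocal-hit (BRH) filtering of pairwise hits, the
standard criterion for drawing orthology-style links between gene sets.

Hits can be read from the 12-column tabular hit format (the BLAST
``-outfmt 6`` dialect) or computed internally with an affine-gap
Smith-Waterman aligner, so that the whole pipeline runs without any
external search tool.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Callable, Iterable

import networkx as nx
import numpy as np
import biotite.sequence as _bseq
import biotite.sequence.align as _balign

__all__ = [
    "SimilarityHit",
    "SSN",
    "ScoringScheme",
    "PROTEIN_SCORING",
    "NUCLEOTIDE_SCORING",
    "read_tabular_hits",
    "write_tabular_hits",
    "local_align",
    "best_reciprocal_edges",
    "build_ssn",
    "read_ssn",
    "write_ssn",
]


@dataclass(frozen=True)
class SimilarityHit:
    """One pairwise local-alignment hit.

    Coordinates are 0-based half-open on both sequences; reverse-oriented
    subject hits are normalized to forward coordinates with
    ``subject_orientation == "-"``.
    """

    query_id: str
    subject_id: str
    percent_identity: float  # 0..100, gap columns included in the denominator
    alignment_length: int  # alignment columns
    query_start: int
    query_end: int
    subject_start: int
    subject_end: int
    e_value: float
    bit_score: float
    subject_orientation: str = "+"

    @property
    def query_interval(self) -> tuple[int, int]:
        return (self.query_start, self.query_end)

    @property
    def subject_interval(self) -> tuple[int, int]:
        return (self.subject_start, self.subject_end)

    def __post_init__(self) -> None:
        if not (0.0 <= self.percent_identity <= 100.0):
            raise ValueError(f"percent identity out of range: {self.percent_identity}")
        if self.query_end <= self.query_start or self.subject_end <= self.subject_start:
            raise ValueError("interval end must exceed start")
        if self.e_value < 0:
            raise ValueError("e-value must be >= 0")


@dataclass(frozen=True)
class SSNEdge:
    """Undirected SSN edge with the hit interval on each endpoint."""

    node_a: str
    node_b: str
    percent_identity: float
    interval_a: tuple[int, int]
    interval_b: tuple[int, int]

    def __post_init__(self) -> None:
        if self.node_a >= self.node_b:
            raise ValueError("edge endpoints must be canonically ordered (node_a < node_b)")


class SSN:
    """Identity-thresholded sequence similarity network.

    Thin wrapper around an undirected :class:`networkx.Graph`; every edge
    carries ``identity`` and per-endpoint ``intervals`` attributes, every
    node may carry a ``species`` attribute.  Isolated nodes are legitimate
    members (genes without any retained similarity).
    """

    def __init__(self, si_threshold: float):
        if not (0.0 <= si_threshold <= 100.0):
            raise ValueError(f"SI threshold must be in [0, 100], got {si_threshold}")
        self.si_threshold = float(si_threshold)
        self.graph = nx.Graph()

    def add_node(self, node: str, species: str | None = None) -> None:
        self.graph.add_node(node, species=species)

    def add_edge(self, edge: SSNEdge) -> None:
        if edge.percent_identity < self.si_threshold:
            raise ValueError(
                f"edge identity {edge.percent_identity} below SSN threshold {self.si_threshold}"
            )
        self.graph.add_edge(
            edge.node_a,
            edge.node_b,
            identity=edge.percent_identity,
            intervals={edge.node_a: edge.interval_a, edge.node_b: edge.interval_b},
        )

    def nodes(self) -> list[str]:
        return sorted(self.graph.nodes)

    def edges(self) -> list[SSNEdge]:
        out = []
        for a, b, data in self.graph.edges(data=True):
            a, b = sorted((a, b))
            out.append(
                SSNEdge(a, b, data["identity"], data["intervals"][a], data["intervals"][b])
            )
        return sorted(out, key=lambda e: (e.node_a, e.node_b))

    def interval_on(self, node: str, other: str) -> tuple[int, int]:
        """Hit interval on `node` for the edge node-other."""
        return self.graph.edges[node, other]["intervals"][node]

    def __contains__(self, node: str) -> bool:
        return node in self.graph


# ---------------------------------------------------------------------------
# Tabular hit I/O
# ---------------------------------------------------------------------------

def read_tabular_hits(path: str | Path) -> list[SimilarityHit]:
    """Parse a 12-column tabular hit file (BLAST outfmt-6 dialect).

    Columns: query, subject, %identity, alignment length, mismatches,
    gap opens, qstart, qend, sstart, send, e-value, bit score, with 1-based
    inclusive coordinates.  Conversion to 0-based half-open is start-1 /
    end unchanged; subject hits with sstart > send are flipped to forward
    coordinates and flagged with orientation "-".
    """
    hits: list[SimilarityHit] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 12:
                raise ValueError(
                    f"{path}:{lineno}: expected 12 tab-separated fields, got {len(fields)}"
                )
            try:
                qid, sid = fields[0], fields[1]
                pident = float(fields[2])
                alen = int(fields[3])
                qstart, qend = int(fields[6]), int(fields[7])
                sstart, send = int(fields[8]), int(fields[9])
                evalue = float(fields[10])
                bits = float(fields[11])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-numeric field ({exc})") from exc
            orientation = "+"
            if sstart > send:
                sstart, send = send, sstart
                orientation = "-"
            try:
                hits.append(
                    SimilarityHit(
                        qid, sid, pident, alen,
                        qstart - 1, qend, sstart - 1, send,
                        evalue, bits, orientation,
                    )
                )
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from exc
    return hits


def write_tabular_hits(hits: Iterable[SimilarityHit], path: str | Path) -> None:
    """Write hits in the 12-column dialect (inverse of :func:`read_tabular_hits`)."""
    with open(path, "w") as fh:
        for h in hits:
            sstart, send = h.subject_start + 1, h.subject_end
            if h.subject_orientation == "-":
                sstart, send = send, sstart
            # mismatches / gap-open counts are not tracked internally
            fh.write(
                "\t".join(
                    [
                        h.query_id, h.subject_id,
                        f"{h.percent_identity:.2f}", str(h.alignment_length),
                        "0", "0",
                        str(h.query_start + 1), str(h.query_end),
                        str(sstart), str(send),
                        f"{h.e_value:.3g}", f"{h.bit_score:.1f}",
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# Built-in local aligner
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ScoringScheme:
    """Substitution matrix plus affine gap penalties and Karlin-Altschul
    parameters used to convert raw Smith-Waterman scores to bit scores and
    e-values (E = K * m * n * exp(-lambda * S))."""

    name: str
    kind: str  # "protein" | "nucleotide"
    gap_open: int
    gap_extend: int
    ka_lambda: float
    ka_k: float
    min_score: int


# Protein: BLOSUM62 with BLASTp-default gaps and its gapped
# Karlin-Altschul parameters.  Nucleotide: match 2 / mismatch -3 with stiff
# EMBOSS-style gaps (10, 4) — cheap gaps let local alignments wander past
# fusion junctions through chance matches, which blurs both the edge
# identity and the breakpoint interval; KA parameters are the blastn 2/-3
# values (adequate for the reciprocal-best e-value cutoff).
PROTEIN_SCORING = ScoringScheme("blosum62", "protein", 11, 1, 0.267, 0.041, 60)
NUCLEOTIDE_SCORING = ScoringScheme("nuc-2-3", "nucleotide", 10, 4, 0.625, 0.41, 50)

_NT_MATRIX = None
_PROT_MATRIX = None


def _matrix_for(scoring: ScoringScheme):
    global _NT_MATRIX, _PROT_MATRIX
    if scoring.kind == "protein":
        if _PROT_MATRIX is None:
            _PROT_MATRIX = _balign.SubstitutionMatrix.std_protein_matrix()
        return _PROT_MATRIX
    if _NT_MATRIX is None:
        alph = _bseq.NucleotideSequence.alphabet_unamb
        arr = np.full((4, 4), -3, dtype=np.int32)
        np.fill_diagonal(arr, 2)
        _NT_MATRIX = _balign.SubstitutionMatrix(alph, alph, arr)
    return _NT_MATRIX


def _as_biotite_seq(s: str, kind: str):
    if kind == "protein":
        return _bseq.ProteinSequence(s)
    return _bseq.NucleotideSequence(s.upper())


def _resolve_scoring(scoring: str | ScoringScheme) -> ScoringScheme:
    if isinstance(scoring, ScoringScheme):
        return scoring
    if scoring == "protein":
        return PROTEIN_SCORING
    if scoring == "nucleotide":
        return NUCLEOTIDE_SCORING
    raise ValueError(f"unknown scoring scheme: {scoring!r}")


def local_align(
    seq_a: str,
    seq_b: str,
    scoring: str | ScoringScheme = "protein",
    query_id: str = "query",
    subject_id: str = "subject",
    min_score: int | None = None,
) -> SimilarityHit | None:
    """Optimal affine-gap local (Smith-Waterman) alignment of two sequences.

    Identity is matches / alignment columns with gap columns counted in the
    denominator.  Returns ``None`` when the best score falls below
    ``min_score`` (default taken from the scoring scheme), which is how
    unrelated sequence pairs are dropped.
    """
    if not seq_a or not seq_b:
        raise ValueError("cannot align empty sequences")
    scheme = _resolve_scoring(scoring)
    if min_score is None:
        min_score = scheme.min_score
    matrix = _matrix_for(scheme)
    bs_a = _as_biotite_seq(seq_a, scheme.kind)
    bs_b = _as_biotite_seq(seq_b, scheme.kind)
    aln = _balign.align_optimal(
        bs_a, bs_b, matrix,
        gap_penalty=(-scheme.gap_open, -scheme.gap_extend),
        local=True, max_number=1,
    )[0]
    if aln.score < min_score or aln.score <= 0 or aln.trace.shape[0] == 0:
        return None
    n_cols = aln.trace.shape[0]
    identity = _balign.get_sequence_identity(aln, mode="all") * 100.0
    q_pos = aln.trace[:, 0][aln.trace[:, 0] != -1]
    s_pos = aln.trace[:, 1][aln.trace[:, 1] != -1]
    m, n = len(seq_a), len(seq_b)
    e_value = scheme.ka_k * m * n * math.exp(-scheme.ka_lambda * aln.score)
    bit_score = (scheme.ka_lambda * aln.score - math.log(scheme.ka_k)) / math.log(2)
    return SimilarityHit(
        query_id, subject_id,
        round(identity, 4), n_cols,
        int(q_pos.min()), int(q_pos.max()) + 1,
        int(s_pos.min()), int(s_pos.max()) + 1,
        e_value, round(bit_score, 2),
    )


def all_vs_all_hits(
    sequences: dict[str, str],
    scoring: str | ScoringScheme = "nucleotide",
    min_score: int | None = None,
) -> list[SimilarityHit]:
    """Align every unordered pair of sequences and emit hits in both
    directions (the aligner is symmetric, so the reverse hit is mirrored
    rather than recomputed)."""
    ids = sorted(sequences)
    hits: list[SimilarityHit] = []
    for i, qid in enumerate(ids):
        for sid in ids[i + 1:]:
            h = local_align(
                sequences[qid], sequences[sid], scoring,
                query_id=qid, subject_id=sid, min_score=min_score,
            )
            if h is None:
                continue
            hits.append(h)
            hits.append(
                replace(
                    h,
                    query_id=sid, subject_id=qid,
                    query_start=h.subject_start, query_end=h.subject_end,
                    subject_start=h.query_start, subject_end=h.query_end,
                )
            )
    return hits


# ---------------------------------------------------------------------------
# Best-reciprocal-hit edges and the SSN
# ---------------------------------------------------------------------------

def best_reciprocal_edges(
    hits: Iterable[SimilarityHit],
    evalue_max: float = 1e-5,
    species_of: Callable[[str], str] | dict[str, str] | None = None,
) -> list[SSNEdge]:
    """Best-reciprocal-hit filtering of a pairwise hit list.

    Self-hits and hits with e-value above ``evalue_max`` are discarded.  For
    each ordered pair the best hit is kept (highest bit score, then lowest
    e-value, then lexicographic subject id).  An undirected edge (a, b) is
    emitted iff b is a's best partner and a is b's best partner.

    When ``species_of`` is given, best partners are resolved per subject
    species (the usual comparative-genomics convention: one best hit per
    query per target gene set); without it a single global best partner per
    query is used.
    """
    if species_of is None:
        sp = lambda _g: ""
    elif callable(species_of):
        sp = species_of
    else:
        sp = lambda g: species_of.get(g, "")

    # best hit per ordered pair
    pair_best: dict[tuple[str, str], SimilarityHit] = {}
    for h in hits:
        if h.query_id == h.subject_id:
            continue
        if h.e_value > evalue_max:
            continue
        key = (h.query_id, h.subject_id)
        prev = pair_best.get(key)
        if prev is None or (h.bit_score, -h.e_value) > (prev.bit_score, -prev.e_value):
            pair_best[key] = h

    # best partner per (query, subject-species)
    best_partner: dict[tuple[str, str], str] = {}
    for (q, s), h in sorted(pair_best.items()):
        gkey = (q, sp(s))
        cur = best_partner.get(gkey)
        if cur is None:
            best_partner[gkey] = s
            continue
        ch = pair_best[(q, cur)]
        if (h.bit_score, -h.e_value, _neg_lex(s)) > (ch.bit_score, -ch.e_value, _neg_lex(cur)):
            best_partner[gkey] = s

    edges: list[SSNEdge] = []
    for (q, _grp), s in sorted(best_partner.items()):
        if q >= s:
            continue  # handle each unordered pair once, from its lower id
        if best_partner.get((s, sp(q))) != q:
            continue
        h = pair_best[(q, s)]
        edges.append(
            SSNEdge(q, s, h.percent_identity, h.query_interval, h.subject_interval)
        )
    return sorted(edges, key=lambda e: (e.node_a, e.node_b))


class _neg_lex(str):
    """Lexicographically *smaller* strings compare as larger (tie-break helper)."""

    def __lt__(self, other):  # pragma: no cover - trivial
        return str.__gt__(self, other)

    def __gt__(self, other):
        return str.__lt__(self, other)


def build_ssn(
    edges: Iterable[SSNEdge],
    si_threshold: float,
    nodes: Iterable[str] | None = None,
    species_of: Callable[[str], str] | dict[str, str] | None = None,
) -> SSN:
    """Threshold an edge list at `si_threshold` percent identity.

    Edges below the tier are dropped; all supplied node identifiers are kept
    (genes with no retained edge become isolated nodes).
    """
    ssn = SSN(si_threshold)
    if species_of is None:
        sp = lambda _g: None
    elif callable(species_of):
        sp = species_of
    else:
        sp = lambda g: species_of.get(g)
    if nodes is not None:
        for n in nodes:
            ssn.add_node(n, species=sp(n))
    for e in edges:
        for n in (e.node_a, e.node_b):
            if n not in ssn:
                ssn.add_node(n, species=sp(n))
        if e.percent_identity >= si_threshold:
            ssn.add_edge(e)
    return ssn


def write_ssn(ssn: SSN, path: str | Path) -> None:
    """TSV export: one `node` line per node, one `edge` line per edge."""
    with open(path, "w") as fh:
        fh.write(f"#si_threshold\t{ssn.si_threshold}\n")
        for n in ssn.nodes():
            species = ssn.graph.nodes[n].get("species") or ""
            fh.write(f"node\t{n}\t{species}\n")
        for e in ssn.edges():
            fh.write(
                "edge\t{}\t{}\t{:.4f}\t{}\t{}\t{}\t{}\n".format(
                    e.node_a, e.node_b, e.percent_identity,
                    e.interval_a[0], e.interval_a[1],
                    e.interval_b[0], e.interval_b[1],
                )
            )


def read_ssn(path: str | Path) -> SSN:
    si = 0.0
    nodes: list[tuple[str, str | None]] = []
    edges: list[SSNEdge] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if fields[0] == "#si_threshold":
                si = float(fields[1])
            elif fields[0] == "node":
                nodes.append((fields[1], fields[2] or None))
            elif fields[0] == "edge":
                edges.append(
                    SSNEdge(
                        fields[1], fields[2], float(fields[3]),
                        (int(fields[4]), int(fields[5])),
                        (int(fields[6]), int(fields[7])),
                    )
                )
            else:
                raise ValueError(f"{path}:{lineno}: unknown record type {fields[0]!r}")
    ssn = SSN(si)
    for n, species in nodes:
        ssn.add_node(n, species=species)
    for e in edges:
        ssn.add_edge(e)
    return ssn
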