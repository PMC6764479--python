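"""Synthetic fixture generation with planted ground truth.

Emulates the statistical structure the fusion-detection analysis assumes:
pairs of unrelated parent coding genes, readthrough fusion transcripts built
from a parent-A prefix and a parent-B suffix at a controlled percent
identity, 76-nt single-end reads with planted junction-spanning reads and
Phred+33 qualities, a genome with segmental-duplication (SD) intervals in
which fusion loci are placed at a configurable enrichment factor, and a
seven-species tree for origin mapping.

Every stage is driven by a single integer seed; an identical configuration
reproduces a byte-identical fixture bundle.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import yaml
from Bio.Seq import Seq

from .phylo_distribution import SpeciesTree, parse_newick, PresenceMatrix, PRESENT, ABSENT

__all__ = [
    "SimulationConfig",
    "TruthRecord",
    "GeneRecord",
    "FastqRead",
    "SyntheticBundle",
    "DEFAULT_TREE_NEWICK",
    "simulate_parents",
    "mutate_to_identity",
    "simulate_fusion",
    "place_genes",
    "simulate_reads",
    "generate_bundle",
    "make_fixture",
    "load_truth",
    "simulate_phylo_presence",
]

# great-ape panel plus outgroups, branch lengths in My
DEFAULT_TREE_NEWICK = (
    "((((((human:6,chimp:6):2,gorilla:8):8,orangutan:16):9,"
    "macaque:25):18,marmoset:43):47,mouse:90);"
)

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_STOPS = {"TAA", "TAG", "TGA"}
_CODONS = np.array(
    [a + b + c for a in "ACGT" for b in "ACGT" for c in "ACGT" if a + b + c not in _STOPS]
)

# overhang a planted junction read keeps on each side of the breakpoint:
# the counter requires 8 nt on both sides of the *inferred* junction, and
# inference is only guaranteed to within a few nt, so planting with 16 nt
# keeps every planted read countable for breakpoint errors up to +/-8 nt
PLANTED_OVERHANG = 16


@dataclass
class SimulationConfig:
    """Tunable study conditions for one synthetic bundle.

    Defaults model the analysis conditions: 30 unrelated parent pairs, 10
    readthrough fusions retaining half of each parent at 90% identity, 76-nt
    single-end reads over six tissues, 5 planted junction reads per fusion
    per tissue, and fusion loci placed in SD at 3x the background rate
    (SD covering 30% of the genome).
    """

    seed: int = 0
    n_parent_pairs: int = 30
    parent_len_range: tuple[int, int] = (300, 600)  # nt, multiples of 3
    target_identity: float = 0.90
    n_fusions: int = 10
    fusion_frac_a: float = 0.5
    fusion_frac_b: float = 0.5
    linker_len: int = 0
    read_length: int = 76
    read_depth: int = 20  # background reads per transcript per tissue
    junction_reads_per_fusion: int = 5  # per tissue
    base_error_rate: float = 0.0
    tissues: tuple[str, ...] = ("brain", "cerebellum", "heart", "kidney", "liver", "testis")
    species: str = "human"
    genome_length: int = 1_000_000
    n_sd_intervals: int = 30
    sd_interval_len: int = 10_000
    sd_enrichment: float = 3.0
    tree_newick: str = DEFAULT_TREE_NEWICK

    def __post_init__(self) -> None:
        lo, hi = self.parent_len_range
        if lo % 3 or hi % 3 or lo < 30 or hi < lo:
            raise ValueError("parent length range must be multiples of 3 with 30 <= lo <= hi")
        if not (0.0 < self.target_identity <= 1.0):
            raise ValueError("target identity must be in (0, 1]")
        if not (0.0 < self.fusion_frac_a < 1.0 and 0.0 < self.fusion_frac_b < 1.0):
            raise ValueError("fusion fractions must be in (0, 1)")
        if self.read_length < 2:
            raise ValueError("read length must be >= 2")
        if min(
            self.n_parent_pairs, self.n_fusions, self.read_depth,
            self.junction_reads_per_fusion, self.n_sd_intervals, self.linker_len,
        ) < 0:
            raise ValueError("counts must be >= 0")
        if self.n_fusions > self.n_parent_pairs:
            raise ValueError("cannot plant more fusions than parent pairs")
        if not (0.0 <= self.base_error_rate < 1.0):
            raise ValueError("base error rate must be in [0, 1)")
        if self.sd_enrichment < 0:
            raise ValueError("sd_enrichment must be >= 0")
        if self.n_sd_intervals * self.sd_interval_len >= self.genome_length:
            raise ValueError("total SD span must be smaller than the genome")

    def to_yaml(self) -> str:
        d = asdict(self)
        d["parent_len_range"] = list(self.parent_len_range)
        d["tissues"] = list(self.tissues)
        return yaml.safe_dump(d, sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "SimulationConfig":
        d = yaml.safe_load(text)
        d["parent_len_range"] = tuple(d["parent_len_range"])
        d["tissues"] = tuple(d["tissues"])
        return cls(**d)


@dataclass
class TruthRecord:
    """Planted ground truth for one fusion."""

    fusion_id: str
    parent_a_id: str
    parent_b_id: str
    true_breakpoint: int  # 0-based offset on the fusion nucleotide sequence
    in_sd: bool = False
    planted_junction_reads: int = 0  # per tissue


@dataclass(frozen=True)
class GeneRecord:
    gene_id: str
    species: str
    nt: str
    protein: str = ""


@dataclass(frozen=True)
class FastqRead:
    read_id: str
    sequence: str
    quality: str  # Phred+33


# ---------------------------------------------------------------------------
# Sequence simulation
# ---------------------------------------------------------------------------

def simulate_parents(
    n: int,
    len_range: tuple[int, int] | int,
    seed: int | np.random.Generator = 0,
    id_prefix: str = "G",
    species: str = "na",
) -> list[GeneRecord]:
    """Random coding nucleotide sequences (uniform over non-stop codons, so
    frame-0 translations contain no stop symbol) with their translations."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if isinstance(len_range, int):
        len_range = (len_range, len_range)
    lo, hi = len_range
    if lo % 3 or hi % 3:
        raise ValueError("sequence lengths must be multiples of 3")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    out: list[GeneRecord] = []
    for i in range(n):
        n_codons = int(rng.integers(lo // 3, hi // 3 + 1))
        nt = "".join(rng.choice(_CODONS, size=n_codons))
        out.append(
            GeneRecord(
                f"{id_prefix}{i + 1:04d}", species, nt, str(Seq(nt).translate())
            )
        )
    return out


def mutate_to_identity(
    seq: str, target_identity: float, seed: int | np.random.Generator = 0
) -> str:
    """Point-substitute a sequence down to a target identity.

    Exactly ``floor((1 - target) * len)`` distinct positions are substituted
    to a different base, so the realized identity equals the target up to
    rounding (within 1/len, never below target) — a sequence mutated "to
    90%" is guaranteed to pass a 90% identity threshold.
    """
    if not seq:
        raise ValueError("cannot mutate an empty sequence")
    if not (0.0 < target_identity <= 1.0):
        raise ValueError("target identity must be in (0, 1]")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    arr = np.frombuffer(seq.upper().encode(), dtype=np.uint8).copy()
    n_sub = math.floor((1.0 - target_identity) * len(seq))
    if n_sub == 0:
        return seq.upper()
    pos = rng.choice(len(seq), size=n_sub, replace=False)
    for p in pos:
        choices = _BASES[_BASES != arr[p]]
        arr[p] = rng.choice(choices)
    return arr.tobytes().decode()


def simulate_fusion(
    parent_a: GeneRecord | str,
    parent_b: GeneRecord | str,
    frac_a: float,
    frac_b: float,
    fusion_id: str = "FUS0001",
    linker: str = "",
    min_segment: int = 30,
) -> tuple[str, TruthRecord]:
    """Readthrough fusion: prefix of parent A joined to suffix of parent B.

    fusion = A[:floor(frac_a * |A|)] + linker + B[-floor(frac_b * |B|):];
    the true breakpoint is the end of the A-derived prefix (midpoint of the
    linker when one is inserted).  Retained segments shorter than
    ``min_segment`` nt are rejected — the breakpoint must be internal with
    alignable sequence on both sides.
    """
    seq_a = parent_a.nt if isinstance(parent_a, GeneRecord) else parent_a
    seq_b = parent_b.nt if isinstance(parent_b, GeneRecord) else parent_b
    if not (0.0 < frac_a < 1.0 and 0.0 < frac_b < 1.0):
        raise ValueError("fusion fractions must be strictly inside (0, 1)")
    len_a = math.floor(frac_a * len(seq_a))
    len_b = math.floor(frac_b * len(seq_b))
    if len_a < min_segment or len_b < min_segment:
        raise ValueError(
            f"retained segments too short ({len_a}, {len_b}); need >= {min_segment} nt"
        )
    fusion = seq_a[:len_a] + linker + seq_b[len(seq_b) - len_b:]
    bp = len_a + len(linker) // 2
    truth = TruthRecord(
        fusion_id=fusion_id,
        parent_a_id=parent_a.gene_id if isinstance(parent_a, GeneRecord) else "parentA",
        parent_b_id=parent_b.gene_id if isinstance(parent_b, GeneRecord) else "parentB",
        true_breakpoint=bp,
    )
    return fusion, truth


# ---------------------------------------------------------------------------
# Genome placement
# ---------------------------------------------------------------------------

def place_genes(
    gene_lengths: Mapping[str, int],
    truth: Sequence[TruthRecord],
    genome_length: int,
    n_sd: int,
    sd_len: int,
    sd_enrichment: float,
    seed: int | np.random.Generator = 0,
    chrom: str = "chr1",
    max_attempts: int = 10_000,
):
    """Place SD intervals and gene loci on a linear genome.

    SD intervals are non-overlapping blocks of ``sd_len``.  Each gene is
    assigned to SD with probability p_sd (the SD fraction of the genome);
    fusion genes (those named in ``truth``) use min(1, p_sd * sd_enrichment)
    instead, and their ``in_sd`` flag is recorded on the truth records.
    Genes are packed without mutual overlap; placement that cannot be
    satisfied raises.

    Returns ``(gene_intervals, sd_intervals)`` as lists of
    :class:`tdgf.sd_enrichment.GenomicInterval`.
    """
    from .sd_enrichment import GenomicInterval

    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if n_sd * sd_len >= genome_length:
        raise ValueError("total SD span must be smaller than the genome")

    # non-overlapping SD blocks via the gap-insertion trick: distribute the
    # free space between blocks uniformly
    free = genome_length - n_sd * sd_len
    cuts = np.sort(rng.integers(0, free + 1, size=n_sd))
    sd_starts = [int(c + i * sd_len) for i, c in enumerate(cuts)]
    sd_intervals = [
        GenomicInterval(chrom, s, s + sd_len, f"sd{i + 1:03d}", "sd")
        for i, s in enumerate(sd_starts)
    ]
    p_sd = (n_sd * sd_len) / genome_length
    fusion_ids = {t.fusion_id for t in truth}
    truth_by_id = {t.fusion_id: t for t in truth}

    import bisect

    placed: list[tuple[int, int]] = []  # kept sorted by start

    def overlaps_placed(start: int, end: int) -> bool:
        i = bisect.bisect_right(placed, (start, end))
        if i > 0 and placed[i - 1][1] > start:
            return True
        return i < len(placed) and placed[i][0] < end

    def overlaps_any(start: int, end: int, ivs: Iterable[tuple[int, int]]) -> bool:
        return any(start < e and end > s for s, e in ivs)

    sd_spans = [(s, s + sd_len) for s in sd_starts]
    gene_intervals: list[GenomicInterval] = []
    for gid in sorted(gene_lengths):
        glen = gene_lengths[gid]
        if glen > genome_length:
            raise ValueError(f"gene {gid} longer than genome")
        p = min(1.0, p_sd * sd_enrichment) if gid in fusion_ids else p_sd
        want_sd = bool(rng.random() < p)
        if want_sd and glen > sd_len:
            raise ValueError(f"gene {gid} ({glen} nt) does not fit in an SD interval")
        start = None
        for _ in range(max_attempts):
            if want_sd:
                block = sd_spans[int(rng.integers(0, n_sd))]
                cand = int(rng.integers(block[0], block[1] - glen + 1))
                inside = True
            else:
                cand = int(rng.integers(0, genome_length - glen + 1))
                inside = False
                if overlaps_any(cand, cand + glen, sd_spans):
                    continue
            if overlaps_placed(cand, cand + glen):
                continue
            start = cand
            break
        if start is None:
            raise RuntimeError(
                f"could not place gene {gid} after {max_attempts} attempts; "
                "genome too crowded"
            )
        bisect.insort(placed, (start, start + glen))
        gene_intervals.append(GenomicInterval(chrom, start, start + glen, gid, "gene"))
        if gid in fusion_ids:
            truth_by_id[gid].in_sd = want_sd
    return gene_intervals, sd_intervals


# ---------------------------------------------------------------------------
# Read simulation
# ---------------------------------------------------------------------------

def _phred_char(error_rate: float) -> str:
    q = 40 if error_rate <= 0 else min(40, round(-10.0 * math.log10(error_rate)))
    return chr(int(q) + 33)


def _apply_errors(seq: str, error_rate: float, rng: np.random.Generator) -> str:
    if error_rate <= 0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    hits = np.nonzero(rng.random(len(arr)) < error_rate)[0]
    for p in hits:
        choices = _BASES[_BASES != arr[p]]
        arr[p] = rng.choice(choices)
    return arr.tobytes().decode()


def simulate_reads(
    transcripts: Mapping[str, str],
    truth: Sequence[TruthRecord],
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> list[FastqRead]:
    """Single-end reads over all transcripts with planted junction reads.

    Background reads start uniformly along each transcript, except that on
    fusion transcripts reads crossing the junction are excluded entirely —
    junction-overlapping coverage comes exclusively from the planted reads,
    so planted counts are exactly recoverable at zero error rate even when
    the analysis localizes the breakpoint a few nt off the truth.  Planted
    reads keep at least ``min(16, read_length // 2)`` nt on each side of
    the junction (comfortably above the counter's 8-nt overhang rule).
    Per-base substitution errors occur at ``base_error_rate``; qualities
    are constant per read at Q = -10 log10(error rate) (Q40 cap), Phred+33.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    rl = config.read_length
    shortest = min(len(s) for s in transcripts.values()) if transcripts else 0
    if transcripts and rl > shortest:
        raise ValueError(
            f"read length {rl} exceeds shortest transcript ({shortest} nt)"
        )
    truth_by_id = {t.fusion_id: t for t in truth}
    qchar = _phred_char(config.base_error_rate)
    reads: list[FastqRead] = []
    counter = 0

    def emit(tid: str, tissue: str, start: int, seq: str, planted: bool) -> None:
        nonlocal counter
        counter += 1
        read_seq = _apply_errors(seq, config.base_error_rate, rng)
        tag = "|planted=1" if planted else ""
        reads.append(
            FastqRead(
                f"r{counter:06d}|src={tid}|tissue={tissue}|species={config.species}|pos={start}{tag}",
                read_seq,
                qchar * len(read_seq),
            )
        )

    for tissue in config.tissues:
        for tid in sorted(transcripts):
            seq = transcripts[tid]
            n_starts = len(seq) - rl + 1
            t = truth_by_id.get(tid)
            if t is None:
                allowed = np.arange(n_starts)
            else:
                # background reads must not cross the junction at all
                cross_lo = max(0, t.true_breakpoint - rl + 1)
                cross_hi = min(n_starts - 1, t.true_breakpoint - 1)
                mask = np.ones(n_starts, dtype=bool)
                if cross_lo <= cross_hi:
                    mask[cross_lo:cross_hi + 1] = False
                allowed = np.nonzero(mask)[0]
            for _ in range(config.read_depth):
                if len(allowed) == 0:
                    break
                start = int(allowed[rng.integers(0, len(allowed))])
                emit(tid, tissue, start, seq[start:start + rl], planted=False)
            if t is not None:
                ov = min(PLANTED_OVERHANG, rl // 2)
                span_lo = max(0, t.true_breakpoint + ov - rl)
                span_hi = min(n_starts - 1, t.true_breakpoint - ov)
                if span_lo > span_hi:
                    raise ValueError(
                        f"cannot plant spanning reads for {tid}: breakpoint too "
                        "close to the transcript end"
                    )
                for _ in range(t.planted_junction_reads):
                    start = int(rng.integers(span_lo, span_hi + 1))
                    emit(tid, tissue, start, seq[start:start + rl], planted=True)
    return reads


# ---------------------------------------------------------------------------
# Bundle assembly and fixture I/O
# ---------------------------------------------------------------------------

@dataclass
class SyntheticBundle:
    """In-memory fixture: sequences, truth, loci, reads and tree."""

    config: SimulationConfig
    parents: dict[str, GeneRecord]
    fusions: dict[str, GeneRecord]
    truth: list[TruthRecord]
    gene_intervals: list
    sd_intervals: list
    reads: list[FastqRead]
    tree_newick: str

    @property
    def species_of(self) -> dict[str, str]:
        out = {gid: rec.species for gid, rec in self.parents.items()}
        out.update({gid: rec.species for gid, rec in self.fusions.items()})
        return out

    @property
    def transcripts(self) -> dict[str, str]:
        out = {gid: rec.nt for gid, rec in self.parents.items()}
        out.update({gid: rec.nt for gid, rec in self.fusions.items()})
        return out


def generate_bundle(config: SimulationConfig) -> SyntheticBundle:
    """Generate a complete synthetic bundle from a configuration.

    Parent-A genes are tagged with one species, parent-B genes with another
    and the fusions with the focal species, so that best-reciprocal-hit
    resolution per gene set links each fusion to both of its parents (as
    cross-species orthology searches do) while unrelated genes stay
    unconnected.
    """
    master = np.random.default_rng(config.seed)
    seeds = master.integers(0, 2**31 - 1, size=5)

    parents_a = simulate_parents(
        config.n_parent_pairs, config.parent_len_range, int(seeds[0]),
        id_prefix="PA", species="species_a",
    )
    parents_b = simulate_parents(
        config.n_parent_pairs, config.parent_len_range, int(seeds[1]),
        id_prefix="PB", species="species_b",
    )
    parents = {r.gene_id: r for r in parents_a + parents_b}

    mut_rng = np.random.default_rng(int(seeds[2]))
    fusions: dict[str, GeneRecord] = {}
    truth: list[TruthRecord] = []
    for i in range(config.n_fusions):
        pa, pb = parents_a[i], parents_b[i]
        fusion_id = f"FUS{i + 1:04d}"
        linker = (
            "".join(mut_rng.choice(list("ACGT"), size=config.linker_len))
            if config.linker_len
            else ""
        )
        raw, t = simulate_fusion(
            pa, pb, config.fusion_frac_a, config.fusion_frac_b,
            fusion_id=fusion_id, linker=linker,
        )
        # mutate each parent-derived segment separately so both retained
        # segments sit at the target identity to their parents
        len_a = math.floor(config.fusion_frac_a * len(pa.nt))
        len_b = len(raw) - len_a - len(linker)
        seg_a = mutate_to_identity(raw[:len_a], config.target_identity, mut_rng)
        seg_b = mutate_to_identity(raw[len(raw) - len_b:], config.target_identity, mut_rng)
        fused = seg_a + linker + seg_b
        t.planted_junction_reads = config.junction_reads_per_fusion
        fusions[fusion_id] = GeneRecord(fusion_id, config.species, fused)
        truth.append(t)

    lengths = {gid: len(rec.nt) for gid, rec in {**parents, **fusions}.items()}
    gene_intervals, sd_intervals = place_genes(
        lengths, truth, config.genome_length, config.n_sd_intervals,
        config.sd_interval_len, config.sd_enrichment, int(seeds[3]),
    )
    reads = simulate_reads(
        {**{g: r.nt for g, r in parents.items()}, **{g: r.nt for g, r in fusions.items()}},
        truth, config, np.random.default_rng(int(seeds[4])),
    )
    return SyntheticBundle(
        config=config,
        parents=parents,
        fusions=fusions,
        truth=truth,
        gene_intervals=gene_intervals,
        sd_intervals=sd_intervals,
        reads=reads,
        tree_newick=config.tree_newick,
    )


def _write_fasta(records: Iterable[GeneRecord], path: Path) -> None:
    with open(path, "w") as fh:
        for r in records:
            fh.write(f">{r.gene_id} species={r.species}\n{r.nt}\n")


def read_gene_fasta(path: str | Path) -> dict[str, GeneRecord]:
    """Read the bundle FASTA dialect (``species=`` tag in the description)."""
    out: dict[str, GeneRecord] = {}
    gid = species = None
    chunks: list[str] = []

    def flush() -> None:
        if gid is not None:
            out[gid] = GeneRecord(gid, species or "na", "".join(chunks))

    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line.startswith(">"):
                flush()
                fields = line[1:].split()
                gid = fields[0]
                species = None
                for tok in fields[1:]:
                    if tok.startswith("species="):
                        species = tok[len("species="):]
                chunks = []
            elif line:
                chunks.append(line)
    flush()
    return out


def make_fixture(config: SimulationConfig, outdir: str | Path) -> SyntheticBundle:
    """Write a full fixture bundle to ``outdir``.

    Files: parents.fasta, fusions.fasta, reads.fastq, genes.bed, sd.bed,
    tree.nwk, truth.tsv, config.yaml — all plain text, cross-referencing by
    gene identifier, byte-identical for identical configurations.
    """
    from .sd_enrichment import write_bed

    bundle = generate_bundle(config)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    _write_fasta(
        [bundle.parents[g] for g in sorted(bundle.parents)], outdir / "parents.fasta"
    )
    _write_fasta(
        [bundle.fusions[g] for g in sorted(bundle.fusions)], outdir / "fusions.fasta"
    )
    with open(outdir / "reads.fastq", "w") as fh:
        for r in bundle.reads:
            fh.write(f"@{r.read_id}\n{r.sequence}\n+\n{r.quality}\n")
    write_bed(bundle.gene_intervals, outdir / "genes.bed")
    write_bed(bundle.sd_intervals, outdir / "sd.bed")
    (outdir / "tree.nwk").write_text(bundle.tree_newick + "\n")
    with open(outdir / "truth.tsv", "w") as fh:
        fh.write(
            "fusion_id\tparent_a_id\tparent_b_id\ttrue_breakpoint\tin_sd\t"
            "planted_junction_reads\n"
        )
        for t in bundle.truth:
            fh.write(
                f"{t.fusion_id}\t{t.parent_a_id}\t{t.parent_b_id}\t"
                f"{t.true_breakpoint}\t{int(t.in_sd)}\t{t.planted_junction_reads}\n"
            )
    (outdir / "config.yaml").write_text(config.to_yaml())
    return bundle


def load_truth(path: str | Path) -> list[TruthRecord]:
    out: list[TruthRecord] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        for line in fh:
            d = dict(zip(header, line.rstrip("\n").split("\t")))
            out.append(
                TruthRecord(
                    d["fusion_id"], d["parent_a_id"], d["parent_b_id"],
                    int(d["true_breakpoint"]), bool(int(d["in_sd"])),
                    int(d["planted_junction_reads"]),
                )
            )
    return out


def simulate_phylo_presence(
    tree: SpeciesTree, n_fusions: int, seed: int = 0
) -> tuple[PresenceMatrix, dict[str, str]]:
    """Plant fusion origins on random tree nodes.

    Each fusion is assigned a uniformly chosen node (tip or internal); it is
    present in exactly the descendant tips of that node and absent
    elsewhere.  Returns the presence matrix and the true origin node id per
    fusion — used to validate single-gain origin recovery.
    """
    import pandas as pd

    rng = np.random.default_rng(seed)
    nodes = list(tree.tree.preorder_node_iter())
    tips = tree.tip_labels
    rows = {}
    origins: dict[str, str] = {}
    for i in range(n_fusions):
        node = nodes[int(rng.integers(0, len(nodes)))]
        present = {leaf.taxon.label for leaf in node.leaf_iter()}
        fid = f"FUS{i + 1:04d}"
        origins[fid] = SpeciesTree.node_id(node)
        rows[fid] = [PRESENT if sp in present else ABSENT for sp in tips]
    frame = pd.DataFrame.from_dict(rows, orient="index", columns=tips)
    return PresenceMatrix(frame), origins
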