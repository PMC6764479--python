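"""Junction-spanning read quantification and expression calls.

Reads are QC-filtered (leading-base trimming, mean-quality cutoff, length
cutoff), then counted against breakpoint probes: a read supports a fusion
junction only if its best ungapped alignment to the probe covers the
junction with a minimum overhang on *both* sides — reads matching a single
parent flank never count.  Counts are turned into tiered expression calls
(>=1, >=3, >=5 reads), a per-tissue two-proportion enrichment statistic,
and TPM values for probes against a background transcriptome.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm
from Bio import SeqIO

__all__ = [
    "ReadRecord",
    "QCStats",
    "JunctionCount",
    "TissueEnrichment",
    "read_fastq",
    "qc_filter_reads",
    "count_junction_reads",
    "count_junction_reads_grouped",
    "call_expressed",
    "tissue_enrichment",
    "compute_tpm",
]

DEFAULT_TIERS = (1, 3, 5)

_COMPLEMENT = bytes.maketrans(b"ACGTacgt", b"TGCATGCA")


@dataclass
class ReadRecord:
    """A sequencing read with per-base Phred qualities and sample labels.

    Tissue and species have no FASTQ field; they are carried in the read
    identifier as ``|tissue=X|species=Y`` suffixes (documented dialect).
    """

    read_id: str
    sequence: str
    quality: np.ndarray  # Phred scores, one per base
    tissue: str | None = None
    species: str | None = None


@dataclass
class QCStats:
    n_input: int = 0
    n_malformed: int = 0
    n_dropped_quality: int = 0
    n_dropped_length: int = 0
    n_kept: int = 0


def _labels_from_id(read_id: str) -> tuple[str | None, str | None]:
    tissue = species = None
    for token in read_id.split("|")[1:]:
        if token.startswith("tissue="):
            tissue = token[len("tissue="):]
        elif token.startswith("species="):
            species = token[len("species="):]
    return tissue, species


def read_fastq(path: str | Path) -> list[ReadRecord]:
    """Load a Phred+33 FASTQ file, decoding tissue/species labels from the
    read-identifier dialect."""
    reads: list[ReadRecord] = []
    for rec in SeqIO.parse(str(path), "fastq"):
        tissue, species = _labels_from_id(rec.id)
        reads.append(
            ReadRecord(
                rec.id,
                str(rec.seq),
                np.asarray(rec.letter_annotations["phred_quality"], dtype=np.int16),
                tissue,
                species,
            )
        )
    return reads


def qc_filter_reads(
    reads: Iterable[ReadRecord],
    min_mean_phred: float = 20.0,
    trim_leading: int = 13,
    min_length: int = 36,
) -> tuple[list[ReadRecord], QCStats]:
    """Trim and quality-filter reads.

    ``trim_leading`` bases are removed from the start of every read (poor
    leading cycles / adaptor remnants), then reads with mean Phred below
    ``min_mean_phred`` or post-trim length below ``min_length`` are dropped.
    Ribosome-footprint data use ``trim_leading=0, min_length=26`` (footprints
    longer than 25 nt are retained).  Records with mismatched sequence /
    quality lengths are skipped and counted, not fatal.
    """
    stats = QCStats()
    kept: list[ReadRecord] = []
    for r in reads:
        stats.n_input += 1
        if len(r.sequence) != len(r.quality):
            stats.n_malformed += 1
            continue
        seq = r.sequence[trim_leading:]
        qual = r.quality[trim_leading:]
        if len(seq) < min_length:
            stats.n_dropped_length += 1
            continue
        if len(qual) == 0 or float(np.mean(qual)) < min_mean_phred:
            stats.n_dropped_quality += 1
            continue
        kept.append(ReadRecord(r.read_id, seq, qual, r.tissue, r.species))
    stats.n_kept = len(kept)
    if stats.n_malformed:
        warnings.warn(
            f"skipped {stats.n_malformed} reads with sequence/quality length mismatch"
        )
    return kept, stats


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)


def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _best_spanning_mismatches(
    probe: np.ndarray, bp: int, read: np.ndarray, min_overhang: int
) -> int | None:
    """Fewest mismatches over all ungapped placements of `read` on `probe`
    whose overlap covers [bp - min_overhang, bp + min_overhang); None when no
    placement spans the junction."""
    L = len(read)
    n = len(probe)
    lo = max(bp + min_overhang - L, -(L - 1))
    hi = min(bp - min_overhang, n - 1)
    best: int | None = None
    for s in range(lo, hi + 1):
        a = max(0, s)
        b = min(n, s + L)
        if a > bp - min_overhang or b < bp + min_overhang:
            continue
        mm = int(np.count_nonzero(probe[a:b] != read[a - s:b - s]))
        if best is None or mm < best:
            best = mm
    return best


def count_junction_reads(
    probe,
    reads: Sequence[ReadRecord],
    min_overhang: int = 8,
    max_mismatches: int = 2,
) -> int:
    """Count reads whose best ungapped alignment to the probe (either
    strand) spans the junction with >= ``min_overhang`` nt on both sides and
    has at most ``max_mismatches`` mismatches.  Each read counts at most
    once."""
    bp = probe.breakpoint_offset
    pseq = probe.sequence
    if bp < min_overhang or len(pseq) - bp < min_overhang:
        raise ValueError(
            f"probe {probe.composite_id}: junction flanks shorter than "
            f"min_overhang={min_overhang}"
        )
    parr = _encode(pseq)
    count = 0
    for r in reads:
        fwd = _best_spanning_mismatches(parr, bp, _encode(r.sequence), min_overhang)
        if fwd is not None and fwd <= max_mismatches:
            count += 1
            continue
        rev = _best_spanning_mismatches(
            parr, bp, _encode(_revcomp(r.sequence)), min_overhang
        )
        if rev is not None and rev <= max_mismatches:
            count += 1
    return count


@dataclass
class JunctionCount:
    """Spanning-read count for one fusion in one species/tissue with tiered
    expression calls (count >= 1 / 3 / 5 reads)."""

    composite_id: str
    species: str
    tissue: str
    count: int
    expressed_at: dict[int, bool] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.count < 0:
            raise ValueError("count must be >= 0")
        if not self.expressed_at:
            self.expressed_at = call_expressed(self.count)


def call_expressed(count: int, thresholds: Sequence[int] = DEFAULT_TIERS) -> dict[int, bool]:
    """Tiered expression calls: expressed at tier k iff count >= k."""
    if count < 0:
        raise ValueError("count must be >= 0")
    return {k: count >= k for k in thresholds}


def count_junction_reads_grouped(
    probes: Sequence,
    reads: Sequence[ReadRecord],
    min_overhang: int = 8,
    max_mismatches: int = 2,
    thresholds: Sequence[int] = DEFAULT_TIERS,
) -> list[JunctionCount]:
    """Count junction-spanning reads per probe per (species, tissue) group."""
    groups: dict[tuple[str, str], list[ReadRecord]] = {}
    for r in reads:
        key = (r.species or "na", r.tissue or "na")
        groups.setdefault(key, []).append(r)
    out: list[JunctionCount] = []
    for probe in probes:
        for (species, tissue) in sorted(groups):
            c = count_junction_reads(
                probe, groups[(species, tissue)], min_overhang, max_mismatches
            )
            out.append(
                JunctionCount(
                    probe.composite_id, species, tissue, c,
                    call_expressed(c, thresholds),
                )
            )
    return out


@dataclass(frozen=True)
class TissueEnrichment:
    """Two-proportion z comparison of one tissue against the pooled rest."""

    tissue: str
    proportion_expressed: float
    z_score: float
    p_one_tailed: float
    p_two_tailed: float


def tissue_enrichment(calls: pd.DataFrame) -> list[TissueEnrichment]:
    """Test each tissue for an excess of expressed fusions.

    ``calls`` is a boolean fusions x tissues matrix.  For tissue t the
    proportion of fusions expressed in t is compared against the proportion
    pooled over all other tissues with the pooled-variance two-proportion z
    statistic; the one-tailed p is the upper normal tail, the two-tailed p is
    ``min(1, 2 * min(p_one, 1 - p_one))``.  A degenerate pooled variance
    (all or none expressed everywhere) yields z = 0, p = 1.
    """
    if calls.shape[1] < 2:
        raise ValueError("tissue enrichment requires >= 2 tissues")
    if calls.shape[0] < 1:
        raise ValueError("tissue enrichment requires >= 1 fusion")
    mat = calls.astype(bool)
    n = mat.shape[0]
    out: list[TissueEnrichment] = []
    for tissue in mat.columns:
        x_t = int(mat[tissue].sum())
        rest = mat.drop(columns=[tissue])
        x_r = int(rest.values.sum())
        n_r = rest.size
        p_t = x_t / n
        p_r = x_r / n_r
        p_pool = (x_t + x_r) / (n + n_r)
        var = p_pool * (1 - p_pool) * (1 / n + 1 / n_r)
        if var == 0:
            z, p_one = 0.0, 1.0
        else:
            z = (p_t - p_r) / np.sqrt(var)
            p_one = float(norm.sf(z))
        p_two = min(1.0, 2 * min(p_one, 1 - p_one))
        out.append(TissueEnrichment(tissue, p_t, float(z), p_one, p_two))
    return out


def compute_tpm(
    counts: Sequence[float] | Mapping[str, float],
    lengths: Sequence[float] | Mapping[str, float],
) -> np.ndarray | pd.Series:
    """Transcripts-per-million from read counts and transcript lengths.

    rate_i = count_i / length_i; TPM_i = 1e6 * rate_i / sum(rates).  When
    every count is zero a warning is issued and all TPM are zero.
    """
    if isinstance(counts, Mapping):
        keys = list(counts)
        c = np.asarray([counts[k] for k in keys], dtype=float)
        l = np.asarray([lengths[k] for k in keys], dtype=float)
    else:
        keys = None
        c = np.asarray(counts, dtype=float)
        l = np.asarray(lengths, dtype=float)
    if np.any(l <= 0):
        raise ValueError("transcript lengths must be > 0")
    rates = c / l
    total = rates.sum()
    if total == 0:
        warnings.warn("all counts are zero; TPM undefined, returning zeros")
        tpm = np.zeros_like(rates)
    else:
        tpm = 1e6 * rates / total
    if keys is not None:
        return pd.Series(tpm, index=keys)
    return tpm
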