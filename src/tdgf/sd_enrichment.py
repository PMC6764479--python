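"""Segmental-duplication (SD) overlap and enrichment testing.

Fusion loci are tested for enrichment in SD regions against a null obtained
by repeatedly sampling equally sized gene sets from the whole protein-coding
universe (no chromosomal restriction) and recording their SD-overlap counts.
Because the null is sampling genes without replacement, the exact
distribution of the overlap count is hypergeometric; the closed-form tail is
provided as an independent check on the permutation p-value.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from scipy.special import gammaln

__all__ = [
    "GenomicInterval",
    "PermutationResult",
    "read_bed",
    "write_bed",
    "overlap_genes",
    "permutation_test",
    "hypergeometric_tail",
]


@dataclass(frozen=True)
class GenomicInterval:
    """0-based half-open genomic interval with a label and a class tag."""

    chrom: str
    start: int
    end: int
    label: str = ""
    interval_class: str = "gene"  # "gene" | "sd"

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if self.end <= self.start:
            raise ValueError(f"interval end must exceed start ({self.start}, {self.end})")


def read_bed(path: str | Path, interval_class: str = "gene") -> list[GenomicInterval]:
    """Read a BED3+ file (0-based half-open); track and comment lines are
    skipped; malformed coordinates raise with the offending line number."""
    out: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: BED needs >= 3 columns")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer coordinate") from exc
            if end <= start:
                raise ValueError(f"{path}:{lineno}: end <= start ({start}, {end})")
            label = fields[3] if len(fields) > 3 else f"{fields[0]}:{start}-{end}"
            out.append(GenomicInterval(fields[0], start, end, label, interval_class))
    return out


def write_bed(intervals: Iterable[GenomicInterval], path: str | Path) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.label}\n")


def overlap_genes(
    genes: Sequence[GenomicInterval], sd_intervals: Sequence[GenomicInterval]
) -> set[str]:
    """Labels of genes intersecting any SD interval by >= 1 nt (half-open
    abutment is not an overlap).  Sorted sweep per chromosome."""
    sd_by_chrom: dict[str, list[tuple[int, int]]] = {}
    for sd in sd_intervals:
        sd_by_chrom.setdefault(sd.chrom, []).append((sd.start, sd.end))
    starts_by_chrom = {}
    for chrom, ivs in sd_by_chrom.items():
        ivs.sort()
        starts = np.asarray([s for s, _ in ivs])
        # running max of ends lets a single bisect answer "any overlap"
        ends = np.maximum.accumulate(np.asarray([e for _, e in ivs]))
        starts_by_chrom[chrom] = (starts, ends)
    hit: set[str] = set()
    for g in genes:
        entry = starts_by_chrom.get(g.chrom)
        if entry is None:
            continue
        starts, ends = entry
        # SD intervals starting before the gene ends
        idx = int(np.searchsorted(starts, g.end, side="left"))
        if idx > 0 and ends[idx - 1] > g.start:
            hit.add(g.label)
    return hit


@dataclass
class PermutationResult:
    """Outcome of the random-gene-set enrichment test."""

    observed_overlap: int  # k: focal genes overlapping SD
    focal_size: int  # n
    universe_size: int  # N
    n_in_sd: int  # m: universe genes overlapping SD
    replicates: int
    null_counts: dict[int, int]  # histogram of per-replicate overlap counts
    p_empirical: float
    seed: int

    def to_json(self) -> str:
        d = dict(self.__dict__)
        d["null_counts"] = {str(k): v for k, v in sorted(self.null_counts.items())}
        return json.dumps(d, indent=2)


def permutation_test(
    universe_genes: Sequence[GenomicInterval],
    sd_intervals: Sequence[GenomicInterval],
    focal_labels: Iterable[str],
    replicates: int = 10_000,
    seed: int = 0,
) -> PermutationResult:
    """Permutation (random gene set) test for SD enrichment of focal genes.

    Each replicate samples ``len(focal)`` genes uniformly without replacement
    from the universe and records how many overlap SD.  The empirical p-value
    uses the (+1)/(+1) correction, p = (1 + #{null >= observed}) /
    (replicates + 1), so it is never exactly zero.
    """
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    focal = sorted(set(focal_labels))
    labels = [g.label for g in universe_genes]
    label_set = set(labels)
    if len(labels) != len(label_set):
        raise ValueError("universe gene labels must be unique")
    missing = [f for f in focal if f not in label_set]
    if missing:
        raise ValueError(f"focal genes not in universe: {missing[:5]}")
    in_sd = overlap_genes(universe_genes, sd_intervals)
    flags = np.asarray([g.label in in_sd for g in universe_genes], dtype=bool)
    k = sum(1 for f in focal if f in in_sd)
    n, big_n, m = len(focal), len(labels), int(flags.sum())

    rng = np.random.default_rng(seed)
    null = np.empty(replicates, dtype=np.int64)
    for i in range(replicates):
        idx = rng.choice(big_n, size=n, replace=False)
        null[i] = int(flags[idx].sum())
    p = (1 + int((null >= k).sum())) / (replicates + 1)
    values, counts = np.unique(null, return_counts=True)
    return PermutationResult(
        observed_overlap=k,
        focal_size=n,
        universe_size=big_n,
        n_in_sd=m,
        replicates=replicates,
        null_counts={int(v): int(c) for v, c in zip(values, counts)},
        p_empirical=float(p),
        seed=seed,
    )


def _log_hyp_pmf(big_n: int, m: int, n: int, k: np.ndarray) -> np.ndarray:
    def lchoose(a, b):
        return gammaln(a + 1) - gammaln(b + 1) - gammaln(a - b + 1)

    return lchoose(m, k) + lchoose(big_n - m, n - k) - lchoose(big_n, n)


def hypergeometric_tail(big_n: int, m: int, n: int, k: int) -> float:
    """Exact upper tail P(X >= k) for X ~ Hypergeometric(N, m, n).

    X is the number of SD-overlapping genes in a uniform sample of n genes
    from a universe of N containing m SD-overlapping ones.  Summation of the
    mass function in log space keeps small tails accurate.
    """
    if not (0 <= m <= big_n):
        raise ValueError("need 0 <= m <= N")
    if not (0 <= n <= big_n):
        raise ValueError("need 0 <= n <= N")
    if not (0 <= k <= n):
        raise ValueError("need 0 <= k <= n")
    lo = max(k, max(0, n - (big_n - m)))
    hi = min(n, m)
    if lo > hi:
        return 0.0
    ks = np.arange(lo, hi + 1)
    logs = _log_hyp_pmf(big_n, m, n, ks)
    mx = logs.max()
    return float(min(1.0, np.exp(mx) * np.exp(logs - mx).sum()))
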