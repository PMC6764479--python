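"""End-to-end orchestration of the fusion-discovery analysis.

Chains the stages on one data bundle: all-vs-all local alignment ->
best-reciprocal-hit edges -> identity-thresholded SSN -> non-transitive
triplet / clique-separator composite detection -> distant-homology
filtering -> breakpoint inference and junction probes -> read QC and
junction-spanning counts -> tiered expression calls and tissue enrichment
-> SD-overlap permutation test -> presence matrix and phylogenetic origin
assignment.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from . import (
    breakpoint_mapping,
    composite_detection,
    junction_expression,
    phylo_distribution,
    sd_enrichment,
    similarity_graph,
)
from .synthetic_data import SyntheticBundle

__all__ = ["PipelineResult", "run_pipeline"]


@dataclass
class PipelineResult:
    si_threshold: float
    hits: list
    ssn: similarity_graph.SSN
    triplets: list
    candidates: list  # kept after distant-homology filtering
    removed: list
    breakpoints: dict[str, breakpoint_mapping.Breakpoint]
    probes: dict[str, breakpoint_mapping.JunctionProbe]
    qc_stats: junction_expression.QCStats | None
    junction_counts: list[junction_expression.JunctionCount]
    expression_calls: pd.DataFrame | None  # fusions x tissues, tier-1 booleans
    tissue_enrichment: list[junction_expression.TissueEnrichment]
    tpm: pd.Series | None
    sd_result: sd_enrichment.PermutationResult | None
    presence: phylo_distribution.PresenceMatrix | None
    origins: list[phylo_distribution.OriginAssignment]

    @property
    def detected_fusions(self) -> list[str]:
        return sorted(c.composite_id for c in self.candidates)


def _family_representative(family: frozenset[str]) -> str:
    return sorted(family)[0]


def run_pipeline(
    bundle: SyntheticBundle,
    si_threshold: float = 90.0,
    evalue_max: float = 1e-5,
    max_overlap_fraction: float = 0.2,
    flank: int = 50,
    min_overhang: int = 8,
    max_mismatches: int = 2,
    qc_trim_leading: int = 0,
    qc_min_mean_phred: float = 20.0,
    qc_min_length: int = 36,
    expression_tier: int = 1,
    replicates: int = 10_000,
    perm_seed: int = 0,
    transcript_counts: Mapping[str, int] | None = None,
    require_separator: bool = True,
) -> PipelineResult:
    """Run the whole analysis on a synthetic (or equivalently structured)
    bundle and return every intermediate product.

    ``qc_trim_leading`` defaults to 0 here: leading-cycle trimming targets
    platform artifacts that the read simulator does not produce.
    ``transcript_counts`` supplies background per-transcript read counts for
    the TPM comparison; when omitted TPM is skipped.
    """
    transcripts = bundle.transcripts
    species_of = bundle.species_of

    hits = similarity_graph.all_vs_all_hits(transcripts, scoring="nucleotide")
    edges = similarity_graph.best_reciprocal_edges(
        hits, evalue_max=evalue_max, species_of=species_of
    )
    ssn = similarity_graph.build_ssn(
        edges, si_threshold, nodes=transcripts, species_of=species_of
    )

    triplets = composite_detection.find_nontransitive_triplets(
        ssn, max_overlap_fraction=max_overlap_fraction
    )
    raw_candidates = composite_detection.aggregate_composites(ssn, triplets)
    if require_separator:
        raw_candidates = [c for c in raw_candidates if c.separator_verified]
    candidates, removed = composite_detection.filter_distant_homology(
        raw_candidates, hits, evalue_max=evalue_max,
        max_family_overlap=max_overlap_fraction,
    )

    breakpoints: dict[str, breakpoint_mapping.Breakpoint] = {}
    probes: dict[str, breakpoint_mapping.JunctionProbe] = {}
    for cand in candidates:
        composite_nt = transcripts[cand.composite_id]
        intervals = []
        reps = []
        for fam in cand.parent_families[:2]:
            rep = _family_representative(fam)
            iv = breakpoint_mapping.align_parent_to_composite(
                composite_nt, transcripts[rep]
            )
            if iv is not None:
                intervals.append(iv)
                reps.append(rep)
        if len(intervals) < 2:
            continue
        try:
            bp = breakpoint_mapping.infer_breakpoint(
                intervals[0], intervals[1], cand.composite_id, reps[0], reps[1]
            )
        except breakpoint_mapping.AmbiguousBreakpointError:
            continue
        breakpoints[cand.composite_id] = bp
        probes[cand.composite_id] = breakpoint_mapping.make_junction_probe(
            composite_nt, bp, flank
        )

    qc_stats = None
    junction_counts: list[junction_expression.JunctionCount] = []
    expression_calls = None
    enrichment: list[junction_expression.TissueEnrichment] = []
    tpm = None
    if bundle.reads:
        reads = [
            junction_expression.ReadRecord(
                r.read_id, r.sequence,
                np.frombuffer(r.quality.encode(), dtype=np.uint8).astype(np.int16) - 33,
                *_labels(r.read_id),
            )
            for r in bundle.reads
        ]
        reads, qc_stats = junction_expression.qc_filter_reads(
            reads, min_mean_phred=qc_min_mean_phred,
            trim_leading=qc_trim_leading, min_length=qc_min_length,
        )
        junction_counts = junction_expression.count_junction_reads_grouped(
            list(probes.values()), reads,
            min_overhang=min_overhang, max_mismatches=max_mismatches,
        )
        if junction_counts:
            tissues = sorted({jc.tissue for jc in junction_counts})
            fusion_ids = sorted({jc.composite_id for jc in junction_counts})
            calls = pd.DataFrame(False, index=fusion_ids, columns=tissues)
            for jc in junction_counts:
                if jc.expressed_at.get(expression_tier, jc.count >= expression_tier):
                    calls.loc[jc.composite_id, jc.tissue] = True
            expression_calls = calls
            if len(tissues) >= 2 and len(fusion_ids) >= 1:
                enrichment = junction_expression.tissue_enrichment(calls)
        if transcript_counts is not None and probes:
            probe_counts = {
                cid: sum(jc.count for jc in junction_counts if jc.composite_id == cid)
                for cid in probes
            }
            counts = dict(transcript_counts)
            lengths = {tid: len(seq) for tid, seq in transcripts.items()}
            for cid, p in probes.items():
                counts[f"{cid}|probe"] = probe_counts[cid]
                lengths[f"{cid}|probe"] = len(p.sequence)
            tpm = junction_expression.compute_tpm(counts, lengths)

    sd_result = None
    if bundle.gene_intervals and candidates:
        universe_labels = {g.label for g in bundle.gene_intervals}
        focal = [c for c in (c.composite_id for c in candidates) if c in universe_labels]
        if focal:
            sd_result = sd_enrichment.permutation_test(
                bundle.gene_intervals, bundle.sd_intervals, focal,
                replicates=replicates, seed=perm_seed,
            )

    presence = None
    origins: list[phylo_distribution.OriginAssignment] = []
    if junction_counts and bundle.tree_newick:
        tree = phylo_distribution.parse_newick(bundle.tree_newick)
        informative = [
            jc for jc in junction_counts if jc.species in tree.tip_labels
        ]
        with_signal = {
            jc.composite_id for jc in informative
            if jc.expressed_at.get(expression_tier, jc.count >= expression_tier)
        }
        informative = [jc for jc in informative if jc.composite_id in with_signal]
        if informative:
            presence = phylo_distribution.build_presence_matrix(
                informative, tier=expression_tier
            )
            origins = phylo_distribution.assign_origins(tree, presence)

    return PipelineResult(
        si_threshold=si_threshold,
        hits=hits,
        ssn=ssn,
        triplets=triplets,
        candidates=candidates,
        removed=removed,
        breakpoints=breakpoints,
        probes=probes,
        qc_stats=qc_stats,
        junction_counts=junction_counts,
        expression_calls=expression_calls,
        tissue_enrichment=enrichment,
        tpm=tpm,
        sd_result=sd_result,
        presence=presence,
        origins=origins,
    )


def _labels(read_id: str) -> tuple[str | None, str | None]:
    from .junction_expression import _labels_from_id

    return _labels_from_id(read_id)
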