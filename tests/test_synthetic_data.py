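"""Generator contracts: determinism, identity control, planted structure."""

import numpy as np
import pytest

from tdgf.sd_enrichment import overlap_genes
from tdgf.similarity_graph import local_align
from tdgf.synthetic_data import (
    SimulationConfig,
    TruthRecord,
    generate_bundle,
    make_fixture,
    mutate_to_identity,
    place_genes,
    simulate_fusion,
    simulate_parents,
    simulate_reads,
)


class TestSimulateParents:
    def test_seed_determinism(self):
        a = simulate_parents(1, 300, seed=7)
        b = simulate_parents(1, 300, seed=7)
        assert a[0].nt == b[0].nt

    def test_unique_ids_and_count(self):
        recs = simulate_parents(5, (300, 600), seed=1)
        assert len(recs) == 5
        assert len({r.gene_id for r in recs}) == 5

    def test_no_internal_stop_codons(self):
        # scan every translation for stop symbols (oracle: direct scan)
        for r in simulate_parents(20, (300, 900), seed=3):
            assert "*" not in r.protein
            assert len(r.nt) % 3 == 0

    def test_length_not_multiple_of_three_rejected(self):
        with pytest.raises(ValueError):
            simulate_parents(1, 100, seed=0)


class TestMutateToIdentity:
    def test_identity_one_is_noop(self):
        seq = simulate_parents(1, 300, seed=5)[0].nt
        assert mutate_to_identity(seq, 1.0, seed=0) == seq

    @pytest.mark.parametrize("target", [0.9, 0.8, 0.7])
    def test_realized_identity_close_to_target(self, target):
        seq = simulate_parents(1, 300, seed=5)[0].nt
        mut = mutate_to_identity(seq, target, seed=1)
        assert len(mut) == len(seq)
        realized = sum(a == b for a, b in zip(seq, mut)) / len(seq)
        assert target - 0.02 <= realized <= target + 0.02

    def test_lower_target_gives_lower_identity(self):
        seq = simulate_parents(1, 600, seed=5)[0].nt
        def realized(t):
            mut = mutate_to_identity(seq, t, seed=9)
            return sum(a == b for a, b in zip(seq, mut)) / len(seq)
        assert realized(0.7) <= realized(0.9)

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            mutate_to_identity("", 0.9)


class TestSimulateFusion:
    def test_half_half_arithmetic(self):
        a = simulate_parents(1, 300, seed=1, id_prefix="A")[0]
        b = simulate_parents(1, 300, seed=2, id_prefix="B")[0]
        fusion, truth = simulate_fusion(a, b, 0.5, 0.5)
        assert len(fusion) == 300
        assert truth.true_breakpoint == 150

    def test_boundary_fraction_rejected(self):
        a = simulate_parents(1, 300, seed=1)[0]
        b = simulate_parents(1, 300, seed=2)[0]
        with pytest.raises(ValueError):
            simulate_fusion(a, b, 1.0, 0.5)

    def test_short_segment_rejected(self):
        a = simulate_parents(1, 300, seed=1)[0]
        b = simulate_parents(1, 300, seed=2)[0]
        with pytest.raises(ValueError):
            simulate_fusion(a, b, 0.05, 0.5)

    def test_realignment_recovers_parent_intervals(self):
        # alignment oracle: un-mutated fusion must realign to its parents
        # exactly at the planted intervals
        a = simulate_parents(1, 300, seed=11, id_prefix="A")[0]
        b = simulate_parents(1, 300, seed=12, id_prefix="B")[0]
        fusion, truth = simulate_fusion(a, b, 0.5, 0.5)
        hit_a = local_align(fusion, a.nt[:150], "nucleotide")
        hit_b = local_align(fusion, b.nt[150:], "nucleotide")
        assert hit_a.query_interval == (0, 150)
        assert hit_b.query_interval == (150, 300)
        assert truth.true_breakpoint == 150


class TestPlaceGenes:
    def _truth(self, fusion_ids):
        return [TruthRecord(f, "pa", "pb", 100) for f in fusion_ids]

    def test_zero_enrichment_puts_no_fusion_in_sd(self):
        lengths = {f"FUS{i:04d}": 500 for i in range(20)}
        truth = self._truth(lengths)
        genes, sds = place_genes(lengths, truth, 500_000, 20, 5_000, 0.0, seed=3)
        assert not any(t.in_sd for t in truth)
        assert not overlap_genes(genes, sds)

    def test_intervals_do_not_overlap(self):
        lengths = {f"G{i:03d}": 800 for i in range(50)}
        genes, sds = place_genes(lengths, [], 400_000, 10, 8_000, 1.0, seed=4)
        for ivs in (genes, sds):
            spans = sorted((iv.start, iv.end) for iv in ivs)
            for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
                assert e1 <= s2
        assert all(iv.end > iv.start for iv in genes + sds)

    def test_neutral_enrichment_matches_background_rate(self):
        # Monte-Carlo: at enrichment 1 the fusion in-SD indicator is
        # Bernoulli(p_sd); check within 3 binomial standard errors
        n_fusions = 250
        lengths = {f"FUS{i:04d}": 300 for i in range(n_fusions)}
        truth = self._truth(lengths)
        genome, n_sd, sd_len = 2_000_000, 25, 20_000
        place_genes(lengths, truth, genome, n_sd, sd_len, 1.0, seed=8)
        p_sd = n_sd * sd_len / genome
        rate = sum(t.in_sd for t in truth) / n_fusions
        se = (p_sd * (1 - p_sd) / n_fusions) ** 0.5
        assert abs(rate - p_sd) <= 3 * se


class TestSimulateReads:
    def test_exact_planted_spanning_reads(self):
        cfg = SimulationConfig(seed=5, n_parent_pairs=4, n_fusions=2,
                               read_depth=10, junction_reads_per_fusion=5,
                               tissues=("brain", "liver"))
        bundle = generate_bundle(cfg)
        truth = {t.fusion_id: t for t in bundle.truth}
        rl = cfg.read_length
        for fid, t in truth.items():
            for tissue in cfg.tissues:
                spanning = 0
                for r in bundle.reads:
                    if f"src={fid}|" not in r.read_id or f"tissue={tissue}|" not in r.read_id:
                        continue
                    pos = int([f for f in r.read_id.split("|") if f.startswith("pos=")][0][4:])
                    ov = min(8, rl // 2)
                    if pos <= t.true_breakpoint - ov and pos + rl >= t.true_breakpoint + ov:
                        spanning += 1
                assert spanning == 5

    def test_no_reads_when_depths_zero(self):
        cfg = SimulationConfig(seed=5, n_parent_pairs=2, n_fusions=1,
                               read_depth=0, junction_reads_per_fusion=0,
                               tissues=("brain",))
        assert generate_bundle(cfg).reads == []

    def test_read_longer_than_transcript_rejected(self):
        cfg = SimulationConfig(seed=5, n_parent_pairs=2, n_fusions=1)
        bundle = generate_bundle(cfg)
        with pytest.raises(ValueError):
            simulate_reads({"t1": "ACGT" * 10}, [], cfg)


class TestFixtureBundle:
    def test_fixture_reproducible_and_consistent(self, tmp_path):
        cfg = SimulationConfig(seed=3, n_parent_pairs=4, n_fusions=2,
                               read_depth=2, tissues=("brain", "liver"))
        d1, d2 = tmp_path / "a", tmp_path / "b"
        b1 = make_fixture(cfg, d1)
        make_fixture(cfg, d2)
        names = ["parents.fasta", "fusions.fasta", "reads.fastq", "genes.bed",
                 "sd.bed", "tree.nwk", "truth.tsv", "config.yaml"]
        for name in names:
            assert (d1 / name).read_bytes() == (d2 / name).read_bytes()
        # truth rows == n_fusions, and referenced parents exist
        lines = (d1 / "truth.tsv").read_text().strip().splitlines()
        assert len(lines) - 1 == cfg.n_fusions
        for t in b1.truth:
            assert t.parent_a_id in b1.parents and t.parent_b_id in b1.parents
            assert 0 < t.true_breakpoint < len(b1.fusions[t.fusion_id].nt)

    def test_seed_changes_sequences_not_schema(self, tmp_path):
        c1 = SimulationConfig(seed=1, n_parent_pairs=3, n_fusions=1, read_depth=1)
        c2 = SimulationConfig(seed=2, n_parent_pairs=3, n_fusions=1, read_depth=1)
        b1 = generate_bundle(c1)
        b2 = generate_bundle(c2)
        assert sorted(b1.parents) == sorted(b2.parents)
        assert b1.parents["PA0001"].nt != b2.parents["PA0001"].nt
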