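"""SSN construction: hit parsing, the local aligner, reciprocal-best edges."""

import random

import pytest

from tdgf.similarity_graph import (
    NUCLEOTIDE_SCORING,
    PROTEIN_SCORING,
    SimilarityHit,
    best_reciprocal_edges,
    build_ssn,
    local_align,
    read_tabular_hits,
    write_tabular_hits,
)


def _hit(q, s, bits=100.0, evalue=1e-30, identity=95.0):
    return SimilarityHit(q, s, identity, 100, 0, 100, 0, 100, evalue, bits)


class TestReadTabularHits:
    def test_parses_line_with_coordinate_conversion(self, tmp_path):
        p = tmp_path / "hits.tsv"
        p.write_text("g1\tg2\t95.00\t100\t5\t0\t1\t100\t1\t100\t1e-50\t200\n")
        (hit,) = read_tabular_hits(p)
        assert hit.query_id == "g1" and hit.subject_id == "g2"
        assert hit.percent_identity == 95.0
        assert hit.query_interval == (0, 100)  # 1-based 1..100 -> [0, 100)
        assert hit.query_end - hit.query_start == 100  # length preserved
        assert hit.e_value == 1e-50 and hit.bit_score == 200.0

    def test_reverse_subject_orientation_normalized(self, tmp_path):
        p = tmp_path / "hits.tsv"
        p.write_text("g1\tg2\t90.00\t50\t0\t0\t1\t50\t80\t31\t1e-10\t90\n")
        (hit,) = read_tabular_hits(p)
        assert hit.subject_interval == (30, 80)
        assert hit.subject_orientation == "-"

    def test_wrong_column_count_rejected(self, tmp_path):
        p = tmp_path / "bad.tsv"
        p.write_text("g1\tg2\t95.00\t100\t5\t0\t1\t100\t1\t100\t1e-50\n")
        with pytest.raises(ValueError, match="12"):
            read_tabular_hits(p)

    def test_round_trip(self, tmp_path):
        hits = [_hit("a", "b"), _hit("b", "c", bits=50, identity=70.0)]
        p = tmp_path / "rt.tsv"
        write_tabular_hits(hits, p)
        back = read_tabular_hits(p)
        assert [(h.query_id, h.subject_id, h.percent_identity,
                 h.query_interval, h.subject_interval) for h in back] == \
               [(h.query_id, h.subject_id, h.percent_identity,
                 h.query_interval, h.subject_interval) for h in hits]


def _oracle_sw_affine(a, b, score, gap_open, gap_extend):
    """Independent affine-gap Smith-Waterman (plain Gotoh recurrences)."""
    n, m = len(a), len(b)
    NEG = -10**9
    best = 0
    M = [[0] * (m + 1) for _ in range(n + 1)]
    X = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in b
    Y = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in a
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            X[i][j] = max(M[i - 1][j] - gap_open, X[i - 1][j] - gap_extend)
            Y[i][j] = max(M[i][j - 1] - gap_open, Y[i][j - 1] - gap_extend)
            M[i][j] = max(
                0,
                max(M[i - 1][j - 1], X[i - 1][j - 1], Y[i - 1][j - 1])
                + score(a[i - 1], b[j - 1]),
            )
            best = max(best, M[i][j], X[i][j], Y[i][j])
    return best


class TestLocalAlign:
    def test_identical_proteins_full_identity(self):
        seq = "MKTLLVAGICSRQWEDNPHYFAKDEGISTVNMKTLLVAGICSRQWEDNPH"
        hit = local_align(seq, seq, "protein")
        assert hit.percent_identity == 100.0
        assert hit.query_interval == (0, 50)
        assert hit.subject_interval == (0, 50)

    def test_score_matches_independent_dp_oracle(self):
        from biotite.sequence.align import SubstitutionMatrix
        blosum = SubstitutionMatrix.std_protein_matrix()

        def prot_score(x, y):
            return int(blosum.get_score(x, y))

        def nt_score(x, y):
            return 2 if x == y else -3

        rnd = random.Random(42)
        for _ in range(15):
            pa = "".join(rnd.choice("ACDEFGHIKLMNPQRSTVWY") for _ in range(rnd.randint(6, 14)))
            pb = "".join(rnd.choice("ACDEFGHIKLMNPQRSTVWY") for _ in range(rnd.randint(6, 14)))
            hit = local_align(pa, pb, "protein", min_score=-1)
            expected = _oracle_sw_affine(
                pa, pb, prot_score, PROTEIN_SCORING.gap_open, PROTEIN_SCORING.gap_extend
            )
            got = 0 if hit is None else _score_from_hit(hit, PROTEIN_SCORING)
            assert got == expected
        for _ in range(15):
            na = "".join(rnd.choice("ACGT") for _ in range(rnd.randint(8, 20)))
            nb = "".join(rnd.choice("ACGT") for _ in range(rnd.randint(8, 20)))
            hit = local_align(na, nb, "nucleotide", min_score=-1)
            expected = _oracle_sw_affine(
                na, nb, nt_score, NUCLEOTIDE_SCORING.gap_open, NUCLEOTIDE_SCORING.gap_extend
            )
            got = 0 if hit is None else _score_from_hit(hit, NUCLEOTIDE_SCORING)
            assert got == expected

    def test_unrelated_sequences_below_min_score_give_none(self):
        rnd = random.Random(1)
        a = "".join(rnd.choice("ACGT") for _ in range(100))
        b = "".join(rnd.choice("ACGT") for _ in range(100))
        assert local_align(a, b, "nucleotide", min_score=120) is None

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            local_align("", "ACGT", "nucleotide")


def _score_from_hit(hit, scheme):
    """Invert the bit-score transform back to the raw alignment score."""
    import math
    return round((hit.bit_score * math.log(2) + math.log(scheme.ka_k)) / scheme.ka_lambda)


def _brute_force_brh(hits, evalue_max=1e-5):
    """Reference reciprocal-best computation by direct enumeration."""
    usable = [h for h in hits if h.query_id != h.subject_id and h.e_value <= evalue_max]
    pair_best = {}
    for h in usable:
        k = (h.query_id, h.subject_id)
        if k not in pair_best or (h.bit_score, -h.e_value) > (
            pair_best[k].bit_score, -pair_best[k].e_value
        ):
            pair_best[k] = h
    queries = {q for q, _ in pair_best}
    best = {}
    for q in queries:
        partners = sorted(
            (s for (qq, s) in pair_best if qq == q),
            key=lambda s: (-pair_best[(q, s)].bit_score, pair_best[(q, s)].e_value, s),
        )
        best[q] = partners[0]
    return sorted(
        tuple(sorted((q, s))) for q, s in best.items() if best.get(s) == q and q < s
    )


class TestBestReciprocalEdges:
    def test_mutual_best_yields_single_edge(self):
        hits = [_hit("g1", "g2"), _hit("g2", "g1")]
        edges = best_reciprocal_edges(hits)
        assert [(e.node_a, e.node_b) for e in edges] == [("g1", "g2")]

    def test_self_hits_removed(self):
        hits = [_hit("g1", "g1"), _hit("g1", "g2"), _hit("g2", "g1")]
        edges = best_reciprocal_edges(hits)
        assert [(e.node_a, e.node_b) for e in edges] == [("g1", "g2")]

    def test_non_mutual_best_gives_no_edge(self):
        hits = [
            _hit("g1", "g2", bits=100), _hit("g2", "g1", bits=50),
            _hit("g2", "g3", bits=100), _hit("g3", "g2", bits=100),
        ]
        edges = best_reciprocal_edges(hits)
        assert [(e.node_a, e.node_b) for e in edges] == [("g2", "g3")]

    def test_matches_brute_force_on_random_hit_lists(self):
        rnd = random.Random(99)
        genes = [f"g{i}" for i in range(6)]
        for _ in range(50):
            hits = []
            for _ in range(rnd.randint(1, 25)):
                q, s = rnd.choice(genes), rnd.choice(genes)
                hits.append(_hit(q, s, bits=rnd.choice([10, 50, 100, 100]),
                                 evalue=rnd.choice([1e-30, 1e-10, 1e-3])))
            got = sorted((e.node_a, e.node_b) for e in best_reciprocal_edges(hits))
            assert got == _brute_force_brh(hits)
            rnd.shuffle(hits)
            again = sorted((e.node_a, e.node_b) for e in best_reciprocal_edges(hits))
            assert again == got  # invariant under input ordering


class TestBuildSSN:
    def test_tier_thresholding(self):
        edges = best_reciprocal_edges(
            [_hit("a", "b", identity=85.0), _hit("b", "a", identity=85.0)]
        )
        assert len(build_ssn(edges, 90).edges()) == 0
        assert len(build_ssn(edges, 80).edges()) == 1
        assert len(build_ssn(edges, 0).edges()) == 1

    def test_tier_monotonicity(self):
        rnd = random.Random(5)
        hits = []
        for i in range(10):
            ident = rnd.uniform(60, 100)
            hits.append(_hit(f"a{i}", f"b{i}", identity=ident))
            hits.append(_hit(f"b{i}", f"a{i}", identity=ident))
        edges = best_reciprocal_edges(hits)
        e90 = {(e.node_a, e.node_b) for e in build_ssn(edges, 90).edges()}
        e80 = {(e.node_a, e.node_b) for e in build_ssn(edges, 80).edges()}
        e70 = {(e.node_a, e.node_b) for e in build_ssn(edges, 70).edges()}
        assert e90 <= e80 <= e70

    def test_out_of_range_threshold_rejected(self):
        with pytest.raises(ValueError):
            build_ssn([], 101)

    def test_isolated_nodes_kept(self):
        ssn = build_ssn([], 90, nodes=["x", "y"])
        assert ssn.nodes() == ["x", "y"]
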