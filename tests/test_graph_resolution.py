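import numpy as np
import pytest

import nas
from nas.graph_resolution import (ContigGraph, clip_to_template_reach,
                                  merge_path, select_best_path,
                                  validate_candidate)
from nas.micro_assembly import AssemblyResult, Contig
from nas.sequence_io import SeqRecord
from nas.template_alignment import ReadBatch

from .conftest import random_dna
from .oracles import best_simple_path_weight


class TestSelectBestPath:
    def test_single_vertex(self):
        g = ContigGraph({"c": 5.0}, [], "c", "c")
        res = select_best_path(g)
        assert res.path == ["c"] and not res.disconnected

    def test_repeat_with_decoys_takes_high_weight_path(self):
        # a repeat vertex of degree 4: true flanks plus two dead-end decoys
        # from the wrong repeat copy
        g = ContigGraph(
            {"c1": 40.0, "c2": 80.0, "c3": 35.0, "d1": 2.0, "d2": 1.0},
            [("c1", "c2"), ("c2", "c3"), ("c2", "d1"), ("c2", "d2")],
            "c1", "c3")
        res = select_best_path(g)
        assert res.path == ["c1", "c2", "c3"]
        assert sorted(g.neighbours("c2")) == ["c1", "c3", "d1", "d2"]

    def test_disconnected_falls_back_to_heaviest_vertex(self):
        g = ContigGraph({"a": 3.0, "b": 9.0}, [], "a", "b")
        res = select_best_path(g)
        assert res.disconnected and res.path == ["b"]

    def test_matches_exhaustive_enumeration_on_random_graphs(self):
        rng = np.random.default_rng(2024)
        for trial in range(60):
            n = int(rng.integers(2, 9))
            names = [f"v{i}" for i in range(n)]
            weights = {v: float(rng.uniform(0, 50)) for v in names}
            edges = [(names[i], names[j]) for i in range(n) for j in range(i + 1, n)
                     if rng.random() < 0.45]
            src, snk = names[0], names[-1]
            g = ContigGraph(weights, edges, src, snk)
            res = select_best_path(g)
            oracle = best_simple_path_weight(weights, edges, src, snk)
            if oracle is None:
                assert res.disconnected
            else:
                assert res.weight == pytest.approx(oracle)

    def test_weight_increase_on_selected_path_keeps_it_selected(self):
        rng = np.random.default_rng(7)
        names = [f"v{i}" for i in range(7)]
        weights = {v: float(rng.uniform(1, 40)) for v in names}
        edges = [(names[i], names[j]) for i in range(7) for j in range(i + 1, 7)
                 if rng.random() < 0.5]
        g = ContigGraph(weights, edges, names[0], names[-1])
        res = select_best_path(g)
        if not res.disconnected:
            boosted = dict(weights)
            boosted[res.path[len(res.path) // 2]] += 25.0
            res2 = select_best_path(ContigGraph(boosted, edges, names[0], names[-1]))
            assert res2.path == res.path


class TestMergePath:
    def _result(self, seqs):
        return AssemblyResult([Contig(cid, s, seed_coverage=10.0)
                               for cid, s in seqs.items()])

    def test_exact_overlap_merge_length(self):
        g = random_dna(1000, 30)
        res = self._result({"a": g[0:600], "b": g[500:1000]})
        merged = merge_path(["a", "b"], res)
        assert len(merged.sequence) == 600 + 500 - 100
        assert merged.sequence == g
        assert not merged.flagged

    def test_no_overlap_falls_back_to_longest(self):
        res = self._result({"a": random_dna(700, 31), "b": random_dna(400, 32)})
        merged = merge_path(["a", "b"], res)
        assert merged.flagged
        assert merged.path == ["a"]
        assert merged.sequence == res.contig("a").sequence

    def test_junction_consensus_from_higher_coverage_contig(self):
        g = random_dna(800, 33)
        a = g[0:500]
        b_list = list(g[400:800])
        b_list[10] = "ACGT"[("ACGT".index(b_list[10]) + 1) % 4]  # divergent junction base
        res = AssemblyResult([Contig("a", a, seed_coverage=50.0),
                              Contig("b", "".join(b_list), seed_coverage=5.0)])
        merged = merge_path(["a", "b"], res)
        assert merged.sequence[:500] == a  # junction bases taken from 'a'


class TestValidateCandidate:
    def _batch(self, genome_seq, coverage=40, seed=0):
        g = nas.GenomeTruth(genome_seq)
        pairs = nas.simulate_read_pairs(g, coverage, error_rate=0.0, seed=seed)
        return ReadBatch([r for p in pairs for r in (p.fwd, p.rev)], 12)

    def test_uniform_depth_valid(self):
        genome_seq = random_dna(6000, 34)
        batch = self._batch(genome_seq)
        out = validate_candidate(genome_seq[500:5500], batch, min_cov2=10)
        assert out.status == "valid"
        assert out.sequence == genome_seq[500:5500]
        assert out.coverage_min >= 10

    def test_junction_gap_trims_to_one_side(self):
        left = random_dna(6000, 35)
        right = random_dna(6000, 36)
        reads = []
        for tag, seq, seed in (("A", left, 1), ("B", right, 2)):
            pairs = nas.simulate_read_pairs(nas.GenomeTruth(seq), 25,
                                            error_rate=0.0, seed=seed)
            reads.extend(SeqRecord(f"{tag}_{r.id}", r.sequence)
                         for p in pairs for r in (p.fwd, p.rev))
        batch = ReadBatch(reads, 12)
        candidate = left[1000:5500] + right[500:5000]
        out = validate_candidate(candidate, batch, min_cov2=10)
        assert out.status == "trimmed"
        assert out.sequence in candidate  # contiguous subregion
        # the kept run must not straddle the junction by more than read noise
        junction = 4500
        kept_start = candidate.find(out.sequence)
        kept_end = kept_start + len(out.sequence)
        assert kept_end <= junction + 50 or kept_start >= junction - 50

    def test_short_candidate_interior_exempt(self):
        genome_seq = random_dna(2000, 37)
        batch = self._batch(genome_seq, coverage=5)
        out = validate_candidate(genome_seq[500:1300], batch, min_cov2=10,
                                 end_margin=500)
        assert out.status == "valid"  # interior shorter than the exempt margins


def test_clip_to_template_reach_bounds_extension():
    genome_seq = random_dna(10_000, 38)
    template = genome_seq[3000:7000]
    candidate = genome_seq[1000:9000]  # 2 kb of extension on both sides
    clipped = clip_to_template_reach(candidate, template, fragment_max=750)
    assert clipped in candidate
    # at most fragment_max beyond the template on each side
    start = genome_seq.find(clipped)
    assert 3000 - 750 <= start <= 3000
    assert 7000 <= start + len(clipped) <= 7000 + 750
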