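import numpy as np
import pytest

import nas
from nas.sequence_io import SeqRecord, reverse_complement
from nas.synthetic_data import apply_errors
from nas.template_alignment import (Alignment, AlignerParams, ReadBatch,
                                    TemplateIndex, align_read_to_template,
                                    build_template_index,
                                    filter_alignments_for_coverage,
                                    select_seed_reads)

from .conftest import random_dna


class TestTemplateIndex:
    def test_sampled_word_positions(self):
        idx = build_template_index("ACGTACGTACGT", tile_size=4, step_size=4)
        assert idx.lookup("ACGT") == [0, 4, 8]

    def test_absent_word_empty(self):
        idx = build_template_index("ACGTACGTACGT", tile_size=4, step_size=4)
        assert idx.lookup("GGGG") == []

    def test_short_template_gives_empty_index(self):
        idx = build_template_index("ACG", tile_size=10, step_size=5)
        assert len(idx) == 0

    def test_ambiguous_bases_skipped(self):
        idx = build_template_index("ACGTNACGTACG", tile_size=4, step_size=1)
        for pos_list in (idx.lookup("ACGT"),):
            assert 1 not in pos_list  # window covering the N is not indexed


class TestAlignment:
    def test_exact_substring_alignment(self):
        template = random_dna(2000, 42)
        read = SeqRecord("r", template[100:350])
        idx = build_template_index(template)
        aln = align_read_to_template(read, idx)[0]
        assert (aln.t_start, aln.t_end, aln.strand) == (100, 350, "+")
        assert aln.identity == 1.0
        assert aln.query_fraction == 1.0

    def test_reverse_complement_flips_strand_same_interval(self):
        template = random_dna(2000, 43)
        read = SeqRecord("r", reverse_complement(template[400:650]))
        idx = build_template_index(template)
        aln = align_read_to_template(read, idx)[0]
        assert aln.strand == "-"
        assert (aln.t_start, aln.t_end) == (400, 650)
        assert aln.identity == 1.0

    def test_interval_consistency_on_noisy_reads(self):
        template = random_dna(3000, 44)
        rng = np.random.default_rng(7)
        profile = nas.ErrorProfile(0.10, 0.05, 0.05)
        idx = build_template_index(template)
        checked = 0
        for i in range(25):
            s = int(rng.integers(0, 2700))
            read = SeqRecord(f"r{i}", apply_errors(template[s:s + 250], profile, rng))
            for aln in align_read_to_template(read, idx):
                assert aln.q_end - aln.q_start == \
                    aln.matches + aln.mismatches + aln.q_gap_bases
                assert aln.t_end - aln.t_start == \
                    aln.matches + aln.mismatches + aln.t_gap_bases
                assert 0 <= aln.q_start < aln.q_end <= 250 + 50
                assert 0.0 <= aln.identity <= 1.0
                checked += 1
        assert checked > 10

    def test_seeded_reads_are_found(self):
        """Any read with a qualifying exact-tile cluster must be reported."""
        params = AlignerParams()
        template = random_dna(2000, 45)
        idx = build_template_index(template, params.tile_size, params.step_size)
        rng = np.random.default_rng(8)
        profile = nas.ErrorProfile(0.10, 0.05, 0.05, label="hot")
        found_with_cluster = 0
        for i in range(60):
            s = int(rng.integers(0, 1700))
            read_seq = apply_errors(template[s:s + 250], profile, rng)
            # oracle: count exact indexed tiles on the true diagonal band
            hits = []
            for q in range(0, len(read_seq) - params.tile_size + 1):
                for t in idx.lookup(read_seq[q:q + params.tile_size]):
                    if abs((t - q) - s) <= params.band_width:
                        hits.append((q, t))
            alns = align_read_to_template(SeqRecord(f"r{i}", read_seq), idx,
                                          params=params)
            if len(hits) >= params.min_seed_hits:
                found_with_cluster += 1
                assert alns, f"read {i} with {len(hits)} tile hits missed"
                spans = [(a.t_start, a.t_end) for a in alns]
                assert any(t0 < s + 250 and t1 > s for t0, t1 in spans)
        assert found_with_cluster > 20


class TestSelectSeedReads:
    def test_zero_error_reads_covering_template_all_selected(self, small_genome):
        template = small_genome.sequence[5000:7000]
        pairs = nas.simulate_read_pairs(small_genome, 10, error_rate=0.0, seed=12)
        seed_set = select_seed_reads(pairs, template)
        selected = set(seed_set.read_ids)
        fwd, rev = small_genome.sequence, reverse_complement(small_genome.sequence)
        for p in pairs:
            for rec in (p.fwd, p.rev):
                pos = fwd.find(rec.sequence)
                if pos < 0:
                    pos = len(fwd) - rev.find(rec.sequence) - len(rec.sequence)
                # fully inside the template window => must be a seed
                if 5000 <= pos and pos + len(rec.sequence) <= 7000:
                    assert rec.id in selected

    def test_unrelated_genome_yields_no_seeds(self, small_genome):
        other = nas.simulate_genome(20_000, seed=99)
        template = other.sequence[2000:5000]
        pairs = nas.simulate_read_pairs(small_genome, 5, seed=13)
        seed_set = select_seed_reads(pairs, template)
        assert seed_set.members == []

    def test_mate_of_seed_joins_set(self, small_genome):
        template = small_genome.sequence[5000:7000]
        pairs = nas.simulate_read_pairs(small_genome, 5, seed=14)
        seed_set = select_seed_reads(pairs, template)
        ids = set(seed_set.read_ids)
        for rid in ids:
            base, mate_no = rid.rsplit("/", 1)
            assert f"{base}/{'2' if mate_no == '1' else '1'}" in ids

    def test_high_error_regions_yield_fewer_seeds(self):
        """Seeds concentrate on accurate flanks, motivating recruitment."""
        genome = nas.simulate_genome(15_000, seed=55)
        rng = np.random.default_rng(3)
        flank_l = apply_errors(genome.sequence[4000:6000], nas.profile_2d(), rng)
        hot = apply_errors(genome.sequence[6000:8000], nas.profile_1d(), rng)
        flank_r = apply_errors(genome.sequence[8000:10000], nas.profile_2d(), rng)
        template = flank_l + hot + flank_r
        pairs = nas.simulate_read_pairs(genome, 30, seed=16)
        seed_set = select_seed_reads(pairs, template)
        mid = [0, 0]  # seeds with best alignment in the 1D-like core vs flanks
        for rid, alns in seed_set.alignments.items():
            centre = (alns[0].t_start + alns[0].t_end) / 2
            mid[0 if len(flank_l) < centre < len(flank_l) + len(hot) else 1] += 1
        assert mid[0] < mid[1]


class TestCoverageFilter:
    def _aln(self, rid, target, qf=1.0, ident=1.0):
        L = 250
        span = int(qf * L)
        matches = int(ident * span)
        return Alignment(rid, target, 0, span, 0, span, "+", matches,
                         span - matches, 0, 0, L)

    def test_multi_contig_reads_dropped(self):
        alns = [self._aln("r1", "cA"), self._aln("r1", "cB"), self._aln("r2", "cA")]
        kept = filter_alignments_for_coverage(alns)
        assert [a.query_id for a in kept] == ["r2"]

    def test_low_query_fraction_dropped(self):
        kept = filter_alignments_for_coverage([self._aln("r", "c", qf=0.4, ident=0.99)])
        assert kept == []

    def test_low_identity_dropped(self):
        kept = filter_alignments_for_coverage([self._aln("r", "c", ident=0.85)])
        assert kept == []

    def test_good_alignment_retained(self):
        kept = filter_alignments_for_coverage([self._aln("r", "c")])
        assert len(kept) == 1
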