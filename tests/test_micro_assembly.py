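import numpy as np
import pytest

import nas
from nas.micro_assembly import (AssemblyParams, assemble, compute_overlaps,
                                compute_seed_coverage, filter_contigs,
                                write_gfa)
from nas.micro_assembly import AssemblyResult, Contig
from nas.sequence_io import SeqRecord, reverse_complement
from nas.template_alignment import Alignment

from .conftest import random_dna


def tiling_reads(source: str, read_len: int, step: int, prefix: str = "r",
                 error_rate: float = 0.0, seed: int = 0):
    rng = np.random.default_rng(seed)
    reads = []
    i = 0
    for s in range(0, len(source) - read_len + 1, step):
        seq = source[s:s + read_len]
        if error_rate > 0:
            arr = list(seq)
            for j in range(len(arr)):
                if rng.random() < error_rate:
                    arr[j] = "ACGT"[(("ACGT".index(arr[j])) + int(rng.integers(1, 4))) % 4]
            seq = "".join(arr)
        reads.append(SeqRecord(f"{prefix}{i:04d}", seq))
        i += 1
    return reads


class TestComputeOverlaps:
    def test_simple_dovetail(self):
        g = random_dna(500, 1)
        r1, r2 = SeqRecord("r1", g[0:250]), SeqRecord("r2", g[150:400])
        (ovl,) = [o for o in compute_overlaps([r1, r2]) if o.contained is None]
        assert ovl.overlap_length == 100
        assert ovl.overlap_identity == 1.0
        assert {ovl.read_a, ovl.read_b} == {"r1", "r2"}

    def test_unrelated_reads_no_overlap(self):
        r1 = SeqRecord("r1", random_dna(250, 2))
        r2 = SeqRecord("r2", random_dna(250, 3))
        assert compute_overlaps([r1, r2]) == []

    def test_opposite_strand_overlap_detected(self):
        g = random_dna(500, 4)
        r1 = SeqRecord("r1", g[0:250])
        r2 = SeqRecord("r2", reverse_complement(g[150:400]))
        ovls = [o for o in compute_overlaps([r1, r2]) if o.contained is None]
        assert ovls and ovls[0].orientation == "opposite"
        assert ovls[0].overlap_length == 100

    def test_containment_flagged(self):
        g = random_dna(400, 5)
        ovls = compute_overlaps([SeqRecord("big", g), SeqRecord("small", g[100:300])])
        assert any(o.contained for o in ovls)

    def test_identity_threshold_respected(self):
        g = random_dna(300, 6)
        a = g[:200]
        b = list(g[100:300])
        for p in (10, 30, 50, 70, 90):  # 5 mismatches in a 100 bp overlap
            b[p] = "ACGT"[("ACGT".index(b[p]) + 1) % 4]
        ovls = [o for o in compute_overlaps([SeqRecord("a", a), SeqRecord("b", "".join(b))])
                if o.contained is None]
        assert ovls == []  # identity 0.95 < 0.98

    def test_duplicate_ids_rejected(self):
        r = SeqRecord("x", random_dna(100, 7))
        with pytest.raises(ValueError):
            compute_overlaps([r, r])


class TestAssemble:
    def test_unique_sequence_single_contig(self):
        source = random_dna(2000, 8)
        reads = tiling_reads(source, 250, 50)  # 5x depth
        result = assemble(reads)
        assert len(result.contigs) == 1
        assert result.contigs[0].sequence in source
        assert len(result.contigs[0]) >= len(source) - 250

    def test_empty_input_empty_result(self):
        result = assemble([])
        assert result.contigs == [] and result.adjacency == []

    def test_consensus_corrects_read_errors(self):
        source = random_dna(4000, 9)
        reads = tiling_reads(source, 250, 16, error_rate=0.005, seed=10)  # ~15x
        result = assemble(reads)
        longest = max(result.contigs, key=len)
        # interior consensus is essentially perfect under majority vote
        import edlib
        interior = longest.sequence[50:-50]
        d = edlib.align(interior, source, mode="HW", task="distance")["editDistance"]
        assert d / len(interior) < 0.0005

    def test_shared_repeat_creates_branched_contigs(self):
        rng_parts = [random_dna(900, s) for s in (11, 12, 13, 14)]
        repeat = random_dna(1000, 15)
        locus_a = rng_parts[0] + repeat + rng_parts[1]
        locus_b = rng_parts[2] + repeat + rng_parts[3]
        reads = (tiling_reads(locus_a, 250, 25, "a") +
                 tiling_reads(locus_b, 250, 25, "b"))
        result = assemble(reads)
        assert len(result.contigs) >= 3
        # the contig carrying the repeat interior is adjacent to >= 2 others
        core = repeat[300:700]
        repeat_contigs = [c.id for c in result.contigs if core in c.sequence]
        assert repeat_contigs
        assert any(len(result.neighbours(cid)) >= 2 for cid in repeat_contigs)

    def test_unoriented_reads_are_coherently_flipped(self):
        source = random_dna(1500, 16)
        reads = tiling_reads(source, 250, 60)
        flipped = [r if i % 2 else r.reverse_complement() for i, r in enumerate(reads)]
        result = assemble(flipped)
        assert len(result.contigs) == 1
        seq = result.contigs[0].sequence
        assert seq in source or reverse_complement(seq) in source


class TestSeedCoverageAndFilter:
    def _contig(self, cid, length, cov=None):
        return Contig(cid, "A" * length, seed_coverage=cov)

    def test_exact_tiling_depth(self):
        contig = self._contig("c", 250)
        alns = [Alignment(f"r{i}", "c", 0, 250, 0, 250, "+", 250, 0, 0, 0, 250)
                for i in range(10)]
        compute_seed_coverage([contig], alns)
        assert contig.seed_coverage == pytest.approx(10.0)

    def test_recruit_only_contig_zero(self):
        contig = self._contig("c", 500)
        compute_seed_coverage([contig], [])
        assert contig.seed_coverage == 0.0

    def test_matches_naive_depth_oracle(self):
        rng = np.random.default_rng(20)
        length = 1000
        contig = self._contig("c", length)
        alns = []
        depth = np.zeros(length)
        for i in range(60):
            s = int(rng.integers(0, length - 100))
            e = s + int(rng.integers(40, 100))
            alns.append(Alignment(f"r{i}", "c", 0, e - s, s, e, "+",
                                  e - s, 0, 0, 0, 250))
            depth[s:e] += 1
        compute_seed_coverage([contig], alns)
        assert contig.seed_coverage == pytest.approx(float(depth.mean()))

    def test_longest_and_covered_kept(self):
        result = AssemblyResult([self._contig("L", 5000, 2.0),
                                 self._contig("S", 1000, 50.0)])
        kept = {c.id for c in filter_contigs(result, 10).contigs}
        assert kept == {"L", "S"}

    def test_foreign_contig_removed(self):
        result = AssemblyResult([self._contig("L", 5000, 50.0),
                                 self._contig("F", 400, 3.0)],
                                adjacency=[("F", "L")])
        out = filter_contigs(result, 10)
        assert {c.id for c in out.contigs} == {"L"}
        assert out.adjacency == []

    def test_never_empty_on_nonempty_input(self):
        result = AssemblyResult([self._contig("only", 300, 0.0)])
        assert len(filter_contigs(result, 10).contigs) == 1

    def test_threshold_is_strict(self):
        result = AssemblyResult([self._contig("L", 5000, 50.0),
                                 self._contig("edge", 1000, 10.0)])
        assert {c.id for c in filter_contigs(result, 10).contigs} == {"L"}


def test_gfa_emission_round_trippable(tmp_path):
    result = AssemblyResult([Contig("c1", "ACGTACGT", seed_coverage=12.5),
                             Contig("c2", "TTTTCCCC", seed_coverage=3.0)],
                            adjacency=[("c1", "c2")])
    path = tmp_path / "asm.gfa"
    write_gfa(result, path)
    lines = path.read_text().splitlines()
    assert lines[0].startswith("H")
    assert sum(1 for ln in lines if ln.startswith("S")) == 2
    assert any(ln.startswith("L\tc1\t+\tc2") for ln in lines)
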