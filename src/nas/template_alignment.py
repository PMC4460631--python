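"""Seed-and-extend local alignment of accurate short reads to noisy templates.

Short reads are anchored on a template (or contig) through a sampled k-mer
word index — every ``tile_size``-mer taken each ``step_size`` bases, the
stringent-seeding configuration of the pipeline — then verified by a local
Smith-Waterman extension (+1 match, -1 mismatch, -1 gap by default).  Reads
that retain an alignment above the identity and query-fraction thresholds
become *seed-reads* for the micro-assembly; the same machinery filters
alignments for contig seed-coverage and for final read validation.

The DP kernel is compiled with numba; all index lookups are vectorised
over the whole read set at once so that aligning tens of thousands of
short reads against one template costs a handful of array operations plus
one small DP per candidate locus.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
from numba import njit

from .sequence_io import SeqRecord

logger = logging.getLogger("nas")

# base encoding: A,C,G,T -> 0..3; anything else (N) -> 4, never matches
_ENCODE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _ENCODE[_b] = _i
_RC_CODE = np.array([3, 2, 1, 0, 4], dtype=np.uint8)


def encode(seq: str) -> np.ndarray:
    return _ENCODE[np.frombuffer(seq.encode(), dtype=np.uint8)]


def rc_codes(codes: np.ndarray) -> np.ndarray:
    return _RC_CODE[codes][::-1]


def kmer_values(codes: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """(values, valid) for every k-window; uint64 wraps exactly at k=32."""
    n = len(codes)
    if n < k:
        return np.empty(0, dtype=np.uint64), np.empty(0, dtype=bool)
    m = n - k + 1
    vals = np.zeros(m, dtype=np.uint64)
    for j in range(k):
        vals = vals * np.uint64(4) + codes[j:m + j].astype(np.uint64)
    bad = (codes >= 4).astype(np.int32)
    cum = np.concatenate(([0], np.cumsum(bad)))
    valid = (cum[k:] - cum[:-k]) == 0
    return vals, valid


# ---------------------------------------------------------------------------
# Smith-Waterman kernel
# ---------------------------------------------------------------------------

@njit(cache=True)
def _sw_kernel(q, t, match, mismatch, gap):  # pragma: no cover - compiled
    nq, nt = len(q), len(t)
    H = np.zeros((nq + 1, nt + 1), np.int32)
    ptr = np.zeros((nq + 1, nt + 1), np.uint8)  # 1 diag, 2 up(q base vs gap), 3 left
    best = 0
    bi = 0
    bj = 0
    for i in range(1, nq + 1):
        qi = q[i - 1]
        for j in range(1, nt + 1):
            s = match if (qi == t[j - 1] and qi < 4) else mismatch
            h = H[i - 1, j - 1] + s
            p = 1
            u = H[i - 1, j] + gap
            if u > h:
                h = u
                p = 2
            l = H[i, j - 1] + gap
            if l > h:
                h = l
                p = 3
            if h <= 0:
                h = 0
                p = 0
            H[i, j] = h
            ptr[i, j] = p
            if h > best:
                best = h
                bi = i
                bj = j
    # traceback
    i, j = bi, bj
    matches = 0
    mismatches = 0
    q_gap = 0
    t_gap = 0
    while i > 0 and j > 0 and ptr[i, j] != 0:
        p = ptr[i, j]
        if p == 1:
            if q[i - 1] == t[j - 1] and q[i - 1] < 4:
                matches += 1
            else:
                mismatches += 1
            i -= 1
            j -= 1
        elif p == 2:
            q_gap += 1  # query base against a gap in the target
            i -= 1
        else:
            t_gap += 1  # target base against a gap in the query
            j -= 1
    return best, i, bi, j, bj, matches, mismatches, q_gap, t_gap


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AlignerParams:
    """Word-index and extension settings for short-read-to-template alignment."""

    tile_size: int = 10
    step_size: int = 5
    min_seed_hits: int = 2
    band_width: int = 50
    min_identity: float = 0.65
    min_query_fraction: float = 0.5
    match: int = 1
    mismatch: int = -1
    gap: int = -1
    max_positions_per_word: int = 100
    max_clusters_per_read: int = 4

    def __post_init__(self) -> None:
        if not 1 <= self.step_size <= self.tile_size:
            raise ValueError("require 1 <= step_size <= tile_size")


@dataclass
class Alignment:
    """A local alignment of a short read to a template or contig.

    Coordinates are 0-based half-open on the forward strands of both
    sequences; for strand '-', query coordinates refer to the original
    (un-complemented) read.  ``q_gap_bases`` counts query bases aligned to
    gaps (insertions w.r.t. the target); ``t_gap_bases`` the converse.
    """

    query_id: str
    target_id: str
    q_start: int
    q_end: int
    t_start: int
    t_end: int
    strand: str
    matches: int
    mismatches: int
    q_gap_bases: int
    t_gap_bases: int
    query_length: int
    score: int = 0

    @property
    def identity(self) -> float:
        cols = self.matches + self.mismatches + self.q_gap_bases + self.t_gap_bases
        return self.matches / cols if cols else 0.0

    @property
    def query_fraction(self) -> float:
        return (self.q_end - self.q_start) / self.query_length

    def to_tsv(self) -> str:
        """12-column PSL-like record (documented field order)."""
        return "\t".join(map(str, (
            self.query_id, self.target_id, self.strand,
            self.q_start, self.q_end, self.query_length,
            self.t_start, self.t_end,
            self.matches, self.mismatches,
            self.q_gap_bases, self.t_gap_bases)))


@dataclass
class SeedReadSet:
    """Seed-reads of one template: directly aligned reads plus their mates."""

    template_id: str
    members: list[tuple[str, str, str]] = field(default_factory=list)  # (read_id, orientation, provenance)
    alignments: dict[str, list[Alignment]] = field(default_factory=dict)

    @property
    def read_ids(self) -> list[str]:
        return [m[0] for m in self.members]

    def orientation_of(self, read_id: str) -> Optional[str]:
        for rid, ori, _prov in self.members:
            if rid == read_id:
                return ori
        return None


# ---------------------------------------------------------------------------
# template word index
# ---------------------------------------------------------------------------

class TemplateIndex:
    """Sampled k-mer positions of one template, sorted for batch lookup."""

    def __init__(self, template: str, tile_size: int = 10, step_size: int = 5):
        if not 1 <= step_size <= tile_size:
            raise ValueError("require 1 <= step_size <= tile_size")
        self.template = template
        self.tile_size = tile_size
        self.step_size = step_size
        self.codes = encode(template)
        if len(template) < tile_size:
            logger.warning("template shorter than tile_size; empty index")
            self._codes_sorted = np.empty(0, dtype=np.uint64)
            self._pos_sorted = np.empty(0, dtype=np.int64)
            return
        vals, valid = kmer_values(self.codes, tile_size)
        sample = np.arange(0, len(vals), step_size)
        sample = sample[valid[sample]]
        order = np.argsort(vals[sample], kind="stable")
        self._codes_sorted = vals[sample][order]
        self._pos_sorted = sample[order].astype(np.int64)

    def lookup(self, word: str) -> list[int]:
        """Template positions of one tile-sized word (empty if absent)."""
        if len(word) != self.tile_size:
            raise ValueError("word length must equal tile_size")
        vals, valid = kmer_values(encode(word), self.tile_size)
        if len(vals) == 0 or not valid[0]:
            return []
        lo = np.searchsorted(self._codes_sorted, vals[0], "left")
        hi = np.searchsorted(self._codes_sorted, vals[0], "right")
        return sorted(int(p) for p in self._pos_sorted[lo:hi])

    def __len__(self) -> int:
        return len(self._codes_sorted)


def build_template_index(template: str, tile_size: int = 10,
                         step_size: int = 5) -> TemplateIndex:
    return TemplateIndex(template, tile_size, step_size)


# ---------------------------------------------------------------------------
# read batches (k-mers precomputed once per read set)
# ---------------------------------------------------------------------------

class ReadBatch:
    """Encoded reads plus concatenated k-mer arrays on both strands."""

    def __init__(self, reads: Sequence[SeqRecord], k: int):
        self.reads = list(reads)
        self.k = k
        self.ids = [r.id for r in self.reads]
        self.codes_fwd = [encode(r.sequence) for r in self.reads]
        self.codes_rc = [rc_codes(c) for c in self.codes_fwd]
        self.lengths = np.array([len(r.sequence) for r in self.reads], dtype=np.int64)
        self._vals = {}
        self._starts = {}
        for strand, codes in (("+", self.codes_fwd), ("-", self.codes_rc)):
            pieces = []
            starts = np.zeros(len(codes) + 1, dtype=np.int64)
            for i, c in enumerate(codes):
                vals, valid = kmer_values(c, k)
                v = vals.copy()
                v[~valid] = np.uint64(0xFFFFFFFFFFFFFFFF)  # sentinel, never indexed
                pieces.append(v)
                starts[i + 1] = starts[i] + len(v)
            self._vals[strand] = (np.concatenate(pieces) if pieces
                                  else np.empty(0, dtype=np.uint64))
            self._starts[strand] = starts

    def kmers(self, strand: str) -> tuple[np.ndarray, np.ndarray]:
        return self._vals[strand], self._starts[strand]


# ---------------------------------------------------------------------------
# alignment
# ---------------------------------------------------------------------------

def _diagonal_fast_path(qcodes: np.ndarray, tpl_codes: np.ndarray,
                        diag: int, params: AlignerParams) -> Optional[tuple]:
    """Gap-free scoring when all seed hits sit on one diagonal.

    Near-exact alignments (accurate reads against contigs or merged
    candidates) need no DP; terminal mismatches are trimmed to match the
    local-alignment convention.  Returns None when the gap-free identity
    is too low to trust, falling back to full DP.
    """
    L = len(qcodes)
    q_lo = max(0, -diag)
    q_hi = min(L, len(tpl_codes) - diag)
    if q_hi - q_lo < params.tile_size:
        return None
    qseg = qcodes[q_lo:q_hi]
    tseg = tpl_codes[diag + q_lo:diag + q_hi]
    eq = (qseg == tseg) & (qseg < 4)
    if not eq.any():
        return None
    # gap-free local alignment == maximum-score subarray on the diagonal
    vals = np.where(eq, params.match, params.mismatch).astype(np.int64)
    prefix = np.concatenate(([0], np.cumsum(vals)))
    run_min = np.minimum.accumulate(prefix[:-1])
    scores = prefix[1:] - run_min
    end = int(scores.argmax())
    score = int(scores[end])
    if score <= 0:
        return None
    start = int(np.nonzero(prefix[:end + 1] == run_min[end])[0][0])
    span = end + 1 - start
    matches = int(eq[start:end + 1].sum())
    if matches / span < 0.90:
        return None  # too noisy for the gap-free model; use full DP
    if span < 0.9 * (q_hi - q_lo):
        return None  # indels likely truncate the diagonal; needs gapped DP
    mismatches = span - matches
    qs, qe = q_lo + start, q_lo + end + 1
    return (score, qs, qe, diag + qs, diag + qe, matches, mismatches, 0, 0)


def _extend_cluster(qcodes: np.ndarray, tpl_codes: np.ndarray,
                    qpos: np.ndarray, tpos: np.ndarray,
                    params: AlignerParams) -> Optional[tuple]:
    L = len(qcodes)
    diag = tpos - qpos
    if diag.min() == diag.max():
        fast = _diagonal_fast_path(qcodes, tpl_codes, int(diag[0]), params)
        if fast is not None:
            return fast
    pad = params.band_width + max(20, L // 5)
    t_lo = max(0, int((tpos - qpos).min()) - pad)
    t_hi = min(len(tpl_codes), int((tpos + (L - qpos)).max()) + pad)
    if t_hi - t_lo < params.tile_size:
        return None
    res = _sw_kernel(qcodes, tpl_codes[t_lo:t_hi],
                     params.match, params.mismatch, params.gap)
    score, qs, qe, ts, te, matches, mismatches, q_gap, t_gap = res
    if score <= 0:
        return None
    return score, qs, qe, t_lo + ts, t_lo + te, matches, mismatches, q_gap, t_gap


def _alignment_sort_key(a: Alignment):
    return (-a.score, a.t_start, 0 if a.strand == "+" else 1, a.q_start)


def align_reads_to_template(batch: ReadBatch, index: TemplateIndex,
                            params: AlignerParams,
                            target_id: str = "template") -> dict[str, list[Alignment]]:
    """Align every read of a batch against one indexed template.

    Returns retained alignments per read id, best-first.  Reads without a
    qualifying seed-hit cluster are absent from the result.
    """
    if batch.k != index.tile_size:
        raise ValueError("batch k-mer length must equal index tile_size")
    out: dict[str, list[Alignment]] = {}
    n_reads = len(batch.reads)
    if n_reads == 0 or len(index) == 0:
        return out
    for strand in ("+", "-"):
        vals, starts = batch.kmers(strand)
        if len(vals) == 0:
            continue
        lo = np.searchsorted(index._codes_sorted, vals, "left")
        hi = np.searchsorted(index._codes_sorted, vals, "right")
        counts = np.minimum(hi - lo, params.max_positions_per_word)
        hit_kmer = np.nonzero(counts > 0)[0]
        if len(hit_kmer) == 0:
            continue
        c = counts[hit_kmer]
        rep_kmer = np.repeat(hit_kmer, c)
        # within-group offsets 0..c-1 to expand multi-position words
        csum = np.concatenate(([0], np.cumsum(c)))
        within = np.arange(csum[-1]) - np.repeat(csum[:-1], c)
        tpl_pos = index._pos_sorted[np.repeat(lo[hit_kmer], c) + within]
        read_idx = np.searchsorted(starts, rep_kmer, "right") - 1
        q_pos = rep_kmer - starts[read_idx]
        # group hits by read
        order = np.lexsort((tpl_pos - q_pos, read_idx))
        read_idx, q_pos, tpl_pos = read_idx[order], q_pos[order], tpl_pos[order]
        bounds = np.nonzero(np.diff(read_idx))[0] + 1
        for grp_lo, grp_hi in zip(np.concatenate(([0], bounds)),
                                  np.concatenate((bounds, [len(read_idx)]))):
            if grp_hi - grp_lo < params.min_seed_hits:
                continue
            ridx = int(read_idx[grp_lo])
            qp = q_pos[grp_lo:grp_hi]
            tp = tpl_pos[grp_lo:grp_hi]
            diag = tp - qp  # already sorted by diagonal
            splits = np.nonzero(np.diff(diag) > params.band_width)[0] + 1
            clusters = []
            for c_lo, c_hi in zip(np.concatenate(([0], splits)),
                                  np.concatenate((splits, [len(diag)]))):
                if c_hi - c_lo >= params.min_seed_hits:
                    clusters.append((c_hi - c_lo, c_lo, c_hi))
            clusters.sort(reverse=True)
            qcodes = (batch.codes_fwd if strand == "+" else batch.codes_rc)[ridx]
            L = int(batch.lengths[ridx])
            rid = batch.ids[ridx]
            seen: set[tuple] = set()
            for _, c_lo, c_hi in clusters[:params.max_clusters_per_read]:
                ext = _extend_cluster(qcodes, index.codes, qp[c_lo:c_hi],
                                      tp[c_lo:c_hi], params)
                if ext is None:
                    continue
                score, qs, qe, ts, te, mat, mis, qg, tg = ext
                if strand == "-":
                    qs, qe = L - qe, L - qs
                aln = Alignment(rid, target_id, qs, qe, ts, te, strand,
                                mat, mis, qg, tg, L, score)
                if (aln.identity < params.min_identity
                        or aln.query_fraction < params.min_query_fraction):
                    continue
                key = (qs, qe, ts, te, strand)
                if key in seen:
                    continue
                seen.add(key)
                out.setdefault(rid, []).append(aln)
    for alns in out.values():
        alns.sort(key=_alignment_sort_key)
    return out


def align_read_to_template(read: SeqRecord, index: TemplateIndex,
                           template: str = None,
                           params: AlignerParams = AlignerParams()) -> list[Alignment]:
    """Single-read convenience wrapper around :func:`align_reads_to_template`."""
    batch = ReadBatch([read], params.tile_size)
    return align_reads_to_template(batch, index, params).get(read.id, [])


def select_seed_reads(pairs, template, params: AlignerParams = AlignerParams(),
                      template_id: str = "template",
                      batch: Optional[ReadBatch] = None) -> SeedReadSet:
    """Stringently align short reads to the template and collect seed-reads.

    A read with at least one retained alignment is a seed; its mate joins
    the set as well (both marked provenance ``seed``), with the mate's
    orientation implied by the innie pair geometry.
    """
    reads = [r for p in pairs for r in (p.fwd, p.rev)]
    mate_of: dict[str, str] = {}
    for p in pairs:
        mate_of[p.fwd.id] = p.rev.id
        mate_of[p.rev.id] = p.fwd.id
    if batch is None:
        batch = ReadBatch(reads, params.tile_size)
    index = template if isinstance(template, TemplateIndex) else \
        build_template_index(template, params.tile_size, params.step_size)
    alns = align_reads_to_template(batch, index, params, target_id=template_id)
    seed_set = SeedReadSet(template_id)
    chosen: dict[str, str] = {}
    for rid in sorted(alns):
        chosen[rid] = alns[rid][0].strand
    for rid, ori in list(sorted(chosen.items())):
        mate = mate_of.get(rid)
        if mate is not None and mate not in chosen:
            chosen[mate] = "-" if ori == "+" else "+"
    for rid in sorted(chosen):
        seed_set.members.append((rid, chosen[rid], "seed"))
        if rid in alns:
            seed_set.alignments[rid] = alns[rid]
    return seed_set


def filter_alignments_for_coverage(alignments: Iterable[Alignment],
                                   min_identity: float = 0.90,
                                   min_query_fraction: float = 0.50) -> list[Alignment]:
    """Quality filter behind contig seed-coverage.

    Reads aligning to more than one distinct contig are removed outright
    (repeat/foreign ambiguity); remaining alignments must cover at least
    half the read at 90% identity or better.
    """
    alignments = list(alignments)
    targets: dict[str, set[str]] = {}
    for a in alignments:
        targets.setdefault(a.query_id, set()).add(a.target_id)
    return [a for a in alignments
            if len(targets[a.query_id]) == 1
            and a.query_fraction >= min_query_fraction
            and a.identity >= min_identity]
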