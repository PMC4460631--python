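"""K-mer similarity recruitment of short reads into a template's seed set.

Template regions with error rates in the 40% range rarely yield direct
seed alignments; the reads covering them are recovered indirectly instead.
Every canonical 32-mer of the seed-reads goes into an index, and any read
of the full collection sharing at least ``t`` *non-overlapping* indexed
k-mers (greedy earliest-end interval scheduling, which is optimal for
counting disjoint intervals) is recruited together with its mate.
Canonical (strand-collapsed) words make recruitment orientation-blind.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np

from .sequence_io import SeqRecord
from .template_alignment import encode, kmer_values, rc_codes

_SENTINEL = np.uint64(0xFFFFFFFFFFFFFFFF)


def canonical_kmers(seq: str, k: int) -> tuple[np.ndarray, np.ndarray]:
    """(canonical values, positions) of all valid k-mers of ``seq``."""
    codes = encode(seq)
    if len(codes) < k:
        return np.empty(0, dtype=np.uint64), np.empty(0, dtype=np.int64)
    fwd, valid_f = kmer_values(codes, k)
    rev, _ = kmer_values(rc_codes(codes), k)
    rev_aligned = rev[::-1]  # rc value of the window starting at i
    canon = np.minimum(fwd, rev_aligned)
    pos = np.nonzero(valid_f)[0]
    return canon[valid_f], pos.astype(np.int64)


@dataclass
class KmerIndex:
    """Sorted canonical k-mer set drawn from seed-read sequences."""

    k: int
    words: np.ndarray  # sorted uint64 canonical codes, unique

    def __contains__(self, word) -> bool:
        if isinstance(word, str):
            vals, _ = canonical_kmers(word, self.k)
            if len(vals) == 0:
                return False
            word = vals[0]
        i = np.searchsorted(self.words, np.uint64(word))
        return bool(i < len(self.words) and self.words[i] == np.uint64(word))

    def __len__(self) -> int:
        return len(self.words)


def index_seed_kmers(seed_sequences: Iterable[str | SeqRecord], k: int = 32) -> KmerIndex:
    """Index every canonical k-mer of every seed-read (both mates included)."""
    if k < 1:
        raise ValueError("k must be >= 1")
    pieces = []
    for s in seed_sequences:
        seq = s.sequence if isinstance(s, SeqRecord) else s
        vals, _ = canonical_kmers(seq, k)
        if len(vals):
            pieces.append(vals)
    if not pieces:
        return KmerIndex(k, np.empty(0, dtype=np.uint64))
    return KmerIndex(k, np.unique(np.concatenate(pieces)))


class CanonicalKmerCache:
    """Concatenated canonical k-mers of a fixed read set, computed once."""

    def __init__(self, reads: Sequence[SeqRecord], k: int):
        self.k = k
        self.ids = [r.id for r in reads]
        vals_pieces = []
        pos_pieces = []
        self.starts = np.zeros(len(reads) + 1, dtype=np.int64)
        for i, r in enumerate(reads):
            vals, pos = canonical_kmers(r.sequence, k)
            vals_pieces.append(vals)
            pos_pieces.append(pos)
            self.starts[i + 1] = self.starts[i] + len(vals)
        self.vals = (np.concatenate(vals_pieces) if vals_pieces
                     else np.empty(0, dtype=np.uint64))
        self.pos = (np.concatenate(pos_pieces) if pos_pieces
                    else np.empty(0, dtype=np.int64))


def _count_disjoint(positions: np.ndarray, k: int) -> int:
    """Greedy earliest-end count of non-overlapping k-mer hits."""
    n = 0
    last_end = -1
    for p in positions:
        if p >= last_end:
            n += 1
            last_end = p + k
    return n


@dataclass
class RecruitResult:
    """Reads recruited by the disjoint-k-mer criterion, plus mate riders.

    ``matched`` holds reads that themselves satisfy the >= t disjoint
    indexed k-mers criterion; ``with_mates`` additionally includes their
    mates.  Iteration and membership refer to ``matched``.
    """

    matched: frozenset[str]
    with_mates: frozenset[str] = field(default=None)

    def __post_init__(self):
        if self.with_mates is None:
            self.with_mates = self.matched

    def __iter__(self):
        return iter(sorted(self.matched))

    def __contains__(self, rid) -> bool:
        return rid in self.matched

    def __len__(self) -> int:
        return len(self.matched)


def recruit_reads(index: KmerIndex, all_pairs, t: int = 3,
                  exclude: Optional[set[str]] = None,
                  cache: Optional[CanonicalKmerCache] = None) -> RecruitResult:
    """Recruit reads sharing >= t non-overlapping indexed k-mers.

    ``all_pairs`` may be ReadPair objects or bare SeqRecords.  When a read
    matches, its mate joins ``with_mates``.  Ids in ``exclude`` (the seed
    set) are not re-reported.
    """
    reads: list[SeqRecord] = []
    mate_of: dict[str, str] = {}
    for item in all_pairs:
        if hasattr(item, "fwd"):
            reads.extend((item.fwd, item.rev))
            mate_of[item.fwd.id] = item.rev.id
            mate_of[item.rev.id] = item.fwd.id
        else:
            reads.append(item)
    exclude = exclude or set()
    if cache is None:
        cache = CanonicalKmerCache(reads, index.k)
    elif cache.k != index.k:
        raise ValueError("cache k-mer length must match index")
    matched: set[str] = set()
    if len(index) and len(cache.vals):
        idx = np.searchsorted(index.words, cache.vals)
        idx[idx >= len(index.words)] = len(index.words) - 1
        member = index.words[idx] == cache.vals
        hit_read = np.searchsorted(cache.starts, np.nonzero(member)[0], "right") - 1
        hit_pos = cache.pos[member]
        order = np.lexsort((hit_pos, hit_read))
        hit_read, hit_pos = hit_read[order], hit_pos[order]
        bounds = np.nonzero(np.diff(hit_read))[0] + 1
        for lo, hi in zip(np.concatenate(([0], bounds)),
                          np.concatenate((bounds, [len(hit_read)]))):
            if hi - lo < t:
                continue
            rid = cache.ids[int(hit_read[lo])]
            if rid in exclude:
                continue
            if _count_disjoint(hit_pos[lo:hi], index.k) >= t:
                matched.add(rid)
    with_mates = set(matched)
    for rid in matched:
        mate = mate_of.get(rid)
        if mate is not None and mate not in exclude:
            with_mates.add(mate)
    return RecruitResult(frozenset(matched), frozenset(with_mates))


def orientation_votes(read: SeqRecord, forward_words: np.ndarray, k: int) -> tuple[int, int]:
    """(forward, reverse) counts of the read's k-mers found in an oriented word set.

    Used to place recruited reads on the template strand before assembly:
    ``forward_words`` holds plain (non-canonical) k-mers of the already
    oriented seed-reads.
    """
    codes = encode(read.sequence)
    if len(codes) < k or len(forward_words) == 0:
        return 0, 0

    def count(vals):
        if len(vals) == 0:
            return 0
        idx = np.searchsorted(forward_words, vals)
        idx[idx >= len(forward_words)] = len(forward_words) - 1
        return int((forward_words[idx] == vals).sum())

    fwd, valid_f = kmer_values(codes, k)
    rev, valid_r = kmer_values(rc_codes(codes), k)
    return count(fwd[valid_f]), count(rev[valid_r])


def forward_kmer_set(sequences: Iterable[str], k: int) -> np.ndarray:
    """Sorted plain-strand k-mer values of already-oriented sequences."""
    pieces = []
    for seq in sequences:
        codes = encode(seq)
        vals, valid = kmer_values(codes, k)
        if len(vals):
            pieces.append(vals[valid])
    if not pieces:
        return np.empty(0, dtype=np.uint64)
    return np.unique(np.concatenate(pieces))
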