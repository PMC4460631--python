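"""Overlap-layout-consensus micro-assembly of one template's read set.

The seed and recruited reads of a single long-read template are assembled
into contigs: all suffix-prefix overlaps above a stringent identity
threshold (default 98%, exploiting short-read accuracy) are found via
shared-word prefiltering and verified base-by-base; the overlap graph is
transitively reduced (Myers-style) and unambiguous paths become unitig
contigs with a column-majority consensus.  Branch points — the signature
of repeats and of foreign reads recruited from look-alike loci — terminate
contigs and are recorded as undirected adjacency edges, the structure the
downstream contig-graph resolution traverses.  Contig ends follow the
outermost read rather than being clipped at a depth cutoff, so low-covered
tips extend the contig (avoiding breaks in thin regions).
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import edlib
import numpy as np

from .sequence_io import SeqRecord, reverse_complement
from .template_alignment import Alignment, encode, kmer_values

logger = logging.getLogger("nas")

_PREFILTER_K = 15
_PREFILTER_WINDOW = 8
_OFFSET_FUZZ = 3


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Overlap:
    """A verified suffix-prefix (or containment) overlap between two reads.

    ``offset`` is where ``read_b`` starts in ``read_a`` coordinates after
    orienting ``read_b`` per ``orientation`` ('same' or 'opposite').
    ``contained`` marks full containment ('b_in_a' / 'a_in_b') instead of a
    proper dovetail.
    """

    read_a: str
    read_b: str
    offset: int
    orientation: str
    overlap_length: int
    overlap_identity: float
    contained: Optional[str] = None


@dataclass
class Contig:
    """A unitig consensus with its member read placements."""

    id: str
    sequence: str
    members: list[tuple[str, int, str]] = field(default_factory=list)  # (read_id, offset, orientation)
    seed_coverage: Optional[float] = None

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class AssemblyResult:
    contigs: list[Contig] = field(default_factory=list)
    adjacency: list[tuple[str, str]] = field(default_factory=list)  # sorted id pairs

    def contig(self, cid: str) -> Contig:
        for c in self.contigs:
            if c.id == cid:
                return c
        raise KeyError(cid)

    def neighbours(self, cid: str) -> list[str]:
        out = []
        for a, b in self.adjacency:
            if a == cid:
                out.append(b)
            elif b == cid:
                out.append(a)
        return sorted(out)


@dataclass(frozen=True)
class AssemblyParams:
    min_overlap: int = 40
    min_overlap_identity: float = 0.98


# ---------------------------------------------------------------------------
# overlap detection
# ---------------------------------------------------------------------------

def _minimizers(seq: str, k: int = _PREFILTER_K,
                w: int = _PREFILTER_WINDOW) -> list[tuple[int, int]]:
    """(value, position) winnowing minimizers of ``seq``.

    Window-minimum sampling is position-stable: two reads sharing genomic
    context select the same words at the same genomic positions, so every
    true overlap yields shared entries regardless of the offset between
    the reads (plain strided sampling would only detect offsets that are
    multiples of the stride).
    """
    codes = encode(seq)
    if len(codes) < k:
        return []
    vals, valid = kmer_values(codes, k)
    # mix bits so ties/low-complexity don't all pick the same end
    mixed = (vals * np.uint64(0x9E3779B97F4A7C15)) ^ (vals >> np.uint64(31))
    mixed = mixed.copy()
    mixed[~valid] = np.uint64(0xFFFFFFFFFFFFFFFF)
    n = len(mixed)
    if n <= w:
        p = int(np.argmin(mixed))
        return [(int(vals[p]), p)] if valid[p] else []
    win = np.lib.stride_tricks.sliding_window_view(mixed, w)
    arg = win.argmin(axis=1) + np.arange(n - w + 1)
    out = []
    seen = -1
    for p in arg:
        if p != seen:
            seen = int(p)
            if valid[seen]:
                out.append((int(vals[seen]), seen))
    return out

def _verify_offset(sa: str, sb: str, offset: int,
                   min_identity: float) -> Optional[tuple[int, float]]:
    """Check the candidate placement of b at ``offset`` within a's coords."""
    if offset >= 0:
        a_lo, b_lo = offset, 0
    else:
        a_lo, b_lo = 0, -offset
    span = min(len(sa) - a_lo, len(sb) - b_lo)
    if span <= 0:
        return None
    seg_a = sa[a_lo:a_lo + span]
    seg_b = sb[b_lo:b_lo + span]
    arr_a = np.frombuffer(seg_a.encode(), dtype=np.uint8)
    arr_b = np.frombuffer(seg_b.encode(), dtype=np.uint8)
    ident = float((arr_a == arr_b).mean())
    if ident < min_identity:
        # allow a small-indel rescue via banded edit distance
        res = edlib.align(seg_b, seg_a, task="distance", k=max(2, int(span * (1 - min_identity)) + 2))
        if res["editDistance"] < 0:
            return None
        ident = 1.0 - res["editDistance"] / span
        if ident < min_identity:
            return None
    return span, ident


def compute_overlaps(reads: Sequence[SeqRecord], min_overlap: int = 40,
                     min_overlap_identity: float = 0.98,
                     assume_oriented: bool = False) -> list[Overlap]:
    """All pairwise dovetail/containment overlaps meeting the thresholds.

    Candidate placements come from shared sampled words; each candidate
    offset is verified over the full implied overlap.  With
    ``assume_oriented`` only same-strand overlaps are considered.
    """
    ids = [r.id for r in reads]
    if len(set(ids)) != len(ids):
        raise ValueError("reads must be deduplicated by id")
    seqs = {r.id: r.sequence for r in reads}
    buckets: dict[int, list[tuple[int, int, int]]] = defaultdict(list)  # word -> (read_idx, pos, strand)
    for i, r in enumerate(reads):
        variants = [(r.sequence, 0)]
        if not assume_oriented:
            variants.append((reverse_complement(r.sequence), 1))
        for seq, strand in variants:
            for word, p in _minimizers(seq):
                buckets[word].append((i, p, strand))
    candidates: set[tuple[int, int, str, int]] = set()
    for word in sorted(buckets):
        entries = buckets[word]
        if len(entries) > 80:
            entries = entries[:80]
        for ia, pa, sa_str in entries:
            la = len(reads[ia].sequence)
            for ib, pb, sb_str in entries:
                if ib <= ia:
                    continue
                lb = len(reads[ib].sequence)
                if sa_str == 0 and sb_str == 0:
                    candidates.add((ia, ib, "same", pa - pb))
                elif sa_str == 0 and sb_str == 1:
                    # pb is a position on rc(b); offset of rc(b) within a
                    candidates.add((ia, ib, "opposite", pa - pb))
                elif sa_str == 1 and sb_str == 1:
                    # both on rc strand: same orientation in forward coords
                    candidates.add((ia, ib, "same", (la - pa) - (lb - pb)))
                else:
                    # word on rc(a) and fwd(b): a vs rc(b) in forward coords
                    candidates.add((ia, ib, "opposite", (la - pa) - (lb - pb)))
    overlaps: list[Overlap] = []
    for ia, ib, orientation, offset in sorted(candidates):
        ra, rb = reads[ia], reads[ib]
        sb = rb.sequence if orientation == "same" else reverse_complement(rb.sequence)
        ver = _verify_offset(ra.sequence, sb, offset, min_overlap_identity)
        if ver is None:
            continue
        span, ident = ver
        la, lb = len(ra.sequence), len(sb)
        contained = None
        if offset >= 0 and offset + lb <= la:
            contained = "b_in_a"
        elif offset <= 0 and -offset + la <= lb:
            contained = "a_in_b"
        elif span < min_overlap:
            continue
        overlaps.append(Overlap(ra.id, rb.id, offset, orientation, span, ident, contained))
    overlaps.sort(key=lambda o: (o.read_a, o.read_b, o.orientation, o.offset))
    return overlaps


# ---------------------------------------------------------------------------
# layout and consensus
# ---------------------------------------------------------------------------

def _orient_reads(reads: Sequence[SeqRecord],
                  orientations: Optional[dict[str, str]]) -> tuple[list[SeqRecord], dict[str, str]]:
    """Flip '-' reads onto the common strand; infer labels when not given."""
    if orientations is None:
        # label propagation over opposite-orientation overlaps
        ovls = compute_overlaps(reads, min_overlap=40, assume_oriented=False)
        adj: dict[str, list[tuple[str, int]]] = defaultdict(list)
        for o in ovls:
            flip = 1 if o.orientation == "opposite" else 0
            adj[o.read_a].append((o.read_b, flip))
            adj[o.read_b].append((o.read_a, flip))
        orientations = {}
        for r in reads:
            if r.id in orientations:
                continue
            orientations[r.id] = "+"
            stack = [r.id]
            while stack:
                u = stack.pop()
                for v, flip in adj.get(u, ()):
                    want = orientations[u] if not flip else ("-" if orientations[u] == "+" else "+")
                    if v not in orientations:
                        orientations[v] = want
                        stack.append(v)
    oriented = []
    for r in reads:
        if orientations.get(r.id, "+") == "-":
            oriented.append(r.reverse_complement())
        else:
            oriented.append(r)
    return oriented, orientations


def assemble(reads: Sequence[SeqRecord],
             params: AssemblyParams = AssemblyParams(),
             orientations: Optional[dict[str, str]] = None) -> AssemblyResult:
    """OLC assembly: overlaps -> transitive reduction -> unitigs -> consensus.

    ``orientations`` maps read ids to the strand they should enter the
    layout on (as recorded at seeding/recruitment); when absent it is
    inferred from opposite-strand overlaps.
    """
    if not reads:
        return AssemblyResult()
    oriented, orientations = _orient_reads(reads, orientations)

    # collapse byte-identical duplicates onto one representative
    by_seq: dict[str, list[SeqRecord]] = defaultdict(list)
    for r in oriented:
        by_seq[r.sequence].append(r)
    reps: list[SeqRecord] = []
    dup_of: dict[str, str] = {}
    for seq in by_seq:
        group = sorted(by_seq[seq], key=lambda r: r.id)
        reps.append(group[0])
        for extra in group[1:]:
            dup_of[extra.id] = group[0].id
    reps.sort(key=lambda r: r.id)

    ovls = compute_overlaps(reps, params.min_overlap, params.min_overlap_identity,
                            assume_oriented=True)
    seqs = {r.id: r.sequence for r in reps}

    # containment removal; resolve nested containments to a live host
    container: dict[str, tuple[str, int]] = {}
    for o in ovls:
        if o.contained == "b_in_a" and o.read_b not in container:
            container[o.read_b] = (o.read_a, o.offset)
        elif o.contained == "a_in_b" and o.read_a not in container:
            container[o.read_a] = (o.read_b, -o.offset)
    live = {r.id for r in reps} - set(container)
    for rid in sorted(container):
        host, off = container[rid]
        hops = 0
        while host in container and hops < len(container):
            host, off2 = container[host]
            off += off2
            hops += 1
        container[rid] = (host, off)

    # directed dovetail edges among live reads: b starts offset>0 into a
    edges: dict[str, dict[str, int]] = defaultdict(dict)
    for o in ovls:
        if o.contained is not None:
            continue
        if o.read_a not in live or o.read_b not in live:
            continue
        if o.offset > 0:
            u, v, off = o.read_a, o.read_b, o.offset
        elif o.offset < 0:
            u, v, off = o.read_b, o.read_a, -o.offset
        else:
            continue
        if v not in edges[u] or off < edges[u][v]:
            edges[u][v] = off

    # Myers transitive reduction with offset consistency (fuzz for rare indels)
    reduced: dict[str, dict[str, int]] = {u: dict(vs) for u, vs in edges.items()}
    for u in sorted(edges):
        succ = sorted(edges[u].items(), key=lambda kv: kv[1])
        for w, off_uw in succ:
            for x, off_wx in edges.get(w, {}).items():
                if x in reduced.get(u, {}) and x != w:
                    if abs(off_uw + off_wx - edges[u][x]) <= _OFFSET_FUZZ:
                        reduced[u].pop(x, None)

    out_deg = {u: len(vs) for u, vs in reduced.items() if vs}
    in_deg: dict[str, int] = defaultdict(int)
    for u, vs in reduced.items():
        for v in vs:
            in_deg[v] += 1

    def is_chain_edge(u: str, v: str) -> bool:
        return out_deg.get(u, 0) == 1 and in_deg.get(v, 0) == 1

    # build maximal chains of chain-edges
    chain_next: dict[str, str] = {}
    chain_prev: dict[str, str] = {}
    for u in sorted(reduced):
        if out_deg.get(u, 0) == 1:
            (v, _off), = reduced[u].items()
            if is_chain_edge(u, v):
                chain_next[u] = v
                chain_prev[v] = u
    chains: list[list[str]] = []
    placed: set[str] = set()
    for u in sorted(live):
        if u in placed or u in chain_prev:
            continue
        chain = [u]
        placed.add(u)
        while chain[-1] in chain_next:
            nxt = chain_next[chain[-1]]
            if nxt in placed:
                break
            chain.append(nxt)
            placed.add(nxt)
        chains.append(chain)
    for u in sorted(live - placed):  # cycles (rare): break arbitrarily
        chains.append([u])
        placed.add(u)

    # consensus per chain
    chain_of: dict[str, int] = {}
    contigs_raw: list[tuple[str, list[tuple[str, int, str]]]] = []
    for ci, chain in enumerate(chains):
        coords = {chain[0]: 0}
        for u, v in zip(chain, chain[1:]):
            coords[v] = coords[u] + reduced[u][v]
        for rid in chain:
            chain_of[rid] = ci
        placements = [(rid, coords[rid]) for rid in chain]
        # anchor contained reads to their container's chain
        for rid in sorted(container):
            host, off = container[rid]
            if host in coords:
                placements.append((rid, coords[host] + off))
                chain_of[rid] = ci
        # duplicates ride on their representative
        extra = []
        for dup, rep in sorted(dup_of.items()):
            for rid, off in placements:
                if rid == rep:
                    extra.append((dup, off))
                    break
        placements.extend(extra)
        placements.sort(key=lambda t: (t[1], t[0]))

        def seq_of(rid: str) -> str:
            return seqs[rid] if rid in seqs else seqs[dup_of[rid]]

        base = min(off for _rid, off in placements)
        if base != 0:  # containment offsets may reach left of the chain head
            placements = [(rid, off - base) for rid, off in placements]
        length = max(off + len(seq_of(rid)) for rid, off in placements)
        counts = np.zeros((4, length), dtype=np.int32)
        backbone = np.full(length, 4, dtype=np.uint8)
        for rid, off in placements:
            codes = encode(seq_of(rid))
            span = slice(off, off + len(codes))
            ok = codes < 4
            np.add.at(counts, (codes[ok], np.arange(off, off + len(codes))[ok]), 1)
            fill = backbone[span] == 4
            seg = backbone[span]
            seg[fill] = codes[fill]
            backbone[span] = seg
        best = counts.argmax(axis=0).astype(np.uint8)
        best_count = counts.max(axis=0)
        bb_safe = np.where(backbone < 4, backbone, best)
        bb_count = counts[bb_safe, np.arange(length)]
        consensus_codes = np.where(best_count > bb_count, best, bb_safe)
        consensus = "".join("ACGTN"[c] for c in consensus_codes)
        members = [(rid, off, orientations.get(rid, "+")) for rid, off in placements]
        contigs_raw.append((consensus, members))

    # adjacency from branch (non-chain) reduced edges
    adj_pairs: set[tuple[int, int]] = set()
    for u in sorted(reduced):
        for v in sorted(reduced[u]):
            cu, cv = chain_of.get(u), chain_of.get(v)
            if cu is None or cv is None or cu == cv:
                continue
            adj_pairs.add((min(cu, cv), max(cu, cv)))

    # stable ids by decreasing length
    order = sorted(range(len(contigs_raw)),
                   key=lambda i: (-len(contigs_raw[i][0]), contigs_raw[i][1][0][0]))
    id_of = {ci: f"contig_{rank:03d}" for rank, ci in enumerate(order, start=1)}
    contigs = [Contig(id_of[ci], contigs_raw[ci][0], contigs_raw[ci][1])
               for ci in order]
    adjacency = sorted({tuple(sorted((id_of[a], id_of[b]))) for a, b in adj_pairs})
    return AssemblyResult(contigs, adjacency)


# ---------------------------------------------------------------------------
# seed coverage and contig filtering
# ---------------------------------------------------------------------------

def compute_seed_coverage(contigs: Sequence[Contig],
                          seed_alignments: Iterable[Alignment]) -> list[Contig]:
    """Populate ``seed_coverage`` = mean per-base depth of retained seed alignments.

    ``seed_alignments`` must already have passed
    :func:`~nas.template_alignment.filter_alignments_for_coverage`; reads
    only present through recruitment contribute nothing.
    """
    span_sum: dict[str, int] = defaultdict(int)
    for a in seed_alignments:
        span_sum[a.target_id] += a.t_end - a.t_start
    for c in contigs:
        c.seed_coverage = span_sum.get(c.id, 0) / len(c.sequence) if len(c.sequence) else 0.0
    return list(contigs)


def filter_contigs(result: AssemblyResult, min_cov1: float = 10.0) -> AssemblyResult:
    """Keep the longest contig plus every contig with seed coverage > ``min_cov1``.

    This is the foreign-contig filter: contigs assembled from reads
    recruited out of a similar but wrong locus attract few or no direct
    seed alignments and are dropped (strictly-greater threshold).
    """
    if not result.contigs:
        return AssemblyResult()
    for c in result.contigs:
        if c.seed_coverage is None:
            raise ValueError("seed_coverage not populated; run compute_seed_coverage first")
    longest = max(result.contigs, key=lambda c: (len(c.sequence), c.id)).id
    keep = {c.id for c in result.contigs
            if c.id == longest or c.seed_coverage > min_cov1}
    contigs = [c for c in result.contigs if c.id in keep]
    adjacency = [(a, b) for a, b in result.adjacency if a in keep and b in keep]
    return AssemblyResult(contigs, adjacency)


# ---------------------------------------------------------------------------
# GFA emission
# ---------------------------------------------------------------------------

def write_gfa(result: AssemblyResult, path) -> None:
    """Contigs and adjacency as GFA 1.0 (seed coverage as an S-line tag)."""
    with open(path, "w") as out:
        out.write("H\tVN:Z:1.0\n")
        for c in result.contigs:
            cov = f"\tdc:f:{c.seed_coverage:.3f}" if c.seed_coverage is not None else ""
            out.write(f"S\t{c.id}\t{c.sequence}{cov}\n")
        for a, b in result.adjacency:
            out.write(f"L\t{a}\t+\t{b}\t+\t0M\n")
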