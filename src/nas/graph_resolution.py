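"""Contig-graph path selection, merging, and coverage validation.

Repeats fragment the micro-assembly into a branched contig graph.  The
graph is vertex-weighted by seed-read coverage — reads that aligned
directly to the template are the trustworthy ones — and the synthetic
read is reconstructed along the maximum-weight *simple* source-to-sink
path (source and sink are the contigs whose seed-reads map nearest the
template's 5' and 3' ends).  Selected contigs are merged at their
suffix-prefix overlaps, and the candidate is finally validated by
re-aligning the complete short-read collection: any interior stretch with
depth below ``min_cov2`` invalidates it, in which case the longest
gap-free region is kept (status ``trimmed``).

Maximum-weight path note: negating edge weights and running an all-pairs
shortest-path pass is only well-defined without cycles; on the tiny,
possibly cyclic graphs this stage sees, the published objective is
honoured exactly by exhaustive simple-path search (graphs here have a
handful of vertices), with a coordinate-ordered DAG relaxation for
anything larger.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .micro_assembly import AssemblyResult
from .template_alignment import (Alignment, AlignerParams, ReadBatch,
                                 TemplateIndex, align_reads_to_template)

logger = logging.getLogger("nas")


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class ContigGraph:
    """Undirected contig adjacency, vertex-weighted by seed coverage."""

    weights: dict[str, float]
    edges: list[tuple[str, str]]
    source: str
    sink: str
    coords: dict[str, float] = field(default_factory=dict)  # median template coord

    def neighbours(self, v: str) -> list[str]:
        out = []
        for a, b in self.edges:
            if a == v:
                out.append(b)
            elif b == v:
                out.append(a)
        return sorted(set(out))


@dataclass
class PathResult:
    path: list[str]
    weight: float
    disconnected: bool = False


@dataclass
class NaSRead:
    """The final synthetic long read for one template."""

    id: str
    sequence: str
    status: str  # valid | trimmed | failed
    contig_path: list[str] = field(default_factory=list)
    coverage_min: float = 0.0
    template_id: str = ""
    flags: list[str] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.sequence)

    def fasta_header(self) -> str:
        return (f"{self.id} status={self.status} path={','.join(self.contig_path)} "
                f"template={self.template_id}")


# ---------------------------------------------------------------------------
# graph construction
# ---------------------------------------------------------------------------

def contig_template_coords(result: AssemblyResult,
                           template_alignments: dict[str, list[Alignment]]) -> dict[str, float]:
    """Median template coordinate of each contig's seed-aligned members."""
    coords: dict[str, float] = {}
    for c in result.contigs:
        mids = []
        for rid, _off, _ori in c.members:
            for a in template_alignments.get(rid, []):
                mids.append((a.t_start + a.t_end) / 2.0)
        if mids:
            coords[c.id] = float(np.median(mids))
    return coords


def build_contig_graph(result: AssemblyResult,
                       template_alignments: dict[str, list[Alignment]]) -> ContigGraph:
    """Vertex-weighted graph; source/sink from seed positions on the template."""
    if not result.contigs:
        raise ValueError("no contigs to build a graph from")
    weights = {c.id: float(c.seed_coverage or 0.0) for c in result.contigs}
    coords = contig_template_coords(result, template_alignments)
    with_coord = sorted(coords, key=lambda cid: (coords[cid], cid))
    if with_coord:
        source, sink = with_coord[0], with_coord[-1]
    else:
        ordered = sorted(weights, key=lambda cid: (-weights[cid], cid))
        source = sink = ordered[0]
    return ContigGraph(weights, list(result.adjacency), source, sink, coords)


# ---------------------------------------------------------------------------
# path selection
# ---------------------------------------------------------------------------

_EXHAUSTIVE_LIMIT = 20
_EXPANSION_CAP = 500_000


def _exhaustive_best_path(graph: ContigGraph) -> Optional[PathResult]:
    """Branch-and-bound over all simple source->sink paths."""
    nbrs = {v: graph.neighbours(v) for v in graph.weights}
    total = sum(graph.weights.values())
    best: list[Optional[tuple]] = [None]
    expansions = [0]

    def better(cand: tuple, inc: Optional[tuple]) -> bool:
        # higher weight, then fewer vertices, then lexicographic path
        if inc is None:
            return True
        return (-cand[0], cand[1], cand[2]) < (-inc[0], inc[1], inc[2])

    def dfs(v: str, visited: set[str], path: list[str], weight: float,
            remaining: float) -> None:
        if expansions[0] > _EXPANSION_CAP:
            return
        expansions[0] += 1
        if v == graph.sink:
            cand = (weight, len(path), tuple(path))
            if better(cand, best[0]):
                best[0] = cand
            return
        if best[0] is not None and weight + remaining <= best[0][0] and \
                (weight + remaining, len(path)) < (best[0][0], best[0][1]):
            return
        for w in nbrs.get(v, ()):
            if w in visited:
                continue
            visited.add(w)
            path.append(w)
            dfs(w, visited, path, weight + graph.weights[w],
                remaining - graph.weights[w])
            path.pop()
            visited.remove(w)

    start_w = graph.weights[graph.source]
    dfs(graph.source, {graph.source}, [graph.source], start_w, total - start_w)
    if best[0] is None:
        return None
    return PathResult(list(best[0][2]), best[0][0])


def _dag_best_path(graph: ContigGraph) -> Optional[PathResult]:
    """Longest-path DP after orienting edges by template coordinate."""
    if not graph.coords:
        return None
    order = sorted(graph.weights, key=lambda v: (graph.coords.get(v, float("inf")), v))
    rank = {v: i for i, v in enumerate(order)}
    best: dict[str, tuple[float, int, tuple]] = {
        graph.source: (graph.weights[graph.source], 1, (graph.source,))}
    for v in order:
        if v not in best:
            continue
        w0, n0, p0 = best[v]
        for w in graph.neighbours(v):
            if rank[w] <= rank[v]:
                continue
            cand = (w0 + graph.weights[w], n0 + 1, p0 + (w,))
            inc = best.get(w)
            if inc is None or (-cand[0], cand[1], cand[2]) < (-inc[0], inc[1], inc[2]):
                best[w] = cand
    if graph.sink not in best:
        return None
    w, _n, p = best[graph.sink]
    return PathResult(list(p), w)


def select_best_path(graph: ContigGraph) -> PathResult:
    """Maximum-seed-coverage simple path from source to sink.

    Disconnected source/sink falls back to the single highest-weight
    contig, flagged via ``disconnected``.
    """
    if graph.source == graph.sink:
        return PathResult([graph.source], graph.weights[graph.source])
    if len(graph.weights) <= _EXHAUSTIVE_LIMIT:
        res = _exhaustive_best_path(graph)
    else:
        res = _dag_best_path(graph) or _exhaustive_best_path(graph)
    if res is not None:
        return res
    fallback = sorted(graph.weights, key=lambda v: (-graph.weights[v], v))[0]
    return PathResult([fallback], graph.weights[fallback], disconnected=True)


# ---------------------------------------------------------------------------
# path merging
# ---------------------------------------------------------------------------

_JUNCTION_MIN_OVERLAP = 20
_JUNCTION_MIN_IDENTITY = 0.98
_JUNCTION_WORD = 16


def _best_junction_overlap(sa: str, sb: str) -> Optional[int]:
    """Longest admissible suffix(sa)/prefix(sb) overlap length."""
    max_ovl = min(len(sa), len(sb))
    window = min(max_ovl + 500, len(sa))
    suffix = sa[len(sa) - window:]
    k = _JUNCTION_WORD
    if len(sb) < k or len(suffix) < k:
        return None
    positions: dict[str, int] = {}
    for p in range(0, min(len(sb) - k + 1, 2000)):
        w = sb[p:p + k]
        if w not in positions:
            positions[w] = p
    cand_ovls: set[int] = set()
    for p in range(len(suffix) - k + 1):
        w = suffix[p:p + k]
        q = positions.get(w)
        if q is not None:
            ovl = (len(suffix) - p) + q  # implied overlap length
            if _JUNCTION_MIN_OVERLAP <= ovl <= max_ovl:
                cand_ovls.add(ovl)
    arr_a = np.frombuffer(sa.encode(), dtype=np.uint8)
    arr_b = np.frombuffer(sb.encode(), dtype=np.uint8)
    for ovl in sorted(cand_ovls, reverse=True):
        seg_a = arr_a[len(sa) - ovl:]
        seg_b = arr_b[:ovl]
        if float((seg_a == seg_b).mean()) >= _JUNCTION_MIN_IDENTITY:
            return ovl
    return None


@dataclass
class MergeResult:
    sequence: str
    path: list[str]
    flagged: bool = False


def merge_path(path: Sequence[str], result: AssemblyResult,
               coverage: Optional[dict[str, float]] = None) -> MergeResult:
    """Join consecutive path contigs at their best suffix-prefix overlap.

    The junction consensus comes from the higher-seed-coverage contig.  If
    some junction admits no overlap (>=20 bp at >=98% identity), the merge
    aborts and the longest single contig of the path is returned, flagged.
    """
    contigs = {c.id: c for c in result.contigs}
    if coverage is None:
        coverage = {c.id: float(c.seed_coverage or 0.0) for c in result.contigs}
    if not path:
        raise ValueError("empty path")
    merged = contigs[path[0]].sequence
    cov_so_far = coverage.get(path[0], 0.0)
    for cid in path[1:]:
        nxt = contigs[cid].sequence
        ovl = _best_junction_overlap(merged, nxt)
        if ovl is None:
            longest = max(path, key=lambda c: (len(contigs[c].sequence), c))
            logger.warning("merge_path: no junction overlap before %s; "
                           "falling back to longest contig %s", cid, longest)
            return MergeResult(contigs[longest].sequence, [longest], flagged=True)
        if coverage.get(cid, 0.0) > cov_so_far:
            merged = merged[:len(merged) - ovl] + nxt
        else:
            merged = merged + nxt[ovl:]
        cov_so_far = coverage.get(cid, 0.0)
    return MergeResult(merged, list(path))


def clip_to_template_reach(candidate: str, template_seq: str,
                           fragment_max: int = 750,
                           end_slack: int = 50) -> str:
    """Clip a candidate to the physical reach of its template.

    Recruitment can chain through read mates and extend the assembly well
    past the template; but sequence more than one library fragment length
    beyond the template-supported span has no template anchoring.  The
    template's image in the candidate is located by edit-distance
    alignment and the candidate is clipped to ``fragment_max`` beyond it,
    with ``end_slack`` absorbing the end uncertainty of aligning a
    high-error template.
    """
    import edlib
    if not candidate or not template_seq:
        return candidate
    res = edlib.align(template_seq, candidate, mode="HW", task="locations")
    if res["editDistance"] < 0 or not res["locations"]:
        return candidate
    loc_start, loc_end = res["locations"][0]
    reach = max(0, fragment_max - end_slack)
    lo = max(0, loc_start - reach)
    hi = min(len(candidate), loc_end + 1 + reach)
    return candidate[lo:hi]


# ---------------------------------------------------------------------------
# validation by short-read coverage
# ---------------------------------------------------------------------------

def coverage_depth(candidate: str, read_batch: ReadBatch,
                   validate_tile: int = 12, step_size: int = 5,
                   min_identity: float = 0.90,
                   min_query_fraction: float = 0.95) -> np.ndarray:
    """Per-base depth of near-full-length short-read alignments.

    Only reads aligning over >=95% of their length count.  The stringency
    matters: at a false junction no read spans the join, but reads clipped
    there still align their near side; with a lax query-fraction cut
    enough clipped tails cover the junction to hide the coverage gap that
    betrays a chimera.  At 95%, expected junction depth is about one
    tenth of the interior depth, far below the validation threshold.
    """
    params = AlignerParams(tile_size=validate_tile, step_size=step_size,
                           min_identity=min_identity,
                           min_query_fraction=min_query_fraction)
    index = TemplateIndex(candidate, validate_tile, step_size)
    alns = align_reads_to_template(read_batch, index, params, target_id="candidate")
    depth = np.zeros(len(candidate) + 1, dtype=np.int64)
    for read_alns in alns.values():
        a = read_alns[0]  # best alignment per read
        depth[a.t_start] += 1
        depth[a.t_end] -= 1
    return np.cumsum(depth[:-1])


def validate_candidate(candidate: str, read_batch: ReadBatch,
                       min_cov2: float = 10.0, validate_tile: int = 12,
                       end_margin: int = 500,
                       template_id: str = "template",
                       contig_path: Sequence[str] = (),
                       flags: Sequence[str] = ()) -> NaSRead:
    """Depth-validate a merged candidate against the full short-read set.

    Interior bases (beyond ``end_margin`` from each end, where physical
    coverage necessarily decays) must reach depth >= ``min_cov2``;
    otherwise the longest contiguous run satisfying the rule is kept
    (status ``trimmed``), or the read fails outright if no run remains.
    """
    if not candidate:
        raise ValueError("empty candidate")
    depth = coverage_depth(candidate, read_batch, validate_tile)
    n = len(candidate)
    lo, hi = min(end_margin, n), max(n - end_margin, 0)
    interior = depth[lo:hi]
    nas_id = f"nas_{template_id}"
    if interior.size == 0 or interior.min() >= min_cov2:
        cov_min = float(interior.min()) if interior.size else float(depth.max(initial=0))
        return NaSRead(nas_id, candidate, "valid", list(contig_path),
                       cov_min, template_id, list(flags))
    ok = depth >= min_cov2
    ok[:lo] = True
    ok[hi:] = True
    # longest True run
    best_len, best_lo = 0, 0
    run_lo = None
    for i, v in enumerate(np.concatenate((ok, [False]))):
        if v and run_lo is None:
            run_lo = i
        elif not v and run_lo is not None:
            if i - run_lo > best_len:
                best_len, best_lo = i - run_lo, run_lo
            run_lo = None
    if best_len == 0:
        return NaSRead(nas_id, "", "failed", list(contig_path), 0.0,
                       template_id, list(flags) + ["coverage_gap"])
    sub = candidate[best_lo:best_lo + best_len]
    run = depth[best_lo:best_lo + best_len]
    inner = run[(max(lo, best_lo) - best_lo):(min(hi, best_lo + best_len) - best_lo)]
    cov_min = float(inner.min()) if inner.size else float(run.min())
    return NaSRead(nas_id, sub, "trimmed", list(contig_path), cov_min,
                   template_id, list(flags) + ["coverage_gap"])


# ---------------------------------------------------------------------------
# pipeline-facing resolution over possibly disconnected graphs
# ---------------------------------------------------------------------------

def resolve_graph(result: AssemblyResult,
                  template_alignments: dict[str, list[Alignment]]) -> Optional[MergeResult]:
    """Best path per connected component, components ordered along the template.

    A single component reduces to select-best-path + merge.  With several
    components (e.g. a chimeric template whose loci assemble separately),
    each component's merged sequence is concatenated in template order and
    the join is flagged — downstream coverage validation arbitrates
    whether the junction is real.
    """
    if not result.contigs:
        return None
    graph = build_contig_graph(result, template_alignments)
    # connected components over vertices
    comp_of: dict[str, int] = {}
    for v in sorted(graph.weights):
        if v in comp_of:
            continue
        ci = len(set(comp_of.values()))
        stack = [v]
        comp_of[v] = ci
        while stack:
            u = stack.pop()
            for w in graph.neighbours(u):
                if w not in comp_of:
                    comp_of[w] = ci
                    stack.append(w)
    comps: dict[int, list[str]] = {}
    for v, ci in comp_of.items():
        comps.setdefault(ci, []).append(v)

    pieces = []
    for ci, members in comps.items():
        coords = {v: graph.coords[v] for v in members if v in graph.coords}
        if coords:
            src = min(coords, key=lambda v: (coords[v], v))
            snk = max(coords, key=lambda v: (coords[v], v))
            order_key = float(np.median(sorted(coords.values())))
        else:
            best_v = sorted(members, key=lambda v: (-graph.weights[v], v))[0]
            src = snk = best_v
            order_key = float("inf")
        sub = ContigGraph({v: graph.weights[v] for v in members},
                          [(a, b) for a, b in graph.edges
                           if a in members and b in members],
                          src, snk,
                          {v: c for v, c in graph.coords.items() if v in members})
        path = select_best_path(sub)
        merged = merge_path(path.path, result)
        pieces.append((order_key, min(members), merged))
    pieces.sort(key=lambda t: (t[0], t[1]))
    sequence = pieces[0][2].sequence
    for _k, _tie, nxt in pieces[1:]:
        # components may still overlap (junction contigs lost to the
        # coverage filter); splice at a real overlap when one exists and
        # let depth validation arbitrate a blunt join otherwise
        ovl = _best_junction_overlap(sequence, nxt.sequence)
        if ovl is not None:
            sequence = sequence[:len(sequence) - ovl] + nxt.sequence
        else:
            sequence = sequence + nxt.sequence
    path = [cid for _k, _tie, m in pieces for cid in m.path]
    flagged = len(pieces) > 1 or any(m.flagged for _k, _tie, m in pieces)
    return MergeResult(sequence, path, flagged=flagged)
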