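"""Per-template orchestration of the whole synthetic-read workflow.

For each noisy long-read template: stringent short-read seeding, k-mer
recruitment of reads from regions too error-rich to seed, OLC
micro-assembly, foreign-contig filtering by seed coverage, contig-graph
path resolution, and depth validation — at most one synthetic read per
template.  ``run_all`` processes a template collection with shared
precomputed read indices; ``coverage_sweep`` reruns a fixed template set
over subsampled/trimmed short-read sets to map the coverage/read-length
response.
"""

from __future__ import annotations

import dataclasses
import logging
import time
from concurrent.futures import ThreadPoolExecutor
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from . import evaluation
from .graph_resolution import (NaSRead, clip_to_template_reach, resolve_graph,
                               validate_candidate)
from .micro_assembly import (AssemblyParams, assemble, compute_seed_coverage,
                             filter_contigs)
from .recruitment import (CanonicalKmerCache, forward_kmer_set,
                          index_seed_kmers, orientation_votes, recruit_reads)
from .sequence_io import SeqRecord, quality_filter_pairs
from .synthetic_data import (GenomeTruth, LongReadTemplate, ReadPair,
                             profile_2d, simulate_long_reads)
from .template_alignment import (AlignerParams, ReadBatch,
                                 filter_alignments_for_coverage,
                                 select_seed_reads)

logger = logging.getLogger("nas")

_ORIENT_K = 16


@dataclass(frozen=True)
class NasConfig:
    """Every tunable of the workflow, with the pipeline's standard defaults."""

    tile_size: int = 10
    step_size: int = 5
    recruit_k: int = 32
    recruit_t: int = 3
    min_overlap_identity: float = 0.98
    min_overlap: int = 40
    min_cov1: float = 10.0
    min_cov2: float = 10.0
    validate_tile: int = 12
    trim_q: int = 20
    trim_min_len: int = 30
    seed: int = 0
    workers: int = 1
    # seeding stringency (survives 25-43% template error)
    min_seed_hits: int = 2
    band_width: int = 50
    seed_min_identity: float = 0.65
    seed_min_query_fraction: float = 0.50
    # library geometry, used for the validation end-margin
    fragment_max: int = 750

    def __post_init__(self) -> None:
        for name in ("tile_size", "step_size", "recruit_k", "recruit_t",
                     "min_overlap", "min_cov1", "min_cov2", "validate_tile",
                     "trim_q", "trim_min_len"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    def aligner_params(self) -> AlignerParams:
        return AlignerParams(tile_size=self.tile_size, step_size=self.step_size,
                             min_seed_hits=self.min_seed_hits,
                             band_width=self.band_width,
                             min_identity=self.seed_min_identity,
                             min_query_fraction=self.seed_min_query_fraction)


def load_config(path: str | Path, **overrides) -> NasConfig:
    """Flat key=value config file; keyword overrides win."""
    values: dict = {}
    fields = {f.name: f.type for f in dataclasses.fields(NasConfig)}
    for line in Path(path).read_text().splitlines():
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        key, _, val = line.partition("=")
        key = key.strip()
        if key not in fields:
            raise ValueError(f"unknown config key: {key}")
        current = getattr(NasConfig(), key)
        values[key] = type(current)(float(val)) if isinstance(current, (int, float)) \
            else val.strip()
    values.update(overrides)
    return NasConfig(**values)


def save_config(config: NasConfig, path: str | Path) -> None:
    with open(path, "w") as out:
        for f in dataclasses.fields(NasConfig):
            out.write(f"{f.name}={getattr(config, f.name)}\n")


# ---------------------------------------------------------------------------
# shared per-read-set caches
# ---------------------------------------------------------------------------

class ReadSetCache:
    """Indices over the full short-read collection, built once per run."""

    def __init__(self, pairs: Sequence[ReadPair], config: NasConfig):
        self.pairs = list(pairs)
        self.reads: list[SeqRecord] = [r for p in self.pairs for r in (p.fwd, p.rev)]
        self.by_id = {r.id: r for r in self.reads}
        self.mate_of: dict[str, str] = {}
        for p in self.pairs:
            self.mate_of[p.fwd.id] = p.rev.id
            self.mate_of[p.rev.id] = p.fwd.id
        self.batch_seed = ReadBatch(self.reads, config.tile_size)
        self.batch_validate = (self.batch_seed if config.validate_tile == config.tile_size
                               else ReadBatch(self.reads, config.validate_tile))
        self.canonical = CanonicalKmerCache(self.reads, config.recruit_k)
        lens = sorted(len(r) for r in self.reads)
        self.median_read_len = lens[len(lens) // 2] if lens else 0


@dataclass
class TemplateResult:
    template_id: str
    nas: Optional[NaSRead] = None
    failure: Optional[str] = None
    n_seeds: int = 0
    n_recruited: int = 0
    n_contigs: int = 0
    seconds: float = 0.0

    @property
    def ok(self) -> bool:
        return self.nas is not None


# ---------------------------------------------------------------------------
# one template end to end
# ---------------------------------------------------------------------------

def run_template(template: LongReadTemplate, pairs, config: NasConfig = NasConfig(),
                 cache: Optional[ReadSetCache] = None) -> TemplateResult:
    """Seed -> recruit -> assemble -> filter -> resolve -> validate."""
    t0 = time.perf_counter()
    if cache is None:
        cache = ReadSetCache(list(pairs), config)
    res = TemplateResult(template.id)
    try:
        _run_template_inner(template, config, cache, res)
    except Exception:  # noqa: BLE001 - per-template isolation contract
        logger.exception("template %s failed unexpectedly", template.id)
        res.failure = "error"
    res.seconds = time.perf_counter() - t0
    return res


def _run_template_inner(template: LongReadTemplate, config: NasConfig,
                        cache: ReadSetCache, res: TemplateResult) -> None:
    params = config.aligner_params()
    seed_set = select_seed_reads(cache.pairs, template.record.sequence, params,
                                 template_id=template.id, batch=cache.batch_seed)
    res.n_seeds = len(seed_set.members)
    if not seed_set.members:
        res.failure = "no_seeds"
        return

    seed_ids = set(seed_set.read_ids)
    kidx = index_seed_kmers((cache.by_id[rid].sequence for rid in sorted(seed_ids)),
                            k=config.recruit_k)
    recruited = recruit_reads(kidx, cache.pairs, t=config.recruit_t,
                              exclude=seed_ids, cache=cache.canonical)
    res.n_recruited = len(recruited.with_mates)

    # orient everything onto the template strand before layout
    orientation: dict[str, str] = {rid: ori for rid, ori, _p in seed_set.members}
    oriented_seed_seqs = []
    for rid, ori, _p in seed_set.members:
        rec = cache.by_id[rid]
        oriented_seed_seqs.append(rec.sequence if ori == "+"
                                  else rec.reverse_complement().sequence)
    fwd_words = forward_kmer_set(oriented_seed_seqs, _ORIENT_K)
    member_ids = sorted(seed_ids | set(recruited.with_mates))
    for rid in member_ids:
        if rid in orientation:
            continue
        nf, nr = orientation_votes(cache.by_id[rid], fwd_words, _ORIENT_K)
        if nf or nr:
            orientation[rid] = "+" if nf >= nr else "-"
    for rid in member_ids:  # mates inherit the flipped strand
        if rid not in orientation:
            mate = cache.mate_of.get(rid)
            if mate in orientation:
                orientation[rid] = "-" if orientation[mate] == "+" else "+"
            else:
                orientation[rid] = "+"

    member_reads = [cache.by_id[rid] for rid in member_ids]
    assembly = assemble(member_reads,
                        AssemblyParams(config.min_overlap, config.min_overlap_identity),
                        orientations=orientation)
    if not assembly.contigs:
        res.failure = "assembly_empty"
        return

    # seed coverage per contig: realign the seed reads to every contig
    seed_reads = [cache.by_id[rid] for rid in sorted(seed_ids)]
    seed_batch = ReadBatch(seed_reads, config.tile_size)
    loose = dataclasses.replace(params, min_identity=0.5, min_query_fraction=0.3)
    from .template_alignment import TemplateIndex, align_reads_to_template
    all_contig_alns = []
    for contig in assembly.contigs:
        cindex = TemplateIndex(contig.sequence, config.tile_size, config.step_size)
        alns = align_reads_to_template(seed_batch, cindex, loose, target_id=contig.id)
        for read_alns in alns.values():
            all_contig_alns.append(read_alns[0])
    retained = filter_alignments_for_coverage(all_contig_alns)
    compute_seed_coverage(assembly.contigs, retained)
    filtered = filter_contigs(assembly, config.min_cov1)
    res.n_contigs = len(filtered.contigs)

    merged = resolve_graph(filtered, seed_set.alignments)
    if merged is None or not merged.sequence:
        res.failure = "disconnected_graph"
        return
    candidate = clip_to_template_reach(merged.sequence, template.record.sequence,
                                       config.fragment_max)

    margin = max(0, config.fragment_max - cache.median_read_len)
    flags = ["merge_flagged"] if merged.flagged else []
    nas = validate_candidate(candidate, cache.batch_validate,
                             min_cov2=config.min_cov2,
                             validate_tile=config.validate_tile,
                             end_margin=margin, template_id=template.id,
                             contig_path=merged.path, flags=flags)
    if nas.status == "failed":
        res.failure = "coverage_failed"
        return
    res.nas = nas


# ---------------------------------------------------------------------------
# many templates
# ---------------------------------------------------------------------------

@dataclass
class RunReport:
    results: list[TemplateResult] = field(default_factory=list)

    @property
    def reads(self) -> list[NaSRead]:
        return [r.nas for r in self.results if r.nas is not None]

    def counts(self) -> dict[str, int]:
        out = {"templates": len(self.results), "valid": 0, "trimmed": 0, "failed": 0}
        for r in self.results:
            if r.nas is not None:
                out[r.nas.status] += 1
            else:
                out["failed"] += 1
                key = f"failed_{r.failure}"
                out[key] = out.get(key, 0) + 1
        return out

    def success_rate(self) -> float:
        if not self.results:
            return 0.0
        return len(self.reads) / len(self.results)

    def length_stats(self) -> dict[str, float]:
        lengths = [len(r) for r in self.reads]
        if not lengths:
            return {"n": 0, "mean_bp": 0.0, "n50_bp": 0, "max_bp": 0}
        return {"n": len(lengths),
                "mean_bp": float(np.mean(lengths)),
                "n50_bp": evaluation.n50(lengths),
                "max_bp": max(lengths)}

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as out:
            out.write("template_id\tstatus\tfailure\tlength\tn_seeds\t"
                      "n_recruited\tn_contigs\tcoverage_min\tpath\tseconds\n")
            for r in self.results:
                status = r.nas.status if r.nas else "failed"
                length = len(r.nas) if r.nas else 0
                cov = f"{r.nas.coverage_min:.1f}" if r.nas else ""
                path_str = ",".join(r.nas.contig_path) if r.nas else ""
                out.write(f"{r.template_id}\t{status}\t{r.failure or ''}\t{length}\t"
                          f"{r.n_seeds}\t{r.n_recruited}\t{r.n_contigs}\t{cov}\t"
                          f"{path_str}\t{r.seconds:.2f}\n")


def run_all(templates: Sequence[LongReadTemplate], pairs,
            config: NasConfig = NasConfig(), qc: bool = True) -> RunReport:
    """Run every template; per-template results are order- and worker-independent."""
    if not templates:
        raise ValueError("need at least one template")
    pairs = list(pairs)
    if qc:
        pairs = quality_filter_pairs(pairs, config.trim_q, config.trim_min_len)
    cache = ReadSetCache(pairs, config)
    if config.workers > 1:
        with ThreadPoolExecutor(max_workers=config.workers) as pool:
            results = list(pool.map(
                lambda t: run_template(t, None, config, cache), templates))
    else:
        results = [run_template(t, None, config, cache) for t in templates]
    results.sort(key=lambda r: r.template_id)
    report = RunReport(results)
    for r in results:
        logger.info("template %s: %s in %.2fs (seeds=%d recruits=%d contigs=%d)",
                    r.template_id,
                    r.nas.status if r.nas else f"FAILURE({r.failure})",
                    r.seconds, r.n_seeds, r.n_recruited, r.n_contigs)
    return report


# ---------------------------------------------------------------------------
# coverage / read-length sweep
# ---------------------------------------------------------------------------

def _trim_pair(pair: ReadPair, read_len: int) -> ReadPair:
    def cut(rec: SeqRecord) -> SeqRecord:
        if len(rec) <= read_len:
            return rec
        q = rec.quality[:read_len] if rec.quality is not None else None
        return SeqRecord(rec.id, rec.sequence[:read_len], q)
    return ReadPair(cut(pair.fwd), cut(pair.rev), pair.fragment_length)


def coverage_sweep(genome: GenomeTruth, coverages: Sequence[float],
                   read_lens: Sequence[int], config: NasConfig = NasConfig(),
                   n_templates: int = 8,
                   template_length: tuple[float, float] = (4000.0, 1200.0),
                   profile=None,
                   templates: Optional[Sequence[LongReadTemplate]] = None,
                   base_pairs: Optional[Sequence[ReadPair]] = None) -> list[dict]:
    """Pipeline quality as a function of short-read coverage and read length.

    A fixed template set is rerun against subsampled (and end-trimmed)
    versions of one maximal short-read set; each cell reports the number
    of synthetic reads, their mean truth identity and mean length.
    """
    from .synthetic_data import simulate_read_pairs
    if profile is None:
        profile = profile_2d()
    if templates is None:
        templates = simulate_long_reads(genome, n_templates, template_length,
                                        profile, seed=config.seed)
    max_cov = max(coverages)
    max_len = max(read_lens)
    if base_pairs is None:
        base_pairs = simulate_read_pairs(genome, max_cov, read_len=max_len,
                                         seed=config.seed + 1)
    base_pairs = list(base_pairs)
    rows = []
    for ci, cov in enumerate(coverages):
        n_sub = int(round(len(base_pairs) * cov / max_cov))
        rng = np.random.default_rng(config.seed * 1000 + ci)
        idx = sorted(rng.permutation(len(base_pairs))[:n_sub])
        subset = [base_pairs[i] for i in idx]
        for rl in read_lens:
            cell_pairs = [_trim_pair(p, rl) for p in subset]
            report = run_all(templates, cell_pairs, config)
            summary, _per_read = evaluation.evaluate_against_truth(
                report.reads, genome, templates,
                fragment_max=config.fragment_max)
            rows.append({
                "coverage": cov, "read_len": rl,
                "n_reads": len(report.reads),
                "n_valid": report.counts()["valid"],
                "mean_identity": summary.mean_identity,
                "mean_length": report.length_stats()["mean_bp"],
            })
    return rows


def write_sweep_tsv(rows: Sequence[dict], path: str | Path) -> None:
    with open(path, "w") as out:
        out.write("coverage\tread_len\tn_reads\tmean_identity\tmean_length\n")
        for r in rows:
            out.write(f"{r['coverage']}\t{r['read_len']}\t{r['n_reads']}\t"
                      f"{r['mean_identity']:.5f}\t{r['mean_length']:.1f}\n")
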