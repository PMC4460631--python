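"""Truth-based quality metrics and read-set summary statistics.

Synthetic reads produced from simulated templates are scored against the
generating genome: each read is aligned (full containment, edit distance)
to its template's truth neighbourhood — the truth interval widened by one
library fragment length on each side, since recruitment legitimately
extends reads past the template borders.  A read is *error-free* when it
aligns with zero edits over its entire length.  Summaries mirror the
standard read-set table: counts, cumulative size, N50, identity and
error-free fractions.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import edlib
import numpy as np

from .graph_resolution import NaSRead
from .sequence_io import reverse_complement
from .synthetic_data import GenomeTruth, LongReadTemplate

_ALIGNED_IDENTITY_FLOOR = 0.70


def n50(lengths: Sequence[int]) -> int:
    """Largest L such that pieces of length >= L hold half the total bases."""
    if not lengths:
        raise ValueError("n50 of an empty length set is undefined")
    arr = np.sort(np.asarray(lengths))[::-1]
    half = arr.sum() / 2.0
    csum = np.cumsum(arr)
    return int(arr[np.searchsorted(csum, half)])


@dataclass
class ReadSetSummary:
    n_reads: int
    n_over_10kb: int
    cumulative_bp: int
    mean_bp: float
    n50_bp: int
    max_bp: int
    n_aligned: int
    mean_identity: float
    n_error_free: int

    def to_tsv(self, path: str | Path) -> None:
        rows = [("Number of reads", self.n_reads),
                ("Reads > 10 kb", self.n_over_10kb),
                ("Cumulative size (bp)", self.cumulative_bp),
                ("Average size (bp)", f"{self.mean_bp:.1f}"),
                ("N50 size (bp)", self.n50_bp),
                ("Longest read (bp)", self.max_bp),
                ("Aligned reads", self.n_aligned),
                ("Mean identity percent", f"{self.mean_identity * 100:.2f}"),
                ("Error-free reads", self.n_error_free)]
        with open(path, "w") as out:
            for name, value in rows:
                out.write(f"{name}\t{value}\n")


def _containment_distance(query: str, window: str) -> int:
    """Edit distance of the best full-query placement inside the window."""
    if not query or not window:
        return max(len(query), len(window))
    res = edlib.align(query, window, mode="HW", task="distance")
    d = res["editDistance"]
    return d if d >= 0 else len(query)


def align_to_truth(sequence: str, genome: GenomeTruth,
                   segments: Sequence[tuple[str, int, int, str]],
                   fragment_max: int = 750) -> int:
    """Best containment edit distance over the truth neighbourhoods (both strands)."""
    best = len(sequence)
    for _gid, start, end, _strand in segments:
        lo = max(0, start - fragment_max)
        hi = min(len(genome), end + fragment_max)
        window = genome.sequence[lo:hi]
        d = min(_containment_distance(sequence, window),
                _containment_distance(reverse_complement(sequence), window))
        best = min(best, d)
    return best


def best_truth_locus(sequence: str, genome: GenomeTruth,
                     loci: Sequence[tuple[str, int, int]],
                     pad: int = 3000) -> list[tuple[str, int]]:
    """(locus_id, distance) per candidate locus, best first.

    Used to check that a repeat-spanning read anchors to the correct
    repeat copy: candidate loci are each copy's neighbourhood widened by
    ``pad`` (enough to include the unique flanks the read carries).
    """
    scored = []
    for locus_id, start, end in loci:
        lo, hi = max(0, start - pad), min(len(genome), end + pad)
        window = genome.sequence[lo:hi]
        d = min(_containment_distance(sequence, window),
                _containment_distance(reverse_complement(sequence), window))
        scored.append((locus_id, d))
    scored.sort(key=lambda t: (t[1], t[0]))
    return scored


def evaluate_against_truth(nas_reads: Sequence[NaSRead], genome: GenomeTruth,
                           templates: Sequence[LongReadTemplate],
                           fragment_max: int = 750
                           ) -> tuple[ReadSetSummary, list[dict]]:
    """Score synthetic reads against the genome truth of their templates.

    Returns the set-level summary plus one record per read with its
    identity (1 - edits/length under full-containment alignment),
    error-free flag and signed elongation relative to the template.
    """
    by_id = {t.id: t for t in templates}
    per_read: list[dict] = []
    identities = []
    n_aligned = 0
    n_error_free = 0
    for read in nas_reads:
        tpl = by_id.get(read.template_id)
        rec = {"read_id": read.id, "template_id": read.template_id,
               "length": len(read), "status": read.status,
               "identity": 0.0, "error_free": False, "elongation_bp": None,
               "aligned": False}
        if tpl is None or not len(read):
            per_read.append(rec)
            continue
        dist = align_to_truth(read.sequence, genome, tpl.truth_segments,
                              fragment_max)
        identity = 1.0 - dist / len(read)
        rec["identity"] = identity
        rec["elongation_bp"] = len(read) - len(tpl.record)
        if identity >= _ALIGNED_IDENTITY_FLOOR:
            rec["aligned"] = True
            n_aligned += 1
            identities.append(identity)
            if dist == 0:
                rec["error_free"] = True
                n_error_free += 1
        per_read.append(rec)
    lengths = [len(r) for r in nas_reads]
    summary = ReadSetSummary(
        n_reads=len(nas_reads),
        n_over_10kb=sum(1 for L in lengths if L > 10_000),
        cumulative_bp=int(sum(lengths)),
        mean_bp=float(np.mean(lengths)) if lengths else 0.0,
        n50_bp=n50(lengths) if lengths else 0,
        max_bp=max(lengths) if lengths else 0,
        n_aligned=n_aligned,
        mean_identity=float(np.mean(identities)) if identities else 0.0,
        n_error_free=n_error_free,
    )
    return summary, per_read


def write_per_read_tsv(per_read: Sequence[dict], path: str | Path) -> None:
    cols = ["read_id", "template_id", "status", "length", "identity",
            "error_free", "elongation_bp", "aligned"]
    with open(path, "w") as out:
        out.write("\t".join(cols) + "\n")
        for rec in per_read:
            out.write("\t".join(str(rec[c]) for c in cols) + "\n")
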