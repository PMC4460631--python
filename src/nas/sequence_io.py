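"""Reading, writing and quality filtering of FASTA/FASTQ sequence records.

All pipeline stages exchange :class:`SeqRecord` objects — a plain id /
sequence / optional Phred-quality triple.  Parsing and formatting are
delegated to Biopython; this module adds the uppercasing / U→T
normalisation contract and the end-trimming quality filter applied to
short reads before any alignment step.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Optional

from Bio import SeqIO

logger = logging.getLogger("nas")

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

#: Sentinel returned by :func:`quality_trim` when a read does not survive.
DISCARD = None


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class SeqRecord:
    """A named DNA sequence with optional per-base Phred qualities."""

    id: str
    sequence: str
    quality: Optional[list[int]] = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("SeqRecord id must be non-empty")
        if self.quality is not None and len(self.quality) != len(self.sequence):
            raise ValueError(
                f"record {self.id!r}: quality length {len(self.quality)} "
                f"!= sequence length {len(self.sequence)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)

    def reverse_complement(self, new_id: Optional[str] = None) -> "SeqRecord":
        qual = None if self.quality is None else self.quality[::-1]
        return SeqRecord(new_id or self.id, reverse_complement(self.sequence), qual)


def _normalise(seq: str) -> str:
    return seq.upper().replace("U", "T")


def read_sequences(path: str | Path, format: Optional[str] = None) -> Iterator[SeqRecord]:
    """Stream records from a FASTA or FASTQ file in file order.

    Sequences are uppercased and U is normalised to T.  The format is
    inferred from the extension when not given.  Malformed input raises
    ``ValueError`` carrying the offending record/line context.
    """
    path = Path(path)
    if format is None:
        suffix = path.suffix.lower()
        format = "fastq" if suffix in {".fastq", ".fq"} else "fasta"
    if format not in {"fasta", "fastq"}:
        raise ValueError(f"unsupported format: {format}")
    seen: set[str] = set()
    line_no = 0
    try:
        with open(path) as handle:
            for rec in SeqIO.parse(handle, format):
                # approximate line bookkeeping for error messages
                line_no += 4 if format == "fastq" else 2
                if rec.id in seen:
                    raise ValueError(f"{path}: duplicate record id {rec.id!r}")
                seen.add(rec.id)
                qual = rec.letter_annotations.get("phred_quality")
                yield SeqRecord(rec.id, _normalise(str(rec.seq)),
                                list(qual) if qual is not None else None)
    except ValueError as exc:
        raise ValueError(f"{path} (near line {line_no + 1}): {exc}") from exc


def write_sequences(records: Iterable[SeqRecord], path: str | Path,
                    format: Optional[str] = None, wrap: int = 80) -> int:
    """Write records as FASTA (wrapped) or FASTQ (Phred+33). Returns the count."""
    path = Path(path)
    if format is None:
        suffix = path.suffix.lower()
        format = "fastq" if suffix in {".fastq", ".fq"} else "fasta"
    n = 0
    with open(path, "w") as out:
        for rec in records:
            if format == "fastq":
                if rec.quality is None:
                    raise ValueError(f"record {rec.id!r} has no quality; cannot write FASTQ")
                qstr = "".join(chr(min(q, 93) + 33) for q in rec.quality)
                out.write(f"@{rec.id}\n{rec.sequence}\n+\n{qstr}\n")
            else:
                out.write(f">{rec.id}\n")
                for i in range(0, len(rec.sequence), wrap):
                    out.write(rec.sequence[i:i + wrap] + "\n")
            n += 1
    return n


def quality_trim(read: SeqRecord, q_min: int = 20, min_len: int = 30) -> Optional[SeqRecord]:
    """End-trim terminal low-quality bases; discard short survivors.

    Bases with quality below ``q_min`` are clipped from both ends (up to the
    first/last base meeting the threshold; internal bases are never
    removed).  Returns ``DISCARD`` (``None``) when the trimmed read is
    shorter than ``min_len``.  Reads without quality pass through unchanged
    with a logged warning.
    """
    if read.quality is None:
        logger.warning("quality_trim: %s has no quality values; passing through", read.id)
        return read
    lo, hi = 0, len(read.sequence)
    while lo < hi and read.quality[lo] < q_min:
        lo += 1
    while hi > lo and read.quality[hi - 1] < q_min:
        hi -= 1
    if hi - lo < min_len:
        return DISCARD
    if lo == 0 and hi == len(read.sequence):
        return read
    return SeqRecord(read.id, read.sequence[lo:hi], read.quality[lo:hi])


def quality_filter_pairs(pairs, q_min: int = 20, min_len: int = 30):
    """Apply :func:`quality_trim` to both mates; keep pairs where both survive."""
    kept = []
    for pair in pairs:
        fwd = quality_trim(pair.fwd, q_min, min_len)
        rev = quality_trim(pair.rev, q_min, min_len)
        if fwd is not DISCARD and rev is not DISCARD:
            pair = type(pair)(fwd=fwd, rev=rev, fragment_length=pair.fragment_length)
            kept.append(pair)
    return kept
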