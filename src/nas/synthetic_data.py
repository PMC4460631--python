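"""Ground-truthed simulation of genomes, noisy long reads and paired short reads.

The generator emulates the study system the pipeline targets: a small
bacterial genome carrying scattered *identical* multi-kilobase repeats
(rDNA-cluster-like), nanopore-style long reads in two accuracy classes
(2D-like ~25.5% error, 1D-like ~43.4% error), and accurate Illumina-like
paired-end reads from a 650-750 bp fragment library.  Every simulated
object carries its truth interval so downstream stages can be scored
without external data.

Error realism note: nanopore error rates are *edit-distance* rates — the
identity an optimal alignment reports.  Independently applied per-base
edits overshoot the intended identity because the optimal alignment finds
cheaper edit paths (e.g. adjacent insertion+deletion collapsing to one
substitution).  Profiles are therefore calibrated internally: applied
rates are scaled by a deterministic pilot-simulation secant iteration
until the realized edit distance per base matches the nominal total rate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import edlib
import numpy as np

from .sequence_io import SeqRecord, reverse_complement, write_sequences

_BASES = "ACGT"


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class GenomeTruth:
    """A simulated genome plus its repeat annotation.

    ``repeat_annotations`` holds ``(copy_id, start, end, family_id)``
    0-based half-open intervals; copies sharing ``family_id`` are exact
    duplicates at generation time.
    """

    sequence: str
    repeat_annotations: list[tuple[str, int, int, str]] = field(default_factory=list)
    id: str = "genome"

    def __post_init__(self) -> None:
        n = len(self.sequence)
        for copy_id, start, end, _fam in self.repeat_annotations:
            if not (0 <= start < end <= n):
                raise ValueError(f"repeat {copy_id} interval ({start},{end}) outside genome")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class ErrorProfile:
    """Per-base substitution / insertion / deletion probabilities.

    ``total`` is the nominal edit-distance error rate; reads simulated
    under the profile have empirical identity ≈ ``1 - total`` against
    their truth interval (enforced by internal calibration).
    """

    substitution_rate: float
    insertion_rate: float
    deletion_rate: float
    label: str = ""

    def __post_init__(self) -> None:
        for r in (self.substitution_rate, self.insertion_rate, self.deletion_rate):
            if not 0.0 <= r <= 1.0:
                raise ValueError("error rates must be probabilities")
        if self.total >= 1.0:
            raise ValueError("total error rate must be < 1")

    @property
    def total(self) -> float:
        return self.substitution_rate + self.insertion_rate + self.deletion_rate

    @property
    def read_class(self) -> str:
        return "1D" if "1d" in self.label.lower() else "2D"


def profile_2d(total: float = 0.255) -> ErrorProfile:
    """2D-like (two-direction consensus) nanopore profile, ~74.5% identity."""
    return ErrorProfile(total * 0.5, total * 0.25, total * 0.25, label="2D-like")


def profile_1d(total: float = 0.434) -> ErrorProfile:
    """1D-like (single strand) nanopore profile, ~56.6% identity."""
    return ErrorProfile(total * 0.5, total * 0.25, total * 0.25, label="1D-like")


def error_free_profile() -> ErrorProfile:
    return ErrorProfile(0.0, 0.0, 0.0, label="error-free")


@dataclass
class LongReadTemplate:
    """A noisy long read plus, when simulated, its truth on the genome.

    ``truth`` is ``(genome_id, start, end, strand)``.  Chimeric templates
    carry every constituent segment in ``truth_segments`` (first segment
    mirrored in ``truth``).
    """

    record: SeqRecord
    read_class: str = "2D"
    truth: Optional[tuple[str, int, int, str]] = None
    truth_segments: list[tuple[str, int, int, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.truth is not None and not self.truth_segments:
            self.truth_segments = [self.truth]

    @property
    def id(self) -> str:
        return self.record.id

    def __len__(self) -> int:
        return len(self.record.sequence)


@dataclass
class ReadPair:
    """An innie-oriented paired-end read from one sequenced fragment."""

    fwd: SeqRecord
    rev: SeqRecord
    fragment_length: int

    def __post_init__(self) -> None:
        if self.fragment_length < max(len(self.fwd), len(self.rev)):
            raise ValueError("fragment shorter than its reads")


# ---------------------------------------------------------------------------
# error injection and calibration
# ---------------------------------------------------------------------------

def _mutate(seq: str, sub: float, ins: float, dele: float,
            rng: np.random.Generator) -> str:
    """Apply i.i.d. per-base edits; geometric run of insertions after each base."""
    if sub == 0.0 and ins == 0.0 and dele == 0.0:
        return seq
    out: list[str] = []
    rand = rng.random
    randint = rng.integers
    for ch in seq:
        r = rand()
        if r < dele:
            pass
        elif r < dele + sub:
            out.append(_BASES[(_BASES.index(ch) + int(randint(1, 4))) % 4])
        else:
            out.append(ch)
        while rand() < ins:
            out.append(_BASES[int(randint(0, 4))])
    return "".join(out)


_CALIBRATION_CACHE: dict[tuple[float, float, float], float] = {}
_PILOT_BP = 30_000
_PILOT_SEED = 271_828_459


def _calibration_scale(profile: ErrorProfile) -> float:
    """Multiplier on applied rates so realized edit distance matches nominal.

    Deterministic: the pilot uses its own fixed seed, so the scale depends
    only on the profile, never on the caller's seed.
    """
    key = (round(profile.substitution_rate, 6), round(profile.insertion_rate, 6),
           round(profile.deletion_rate, 6))
    if key in _CALIBRATION_CACHE:
        return _CALIBRATION_CACHE[key]
    total = profile.total
    if total == 0.0:
        _CALIBRATION_CACHE[key] = 1.0
        return 1.0
    rng = np.random.default_rng(_PILOT_SEED)
    pilot = "".join(rng.choice(list(_BASES), _PILOT_BP))

    def realized(scale: float) -> float:
        mut = _mutate(pilot, profile.substitution_rate * scale,
                      profile.insertion_rate * scale,
                      profile.deletion_rate * scale,
                      np.random.default_rng(_PILOT_SEED + 1))
        dist = edlib.align(mut, pilot, task="distance")["editDistance"]
        return dist / max(len(mut), len(pilot))

    x0, x1 = 1.0, 1.2
    f0, f1 = realized(x0) - total, realized(x1) - total
    for _ in range(8):
        if abs(f1) < 0.0015 or f1 == f0:
            break
        x2 = x1 - f1 * (x1 - x0) / (f1 - f0)
        x2 = min(max(x2, 0.1), 0.99 / total)
        x0, f0 = x1, f1
        x1, f1 = x2, realized(x2) - total
    _CALIBRATION_CACHE[key] = x1
    return x1


def apply_errors(seq: str, profile: ErrorProfile, rng: np.random.Generator) -> str:
    """Mutate ``seq`` under the (calibrated) error profile."""
    scale = _calibration_scale(profile)
    return _mutate(seq, profile.substitution_rate * scale,
                   profile.insertion_rate * scale,
                   profile.deletion_rate * scale, rng)


# ---------------------------------------------------------------------------
# simulators
# ---------------------------------------------------------------------------

def simulate_genome(length: int,
                    repeat_spec: Sequence[tuple] = (),
                    seed: int = 0) -> GenomeTruth:
    """Random genome with scattered identical repeat families.

    ``repeat_spec`` elements are ``(copy_size_bp, copy_count)`` or
    ``(copy_size_bp, copy_count, n_families)``; each family's copies are
    byte-identical and placed at non-overlapping random loci separated by
    at least one base of unique sequence.
    """
    families: list[tuple[int, int]] = []
    for item in repeat_spec:
        if len(item) == 2:
            size, count = item
            nfam = 1
        else:
            size, count, nfam = item
        if count < 1 or size < 1:
            raise ValueError("repeat copy_count and size must be >= 1")
        families.extend([(int(size), int(count))] * int(nfam))
    total_repeat = sum(size * count for size, count in families)
    if length <= total_repeat:
        raise ValueError("genome length must exceed total repeat content")

    rng = np.random.default_rng(seed)
    seq = rng.choice(np.frombuffer(b"ACGT", dtype="S1"), length)
    annotations: list[tuple[str, int, int, str]] = []
    occupied: list[tuple[int, int]] = []

    def place(size: int) -> int:
        for _ in range(10_000):
            start = int(rng.integers(0, length - size + 1))
            if all(start + size + 1 <= s or start >= e + 1 for s, e in occupied):
                occupied.append((start, start + size))
                return start
        raise ValueError("could not place repeats without overlap; genome too crowded")

    for fam_idx, (size, count) in enumerate(families):
        fam_id = f"fam{fam_idx}"
        fam_seq = rng.choice(np.frombuffer(b"ACGT", dtype="S1"), size)
        for copy_idx in range(count):
            start = place(size)
            seq[start:start + size] = fam_seq
            annotations.append((f"{fam_id}_copy{copy_idx}", start, start + size, fam_id))
    annotations.sort(key=lambda a: a[1])
    return GenomeTruth(seq.tobytes().decode(), annotations)


def simulate_long_reads(genome: GenomeTruth, n: int,
                        length_dist: tuple[float, float] = (5000.0, 2000.0),
                        profile: ErrorProfile = None,
                        seed: int = 0,
                        min_length: int = 500,
                        id_prefix: str = "template") -> list[LongReadTemplate]:
    """Noisy long-read templates with truth intervals.

    Lengths are log-normal with the given (mean, sd), truncated at
    ``min_length`` and capped at the genome length; strand is uniform.
    """
    if profile is None:
        profile = profile_2d()
    mean, sd = length_dist
    if mean >= len(genome):
        raise ValueError("mean template length must be below genome length")
    sigma2 = math.log(1.0 + (sd * sd) / (mean * mean)) if sd > 0 else 0.0
    mu = math.log(mean) - sigma2 / 2.0
    rng = np.random.default_rng(seed)
    reads = []
    for i in range(n):
        for _ in range(1000):
            raw = math.exp(rng.normal(mu, math.sqrt(sigma2))) if sd > 0 else mean
            if raw >= min_length:
                break
        span = min(int(round(raw)), len(genome))
        start = int(rng.integers(0, len(genome) - span + 1))
        strand = "+" if rng.random() < 0.5 else "-"
        source = genome.sequence[start:start + span]
        if strand == "-":
            source = reverse_complement(source)
        mutated = apply_errors(source, profile, rng)
        rec = SeqRecord(f"{id_prefix}_{i:04d}", mutated)
        reads.append(LongReadTemplate(rec, read_class=profile.read_class,
                                      truth=(genome.id, start, start + span, strand)))
    return reads


def simulate_read_pairs(genome: GenomeTruth, coverage: float,
                        read_len: int = 250,
                        fragment_dist: tuple[int, int] = (650, 750),
                        error_rate: float = 0.001,
                        seed: int = 0) -> list[ReadPair]:
    """Innie paired-end reads to a target genome coverage.

    Substitution-only errors at ``error_rate`` (Illumina-like); constant
    per-base quality consistent with the error rate.  Total sequenced
    bases come within one pair of ``coverage * len(genome)``.
    """
    fmin, fmax = fragment_dist
    if read_len > fmin:
        raise ValueError("read_len must not exceed the minimum fragment length")
    if fmax > len(genome):
        raise ValueError("fragments longer than the genome")
    n_pairs = int(round(coverage * len(genome) / (2.0 * read_len)))
    rng = np.random.default_rng(seed)
    qual_val = 40 if error_rate <= 0 else min(40, int(round(-10.0 * math.log10(error_rate))))
    gcodes = np.frombuffer(genome.sequence.encode(), dtype=np.uint8)
    base_codes = np.frombuffer(b"ACGT", dtype=np.uint8)
    code_of = np.zeros(256, dtype=np.uint8)
    for v, b in enumerate(b"ACGT"):
        code_of[b] = v
    comp = np.zeros(256, dtype=np.uint8)
    for a, b in zip(b"ACGT", b"TGCA"):
        comp[a] = b
    pairs = []
    quality = [qual_val] * read_len
    for i in range(n_pairs):
        frag_len = int(rng.integers(fmin, fmax + 1))
        start = int(rng.integers(0, len(genome) - frag_len + 1))
        top = rng.random() < 0.5
        frag = gcodes[start:start + frag_len]
        if not top:
            frag = comp[frag][::-1]
        fwd = frag[:read_len].copy()
        rev = comp[frag][::-1][:read_len].copy()
        if error_rate > 0:
            for arr in (fwd, rev):
                mask = rng.random(read_len) < error_rate
                k = int(mask.sum())
                if k:
                    shift = rng.integers(1, 4, size=k).astype(np.uint8)
                    arr[mask] = base_codes[(code_of[arr[mask]] + shift) % 4]
        pairs.append(ReadPair(
            SeqRecord(f"pair_{i:06d}/1", fwd.tobytes().decode(), list(quality)),
            SeqRecord(f"pair_{i:06d}/2", rev.tobytes().decode(), list(quality)),
            frag_len))
    return pairs


def make_chimeric_template(genome: GenomeTruth,
                           locus_a: tuple[int, int],
                           locus_b: tuple[int, int],
                           profile: ErrorProfile = None,
                           seed: int = 0,
                           min_separation: int = 750,
                           id: str = "chimera_0000") -> LongReadTemplate:
    """A chimeric template joining two distant loci — the validation fixture.

    The read is the concatenation of the two error-mutated loci; no short
    read spans the artificial junction, so the downstream coverage check
    must trim the output back to a single locus.
    """
    if profile is None:
        profile = profile_2d()
    (a0, a1), (b0, b1) = locus_a, locus_b
    if not (0 <= a0 < a1 <= len(genome) and 0 <= b0 < b1 <= len(genome)):
        raise ValueError("loci outside genome")
    gap = max(a0, b0) - min(a1, b1)
    if gap <= min_separation:
        raise ValueError("loci must be non-overlapping and separated by more than "
                         f"{min_separation} bp (got gap {gap})")
    rng = np.random.default_rng(seed)
    seg_a = apply_errors(genome.sequence[a0:a1], profile, rng)
    seg_b = apply_errors(genome.sequence[b0:b1], profile, rng)
    rec = SeqRecord(id, seg_a + seg_b)
    segments = [(genome.id, a0, a1, "+"), (genome.id, b0, b1, "+")]
    return LongReadTemplate(rec, read_class=profile.read_class,
                            truth=segments[0], truth_segments=segments)


# ---------------------------------------------------------------------------
# file emission
# ---------------------------------------------------------------------------

def write_genome(genome: GenomeTruth, path: str | Path) -> None:
    write_sequences([SeqRecord(genome.id, genome.sequence)], path, format="fasta")


def write_repeat_bed(genome: GenomeTruth, path: str | Path) -> None:
    with open(path, "w") as out:
        for copy_id, start, end, fam in genome.repeat_annotations:
            out.write(f"{genome.id}\t{start}\t{end}\t{copy_id};{fam}\n")


def write_truth_bed(templates: Sequence[LongReadTemplate], path: str | Path) -> None:
    with open(path, "w") as out:
        for tpl in templates:
            for gid, start, end, strand in tpl.truth_segments:
                out.write(f"{gid}\t{start}\t{end}\t{tpl.id}\t0\t{strand}\n")


def write_templates(templates: Sequence[LongReadTemplate], path: str | Path) -> None:
    write_sequences([t.record for t in templates], path, format="fasta")


def write_pairs(pairs: Sequence[ReadPair], prefix: str | Path) -> tuple[Path, Path]:
    """Write mates to ``<prefix>_1.fastq`` / ``<prefix>_2.fastq`` (Phred+33)."""
    prefix = Path(prefix)
    p1 = prefix.parent / (prefix.name + "_1.fastq")
    p2 = prefix.parent / (prefix.name + "_2.fastq")
    write_sequences((p.fwd for p in pairs), p1, format="fastq")
    write_sequences((p.rev for p in pairs), p2, format="fastq")
    return p1, p2
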