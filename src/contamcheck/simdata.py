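"""Synthetic genomes, strains, transcript models and read libraries.

The generator emulates the structure of a contamination-confounded
low-biomass sequencing study: a dominant host genome, a spike-in phage
shared by every library, one or two contaminant bacterial strains shared
across wells, a positive control dominated by a lab strain, a negative
control carrying the same contaminants, and RNA libraries with a tunable
genomic-DNA carryover fraction. Every simulated read is recorded in a
truth table so downstream inference can be scored against ground truth.

Conventions: single-end reads; Sanger Phred+33 qualities; circular
genomes are written and sampled linearly (no origin-spanning reads);
mixing weights are read-count proportions; strain variation is
substitution-only (no indels).
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .seqio import Read, revcomp, write_fasta, write_fastq

BASES = "ACGT"
_BASE_ARR = np.frombuffer(b"ACGT", np.uint8)


# ---------------------------------------------------------------------------
# domain types


@dataclass(frozen=True)
class Genome:
    """A named nucleotide sequence over {A,C,G,T}."""

    name: str
    sequence: str
    circular: bool = False

    def __post_init__(self) -> None:
        if len(self.sequence) == 0:
            raise ValueError(f"genome {self.name!r} has zero length")
        if set(self.sequence) - set(BASES):
            bad = sorted(set(self.sequence) - set(BASES))
            raise ValueError(f"genome {self.name!r} contains non-ACGT symbols: {bad}")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class StrainTruth:
    """Ground-truth SNVs separating a derived strain from its parent.

    ``variants`` holds (0-based position, ref allele, alt allele) triples.
    """

    parent: str
    variants: frozenset[tuple[int, str, str]]

    def positions(self) -> set[int]:
        return {p for p, _, _ in self.variants}


@dataclass(frozen=True)
class TranscriptModel:
    """Transcribed intervals of a genome, 0-based half-open, sorted,
    non-overlapping. The complement models non-transcribed regions
    (e.g. around a phage origin of replication)."""

    genome: str
    intervals: tuple[tuple[int, int], ...]
    genome_length: int

    def __post_init__(self) -> None:
        prev = 0
        for start, end in self.intervals:
            if not (0 <= start < end <= self.genome_length):
                raise ValueError(f"interval ({start},{end}) out of bounds")
            if start < prev:
                raise ValueError("intervals must be sorted and non-overlapping")
            prev = end

    def non_transcribed(self) -> tuple[tuple[int, int], ...]:
        """Complement of the transcribed intervals within the genome."""
        out = []
        cursor = 0
        for start, end in self.intervals:
            if start > cursor:
                out.append((cursor, start))
            cursor = end
        if cursor < self.genome_length:
            out.append((cursor, self.genome_length))
        return tuple(out)


@dataclass(frozen=True)
class QualityProfile:
    """Base-quality model: flat ``base_q`` with two degraded-tail read
    classes to exercise sliding-window trimming. ``degraded`` reads get a
    tail that trims but leaves the read long enough to keep; ``junk``
    reads get a longer tail that typically pushes them below the length
    floor."""

    base_q: int = 35
    degraded_frac: float = 0.0
    degraded_tail: int = 40
    junk_frac: float = 0.0
    junk_tail: int = 80
    floor_q: int = 2


@dataclass(frozen=True)
class SampleDesign:
    """One library to simulate.

    ``sources`` maps genome/strain ids to mixing weights (read-count
    proportions, normalised to sum to 1). ``dna_carryover`` is the
    fraction of an RNA library drawn uniformly from the whole genome
    rather than from transcribed intervals; it is 1 for DNA libraries by
    convention.
    """

    sample_id: str
    library: str  # "DNA" | "RNA"
    role: str  # "specimen" | "negative_control" | "positive_control"
    sources: tuple[tuple[str, float], ...]
    n_reads: int
    read_length: int = 100
    error_rate: float = 0.001
    quality: QualityProfile = field(default_factory=QualityProfile)
    dna_carryover: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.library not in ("DNA", "RNA"):
            raise ValueError(f"library must be DNA or RNA, got {self.library!r}")
        if self.role not in ("specimen", "negative_control", "positive_control"):
            raise ValueError(f"unknown role {self.role!r}")
        if any(w < 0 for _, w in self.sources) or not self.sources:
            raise ValueError("source weights must be non-negative and non-empty")
        total = sum(w for _, w in self.sources)
        if total <= 0:
            raise ValueError("source weights must sum to a positive value")
        if not (0.0 <= self.dna_carryover <= 1.0):
            raise ValueError("dna_carryover must lie in [0, 1]")
        if self.library == "DNA" and self.dna_carryover != 1.0:
            object.__setattr__(self, "dna_carryover", 1.0)

    def normalised_sources(self) -> tuple[tuple[str, float], ...]:
        total = sum(w for _, w in self.sources)
        return tuple((name, w / total) for name, w in self.sources)


# ---------------------------------------------------------------------------
# generators


def generate_genome(length: int, gc: float, seed: int, name: str = "genome",
                    circular: bool = False) -> Genome:
    """Generate a random genome with i.i.d. bases at GC fraction ``gc``."""
    if length < 1:
        raise ValueError(f"genome length must be positive, got {length}")
    if not (0.0 < gc < 1.0):
        raise ValueError(f"gc must lie in (0, 1), got {gc}")
    rng = np.random.default_rng(seed)
    at = (1.0 - gc) / 2.0
    probs = np.array([at, gc / 2.0, gc / 2.0, at])  # A C G T
    idx = rng.choice(4, size=length, p=probs)
    seq = _BASE_ARR[idx].tobytes().decode()
    return Genome(name, seq, circular)


def derive_strain(parent: Genome, n_snvs: int, seed: int,
                  name: str | None = None) -> tuple[Genome, StrainTruth]:
    """Derive a strain from ``parent`` by planting ``n_snvs`` substitutions
    at uniformly drawn positions (without replacement)."""
    if n_snvs > len(parent):
        raise ValueError(f"n_snvs={n_snvs} exceeds genome length {len(parent)}")
    rng = np.random.default_rng(seed)
    positions = rng.choice(len(parent), size=n_snvs, replace=False)
    seq = bytearray(parent.sequence.encode())
    variants = []
    for pos in sorted(int(p) for p in positions):
        ref = chr(seq[pos])
        alt = BASES[(BASES.index(ref) + int(rng.integers(1, 4))) % 4]
        seq[pos] = ord(alt)
        variants.append((pos, ref, alt))
    strain_name = name or f"{parent.name}_strain{seed}"
    genome = Genome(strain_name, seq.decode(), parent.circular)
    return genome, StrainTruth(parent.name, frozenset(variants))


def apply_variants(parent: Genome, truth: StrainTruth, name: str = "replayed") -> Genome:
    """Replay a truth set onto the parent sequence (inverse of derive)."""
    seq = bytearray(parent.sequence.encode())
    for pos, ref, alt in truth.variants:
        if chr(seq[pos]) != ref:
            raise ValueError(f"ref allele mismatch at {pos}: {chr(seq[pos])} != {ref}")
        seq[pos] = ord(alt)
    return Genome(name, seq.decode(), parent.circular)


def make_transcript_model(genome: Genome, intervals: Sequence[tuple[int, int]] | None = None,
                          transcribed_fraction: float = 0.7,
                          block: int = 3000) -> TranscriptModel:
    """Build a transcript model, either from explicit intervals or by
    deterministic tiling: each ``block``-sized window gets a transcribed
    prefix covering ``transcribed_fraction`` of it."""
    if intervals is not None:
        return TranscriptModel(genome.name, tuple(tuple(iv) for iv in sorted(intervals)),
                               len(genome))
    out = []
    g = len(genome)
    for start in range(0, g, block):
        end = min(start + int(round(block * transcribed_fraction)), g)
        if end > start:
            out.append((start, end))
    return TranscriptModel(genome.name, tuple(out), g)


# ---------------------------------------------------------------------------
# read simulation


def _quality_string(rng: np.random.Generator, length: int, prof: QualityProfile) -> str:
    """Draw one read's quality string from the profile's read classes."""
    u = rng.random()
    q = np.full(length, prof.base_q, dtype=np.int64)
    if u < prof.junk_frac:
        tail = min(prof.junk_tail, length)
    elif u < prof.junk_frac + prof.degraded_frac:
        tail = min(prof.degraded_tail, length)
    else:
        tail = 0
    if tail:
        ramp = prof.base_q - (prof.base_q - prof.floor_q) * (
            np.arange(1, tail + 1) / tail)
        q[length - tail:] = np.rint(ramp).astype(np.int64)
    return (q + 33).astype(np.uint8).tobytes().decode()


def _valid_starts(intervals: Iterable[tuple[int, int]], read_len: int) -> list[tuple[int, int]]:
    """Start ranges [s0, s1) such that a read of read_len fits wholly
    inside one interval."""
    out = []
    for start, end in intervals:
        if end - start >= read_len:
            out.append((start, end - read_len + 1))
    return out


def simulate_sample(design: SampleDesign, panel: Mapping[str, Genome],
                    transcripts: Mapping[str, TranscriptModel] | None = None,
                    ) -> tuple[list[Read], pd.DataFrame]:
    """Simulate one library.

    Returns the reads and a truth table with one row per read:
    (read_id, source, position, strand, is_dna_derived).

    RNA reads that are not DNA-derived lie wholly within transcribed
    intervals of their source; a fraction ``dna_carryover`` of RNA reads
    is drawn uniformly from the whole genome and flagged DNA-derived.
    Substitution errors are i.i.d. at ``error_rate``.
    """
    sources = design.normalised_sources()
    L = design.read_length
    for name, _ in sources:
        if name not in panel:
            raise ConfigurationError(f"sample {design.sample_id}: unknown source {name!r}")
        if L > len(panel[name]):
            raise ValueError(
                f"read length {L} exceeds genome {name!r} length {len(panel[name])}")
    if design.library == "RNA":
        transcripts = transcripts or {}
        for name, _ in sources:
            if name not in transcripts:
                raise ConfigurationError(
                    f"RNA sample {design.sample_id}: source {name!r} has no transcript model")

    rng = np.random.default_rng(design.seed)
    weights = np.array([w for _, w in sources])
    counts = rng.multinomial(design.n_reads, weights)

    reads: list[Read] = []
    rows: list[tuple[str, str, int, str, bool]] = []
    read_no = 0
    for (src_name, _), n_src in zip(sources, counts):
        genome = panel[src_name]
        g = len(genome)
        seq_bytes = genome.sequence.encode()
        if design.library == "RNA":
            tm = transcripts[src_name]
            tx_ranges = _valid_starts(tm.intervals, L)
            if not tx_ranges:
                raise ConfigurationError(
                    f"RNA sample {design.sample_id}: no transcribed interval of "
                    f"{src_name!r} can hold a {L} bp read")
            tx_sizes = np.array([b - a for a, b in tx_ranges])
            tx_cum = np.cumsum(tx_sizes)
        for _ in range(int(n_src)):
            if design.library == "RNA" and rng.random() >= design.dna_carryover:
                # transcript-derived: wholly inside a transcribed interval
                flat = int(rng.integers(0, tx_cum[-1]))
                k = int(np.searchsorted(tx_cum, flat, side="right"))
                pos = tx_ranges[k][0] + flat - (int(tx_cum[k - 1]) if k else 0)
                is_dna = False
            else:
                pos = int(rng.integers(0, g - L + 1))
                is_dna = True
            fragment = bytearray(seq_bytes[pos:pos + L])
            # sequencing errors before strand flip: symmetric either way
            n_err = rng.binomial(L, design.error_rate)
            if n_err:
                for epos in rng.choice(L, size=n_err, replace=False):
                    cur = chr(fragment[epos])
                    fragment[epos] = ord(BASES[(BASES.index(cur) + int(rng.integers(1, 4))) % 4])
            seq = fragment.decode()
            strand = "+" if rng.random() < 0.5 else "-"
            if strand == "-":
                seq = revcomp(seq)
            rid = f"{design.sample_id}_r{read_no}"
            reads.append(Read(rid, seq, _quality_string(rng, L, design.quality)))
            rows.append((rid, src_name, pos, strand, is_dna))
            read_no += 1

    truth = pd.DataFrame(rows, columns=["read_id", "source", "position", "strand",
                                        "is_dna_derived"])
    return reads, truth


# ---------------------------------------------------------------------------
# whole-study construction


@dataclass
class Study:
    """A fully materialised synthetic study: references, strains,
    transcript models, designs, simulated reads and truth tables."""

    references: dict[str, Genome]          # reference panel (mapping targets)
    sources: dict[str, Genome]             # all source genomes incl. strains
    strain_truths: dict[str, StrainTruth]
    transcripts: dict[str, TranscriptModel]
    designs: dict[str, SampleDesign]
    reads: dict[str, list[Read]]
    truths: dict[str, pd.DataFrame]
    panel_order: list[str]
    source_reference: dict[str, str]       # source id -> panel reference name


def simulate_study(designs: Sequence[SampleDesign], references: Mapping[str, Genome],
                   sources: Mapping[str, Genome],
                   strain_truths: Mapping[str, StrainTruth],
                   transcripts: Mapping[str, TranscriptModel],
                   panel_order: Sequence[str],
                   source_reference: Mapping[str, str]) -> Study:
    """Simulate every design; raises on duplicate sample ids."""
    ids = [d.sample_id for d in designs]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ConfigurationError(f"duplicate sample ids: {dupes}")
    reads: dict[str, list[Read]] = {}
    truths: dict[str, pd.DataFrame] = {}
    for design in designs:
        r, t = simulate_sample(design, sources, transcripts)
        reads[design.sample_id] = r
        truths[design.sample_id] = t
    return Study(dict(references), dict(sources), dict(strain_truths), dict(transcripts),
                 {d.sample_id: d for d in designs}, reads, truths, list(panel_order),
                 dict(source_reference))


def write_study(study: Study, outdir: str | os.PathLike) -> pd.DataFrame:
    """Write FASTQ files, reference FASTA, transcript BEDs, truth tables
    and a sample sheet. Returns the sample sheet."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    write_fasta(out / "references.fasta",
                {name: study.references[name].sequence for name in study.panel_order})
    for name, tm in study.transcripts.items():
        ref = study.source_reference.get(name, name)
        if ref in study.references and name == ref:
            with open(out / f"{ref}.transcribed.bed", "w") as fh:
                for start, end in tm.intervals:
                    fh.write(f"{ref}\t{start}\t{end}\n")
    rows = []
    for sid, design in study.designs.items():
        fq = out / f"{sid}.fastq"
        write_fastq(fq, study.reads[sid])
        study.truths[sid].to_csv(out / f"{sid}.truth.tsv", sep="\t", index=False)
        rows.append((sid, design.library, design.role, fq.name))  # path relative to sheet
    sheet = pd.DataFrame(rows, columns=["sample_id", "library", "role", "fastq_path"])
    sheet.to_csv(out / "samples.tsv", sep="\t", index=False)
    return sheet
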