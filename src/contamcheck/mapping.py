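"""Deterministic seed-and-extend read mapping and ordered competitive
(iterative map-and-remove) assignment.

The mapper is intentionally simple and fully specified: exact k-mer
seeds on both strands propose candidate loci, each candidate is scored
by ungapped full-length identity, and the best hit is reported if it
reaches ``min_identity``. Ties break to the forward strand, then the
lowest start coordinate. Competitive assignment walks an *ordered*
reference panel: a read mapping to panel member i is removed from the
pool before member i+1, which suppresses cross-mapping between related
genomes (host first, spike-in virus last by convention).

SAM import/export via pysam allows substituting an external mapper.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pysam

from .errors import ConfigurationError, DataFormatError
from .seqio import Read, revcomp
from .simdata import Genome

log = logging.getLogger(__name__)

DEFAULT_K = 21
DEFAULT_MIN_IDENTITY = 0.90
MAX_CANDIDATES = 50  # deterministic cap per strand; lowest start positions kept


@dataclass(frozen=True)
class AlignmentRecord:
    """An ungapped full-length alignment of a read to a reference."""

    read_id: str
    reference: str
    start: int                  # 0-based
    strand: str                 # "+" | "-"
    aligned_length: int
    mismatch_positions: tuple[int, ...]  # reference coordinates

    @property
    def end(self) -> int:
        return self.start + self.aligned_length

    @property
    def identity(self) -> float:
        return 1.0 - len(self.mismatch_positions) / self.aligned_length


class GenomeIndex:
    """Exact k-mer index over the forward strand of one genome."""

    def __init__(self, genome: Genome, k: int = DEFAULT_K):
        self.genome = genome
        self.k = k
        seq = genome.sequence.encode()
        self.arr = np.frombuffer(seq, np.uint8)
        index: dict[bytes, list[int]] = {}
        for i in range(len(seq) - k + 1):
            index.setdefault(seq[i : i + k], []).append(i)
        self.index = index

    def __len__(self) -> int:
        return len(self.genome)


def _candidate_starts(idx: GenomeIndex, seq: bytes, stride: int) -> list[int]:
    """Candidate alignment start positions from exact seed hits,
    deduplicated, sorted, capped at MAX_CANDIDATES lowest."""
    k = idx.k
    limit = len(idx.arr) - len(seq)
    cands: set[int] = set()
    for off in range(0, len(seq) - k + 1, stride):
        hits = idx.index.get(seq[off : off + k])
        if hits:
            for p in hits:
                s = p - off
                if 0 <= s <= limit:
                    cands.add(s)
    return sorted(cands)[:MAX_CANDIDATES]


def map_read(read: Read, index: GenomeIndex,
             min_identity: float = DEFAULT_MIN_IDENTITY,
             seed_stride: int = 1) -> AlignmentRecord | None:
    """Map one read; returns the best hit or None.

    Both strands are scanned (the read's reverse complement against the
    forward index). Reads shorter than k are treated as no-hit with a
    logged warning.
    """
    L = len(read)
    if L < index.k:
        log.warning("read %s shorter than seed length %d: no-hit", read.id, index.k)
        return None
    if L > len(index.arr):
        return None
    best: tuple[float, int, int] | None = None  # (identity, strand_rank, start)
    best_mm: np.ndarray | None = None
    for strand_rank, seq in enumerate((read.sequence, revcomp(read.sequence))):
        sb = seq.encode()
        rarr = np.frombuffer(sb, np.uint8)
        for s in _candidate_starts(index, sb, seed_stride):
            mm = np.nonzero(index.arr[s : s + L] != rarr)[0]
            ident = 1.0 - mm.size / L
            if ident < min_identity:
                continue
            key = (ident, -strand_rank, -s)
            if best is None or key > (best[0], -best[1], -best[2]):
                best = (ident, strand_rank, s)
                best_mm = mm
    if best is None:
        return None
    _, strand_rank, start = best
    assert best_mm is not None
    return AlignmentRecord(read.id, index.genome.name, start,
                           "+" if strand_rank == 0 else "-", L,
                           tuple(int(start + i) for i in best_mm))


@dataclass
class ReferencePanel:
    """Ordered, named reference genomes with k-mer indexes. Order is
    significant: it is the competitive-mapping precedence."""

    genomes: Sequence[Genome]
    k: int = DEFAULT_K
    indexes: dict[str, GenomeIndex] = field(init=False)

    def __post_init__(self) -> None:
        names = [g.name for g in self.genomes]
        if len(set(names)) != len(names):
            raise ConfigurationError(f"duplicate reference names in panel: {names}")
        self.indexes = {g.name: GenomeIndex(g, self.k) for g in self.genomes}

    @property
    def order(self) -> list[str]:
        return [g.name for g in self.genomes]

    def reordered(self, order: Sequence[str]) -> "ReferencePanel":
        by_name = {g.name: g for g in self.genomes}
        missing = [n for n in order if n not in by_name]
        if missing:
            raise ConfigurationError(f"unknown panel members in order: {missing}")
        panel = ReferencePanel.__new__(ReferencePanel)
        panel.genomes = [by_name[n] for n in order]
        panel.k = self.k
        panel.indexes = {n: self.indexes[n] for n in order}
        return panel


@dataclass
class AssignmentTable:
    """Per-read competitive assignment plus per-reference counts."""

    assignments: dict[str, str]       # read id -> reference name ("unassigned" excluded)
    counts: dict[str, int]            # reference -> mapped read count
    unassigned: int
    input_reads: int
    records: dict[str, list[AlignmentRecord]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if sum(self.counts.values()) + self.unassigned != self.input_reads:
            raise ValueError("assignment counts do not partition the input reads")

    def assignment_of(self, read_id: str) -> str:
        return self.assignments.get(read_id, "unassigned")


def iterative_assign(reads: Sequence[Read], panel: ReferencePanel,
                     min_identity: float = DEFAULT_MIN_IDENTITY,
                     seed_stride: int = 1,
                     keep_records: bool = True) -> AssignmentTable:
    """Ordered competitive assignment over the panel.

    Reads are mapped against panel members in order; a read that maps to
    member i is removed from the pool before member i+1. The partition
    invariant (sum of per-reference counts + unassigned = input) is
    enforced structurally.
    """
    pool = list(reads)
    assignments: dict[str, str] = {}
    counts: dict[str, int] = {}
    records: dict[str, list[AlignmentRecord]] = {}
    for name in panel.order:
        index = panel.indexes[name]
        remaining: list[Read] = []
        hits: list[AlignmentRecord] = []
        for read in pool:
            rec = map_read(read, index, min_identity, seed_stride)
            if rec is None:
                remaining.append(read)
            else:
                assignments[read.id] = name
                hits.append(rec)
        counts[name] = len(hits)
        if keep_records:
            records[name] = hits
        pool = remaining
    return AssignmentTable(assignments, counts, len(pool), len(reads),
                           records if keep_records else {})


# ---------------------------------------------------------------------------
# SAM interoperability


def export_alignments(path: str | os.PathLike, alignments: Iterable[AlignmentRecord],
                      reads: Mapping[str, Read], panel_genomes: Sequence[Genome]) -> None:
    """Write alignments as plain SAM (1-based in the file; pysam handles
    the coordinate shift). Reverse-strand records store the
    reverse-complemented read sequence, per SAM convention."""
    header = {"HD": {"VN": "1.6", "SO": "unknown"},
              "SQ": [{"SN": g.name, "LN": len(g)} for g in panel_genomes]}
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for rec in alignments:
            read = reads[rec.read_id]
            a = pysam.AlignedSegment(out.header)
            a.query_name = rec.read_id
            seq = read.sequence if rec.strand == "+" else revcomp(read.sequence)
            qual = read.quality if rec.strand == "+" else read.quality[::-1]
            a.query_sequence = seq
            a.query_qualities = pysam.qualitystring_to_array(qual)
            a.flag = 0 if rec.strand == "+" else 16
            a.reference_id = out.header.get_tid(rec.reference)
            a.reference_start = rec.start
            a.mapping_quality = 60
            a.cigarstring = f"{rec.aligned_length}M"
            a.set_tag("NM", len(rec.mismatch_positions))
            out.write(a)


def import_alignments(path: str | os.PathLike, reference: str,
                      genome: Genome | None = None) -> list[AlignmentRecord]:
    """Read SAM/BAM records for one reference into AlignmentRecords.

    Unmapped records are ignored. Mismatch positions are recomputed from
    the genome when given, else taken as empty with identity implied by
    the NM tag absent. 1-based file coordinates become 0-based here.
    """
    garr = (np.frombuffer(genome.sequence.encode(), np.uint8) if genome is not None else None)
    out: list[AlignmentRecord] = []
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as fh:
        if reference not in fh.references:
            raise ConfigurationError(
                f"reference {reference!r} absent from alignment header "
                f"(has: {list(fh.references)})")
        for a in fh.fetch(until_eof=True):
            if a.is_unmapped or fh.get_reference_name(a.reference_id) != reference:
                continue
            length = a.query_length or len(a.query_sequence or "")
            if genome is not None and a.reference_start + length > len(genome):
                raise DataFormatError(
                    f"alignment of {a.query_name!r} exceeds reference bounds")
            mism: tuple[int, ...] = ()
            if garr is not None and a.query_sequence:
                seg = np.frombuffer(a.query_sequence.upper().encode(), np.uint8)
                ref_seg = garr[a.reference_start : a.reference_start + length]
                mism = tuple(int(a.reference_start + i)
                             for i in np.nonzero(ref_seg != seg)[0])
            out.append(AlignmentRecord(a.query_name, reference, a.reference_start,
                                       "-" if a.is_reverse else "+", length, mism))
    return out


def aligned_bases(rec: AlignmentRecord, read: Read) -> str:
    """The read sequence in reference orientation for pileup tallying."""
    return read.sequence if rec.strand == "+" else revcomp(read.sequence)
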