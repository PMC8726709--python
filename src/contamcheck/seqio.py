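"""Sequence containers and FASTA/FASTQ I/O.

Reads are single-end with Sanger (Phred+33) qualities. Parsing goes
through Biopython; record formatting on output is the plain four-line
FASTQ layout.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from typing import Iterable, Iterator

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqIO.QualityIO import FastqGeneralIterator
from Bio.SeqRecord import SeqRecord

from .errors import DataFormatError

PHRED_OFFSET = 33

_COMPLEMENT = bytes.maketrans(b"ACGTacgt", b"TGCAtgca")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class Read:
    """A single-end read: sequence plus Phred+33 quality string."""

    id: str
    sequence: str
    quality: str

    def __post_init__(self) -> None:
        if len(self.sequence) != len(self.quality):
            raise DataFormatError(
                f"read {self.id!r}: sequence length {len(self.sequence)} != "
                f"quality length {len(self.quality)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)

    def phred(self) -> np.ndarray:
        """Quality scores as an integer array."""
        return np.frombuffer(self.quality.encode(), np.uint8).astype(np.int64) - PHRED_OFFSET


def read_fastq(path: str | os.PathLike) -> Iterator[Read]:
    """Iterate FASTQ records as :class:`Read` objects.

    Raises :class:`DataFormatError` naming the record index on malformed
    input.
    """
    index = 0
    try:
        with open(path) as fh:
            for title, seq, qual in FastqGeneralIterator(fh):
                if len(seq) != len(qual):
                    raise DataFormatError(
                        f"FASTQ record {index} ({title.split()[0]!r}): "
                        "sequence/quality length mismatch"
                    )
                yield Read(title.split()[0], seq, qual)
                index += 1
    except ValueError as exc:  # Biopython signals malformed records this way
        raise DataFormatError(f"malformed FASTQ record at index {index}: {exc}") from exc


def write_fastq(path: str | os.PathLike, reads: Iterable[Read]) -> int:
    """Write reads in four-line FASTQ; returns the number written."""
    n = 0
    with open(path, "w") as fh:
        for r in reads:
            fh.write(f"@{r.id}\n{r.sequence}\n+\n{r.quality}\n")
            n += 1
    return n


def read_fasta(path: str | os.PathLike) -> dict[str, str]:
    """Load a (multi-)FASTA as an ordered name -> sequence mapping."""
    out: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        out[rec.id] = str(rec.seq).upper()
    return out


def write_fasta(path: str | os.PathLike, entries: dict[str, str]) -> None:
    records = [SeqRecord(Seq(seq), id=name, description="") for name, seq in entries.items()]
    SeqIO.write(records, str(path), "fasta")
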