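"""DNA-carryover detection for RNA libraries.

An RNA library free of genomic DNA should only cover transcribed
regions. Reads falling *wholly inside* annotated non-transcribed
intervals (e.g. around a phage origin of replication) can only come
from DNA templates. Under uniform DNA read starts, the chance that a
read of length L lands wholly inside the non-transcribed intervals of a
genome of length G is

    E = sum_i max(0, l_i - L + 1) / (G - L + 1)

over non-transcribed interval lengths l_i, so the observed fraction w/n
of such reads estimates the DNA-derived fraction as

    delta_hat = min(1, (w/n) / E).

Only fully interior reads count as DNA evidence — transcript reads may
legitimately touch interval boundaries — which makes the estimator
conservative by construction. A per-base depth ratio is offered as a
cross-check alongside.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .mapping import AlignmentRecord
from .simdata import TranscriptModel

DEFAULT_REPORTING_FLOOR = 0.01


@dataclass
class CoverageBreadth:
    reference: str
    intervals: tuple[tuple[int, int], ...]
    covered_bases: int
    total_bases: int

    @property
    def breadth_percent(self) -> float | None:
        """None (undefined) for an empty interval set."""
        if self.total_bases == 0:
            return None
        return 100.0 * self.covered_bases / self.total_bases


def breadth(alignments: Iterable[AlignmentRecord],
            intervals: Sequence[tuple[int, int]],
            genome_length: int, reference: str = "") -> CoverageBreadth:
    """Breadth of coverage over the union of ``intervals``: a base is
    covered iff at least one aligned read overlaps it. Invariant to read
    order and to duplicate alignments of the same read."""
    cover = np.zeros(genome_length, dtype=bool)
    ref = reference
    for rec in alignments:
        ref = ref or rec.reference
        cover[rec.start : rec.end] = True
    mask = np.zeros(genome_length, dtype=bool)
    ivs = tuple(tuple(iv) for iv in intervals)
    for start, end in ivs:
        if not (0 <= start <= end <= genome_length):
            raise ValueError(f"interval ({start},{end}) outside reference bounds")
        mask[start:end] = True
    total = int(mask.sum())
    covered = int((cover & mask).sum())
    return CoverageBreadth(ref, ivs, covered, total)


@dataclass
class DnaCarryoverResult:
    sample_id: str
    reference: str
    interior_reads: int          # w: reads wholly inside non-transcribed intervals
    total_reads: int             # n: mapped reads considered
    expected_fraction: float     # E under a pure-DNA library
    delta_hat: float             # estimated DNA-derived fraction, in [0, 1]
    verdict: bool                # DNA carryover present above reporting floor
    depth_ratio: float | None = None  # cross-check: mean depth non-transcribed / overall
    status: str = "ok"           # "ok" | "insufficient-data"


def _expected_fraction(non_tx: Sequence[tuple[int, int]], read_len: int,
                       genome_length: int) -> float:
    inside = sum(max(0, (end - start) - read_len + 1) for start, end in non_tx)
    return inside / (genome_length - read_len + 1)


def estimate_dna_fraction(alignments: Iterable[AlignmentRecord],
                          transcript_model: TranscriptModel,
                          sample_id: str = "sample",
                          read_length: int | None = None,
                          reporting_floor: float = DEFAULT_REPORTING_FLOOR,
                          ) -> DnaCarryoverResult:
    """Estimate the DNA-derived read fraction of an RNA library from the
    reads wholly inside non-transcribed intervals.

    With ``read_length`` given, all reads are assumed that length; with
    None the per-read aligned length is used (a warning is emitted when
    lengths vary and no uniform length was declared).
    """
    non_tx = transcript_model.non_transcribed()
    if not non_tx:
        raise ValueError("transcript model has no non-transcribed complement")
    G = transcript_model.genome_length
    recs = list(alignments)
    n = len(recs)
    ref = transcript_model.genome
    if n == 0:
        return DnaCarryoverResult(sample_id, ref, 0, 0, 0.0, 0.0, False,
                                  status="insufficient-data")
    lengths = {r.aligned_length for r in recs}
    if read_length is None and len(lengths) > 1:
        warnings.warn(f"{sample_id}: non-uniform read lengths "
                      f"({min(lengths)}-{max(lengths)}); using per-read lengths")
    w = 0
    e_sum = 0.0
    cover = np.zeros(G, dtype=np.int64)
    for rec in recs:
        L = read_length if read_length is not None else rec.aligned_length
        e_sum += _expected_fraction(non_tx, L, G)
        if any(start <= rec.start and rec.end <= end for start, end in non_tx):
            w += 1
        cover[rec.start : rec.end] += 1
    E = e_sum / n
    delta_hat = min(1.0, (w / n) / E) if E > 0 else 0.0
    ntx_mask = np.zeros(G, dtype=bool)
    for start, end in non_tx:
        ntx_mask[start:end] = True
    overall_depth = float(cover.mean())
    depth_ratio = (float(cover[ntx_mask].mean()) / overall_depth
                   if overall_depth > 0 else None)
    verdict = w > 0 and delta_hat >= reporting_floor
    return DnaCarryoverResult(sample_id, ref, w, n, E, delta_hat, verdict, depth_ratio)
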