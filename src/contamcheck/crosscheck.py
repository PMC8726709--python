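"""Deliberately naive reference implementations used to validate the
production code paths.

These are written for obviousness, not speed, and share no code with
the modules they check: the trimmer below walks windows one by one in
pure Python; the aligner below scores every offset on both strands
exhaustively. They exist so the fast implementations can be held to a
zero-discrepancy standard on randomized inputs.
"""

from __future__ import annotations

from .seqio import Read, revcomp
from .simdata import Genome


def bruteforce_trim(sequence: str, quality: str, window: int = 4,
                    threshold: float = 20.0, min_length: int = 70,
                    offset: int = 33) -> tuple[str, str] | None:
    """Window-by-window scan; returns (sequence, quality) or None for a
    discard verdict."""
    phred = [ord(c) - offset for c in quality]
    n = len(phred)
    if n == 0:
        return None
    clip = n
    if n < window:
        if sum(phred) / n < threshold:
            clip = 0
    else:
        for start in range(0, n - window + 1):
            mean = sum(phred[start : start + window]) / window
            if mean < threshold:
                clip = start
                break
    if clip < min_length:
        return None
    return sequence[:clip], quality[:clip]


def bruteforce_map(read: Read, genome: Genome, min_identity: float = 0.90
                   ) -> tuple[int, str, int] | None:
    """Exhaustive all-offset, both-strand ungapped scoring.

    Returns (start, strand, mismatches) of the best alignment at or
    above ``min_identity``, or None. Ties break to the forward strand,
    then the lowest start, matching the production mapper's contract.
    """
    L = len(read)
    G = len(genome)
    if L > G:
        return None
    best: tuple[int, str, int] | None = None
    best_mm = L + 1
    for strand, seq in (("+", read.sequence), ("-", revcomp(read.sequence))):
        for start in range(0, G - L + 1):
            mm = sum(1 for a, b in zip(seq, genome.sequence[start : start + L]) if a != b)
            if 1.0 - mm / L < min_identity:
                continue
            if mm < best_mm:
                best, best_mm = (start, strand, mm), mm
            # equal-score later candidates never replace: scan order is
            # forward strand first, then ascending start
    return best
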