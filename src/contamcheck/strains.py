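"""Strain-level forensics: pileups, consensus SNV calling, pairwise
strain-sharing, within-sample mixture detection, and consensus ANI.

The logic mirrors how one reads an alignment viewer: a sample's strain
identity is its set of consensus single-nucleotide variants against a
reference; two samples carry the same strain when their variant alleles
agree at essentially every site callable in both; a sample carries a
strain *mixture* when many sites show intermediate allele frequencies;
and consensus ANI against the reference quantifies how close a sample's
consensus genome is to a known lab strain. Finding the same strain in
nominally independent samples — or in negative controls — is the
genomic-independence violation that indicates contamination.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .mapping import AlignmentRecord, aligned_bases
from .seqio import Read
from .simdata import BASES, Genome
from .errors import DataFormatError

_BASE_TO_IDX = np.full(256, -1, dtype=np.int64)
for _i, _b in enumerate(BASES):
    _BASE_TO_IDX[ord(_b)] = _i

DEFAULT_CMIN = 5
DEFAULT_FCONS = 0.8
DEFAULT_M_MIN = 10
DEFAULT_AGREEMENT = 0.99
DEFAULT_BAND = (0.2, 0.8)
DEFAULT_MIXTURE_SITES = 5
MIXTURE_SD_COHERENCE = 0.15


@dataclass
class Pileup:
    """Per-position A/C/G/T counts over one reference."""

    reference: str
    counts: np.ndarray  # shape (4, genome length), int64

    @property
    def depth(self) -> np.ndarray:
        return self.counts.sum(axis=0)


def build_pileup(alignments: Iterable[AlignmentRecord], reads: Mapping[str, Read],
                 genome: Genome) -> Pileup:
    """Tally every aligned base (matches and mismatches alike) once."""
    counts = np.zeros((4, len(genome)), dtype=np.int64)
    for rec in alignments:
        if rec.reference != genome.name:
            raise DataFormatError(
                f"alignment of {rec.read_id!r} targets {rec.reference!r}, "
                f"pileup is over {genome.name!r}")
        if rec.end > len(genome):
            raise DataFormatError(f"alignment of {rec.read_id!r} exceeds reference bounds")
        seq = aligned_bases(rec, reads[rec.read_id])
        idx = _BASE_TO_IDX[np.frombuffer(seq.encode(), np.uint8)]
        pos = np.arange(rec.start, rec.end)
        ok = idx >= 0
        np.add.at(counts, (idx[ok], pos[ok]), 1)
    return Pileup(genome.name, counts)


@dataclass
class SNVProfile:
    """A sample's consensus variants against a reference, plus the mask
    of callable sites (depth >= cmin)."""

    reference: str
    sample_id: str
    variants: dict[int, tuple[str, float, int]]  # pos -> (alt allele, freq, depth)
    callable_mask: np.ndarray                    # bool per position

    def positions(self) -> set[int]:
        return set(self.variants)


def call_snvs(pileup: Pileup, genome: Genome, sample_id: str = "sample",
              fcons: float = DEFAULT_FCONS, cmin: int = DEFAULT_CMIN) -> SNVProfile:
    """Consensus SNV calling: a site is a variant iff depth >= cmin and
    the most frequent non-reference allele reaches frequency fcons."""
    if not fcons > 0.5:
        raise ValueError("fcons must exceed 0.5 for a consensus call")
    depth = pileup.depth
    callable_mask = depth >= cmin
    ref_idx = _BASE_TO_IDX[np.frombuffer(genome.sequence.encode(), np.uint8)]
    nonref = pileup.counts.copy()
    nonref[ref_idx, np.arange(len(genome))] = -1
    alt_idx = nonref.argmax(axis=0)
    alt_count = nonref.max(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        alt_freq = np.where(depth > 0, alt_count / np.maximum(depth, 1), 0.0)
    is_var = callable_mask & (alt_count > 0) & (alt_freq >= fcons)
    variants = {
        int(p): (BASES[int(alt_idx[p])], float(alt_freq[p]), int(depth[p]))
        for p in np.nonzero(is_var)[0]
    }
    return SNVProfile(pileup.reference, sample_id, variants, callable_mask)


@dataclass
class ShareResult:
    sample_a: str
    sample_b: str
    comparable_sites: int
    agreeing_sites: int
    verdict: str  # "same-strain" | "distinct" | "insufficient-data"

    @property
    def agreement(self) -> float:
        return self.agreeing_sites / self.comparable_sites if self.comparable_sites else 0.0


def share_score(a: SNVProfile, b: SNVProfile, m_min: int = DEFAULT_M_MIN,
                agreement_threshold: float = DEFAULT_AGREEMENT) -> ShareResult:
    """Compare two samples' strain identity on one reference.

    Comparable sites are callable in both samples and variant in at
    least one; agreement is the fraction with identical major alleles.
    At a site variant in only one sample the major alleles necessarily
    differ (variant alt vs reference base), so no reference sequence is
    needed. Symmetric in its arguments.
    """
    if a.reference != b.reference:
        raise ValueError(f"profiles target different references: "
                         f"{a.reference!r} vs {b.reference!r}")
    both = a.callable_mask & b.callable_mask
    sites = [p for p in (a.positions() | b.positions()) if both[p]]
    agree = sum(1 for p in sites
                if p in a.variants and p in b.variants
                and a.variants[p][0] == b.variants[p][0])
    m = len(sites)
    if m < m_min:
        verdict = "insufficient-data"
    elif agree / m >= agreement_threshold:
        verdict = "same-strain"
    else:
        verdict = "distinct"
    return ShareResult(a.sample_id, b.sample_id, m, agree, verdict)


@dataclass
class MixtureCall:
    sample_id: str
    reference: str
    intermediate_sites: int
    mean_minor_freq: float
    sd_minor_freq: float
    verdict: str  # "single" | "mixture" | "insufficient-data"

    @property
    def frequency_coherent(self) -> bool:
        """Whether the intermediate frequencies cluster tightly enough to
        support a two-strain (rather than noise) interpretation."""
        return self.intermediate_sites > 0 and self.sd_minor_freq <= MIXTURE_SD_COHERENCE


def detect_mixture(pileup: Pileup, sample_id: str = "sample",
                   band: tuple[float, float] = DEFAULT_BAND,
                   site_minimum: int = DEFAULT_MIXTURE_SITES,
                   cmin: int = DEFAULT_CMIN,
                   min_minor_count: int = 2) -> MixtureCall:
    """Call a within-sample strain mixture from intermediate-frequency
    sites: positions with depth >= cmin whose minor (second most
    frequent) allele frequency falls in ``band``. A minor allele needs
    ``min_minor_count`` supporting reads — a single read is never
    mixture evidence (it is indistinguishable from a sequencing error
    at marginal depth)."""
    flo, fhi = band
    if not (0.0 < flo < fhi < 1.0):
        raise ValueError(f"band must satisfy 0 < flo < fhi < 1, got {band}")
    depth = pileup.depth
    deep = depth >= cmin
    if not deep.any():
        return MixtureCall(sample_id, pileup.reference, 0, 0.0, 0.0, "insufficient-data")
    srt = np.sort(pileup.counts, axis=0)
    minor = srt[-2]  # second most frequent allele count
    with np.errstate(divide="ignore", invalid="ignore"):
        mfreq = np.where(deep, minor / np.maximum(depth, 1), 0.0)
    in_band = deep & (mfreq >= flo) & (mfreq <= fhi) & (minor >= min_minor_count)
    n = int(in_band.sum())
    freqs = mfreq[in_band]
    mean = float(freqs.mean()) if n else 0.0
    sd = float(freqs.std()) if n else 0.0
    verdict = "mixture" if n >= site_minimum else "single"
    return MixtureCall(sample_id, pileup.reference, n, mean, sd, verdict)


@dataclass
class AniResult:
    sample_id: str
    reference: str
    compared_positions: int
    identical_positions: int
    verdict: str  # "ok" | "insufficient-data"

    @property
    def ani_percent(self) -> float:
        return (100.0 * self.identical_positions / self.compared_positions
                if self.compared_positions else float("nan"))


def consensus_ani(pileup: Pileup, genome: Genome, sample_id: str = "sample",
                  cmin: int = DEFAULT_CMIN) -> AniResult:
    """Average nucleotide identity of the sample's consensus sequence to
    the reference, over sites with depth >= cmin. Consensus ties break
    alphabetically (A<C<G<T), deterministically."""
    depth = pileup.depth
    mask = depth >= cmin
    compared = int(mask.sum())
    if compared == 0:
        return AniResult(sample_id, genome.name, 0, 0, "insufficient-data")
    consensus = pileup.counts.argmax(axis=0)  # first max wins: alphabetical
    ref_idx = _BASE_TO_IDX[np.frombuffer(genome.sequence.encode(), np.uint8)]
    identical = int((consensus[mask] == ref_idx[mask]).sum())
    return AniResult(sample_id, genome.name, compared, identical, "ok")


# ---------------------------------------------------------------------------
# tabular output


def profile_to_frame(profile: SNVProfile, genome: Genome) -> pd.DataFrame:
    """VCF-like table (1-based POS on output)."""
    rows = [(profile.reference, pos + 1, genome.sequence[pos], alt, round(freq, 4), depth)
            for pos, (alt, freq, depth) in sorted(profile.variants.items())]
    return pd.DataFrame(rows, columns=["CHROM", "POS", "REF", "ALT", "AF", "DP"])


def share_matrix(profiles: Sequence[SNVProfile], m_min: int = DEFAULT_M_MIN,
                 agreement_threshold: float = DEFAULT_AGREEMENT) -> pd.DataFrame:
    """Pairwise share verdicts as a long-form table."""
    rows = []
    for i, a in enumerate(profiles):
        for b in profiles[i + 1:]:
            r = share_score(a, b, m_min, agreement_threshold)
            rows.append((a.sample_id, b.sample_id, r.comparable_sites, r.agreeing_sites,
                         round(r.agreement, 4), r.verdict))
    return pd.DataFrame(rows, columns=["sample_a", "sample_b", "comparable_sites",
                                       "agreeing_sites", "agreement", "verdict"])
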