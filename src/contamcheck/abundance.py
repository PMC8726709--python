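"""Read accounting, dual-denominator relative abundance, and the
negative-control filters.

Two denominators are used deliberately: the host percentage is relative
to quality-filtered (retained) reads, while every non-host taxon is
relative to the host-depleted ("filtered") read pool. Percentages are
rounded half away from zero to one decimal, matching how sequencing
accounting tables are typically printed.

The ``control_filter`` reimplements the fold-change contaminant filter
used by gene-centric microbiome pipelines (keep a taxon only if its mean
relative abundance across specimens exceeds 4x the negative control,
i.e. log2 fold change > 2), here applied at the taxon level with an
explicit pseudocount. ``control_similarity_flag`` is the converse
forensic check: a specimen whose entire non-host profile sits within a
small fold of the negative control is indistinguishable from
contamination background.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import pandas as pd

from .errors import ConfigurationError


def percent(numerator: float, denominator: float) -> float:
    """100*num/den, rounded half away from zero to one decimal.

    A zero denominator yields 0.0 with a warning rather than an error so
    empty samples propagate as all-zero rows.
    """
    if numerator < 0 or denominator < 0:
        raise ValueError(f"counts must be non-negative, got ({numerator}, {denominator})")
    if denominator == 0:
        if numerator != 0:
            warnings.warn("percent() with zero denominator; reporting 0.0")
        return 0.0
    x = 100.0 * numerator / denominator
    return math.floor(x * 10.0 + 0.5) / 10.0 if x >= 0 else -math.floor(-x * 10.0 + 0.5) / 10.0


@dataclass
class AccountingRow:
    """One sample's read accounting from raw input to per-taxon counts."""

    sample_id: str
    library: str
    raw_reads: int
    removed_reads: int          # low-quality
    host_mapped: int
    taxon_counts: dict[str, int] = field(default_factory=dict)
    unassigned: int = 0

    @property
    def retained_reads(self) -> int:
        return self.raw_reads - self.removed_reads

    @property
    def filtered_reads(self) -> int:
        """Host-depleted read pool (denominator for non-host taxa)."""
        return self.retained_reads - self.host_mapped

    def __post_init__(self) -> None:
        if self.host_mapped > self.retained_reads:
            raise ValueError(f"{self.sample_id}: host mapped exceeds retained reads")
        if sum(self.taxon_counts.values()) + self.unassigned != self.filtered_reads:
            raise ValueError(
                f"{self.sample_id}: taxon counts + unassigned != filtered reads")

    @property
    def host_percent(self) -> float:
        return percent(self.host_mapped, self.retained_reads)

    def taxon_percent(self, taxon: str) -> float:
        return percent(self.taxon_counts.get(taxon, 0), self.filtered_reads)


@dataclass
class AbundanceProfile:
    """Dual-denominator relative abundance for one sample."""

    sample_id: str
    host_percent: float
    taxa: dict[str, float]  # taxon -> percent of host-depleted reads


def build_accounting(qc_summaries: Mapping[str, "object"],
                     assignments: Mapping[str, "object"],
                     host: str,
                     libraries: Mapping[str, str] | None = None) -> list[AccountingRow]:
    """Assemble accounting rows from per-sample QC summaries and
    competitive-mapping assignment tables.

    ``qc_summaries`` maps sample id -> QCSummary; ``assignments`` maps
    sample id -> AssignmentTable (see :mod:`contamcheck.mapping`).
    """
    missing = sorted((set(qc_summaries) | set(assignments)) -
                     (set(qc_summaries) & set(assignments)))
    if missing:
        raise ConfigurationError(f"samples missing a QC summary or assignment table: {missing}")
    rows = []
    for sid in qc_summaries:
        qs = qc_summaries[sid]
        table = assignments[sid]
        counts = dict(table.counts)
        host_mapped = counts.pop(host, 0)
        rows.append(AccountingRow(
            sample_id=sid,
            library=(libraries or {}).get(sid, "DNA"),
            raw_reads=qs.input_reads,
            removed_reads=qs.removed_reads,
            host_mapped=host_mapped,
            taxon_counts=counts,
            unassigned=table.unassigned,
        ))
    return rows


def accounting_to_frame(rows: Sequence[AccountingRow]) -> pd.DataFrame:
    taxa = sorted({t for r in rows for t in r.taxon_counts})
    out = []
    for r in rows:
        rec: dict[str, object] = {
            "sample": r.sample_id, "library": r.library, "raw": r.raw_reads,
            "removed": r.removed_reads, "retained": r.retained_reads,
            "host": r.host_mapped, "host_pct": r.host_percent,
            "filtered": r.filtered_reads, "unassigned": r.unassigned,
        }
        for t in taxa:
            rec[t] = r.taxon_counts.get(t, 0)
            rec[f"{t}_pct"] = r.taxon_percent(t)
        out.append(rec)
    return pd.DataFrame(out)


def profile_from_accounting(row: AccountingRow) -> AbundanceProfile:
    return AbundanceProfile(row.sample_id, row.host_percent,
                            {t: row.taxon_percent(t) for t in row.taxon_counts})


@dataclass(frozen=True)
class ControlFilterParams:
    """log2 fold-change threshold (default 2, i.e. >4-fold) and the
    pseudocount, in reads, converted to the percent scale per sample."""

    log2_fold_threshold: float = 2.0
    pseudocount: float = 1.0

    def __post_init__(self) -> None:
        if self.log2_fold_threshold <= 0:
            raise ValueError("log2_fold_threshold must be positive")


@dataclass
class FilterVerdict:
    taxon: str
    mean_abundance: float
    control_abundance: float
    log2_fold: float
    kept: bool


def control_filter(mean_abundance: Mapping[str, float],
                   control_abundance: Mapping[str, float],
                   params: ControlFilterParams = ControlFilterParams(),
                   mean_denominator: float | None = None,
                   control_denominator: float | None = None) -> list[FilterVerdict]:
    """Per-taxon keep/remove verdicts under the fold-change rule.

    A taxon is kept iff log2((mean+eps_m)/(control+eps_c)) > threshold,
    where the epsilons are the pseudocount expressed on the percent
    scale (100*pseudocount/denominator); with no denominators given the
    pseudocount degenerates to a tiny floor that only guards zeros.
    """
    if set(mean_abundance) != set(control_abundance):
        raise ConfigurationError(
            "taxon sets differ between specimens and control: "
            f"{sorted(set(mean_abundance) ^ set(control_abundance))}")
    eps_m = (100.0 * params.pseudocount / mean_denominator if mean_denominator
             else 1e-9)
    eps_c = (100.0 * params.pseudocount / control_denominator if control_denominator
             else 1e-9)
    out = []
    for taxon in sorted(mean_abundance):
        m = mean_abundance[taxon] + eps_m
        c = control_abundance[taxon] + eps_c
        lfc = math.log2(m / c)
        out.append(FilterVerdict(taxon, mean_abundance[taxon], control_abundance[taxon],
                                 lfc, lfc > params.log2_fold_threshold))
    return out


@dataclass
class SimilarityVerdict:
    sample_id: str
    flagged: bool
    supporting_taxa: list[str]   # taxa within kc-fold of (or below) the control
    offending_taxa: list[str]    # taxa exceeding kc-fold of the control
    note: str = ""


def control_similarity_flag(profiles: Mapping[str, Mapping[str, float]],
                            control_profile: Mapping[str, float] | None,
                            kc: float = 4.0) -> list[SimilarityVerdict]:
    """Flag samples whose every detected taxon sits within ``kc``-fold of
    (or below) the negative control's abundance — the signature of a
    profile explainable by contamination background alone."""
    if control_profile is None:
        raise ConfigurationError("no negative control profile available")
    out = []
    for sid in profiles:
        prof = profiles[sid]
        detected = [t for t, v in prof.items() if v > 0]
        if not detected:
            out.append(SimilarityVerdict(sid, True, [], [],
                                         note="no signal above control"))
            continue
        supporting, offending = [], []
        for t in sorted(detected):
            ctrl = control_profile.get(t, 0.0)
            (supporting if prof[t] <= kc * ctrl else offending).append(t)
        out.append(SimilarityVerdict(sid, not offending, supporting, offending))
    return out
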