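"""End-to-end orchestration: simulate -> qc -> map -> profile -> strains
-> rnacheck -> report, as one reproducible, seeded run.

Each stage writes its tables under the run's output directory; the
verdict report synthesizes three independent evidence classes per
specimen:

1. control similarity — the specimen's non-host profile sits within a
   small fold of the negative control (contamination background);
2. strain sharing — a reference on which the specimen carries the same
   strain (shared consensus SNV profile) as a different subject or a
   control (violated genomic independence);
3. DNA carryover — the specimen's RNA library covers non-transcribed
   intervals, i.e. part of the "transcriptome" came from DNA templates.

A specimen is "suspect contamination" iff at least one evidence line is
present; each line cites the producing module and the concrete numbers.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import pandas as pd
import yaml

from . import designs as _designs
from .abundance import (accounting_to_frame, build_accounting, control_filter,
                        control_similarity_flag, ControlFilterParams,
                        profile_from_accounting)
from .errors import ConfigurationError
from .mapping import ReferencePanel, iterative_assign
from .qc import QCParams, qc_reads, summaries_to_frame, QCSummary
from .rnacheck import estimate_dna_fraction
from .seqio import write_fastq
from .simdata import Study, write_study
from .strains import (build_pileup, call_snvs, consensus_ani, detect_mixture,
                      profile_to_frame, share_matrix)

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Declarative configuration of one pipeline run. CLI flags override
    fields loaded from a YAML file; the global seed propagates to every
    stochastic stage."""

    outdir: str = "contamcheck_run"
    seed: int = 0
    design: str = "default"            # "default" | "independent"
    design_params: dict = field(default_factory=dict)
    panel_order: list[str] | None = None
    qc: QCParams = field(default_factory=QCParams)
    min_identity: float = 0.90
    k: int = 21
    seed_stride: int = 1
    cmin: int = 5
    fcons: float = 0.8
    m_min: int = 10
    agreement: float = 0.99
    band: tuple[float, float] = (0.2, 0.8)
    mixture_sites: int = 5
    kc: float = 4.0
    reporting_floor: float = 0.01
    write_data: bool = True

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "qc" in raw:
            raw["qc"] = QCParams(**raw["qc"])
        if "band" in raw:
            raw["band"] = tuple(raw["band"])
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)


@dataclass
class EvidenceLine:
    module: str
    text: str


@dataclass
class SubjectVerdict:
    subject: str
    suspect: bool
    evidence: list[EvidenceLine]
    evidence_classes: set[str]  # subset of {"control_similarity", "strain_sharing", "dna_carryover"}


@dataclass
class VerdictReport:
    subjects: list[SubjectVerdict]
    notes: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "subjects": [
                {"subject": s.subject, "suspect": s.suspect,
                 "evidence_classes": sorted(s.evidence_classes),
                 "evidence": [{"module": e.module, "text": e.text} for e in s.evidence]}
                for s in self.subjects
            ],
            "notes": self.notes,
        }

    def summary_text(self) -> str:
        lines = []
        for s in self.subjects:
            status = "SUSPECT CONTAMINATION" if s.suspect else "no contamination evidence"
            lines.append(f"{s.subject}: {status}")
            for e in s.evidence:
                lines.append(f"  [{e.module}] {e.text}")
        for note in self.notes:
            lines.append(f"note: {note}")
        return "\n".join(lines) + "\n"


def subject_of(sample_id: str) -> str:
    """Sample naming convention: <subject>_<DNA|RNA>."""
    return sample_id.rsplit("_", 1)[0]


def report(share_df: pd.DataFrame | None,
           similarity_df: pd.DataFrame | None,
           carryover_df: pd.DataFrame | None,
           roles: Mapping[str, str]) -> VerdictReport:
    """Synthesize the verdict report from intermediate tables.

    ``roles`` maps sample id -> specimen/negative_control/positive_control.
    Missing optional tables degrade gracefully to a note.
    """
    if not roles:
        raise ConfigurationError("no samples declared; cannot build a report")
    subjects = sorted({subject_of(s) for s, r in roles.items() if r == "specimen"})
    notes: list[str] = []
    verdicts: list[SubjectVerdict] = []

    if similarity_df is None:
        notes.append("control-similarity evidence unavailable (no negative control declared)")
    if share_df is None or share_df.empty:
        notes.append("no strain-sharing data" if share_df is not None else
                     "strain-sharing table missing")
    if carryover_df is None or carryover_df.empty:
        notes.append("no DNA-carryover data" if carryover_df is not None else
                     "DNA-carryover table missing")

    for subj in subjects:
        evidence: list[EvidenceLine] = []
        classes: set[str] = set()
        samples = {s for s in roles if subject_of(s) == subj}

        if similarity_df is not None and not similarity_df.empty:
            hits = similarity_df[similarity_df["sample"].isin(samples)
                                 & similarity_df["flagged"]]
            for _, row in hits.iterrows():
                classes.add("control_similarity")
                evidence.append(EvidenceLine(
                    "abundance",
                    f"{row['sample']}: every detected taxon within {row['kc']}x of the "
                    f"negative control ({row['supporting_taxa']})"))

        if share_df is not None and not share_df.empty:
            same = share_df[share_df["verdict"] == "same-strain"]
            seen_pairs: set[tuple[str, str, str]] = set()
            for _, row in same.iterrows():
                a, b = row["sample_a"], row["sample_b"]
                if {a, b} & samples and subject_of(a) != subject_of(b):
                    own, other = (a, b) if a in samples else (b, a)
                    key = (row["reference"], own, other)
                    if key in seen_pairs:
                        continue
                    seen_pairs.add(key)
                    classes.add("strain_sharing")
                    evidence.append(EvidenceLine(
                        "strains",
                        f"{own}: same {row['reference']} strain as {other} "
                        f"(agreement {row['agreement']:.3f} over "
                        f"{row['comparable_sites']} sites)"))

        if carryover_df is not None and not carryover_df.empty:
            hits = carryover_df[carryover_df["sample"].isin(samples)
                                & carryover_df["verdict"]]
            for _, row in hits.iterrows():
                classes.add("dna_carryover")
                evidence.append(EvidenceLine(
                    "rnacheck",
                    f"{row['sample']}: {row['w']} reads wholly inside non-transcribed "
                    f"{row['reference']} intervals; estimated DNA fraction "
                    f"{row['delta_hat']:.3f}"))

        verdicts.append(SubjectVerdict(subj, bool(evidence), evidence, classes))
    return VerdictReport(verdicts, notes)


@dataclass
class PipelineResult:
    """Everything a run produced, in memory, plus the output directory."""

    outdir: Path
    study: Study
    qc_summaries: dict[str, QCSummary]
    assignments: dict
    accounting: pd.DataFrame
    similarity: pd.DataFrame | None
    filter_report: pd.DataFrame | None
    share: pd.DataFrame
    mixtures: pd.DataFrame
    ani: pd.DataFrame
    carryover: pd.DataFrame
    verdict: VerdictReport


def run(config: RunConfig) -> PipelineResult:
    """Execute the full pipeline on a synthetic study. Identical
    config+seed yields byte-identical table output."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    _setup_logging(out / "run.log")
    log.info("run config: %s", config)

    # -- simulate ----------------------------------------------------------
    stage = "simulate"
    try:
        if config.design == "default":
            study = _designs.default_study(config.seed, **config.design_params)
        elif config.design == "independent":
            study = _designs.independent_study(config.seed, **config.design_params)
        else:
            raise ConfigurationError(f"unknown design {config.design!r}")
        if config.write_data:
            write_study(study, out / "data")
        roles = {sid: d.role for sid, d in study.designs.items()}
        libraries = {sid: d.library for sid, d in study.designs.items()}

        # -- qc ------------------------------------------------------------
        stage = "qc"
        qcdir = out / "qc"
        qcdir.mkdir(exist_ok=True)
        qc_summaries: dict[str, QCSummary] = {}
        clean_reads = {}
        for sid in study.designs:
            kept, n_in, n_removed = qc_reads(study.reads[sid], config.qc)
            clean_reads[sid] = kept
            qc_summaries[sid] = QCSummary(sid, n_in, n_removed, n_in - n_removed)
            if config.write_data:
                write_fastq(qcdir / f"{sid}.fastq", kept)
        summaries_to_frame(qc_summaries.values()).to_csv(
            out / "qc_summary.tsv", sep="\t", index=False)

        # -- map -----------------------------------------------------------
        stage = "map"
        order = config.panel_order or study.panel_order
        panel = ReferencePanel([study.references[n] for n in order], k=config.k)
        assignments = {}
        for sid in study.designs:
            table = iterative_assign(clean_reads[sid], panel, config.min_identity,
                                     config.seed_stride)
            assignments[sid] = table
            log.info("%s: %s, unassigned=%d", sid, table.counts, table.unassigned)
        pd.DataFrame(
            [(sid, ref, assignments[sid].counts[ref]) for sid in assignments
             for ref in order],
            columns=["sample", "reference", "mapped_reads"],
        ).to_csv(out / "mapped_counts.tsv", sep="\t", index=False)

        # -- profile -------------------------------------------------------
        stage = "profile"
        host = order[0]
        rows = build_accounting(qc_summaries, assignments, host, libraries)
        acc_df = accounting_to_frame(rows)
        acc_df.to_csv(out / "accounting.tsv", sep="\t", index=False)
        profiles = {r.sample_id: profile_from_accounting(r) for r in rows}
        similarity_df = filter_df = None
        sim_frames = []
        for lib in ("DNA", "RNA"):
            neg = next((sid for sid, r in roles.items()
                        if r == "negative_control" and libraries[sid] == lib), None)
            if neg is None:
                continue
            control = profiles[neg].taxa
            spec_profiles = {sid: profiles[sid].taxa for sid, r in roles.items()
                             if r == "specimen" and libraries[sid] == lib}
            verdicts = control_similarity_flag(spec_profiles, control, config.kc)
            sim_frames.append(pd.DataFrame(
                [(v.sample_id, v.flagged, ",".join(v.supporting_taxa),
                  ",".join(v.offending_taxa), config.kc, v.note) for v in verdicts],
                columns=["sample", "flagged", "supporting_taxa", "offending_taxa",
                         "kc", "note"]))
            if lib == "DNA":
                # the original study's fold-change contaminant filter, taxon-level
                taxa = sorted({t for p in spec_profiles.values() for t in p}
                              | set(control))
                mean_ab = {t: sum(p.get(t, 0.0) for p in spec_profiles.values())
                           / max(len(spec_profiles), 1) for t in taxa}
                ctrl_ab = {t: control.get(t, 0.0) for t in taxa}
                fverd = control_filter(mean_ab, ctrl_ab, ControlFilterParams())
                filter_df = pd.DataFrame(
                    [(v.taxon, v.mean_abundance, v.control_abundance,
                      round(v.log2_fold, 3), v.kept) for v in fverd],
                    columns=["taxon", "mean_abundance", "control_abundance",
                             "log2_fold", "kept"])
                filter_df.to_csv(out / "control_filter.tsv", sep="\t", index=False)
        if sim_frames:
            similarity_df = pd.concat(sim_frames, ignore_index=True)
            similarity_df.to_csv(out / "control_similarity.tsv", sep="\t", index=False)

        # -- strains -------------------------------------------------------
        stage = "strains"
        reads_by_id = {sid: {r.id: r for r in clean_reads[sid]} for sid in study.designs}
        share_frames = []
        mixture_rows = []
        ani_rows = []
        snv_dir = out / "snv"
        snv_dir.mkdir(exist_ok=True)
        for ref_name in order[1:]:  # non-host references
            genome = study.references[ref_name]
            ref_profiles = []
            for sid in study.designs:
                recs = assignments[sid].records.get(ref_name, [])
                if not recs:
                    continue
                pile = build_pileup(recs, reads_by_id[sid], genome)
                prof = call_snvs(pile, genome, sid, config.fcons, config.cmin)
                if prof.callable_mask.any():
                    ref_profiles.append(prof)
                    profile_to_frame(prof, genome).to_csv(
                        snv_dir / f"{sid}.{ref_name}.snv.tsv", sep="\t", index=False)
                mix = detect_mixture(pile, sid, config.band, config.mixture_sites,
                                     config.cmin)
                mixture_rows.append((sid, ref_name, mix.intermediate_sites,
                                     round(mix.mean_minor_freq, 4),
                                     round(mix.sd_minor_freq, 4), mix.verdict))
                ani = consensus_ani(pile, genome, sid, config.cmin)
                ani_rows.append((sid, ref_name, ani.compared_positions,
                                 ani.identical_positions,
                                 round(ani.ani_percent, 2) if ani.compared_positions
                                 else "NA", ani.verdict))
            if len(ref_profiles) > 1:
                sdf = share_matrix(ref_profiles, config.m_min, config.agreement)
                sdf.insert(0, "reference", ref_name)
                share_frames.append(sdf)
        share_df = (pd.concat(share_frames, ignore_index=True) if share_frames
                    else pd.DataFrame(columns=["reference", "sample_a", "sample_b",
                                               "comparable_sites", "agreeing_sites",
                                               "agreement", "verdict"]))
        share_df.to_csv(out / "strain_share.tsv", sep="\t", index=False)
        mix_df = pd.DataFrame(mixture_rows, columns=[
            "sample", "reference", "intermediate_sites", "mean_minor_freq",
            "sd_minor_freq", "verdict"])
        mix_df.to_csv(out / "mixtures.tsv", sep="\t", index=False)
        ani_df = pd.DataFrame(ani_rows, columns=[
            "sample", "reference", "compared", "identical", "ani_percent", "verdict"])
        ani_df.to_csv(out / "ani.tsv", sep="\t", index=False)

        # -- rnacheck ------------------------------------------------------
        stage = "rnacheck"
        carry_rows = []
        for sid, d in study.designs.items():
            if d.library != "RNA":
                continue
            for ref_name in order[1:]:
                tm = study.transcripts.get(ref_name)
                if tm is None or not tm.non_transcribed():
                    continue
                recs = assignments[sid].records.get(ref_name, [])
                if not recs:
                    continue
                res = estimate_dna_fraction(recs, tm, sid,
                                            reporting_floor=config.reporting_floor)
                carry_rows.append((sid, ref_name, res.interior_reads, res.total_reads,
                                   round(res.expected_fraction, 4),
                                   round(res.delta_hat, 4), res.verdict, res.status))
        carry_df = pd.DataFrame(carry_rows, columns=[
            "sample", "reference", "w", "n", "E", "delta_hat", "verdict", "status"])
        carry_df.to_csv(out / "dna_carryover.tsv", sep="\t", index=False)

        # -- report --------------------------------------------------------
        stage = "report"
        verdict = report(share_df, similarity_df, carry_df, roles)
        with open(out / "verdict.json", "w") as fh:
            json.dump(verdict.to_dict(), fh, indent=2)
        with open(out / "verdict.txt", "w") as fh:
            fh.write(verdict.summary_text())
    except Exception:
        (out / "FAILED").write_text(f"stage: {stage}\n")
        log.exception("pipeline failed at stage %s", stage)
        raise

    return PipelineResult(out, study, qc_summaries, assignments, acc_df,
                          similarity_df, filter_df, share_df, mix_df, ani_df,
                          carry_df, verdict)


def _setup_logging(logfile: Path) -> None:
    root = logging.getLogger("contamcheck")
    root.setLevel(logging.INFO)
    if not any(isinstance(h, logging.FileHandler)
               and getattr(h, "baseFilename", "") == str(logfile.resolve())
               for h in root.handlers):
        fh = logging.FileHandler(logfile)
        fh.setFormatter(logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s"))
        root.addHandler(fh)
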