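"""Canned synthetic study designs.

``default_study`` is the contamination-confounded layout this package
exists to diagnose: six specimens plus a negative and a positive
control, each sequenced as one DNA and one RNA library (16 libraries).
Every library carries the same spike-in phage strain, the specimens and
the negative control share the same contaminant bacterial strains, the
positive control holds a two-strain mixture of the lab reference strain
and the shared contaminant, and every RNA library carries genomic-DNA
carryover. Run through the pipeline, every specimen should be flagged on
all three evidence classes.

``independent_study`` is the genomically independent counterfactual:
each specimen carries its own private strains and RNA libraries are
DNA-free. No specimen should be flagged.

Genome sizes are desk-scale stand-ins (5.4-40 kb) chosen so the spike-in
phage reaches the high relative depth that makes strain comparison
sharpest, mirroring how a real spike-in dominates the host-depleted
read pool.
"""

from __future__ import annotations

from .simdata import (Genome, QualityProfile, SampleDesign, StrainTruth, Study,
                      TranscriptModel, derive_strain, generate_genome,
                      make_transcript_model, simulate_study)

HOST = "host"
HUMAN = "human"
ECOLI = "ecoli"
CATELLI = "catellicoccus"
PHIX = "phix"

PANEL_ORDER = [HOST, HUMAN, ECOLI, CATELLI, PHIX]

# phage transcript layout: one contiguous non-transcribed block stands in
# for the region around the origin of replication
PHIX_TRANSCRIBED = ((0, 2500), (3800, 5386))

DEFAULT_QUALITY = QualityProfile(base_q=35, degraded_frac=0.10, degraded_tail=40,
                                 junk_frac=0.05, junk_tail=80)


def reference_panel_genomes(seed: int) -> dict[str, Genome]:
    """The five-member reference panel: host, human, two bacteria, phage."""
    return {
        HOST: generate_genome(40_000, 0.42, seed * 10 + 1, HOST),
        HUMAN: generate_genome(20_000, 0.41, seed * 10 + 2, HUMAN),
        ECOLI: generate_genome(30_000, 0.50, seed * 10 + 3, ECOLI),
        CATELLI: generate_genome(15_000, 0.35, seed * 10 + 4, CATELLI),
        PHIX: generate_genome(5_386, 0.45, seed * 10 + 5, PHIX, circular=True),
    }


def _transcript_models(refs: dict[str, Genome]) -> dict[str, TranscriptModel]:
    return {
        HOST: make_transcript_model(refs[HOST], transcribed_fraction=0.6),
        HUMAN: make_transcript_model(refs[HUMAN], transcribed_fraction=0.6),
        ECOLI: make_transcript_model(refs[ECOLI], transcribed_fraction=0.8),
        CATELLI: make_transcript_model(refs[CATELLI], transcribed_fraction=0.8),
        PHIX: make_transcript_model(refs[PHIX], intervals=PHIX_TRANSCRIBED),
    }


def _share_transcripts(transcripts: dict[str, TranscriptModel],
                       source_reference: dict[str, str]) -> None:
    """Strains inherit their parent reference's transcript intervals
    (substitution-only strains preserve coordinates)."""
    for source, ref in source_reference.items():
        if source not in transcripts and ref in transcripts:
            tm = transcripts[ref]
            transcripts[source] = TranscriptModel(source, tm.intervals, tm.genome_length)


def default_study(seed: int = 0, n_specimen_reads: int = 8000,
                  n_control_reads: int = 6000, n_specimens: int = 6,
                  dna_carryover: float = 0.3, error_rate: float = 0.001,
                  read_length: int = 100,
                  quality: QualityProfile = DEFAULT_QUALITY) -> Study:
    """The contamination-confounded study (see module docstring)."""
    refs = reference_panel_genomes(seed)
    ecoli_contam, t_ec = derive_strain(refs[ECOLI], 50, seed * 100 + 11, "ecoli_contam")
    catelli_contam, t_cm = derive_strain(refs[CATELLI], 40, seed * 100 + 12, "catelli_contam")
    phix_spike, t_px = derive_strain(refs[PHIX], 30, seed * 100 + 13, "phix_spike")
    sources = dict(refs)
    sources.update({g.name: g for g in (ecoli_contam, catelli_contam, phix_spike)})
    strain_truths: dict[str, StrainTruth] = {
        "ecoli_contam": t_ec, "catelli_contam": t_cm, "phix_spike": t_px}
    source_reference = {name: name for name in refs}
    source_reference.update({"ecoli_contam": ECOLI, "catelli_contam": CATELLI,
                             "phix_spike": PHIX})
    transcripts = _transcript_models(refs)
    _share_transcripts(transcripts, source_reference)

    specimen_sources = ((HOST, 0.80), (HUMAN, 0.01), ("ecoli_contam", 0.05),
                        ("catelli_contam", 0.02), ("phix_spike", 0.12))
    negative_sources = ((HUMAN, 0.10), ("ecoli_contam", 0.45),
                        ("catelli_contam", 0.10), ("phix_spike", 0.35))
    positive_sources = ((ECOLI, 0.651), ("ecoli_contam", 0.279), ("phix_spike", 0.07))

    designs = []
    sidx = 0
    for i in range(1, n_specimens + 1):
        for lib in ("DNA", "RNA"):
            designs.append(SampleDesign(
                f"C{i}_{lib}", lib, "specimen", specimen_sources, n_specimen_reads,
                read_length, error_rate, quality,
                dna_carryover=(1.0 if lib == "DNA" else dna_carryover),
                seed=seed * 1000 + sidx))
            sidx += 1
    for lib in ("DNA", "RNA"):
        designs.append(SampleDesign(
            f"N_{lib}", lib, "negative_control", negative_sources, n_control_reads,
            read_length, error_rate, quality,
            dna_carryover=(1.0 if lib == "DNA" else dna_carryover),
            seed=seed * 1000 + sidx))
        sidx += 1
    for lib in ("DNA", "RNA"):
        designs.append(SampleDesign(
            f"P_{lib}", lib, "positive_control", positive_sources, n_specimen_reads,
            read_length, error_rate, quality,
            dna_carryover=(1.0 if lib == "DNA" else dna_carryover),
            seed=seed * 1000 + sidx))
        sidx += 1

    return simulate_study(designs, refs, sources, strain_truths, transcripts,
                          PANEL_ORDER, source_reference)


def independent_study(seed: int = 0, n_specimen_reads: int = 8000,
                      n_specimens: int = 6, error_rate: float = 0.001,
                      read_length: int = 100,
                      quality: QualityProfile = DEFAULT_QUALITY) -> Study:
    """The genomically independent counterfactual: private strains per
    specimen, DNA-free RNA libraries, near-clean negative control."""
    refs = reference_panel_genomes(seed)
    sources = dict(refs)
    strain_truths: dict[str, StrainTruth] = {}
    source_reference = {name: name for name in refs}
    transcripts = _transcript_models(refs)

    designs = []
    sidx = 0
    for i in range(1, n_specimens + 1):
        ec_name, px_name = f"ecoli_C{i}", f"phix_C{i}"
        ec, t_ec = derive_strain(refs[ECOLI], 50, seed * 100 + 20 + i, ec_name)
        px, t_px = derive_strain(refs[PHIX], 30, seed * 100 + 60 + i, px_name)
        sources[ec_name] = ec
        sources[px_name] = px
        strain_truths[ec_name] = t_ec
        strain_truths[px_name] = t_px
        source_reference[ec_name] = ECOLI
        source_reference[px_name] = PHIX
        spec_sources = ((HOST, 0.85), (ec_name, 0.10), (px_name, 0.05))
        for lib in ("DNA", "RNA"):
            designs.append(SampleDesign(
                f"C{i}_{lib}", lib, "specimen", spec_sources, n_specimen_reads,
                read_length, error_rate, quality,
                dna_carryover=(1.0 if lib == "DNA" else 0.0),
                seed=seed * 1000 + sidx))
            sidx += 1
    # negative control: its own private phage strain only (clean extraction)
    px_n, t_pn = derive_strain(refs[PHIX], 30, seed * 100 + 90, "phix_N")
    sources["phix_N"] = px_n
    strain_truths["phix_N"] = t_pn
    source_reference["phix_N"] = PHIX
    for lib in ("DNA", "RNA"):
        designs.append(SampleDesign(
            f"N_{lib}", lib, "negative_control", (("phix_N", 1.0),), 3000,
            read_length, error_rate, quality,
            dna_carryover=(1.0 if lib == "DNA" else 0.0), seed=seed * 1000 + sidx))
        sidx += 1
    for lib in ("DNA", "RNA"):
        designs.append(SampleDesign(
            f"P_{lib}", lib, "positive_control", ((ECOLI, 1.0),), 6000,
            read_length, error_rate, quality,
            dna_carryover=(1.0 if lib == "DNA" else 0.0), seed=seed * 1000 + sidx))
        sidx += 1

    _share_transcripts(transcripts, source_reference)
    return simulate_study(designs, refs, sources, strain_truths, transcripts,
                          PANEL_ORDER, source_reference)
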