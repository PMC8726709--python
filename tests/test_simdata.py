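"""Simulator tests: every downstream stage leans on these guarantees."""

import math

import numpy as np
import pytest

from contamcheck.errors import ConfigurationError
from contamcheck.seqio import revcomp
from contamcheck.simdata import (Genome, QualityProfile, SampleDesign,
                                 TranscriptModel, apply_variants, derive_strain,
                                 generate_genome, make_transcript_model,
                                 simulate_sample, simulate_study)
from contamcheck.designs import default_study


@pytest.mark.parametrize("length,gc", [(5386, 0.45), (10_000, 0.5), (1, 0.3)])
def test_generate_genome_has_requested_length_and_is_deterministic(length, gc):
    g1 = generate_genome(length, gc, seed=1)
    g2 = generate_genome(length, gc, seed=1)
    assert len(g1) == length
    assert g1.sequence == g2.sequence
    assert generate_genome(length, gc, seed=2).sequence != g1.sequence or length < 20


def test_generate_genome_gc_within_three_sd_of_binomial():
    g = generate_genome(10_000, 0.5, seed=7)
    gc = sum(g.sequence.count(b) for b in "GC")
    assert abs(gc - 5000) <= 3 * math.sqrt(10_000 * 0.25)


@pytest.mark.parametrize("length,gc", [(0, 0.5), (-5, 0.5), (100, 0.0), (100, 1.0)])
def test_generate_genome_rejects_bad_arguments(length, gc):
    with pytest.raises(ValueError):
        generate_genome(length, gc, seed=0)


def test_derive_strain_hamming_distance_equals_n_snvs():
    parent = generate_genome(10_000, 0.45, 3)
    strain, truth = derive_strain(parent, 50, seed=4)
    hamming = sum(a != b for a, b in zip(parent.sequence, strain.sequence))
    assert hamming == 50 == len(truth.variants)
    for pos, ref, alt in truth.variants:
        assert parent.sequence[pos] == ref
        assert strain.sequence[pos] == alt != ref


def test_derive_strain_zero_snvs_is_identity():
    parent = generate_genome(500, 0.5, 5)
    strain, truth = derive_strain(parent, 0, seed=6)
    assert strain.sequence == parent.sequence
    assert truth.variants == frozenset()


def test_derive_strain_truth_replays_onto_parent():
    parent = generate_genome(3000, 0.4, 8)
    strain, truth = derive_strain(parent, 25, seed=9)
    assert apply_variants(parent, truth).sequence == strain.sequence


def test_derive_strain_rejects_excess_snvs():
    with pytest.raises(ValueError):
        derive_strain(generate_genome(10, 0.5, 1), 11, seed=0)


def _one_source_design(**kw):
    base = dict(sample_id="s", library="DNA", role="specimen",
                sources=(("g", 1.0),), n_reads=100, seed=1)
    base.update(kw)
    return SampleDesign(**base)


def test_simulate_sample_source_counts_match_multinomial_within_three_sd():
    genomes = {"a": generate_genome(5000, 0.5, 1, "a"),
               "b": generate_genome(5000, 0.5, 2, "b")}
    design = _one_source_design(sources=(("a", 0.9), ("b", 0.1)), n_reads=10_000)
    _, truth = simulate_sample(design, genomes)
    counts = truth["source"].value_counts()
    sd = math.sqrt(10_000 * 0.9 * 0.1)
    assert abs(counts["a"] - 9000) <= 3 * sd
    assert abs(counts["b"] - 1000) <= 3 * sd
    assert counts.sum() == 10_000


def test_simulate_sample_error_rate_within_three_sd():
    genome = generate_genome(8000, 0.5, 11, "g")
    design = _one_source_design(n_reads=1000, error_rate=0.01, read_length=100)
    reads, truth = simulate_sample(design, {"g": genome})
    by_id = {r.id: r for r in reads}
    mismatches = 0
    for row in truth.itertuples():
        frag = genome.sequence[row.position:row.position + 100]
        seq = by_id[row.read_id].sequence
        if row.strand == "-":
            seq = revcomp(seq)
        mismatches += sum(a != b for a, b in zip(frag, seq))
    expected = 1000 * 100 * 0.01
    assert abs(mismatches - expected) <= 3 * math.sqrt(expected)


def test_rna_sample_with_zero_carryover_stays_inside_transcribed_intervals():
    genome = generate_genome(5386, 0.45, 12, "g")
    tm = TranscriptModel("g", ((0, 2500), (3800, 5386)), 5386)
    design = _one_source_design(library="RNA", n_reads=2000, dna_carryover=0.0)
    _, truth = simulate_sample(design, {"g": genome}, {"g": tm})
    assert not truth["is_dna_derived"].any()
    for row in truth.itertuples():
        assert any(a <= row.position and row.position + 100 <= b
                   for a, b in tm.intervals)


def test_rna_carryover_fraction_close_to_delta():
    genome = generate_genome(5386, 0.45, 13, "g")
    tm = TranscriptModel("g", ((0, 2500), (3800, 5386)), 5386)
    design = _one_source_design(library="RNA", n_reads=5000, dna_carryover=0.3)
    _, truth = simulate_sample(design, {"g": genome}, {"g": tm})
    frac = truth["is_dna_derived"].mean()
    assert abs(frac - 0.3) <= 3 * math.sqrt(0.3 * 0.7 / 5000)


def test_simulate_sample_is_deterministic():
    genome = {"g": generate_genome(3000, 0.5, 14, "g")}
    design = _one_source_design(n_reads=200,
                                quality=QualityProfile(degraded_frac=0.2, junk_frac=0.1))
    r1, t1 = simulate_sample(design, genome)
    r2, t2 = simulate_sample(design, genome)
    assert [(r.id, r.sequence, r.quality) for r in r1] == \
           [(r.id, r.sequence, r.quality) for r in r2]
    assert t1.equals(t2)


def test_simulate_sample_rejects_long_reads_and_missing_transcripts():
    genome = {"g": generate_genome(80, 0.5, 15, "g")}
    with pytest.raises(ValueError):
        simulate_sample(_one_source_design(read_length=100), genome)
    with pytest.raises(ConfigurationError):
        simulate_sample(_one_source_design(library="RNA", read_length=50), genome, {})


def test_transcript_model_complement_partitions_genome():
    tm = TranscriptModel("g", ((100, 400), (600, 900)), 1000)
    assert tm.non_transcribed() == ((0, 100), (400, 600), (900, 1000))
    total = sum(b - a for a, b in tm.intervals + tm.non_transcribed())
    assert total == 1000


def test_default_study_layout_and_truth_coverage(tmp_path):
    study = default_study(seed=0, n_specimen_reads=300, n_control_reads=200)
    assert len(study.designs) == 16  # 6 specimens x 2 + 2 controls x 2
    from contamcheck.simdata import write_study
    sheet = write_study(study, tmp_path)
    assert len(sheet) == 16
    assert sorted(p.name for p in tmp_path.glob("*.fastq")) == \
           sorted(f"{sid}.fastq" for sid in study.designs)
    for sid, truth in study.truths.items():
        assert truth["read_id"].is_unique
        assert len(truth) == study.designs[sid].n_reads
    # negative control: contaminants and spike-in only, no host
    neg_sources = {s for s, _ in study.designs["N_DNA"].sources}
    assert "host" not in neg_sources
    assert "phix_spike" in neg_sources


def test_duplicate_sample_ids_rejected():
    genome = generate_genome(500, 0.5, 16, "g")
    d = _one_source_design(n_reads=10, read_length=50)
    with pytest.raises(ConfigurationError, match="duplicate"):
        simulate_study([d, d], {"g": genome}, {"g": genome}, {}, {}, ["g"], {"g": "g"})


def test_quality_profile_tail_classes_appear():
    genome = {"g": generate_genome(3000, 0.5, 17, "g")}
    prof = QualityProfile(degraded_frac=0.3, junk_frac=0.2)
    reads, _ = simulate_sample(_one_source_design(n_reads=500, quality=prof), genome)
    tails = {r.quality[-1] for r in reads}
    assert chr(35 + 33) in tails  # flat high-quality reads
    assert chr(2 + 33) in tails   # degraded tails end at the floor quality
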