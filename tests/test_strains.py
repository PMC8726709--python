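"""Pileup, SNV calling, strain sharing, mixtures, consensus ANI."""

import math

import numpy as np
import pytest

from contamcheck.errors import DataFormatError
from contamcheck.mapping import AlignmentRecord, GenomeIndex, map_read
from contamcheck.seqio import Read
from contamcheck.simdata import (Genome, SampleDesign, derive_strain,
                                 generate_genome, simulate_sample)
from contamcheck.strains import (build_pileup, call_snvs, consensus_ani,
                                 detect_mixture, share_score)


def _aln(read_id, start, length, strand="+"):
    return AlignmentRecord(read_id, "g", start, strand, length, ())


def test_single_perfect_read_gives_unit_depth_of_reference_base():
    genome = generate_genome(200, 0.5, 1, "g")
    read = Read("r", genome.sequence[50:150], "I" * 100)
    pile = build_pileup([_aln("r", 50, 100)], {"r": read}, genome)
    assert (pile.depth[50:150] == 1).all()
    assert (pile.depth[:50] == 0).all() and (pile.depth[150:] == 0).all()
    base_idx = "ACGT".index(genome.sequence[50])
    assert pile.counts[base_idx, 50] == 1


def test_disagreeing_overlapping_reads_split_allele_counts():
    genome = Genome("g", "A" * 100)
    r1 = Read("r1", "A" * 50, "I" * 50)
    r2 = Read("r2", "A" * 20 + "G" + "A" * 29, "I" * 50)
    pile = build_pileup([_aln("r1", 0, 50), _aln("r2", 0, 50)],
                        {"r1": r1, "r2": r2}, genome)
    assert pile.counts["ACGT".index("A"), 20] == 1
    assert pile.counts["ACGT".index("G"), 20] == 1
    assert pile.depth[20] == 2


def test_out_of_bounds_alignment_raises():
    genome = Genome("g", "A" * 60)
    with pytest.raises(DataFormatError):
        build_pileup([_aln("r", 20, 50)], {"r": Read("r", "A" * 50, "I" * 50)}, genome)


def _mapped_pileup(source, reference, coverage, error_rate, seed):
    n = int(round(len(reference) * coverage / 100))
    design = SampleDesign("s", "DNA", "specimen", ((source.name, 1.0),), n,
                          100, error_rate, seed=seed)
    reads, _ = simulate_sample(design, {source.name: source})
    index = GenomeIndex(reference)
    recs = [r for r in (map_read(rd, index) for rd in reads) if r is not None]
    return build_pileup(recs, {r.id: r for r in reads}, reference)


def test_mean_depth_matches_target_coverage_within_three_sd():
    genome = generate_genome(5000, 0.5, 2, "g")
    pile = _mapped_pileup(genome, genome, 20.0, 0.0, seed=3)
    # interior positions (edge effects shrink depth near the ends)
    interior = pile.depth[100:-100]
    assert abs(interior.mean() - 20.0) <= 3 * 20.0 / math.sqrt(len(interior) / 100)


def test_reads_matching_reference_yield_no_variants():
    genome = generate_genome(3000, 0.5, 4, "g")
    pile = _mapped_pileup(genome, genome, 15.0, 0.0, seed=5)
    profile = call_snvs(pile, genome)
    assert profile.variants == {}


def test_planted_snvs_recovered_at_20x():
    from contamcheck.evaluation import snv_recall_precision
    recall, precision = snv_recall_precision(seed=11, n_snvs=20, genome_length=5000)
    assert recall >= 0.95 and precision >= 0.95


def test_unit_depth_with_cmin_5_leaves_nothing_callable():
    genome = Genome("g", "ACGT" * 25)
    read = Read("r", genome.sequence, "I" * 100)
    pile = build_pileup([_aln("r", 0, 100)], {"r": read}, genome)
    profile = call_snvs(pile, genome, cmin=5)
    assert not profile.callable_mask.any() and profile.variants == {}


def _profiles_for_sharing(seed, shared=True):
    parent = generate_genome(5000, 0.5, seed, "p")
    x, _ = derive_strain(parent, 40, seed + 100, "x")
    y, _ = derive_strain(parent, 40, seed + 200, "y")
    a = call_snvs(_mapped_pileup(x, parent, 20, 0.001, seed + 1), parent, "A")
    b_src = x if shared else y
    b = call_snvs(_mapped_pileup(b_src, parent, 20, 0.001, seed + 2), parent, "B")
    return a, b


def test_same_strain_pair_called_same_and_symmetric():
    a, b = _profiles_for_sharing(30, shared=True)
    r = share_score(a, b)
    assert r.verdict == "same-strain" and r.agreement == 1.0
    mirrored = share_score(b, a)
    assert (mirrored.comparable_sites, mirrored.agreeing_sites, mirrored.verdict) == \
           (r.comparable_sites, r.agreeing_sites, r.verdict)


def test_distinct_strains_called_distinct():
    a, b = _profiles_for_sharing(31, shared=False)
    assert share_score(a, b).verdict == "distinct"


def test_profile_against_itself_is_same_strain():
    a, _ = _profiles_for_sharing(32)
    r = share_score(a, a)
    assert r.verdict == "same-strain" and r.agreement == 1.0


def test_disjoint_callable_regions_are_insufficient_data():
    import numpy as np
    from contamcheck.strains import SNVProfile
    mask_a = np.zeros(100, bool); mask_a[:50] = True
    mask_b = np.zeros(100, bool); mask_b[50:] = True
    a = SNVProfile("g", "A", {10: ("G", 1.0, 20)}, mask_a)
    b = SNVProfile("g", "B", {70: ("T", 1.0, 20)}, mask_b)
    assert share_score(a, b).verdict == "insufficient-data"


def test_profiles_on_different_references_rejected():
    import numpy as np
    from contamcheck.strains import SNVProfile
    a = SNVProfile("g1", "A", {}, np.ones(10, bool))
    b = SNVProfile("g2", "B", {}, np.ones(10, bool))
    with pytest.raises(ValueError):
        share_score(a, b)


def test_pure_sample_called_single_and_mix_called_mixture():
    parent = generate_genome(5000, 0.5, 40, "p")
    major, _ = derive_strain(parent, 40, 41, "major")
    minor, _ = derive_strain(parent, 40, 42, "minor")
    n = 2500  # 50x over 5 kb
    pure_reads, _ = simulate_sample(
        SampleDesign("pure", "DNA", "specimen", (("major", 1.0),), n, 100, 0.001,
                     seed=43), {"major": major})
    mix_reads, _ = simulate_sample(
        SampleDesign("mix", "DNA", "specimen", (("major", 0.7), ("minor", 0.3)),
                     n, 100, 0.001, seed=44), {"major": major, "minor": minor})
    index = GenomeIndex(parent)
    calls = {}
    for name, reads in (("pure", pure_reads), ("mix", mix_reads)):
        recs = [r for r in (map_read(rd, index) for rd in reads) if r is not None]
        pile = build_pileup(recs, {r.id: r for r in reads}, parent)
        calls[name] = detect_mixture(pile, name)
    assert calls["pure"].verdict == "single"
    assert calls["mix"].verdict == "mixture"
    assert calls["mix"].mean_minor_freq == pytest.approx(0.3, abs=0.08)
    assert calls["mix"].frequency_coherent


def test_empty_pileup_is_insufficient_for_mixture_and_ani():
    genome = Genome("g", "ACGT" * 10)
    pile = build_pileup([], {}, genome)
    assert detect_mixture(pile).verdict == "insufficient-data"
    assert consensus_ani(pile, genome).verdict == "insufficient-data"


def test_error_free_reads_give_100_percent_ani():
    genome = generate_genome(3000, 0.5, 50, "g")
    pile = _mapped_pileup(genome, genome, 20, 0.0, seed=51)
    ani = consensus_ani(pile, genome)
    assert ani.ani_percent == 100.0


def test_ani_reflects_planted_divergence_and_decreases_with_it():
    parent = generate_genome(10_000, 0.5, 60, "p")
    results = []
    for n_snvs in (0, 10, 30):
        strain, _ = derive_strain(parent, n_snvs, 61 + n_snvs, "s")
        pile = _mapped_pileup(strain, parent, 30, 0.0, seed=62 + n_snvs)
        ani = consensus_ani(pile, parent)
        results.append(ani.ani_percent)
        if n_snvs == 10 and ani.compared_positions == 10_000:
            assert ani.ani_percent == pytest.approx(99.9, abs=0.01)
    assert results[0] >= results[1] >= results[2]
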