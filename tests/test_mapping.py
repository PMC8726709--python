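"""Mapper contract and competitive-assignment semantics."""

import numpy as np
import pysam
import pytest

from contamcheck.crosscheck import bruteforce_map
from contamcheck.errors import ConfigurationError
from contamcheck.mapping import (GenomeIndex, ReferencePanel, export_alignments,
                                 import_alignments, iterative_assign, map_read)
from contamcheck.seqio import Read, revcomp
from contamcheck.simdata import Genome, generate_genome


def _read_from(genome, start, length=100, name="r", strand="+", mutate=()):
    seq = list(genome.sequence[start:start + length])
    for pos in mutate:
        seq[pos] = {"A": "C", "C": "G", "G": "T", "T": "A"}[seq[pos]]
    s = "".join(seq)
    if strand == "-":
        s = revcomp(s)
    return Read(name, s, "I" * length)


def test_exact_substring_maps_with_identity_one(small_genome):
    index = GenomeIndex(small_genome)
    rec = map_read(_read_from(small_genome, 500), index)
    assert rec is not None
    assert (rec.start, rec.strand, rec.identity) == (500, "+", 1.0)


def test_two_substitutions_give_identity_098_matching_bruteforce(small_genome):
    index = GenomeIndex(small_genome)
    read = _read_from(small_genome, 700, mutate=(10, 60))
    rec = map_read(read, index, min_identity=0.9)
    assert rec is not None and rec.identity == pytest.approx(0.98)
    assert bruteforce_map(read, small_genome) == (700, "+", 2)
    assert (rec.start, rec.strand, len(rec.mismatch_positions)) == (700, "+", 2)


def test_reverse_strand_read_found_with_reference_coordinates(small_genome):
    index = GenomeIndex(small_genome)
    rec = map_read(_read_from(small_genome, 300, strand="-"), index)
    assert rec is not None
    assert (rec.start, rec.strand) == (300, "-")


def test_random_read_with_no_shared_kmer_is_no_hit(small_genome):
    rng = np.random.default_rng(0)
    seq = "".join(rng.choice(list("ACGT"), size=100))
    assert map_read(Read("r", seq, "I" * 100), GenomeIndex(small_genome)) is None


def test_read_shorter_than_seed_is_no_hit_with_warning(small_genome, caplog):
    with caplog.at_level("WARNING"):
        out = map_read(Read("tiny", "ACGTACGT", "I" * 8), GenomeIndex(small_genome))
    assert out is None
    assert "shorter than seed" in caplog.text


def test_duplicated_locus_tie_breaks_to_lowest_start():
    half = generate_genome(400, 0.5, 5, "h").sequence
    genome = Genome("dup", half + half)
    rec = map_read(Read("r", half[:100], "I" * 100), GenomeIndex(genome))
    assert rec is not None and rec.start == 0


def test_iterative_assignment_order_precedence():
    g = generate_genome(1000, 0.5, 6, "first")
    twin = Genome("second", g.sequence)  # identical content, later in panel
    other = generate_genome(1000, 0.5, 8, "third")
    reads = [_read_from(g, 100, name="shared"), _read_from(other, 200, name="unique")]
    panel = ReferencePanel([g, twin, other])
    table = iterative_assign(reads, panel)
    assert table.assignment_of("shared") == "first"
    assert table.assignment_of("unique") == "third"
    # permuting the panel moves the ambiguous read but not the unique one
    flipped = iterative_assign(reads, panel.reordered(["second", "first", "third"]))
    assert flipped.assignment_of("shared") == "second"
    assert flipped.assignment_of("unique") == "third"


def test_assignment_partitions_input_reads():
    from contamcheck.evaluation import conservation_violations
    assert conservation_violations(seed=3) == 0


def test_assignment_accuracy_above_99_percent_on_truth_tables():
    from contamcheck.evaluation import assignment_accuracy
    assert assignment_accuracy(seed=2) >= 0.99


def test_empty_read_set_yields_empty_table(small_genome):
    table = iterative_assign([], ReferencePanel([small_genome]))
    assert table.unassigned == 0 and table.counts == {"ref": 0}


def test_sam_round_trip_preserves_coordinates(small_genome, tmp_path):
    index = GenomeIndex(small_genome)
    reads = [_read_from(small_genome, 150, name="f"),
             _read_from(small_genome, 900, name="rv", strand="-")]
    recs = [map_read(r, index) for r in reads]
    sam = tmp_path / "out.sam"
    export_alignments(sam, recs, {r.id: r for r in reads}, [small_genome])
    back = import_alignments(sam, "ref", small_genome)
    assert [(r.read_id, r.start, r.strand) for r in back] == \
           [(r.read_id, r.start, r.strand) for r in recs]
    # SAM text is 1-based; internal records are 0-based
    pos_by_name = {}
    with pysam.AlignmentFile(sam, "r") as fh:
        for a in fh.fetch(until_eof=True):
            pos_by_name[a.query_name] = int(str(a).split("\t")[3])
    assert pos_by_name == {"f": 151, "rv": 901}


def test_import_ignores_unmapped_records(small_genome, tmp_path):
    sam = tmp_path / "mixed.sam"
    sam.write_text(
        "@HD\tVN:1.6\n@SQ\tSN:ref\tLN:2000\n"
        "m1\t0\tref\t11\t60\t4M\t*\t0\t0\tACGT\tIIII\n"
        "u1\t4\t*\t0\t0\t*\t*\t0\t0\tACGT\tIIII\n"
        "m2\t16\tref\t21\t60\t4M\t*\t0\t0\tACGT\tIIII\n"
        "u2\t4\t*\t0\t0\t*\t*\t0\t0\tACGT\tIIII\n"
        "m3\t0\tref\t31\t60\t4M\t*\t0\t0\tACGT\tIIII\n")
    recs = import_alignments(sam, "ref")
    assert [(r.read_id, r.start) for r in recs] == [("m1", 10), ("m2", 20), ("m3", 30)]


def test_import_with_absent_reference_raises(tmp_path):
    sam = tmp_path / "hdr.sam"
    sam.write_text("@HD\tVN:1.6\n@SQ\tSN:other\tLN:100\n")
    with pytest.raises(ConfigurationError, match="absent"):
        import_alignments(sam, "ref")
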