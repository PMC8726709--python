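"""Self-contained evaluation routines for the whole inference chain.

Each function builds its own synthetic inputs from a seed, runs the
production code path, and scores it against either ground truth from
the simulator or an independent brute-force implementation from
:mod:`contamcheck.crosscheck`. The acceptance script and the test suite
both call these, so the published numbers and the tested numbers are
the same computation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .crosscheck import bruteforce_map, bruteforce_trim
from .designs import default_study, independent_study
from .mapping import GenomeIndex, iterative_assign, map_read, ReferencePanel
from .pipeline import RunConfig, run, subject_of
from .qc import QCParams, trim_read
from .rnacheck import estimate_dna_fraction
from .seqio import Read
from .simdata import (Genome, SampleDesign, TranscriptModel, derive_strain,
                      generate_genome, simulate_sample)
from .strains import build_pileup, call_snvs, detect_mixture, share_score

BASES = "ACGT"


def _sub_seed(seed: int, offset: int) -> int:
    return (seed * 1009 + offset) % (2**31 - 1)


# ---------------------------------------------------------------------------
# oracle equivalence


def qc_oracle_discrepancies(n_reads: int = 1000, seed: int = 0) -> int:
    """Compare trim_read against the window-by-window scanner on random
    reads (random lengths, uniform qualities 2-40)."""
    rng = np.random.default_rng(_sub_seed(seed, 1))
    params = QCParams()
    bad = 0
    for i in range(n_reads):
        length = int(rng.integers(1, 151))
        seq = "".join(rng.choice(list(BASES), size=length))
        qual = "".join(chr(int(q) + 33) for q in rng.integers(2, 41, size=length))
        got = trim_read(Read(f"r{i}", seq, qual), params)
        want = bruteforce_trim(seq, qual)
        if (got is None) != (want is None):
            bad += 1
        elif got is not None and (got.sequence, got.quality) != want:
            bad += 1
    return bad


def mapper_oracle_disagreements(n_reads: int = 500, seed: int = 0,
                                ref_length: int = 2000, read_length: int = 100) -> int:
    """Compare map_read against exhaustive all-offset, both-strand
    scoring on a small reference.

    Reads are drawn from the reference with 0-3 substitutions (so an
    intact seed k-mer always exists) on either strand, plus one third
    random no-hit reads.
    """
    rng = np.random.default_rng(_sub_seed(seed, 2))
    genome = generate_genome(ref_length, 0.5, _sub_seed(seed, 3), "oracle_ref")
    index = GenomeIndex(genome)
    from .seqio import revcomp

    bad = 0
    for i in range(n_reads):
        if i % 3 == 2:
            seq = "".join(rng.choice(list(BASES), size=read_length))
        else:
            start = int(rng.integers(0, ref_length - read_length + 1))
            frag = list(genome.sequence[start:start + read_length])
            for pos in rng.choice(read_length, size=int(rng.integers(0, 4)),
                                  replace=False):
                frag[pos] = BASES[(BASES.index(frag[pos]) + int(rng.integers(1, 4))) % 4]
            seq = "".join(frag)
            if rng.random() < 0.5:
                seq = revcomp(seq)
        read = Read(f"r{i}", seq, "I" * read_length)
        got = map_read(read, index)
        want = bruteforce_map(read, genome)
        if (got is None) != (want is None):
            bad += 1
        elif got is not None and want is not None:
            if (got.start, got.strand, len(got.mismatch_positions)) != want:
                bad += 1
    return bad


# ---------------------------------------------------------------------------
# conservation and assignment accuracy


def conservation_violations(seed: int = 0, n_reads: int = 5000) -> int:
    """Partition check on a mixed synthetic sample: assigned + unassigned
    must equal the input count (structurally enforced; recounted here)."""
    genomes = {f"g{i}": generate_genome(8000, 0.45, _sub_seed(seed, 10 + i), f"g{i}")
               for i in range(3)}
    design = SampleDesign("s", "DNA", "specimen",
                          (("g0", 0.6), ("g1", 0.3), ("g2", 0.1)),
                          n_reads, seed=_sub_seed(seed, 20))
    reads, _ = simulate_sample(design, genomes)
    panel = ReferencePanel(list(genomes.values()))
    table = iterative_assign(reads, panel, keep_records=False)
    total = sum(table.counts.values()) + table.unassigned
    return 0 if total == table.input_reads == len(reads) else 1


def assignment_accuracy(seed: int = 0, n_reads: int = 5000) -> float:
    """Fraction of reads assigned to their true source reference."""
    genomes = {f"g{i}": generate_genome(8000, 0.45, _sub_seed(seed, 30 + i), f"g{i}")
               for i in range(3)}
    design = SampleDesign("s", "DNA", "specimen",
                          (("g0", 0.5), ("g1", 0.3), ("g2", 0.2)),
                          n_reads, seed=_sub_seed(seed, 40))
    reads, truth = simulate_sample(design, genomes)
    panel = ReferencePanel(list(genomes.values()))
    table = iterative_assign(reads, panel, keep_records=False)
    correct = sum(1 for _, row in truth.iterrows()
                  if table.assignment_of(row["read_id"]) == row["source"])
    return correct / len(reads)


# ---------------------------------------------------------------------------
# SNV calling, strain sharing, mixtures


def _sample_pileup(genome_from: Genome, reference: Genome, coverage: float,
                   error_rate: float, seed: int, sample_id: str = "s"):
    n = int(round(len(reference) * coverage / 100))
    design = SampleDesign(sample_id, "DNA", "specimen", ((genome_from.name, 1.0),),
                          n, 100, error_rate, seed=seed)
    reads, _ = simulate_sample(design, {genome_from.name: genome_from})
    index = GenomeIndex(reference)
    recs = [r for r in (map_read(rd, index) for rd in reads) if r is not None]
    by_id = {r.id: r for r in reads}
    return build_pileup(recs, by_id, reference)


def snv_recall_precision(seed: int = 0, coverage: float = 20.0,
                         n_snvs: int = 50, error_rate: float = 0.001,
                         genome_length: int = 10_000) -> tuple[float, float]:
    """Score consensus SNV calls against planted strain truth."""
    parent = generate_genome(genome_length, 0.45, _sub_seed(seed, 50), "parent")
    strain, truth = derive_strain(parent, n_snvs, _sub_seed(seed, 51), "strain")
    pile = _sample_pileup(strain, parent, coverage, error_rate, _sub_seed(seed, 52))
    profile = call_snvs(pile, parent)
    truth_set = {(p, alt) for p, _, alt in truth.variants}
    called = {(p, alt) for p, (alt, _, _) in profile.variants.items()}
    tp = len(called & truth_set)
    recall = tp / len(truth_set)
    precision = tp / len(called) if called else 0.0
    return recall, precision


def strain_sharing_confusion(n_seeds: int = 100, seed: int = 0,
                             coverage: float = 20.0, n_snvs: int = 50,
                             min_separation: int = 30,
                             genome_length: int = 10_000) -> tuple[int, int]:
    """Same-strain vs distinct confusion over seeded synthetic pairs.

    Per seed: samples A and B carry the same strain, C a different one
    (independent SNV draws; separation re-checked against
    ``min_separation``). Returns (errors, evaluated pairs).
    """
    errors = 0
    pairs = 0
    parent = generate_genome(genome_length, 0.45, _sub_seed(seed, 60), "parent")
    for i in range(n_seeds):
        s = _sub_seed(seed, 1000 + i)
        x, tx = derive_strain(parent, n_snvs, s * 2 + 1, "x")
        y, ty = derive_strain(parent, n_snvs, s * 2 + 2, "y")
        separation = len(tx.variants ^ ty.variants)
        if separation < min_separation:  # astronomically unlikely; skip if so
            continue
        profs = {}
        for sid, src in (("A", x), ("B", x), ("C", y)):
            pile = _sample_pileup(src, parent, coverage, 0.001,
                                  _sub_seed(s, ord(sid)), sid)
            profs[sid] = call_snvs(pile, parent, sid)
        for a, b, want in (("A", "B", "same-strain"), ("A", "C", "distinct"),
                           ("B", "C", "distinct")):
            got = share_score(profs[a], profs[b]).verdict
            pairs += 1
            if got != want:
                errors += 1
    return errors, pairs


def mixture_detection_rates(n_seeds: int = 100, seed: int = 0,
                            coverage: float = 50.0, n_snvs: int = 40,
                            minor_fraction: float = 0.3,
                            genome_length: int = 5_000) -> tuple[int, int]:
    """(mixtures detected, pure samples falsely called) over seeds.

    Each seed simulates a 70:30 two-strain mix and a pure single-strain
    sample at the same coverage.
    """
    detected = 0
    false_calls = 0
    parent = generate_genome(genome_length, 0.45, _sub_seed(seed, 70), "parent")
    ref_index = GenomeIndex(parent)
    for i in range(n_seeds):
        s = _sub_seed(seed, 2000 + i)
        major, _ = derive_strain(parent, n_snvs, s * 2 + 1, "major")
        minor, _ = derive_strain(parent, n_snvs, s * 2 + 2, "minor")
        n = int(round(genome_length * coverage / 100))
        mix_design = SampleDesign("mix", "DNA", "specimen",
                                  (("major", 1 - minor_fraction),
                                   ("minor", minor_fraction)), n, 100, 0.001, seed=s)
        pure_design = SampleDesign("pure", "DNA", "specimen", (("major", 1.0),),
                                   n, 100, 0.001, seed=s + 1)
        sources = {"major": major, "minor": minor}
        for design, is_mix in ((mix_design, True), (pure_design, False)):
            reads, _ = simulate_sample(design, sources)
            recs = [r for r in (map_read(rd, ref_index) for rd in reads)
                    if r is not None]
            pile = build_pileup(recs, {r.id: r for r in reads}, parent)
            call = detect_mixture(pile, design.sample_id)
            if is_mix and call.verdict == "mixture":
                detected += 1
            if not is_mix and call.verdict == "mixture":
                false_calls += 1
    return detected, false_calls


# ---------------------------------------------------------------------------
# DNA carryover recovery


def dna_fraction_errors(deltas: tuple[float, ...] = (0.0, 0.1, 0.3, 0.5, 1.0),
                        n_reads: int = 50_000, seed: int = 0,
                        genome_length: int = 5_386) -> dict[float, float]:
    """|delta_hat - delta| per true carryover fraction, on an RNA library
    mapped back to its source genome."""
    genome = generate_genome(genome_length, 0.45, _sub_seed(seed, 80), "phage")
    tm = TranscriptModel("phage", ((0, 2500), (3800, genome_length)), genome_length)
    index = GenomeIndex(genome)
    out = {}
    for j, delta in enumerate(deltas):
        design = SampleDesign("s", "RNA", "specimen", (("phage", 1.0),), n_reads,
                              100, 0.001, dna_carryover=delta,
                              seed=_sub_seed(seed, 81 + j))
        reads, _ = simulate_sample(design, {"phage": genome}, {"phage": tm})
        recs = [r for r in (map_read(rd, index) for rd in reads) if r is not None]
        res = estimate_dna_fraction(recs, tm, read_length=100)
        out[delta] = abs(res.delta_hat - delta)
    return out


# ---------------------------------------------------------------------------
# end-to-end study assessments


@dataclass
class StudyAssessment:
    specimens: int
    flagged: int
    flagged_all_three: int
    spikein_cross_pairs: int          # cross-subject pairs with enough shared sites
    spikein_cross_same_strain: int    # of those, called same-strain
    positive_control_mixture: bool
    taxa_surviving_control_filter: int | None


def assess_study(design: str, seed: int, outdir: str) -> StudyAssessment:
    """Run the full pipeline on a canned design and summarise the
    verdicts against that design's expectations."""
    res = run(RunConfig(outdir=outdir, seed=seed, design=design, write_data=False))
    subj = [s for s in res.verdict.subjects]
    flagged = sum(1 for s in subj if s.suspect)
    all_three = sum(1 for s in subj if len(s.evidence_classes) == 3)
    phix = res.share[res.share["reference"] == "phix"]
    cross = phix[[subject_of(a) != subject_of(b)
                  for a, b in zip(phix["sample_a"], phix["sample_b"])]]
    informative = cross[cross["verdict"] != "insufficient-data"]
    same = (informative["verdict"] == "same-strain").sum()
    pos_mix = bool(((res.mixtures["sample"] == "P_DNA")
                    & (res.mixtures["reference"] == "ecoli")
                    & (res.mixtures["verdict"] == "mixture")).any())
    surviving = (int(res.filter_report["kept"].sum())
                 if res.filter_report is not None else None)
    return StudyAssessment(len(subj), flagged, all_three, len(informative),
                           int(same), pos_mix, surviving)


def assess_default(seed: int = 0, outdir: str = "scratch/eval_default") -> StudyAssessment:
    return assess_study("default", seed, outdir)


def assess_independent(seed: int = 0,
                       outdir: str = "scratch/eval_independent") -> StudyAssessment:
    return assess_study("independent", seed, outdir)
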