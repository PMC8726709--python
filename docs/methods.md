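# Methods

This note documents the models, default parameters, numerical choices
and known limitations behind `contamcheck`. Nothing here states an
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## The forensic model

The package treats a claimed low-biomass microbiome as a hypothesis to
be falsified against three independent signatures of contamination:

1. **Control similarity.** Reagent and well-to-well contamination affect
   specimens and template-free negative controls alike. If every taxon
   detected in a specimen occurs at comparable (within a fold *k*c) or
   higher relative abundance in the negative control, the specimen's
   profile carries no information beyond background. The same abundances
   feed the classical fold-change contaminant filter (keep a taxon iff
   its mean specimen abundance exceeds 4× the control, i.e.
   log₂ fold change > 2): a dataset whose entire profile fails its own
   contaminant filter should never have been interpreted as a community.
2. **Genomic independence.** Truly independent biological samples carry
   distinguishable strains even within one species. Consensus SNV
   profiles against a shared reference act as strain fingerprints;
   finding the *same* fingerprint across specimens and controls — or
   two fingerprints mixed inside a positive control and one of them
   recurring in specimens — indicates material transfer rather than
   colonization.
3. **DNA carryover in metatranscriptomes.** RNA libraries should not
   cover regions that are never transcribed. Coverage of such regions
   (e.g. around a phage origin of replication) proves a DNA-template
   component, quantified by the estimator below.

A specimen is "suspect contamination" iff at least one evidence class
fires; each evidence line cites its producing module and the underlying
numbers.

## Read QC

Sliding-window trimming with window 4, threshold Q20, minimum length
70 (Phred+33; offset configurable). The scan runs 5′→3′ over windows
starting at every position up to length − window; the read is clipped at
the *start* of the first failing window (mean quality < threshold) and
discarded if the clipped length is below the floor. Reads shorter than
one window are judged as a single window. Trailing bases past the last
full window start are never re-scanned; some published trimmers do
re-scan them, so absolute retained-read counts can differ slightly from
other tools on real data even with identical parameters. The minimum
length is absolute bases (70), which coincides with "drop reads
truncated by > 30 %" only for 100 bp reads; the absolute form is
canonical here. Window means are exact in float64 (integer sums ≤ 164).

## Mapper

A deterministic seed-and-extend mapper with an explicit contract, so
every downstream count is reproducible bit for bit:

- exact *k*-mer seeds, *k* = 21 (default), hashed over the forward
  strand of each reference; the read and its reverse complement are
  both scanned;
- candidate loci = deduplicated alignment start positions implied by
  seed hits, capped at the 50 lowest per strand (deterministic cap);
- ungapped full-length extension scored by identity; best hit reported
  iff identity ≥ 0.9 (default); ties break to the forward strand, then
  the lowest start coordinate;
- reads shorter than *k* are no-hits (logged).

Ungapped extension is deliberate: the strain evidence is
substitution-based, and indel alignment would buy nothing here. The
mapper is validated against an exhaustive all-offset, both-strand
scorer (`contamcheck.crosscheck`) with zero tolerated disagreements.
Competitive assignment maps the surviving pool against the ordered
panel, removing each member's hits before the next member; the
partition invariant (Σ per-reference counts + unassigned = input) is
enforced structurally. Panel order is user configuration; the default
mirrors host → human → bacteria → spike-in phage. External SAM
alignments can be imported in place of the built-in mapper (1-based
file coordinates, 0-based internal).

## Abundance accounting

Percentages are rounded half away from zero to one decimal, matching
standard accounting-table presentation, and use two denominators: host
over quality-retained reads, all other taxa over host-depleted
("filtered") reads. The fold-change filter uses a pseudocount of 1 read
converted to the percent scale per sample (ε = 100/denominator), making
explicit a calculation that gene-centric pipelines often leave
unstated; the boundary is strict (exactly 4-fold is removed). The
filter operates on genome-level taxon bins, not assembled genes — a
deliberate simplification documented as such (no assembly, no BLASTx
taxonomy here). Keep-sets are monotone in the threshold. The
control-similarity flag defaults to *k*c = 4, mirroring the filter's
fold; both are configurable. Samples are compared to the negative
control of the same library type (DNA vs DNA, RNA vs RNA).

## Strain inference

- **Pileup / SNV calls:** every aligned base is tallied; a site is a
  consensus SNV iff depth ≥ *c*min = 5 and the top non-reference allele
  frequency ≥ *f*cons = 0.8. Callable = depth ≥ *c*min.
- **Strain sharing:** comparable sites are callable in both samples and
  variant in at least one; agreement is the fraction with identical
  major alleles (a site variant in only one sample necessarily
  disagrees). Verdicts: same-strain iff agreement ≥ 0.99 over
  ≥ *m*min = 10 sites; insufficient-data below *m*min; distinct
  otherwise. The score is symmetric.
- **Mixture detection:** a sample is a mixture iff ≥ 5 sites with depth
  ≥ *c*min have a minor-allele frequency in [0.2, 0.8] supported by ≥ 2
  reads (a single read is indistinguishable from a sequencing error at
  marginal depth). The mean and SD of the in-band frequencies are
  reported; SD ≤ 0.15 marks the frequencies as coherent with a single
  two-strain ratio.
- **Consensus ANI:** majority base (ties alphabetical, deterministic)
  vs reference over callable sites. This is consensus-vs-reference
  identity, *not* the fragment-based ANI of sketch/assembly tools —
  those need assembled queries this read-level workflow does not
  produce; for substitution-only strains on a shared coordinate system
  the two agree closely.

All thresholds exist because strain identification in alignment viewers
is visual; fixing them numerically is what makes the procedure testable.
They are exposed in configuration. Within-read co-occurrence (linkage)
of adjacent shared SNVs is not required — frequency- and
consensus-level agreement suffices at the depths simulated.

## DNA-carryover estimator

Only reads *wholly inside* a non-transcribed interval count as DNA
evidence *w*: transcript reads may legitimately straddle interval
boundaries, so interior counting is conservative by construction.
Under uniform DNA read starts, E = Σᵢ max(0, ℓᵢ−L+1)/(G−L+1) is the
chance a DNA read lands wholly inside, giving δ̂ = min(1, (w/n)/E);
E[w] = δ·n·E makes δ̂ unbiased before clamping. With QC-trimmed
(variable-length) reads, E is averaged per read. A per-base depth ratio
(mean non-transcribed depth / overall) is emitted as a cross-check. The
boolean verdict requires w > 0 and δ̂ ≥ 0.01 (reporting floor,
configurable) so a single stray alignment does not flag a library.
Transcribed-interval annotations are always user input; no organism's
biology is hard-coded.

## Synthetic data generator

Genomes are i.i.d. base strings at a target GC; strains plant a given
number of substitutions at uniform positions (no indels — the strain
evidence is SNV-based); transcript models are non-overlapping 0-based
half-open intervals. Reads are single-end, fixed length before QC, with
i.i.d. substitution errors and Sanger Phred+33 qualities; the quality
model is flat Q35 with two degraded-tail read classes (10 % of reads
with a 40-base tail that trims but survives, 5 % with an 80-base tail
that usually falls below the length floor) to exercise trimming.
Mixing weights are read-count proportions drawn multinomially. RNA
reads lie wholly within transcribed intervals except for a fraction δ
(DNA carryover) drawn uniformly genome-wide and flagged in the truth
table. Circular genomes are sampled linearly: no origin-spanning reads,
so the terminal L−1 bases of each end are structurally undersampled
(whole-genome breadth saturates over the interior but the extreme
termini may stay uncovered at realistic depth). Identical seeds give
byte-identical FASTQ.

### Canned designs

The **default (contamination-confounded) study** mirrors a
16-library layout: six specimens and a negative and positive control,
each as one DNA and one RNA library. Desk-scale genome stand-ins: host
40 kb, human 20 kb, *E. coli*-like 30 kb, *Catellicoccus*-like 15 kb,
phage 5,386 b (the real spike-in phage's length). Strains: one shared
contaminant *E. coli* (50 SNVs from the panel reference), one shared
*Catellicoccus* (40 SNVs), one shared spike-in phage strain (30 SNVs).
Specimen weights 0.80/0.01/0.05/0.02/0.12
(host/human/*E. coli*/*Catellicoccus*/phage) at 8,000 reads; the
negative control carries the same contaminants without host
(0.10/0.45/0.10/0.35 at 6,000 reads); the positive control is a
70:30 mixture of the reference lab strain and the shared contaminant
strain plus 7 % phage. RNA libraries carry δ = 0.3. These proportions
give the phage ~15–40× depth (it is the sharpest strain marker, as a
real spike-in is) and the positive-control mixture ~25×; read error
rate 0.001 approximates post-QC short-read data. No quantitative
well-to-well transfer proportions exist to copy, so these are the
package's own fixed choices, configurable per design parameter.

The **independent study** is the negative control for the pipeline
itself: each specimen carries private *E. coli* and phage strains
(independent 50- and 30-SNV draws), the negative control holds only its
own private phage strain, the positive control only the reference
strain, and δ = 0 everywhere.

What the generator deliberately does not model: paired ends, indels and
structural variation, PCR duplicates, GC or strand bias, quality-error
correlation, splicing, and origin-spanning reads. Passing tests
therefore demonstrate correctness of the inference logic under clean
sampling assumptions, not robustness to every real-data artifact;
absolute counts from real libraries additionally depend on the external
aligner used.

## Validation problem sizes

The test suite and acceptance script validate at sizes chosen to make
the statistics decisive while staying desk-scale: oracle equivalence on
1,000 random reads (trimmer) and 500 reads vs a 2 kb reference
(mapper), both at zero tolerated discrepancies; SNV recall/precision
with 50 planted SNVs at 20×; the same-strain/distinct confusion matrix
over 100 seeded pairs at ≥ 30-SNV separation (zero tolerated errors);
mixture detection over 100 seeds of 70:30 mixes at 50× (≥ 95 detected,
≤ 1 false call on pure samples); DNA-fraction recovery within ±0.05 at
50,000 reads for δ ∈ {0, 0.1, 0.3, 0.5, 1}; and the two end-to-end
designs (all six specimens flagged with all three evidence classes vs
zero flags). Oracle-generated reads for the mapper check carry at most
3 substitutions per 100 bp so an intact 21-mer seed is guaranteed by
construction and disagreements are attributable to logic, not seeding
luck.

## Degenerate inputs and tie-breaks

Zero-denominator percentages report 0.0 with a warning; empty read sets
yield empty tables, not errors; zero-coverage pileups give
insufficient-data verdicts for mixture and ANI; disjoint callable
regions give insufficient-data share verdicts; an empty transcribed
interval set makes breadth undefined (reported NA). Consensus ties
break alphabetically; mapper ties break forward strand, then lowest
coordinate; all RNG use is `numpy.random.default_rng` seeded from the
design or run seed, so identical configurations are byte-identical.
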