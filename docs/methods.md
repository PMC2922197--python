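# Methods

## Model

The package treats functional profiling of short reads as an exact
string-counting problem. A dictionary of Specific Peptides (SPs) — amino-acid
strings of length ≥ 7 over the 20-letter alphabet, each labelled with an EC
category at level 3 or 4 — is matched against the six pseudo-peptides of each
read (3 frames × 2 strands). The core quantities:

* **Raw factor** RF(EC) = SP hits / annotated enzyme genes, per EC level-3
  category. Evaluated on a full genome it equals the mean SP hits per enzyme
  of that category (asymptotic factor). Level-4 SP labels aggregate upward to
  their level-3 parent and only upward: without evidence on how sibling
  level-4 categories should share hits, upward aggregation is the
  conservative choice.
* **Efficiency model.** At read length k only W = ⌊k/3⌋ residues per frame
  are available, so an L-residue SP is seen with relative efficiency
  max(0, W − L + 1)/W; for k = 50 this is the (17 − L)/16 rule and SPs longer
  than 16 residues are invisible. Total efficiency is the expectation over
  the SP length distribution; it is monotone in k with limit 1. The W = ⌊k/3⌋
  window generalizes the 50-nt case to arbitrary read lengths. Note the model
  normalizes by W while the exact per-occurrence covering count is
  ≈ 3(W − L + 1)/k; the difference is a uniform bias of 0–4% depending on
  k mod 3, well inside the tolerances used here.
* **Normalized factor** NF(EC) = RF(EC)/RF(6.1.1). The aminoacyl-tRNA
  synthetases have the largest factor and are near single-copy; dividing by
  them cancels the shared read-length geometry, making NF approximately
  read-length invariant and hence transferable across datasets. Absolute
  predictions use RF; relative spectra use NF.
* **Prediction.** predicted(EC) = hits(EC)/RF(EC). Since factors are
  calibrated per unit coverage (see below), predictions on a metagenome of
  unknown depth equal gene copies × coverage ("coverage content");
  predicted 6.1.1 / 20 estimates genome equivalents (one aaRS per amino
  acid; configurable).
* **Taxonomy.** Taxon-Specific Peptides (TSPs) are aaRS SPs restricted to
  one taxon at one rank (kingdom/phylum/class; each TSP is specific to
  exactly one taxon at its own rank, and ranks are classified
  independently). The S61 subset keeps aaRS level-4 categories whose
  multiple-entry percentage, 100·(doublets + 2·triplets)/proteins rounded to
  one decimal, is ≤ 2%. predicted(taxon) = hits/factor; predictions below
  the no-call threshold (default 1 enzyme, applied to the unrounded value)
  are refused. Packaged factors were calibrated on curated proteomes and are
  lower bounds for environmental data; reports carry that caveat. Two
  entries of the packaged hierarchy (Bacillales, Chroococcales) are
  taxonomic orders sitting at the class slot of the three-level calibration
  table; the registry ranks them by depth.
* **Anomaly rule.** A category whose count exceeds every other category by
  more than a configurable fold (default 10×) while supported by at most 2
  distinct SP sequences is flagged as a likely artifact (e.g. one
  over-amplified fragment carrying two overlapping SPs).

## Coverage convention

Both statements "finite-read factors are lower than asymptotic ones" and
"predicted reference counts measure cell content" require finite-read RF to
be expressed per unit coverage. `compute_raw_factors` keeps the literal
hits/genes contract (used for the packaged taxon-factor table, whose factors
are asymptotic) and takes an optional `coverage` argument; the calibration
drivers divide simulated hit counts by the simulated coverage. Predictions
on real data therefore return gene copies × coverage, which is exactly the
quantity the cell-content estimate needs.

## Calibration protocol

Genomes are fragmented into ⌈coverage·G/k⌉ reads with independent uniform
start positions on the forward strand (six-frame search restores strand
symmetry; no sequencing-error model). Training pools random k-subsets of the
genomes into "super-organisms": subsets are sampled uniformly without
replacement among all C(n, k) combinations, seeded; per-EC NF mean and
sample SD (ddof = 1) are reported across combinations, with categories
absent from a combination's annotation skipped rather than scored 0/0. With
the full training set of the original protocol (11 genomes) the defaults are
7-of-11 with 15 combinations; the desk-scale experiments here use the scaled
analogue 3-of-5 with all 10 combinations.

## Matching

Multi-pattern search uses a hand-built Aho–Corasick automaton (trie +
failure links, outputs merged along suffix links): one pass per
pseudo-peptide, linear in text length plus hits, reporting every occurrence
including overlapping and tandem ones and multiple occurrences per read —
counts are occurrence counts, not read counts (the aggregation lives in one
place, so switching policy would be a one-line change). Equivalence with a
naive all-positions scan is enforced by seeded property tests; per-pattern
KMP would give identical output with a worse constant for large
dictionaries. Ambiguous bases (N) translate to X, which matches no SP
letter; stop codons translate to `*` and are not used to split
pseudo-peptides — SPs contain neither, so a match can never span a stop,
reproducing the fully-contained-hit contract without ORF calling.

## Synthetic study sets

`fixtures` builds genomes in which every planted gene encodes its EC
category's SPs via uniformly random synonymous codons (standard table 1), so
matches arise from translation, not nucleotide repeats. Roughly half the
genes go on the reverse strand (seeded coin flip). Background is random
nucleotide sequence; after assembly the genome is re-scanned in six frames
and re-rolled unless every SP occurs exactly its planted number of times, so
all expected values are fixed at construction time (asymptotic RF per
category = SPs per gene, or the gene-count-weighted mean when per-genome SP
densities differ). Heterogeneity knobs — per-genome gene counts and
per-genome SP-density multipliers — emulate organisms that differ in enzyme
repertoire and in marker-peptide content per enzyme; the latter is what
makes single-genome predictions degrade relative to pooled metagenomes, as
observed on real organisms. What fixtures do **not** emulate: sequencing
error, GC/codon bias, shared sequence between categories, SP length–function
correlations, and realistic dictionary sizes (a handful of SPs, not 10^5).
Passing recovery tests therefore demonstrates correctness of the counting
and calibration machinery, not the biological accuracy of any particular SP
dictionary.

## Recovery experiments (problem sizes and error model)

`evaluation.parameter_recovery` uses five 36-kb genomes with 48–63 genes
each over four EC categories at 5× coverage and read lengths 50/100/200 —
sizes chosen so per-category hit counts are in the hundreds, putting
counting noise (including the overdispersion caused by one read covering
several clustered SP occurrences) at a few percent. The pooled-metagenome
comparison uses the propagated standard deviation
sd_NF/NF · truth · √(1 + 1/n_combinations); for the reference category,
whose table SD is 0 by construction, a two-sided Poisson counting term
√(2/hits) · truth substitutes. The chi-square statistic is the mean of
((predicted − known)/sd)² over compared categories; it sits near 1 for
pooled metagenomes and grows for single genomes whose SP densities deviate
from the training average. `taxon_mixture_recovery` mixes one
Proteobacteria-labelled and one Firmicutes-labelled genome (24 aaRS-like
genes each) at coverages 15:5 after calibrating per-taxon factors at 40×,
and averages the recovered ratio over five replicates. The no-call check
feeds a single-TSP-hit read set through the classifier: one hit over a
factor > 1 predicts < 1 enzyme and must be refused.

## Numerical choices and degenerate inputs

* Ties/rounding: S61 selection rounds to 1 decimal before thresholding
  (chosen because it reproduces the published member set, including the
  2.03% borderline category); published-table regression tests compare at
  the printed 2 decimals.
* Equal-length duplicate sequences with different EC labels are both kept by
  the redundancy filter; the rule only discards supersequences of strictly
  shorter same-EC peptides. The filter is idempotent.
* Zero-gene categories with hits are reported separately (`orphans`), never
  divided; a zero reference factor is an error, not a NaN.
* Heterogeneous read lengths: factors for the mean read length are applied,
  with a warning when the length CV exceeds 20%.
* Degenerate coverage (< 1 expected read) emits one read with a warning;
  empty dictionaries and empty pattern sets are errors; a single-category
  hit table can never be anomalous (no comparator).
* All randomness flows from explicit integer seeds through
  `numpy.random.default_rng`; CLI runs are byte-reproducible under a fixed
  `--seed`.

## Limitations

* Exact matching only — no mismatch tolerance, so sequencing errors strictly
  reduce sensitivity (as in the original design, which uses no quality
  filtering).
* Factors transfer to unknown taxa only approximately; absolute predictions
  from database-calibrated factors are lower bounds.
* The packaged demo dictionary is illustrative; real profiling needs a real
  SP dictionary (~10^5 peptides), whose extraction from curated enzyme data
  is outside this package's scope.
* Pure-Python matching processes on the order of megabases of reads per
  minute per core; very large runs would want a compiled automaton behind
  the same interface.
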