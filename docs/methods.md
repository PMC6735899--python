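# Methods

`poolscreen` implements the computational half of a pooled-colony
drug-resistance screen: colonies surviving selection on a topoisomerase
poison are scraped together, the plasmid-borne ORF is PCR-amplified from
the pool, fragmented and sequenced, and the mutations enriched in the
surviving pool are read out as a ranked list of amino-acid
substitutions. Because the raw sequencing data of such screens are
usually not portable, the package pairs the analysis with a synthetic
pool generator that reproduces the statistical structure the analysis
assumes, so every stage is testable end to end without downloads.

## The pool model

A plasmid pool is a set of alleles, each a list of single-nucleotide
substitutions on the ORF with a positive abundance weight. The
generator emulates hydroxylamine chemical mutagenesis, which strongly
favors GC→AT transitions:

* the number of induced changes per plasmid is Poisson with mean
  `mean_mutations_per_plasmid` (default 1.5 — single point mutants
  should dominate the functional pool, as they do in validated screen
  isolates);
* with probability `gc_to_at_fraction` (default 0.9) a change is a
  forced C→T or G→A at a uniformly drawn C/G site; otherwise a uniform
  site receives a uniform alternative base *excluding* the C→T/G→A
  outcome. The exclusion makes the realized GC→AT fraction exactly
  Binomial(n, f), so spectrum-recovery checks are well-posed. The 0.9
  default encodes a strong bias while leaving transversion hits (the
  P716H class) possible; the true chemistry-specific fraction is not a
  published constant, so it is an exposed parameter;
* colony abundances are log-normal with σ = 1 (pooled colonies are
  scraped, not normalized; read counts are expected *not* to track
  colony numbers). A uniform model is available for tests. PCR
  amplification bias is deliberately not modeled separately — abundance
  skew subsumes it at the resolution this pipeline uses.

Selection is purely phenotype-driven: a truth map assigns labels to
known substitutions, alleles without a listed change are `sensitive`,
and only alleles whose label is in the survival set are kept (plus an
optional escape fraction for plating noise, default 0). The compound
lethality/plasmid-damage colony drop seen after real mutagenesis is not
reproduced.

## The read channel

Reads are single-end, default 100 nt, drawn from alleles proportional
to abundance. Fragment lengths are uniform in 200–500 nt (the library's
size selection) with uniform starts over the amplicon; the read is the
first `read_length` bases of a uniformly chosen strand of the fragment.
Per-base Phred qualities are i.i.d. from a discrete distribution; the
default mixture (Q40 : 0.70, Q38 : 0.15, Q35 : 0.10, Q20 : 0.05)
caricatures a high-quality HiSeq run with a low-quality tail that the
Q38 filter must reject. With `error_coupling` on, each base miscalls to
a uniformly random other base with probability 10^(−Q/10), so quality
and error are coupled exactly as the downstream filter assumes.

The generator does not emulate adapter read-through, quality trimming,
paired ends, indels or chimeric PCR artifacts: inputs to the aligner
are assumed pre-trimmed, as they would be after standard read cleanup.
Passing tests therefore demonstrate correctness of the counting
pipeline under its stated error model, not robustness to upstream
processing pathologies in real data.

Identical configuration + seed yields byte-identical FASTQ and truth
tables; all randomness flows through `numpy.random.default_rng`.

## Alignment

Reads are mapped to the amplicon with the screen's two constraints:
unique placements only, at most one mismatch per read. The reference is
a single ORF-scale amplicon, so the package uses its own exact k-mer
seed index with full ungapped verification rather than a genome
aligner; this makes the mapping contract exactly specifiable:

* placements with ≤1 mismatch survive; a read is `unique` iff exactly
  one placement attains the minimal surviving mismatch count (one exact
  placement plus stray 1-mismatch placements is still unique — the
  best-stratum convention), otherwise `ambiguous`;
* if the best placement anywhere has 2–3 mismatches the read is
  `too_many_mismatches`; beyond 3 (or read shorter than the seed) it is
  `unmapped`;
* an N in the read counts as a mismatch but never becomes an
  observation; qualities must be Phred+33.

The default seed length is k = 25 with non-overlapping seed placement
plus a tail seed: 100-nt reads carry four disjoint seeds, so every
placement with ≤3 mismatches is guaranteed to be found by an exact seed
(pigeonhole). That makes all four statuses — including the
near-miss/unmapped boundary — deterministic and exactly reproducible by
the brute-force all-offset oracle used in the tests.

Mismatches are strand-normalized to the coding strand, with the quality
taken from the original read position. Reads aligning wholly or partly
in flank sequence are counted but contribute no ORF observations.

## Calling and ranking

Observations with quality < `min_quality` (default Q38 — 99.98%
base-call confidence, 100·(1−10^(−38/10))) are dropped; a read whose
single mismatch fails the filter contributes nothing (it is not
recounted as wild type). Surviving observations are grouped by
(ORF position, alternate base); support is counted per distinct read
id. Each group is translated codon-aware: residue = ⌈pos/3⌉, alternate
codon = reference codon with one base replaced. Synonymous changes are
computed and flagged but excluded from ranking by default; stop gains
(the W653STOP class) are kept.

The table is sorted by supporting reads descending with a deterministic
tie-break (residue ascending, then alternate amino acid, then
nucleotide change) and truncated to `top_n` (default 100). The support
count at the last kept rank is reported as `threshold_reads` — the
screen's read-cutoff statistic. Entries beyond rank N tied with that
count go to a `boundary_ties` annex, never silently in or out. Rows
are keyed at nucleotide level; where two degenerate nucleotide routes
give the same amino-acid change, both rows are kept and an AA-collapsed
view (`collapse_aa`) sums them — both conventions for "top 100" are
therefore available.

## Landscape analyses

* **Domain tallies** assign each called substitution to the most deeply
  nested annotated domain containing its residue (with an explicit
  `unannotated` bucket); because nested-domain bookkeeping is ambiguous
  in figure-style reporting, a parent-rollup tally is provided
  alongside the deepest-domain one.
* **Screen comparison** partitions two screens' calls into A-only /
  B-only / shared by residue-level identity (residue, alternate AA) by
  default, matching residue-sphere overlap displays; nucleotide-level
  identity is a flag.
* **Spectrum audit** reports the fraction of calls that are C→T/G→A and
  lists every other call for inspection (undefined on an empty table).
* **Selection summary** is the plating arithmetic: percent of plated
  transformants confirmed resistant, to 2 d.p. (363 of 28 000 → 1.30%).
* **Resistance classification** labels a validated mutant resistant
  when its log10 viable-count fold change meets the threshold (default
  2, the 100-fold class) and stratifies resistant records into weak
  [2, 4) and strong [4, ∞) — the 100-fold versus 10 000-fold strata;
  concordance is the fraction of records matching the screen's
  expectation.

## Numerical and design choices

* All I/O coordinates are 1-based (residues from the initiator
  methionine, ORF nucleotide positions); internal array math is
  0-based.
* The caller validates every observation's reference base against the
  reference and fails loudly on disagreement (corruption guard).
* `selection_summary` and `quality_confidence` round only at the
  reporting surface (2 d.p.); nothing upstream is rounded.
* With several truth-listed substitutions on one allele, selection uses
  the label of the lowest-position listed change (deterministic).
* Degenerate inputs: empty FASTQ gives an all-zero summary; an empty
  call table round-trips as a header-only file; an empty pool after
  selection warns rather than raises.

## Problem sizes used in checks

The packaged benchmark experiments run at desk scale, chosen so that
expected per-site coverage comfortably exceeds the decision margins:
spike-in recovery uses 1 000 alleles over 30 known substitutions and
60 000 reads on the 1 kb toy amplicon (≥50× expected coverage per
spiked site), the aligner oracle uses 10⁴ reads against a 2 kb
duplicated-segment reference, the null calibration 20 000 reads, and
spectrum recovery 3 000 alleles per configured fraction. The null
calibration's analytic expectation is
`n_reads · L · E[p·1(Q≥38)] · (1−E[p])^(L−1)` with `p = 10^(−Q/10)`:
the last factor accounts for reads rejected by the ≤1-mismatch rule
after a second error.

## Known limitations

Real screen libraries add PCR jackpotting, position-dependent quality
decay, adapter contamination and multi-mutant alleles whose secondary
changes break the ≤1-mismatch assumption for reads spanning two sites;
none of these are modeled, so quantitative test outcomes (e.g. perfect
spike-in precision) bound ideal-case behavior rather than predicting
field performance. The aligner is ungapped and single-end by design and
is not a general-purpose replacement for genome-scale mappers.
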