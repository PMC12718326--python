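# Methods

This note documents the models behind t6kit's simulators and analyses, the
parameters that matter, the numerical conventions, and what the synthetic
data do and do not establish about real experiments.

## Tn-seq simulation and analysis

**Model.** A barcoded transposon library is a set of insertions
(barcode, genome position, gene or intergenic) with initial relative
abundances and ground-truth fitness multipliers `w(gene, condition) ≥ 0`
(default 1). Selection is multiplicative: the expected post-selection
frequency of barcode *b* is `f₀(b)·w(gene(b), condition)`, renormalized.
Sequencing is seeded multinomial sampling at the requested depth, routed
through a finite cell bottleneck (default 1,000 × the number of barcodes,
mirroring the screen design's ≥1,000-fold clone excess). Optional
mean-preserving Dirichlet overdispersion of the pre-selection frequencies
models bottleneck noise; it is off by default so expectations stay exact.

**Scale.** The default desk scale is 5,000 barcodes over 500 genes (the
real library had ~3.2 × 10⁵ barcoded mutants); both are knobs. Initial
abundances are lognormal (σ = 0.5 on the log scale) to mimic uneven
library representation.

**Analysis.** Reads are assigned to barcodes at a fixed window
(exact match by default; an optional unique-one-mismatch rescue exists but
RB-Tn-seq barcodes are designed for exact matching). Reads per barcode are
summed per coding sequence; intergenic insertions are excluded from gene
sums but retained in totals, and the tally conserves reads exactly
(assigned + unassigned = input). Normalized abundance is

    N_g = ((S_g + α) / L_g[kb]) / median_over_genes((S + α) / L[kb])

per sample, so the per-sample median gene has N = 1, and fold enrichment is
`FE_g = N_sel/N_ctrl`, ranked descending with ties broken lexicographically
by gene id. The pseudocount α = 0.5 (raw-count scale) keeps FE finite for
zero-count genes without influencing typical depths. The "median insertion
abundance" normalizer is interpreted as the per-sample median over *genes*
of length-normalized abundance; a per-insertion median and central-gene
trimming are plausible alternatives in the field and would be configuration
extensions. Gene membership uses 0-based half-open intervals (insertion at
p belongs to g iff start ≤ p < end), strand ignored; on-disk gene tables
are 1-based inclusive and converted at the boundary.

## Error-prone-PCR mutant screen

**Mutagenesis model.** Per-clone substitution counts are Poisson(λ) with
λ = 3 by default (the screen's design rate); positions are uniform over the
locus and unique within a clone; the alternate base is uniform over the
three non-reference bases. Indels in clones are not simulated — the screen
analyzes amino-acid substitutions. Amino-acid changes are derived by codon
translation (bacterial code, table 11; stops TAA/TAG/TGA), applying all of
a clone's substitutions within a codon jointly. Residue indices are
1-based.

A note on mutation spectra: real error-prone PCR is transition-biased, and
the published screen's clone counts imply a nonsense load well above the
uniform-spectrum expectation. The simulator's uniform spectrum is the
analytically transparent default; the brute-force stop-fraction oracle
(`brute_force_stop_fraction`, enumerating all 3L single-nucleotide
substitutions) gives the closed form `P(nonsense-free) ≈ exp(−λq)` that the
tests verify, and a biased spectrum would slot in as a configuration
extension without changing the analysis code.

**Selection model.** `SelectionRules` declares inactivating residues
(missense there, or nonsense anywhere, abolishes Rnf function), resistance
alleles (protein, residue, alt-aa triples), and survival probabilities:
`rnf_selection_kill` for non-functional clones on selective media,
`s_sensitive`/`s_resistant` per toxin round. Selection is deterministic
multiplication of abundances followed by renormalization (conserving total
abundance to 1 within 1e-9); optional multinomial resampling adds drift.
The full screen design is input pool (after Rnf selection) → two toxin
rounds and, in parallel, two no-toxin control rounds → final Rnf selection.
Zero surviving abundance raises an explicit "library extinct" error.

**Long-read readout.** Reads are drawn from clones proportional to
abundance; per-base substitution/insertion/deletion errors are injected;
with probability `truncation_prob` a read loses one terminal segment of
length uniform in [min_truncation, L/2] (min_truncation = 50, deliberately
above the 20 bp clip tolerance so truncation and clip slack never
overlap). The amplicon carries ~30 bp non-coding flanks around the
mutagenized cassette, as a targeted amplicon would; this also keeps
terminal CDS variants interior to the alignment.

**Readout analysis.** Per sample: uniform subsampling without replacement
(default 55,000 reads, the screen used 50–60k; a dedicated subsample seed
keeps the analysis arm reproducible independent of simulation seeds);
semi-global alignment of each read within the locus via edlib
(edit-distance, banded — fast at long-read scale). Unit-cost alignment can
tie two nearby substitutions against a balanced insertion/deletion pair;
a repair pass collapses such balanced pairs (separated by ≤ 20 aligned
columns) back into direct base comparisons, which is the strictly better
representation under affine-gap scoring and avoids spurious no-calls.
Reads below 60% identity are discarded with a logged count. The
full-length filter keeps alignments with reference start ≤ t, end ≥ L − t
and clips ≤ t (t = 20 bp).

Variant calling tallies alternate bases per reference position over
covering reads (read deletions are no-calls, excluded from the
denominator; an uncovered site yields no call, not frequency zero), with
`min_variant_reads = 3` support and a noise floor of 3× the configured
per-base error rate — at nanopore-like error the floor suppresses
error-driven alleles (~error/3 per alternate base) while true selected
alleles pass. Per-residue substitution frequency sums the frequencies of
missense/nonsense alleles at that residue; synonymous and non-CDS alleles
never contribute. Two calling modes: `variant_level` (default) classifies
each nucleotide allele in reference codon context — the per-allele
summation the field uses — while `codon_level` translates each read's
codon and so phases two substitutions within one codon; they differ only
for multi-hit codons. Differential enrichment is
`E = f_sel / max(mean(f_ctrl), ε)` with ε = 1/subsample_n (the smallest
observable frequency); residues with control mean below ε and observed
selected frequency are flagged selected-only. Both the input pool and the
no-toxin-competed pool serve as controls by default.

## Competition statistics

C.I. = (CFU_f^rec/CFU_i^rec)/(CFU_f^don/CFU_i^don). Zero final recipient
CFU gives C.I. = 0 with a recipient-extinct flag; zero final donor CFU
makes the C.I. undefined (reported missing, never infinity) — zeros are
plating-censoring events, and a detection-limit substitution mode
(`censor_zeros`, limit = 1/lowest plated dilution volume) is provided
rather than imposed. Replicate summaries default to the geometric mean
(C.I. is a ratio quantity). Relative competitiveness is the toxin-arm C.I.
over the no-toxin-arm C.I., also as percent. Outcome proportions carry
exact Clopper–Pearson intervals; interior points use the two-sided α/2
construction, while the boundary cases put the whole α on the one
informative side, so the upper bound at 0 of n is 1 − α^(1/n).

The competition simulator grows both populations by a common factor and
divides the recipient by a kill factor, with optional lognormal noise; at
zero noise the downstream C.I. is exactly 1/kill. The exactness tests
draw power-of-two CFUs and factors, for which IEEE-754 division is exact,
so the scale-invariance and inversion identities can be asserted with
equality rather than tolerance.

## Comparative screen

Ortholog hits are retained iff the aligned region is ≥ 850 aa and (by
default) the C-terminal Ig domain is present. Rnf presence requires BOTH
diagnostic labels (COG4657 and COG2878) somewhere in the genome — AND, not
OR. Immunity adjacency examines immediate neighbors (index ± 1,
configurable window) of each toxin gene; the default predicate accepts a
neighbor carrying a declared immunity label or one that is ≤ 400 aa and
free of toxin/Rnf labels. The real criterion ("strongly predicted cognate
immunity factor") is a structure-level judgement; this predicate is the
module's declared operational stand-in, and the annotation simulator
plants background genes > 400 aa so the predicate identifies exactly the
planted immunity genes (making truth-table equality testable).

Global alignment is affine-gap (a gap of length k scores
gap_open + (k−1)·gap_extend), backed by Biopython's PairwiseAligner with
deterministic tie enumeration; empty-sequence edge cases are scored as a
single terminal gap run. Percent identity defaults to identical columns
over columns where both sequences are non-gap (the alternative
denominator, all alignment columns, is a switch). Conservation scores are
the mean over all unordered pairs of percent identity per subunit, and the
unweighted mean across subunits; subunits with fewer than two sequences
are excluded with a warning.

## Determinism and configuration

Every stochastic operation is a pure function of its inputs and a seed;
seeds derive from a single global seed plus an operation tag
(`config.derive_seed`), and no module reads ambient entropy. Tables are
TSV (UTF-8, '.' for missing); generated files carry their seed in a header
comment. The CLI writes a manifest with the config hash and output
checksums; identical configs give byte-identical outputs.

## Problem sizes in the test suite

The acceptance checks run at the package's reference desk scale: 500 genes
/ 5,000 barcodes / 5 × 10⁵ reads over 20 replicates for the Tn-seq arm; a
~960 bp four-protein cassette with 10⁴ clones and 3,000 reads per sample
at 5% read error for the resistance screen; 10⁴ clones per λ for the
mutagenesis-load closed form; 1,024 clones for the exact oracle; 1,200
randomized cases for the C.I. invariants; and all 16,129 pairs of
two-letter sequences of length ≤ 6 for the alignment oracle.

## What passing tests do and do not show

The generators reproduce the *structure* of the experiments — selection
acting multiplicatively on clone frequencies, Poisson mutational load,
truncated long reads, censored CFU counts — not their biology. Passing
tests establish that the pipelines recover planted parameters under the
stated noise models; they do not validate fitness estimates against real
transposon libraries (no PCR jackpotting or chimeras, no positional
insertion bias, no basecalling error structure beyond i.i.d.
substitutions/indels), and the uniform mutation spectrum understates the
nonsense load of real error-prone PCR. The co-occurrence screen's immunity
predicate is an annotation-level proxy for structure-based immunity
prediction. Known further limitations: per-allele variant calling cannot
phase more than one codon (use codon_level mode for that); alignment is
edit-distance-based rather than quality-aware; and wet-lab stages
(basecalling, Cas9 enrichment, qPCR quantification) are out of scope.
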