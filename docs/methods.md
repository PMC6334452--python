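# Methods

`ampedit` quantifies genome-editing outcomes from single-end amplicon
sequencing of CRISPR-Cas9 (nuclease) and BE3 (cytidine base editor)
experiments, and ships a simulator that generates such libraries with
known ground truth. This note records the models, conventions, numerical
choices, and limitations.

## Target model and coordinates

A target is an amplicon plus guide geometry: a 20–21 nt protospacer on
either strand, an NGG PAM immediately 3' of it on the protospacer strand,
and analysis windows. Internally all amplicon coordinates are 0-based
half-open on the plus strand; report files are 1-based inclusive and say
so in a header token. Protospacer positions are 1..L in PAM-distal
numbering (position 1 = 5'-most base); PAM-proximal numbering is available
everywhere through the involution p' = L + 1 − p. Both conventions appear
in the literature for the same guide, which is why the conversion is a
first-class operation.

The cleavage site uses the canonical SpCas9 blunt-cut rule: the
double-strand break falls 3 bp 5' of the PAM, between protospacer
positions L−3 and L−2 (17|18 for a 20-mer). `cut_site` returns the
plus-strand coordinate of the first base 3' of the break; the
quantification window is `[cut − h, cut + h)` with h = 15 by default
(a 30-bp window). The BE3 editing window defaults to protospacer
positions 4–8 (PAM-distal), the canonical deamination window; it is
configurable per target.

## Windowed allele quantification

Reads are kept when their arithmetic-mean Phred quality is ≥ 33 (boundary
inclusive). Surviving reads are globally aligned to the amplicon with
affine gap scoring +2 match / −4 mismatch / −10 gap open / −1 gap extend,
where the opening penalty covers the first gapped base (a k-base gap costs
10 + (k − 1)). These values make a 2-bp indel strictly preferable to two
mismatches, so small NHEJ lesions align unambiguously. Among co-optimal
alignments the engine's first is taken and indels are then shifted to
their leftmost equivalent placement, which fixes tie-breaking
deterministically. Reads with alignment identity below 60% (matches over
the longer sequence) are flagged unalignable and counted separately.

An allele is the read's sequence across the window columns: deleted
reference columns are marked `-`, and an insertion belongs to the window
exactly when its left reference neighbour lies inside it (so right-edge
insertions count, left-edge ones do not — half-open logic keeps allele
identity unambiguous). Edits outside the window never affect allele
identity. Reads with identical window sequences are consolidated;
frequencies are counts over the denominator of reads that passed QC,
aligned, and span the window. Alleles with frequency strictly below
0.01% (configurable) are excluded; their summed mass is reported as
`excluded_lowfreq_mass` rather than renormalised away, so retained
frequencies plus excluded mass always total exactly 1. Read accounting is
exact at every stage: input = QC-discarded + unalignable + non-spanning +
denominator.

## Consequence classification

Each allele is spliced back into the amplicon and translated with the
standard nuclear genetic code from the first in-frame coordinate at or
after the CDS start (the frame is anchored to a known in-frame codon
coordinate, so edits cannot shift it). Ambiguous bases translate to X,
never silently dropped. Classes are assigned in precedence order:

1. reference — no edits;
2. frameshift — net indel length not a multiple of 3;
3. nonsense — a premature stop in the translated segment;
4. in-frame indel — net indel ≠ 0, multiple of 3, no premature stop;
5. missense — at least one changed residue;
6. silent — otherwise.

Frameshift outranks nonsense so that a frameshifted downstream stop is
reported as a frameshift consequence; the categories stay disjoint.
Frameshift and nonsense alleles are null alleles. A nonsense allele
carries a *targeted stop* when every one of its edits is an
editing-window C→T conversion on the protospacer strand (G→A on the
plus strand for a minus-strand protospacer) — the programmed base-editing
outcome, e.g. TGG→TAG/TGA/TAA at a tryptophan codon. Novel residues are
counted by aligning the mutant peptide prefix (before its first stop)
against the reference peptide with a longest-common-subsequence matcher,
so residues that merely shift after an in-frame indel are not counted as
novel; targeted stops have zero by construction.

The relative null percentage divides null read mass by *edited* mass,
where edited excludes reference and silent alleles (a silent substitution
has no protein-level consequence); the denominator definition is recorded
in the output. Mutation-type composition partitions edited mass into
single-substitution, multi-substitution, insertion-containing,
deletion-containing, and mixed (insertion + deletion) alleles.

## Base-substitution profiling

The substitution matrix counts base changes per protospacer position
across aligned reads, reported on the protospacer strand. A read enters a
position's denominator only when that position is aligned to a read base:
positions under deletions are excluded rather than counted as non-edits,
so indel-rich nuclease samples do not dilute substitution percentages.
The targeted-transition fraction is the share of all substitution events
over positions 1..L that are C→T at editing-window cytosines; 0/0 is
reported absent, not zero. Because the Figure-style per-position report
has no stated denominator convention in the field, the long-format output
carries coverage alongside frequency so either per-read or
per-substitution views can be derived.

## Off-target panel

Candidate sites arrive as a TSV (nominated upstream by CIRCLE-seq or
bioinformatic prediction; discovery is out of scope). The base-editing
panel rule keeps sites with at most 3 mismatches to the guide (inclusive)
AND at least one editing-window cytosine on the protospacer strand; every
decision is logged with its reason. Per-site mutation frequency reuses
the windowed quantification (edited = retained non-reference allele
reads), returning integer counts so exact tests apply; zero usable reads
yield an absent entry, distinct from zero frequency. The default group
comparison is a two-sided Fisher exact test on pooled treated vs control
counts with Benjamini–Hochberg adjustment across panel sites
(significant ⇔ q < 0.05); exact tests behave well at the near-zero counts
expected of clean off-targets. A per-sample Mann–Whitney alternative is
available behind a method switch, and unadjusted p-values are emitted,
because the original assay's exact test and multiplicity handling are not
documented anywhere.

## Translocation assay

Two cut loci joined at their cleavage sites give two junction geometries:
balanced (reciprocal), `A[0:cut_A] + B[cut_B:]`, and acentric
(head-to-head), `A[0:cut_A] + revcomp(B[0:cut_B])`. The acentric strand
arrangement is an inference from primer geometry — on a head-to-head
fragment two primers that are each "forward" on their own locus become
convergent and can amplify — and is labelled an assumption in report
headers. In-silico PCR uses exact-match primer semantics (the assay is
presence/absence; mismatch tolerance would manufacture bands): a product
exists when the forward primer matches the plus strand and the second
primer's reverse complement occurs downstream, with length measured 5'
end to 5' end inclusive. Multiple binding sites produce all products with
an ambiguity flag. Junction reads are reads containing the exact
`min_flank` = 15 bases on each side of the junction; at zero sequencing
error this yields zero false positives provided the two loci differ in
sequence within `min_flank` of their cuts — loci sharing an identical
protospacer core are not junction-distinguishable at that flank depth,
which is why fixtures pair two different guides.

## Simulator

The simulator is the package's test bed and defines its study conditions.
Reads are single-end and amplicon-length (the analysis is amplicon-wide;
trimming/merging is out of scope), Phred+33, with substitution-only
sequencing error at a uniform per-base rate (default 2 × 10⁻⁴, coherent
with the default Gaussian quality model of mean Q37, sd 2, clipped to
[2, 41]). Substitution-only error keeps truth attribution exact: at error
rate zero every read equals its source allele string. A truth table maps
every read to its source allele and edit list.

Editing profiles are mixtures over edited alleles with an overall edited
fraction `p_edit`:

- **BE3-like** — all non-empty subsets of editing-window cytosines
  converted C→T share 75% of edited mass; non-C→T conversions (C→G, C→A)
  at the same cytosines get 15%; 1–2 bp deletions at the cut get 10%.
  With these weights substitution-only alleles are ~90% of edited mass,
  the class balance reported for BE3 treatment in vivo.
- **Cas9-like** — deletions of 1–9 bp centred on the cut with geometric
  size decay 0.85 (85% of edited mass), 1-bp insertions (10%), and
  cut-site substitutions (5%); frameshifting outcomes are ~70% of edited
  mass, matching reported relative null-allele percentages for nuclease
  treatment.

Fusion libraries mix intact-locus reads from two targets with junction
reads from a chosen geometry at rate `p_fusion`.

Because no sequencing data or amplicon context for the original loci is
deposited, synthetic targets embed the real guide sequences
(`CAGGTTCCATGGGATGCTCT` and relatives) as minus-strand protospacers in
seeded random flanks, with the PAM-adjacent geometry of the analysed
locus and the targeted TGG (tryptophan) codon spanning protospacer
positions 7–9. Coding targets resample flank codons until the in-frame
reference segment is stop-free, emulating a coding exon — otherwise a
random in-frame flank stop shifted forward by an in-frame deletion would
masquerade as nonsense. What the simulator does *not* emulate: PCR
duplicates and chimeras, paired-end structure, coverage nonuniformity,
quality-correlated errors, indel sequencing errors, and guide-dependent
editing efficiency differences. Passing tests therefore demonstrate
correctness of the analysis under idealised library structure, not
robustness to those artefacts.

## Numerical and degenerate-input choices

- Frequencies are exact ratios of integer counts; conservation checks use
  exact integer identities and a 1e-9 tolerance only for float mass sums.
- Sort order of alleles is descending count with lexicographic window
  sequence tie-break; all outputs are byte-deterministic for a fixed seed
  (single RNG stream per simulation, enumeration-order derived sub-seeds).
- Zero denominators are reported absent (None/NA), never as 0: relative
  null percentage with no edited mass, substitution fraction with no
  substitutions, site frequency with no usable reads.
- Empty allele tables raise a data error naming the sample and target.
- The 0.01% floor is strict less-than; the Q33 filter and ≤3-mismatch
  panel rule are inclusive.

## Problem sizes used in verification

The self-checks run at desk scale, chosen to balance statistical power
and runtime: alignment oracle equivalence on 200 reads × 120 bp;
parameter recovery over 20 seeds × 50,000 reads against binomial
envelopes; substitution-matrix recovery at 10,000 reads; off-target null
calibration on 24 sites × (4 + 4) samples × 1,200 reads × 20 seeds;
junction detection on 3,000–4,000 read libraries. The acceptance script
simulates 20,000-read samples per locus/treatment with editing
efficiencies at the midpoints of the reported in vivo ranges.

## Known limitations

- Reads must span the full window; partial-coverage (e.g. trimmed or
  merged-pair) data would need an upstream preparation step.
- Novel-residue counting is LCS-based and can undercount when a
  frameshifted tail coincidentally matches reference residues.
- Junction detection is exact-match; at realistic error rates a small
  fraction of true junction reads carrying an error within the 30-base
  probe is missed (detection is conservative).
- The per-site off-target test pools samples by default; per-animal
  dispersion is emitted for inspection but not modelled (no overdispersed
  count model).
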