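# Methods

This note documents the models and procedures the package implements,
the parameters that matter, what the synthetic data does and does not
emulate, and the design choices made where the design was genuinely
open. Nothing here asserts an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Synthetic receptor loci

The generator builds a multi-family Ig-receptor locus with complete
ground truth.

**Family profiles.** Each family's ~90-aa C2-set Ig domain consensus is
derived from one shared ancestral sequence mutated at an
`inter_family_divergence` fraction of positions (default 0.4). A profile
set is regenerated until (a) every consensus pair differs at ≥ half the
nominal divergence, and (b) no consensus contains a 19-residue window of
mean Kyte–Doolittle hydropathy ≥ 1.3 — Ig ectodomains are extracellular,
and a TM-grade stretch inside a domain would make soluble receptors
built from it impossible.

**Genes.** A receptor protein is
`signal (15 aa, polar) + n × [domain + LTNH linker] + stalk (12 aa) +
[TM block (21 aa from {L,I,V,F,A,M})] + tail (30 aa, polar)`, with
`n ∈ {2, 4, 6}` (six-domain genes emulate PIR-like receptors). Domains
are consensus copies mutated at `within_divergence` (default 0.1).
Class truth is *verified on the final mutated protein* by the
generator's own independent checks (its own hydropathy window scan and
ITIM regex), resampling mutations until the intended class holds:
inhibitory tails carry one `[VLSN]xYxx[LV]` motif placed clear of the
detected TM span, activating TM blocks carry a central arginine and a
motif-free tail, soluble proteins contain no detectable TM window. The
classifier module is never consulted during generation, so
generator/classifier agreement is a genuine cross-implementation test
(and is tested).

The fixed `LTNH` inter-domain linker is a structural safeguard: its
codons (`TTAACTAATCAT`) place a stop codon in every non-coding reading
frame on both strands, so spurious off-frame ORFs can never span a
domain junction in the assembled contig. Short linkers between Ig
domains are realistic for these receptors.

**Coding sequence.** Back-translation uses one fixed codon per amino
acid; `L=TTA` and `S=TCA` were chosen so the frame-aligned reverse
reading of coding sequence is stop-rich, suppressing spurious
reverse-strand ORFs.

**Contigs.** Genes and decoy ORFs (random proteins of 160–230 aa with no
Ig content) are shuffled across three contigs on both strands, separated
by random intergenic spacers flanked by stop-codon guards
(`TAAATAAATAA` and its complement) that provide stops in all six frames,
so no ORF can extend across a placement boundary. After assembly the
contigs are re-scanned with the package's own ORF finder and domain
scanner; if the ORF census or the per-protein domain hits disagree with
truth in any way, the whole bundle is regenerated from a derived
sub-seed (deterministic, bounded). The default fixture therefore always
contains exactly 77 ORFs of which exactly 26 carry Ig domains.

**Default repertoire.** 26 genes: 16 unannotated (7 inhibitory /
4 activating / 5 soluble, including one six-domain inhibitory and one
six-domain activating receptor) plus 10 genes also present in the
"previously annotated" set; all expressed. Novelty then follows from
the redundancy rule alone: annotated genes duplicate themselves
(100% identity, full overlap) while unannotated genes never overlap the
annotated loci.

**Reads.** Each expressed gene's mRNA is its coding span plus 50 nt of
flanking genomic sequence on each side (UTR stand-ins), from which
36-nt reads are drawn uniformly on both strands at `depth ×
length / 36` reads per transcript, with independent per-base
substitution errors (default 0.005). Qualities are a constant Q30
placeholder. Not emulated: realistic error profiles, indels, paired
ends, splice isoforms, genomic repeats — the mapping model this feeds is
ungapped with substitution costs, so none of these would exercise
additional code paths. Consequently, passing tests show the *logic* of
the pipeline recovers truth under controlled divergence; they say
nothing about performance on real Illumina artefacts.

## Discovery

`find_orfs` reports every ATG→stop span of ≥ `min_aa_length` codons in
all six frames (nested ORFs sharing a stop collapse to the longest);
codons containing `N` translate to `X` and are never starts or stops.
The default `min_aa_length` is 150 codons: receptor genes are ≥ ~280 aa,
decoys are generated at ≥160 aa, and shorter cutoffs admit stochastic
off-frame ORFs from the locus itself.

Domain detection is a windowed position-specific scoring matrix scan:
per family, `entry(i,a) = ln[(count(i,a)+p/20)/(n+p)] − ln(1/20)`
(pseudocount `p`, default 1). Every window is scored against every
family; windows at or above the threshold are kept with greedy
non-overlap resolution (descending score, ties leftmost). The default
threshold is half the mean per-family self-score — with single-sequence
profiles this sits far above the score of unrelated sequence (negative
in expectation) and far below a 10%-mutated domain copy, so the margin
is wide on both sides. `X` scores as the per-column matrix mean.

## Phylogenetics

Distances are amino-acid p-distances with pairwise deletion: columns
where either row is `-` or `X` are skipped per pair; a pair with zero
comparable columns is flagged undefined (NaN) and refused by tree
building. Neighbour joining is the classic algorithm:
`Q(i,j) = (n−2)d(i,j) − Σₖd(i,k) − Σₖd(j,k)`, minimal-Q join with ties
broken by the lexicographically smallest cluster-label pair (a cluster
is labelled by its smallest leaf), two-term branch lengths with negative
values clamped to zero, reduction
`d(u,k) = (d(i,k)+d(j,k)−d(i,j))/2`, closed-form three-taxon
termination. One numerical subtlety: the Q matrix is symmetric only up
to floating-point summation order, so tie detection canonicalises index
pairs rather than assuming both orientations appear.

Bootstrap supports resample alignment columns with replacement per
replicate (replicates with an undefined pair are redrawn and counted),
rebuild the NJ tree, and annotate each internal edge of the
original-data tree with the percentage of replicates containing the same
leaf bipartition. Majority-rule consensus (threshold ≥ 50%) is also
provided. The pipeline default is 1000 replicates; the end-to-end test
and the acceptance script run 50–300 replicates, a problem-size choice
that leaves the computation identical.

Multiple alignment is a star alignment: each domain is globally aligned
(match +2, mismatch −1, gap −2, traceback ties diagonal > up > left) to
a profile-anchor consensus and stacked in anchor coordinates, dropping
(and counting) insertions relative to the anchor. This trades insertion
information for a fixed coordinate frame and O(n) alignments; adequacy
is tested through family-recovery properties, not by matching any
progressive aligner.

Family assignment is distance-based rather than tree-reading (the
nearest testable formalisation of "clusters with"): a query domain takes
the family with the smallest mean pairwise-deletion p-distance to its
reference set, provided the runner-up is at least `ambiguity_margin`
(default 0.05) further; otherwise "unassigned". Receptors take the
majority family over their domains (ties → unassigned) and are flagged
chimeric when assigned domains span ≥2 families. At the default
divergences (0.1 within, 0.4 between) the expected margin is ~0.25, so
0.05 is conservative.

## Redundancy

Evidence per query/subject pair: global-alignment percent identity
(identical aligned pairs over columns where both rows are residues —
gap columns do not enter the denominator), locus overlap in bp (0-based
half-open intervals; any positive overlap counts as "same locus"), and
the number of query domains with p-distance exactly 0 to some subject
domain. Verdict: `duplicate` iff identity ≥ 95% and overlap > 0;
`alt_transcript_candidate` iff overlap > 0, identity < 95%, and *every*
query domain is identical to a subject domain; otherwise `novel` —
including the high-identity-without-overlap case, which is a paralogous
copy, not a duplicate. The threshold boundary is sharp (95.0 is a
duplicate, 94.999 is not) and the rule is total. The
alternative-transcript verdict deliberately preserves ambiguity rather
than forcing a duplicate/novel call.

## Structural classification

TM detection is a Kyte–Doolittle sliding-window scan (window 19,
threshold 1.6): consecutive passing window starts form runs, the run
with the highest peak window mean wins, ties resolve toward the C
terminus (these are type-I receptors anchored near the C-terminal end,
and this also avoids mistaking a hydrophobic signal peptide for the TM —
signal peptides are otherwise not modelled, a logged limitation). The
reported segment spans all residues of the run's windows and can
therefore extend a few residues into a mildly polar tail; the segment's
`mean_hydropathy` is its peak window mean. Unknown residues score 0
(neutral).

ITIMs are all (overlapping) 6-residue windows matching `[VLSN].Y..[LV]`,
scanned *only* C-terminal of the TM; for TM-less proteins, motif matches
are reported separately as non-signalling and do not affect the class.
Decision table: no TM → soluble; TM ∧ ≥1 ITIM → inhibitory; TM ∧ 0
ITIMs ∧ TM-arginine → activating; TM ∧ 0 ITIMs ∧ no arginine →
"unclassified", a totality fallback with no biological claim attached.

## Expression

A read of length L placed ungapped scores `matches − cost × mismatches`
(`N` never matches, on either side) and is accepted at
`score ≥ ceil(0.8 L)`; at L=36 this admits ≤2 mismatches at cost 2 and
≤3 at cost 1. Each read takes a single placement. Since score orders
placements exactly as mismatch count does at either cost, the minimal-
mismatch tied set is cost-invariant; the two-pass protocol (cost 2, then
re-map at cost 1) therefore shares one mapping computation, and the
permissive pass can only add placements — coverage is provably monotone
between passes. Equal-scoring candidates are resolved by a
deterministic read-keyed draw (CRC32 of the read id modulo the tied
candidate list, enumerated in reference order, '+' strand first, left to
right): these loci are internally repetitive (tandem domain copies) and
paralogs share long identical stretches, so any fixed positional
preference would systematically starve all but the first copy and bias
coverage downward, while a read-keyed draw is unbiased, reproducible and
still single-placement. Match counting is vectorised as a one-hot
matrix product over sliding reference windows.

The pipeline maps reads onto the *contigs* and evaluates coverage over
each predicted gene region (the generic per-transcript reference mode is
also available). This mirrors mapping transcript reads back to
chromosomal segments: real mRNAs extend beyond the coding sequence, so
boundary-straddling reads anchor the region ends, whereas an exact-CDS
reference structurally under-covers its own termini (no read can
overhang a reference end). A region is expressed iff percent covered is
*strictly* greater than the threshold (default 99) — full precision is
used for the call even though tabular reports round to integers.
Limitation: with single-placement mapping onto a genomic reference, a
silent gene with an expressed close paralog can show partial coverage in
their shared stretches; the strict >99% rule keeps such genes below the
expression call at the default divergences, and the one-gene-per-family
tests verify the clean 100%/0% separation.

## Pipeline

Stages run discovery → phylogeny → redundancy → structure → coverage
under one `PipelineConfig`; one seed governs fixture generation, read
simulation, reference-domain sampling and bootstrap (per-stage derived
substreams). All outputs are plain text (FASTA/FASTQ/GFF3/TSV/JSON/
newick) written with fixed ordering and float formats, so identical
configs give byte-identical run directories — verified by checksum in
the tests. GFF3 is 1-based inclusive on disk; everything in memory is
0-based half-open.

Defaults follow the published protocol where one is stated (1000
bootstrap replicates, 95% identity, 36-nt reads, mismatch costs 2 then
1, >99% expression); remaining defaults (read depth 20, error rate
0.005, divergences 0.4/0.1, 51 decoys, three contigs) are fixed
realistic choices documented above. Test and acceptance runs scale
replicate counts and read depth down (50–300 replicates, depth 6–20) as
problem-size choices; no threshold or condition differs between scales.

## Known limitations

- Single-exon genes only; splice-aware prediction is out of scope.
- The star alignment discards insertions relative to the anchor.
- No E-value statistics for domain hits; the threshold is explicit and
  configurable, with no claim of matching any external search tool.
- Signal peptides are neither trimmed nor predicted.
- Expression calling inherits the multi-mapping ambiguity of repetitive
  loci described above.
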