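# Methods

This note documents the procedures, parameter choices and limitations of
`ryrseq`. The package recomputes the characterization of the CmRyR cDNA
(GenBank JQ799046) on synthetic fixtures whose construction is part of the
package itself, so every claim the tests make is checked against planted
ground truth.

## Synthetic transcript fixtures

The reference transcript mirrors the architecture of the deposited cDNA:
289 nt of 5′UTR, a 15,264-nt ORF (5,087 residues + TGA stop) and 220 nt of
3′UTR. ORF background codons are drawn uniformly from the 61 sense codons,
which guarantees the absence of internal in-frame stops without rejection
sampling and yields a roughly uniform nucleotide background. UTR composition
is scaled exactly to the published values (5′UTR 41% GC, 3′UTR 65% AT) by
fixing base counts before shuffling; forbidden motifs (any `ATG` in the
5′UTR, `TATAAA`, `AATAAA`) are removed by composition-preserving swaps. The
real transcript's 5′UTR is not guaranteed to be ATG-free; the fixture is,
so that the "longest ATG-to-stop ORF" rule is unambiguous by construction.

Peptide features are planted at their published protein coordinates (P-loop
instance at 1088–1095, pore motif `GIRTGGGIGD` at 4939–4948, tandem EF-hand
loops inside 4175–4202 and 4210–4237, six 23-residue hydrophobic stretches
at the TM positions), each encoded with lexicographically smallest codons
for determinism. Codon-aligned nucleotide blocks plant the two
alternative-splice contexts and all eight diagnostic-primer binding sites.
Feature collisions (with the start/stop codon or with each other) are
rejected with an error rather than silently shifted.

The published EF-hand coordinates for CmRyR are reported inconsistently
(4175–4202/4210–4237 in one place, 4183–4194/4285–4296 in another); the
fixtures use the first pair and the discrepancy is simply recorded here.

### Substitution planting

The 35 polymorphisms are planted by constraint solving over the genetic
code: for each affected codon, the 61 sense codons are enumerated and the
lexicographically smallest codon is chosen that (i) carries the tabulated
reference base at the tabulated offset, (ii) translates to the tabulated
reference residue, and (iii) yields the tabulated effect after applying all
substitutions that fall in that codon jointly (the 14326/14327 pair jointly
produces K4776→L). The reference transcript is rewritten at the solved
codons; the variant haplotype then differs from it at exactly the planned
positions.

### Clone libraries

Single-haplotype libraries tile the transcript with n fragments around
evenly spaced cuts; overlap lengths are drawn **without replacement** from
the requested range, so greedy assembly never faces a genuinely ambiguous
tie. Two-haplotype libraries add a second, half-grid-staggered tiling of the
variant haplotype (44 + 45 fragments of ≈450 nt by default), which makes
every substituted position covered by clones of both haplotypes. Fragment
sizing keeps every cross-haplotype overlap region short enough that it
contains at most 5 substitution mismatches — the assembler's default
tolerance; the generator asserts this bound at build time.

### Splice exons

The real exon sequences are published only as a figure, so the fixtures use
synthetic stand-ins satisfying every text-anchored constraint: the mutually
exclusive pair is 99 nt (33 codons, residues 1136–1168), translates without
stops, and differs at exactly 13 of 33 residues with the divergence spread
across the whole exon (no identical run reaches the 20-nt detection anchor,
matching the strongly divergent character of the real pair); the optional
exon is 18 nt in frame (residues 2915–2920). The exon-specific primer sites
(371/373) form the exon 5′ ends, and the junction primers (375 spanning the
flank–flank junction without exon c, 377 spanning the flank–exon junction
with it) are embedded so that the printed primer sequences work verbatim.
Pool compositions follow the published clone counts (exon a in 16/23 pupal
and 11/21 adult-body clones; exon b absent from eggs and adult heads).
Where the study prints only a frequency, counts were chosen once inside the
reported 18–27-clone range; the pupal exon-c pool uses 16/23 (70%) because
a single clone set serves both loci in this design, whereas the published
71% evidently derives from a separate clone set for the second locus.

## Assembly

Greedy maximal-overlap merging: all pairwise suffix–prefix overlaps with at
least `min_overlap` (20 nt) matching positions and at most
`max_overlap_mismatch` (5) mismatches are computed (N matches anything);
the largest overlap is merged repeatedly until one contig remains. Overlap
mismatch counts for every overlap length are obtained at once by per-base
FFT correlation. A tie between maximal overlaps is an error only when the
tied candidates compete for the same clone end — disjoint ties merge in
deterministic lexicographic order, since either order produces the same
contig. Consensus at conflicting columns is taken from the clone whose id
sorts first (clone ids are chosen so the reference haplotype wins); all
observed alleles are kept in the conflict record. Coordinates are 0-based
half-open internally and rendered 1-based in reports. The assembly
parameters are declared defaults; the settings used for the original
clone compilation were never published.

## Annotation

The ORF rule is longest ATG-initiated, stop-terminated frame, leftmost on
ties. Protein mass uses average (not monoisotopic) residue masses via
Biopython and is rounded half-up to integer daltons, the convention of
standard translation tools at this protein size. The TATA-box check is the
literal hexamer `TATAAA`; no positional weight matrix is implied.
Conflict classification groups same-codon sites (`mnv_group`), translates
the jointly mutated codon, and counts each site individually in the
silent/missense tallies; conflicts outside the ORF pass through as
`noncoding`.

## Motifs and TM prediction

Motif patterns support residue letters, `X`, `[..]` alternatives and
`{..}` exclusions; `X` matches the 20 standard residues, never a gap.
EF-hands use a PROSITE-PS00018-style 13-position loop consensus. TM
prediction is a deliberately simple, fully declared hydropathy method —
window 19, Kyte–Doolittle means ≥ 1.6, minimum run 18 — standing in for HMM
predictors; it is validated only on planted fixtures, and no claim is made
that it reproduces TMHMM segment boundaries on real proteins. Domain
intervals (MIR, RIH, SD, SPRY, RyR repeats, RIH-associated) are homology
annotations carried as a validated, overlap-flagged track, not re-detected.

## Comparative analysis

Pairwise identity uses Needleman–Wunsch with BLOSUM62, gap open 10 /
extend 0.5 (conventional declared defaults; a gap of length k costs
10 + 0.5·(k−1)), and the identity denominator is the shorter unaligned
sequence — the published "overall identity" method is unstated, so this
choice is declared. Distances are uncorrected p-distances with pairwise gap
deletion; whether the original tree used corrected distances is unstated,
so tree comparisons are topological. Neighbor joining breaks Q-matrix ties
by the lexicographically smallest label pair (internal nodes inherit the
smallest leaf label of their subtree) and clamps negative branch lengths to
zero, moving the deficit to the sister branch. Bootstrap replicates resample
columns with replacement using replicate-indexed RNG streams derived from
one seed, so supports are reproducible under any evaluation order; an
alignment of identical sequences is returned as a flagged zero-branch star.

In the diagnostic-residue scanner a column qualifies when the focal group
is gap-free and monomorphic for X and some residue Y ≠ X covers all
non-focal sequences up to the exception allowance; the background residue
is the deviation-minimizing Y (alphabetical on ties), a gap in any focal
sequence disqualifies the column, and non-focal gaps count as deviations.

## Splice detection and quantification

Clones are aligned to the reference by edit distance (edlib, infix mode);
runs of non-match operations separated by fewer than 20 matching bases
merge into one variant block, blocks are trimmed to their outermost
disagreement and pure deletions are normalized to their leftmost equivalent
placement. A locus with same-length divergent blocks is a mutually
exclusive pair (labels follow first-observed order: 'a' is the variant of
the first clone encountered, matching the convention that the a/b naming is
historical rather than sequence-derived); a clean presence/absence block
with length divisible by three is an optional exon; frame-breaking indels
are flagged, not classified. Detection assumes clones differ from the
reference only at splice loci — inter-clone point polymorphisms are the
assembly module's concern, and pools mixing both would need the two stages
combined.

Degenerate primers back-translate each residue to the minimal IUPAC codon
covering all of its codons; the back-translated sense sequence is truncated
at its 3′ end to the requested length, and reverse primers are its reverse
complement. This reproduces all fifteen published degenerate primer rows
byte-identically. In-silico PCR requires the primer's 3′-terminal base to
be covered unconditionally (standard specificity heuristic) and tolerates
`max_mismatch` (default 0) violations elsewhere; products pair each forward
site with every downstream reverse site within `max_product` (3,000 nt).

Exon usage reports integer percentages rounded half-up. For a mutually
exclusive pair the first exon is rounded and the partner reported as its
complement, which guarantees the a+b = 100% invariant that independent
rounding would violate (e.g. at counts of 1/8 and 7/8) and reproduces the
published 30%/48% values. Confidence intervals are exact Clopper–Pearson at
95%, added for reusability; the original study reports none.

## Problem sizes and determinism

All randomness flows from explicit integer seeds; identical seeds give
byte-identical FASTA output. The test suite runs the full-scale fixtures
once (15,773-nt transcript; 89-clone two-haplotype library) and uses
reduced sizes for property tests (transcripts of a few hundred nt, trees of
up to 8 taxa, 200 bootstrap replicates on a 12-sequence alignment — the
sampling argument for clade support does not need more at the divergence
used). The acceptance script reruns the full-scale pipeline from scratch in
roughly ten seconds.

## Limitations

The generator does not simulate sequencing error profiles, chromatograms,
RACE artifacts, or quality scores, so passing tests demonstrate the
correctness of the algorithms on clean clone sequences, not robustness to
noisy reads. The assembler handles a single linear contig only (no
circularity, no multi-contig output), as appropriate for a clone-walking
design. Accession-dependent quantities (identity to the *Drosophila*
homologue, the 574,339-Da mass of the deposited translation) require the
GenBank records as input; the functions to compute them
(`global_align`/`percent_identity`, `molecular_mass`) are unit-tested on
synthetic data.
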