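# Methods

This note documents the models implemented in `plegenes`, the parameter
defaults and why they were chosen, what the synthetic-data generator does
and does not emulate, and the package's numerical conventions and known
limitations.

## Coordinate conventions

All genomic intervals are 1-based inclusive (GFF3 convention). Promoter
positions are signed: +1 is the A of the start codon, −1 the base
immediately upstream, and there is no position 0. A 6,000-bp promoter
therefore spans −6000..−1.

## Spliced alignment (GT-AG two-state DP)

A reference cDNA is aligned to genomic DNA, globally in the cDNA and
locally ("fit") in the genomic sequence, under a two-state model:

* **Exon state** — match `+2`, mismatch `−3`, gap `−4` per base.
* **Intron state** — enterable only where the genomic dinucleotide is `GT`
  and closeable only at `AG`, cost `−10` flat (length-independent), with
  intron length constrained to `[min_intron, max_intron]` =
  `[40, 20000]` nt by default.

This is the minimal scoring model that encodes the canonical GT-AG splice
rule; the flat intron penalty mirrors the biology (intron length carries
no signal for this family, whose homologous introns range from 281 bp to
5.4 kb). `max_intron` (20 kb) sits above the largest family intron but
below the ~22 kb intergenic spacing, which stops a single alignment from
bridging two neighbouring genes. `min_intron` 40 nt is below the smallest
real intron (281 nt) but large enough not to misread short deletions as
splicing. An `N` never matches anything (used for masking).

Ties are broken lexicographically toward **fewer introns** (the intron
count is carried as a scaled secondary score component) and then toward
**leftmost donor sites** (the sliding-window donor maximum keeps the
earliest donor among equals). The intron-state maximum over donors is
maintained with one monotone deque per cDNA column, so the full DP is
O(n·m) despite the length window.

Two modes share this scoring:

* `full_dp` — the exact recursion over the whole genomic sequence; the
  global optimum by construction. It is the oracle for the fast mode and is
  practical up to a few kb.
* `anchored` (default) — exact 15-mer seeding, maximal co-diagonal run
  merging, collinear chaining (quadratic DP over anchors with gap-cost
  estimates; chain links may not span more than `max_intron`), then the
  same exact DP inside each inter-anchor window (anchors padded back by up
  to 8 bases so junctions are re-derived by DP, not trusted to seeding).
  Head/tail cDNA overhangs get free-ended windows sized
  `2·overhang + 50` nt, extended by `max_intron` when the overhang is long
  enough (≥ k) to hide a whole missed exon. On instances where the optimal
  path passes through the anchor chain — which the oracle suite checks on
  planted genes ≤ 3 kb — anchored mode reproduces the full-DP score and
  intervals exactly.

`annotate_contig` iterates: align, record the model, mask its span with
`N`, realign; it stops when the best remaining score falls below 50% of
the first gene's score. Within one gene family all true copies score
alike (mismatches only at diagnostic codons), so a 50% cutoff separates
real genes from spurious partial hits. On anchored mode a random contig
yields no seeds and hence an empty result; `full_dp` on random sequence
can in principle assemble a weak positive-scoring chain of chance matches,
which is why the fit-alignment oracle is not used for decoy scanning.

A "no gene" outcome (score ≤ 0 or no anchors) is an empty `GeneModel`,
not an exception.

## Inverted-repeat detection

An inverted-repeat pair in lock-step extension lives on one anti-diagonal
`a = start(copy1) + end(copy2)` of the sequence-versus-complement
comparison. Reported pairs are the **maximal scoring subsequences**
(Ruzzo–Tompa) of each anti-diagonal's match profile with match `+1` and
mismatch `−(1−r)/r`, where `r` is `max_mismatch_rate` (default 0.02). This
penalty makes a mismatch density of exactly `r` score-neutral: runs
tolerate interior mismatches up to the budget but never extend through
low-identity flanks, so an exactly planted repeat is reported at exactly
its planted length. At `r = 0` runs are simply the clean match blocks.
Overlapping (hairpin-contiguous) copies are excluded: enumeration stops at
the anti-diagonal midpoint, so `end(copy1) < start(copy2)` strictly.

One consequence worth knowing: a mismatch within ~`(1−r)/r` bases
(≈ 49 at the default rate) of a repeat end is trimmed off rather than
bridged, shortening the reported run — score-maximality prefers the clean
core. Mismatches deeper inside are bridged.

The fast finder visits only anti-diagonals hit by an exact k-mer seed
(k = 20, lowered automatically if `min_len`/`r` cannot guarantee a clean
20-mer in every reportable run; below k = 8 it falls back to scanning all
anti-diagonals). The brute-force oracle enumerates every anti-diagonal of
sequences ≤ 2 kb. Both share the run definition, so their equivalence
(checked on 100 random planted instances) validates the seeding logic.

Separation is reported as `start(copy2) − end(copy1)` on the signed
promoter scale — for copies at −5132..−4413 and −802..−83 this gives
3611, reproducing the printed arithmetic of the source coordinates.

## Clone assembly

* **Vector trimming**: the vector (both orientations) is located by edlib
  infix alignment; hits under 95% identity leave the clone untouched with
  a warning flag. The bundled vector is a *synthetic*, fixed-seed 8,128-nt
  stand-in of the published vector length; users may substitute the real
  vector FASTA.
* **Overlap detection**: shared 31-mers vote for a diagonal offset per
  clone pair (both orientations); the implied suffix/prefix segments are
  verified by edlib global alignment, and overlaps must reach 2 kb at 99%
  identity by default. The defaults follow the reported upstream-overlap
  homology of real clone pairs (99%) with the 2-kb floor leaving margin
  under the real ≥ 6-kb overlaps. Identity is identical columns over
  alignment columns; gaps are the inserted/deleted columns.
* **Ordering**: the overlap graph must decompose into simple paths —
  branching or cyclic components raise an error naming the clones rather
  than guessing a genome order. Each path is linearized from an end;
  orientations propagate along edges, offsets come from clone lengths
  minus overlap lengths, and the frame is flipped if most clones ended up
  reverse-complemented (so the reported direction is stable under
  flipping any single clone). Genes from different clones that land within
  5 kb of the same frame position under the same name are merged, giving
  the cluster's gene order. On mutation-free synthetic data the
  reconstructed cluster span equals the source locus length exactly.

## Isoform classification

Proteins are translated with the standard code; a CDS must be a whole
number of codons with one terminal stop (internal stops are errors naming
the codon; a non-ATG start is flagged, not fatal). The signal peptide is
defined positionally as residues 1–18 (the family's fixed length — no de
novo prediction), and the diagnostic profile reads 25 fixed positions of
the mature peptide (full-length residue = mature + 18). Classification is
nearest-reference by mismatch count over those 25 positions, with ties
resolved by table column order; any nonzero minimum is reported as
"novel". Ambiguous codons translate to `X`, which never matches a
reference residue — unknowns cannot fake an identity. Percent identity
(for full-protein comparisons) is global alignment (BLOSUM62, gap open
−11/extend −1) identities over alignment columns.

## In-silico PCR and pooled screening

A primer site is an exact substring match by default. With
`max_mismatch > 0`, mismatches are allowed anywhere except the 3'-terminal
5 nt (`three_prime_exact`), since extension requires a matched 3' end.
Products are all forward/reverse site combinations facing each other
within `max_product` (10 kb default), on either strand; a well is *called*
positive when any panel pair yields a product within ±5% of one of its
expected sizes — a gel-calling window, since gels are not base-exact.
Annealing temperature is metadata only; no thermodynamics is simulated.

The three-step screen pools each plate (step 1), then each positive plate's
24 columns of 16 wells (step 2, following the bench geometry of 24 tubes
of 16 colonies), then tests the 16 wells of each positive column singly
(step 3). `pcr_count` counts templates assayed — `n_plates + 24·(positive
plates) + 16·(positive pools)` — the quantity pooling is designed to keep
far below one reaction per well (220 versus 7,680 for the default 20-plate
demonstration). Whether step 2 pools rows or columns is configurable
geometry; columns-of-16 is the default reading.

## Synthetic data: what it emulates, and what it does not

The generator plants, with exact bookkeeping (`GroundTruth`):

* genes with the bundled per-isoform exon/intron sizes (14 exons,
  13 introns; identical exon sizes across isoforms, intron sizes varying
  per gene), introns forced to `GT..AG`;
* one shared random-composition coding sequence per locus, overlaid with a
  fixed 18-residue signal peptide, the C-terminal HAEL ER-retention
  signal, and each gene's diagnostic-residue column (codons are only
  touched where the residue differs, so isoforms stay as similar as their
  profiles imply — and PLE-1 stays nucleotide-identical to the γ-PLE
  reference);
* a 6,000-bp promoter per gene with a planted 720-bp reverse-complement
  pair at −5132..−4413 / −802..−83 (flanking bases are adjusted so the
  planted pair is not extendable by chance, keeping its detected length
  exact);
* primer cassettes (forward primer + filler + reverse-complemented
  reverse primer) inside introns, greedily placed where they fit, for
  pairs 1, 2, 4, 5 and 6; two-product pairs alternate their printed sizes
  along the gene order. Pairs 3, 7 and 8 are planted nowhere, so panel
  verification rejects them;
* ~22-kb random intergenic spacers; BAC clones as locus windows with the
  vector stand-in prepended; 384-well plates whose decoy wells are
  guaranteed free of any primer site.

Point mutations (uniform substitutions, rate ≤ 5%) spare the GT/AG
dinucleotides, start/stop codons and primer 3' ends, and in-frame
substitutions avoid creating stop codons, so mutated loci remain
annotatable and translatable ground truth. Base composition is uniform
i.i.d. ACGT away from forced motifs.

Not emulated: sequencing error profiles or assembly artefacts (clones are
finished sequences, so clone–clone overlaps are exact rather than the
~99%-with-gaps seen in real assemblies), isochore/GC structure, TSS/UTRs
(the "cDNA" is the CDS), non-canonical splice sites, and PCR
thermodynamics. Passing round-trip tests therefore demonstrates the
correctness of the algorithms on structurally faithful input, not
robustness to assembly noise — the mutation-rate parameter probes
substitution noise only.

Default seed 1063 everywhere a seed is unspecified; identical spec + seed
gives byte-identical output (per-component RNG streams are derived from
the seed plus a role label, so changing one component does not reshuffle
the others).

## Problem sizes used in the tests

The suite annotates full-size genes (~40-kb units) and multi-gene loci
(~155 kb), orders five ~100–160-kb clones, and screens 20-plate (7,680
well) libraries; oracle suites run 100 spliced-alignment instances ≤ 3 kb
and 100 inverted-repeat instances ≤ 2 kb. The boundary-robustness check
fixes 20 simulated genes (4 isoforms × 5 seeds) at 0.5% substitution rate
and requires ≥ 19 exact recoveries — a deterministic, seeded stand-in for
a ≥ 95% recovery rate.

## Known limitations and open choices

* The printed second repeat copy interval (−802/−82) spans 721 nt against
  the stated 720-nt length; the generator plants both copies at exactly
  720 nt (copy 2 at −802..−83). Internal consistency was preferred over
  reproducing a likely off-by-one.
* Whether the 6,000-bp regulatory region is measured from the ATG or a
  transcription start site is not specified; the ATG is assumed.
* Summing the bundled exon and intron sizes for PLE-1 gives a 33,767-bp
  gene body; gene-span lengths are reported but not asserted against
  externally quoted totals, whose span convention is unknown.
* `full_dp` fit alignment on unrelated random sequence can return weak
  positive scores (chance chains of short matches bridged by cheap flat
  introns); decoy rejection is a property of the anchored default.
* Full-sequence identity of real isoforms can only be checked against the
  deposited accessions, which are deliberately not bundled;
  `pairwise_identity` and `identity_matrix` accept user-supplied FASTA for
  that comparison.
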