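# Methods

This note documents the models, rules and numerical choices behind
`scisote`, and what the synthetic data does and does not emulate.

## Read model and library processing

A read is `5' primer + cell barcode (16 nt) + UMI (10 nt) + cDNA +
polyA + 3' primer`, in either orientation. Full-length identification
scans for each primer near the appropriate read end (Hamming distance ≤ 2
by default, configurable); both primers → FL, one → non-FL, none →
unknown, and the three statuses partition the read set. The polyA tail
(a terminal run of ≥ 10 A's) is trimmed from the insert; a genuine
transcript-terminal A adjacent to the tail is indistinguishable from the
tail and is trimmed with it — a universal ambiguity of polyA-primed
protocols with no effect on any downstream statistic used here.

Barcode correction is whitelist-based at Hamming distance ≤ 1 with a
unique-neighbour requirement: an exact member passes through, a raw
barcode with exactly one whitelist member at distance 1 is corrected to
it, anything else is dropped. Distance 1 is the right radius for
HiFi-grade accuracy: with per-base error well below 1%, two errors in a
16-mer are rare, and distance-2 correction against realistic whitelists
is frequently ambiguous. UMI collapse is exact-match for the same reason
— distinct molecules are far more likely than a UMI sequencing error —
so molecules are distinct (barcode, UMI, feature) triples and counts per
(cell, feature) are distinct-UMI counts.

## Isoform collapse and classification

Primary spliced alignments are grouped by (chromosome, strand). Multi-exon
reads merge into one isoform iff their intron chains are identical and
both terminal ends lie within 50 nt of the cluster seed (the leftmost read
of the chain bucket); 50 nt absorbs polyA-priming and TSS jitter without
merging distinct termini. Using the seed's termini as the isoform's
coordinates makes collapse idempotent: seeds are pairwise farther apart
than the tolerance, so re-collapsing the collapsed set is a no-op. A read
whose chain is a 3'-anchored strict suffix of a longer chain is *not*
merged into it — 5'-degraded molecules keep their own isoform, which is
what preserves the 5'-truncation signal downstream. Mono-exon reads merge
by reciprocal overlap ≥ 0.5 with the cluster seed. Isoform ids are
PB-style `PB.<gene cluster>.<n>`, clusters being connected components of
span overlap per strand.

Structural classes against reference models: FSM (chain equals a
reference chain), ISM (consecutive sub-chain), NIC (novel chain, all
splice sites known), NNC (≥ 1 novel site), other (antisense, intergenic,
or unmatched mono-exon). Mono-exon isoforms overlapping a reference exon
are FSM when the matching transcript is itself mono-exon, else ISM, with
FSM preferred when both match. Artifact filtering keeps FSM/ISM/NIC/NNC
isoforms whose every junction is spanned by at least one read with ≥ 10
aligned nt on both sides; the full rule set of reference-based QC tools is
deliberately out of scope.

CAGE support: an isoform's 5'-terminal genomic position within 200 bp of a
same-strand peak (distance 0 inside the peak). Strand-awareness is a
design choice: a TSS peak on the opposite strand is not evidence for this
transcript's start.

## ORF integrity typing

The longest-ORF finder scans the three forward frames of the 5'→3'
transcript (orientation is resolved upstream). Candidates per stop-free
stretch of a frame: first-ATG→stop (complete), frame-start→stop with no
ATG (5'-open; only when the stretch is anchored at the sequence start),
first-ATG→sequence-end with no stop (3'-open), frame-start→sequence-end
with neither (open both ends). The longest candidate wins, ties broken by
leftmost start then lowest frame; below 100 aa (the conventional minimum)
the isoform is typed `others`. Flags map to types: start+stop → complete;
start only → 3'-partial; stop only → 5'-partial; neither → internal.

## TE locus assignment

Uniquely aligned is pinned as: primary, not secondary, no supplementary
segment, mapq ≥ 30 — "unique" has no universal definition, and this
matches common spliced-aligner practice. Overlap with a locus is
the total exon-block intersection — spliced cDNA must not claim intronic
TE bases. Candidate loci are those containing the alignment's genomic
start or end position (span endpoints of the primary alignment); among
candidates the longest overlap wins, ties broken by locus start then
locus id, so assignment is a deterministic partial function. Strand is
ignored: antisense TE transcription is real and the rmsk strand refers to
the repeat consensus. Removing the endpoint rule can only grow the
assigned set (verified as a property test).

Reads with supplementary alignments are routed exclusively to chimera
detection: a split read links a TE locus (same rules, applied per
segment) to a different segment overlapping protein-coding exons by
≥ 50 nt; links are UMI-deduplicated and aggregated to a TE-locus × gene
table.

## Matrices and normalization

Counts are sparse cells × features integers; total matrix sum equals the
number of distinct molecules of that feature kind (asserted, exact).
CPM/10 divides each cell's counts by that cell's total molecules *of the
matrix's kind* and multiplies by 100,000; the "mapped reads" denominator
is taken at the UMI level, consistent with UMI-based matrices. Isoform
matrices drop features detected in fewer than 5 cells. Spike-in
evaluation correlates log10(x+1) of known copies against observed UMIs
per spike-in gene (Pearson; with < 3 distinct abundance levels the
correlation is flagged undefined), and tabulates a truth × assigned
isoform confusion matrix at the molecule level.

## Stage-level statistics

*Stage-specific selection.* For each adjacent stage pair: log₂ fold
change on pseudocount-1 stage means of CPM/10, and a two-sided Wilcoxon
rank-sum test on per-cell CPM/10. Selection requires |logFC| > 1 and
p < 0.01 for at least one pair. The rank-sum + mean-logFC pairing is a
deliberate re-definition of the usual negative-binomial differential
test: the selection contract (thresholds, peak-stage clustering) is
preserved while avoiding an NB fitting machinery this package does not
otherwise need. Selected features are grouped by arg-max stage of their
mean expression; the number of clusters is the number of stages with at
least one peaking feature, so the "6 clusters for genes, 5 for TEs"
pattern of real data is an outcome, not a parameter.

*Isoform switching.* Isoform fraction IF = isoform UMIs / gene UMIs,
pooled per stage; dIF = IF₂ − IF₁. Isoform p comes from a two-sided
Fisher exact test of the pooled 2×2 table (isoform vs other-isoform UMIs
across the pair); gene p is the Bonferroni-adjusted minimum isoform p.
Both sets are BH-adjusted; a switch requires |dIF| ≥ 0.1, isoform
q < 0.05 and gene q < 0.01. Genes with < 10 pooled UMIs in either stage
are skipped. Swapping the stage order negates dIF and leaves q-values
unchanged (property-tested).

*TE–gene adjacency.* TE loci with mean UMI count > 5 across cells are
correlated (Pearson on CPM/10) with genes by distance between closest
interval edges: < 10 kb is adjacent, > 1 Mb non-adjacent, in between
excluded. Pairs on different chromosomes are treated as infinitely
distant, hence non-adjacent — this is also how the toy genome realises
">1 Mb" loci (a dedicated gene-free contig) within contigs of a few
hundred kb.

## The synthetic data generator

The generator emulates what the analysis assumes: stage-structured
Poisson molecule counts per (cell, feature); per-gene isoform usage
(Dirichlet, with a dominant major isoform); planted stage-specific
features (default 8-fold peak in one stage); planted switches (major
isoform fractions 0.9 → 0.1 across a boundary); per-stage 3'/5'
truncation probabilities; TE-locus transcripts as sub-intervals of their
locus; TE–gene chimeras (TE segment 5' of a full gene transcript, with
split truth alignments); spike-ins at fixed copies per cell spanning
two-fold dilution levels; a 0.2 PCR-duplicate rate (flat — per-molecule
amplification bias is not modelled); and substitution-only sequencing
errors, default 0 (HiFi-grade consensus accuracy), configurable.

Two sequence-composition choices make truth unambiguous rather than
merely likely: 5' UTRs are generated A-free, so no spurious upstream ATG
exists, and CDS codons are drawn from the 60 non-stop, non-ATG codons,
so the annotated start is the only in-frame ATG and the annotated stop
the only in-frame stop. A planted truncation therefore maps
deterministically to its ORF-integrity class, which is what lets
classification be scored against truth at the 99% level. Alternative
isoforms vary by skipping codon-aligned internal CDS exons (kept ≥ 130
codons so every variant stays above the ORF-length floor), skipping UTR
exons, or starting at a later exon (the 5'-shorter suffix case).

Truth alignments are emitted directly in SAM, so no aligner runs in the
loop; the pipeline equally consumes a real aligner's spliced SAM. What
passing tests on this generator shows is that the *rules* are implemented
correctly and recover planted structure under the stated noise; it does
not show robustness to alignment artifacts, concatemeric reads, indels,
degraded RNA beyond the modelled truncations, or mapping ambiguity among
near-identical TE copies — multi-mapping rescue across TE copies is
explicitly out of scope (assignment requires unique alignments).

## Problem sizes and numerics

The bundled verification study runs at desk scale, chosen to make every
statistic well-powered while keeping the whole suite in seconds-to-
minutes: toy genomes of 2–4 contigs (≲ 500 kb each), 12–20 genes with 1–6
isoforms, 30–40 TE loci, 2–8 stages × 4–20 cells, libraries of 10³–10⁴
molecules; oracle-equivalence checks use 5,000 random reads × 500 loci
(TE assignment), 20 × ~100-read instances (collapse), and 500 random
sequences (ORF finder); stage-specific recovery uses 2,000 features (200
planted) over 8 × 20 cells, and switch null calibration 10 seeds × 100
genes. All randomness flows from explicit integer seeds; reruns are
byte-identical. Results at full experimental scale (tens of thousands of
isoforms, thousands of stage-specific TE loci) require deep long-read
data and are out of reach at these sizes by design; the package verifies
the method's correctness properties instead.

## Known limitations

- No concatemer splitting: the simulator emits one cDNA per read, and the
  processor assumes demultiplexed full-length reads.
- Barcode correction radius and UMI collapse rule are pinned (distance 1,
  exact match); heavily error-prone platforms would need both relaxed.
- The DE and switch statistics are re-definitions with the same selection
  contracts as the conventional external tools, not re-implementations of
  those tools' models.
- CAGE support is strand-aware by choice; annotation sets with unstranded
  peaks would need the check relaxed.
- Cross-chromosome TE–gene pairs are non-adjacent by definition; no
  attempt is made to model trans-acting regulation.
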