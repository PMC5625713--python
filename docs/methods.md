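# Methods

## The detection model

A hyper-edited RNA molecule carries many A→G changes relative to the genome.
A mismatch-limited gapless aligner with budget `max_mm` (default 3) rejects
any read with ≥ 4 mismatches, which is exactly the regime dense editing
creates — that rejection is the premise of the screen, not a failure. The
rescue collapses the edited base pair: substituting A with G in both the
read and the reference removes every A→G difference (and, unavoidably, every
G→A difference) from the comparison space while leaving all other mismatch
types visible. A read that realigns cleanly in the collapsed alphabet is
placed, its native-alphabet mismatches are recovered from the placement, and
it is called hyper-edited when its candidate-type mismatches form a dense
cluster.

**Threshold.** The calling rule requires the candidate count to reach 5% of
the read length. The default is `ceil(0.05·L)` — 4 sites for 80-bp reads,
the worked value of the rule — with a strict variant (`floor(0.05·L)+1`,
i.e. 5 sites at 80 bp) available via `strict=True`. Reads shorter than 20 bp
are rejected.

**Strand conventions.** The aligner searches both strands of the forward
reference; the transform is applied to the read copy being compared after
strand resolution. A minus-strand placement under scheme X→Y therefore masks
mismatches reading complement(X)→complement(Y) on the read's own strand, and
detections are typed on the read strand. Consequences: a stranded library
(reads = transcript strand) yields virtually only A→G clusters, while an
unstranded library splits the signal roughly equally between A→G and T→C;
site collapsing in unstranded mode reports T→C clusters as A→G on the
inferred opposite strand and merges them with plus-strand support by genomic
position.

**Clean-read filters.** Three reconstructed filters reject artifact
clusters, all exposed in `DetectConfig`: (a) non-candidate mismatches at the
placement ≤ `max(1, floor(0.025·L))` (also the transformed-space alignment
budget); (b) the candidate sites must not all lie within the first or last
10% of the read (junction and end-of-read error pileups); (c) mean Phred
quality over candidate sites ≥ 25 when qualities are informative (constant
quality strings are uninformative and skipped). Ambiguous placements
(tie for best) are discarded.

**Cross-screen arbitration.** The 12 ordered mismatch-type screens are run
with identical parameters. A read can occasionally be "rescued" under more
than one screen: a hyper-edited read from a repeat also realigns at a
paralogous copy, where its edits line up with conserved adenosines and are
masked again, planting spurious sites. `run_all_types` therefore keeps, per
read, only the detection with the fewest total native mismatches (ties
broken by fewest non-candidate mismatches, then a fixed type order). The
true placement explains the read with fewer mismatches than any paralog in
all but pathological cases; the residual risk — a paralog whose visible
differences from the origin fall below the non-candidate budget *and* whose
total is strictly smaller — is the screen's main known failure mode and is
rare (well under 1% of detections in the shipped study conditions, zero in
the noiseless limit where the origin placement is exact).

**No SNP database.** The screen uses no prior variant knowledge. Homozygous
SNPs are absorbed either by the initial pass's mismatch budget (the read
still maps, so it never reaches the screen) or by the non-candidate cap.

## Quantification

`normalized_signal = events × 10⁶ / mapped_bases`. Mapped bases include the
rescued hyper-edited reads' bases — they are mapped after rescue; at
realistic editing abundances the choice moves the denominator by well under
1% either way. Specificity is the fraction of unique cluster sites of type
A→G (plus T→C when unstranded) among all 12 types; G→A clusters (C→T added
when unstranded), found with identical parameters, give the false-positive
signal. Replicates aggregate as mean ± standard error of the normalized
signal.

## Motif profiles

Counts of the −1 and +1 neighbor bases are tallied on the edited strand over
unique A→G sites (sites at sequence boundaries are skipped; profiles with
< 50 usable sites are flagged low-confidence). The default background is the
unedited adenosines inside the detected cluster spans, which controls for
the local composition of edited regions; a genome-wide background is
available (`background="genome"`). Enrichment is the ratio of foreground to
background base fractions per position; entries with zero background are
NaN. Species profiles are compared as 8-dimensional enrichment vectors under
average-linkage hierarchical clustering with Euclidean distance; group ids
are renumbered by first appearance in input order, which makes degenerate
ties deterministic under label order.

## dsRNA structure search

Local alignment uses Smith–Waterman with the scoring regime of the classic
pairwise-BLAST settings for reward +2: match +2, mismatch −3, gap open 5,
gap extend 2, no low-complexity filter. The implementation is Biopython's
`PairwiseAligner` (exact affine-gap DP; the `word_size` field documents the
original seeding granularity but exact DP needs no seeding, and the test
suite checks the scores against an independent Gotoh dynamic program).
Identity is matches / aligned columns with gaps counted as mismatches;
coverage is the ungapped query-span fraction of the cluster length.

A cluster's partner search takes the ±2 kb flanking region (truncated at
sequence ends), reverse-complements it, and requires identity ≥ 0.65 with
coverage ≥ 0.80. The cluster's own locus stays in the subject because a
palindromic cluster legitimately partners with itself in reverse
orientation. The same-strand control runs the identical search without
reverse-complementing, with the query's own span masked by N (N matches
nothing) and residual self-overlapping partners (> 50%) discarded. The
genomic dsRNA potential samples `n` 50-bp windows (length-weighted across
chromosomes; windows with > 10% N resampled) and scores a window when a
reverse-oriented alignment of ≥ 40 columns reaches ≥ 95% identity; the
threshold is applied inclusively (≥), which differs from a strict reading
(>) only for alignments at exactly the boundary. Editing enrichment is the
site density inside the union of reverse-hit query+partner intervals over
the density outside (NaN without sites, +inf when no site falls outside).

## The synthetic-data generator

The generator emulates the statistical structure the screen assumes; its
defaults are the study conditions of the shipped tests.

- **Genome** (default 50 kb, GC 0.42, single sequence): random background
  plus planted repeat families. Defaults: an inverted-pairing family (8
  copies of a 300-bp consensus at 8% divergence, all placed as
  reverse-complement pairs within ≤ 2 kb), a palindromic self-folding family
  (3 copies, 6% divergence), and dispersed non-pairing fragments (5 copies,
  12% divergence). Copies carry exactly `round(divergence·L)` substitutions,
  which also guarantees the 1 − 2·divergence reverse-complement
  self-similarity bound for palindromic copies. dsRNA-forming spans are the
  union of inverted-pair members plus the intervening sequence, and
  palindromic copies.
- **Transcripts** tile the whole genome in 1–3-kb pieces on random strands;
  a configurable fraction contributes coding intervals. Real transcriptomes
  have highly non-uniform expression and splicing; neither is modeled, so
  coverage here is far more even than in real data.
- **Editing** is two-level, mirroring ADAR's site-consistent preference.
  Once per genome each span adenosine is marked *editable* with probability
  0.9 when its +1 base matches the planted motif group (`downstream_G` or
  `downstream_A`), 0.25 otherwise, × 0.3 when the −1 base is G. A sampled
  molecule overlapping a span is hyper-edited with probability
  `p_transcript_edited` (default 0.8, reflecting that most hyper-edited loci
  express few unedited molecules), and each editable A in it is deaminated
  at `edit_rate_per_A / editable_fraction`, keeping `edit_rate_per_A`
  (default 0.3) the marginal per-A rate — that value makes an edited 80-bp
  read carry ~6–7 sites, comfortably above the 4-site threshold and
  consistent with a ≥ 10% edited-base floor for the duplex. The two-level
  structure matters: with a purely per-molecule rate model, deep coverage
  saturates every span adenosine into a "unique site" and the motif washes
  out of site-level profiles.
- **SNPs** are homozygous: the reads are sampled from a donor sequence that
  differs from the reference at `snp_rate` positions, so the variant appears
  in every read of a locus (unlike editing, which is per-molecule).
  Sequencing errors are uniform substitutions applied after editing;
  qualities are constant Q30; indels are not modeled. Unstranded mode flips
  read orientation with probability 0.5 after editing.
- The ADAR-null control runs the identical process with editing forced off.

What passing tests show — and don't. Perfect noiseless recovery and ~100%
specificity on this generator demonstrate the mechanics of the screen
(transform, placement, recovery, filters, strand inference) under the
structural assumptions above; they do not bound performance on real data,
where coverage heterogeneity, indels, splicing, quality artifacts, and
repeat families far larger and older than the planted ones all operate.

## Problem sizes and numerics

The shipped study conditions are desk-scale: 50-kb genomes with 20,000
80-bp reads for the recovery/specificity suites, 15 kb × 5,000 reads per
synthetic species for the motif suite (eight species, four per planted
group), 40 kb × 10,000 reads for the dsRNA linkage suite, and a few hundred
windows for the potential scan. All randomness flows from explicit integer
seeds through `numpy.random.default_rng`; identical seeds give byte-identical
genomes, reads, truth tables, and pipeline outputs. k-mer seeding uses k=16
with `max_mm+1` non-overlapping tiles (pigeonhole guarantee); reads shorter
than `(max_mm+1)·k` fall back to fewer tiles, weakening the guarantee —
irrelevant at the default 80 bp.

## Known limitations

- Gapless alignment only: indels (rare in the substitution-dominated
  regime the screen targets) shift placements and are not modeled.
- The paralog-masking failure mode described under arbitration.
- The editing-level analysis counts covering reads from the two alignment
  passes only; no duplicate-fragment removal is attempted.
- The dsRNA potential reports only the best-scoring local alignment per
  window; a window whose optimal alignment fails the identity rule but that
  contains a shorter qualifying sub-alignment is scored conservatively.
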