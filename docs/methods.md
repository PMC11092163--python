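# Methods

## Signal model and coordinate conventions

A Rend-seq sample is four sparse end-count vectors over one chromosome: 5′
and 3′ read termini per strand, per nucleotide. Coordinates are 1-based
inclusive everywhere (wig/GFF3 convention); the only 0-based interchange is
BED ingestion of external coordinate sets, converted on read. Counts are
stored as floats so depth-normalised wig files pass through unchanged;
zero-valued wig records are dropped on read, and density computations treat
absent positions as zeros. On the reverse strand, "downstream" always means
decreasing genomic coordinate; the simulator places each terminus count on
the terminus nucleotide itself on both strands (wig producers differ here —
tracks from other pipelines should be checked against a known locus).

## Peak calling

For a candidate position the null window is the `window` positions
immediately downstream of it in transcription direction (5′ tracks /
start sites) or upstream (3′ tracks / stop sites), with the focal position
excluded and absent positions counted as zeros. Two windows are scored.

| parameter | default | meaning |
|---|---|---|
| `z_start` | 7 | 50-bp z threshold calling start sites |
| `z_stop` | 6 | 50-bp z threshold calling stop sites (3′ ends smear over up to ~4 nt, so their enrichment is weaker) |
| `z_small` | 5 | flag-band floor, reached in either the 50-bp or the 25-bp window |
| `z_ii` | 7 | flag-band ceiling; flagged peaks need verification |
| `window_large` / `window_small` | 50 / 25 nt | the 25-bp window exists because a large window lets a big neighbouring peak inflate the mean and mask the minor of two close peaks |
| `min_peak_value` | 3 reads | absolute floor; without one a 1-read spike in an empty window would be callable. z-scores are scale-free, an absolute floor is the only guard at very low depth |
| `sd_floor` | 1 read | on a flat-zero window σ = 0 and z is undefined; flooring at one read makes z degrade to the excess read count — conservative and scale-respecting |
| `prune_radius` | 5 nt | within ±5 bp only the highest same-kind peak survives |

Numerical choices: population (ddof = 0) standard deviation — at n = 25/50
the sample/population difference is negligible and the population form is
the simpler contract (a config switch `population_sd` flips it, and
`exclude_focal` re-includes the focal position for sensitivity analyses).
Pruning is greedy by descending value, so every survivor dominates the
peaks it displaced and the operation is idempotent; value ties break toward
the transcript-extending coordinate (most upstream for starts, most
downstream for stops, mirrored on the reverse strand), which is
deterministic and never shortens an annotation. Positions whose truncated
window at a chromosome end holds fewer than half the requested positions
are skipped and logged. A peak is called outright only by the large
window; the small window can only flag.

## Verification

Flagged peaks (z between `z_small` and the calling threshold) survive only
with corroboration:

* **cross-sample** — a flagged terminus present (as any peak) in more than
  `unique_N` samples (default 1) is verified; one confined to at most
  `unique_N` samples is rejected. Matching is exact-coordinate by default
  (`cross_sample_tolerance = 0`): per-sample pruning has already collapsed
  ±5 bp clusters.
* **external coordinates** — terminus-level sets (Cappable-seq-like TSS,
  Term-seq-like 3′ ends) verify within ±`search_distance` (5 bp);
  coarse operon-boundary sets (tiling-array-like) within
  ±`search_distance_0` (30 bp). Sets are kind- and strand-matched.

External verification runs *before* the cross-sample filter, so orthogonal
evidence can rescue a flagged peak seen in only one sample; the
cross-sample step then rejects whatever flagged singletons remain. Evidence
only ever changes status, never positions or z-scores, and no flagged peak
survives to the end of the pipeline.

**FDR filter.** For each peak, the read sum `S` of the 50-bp window centred
on it (peak included; the window sum is taken on the peak's own end track)
is dropped uniformly on a hypothetical gene of `L = fdr_window` positions.
Under that multinomial null a position's count has mean `S/L` and variance
`S·(1/L)(1−1/L)`; the peak is discarded below
`T = S/L + fdr_z·sqrt(S·(1/L)(1−1/L))` with `fdr_z = 2`. The analytic form
is the default (deterministic, seed-free); a seeded Monte-Carlo mode pools
squared deviations about the exact mean `S/L` across draws and exists as an
independent cross-check — averaging per-draw standard deviations instead
would be biased low (Jensen).

## Operons, transcripts, isoforms

Read density between coordinates `a ≤ b` is the count of non-zero 5′ plus
non-zero 3′ values on the strand divided by `2(b−a+1)` (each position
carries two values). Scanning peaks in transcription order on the guide
sample (the `--guide` flag; defaulting to the highest-density sample, which
is logged), an operon opens at a start whose density to the next stop is
strictly above `operon_cutoff` (0.8), extends while the density from its
last stop to the next peak stays at or above the cutoff (boundaries exactly
at the cutoff extend — mirroring the asymmetric above/below phrasing of the
rule), and closes at the last stop before the density break. A start
absorbed into an extending operon never re-opens a nested operon. Spans are
disjoint per strand. Externally supplied operon coordinates bypass
segmentation but feed the same assignment logic.

Peaks are assigned to the same-strand operon containing them. Unassigned
starts pair with the nearest unassigned stop downstream when no operon lies
in the interval ("orphan pairs", the boundaries of one low-expressed
transcript); remaining orphans attach to the nearest operon downstream
(starts) or upstream (stops).

Within an operon, every transcription-ordered (start, stop) pair whose
interval density reaches `density_threshold` (0.20) becomes a transcript —
the check is applied to *every* pair, the conservative reading. Transcripts
sharing a 5′ or 3′ terminus are isoforms; groups are the transitive closure
of that relation. A surviving peak appearing in no transcript is completed
against the old annotation into a *hybrid*: the borrowed terminus is the
nearest transcription-direction edge among same-strand overlapping records
(ties to the longest record), the single-nucleotide coordinate is named in
a Note attribute, and the row carries phase 0 in GFF3 output. Because phase
is ordinarily reserved for CDS rows, `--strict-gff3` keeps the phase column
"." and leaves the mark in the Note only.

## Feature transfer and sRNA classes

Same-strand overlap against the prior annotation decides labels (container
record types — operon, region, gene, source — are ignored so GenBank-style
gene+CDS pairs do not trigger the multiple-class rule; antisense overlap
counts as no overlap):

* contains ≥ 1 whole CDS → `CDS`, names inherited, then tiled into
  5′UTR / CDS(s) / 3′UTR (zero-length UTRs omitted; intercistronic gaps stay
  inside the CDS block; a CDS reaching beyond the transcript is demoted to
  `transcript` with a warning);
* exactly one overlapped feature class → that class (this deliberately
  labels transcripts covering only the 3′ portion of an ORF as CDS);
* several distinct classes → `transcript`; no overlap → `novel_transcript`.

Non-coding transcripts get one origin class: `putative_srna` (covers an
annotated start codon but ends before that gene's stop codon — possibly an
unannotated small peptide), `five_utr_derived` / `three_utr_derived`
(shares an mRNA's 5′/3′ terminus while staying clear of the coding
region's far boundary), `intergenic` / `intragenic` (inside an operon,
between/within coding genes — an interpretation of the tiling-array
vocabulary, flagged as such), or `independent_with(out)_isoform`.
rRNA/tRNA/tmRNA overlaps keep their structural labels and are never
reclassified as sRNA.

## Differential termini

A terminus surviving the full pipeline in one condition with no same-kind
peak within ±2 nt in the other is reported — but only when the 50-nt
neighbourhood centred on it reaches a read density of 0.20 in **both**
samples, so uneven library depth cannot masquerade as a processing event.
The neighbourhood size is this package's choice (the pipeline's canonical
window); the comparison is presence/absence, not fold change.

## Synthetic data

The generator plants transcripts with uniform Poisson fragmentation
background on both end tracks of their strand (`body_density`, default
0.5 reads/nt), single-nucleotide terminus spikes of mean
`enrichment × body_density` (default 50×) on the matching track, and
genome-wide Poisson noise (0.02 reads/nt) on all four tracks. An option
widens stop spikes over up to 4 nt with ≥ 50 % of the mass on the summit,
reflecting the empirically broader 3′ boundaries. Identical seeds give
byte-identical wig output. Cohorts share a configurable fraction of
termini; private termini keep their transcript bodies in all samples so
cross-sample tests isolate the terminus, not the coverage.

What it does **not** model: fragment-length and ligation biases, read-depth
gradients along transcripts, overlapping antisense transcription, copy-number
variation, or the broad processed-end heterogeneity of real libraries.
Passing tests therefore demonstrate the pipeline's arithmetic and decision
logic under the stated signal model, not performance on any particular real
library.

Default problem sizes in the test-suite and acceptance experiments — 100 kb
genomes, 40 transcripts, 500–1500 nt spans with ≥ 200 nt gaps — are chosen
as the smallest scale at which every stage (windows, pruning, FDR, operon
segmentation) operates exactly as on a full bacterial genome.

## Known limitations

* The operon segmentation cutoff (0.8 non-zero fraction) requires genuinely
  dense bodies: a Poisson body of 0.5 reads/nt has a non-zero fraction of
  1−e^(−0.5) ≈ 0.39 and will never open an operon. Low-coverage transcripts
  are instead recovered via orphan pairing; operon-recovery experiments use
  2.5 reads/nt bodies (non-zero fraction ≈ 0.92, a realistically expressed
  operon).
* At high body density, body noise on the 3′ track just downstream of a
  transcript's 5′ boundary can exceed `z_stop`, because its upstream window
  lies mostly in the low background outside the transcript; the FDR filter
  does not remove such peaks (their window sum is high). This is inherent
  to the window geometry and also affects real data; cross-sample
  verification is the practical mitigation.
* The per-sample FDR null assumes reads are exchangeable within 50 bp; it
  is blind to structured artefacts (e.g. rRNA contamination edges).
* Feature transfer trusts the prior annotation's CDS coordinates; no de
  novo ORF scanning is attempted.
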