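# rendannot

Genome-wide annotation of bacterial transcript boundaries from Rend-seq
end-count tracks.

Rend-seq sequences short RNA fragments so that the true 5′ and 3′ ends of
transcripts are enriched as single-nucleotide read-count spikes over a
uniform fragmentation background. Each sample is summarised as four wig
tracks (5′ and 3′ read termini per strand, per nucleotide). `rendannot`
turns those tracks into annotation files: it calls transcription start and
stop sites at single-nucleotide resolution, reconstructs operons and
transcript isoforms (including 5′/3′ UTRs and small RNAs), transfers names
and features from an existing annotation, and writes GFF3 or GTF. It is
aimed at microbial transcriptomics — annotating UTRs and non-coding RNAs
that GenBank-style annotations lack, and locating RNase processing sites by
comparing conditions.

## Method

At every genomic position `i` with read value `x_i`, the pipeline computes

```
z_i = (x_i − μ_w) / max(σ_w, σ_floor)
```

where `μ_w`, `σ_w` are the mean and standard deviation of the read values in
a window next to `i`: the *downstream* window (in transcription direction)
for 5′ tracks, the *upstream* window for 3′ tracks, with absent positions
counted as zeros. Two windows are scored, 50 bp and 25 bp. A position is
**called** a start site when its 50-bp z-score reaches 7 (stop sites: 6);
positions reaching z = 5 in either window are **flagged** and only kept when
corroborated — by recurring at the same coordinate in another sample, or by
lying within ±5 bp of an external terminus coordinate (e.g. Cappable-seq
TSS, Term-seq 3′ ends) or ±30 bp of a coarse operon boundary set. Within any
±5 bp cluster only the highest peak survives. Every peak must additionally
beat a randomisation null: the read sum `S` of the surrounding 50-bp window
is imagined dropped uniformly on a hypothetical 50-bp gene, and the peak is
discarded below `T = S/L + 2·sqrt(S·(1/L)(1−1/L))`.

Operons are segmented by read density — the fraction of non-zero 5′/3′
values between consecutive peaks — opening above 0.8 between a start and the
next stop and closing where density falls below. Every start–stop pair
inside an operon whose interval density reaches 0.20 becomes a transcript;
transcripts sharing a terminus form isoform groups. Against a prior
annotation, transcripts containing whole coding sequences become CDS
transcripts tiled into 5′UTR/CDS/3′UTR, non-coding transcripts are
subclassified (UTR-derived, intergenic/intragenic, independent with/without
isoforms, putative sRNA), and peaks lacking a partner are completed into
"hybrid" annotations whose borrowed terminus is marked in the GFF3 phase
column.

A synthetic-data generator (`rendannot.simulate`) emulates the Rend-seq
signal model — Poisson fragmentation background over transcript bodies plus
sharp terminus spikes — so the whole pipeline is testable with known ground
truth and no downloads.

## Worked example

```python
from rendannot import (random_transcripts, simulate_sample, run_pipeline,
                       read_density_report)

planted = random_transcripts(100_000, 40, seed=1, body_density=0.5,
                             enrichment=50.0)
sample, truth = simulate_sample(100_000, planted, noise_rate=0.02, seed=1,
                                sample_id="demo")
result = run_pipeline([sample])

peaks = result.surviving_peaks
truth_keys = {(r.strand, r.kind, r.position) for r in truth.itertuples()}
print(f"read density        : {read_density_report(sample):.3f} reads/nt")
print(f"surviving termini   : {len(peaks)} "
      f"({sum(p.kind == 'start' for p in peaks)} starts, "
      f"{sum(p.kind == 'stop' for p in peaks)} stops)")
print(f"exact-nt recovery   : {sum(p.key in truth_keys for p in peaks)}"
      f"/{len(truth_keys)} planted boundaries")
print(f"transcripts drawn   : {len(result.all_transcripts)}")
```

prints

```
read density        : 0.386 reads/nt
surviving termini   : 80 (40 starts, 40 stops)
exact-nt recovery   : 80/80 planted boundaries
transcripts drawn   : 40
```

i.e. on a 100-kb genome carrying 40 low-coverage transcripts (0.5 reads/nt
bodies, 50-fold end enrichment, 0.02 reads/nt noise) every planted boundary
is recovered at the exact nucleotide with no false calls, and one transcript
is drawn per planted start–stop pair.

The same pipeline is available from the shell:

```
rendannot simulate --genome-length 100000 --n-transcripts 40 --seed 1 --outdir sim
rendannot run --wig-manifest sim/sim_manifest.json --old_annotation old.gff3 \
              --z_start 7 --z_stop 6 --z_small 5 --unique 1 --fdr 2 \
              --operon_cutoff 0.8 --outdir out
```

`run` writes, per sample, a transcript-configurations file and a
subcategorised (UTR/CDS) file, plus the cross-sample `All_conditions` union
and `supplied_with_AA` (union supplemented with prior-annotation records for
loci without Rend-seq coverage). `--output All` additionally writes
per-position z-score tables.

## Documentation

`docs/methods.md` describes the model, every tunable threshold with its
default, the synthetic-data generator and its limits, and the numerical
choices made where the method description left the design open.
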