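"""Synthetic Rend-seq samples with known ground truth.

The generator emulates the Rend-seq signal model: transcript bodies
receive a uniform Poisson fragmentation background on both end tracks of
their strand, true 5' boundaries an additional sharp spike on the 5'
track (and 3' boundaries on the 3' track), and the whole genome a low
Poisson noise floor on all four tracks.  Spikes occupy a single
nucleotide by default; an option spreads stop spikes over up to four
nucleotides with the summit keeping at least half of the spike mass,
mirroring the empirically broader 3' boundaries.

Identical seeds give byte-identical samples.  Default rates — 0.5 reads/nt
transcript bodies, 50-fold terminus enrichment, 0.02 reads/nt noise —
correspond to a low-coverage bacterial Rend-seq library, the regime where
sensitivity matters most.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .tracks import (
    ENDS,
    EndTrack,
    FIVE_PRIME,
    RendSample,
    STRANDS,
    THREE_PRIME,
    TRACK_SLOTS,
    write_end_track,
)

#: relative spike mass per nucleotide when stop spikes are widened;
#: the summit always carries at least half of the mass
STOP_SPIKE_WEIGHTS = (0.55, 0.25, 0.13, 0.07)


@dataclass
class PlantedTranscript:
    """Ground-truth transcript for the simulator.

    ``starts``/``stops`` list the true 5'/3' terminus positions (several of
    each model isoforms); all must lie within the span, with every start
    upstream of every stop in transcription direction.
    """

    left: int
    right: int
    strand: str
    starts: Tuple[int, ...] = ()
    stops: Tuple[int, ...] = ()
    body_density: float = 0.5
    enrichment: float = 50.0

    def __post_init__(self) -> None:
        if self.left > self.right:
            raise ValueError("span left must not exceed right")
        if self.strand not in STRANDS:
            raise ValueError("strand must be + or -")
        if self.enrichment <= 1:
            raise ValueError("enrichment must exceed 1")
        if self.body_density < 0:
            raise ValueError("body_density must be non-negative")
        self.starts = tuple(self.starts)
        self.stops = tuple(self.stops)
        for pos in self.starts + self.stops:
            if not self.left <= pos <= self.right:
                raise ValueError(f"terminus {pos} outside span")
        for s in self.starts:
            for t in self.stops:
                upstream = s <= t if self.strand == "+" else s >= t
                if not upstream:
                    raise ValueError(
                        f"start {s} not upstream of stop {t} on strand {self.strand}"
                    )


def simulate_sample(
    genome_length: int,
    planted: Sequence[PlantedTranscript],
    noise_rate: float = 0.02,
    seed: Optional[int] = None,
    sample_id: str = "sim",
    condition: str = "synthetic",
    stop_spike_width: int = 1,
) -> Tuple[RendSample, pd.DataFrame]:
    """Simulate one Rend-seq sample plus its terminus truth table.

    Returns ``(sample, truth)`` where ``truth`` has columns position,
    strand, kind and transcript index.
    """
    if not 1 <= stop_spike_width <= len(STOP_SPIKE_WEIGHTS):
        raise ValueError(
            f"stop_spike_width must be in [1, {len(STOP_SPIKE_WEIGHTS)}]"
        )
    _check_overlaps(planted, genome_length)
    rng = np.random.default_rng(seed)
    arrays: Dict[Tuple[str, str], np.ndarray] = {
        slot: np.zeros(genome_length + 1) for slot in TRACK_SLOTS
    }
    truth_rows = []
    for idx, tx in enumerate(planted):
        length = tx.right - tx.left + 1
        for end in ENDS:
            arrays[(tx.strand, end)][tx.left : tx.right + 1] += rng.poisson(
                tx.body_density, size=length
            )
        spike_lam = tx.enrichment * tx.body_density
        for pos in tx.starts:
            arrays[(tx.strand, FIVE_PRIME)][pos] += rng.poisson(spike_lam)
            truth_rows.append(
                {"position": pos, "strand": tx.strand, "kind": "start", "transcript": idx}
            )
        inward = -1 if tx.strand == "+" else 1  # from the stop back into the body
        weights = np.asarray(STOP_SPIKE_WEIGHTS[:stop_spike_width])
        weights = weights / weights.sum()
        for pos in tx.stops:
            for offset, w in enumerate(weights):
                at = pos + inward * offset
                if 1 <= at <= genome_length:
                    arrays[(tx.strand, THREE_PRIME)][at] += rng.poisson(spike_lam * w)
            truth_rows.append(
                {"position": pos, "strand": tx.strand, "kind": "stop", "transcript": idx}
            )
    if noise_rate > 0:
        for slot in TRACK_SLOTS:
            arrays[slot][1:] += rng.poisson(noise_rate, size=genome_length)
    tracks = {}
    for (strand, end), arr in arrays.items():
        counts = {
            int(pos): float(arr[pos]) for pos in np.nonzero(arr)[0] if pos >= 1
        }
        tracks[(strand, end)] = EndTrack(
            strand=strand, end=end, genome_length=genome_length, counts=counts
        )
    sample = RendSample(
        sample_id=sample_id,
        condition=condition,
        genome_length=genome_length,
        tracks=tracks,
    )
    truth = pd.DataFrame(
        truth_rows, columns=["position", "strand", "kind", "transcript"]
    )
    return sample, truth


def _check_overlaps(planted: Sequence[PlantedTranscript], genome_length: int) -> None:
    for tx in planted:
        if tx.right > genome_length:
            raise ValueError(f"planted span {tx.left}-{tx.right} outside genome")
    by_strand: Dict[str, List[PlantedTranscript]] = {}
    for tx in planted:
        by_strand.setdefault(tx.strand, []).append(tx)
    for txs in by_strand.values():
        txs = sorted(txs, key=lambda t: t.left)
        for a, b in zip(txs, txs[1:]):
            if b.left <= a.right and a.body_density != b.body_density:
                raise ValueError(
                    "overlapping same-strand transcripts with conflicting "
                    f"body densities at {a.left}-{a.right} / {b.left}-{b.right}"
                )


def random_transcripts(
    genome_length: int,
    n: int,
    seed: Optional[int] = None,
    min_length: int = 500,
    max_length: int = 1500,
    gap: int = 200,
    body_density: float = 0.5,
    enrichment: float = 50.0,
) -> List[PlantedTranscript]:
    """Lay out ``n`` non-overlapping transcripts with random spans/strands.

    Each transcript gets one start at its 5' boundary and one stop at its
    3' boundary.  Spans are placed left to right with at least ``gap`` nt
    between consecutive spans so neighbouring scoring windows stay clean.
    """
    rng = np.random.default_rng(seed)
    lengths = rng.integers(min_length, max_length + 1, size=n)
    total = int(lengths.sum()) + gap * (n + 1)
    if total > genome_length:
        raise ValueError(
            f"cannot place {n} transcripts of up to {max_length} nt in "
            f"{genome_length} nt with {gap} nt gaps"
        )
    slack = genome_length - total
    # distribute the slack randomly between the fixed minimum gaps
    extra = rng.multinomial(slack, np.full(n + 1, 1.0 / (n + 1)))
    out = []
    cursor = 1
    for i in range(n):
        cursor += gap + int(extra[i])
        left = cursor
        right = left + int(lengths[i]) - 1
        strand = "+" if rng.random() < 0.5 else "-"
        start = left if strand == "+" else right
        stop = right if strand == "+" else left
        out.append(
            PlantedTranscript(
                left=left,
                right=right,
                strand=strand,
                starts=(start,),
                stops=(stop,),
                body_density=body_density,
                enrichment=enrichment,
            )
        )
        cursor = right + 1
    return out


def simulate_cohort(
    genome_length: int,
    planted: Sequence[PlantedTranscript],
    n_samples: int,
    shared_fraction: float = 1.0,
    noise_rate: float = 0.02,
    seed: Optional[int] = None,
    condition: str = "synthetic",
) -> Tuple[List[RendSample], pd.DataFrame]:
    """Simulate a cohort sharing a fraction of the planted termini.

    A ``shared_fraction`` of all termini appears in every sample; the rest
    are assigned round-robin to single samples (their transcript bodies
    remain in all samples, only the terminus spike is sample-private).
    Poisson noise and body counts are drawn independently per sample.

    Returns ``(samples, truth)``; the truth table lists, per terminus, the
    samples whose library carries its spike (comma-joined sample ids).
    """
    if n_samples < 2:
        raise ValueError("a cohort needs at least two samples")
    if not 0 <= shared_fraction <= 1:
        raise ValueError("shared_fraction must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    termini = []  # (transcript index, kind, position)
    for idx, tx in enumerate(planted):
        for pos in tx.starts:
            termini.append((idx, "start", pos))
        for pos in tx.stops:
            termini.append((idx, "stop", pos))
    n_shared = int(round(shared_fraction * len(termini)))
    order = rng.permutation(len(termini))
    shared = set(order[:n_shared].tolist())
    owner = {}  # private terminus -> sample index
    for rank, t_idx in enumerate(order[n_shared:].tolist()):
        owner[t_idx] = rank % n_samples

    sample_ids = [f"sample_{i}" for i in range(n_samples)]
    samples = []
    for s_idx, sample_id in enumerate(sample_ids):
        local = []
        for idx, tx in enumerate(planted):
            starts, stops = [], []
            for t_idx, (tx_idx, kind, pos) in enumerate(termini):
                if tx_idx != idx:
                    continue
                if t_idx in shared or owner.get(t_idx) == s_idx:
                    (starts if kind == "start" else stops).append(pos)
            local.append(
                PlantedTranscript(
                    left=tx.left,
                    right=tx.right,
                    strand=tx.strand,
                    starts=tuple(starts),
                    stops=tuple(stops),
                    body_density=tx.body_density,
                    enrichment=tx.enrichment,
                )
            )
        child_seed = int(rng.integers(0, 2**31 - 1))
        sample, _ = simulate_sample(
            genome_length,
            local,
            noise_rate=noise_rate,
            seed=child_seed,
            sample_id=sample_id,
            condition=condition,
        )
        samples.append(sample)

    truth_rows = []
    for t_idx, (tx_idx, kind, pos) in enumerate(termini):
        if t_idx in shared:
            present = list(sample_ids)
        else:
            present = [sample_ids[owner[t_idx]]]
        truth_rows.append(
            {
                "position": pos,
                "strand": planted[tx_idx].strand,
                "kind": kind,
                "transcript": tx_idx,
                "samples": ",".join(present),
                "shared": t_idx in shared,
            }
        )
    truth = pd.DataFrame(
        truth_rows,
        columns=["position", "strand", "kind", "transcript", "samples", "shared"],
    )
    return samples, truth


def write_fixture(
    sample: RendSample,
    outdir,
    truth: Optional[pd.DataFrame] = None,
) -> Path:
    """Serialise a sample as four wig files (+ truth GFF3) and a manifest.

    Returns the manifest path, which :func:`rendannot.tracks.load_manifest`
    reads back.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    strand_tag = {"+": "fwd", "-": "rev"}
    end_tag = {FIVE_PRIME: "5p", THREE_PRIME: "3p"}
    track_paths: Dict[str, Dict[str, str]] = {"+": {}, "-": {}}
    for (strand, end), track in sample.tracks.items():
        name = f"{sample.sample_id}_{end_tag[end]}_{strand_tag[strand]}.wig"
        write_end_track(track, outdir / name)
        track_paths[strand][end] = name
    manifest = {
        "samples": [
            {
                "sample_id": sample.sample_id,
                "condition": sample.condition,
                "genome_length": sample.genome_length,
                "tracks": track_paths,
            }
        ]
    }
    if truth is not None:
        truth_path = outdir / f"{sample.sample_id}_truth.gff3"
        with open(truth_path, "w") as handle:
            handle.write("##gff-version 3\n")
            for _, row in truth.iterrows():
                handle.write(
                    "genome\trendannot_sim\t{kind}\t{pos}\t{pos}\t.\t{strand}\t.\t"
                    "ID=truth_{kind}_{pos}\n".format(
                        kind=row["kind"], pos=int(row["position"]), strand=row["strand"]
                    )
                )
        manifest["truth"] = truth_path.name
    manifest_path = outdir / f"{sample.sample_id}_manifest.json"
    with open(manifest_path, "w") as handle:
        json.dump(manifest, handle, indent=2)
        handle.write("\n")
    return manifest_path
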