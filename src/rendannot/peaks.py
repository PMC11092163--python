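"""Dual-window z-score peak calling on Rend-seq end tracks.

A transcript start site appears as a count spike on a 5'-end track and is
scored against the window immediately *downstream* of it (in the direction
of transcription); a stop site appears on a 3'-end track and is scored
against its *upstream* window.  The z-score is the number of standard
deviations the focal read value lies above the window mean, with absent
positions counted as zeros and the focal position excluded from its own
null window.  Two window sizes are used: the large (50 bp) window decides
outright calls, while the small (25 bp) window can rescue marginal peaks
that sit next to a larger peak inflating the large-window mean — those
enter the 5-to-7 "flag band" and require verification downstream.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Set, Tuple

import numpy as np

from .config import PipelineConfig
from .tracks import EndTrack, FIVE_PRIME, RendSample, THREE_PRIME

logger = logging.getLogger(__name__)

START = "start"
STOP = "stop"
KINDS = (START, STOP)

CALLED = "called"
FLAGGED = "flagged"
VERIFIED = "verified"
REJECTED = "rejected"

#: end-type of the track a peak kind is read from
KIND_TO_END = {START: FIVE_PRIME, STOP: THREE_PRIME}
END_TO_KIND = {FIVE_PRIME: START, THREE_PRIME: STOP}
#: window side relative to transcription for each kind
KIND_TO_DIRECTION = {START: "downstream", STOP: "upstream"}


@dataclass
class Peak:
    """A candidate transcript terminus."""

    position: int
    strand: str
    kind: str
    value: float
    z_large: float
    z_small_win: float
    status: str
    sample_id: str = ""
    evidence: Set[str] = field(default_factory=set)
    operon: Optional[object] = None

    @property
    def key(self) -> Tuple[str, str, int]:
        """Identity of the terminus irrespective of sample: (strand, kind, position)."""
        return (self.strand, self.kind, self.position)

    @property
    def surviving(self) -> bool:
        return self.status in (CALLED, VERIFIED)


def _window_bounds(
    strand: str, pos: int, size: int, direction: str, genome_length: int
) -> Tuple[int, int]:
    """Genomic [lo, hi] of the scoring window, clipped to the chromosome.

    'downstream' follows transcription: increasing coordinates on '+',
    decreasing on '-'.
    """
    if direction not in ("downstream", "upstream"):
        raise ValueError(f"direction must be downstream/upstream, got {direction!r}")
    rightward = (direction == "downstream") == (strand == "+")
    if rightward:
        lo, hi = pos + 1, pos + size
    else:
        lo, hi = pos - size, pos - 1
    return max(lo, 1), min(hi, genome_length)


def _window_stats_arr(
    arr: np.ndarray,
    strand: str,
    genome_length: int,
    pos: int,
    size: int,
    direction: str,
    population_sd: bool = True,
    include_focal: bool = False,
) -> Tuple[float, float, int]:
    lo, hi = _window_bounds(strand, pos, size, direction, genome_length)
    if include_focal:
        # widen the window by one position so the focal value enters its own null
        lo, hi = min(lo, pos), max(hi, pos)
    n = hi - lo + 1
    if n <= 0:
        return 0.0, 0.0, 0
    window = arr[lo : hi + 1]
    mean = float(window.mean())
    ddof = 0 if population_sd else 1
    if n - ddof <= 0:
        sd = 0.0
    else:
        sd = float(window.std(ddof=ddof))
    return mean, sd, n


def window_stats(
    track: EndTrack,
    pos: int,
    size: int,
    direction: str,
    population_sd: bool = True,
) -> Tuple[float, float, int]:
    """Mean, sd and in-genome length of the null window next to ``pos``.

    The focal position is excluded; absent positions count as zeros; the
    window is truncated at chromosome ends (callers skip positions whose
    returned ``n`` falls below half the requested size).
    """
    if not 1 <= pos <= track.genome_length:
        raise ValueError(f"position {pos} outside [1, {track.genome_length}]")
    return _window_stats_arr(
        track.to_array(), track.strand, track.genome_length, pos, size, direction,
        population_sd=population_sd,
    )


def z_score(value: float, mean: float, sd: float, sd_floor: float = 1.0) -> float:
    """(value - mean) / max(sd, sd_floor).

    Flooring the denominator keeps the score defined on flat-zero windows,
    where it degrades to the raw excess read count.
    """
    if sd < 0:
        raise ValueError("sd must be non-negative")
    return (value - mean) / max(sd, sd_floor)


def call_peaks(sample: RendSample, config: Optional[PipelineConfig] = None) -> List[Peak]:
    """Scan all four tracks of a sample and call/flag candidate termini.

    Every position whose value reaches ``config.min_peak_value`` is scored
    in both windows.  A peak is *called* when its large-window z-score
    reaches the kind-specific threshold (z_start for starts, z_stop for
    stops); otherwise it is *flagged* when either window's z-score reaches
    z_small.  The result is pruned so only the highest peak within the
    pruning radius survives per (strand, kind).
    """
    config = config or PipelineConfig()
    peaks: List[Peak] = []
    skipped = 0
    for (strand, end), track in sample.tracks.items():
        kind = END_TO_KIND[end]
        direction = KIND_TO_DIRECTION[kind]
        threshold = config.z_start if kind == START else config.z_stop
        arr = track.to_array()
        for pos in sorted(track.counts):
            value = track.counts[pos]
            if value < config.min_peak_value:
                continue
            include_focal = not config.exclude_focal
            mean_l, sd_l, n_l = _window_stats_arr(
                arr, strand, track.genome_length, pos,
                config.window_large, direction, config.population_sd,
                include_focal=include_focal,
            )
            mean_s, sd_s, n_s = _window_stats_arr(
                arr, strand, track.genome_length, pos,
                config.window_small, direction, config.population_sd,
                include_focal=include_focal,
            )
            if n_l < config.window_large / 2 or n_s < config.window_small / 2:
                skipped += 1
                continue
            z_l = z_score(value, mean_l, sd_l, config.sd_floor)
            z_s = z_score(value, mean_s, sd_s, config.sd_floor)
            if z_l >= threshold:
                status = CALLED
            elif max(z_l, z_s) >= config.z_small:
                status = FLAGGED
            else:
                continue
            peaks.append(
                Peak(
                    position=pos,
                    strand=strand,
                    kind=kind,
                    value=value,
                    z_large=z_l,
                    z_small_win=z_s,
                    status=status,
                    sample_id=sample.sample_id,
                )
            )
    if skipped:
        logger.info(
            "sample %s: skipped %d candidate positions with truncated windows",
            sample.sample_id, skipped,
        )
    return prune_local_maxima(peaks, config.prune_radius)


def _outward_key(peak: Peak) -> int:
    """Tie-break sort key preferring the position that extends the transcript.

    Starts keep the most upstream-in-transcription coordinate, stops the
    most downstream — on '+' that is the smallest/largest position
    respectively, mirrored on '-'.
    """
    outward_left = (peak.kind == START) == (peak.strand == "+")
    return peak.position if outward_left else -peak.position


def prune_local_maxima(peaks: Iterable[Peak], prune_radius: int) -> List[Peak]:
    """Keep only the highest peak within ``prune_radius`` nt per (strand, kind).

    Greedy by descending value: a peak survives iff no already-kept peak of
    the same strand and kind lies within the radius, so every survivor has
    a value at least as high as every peak it displaced.  Equal values are
    broken deterministically toward the transcript-extending position.
    """
    groups: Dict[Tuple[str, str], List[Peak]] = {}
    for peak in peaks:
        groups.setdefault((peak.strand, peak.kind), []).append(peak)
    survivors: List[Peak] = []
    for group in groups.values():
        group.sort(key=lambda p: (-p.value, _outward_key(p)))
        kept_positions: List[int] = []
        for peak in group:
            if all(abs(peak.position - q) > prune_radius for q in kept_positions):
                kept_positions.append(peak.position)
                survivors.append(peak)
    survivors.sort(key=lambda p: (p.strand, p.kind, p.position))
    return survivors
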