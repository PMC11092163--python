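"""Operon segmentation by inter-peak read density and peak-to-operon
assignment.

Operons are density-contiguous transcribed spans on one strand.  Read
density between two coordinates is the fraction of non-zero values on the
strand's two end tracks (each genomic position carries a 5' and a 3'
value, hence the division by twice the span length).  Scanning peaks in
transcription order on a designated guide sample, an operon opens at a
start site whose density to the next stop exceeds the cutoff, keeps
extending while the density from its last stop to the next peak stays at
or above the cutoff, and closes at the stop where the density falls below.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

from .peaks import Peak, START, STOP
from .tracks import FIVE_PRIME, RendSample, THREE_PRIME

logger = logging.getLogger(__name__)


@dataclass
class Operon:
    """A density-contiguous transcribed span with its member peaks."""

    left: int
    right: int
    strand: str
    density: float
    member_peaks: List[Peak] = field(default_factory=list)
    source: str = "rendseq_auto"

    def __post_init__(self) -> None:
        if self.left > self.right:
            raise ValueError("operon left must not exceed right")
        if not 0 <= self.density <= 1:
            raise ValueError("density must lie in [0, 1]")

    @property
    def span(self) -> Tuple[int, int]:
        return (self.left, self.right)

    def contains(self, position: int, strand: str) -> bool:
        return strand == self.strand and self.left <= position <= self.right


def read_density(sample: RendSample, strand: str, a: int, b: int) -> float:
    """Fraction of non-zero 5'/3' values over [a, b] on one strand.

    Each coordinate carries two values (a 5' and a 3' read count), so the
    non-zero count is divided by twice the inclusive span length.
    """
    if a > b:
        raise ValueError("region start must not exceed end")
    a = max(1, a)
    b = min(sample.genome_length, b)
    length = b - a + 1
    five = sample.track(strand, FIVE_PRIME).counts
    three = sample.track(strand, THREE_PRIME).counts
    if length > len(five) + len(three):
        # sparse path: walk the stored positions instead of the region
        nonzero = sum(1 for p in five if a <= p <= b) + sum(
            1 for p in three if a <= p <= b
        )
    else:
        nonzero = sum(1 for p in range(a, b + 1) if five.get(p)) + sum(
            1 for p in range(a, b + 1) if three.get(p)
        )
    return nonzero / (2 * length)


def _transcription_order(peaks: Iterable[Peak], strand: str) -> List[Peak]:
    """Surviving peaks of one strand sorted 5' -> 3' in transcription direction."""
    subset = [p for p in peaks if p.strand == strand and p.surviving]
    return sorted(subset, key=lambda p: p.position, reverse=(strand == "-"))


def build_operons(
    peaks: Iterable[Peak],
    sample: RendSample,
    operon_cutoff: float = 0.8,
) -> List[Operon]:
    """Segment each strand into operons from the guide sample's peaks.

    Opening requires density strictly above the cutoff between a start and
    the next stop downstream; extension requires density at or above the
    cutoff between the operon's last stop and the next peak (so boundaries
    sitting exactly at the cutoff extend).  Operon spans never overlap on
    the same strand.
    """
    peaks = list(peaks)
    operons: List[Operon] = []
    for strand in ("+", "-"):
        ordered = _transcription_order(peaks, strand)
        n = len(ordered)
        i = 0
        while i < n:
            if ordered[i].kind != START:
                i += 1
                continue
            start_peak = ordered[i]
            j = i + 1
            while j < n and ordered[j].kind != STOP:
                j += 1
            if j >= n:
                break
            stop_peak = ordered[j]
            a, b = sorted((start_peak.position, stop_peak.position))
            opening_density = read_density(sample, strand, a, b)
            if opening_density <= operon_cutoff:
                i += 1
                continue
            last_stop_idx = j
            k = j + 1
            while k < n:
                a2, b2 = sorted((ordered[last_stop_idx].position, ordered[k].position))
                if read_density(sample, strand, a2, b2) < operon_cutoff:
                    break
                if ordered[k].kind == STOP:
                    last_stop_idx = k
                k += 1
            left, right = sorted(
                (start_peak.position, ordered[last_stop_idx].position)
            )
            operons.append(
                Operon(left=left, right=right, strand=strand, density=opening_density)
            )
            i = last_stop_idx + 1
    logger.info("built %d operons", len(operons))
    return operons


def assign_peaks(peaks: Iterable[Peak], operons: Sequence[Operon]) -> List[Peak]:
    """Attach every surviving peak to the same-strand operon containing it.

    Returns the peaks that remained unassigned.
    """
    unassigned = []
    for peak in peaks:
        if not peak.surviving:
            continue
        home = None
        for operon in operons:
            if operon.contains(peak.position, peak.strand):
                home = operon
                break
        if home is not None:
            peak.operon = home
            home.member_peaks.append(peak)
        else:
            peak.operon = None
            unassigned.append(peak)
    return unassigned


def _downstream_distance(peak: Peak, operon: Operon) -> Optional[int]:
    """Distance from a start peak forward (in transcription) to an operon,
    None when the operon is behind the peak."""
    if peak.strand == "+":
        d = operon.left - peak.position
    else:
        d = peak.position - operon.right
    return d if d >= 0 else None


def _upstream_distance(peak: Peak, operon: Operon) -> Optional[int]:
    if peak.strand == "+":
        d = peak.position - operon.right
    else:
        d = operon.left - peak.position
    return d if d >= 0 else None


def resolve_orphans(
    unassigned: Iterable[Peak],
    operons: Sequence[Operon],
) -> Tuple[List[Peak], List[Tuple[Peak, Peak]]]:
    """Place peaks that fell outside every operon.

    Orphan starts pair with the nearest orphan stop downstream when no
    operon lies in between — such pairs bound the same low-expressed
    transcript and are emitted as candidate annotations.  Remaining starts
    attach to the nearest downstream operon and remaining stops to the
    nearest upstream operon (both in transcription direction).

    Returns (newly assigned peaks, orphan start/stop pairs).
    """
    assigned: List[Peak] = []
    pairs: List[Tuple[Peak, Peak]] = []
    by_strand: Dict[str, List[Peak]] = {}
    for peak in unassigned:
        by_strand.setdefault(peak.strand, []).append(peak)

    for strand, orphans in by_strand.items():
        ordered = sorted(orphans, key=lambda p: p.position, reverse=(strand == "-"))
        consumed = set()
        same_strand_ops = [o for o in operons if o.strand == strand]
        for idx, peak in enumerate(ordered):
            if peak.kind != START or id(peak) in consumed:
                continue
            for partner in ordered[idx + 1 :]:
                if partner.kind != STOP or id(partner) in consumed:
                    continue
                a, b = sorted((peak.position, partner.position))
                blocked = any(
                    not (o.right < a or o.left > b) for o in same_strand_ops
                )
                if not blocked:
                    pairs.append((peak, partner))
                    consumed.add(id(peak))
                    consumed.add(id(partner))
                break
        for peak in ordered:
            if id(peak) in consumed:
                continue
            metric = _downstream_distance if peak.kind == START else _upstream_distance
            best, best_d = None, None
            for operon in same_strand_ops:
                d = metric(peak, operon)
                if d is not None and (best_d is None or d < best_d):
                    best, best_d = operon, d
            if best is not None:
                peak.operon = best
                best.member_peaks.append(peak)
                assigned.append(peak)
            else:
                logger.info(
                    "orphan %s at %s%d has no operon to attach to",
                    peak.kind, peak.strand, peak.position,
                )
    return assigned, pairs
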