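"""Transcript assembly: connect start and stop peaks within operons,
group isoforms, and borrow missing termini from a prior annotation.

Within an operon every (start, stop) pair in transcription order becomes a
transcript provided the read density over the interval reaches the
density threshold (default 0.20).  Transcripts sharing a terminus are
isoforms of one another; the relation is closed transitively into isoform
groups.  A peak left without a qualifying partner can be completed from an
overlapping record of an older annotation, producing a "hybrid" transcript
whose borrowed terminus is only as precise as that annotation — hybrids
carry a note naming the coordinate that *is* single-nucleotide resolved
and are marked in the GFF3 phase column on output.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple

from .operons import Operon, read_density
from .peaks import Peak, START, STOP
from .tracks import RendSample

logger = logging.getLogger(__name__)

SINGLE_NT = "single_nt"
BORROWED = "borrowed"


@dataclass
class Transcript:
    """A start-stop annotation on one strand."""

    left: int
    right: int
    strand: str
    start_resolution: str = SINGLE_NT
    stop_resolution: str = SINGLE_NT
    feature: str = ""
    attributes: Dict[str, str] = field(default_factory=dict)
    source_samples: Set[str] = field(default_factory=set)
    isoform_group: Optional[int] = None

    def __post_init__(self) -> None:
        if self.left > self.right:
            raise ValueError("transcript left must not exceed right")

    @property
    def five_prime(self) -> int:
        """Genomic coordinate of the 5' terminus (start site)."""
        return self.left if self.strand == "+" else self.right

    @property
    def three_prime(self) -> int:
        return self.right if self.strand == "+" else self.left

    @property
    def hybrid(self) -> bool:
        return (self.start_resolution == BORROWED) != (
            self.stop_resolution == BORROWED
        )

    @property
    def length(self) -> int:
        return self.right - self.left + 1

    def overlaps(self, left: int, right: int, strand: Optional[str] = None) -> bool:
        if strand is not None and strand != self.strand:
            return False
        return not (self.right < left or self.left > right)


def enumerate_transcripts(
    operon: Operon,
    sample: RendSample,
    density_threshold: float = 0.20,
) -> List[Transcript]:
    """All (start, stop) combinations of an operon's member peaks that pass
    the read-density threshold over their interval."""
    starts = [p for p in operon.member_peaks if p.kind == START and p.surviving]
    stops = [p for p in operon.member_peaks if p.kind == STOP and p.surviving]
    out: List[Transcript] = []
    for s in starts:
        for t in stops:
            upstream = s.position <= t.position if operon.strand == "+" else s.position >= t.position
            if not upstream:
                continue
            a, b = sorted((s.position, t.position))
            if read_density(sample, operon.strand, a, b) < density_threshold:
                continue
            out.append(
                Transcript(
                    left=a,
                    right=b,
                    strand=operon.strand,
                    source_samples={s.sample_id} if s.sample_id else set(),
                )
            )
    return out


def orphan_pair_transcripts(
    pairs: Iterable[Tuple[Peak, Peak]],
) -> List[Transcript]:
    """Candidate transcripts drawn between orphan start/stop pairs."""
    out = []
    for start_peak, stop_peak in pairs:
        a, b = sorted((start_peak.position, stop_peak.position))
        out.append(
            Transcript(
                left=a,
                right=b,
                strand=start_peak.strand,
                source_samples={start_peak.sample_id} if start_peak.sample_id else set(),
            )
        )
    return out


def assign_isoform_groups(transcripts: Sequence[Transcript]) -> None:
    """Label transcripts with isoform-group ids.

    Two transcripts are isoforms when they share a 5' or a 3' terminus on
    the same strand; groups are the transitive closure of that relation
    (union-find over terminus keys).
    """
    parent: Dict[object, object] = {}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(a, b):
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[rb] = ra

    keys = []
    for idx, t in enumerate(transcripts):
        node = ("t", idx)
        k5 = ("5", t.strand, t.five_prime)
        k3 = ("3", t.strand, t.three_prime)
        for key in (node, k5, k3):
            parent.setdefault(key, key)
        union(node, k5)
        union(node, k3)
        keys.append(node)

    roots: Dict[object, int] = {}
    for idx, node in enumerate(keys):
        root = find(node)
        group = roots.setdefault(root, len(roots))
        transcripts[idx].isoform_group = group


def isoform_partners(
    transcript: Transcript, transcripts: Iterable[Transcript]
) -> List[Transcript]:
    """Transcripts sharing a terminus with ``transcript`` (directly)."""
    out = []
    for other in transcripts:
        if other is transcript or other.strand != transcript.strand:
            continue
        if (
            other.five_prime == transcript.five_prime
            or other.three_prime == transcript.three_prime
        ):
            out.append(other)
    return out


def make_hybrids(
    partnerless: Iterable[Peak],
    old_annotation: Sequence,
) -> List[Transcript]:
    """Complete partner-less peaks against an older annotation.

    A resolved start borrows the nearest downstream 3' edge among
    same-strand old records overlapping the start (nearest first, longest
    transcript on ties); a resolved stop symmetrically borrows a 5' edge.
    Peaks overlapping nothing are dropped with a log entry.  ``old_annotation``
    records need ``left``, ``right`` and ``strand`` attributes.
    """
    out: List[Transcript] = []
    for peak in partnerless:
        candidates = [
            r
            for r in old_annotation
            if r.strand == peak.strand and r.left <= peak.position <= r.right
        ]
        best = None  # (distance, -record_length, borrowed_coordinate)
        for record in candidates:
            if peak.kind == START:
                borrowed = record.right if peak.strand == "+" else record.left
                distance = (
                    borrowed - peak.position
                    if peak.strand == "+"
                    else peak.position - borrowed
                )
            else:
                borrowed = record.left if peak.strand == "+" else record.right
                distance = (
                    peak.position - borrowed
                    if peak.strand == "+"
                    else borrowed - peak.position
                )
            if distance < 0:
                continue
            key = (distance, -(record.right - record.left + 1))
            if best is None or key < best[0]:
                best = (key, borrowed)
        if best is None:
            logger.info(
                "partner-less %s at %s%d overlaps no prior annotation; dropped",
                peak.kind, peak.strand, peak.position,
            )
            continue
        borrowed = best[1]
        a, b = sorted((peak.position, borrowed))
        if peak.kind == START:
            t = Transcript(
                left=a,
                right=b,
                strand=peak.strand,
                start_resolution=SINGLE_NT,
                stop_resolution=BORROWED,
            )
            t.attributes["Note"] = (
                f"hybrid; single-nucleotide resolution at start {peak.position}"
            )
        else:
            t = Transcript(
                left=a,
                right=b,
                strand=peak.strand,
                start_resolution=BORROWED,
                stop_resolution=SINGLE_NT,
            )
            t.attributes["Note"] = (
                f"hybrid; single-nucleotide resolution at stop {peak.position}"
            )
        if peak.sample_id:
            t.source_samples.add(peak.sample_id)
        out.append(t)
    return out
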