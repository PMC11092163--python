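"""Verification of flagged peaks and the randomisation-null FDR filter.

Peaks in the marginal z-score band ("flagged") are only accepted when
corroborated: either the same terminus recurs across samples, or it lies
near a coordinate from an orthogonal method (e.g. a Cappable-seq TSS list
or a Term-seq terminator list at +/- search_distance, or coarser operon
boundary sets at +/- search_distance_0).  Unverified flagged peaks are
rejected at the end of the pipeline.

Independently, every peak must beat a randomisation null: the reads in a
window around the peak are imagined dropped uniformly on a hypothetical
gene of the same length, and the peak must exceed
``T = mean + fdr_z * sd`` of the resulting per-position counts.  Under a
multinomial drop of S reads on L positions the per-position count has mean
S/L and variance S * (1/L) * (1 - 1/L), which the analytic mode uses
directly; a seeded Monte-Carlo mode serves as an independent check.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple

import numpy as np

from .peaks import FLAGGED, KIND_TO_END, KINDS, Peak, REJECTED, VERIFIED
from .tracks import RendSample

logger = logging.getLogger(__name__)

MULTI_SAMPLE = "multi_sample"
EXTERNAL_NEAR = "external_near"
EXTERNAL_FAR = "external_far"


@dataclass
class ExternalCoordinateSet:
    """Terminus coordinates from an orthogonal method.

    ``kind_served`` says whether the coordinates corroborate start or stop
    peaks; ``far`` marks coarse (operon-level) sets matched at the wider
    search_distance_0 radius.
    """

    label: str
    kind_served: str
    coords: Set[Tuple[int, str]] = field(default_factory=set)
    far: bool = False

    def __post_init__(self) -> None:
        if self.kind_served not in KINDS:
            raise ValueError(f"kind_served must be one of {KINDS}")


def read_coordinate_set(
    path,
    label: str,
    kind_served: str,
    genome_length: Optional[int] = None,
    far: bool = False,
    fmt: Optional[str] = None,
) -> ExternalCoordinateSet:
    """Load an external coordinate set from GFF3, BED or 2-column TSV.

    GFF3/BED intervals contribute their transcription-direction boundary:
    the 5' edge for start sets, the 3' edge for stop sets.  BED input is
    0-based half-open and converted on read.  Coordinates outside the
    genome (when ``genome_length`` is given) are skipped with a warning.
    """
    path = Path(path)
    if fmt is None:
        suffix = path.suffix.lower()
        fmt = {"gff3": "gff3", ".gff3": "gff3", ".gff": "gff3", ".bed": "bed"}.get(
            suffix, "tsv"
        )
    coords: Set[Tuple[int, str]] = set()

    def add(pos: int, strand: str) -> None:
        if genome_length is not None and not 1 <= pos <= genome_length:
            logger.warning("%s: coordinate %d outside genome, skipped", label, pos)
            return
        coords.add((pos, strand))

    with open(path) as handle:
        for raw in handle:
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            cols = line.split("\t")
            if fmt == "gff3":
                if len(cols) < 7:
                    continue
                left, right, strand = int(cols[3]), int(cols[4]), cols[6]
                add(_directed_edge(left, right, strand, kind_served), strand)
            elif fmt == "bed":
                left = int(cols[1]) + 1  # BED chromStart is 0-based
                right = int(cols[2])
                strand = cols[5] if len(cols) > 5 else "+"
                add(_directed_edge(left, right, strand, kind_served), strand)
            else:
                cols = line.split()
                add(int(cols[0]), cols[1] if len(cols) > 1 else "+")
    return ExternalCoordinateSet(label=label, kind_served=kind_served, coords=coords, far=far)


def _directed_edge(left: int, right: int, strand: str, kind: str) -> int:
    """5' edge of an interval for start sets, 3' edge for stop sets."""
    if (kind == "start") == (strand == "+"):
        return left
    return right


def unique_filter(
    peak_sets: Dict[str, List[Peak]],
    unique_N: int = 1,
    tolerance: int = 0,
) -> Dict[str, List[Peak]]:
    """Cross-sample resolution of flagged peaks.

    A flagged peak whose terminus (strand, kind, position +/- tolerance)
    occurs in more than ``unique_N`` samples is verified with
    ``multi_sample`` evidence; one confined to at most ``unique_N`` samples
    is rejected.  Called and already-verified peaks are untouched.  Peaks
    are mutated in place; positions and z-scores never change.
    """
    occurrences: Dict[Tuple[str, str], Dict[int, Set[str]]] = {}
    for sample_id, peaks in peak_sets.items():
        for peak in peaks:
            if peak.status == REJECTED:
                continue
            bucket = occurrences.setdefault((peak.strand, peak.kind), {})
            bucket.setdefault(peak.position, set()).add(sample_id)

    for sample_id, peaks in peak_sets.items():
        for peak in peaks:
            if peak.status != FLAGGED:
                continue
            bucket = occurrences.get((peak.strand, peak.kind), {})
            samples_with = set()
            for pos, ids in bucket.items():
                if abs(pos - peak.position) <= tolerance:
                    samples_with |= ids
            if len(samples_with) > unique_N:
                peak.status = VERIFIED
                peak.evidence.add(MULTI_SAMPLE)
            else:
                peak.status = REJECTED
    return peak_sets


def external_verify(
    peaks: Iterable[Peak],
    external_sets: Sequence[ExternalCoordinateSet],
    search_distance: int = 5,
    search_distance_0: int = 30,
) -> List[Peak]:
    """Verify flagged peaks lying near external coordinates.

    Terminus-level sets match within +/- ``search_distance``; coarse
    (``far``) operon-level sets within +/- ``search_distance_0``.  Only the
    status and evidence of flagged peaks change; unmatched flagged peaks
    stay flagged for rejection at pipeline end.
    """
    peaks = list(peaks)
    for ext in external_sets:
        radius = search_distance_0 if ext.far else search_distance
        tag = EXTERNAL_FAR if ext.far else EXTERNAL_NEAR
        positions = {}
        for pos, strand in ext.coords:
            positions.setdefault(strand, []).append(pos)
        for plist in positions.values():
            plist.sort()
        for peak in peaks:
            if peak.kind != ext.kind_served:
                continue
            if peak.status not in (FLAGGED, VERIFIED):
                continue
            plist = positions.get(peak.strand, [])
            idx = np.searchsorted(plist, peak.position)
            near = False
            for j in (idx - 1, idx):
                if 0 <= j < len(plist) and abs(plist[j] - peak.position) <= radius:
                    near = True
            if near:
                peak.status = VERIFIED
                peak.evidence.add(tag)
    return peaks


def finalize_statuses(peaks: Iterable[Peak]) -> List[Peak]:
    """Reject any peak still flagged; return the surviving peaks.

    After this step every surviving peak has status called or verified.
    """
    surviving = []
    for peak in peaks:
        if peak.status == FLAGGED:
            peak.status = REJECTED
        if peak.surviving:
            surviving.append(peak)
    return surviving


@dataclass
class FdrNull:
    """Randomisation null for one peak: S reads on a hypothetical L-nt gene."""

    S: float
    L: int
    mean_null: float
    sd_null: float
    T: float


def fdr_null(
    S: float,
    L: int,
    fdr_z: float = 2.0,
    mode: str = "analytic",
    seed: Optional[int] = None,
    n_draws: int = 10_000,
) -> FdrNull:
    """Threshold T = mean + fdr_z * sd of per-position counts when S reads
    are dropped uniformly on L positions.

    ``analytic`` uses the multinomial moments (mean S/L, variance
    S*(1/L)*(1-1/L)); ``montecarlo`` estimates the per-position variance
    from seeded multinomial draws (deviations taken about the exact mean
    S/L, pooled across draws).
    """
    if L < 2:
        raise ValueError("L must be at least 2")
    mean_null = S / L
    if mode == "analytic":
        sd_null = math.sqrt(S * (1.0 / L) * (1.0 - 1.0 / L))
    elif mode == "montecarlo":
        rng = np.random.default_rng(seed)
        reads = int(round(S))
        draws = rng.multinomial(reads, np.full(L, 1.0 / L), size=n_draws)
        sd_null = float(np.sqrt(np.mean((draws - mean_null) ** 2)))
    else:
        raise ValueError(f"unknown FDR mode {mode!r}")
    return FdrNull(S=S, L=L, mean_null=mean_null, sd_null=sd_null, T=mean_null + fdr_z * sd_null)


def fdr_window_sum(sample: RendSample, peak: Peak, fdr_window: int) -> float:
    """Sum of the peak's own track over the window centred on the peak
    (peak included, truncated at chromosome ends)."""
    track = sample.track(peak.strand, KIND_TO_END[peak.kind])
    half = fdr_window // 2
    lo = max(1, peak.position - half)
    hi = min(sample.genome_length, peak.position + fdr_window - half - 1)
    return float(sum(track.counts.get(p, 0.0) for p in range(lo, hi + 1)))


def fdr_filter(
    peaks: Iterable[Peak],
    sample: RendSample,
    fdr_window: int = 50,
    fdr_z: float = 2.0,
    mode: str = "analytic",
    seed: Optional[int] = None,
) -> List[Peak]:
    """Reject peaks whose read value could plausibly arise by chance.

    For each peak, S is the read sum over ``fdr_window`` nt around it; the
    peak is rejected when its value falls below the null threshold T.
    """
    peaks = list(peaks)
    n_rejected = 0
    for peak in peaks:
        S = fdr_window_sum(sample, peak, fdr_window)
        null = fdr_null(S, fdr_window, fdr_z, mode=mode, seed=seed)
        if peak.value < null.T:
            peak.status = REJECTED
            n_rejected += 1
    if n_rejected:
        logger.info("FDR filter rejected %d peaks in sample %s", n_rejected, sample.sample_id)
    return peaks
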