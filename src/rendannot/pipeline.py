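"""End-to-end orchestration: from end-count tracks to annotation files.

Stages, in order: per-sample dual-window peak calling; external-coordinate
verification of flagged peaks; cross-sample uniqueness resolution;
rejection of remaining flagged peaks; the randomisation-null FDR filter;
operon segmentation on the guide sample; peak-to-operon assignment and
orphan pairing; transcript enumeration (with isoform grouping) and hybrid
completion; feature transfer from a prior annotation; sRNA
subclassification; GFF3/GTF emission.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import pandas as pd

from .config import PipelineConfig
from .features import (
    AnnotationRecord,
    CDS,
    CdsConsistencyError,
    GENERIC,
    NOVEL,
    PUTATIVE_SRNA,
    classify_srna,
    subcategorize_cds,
    transfer_features,
)
from .gff3 import Gff3Record, transcript_record, write_gff3, write_gtf
from .operons import Operon, assign_peaks, build_operons, resolve_orphans
from .peaks import Peak, call_peaks
from .tracks import RendSample
from .transcripts import (
    Transcript,
    assign_isoform_groups,
    enumerate_transcripts,
    isoform_partners,
    make_hybrids,
    orphan_pair_transcripts,
)
from .verification import (
    ExternalCoordinateSet,
    external_verify,
    fdr_filter,
    finalize_statuses,
    unique_filter,
)

logger = logging.getLogger(__name__)


@dataclass
class SampleResult:
    sample: RendSample
    peaks: List[Peak]
    transcripts: List[Transcript] = field(default_factory=list)
    subrecords: Dict[int, List[AnnotationRecord]] = field(default_factory=dict)


@dataclass
class PipelineResult:
    samples: Dict[str, SampleResult]
    operons: List[Operon]
    guide: str
    config: PipelineConfig

    @property
    def surviving_peaks(self) -> List[Peak]:
        out = []
        for result in self.samples.values():
            out.extend(p for p in result.peaks if p.surviving)
        return out

    @property
    def all_transcripts(self) -> List[Transcript]:
        out = []
        for result in self.samples.values():
            out.extend(result.transcripts)
        return out


def _pick_guide(samples: Sequence[RendSample]) -> str:
    """Default guide: the sample with the highest genome-wide read density."""
    best = max(samples, key=lambda s: read_density_report(s))
    logger.info("no guide given; using highest-density sample %s", best.sample_id)
    return best.sample_id


def run_pipeline(
    samples: Sequence[RendSample],
    config: Optional[PipelineConfig] = None,
    external_sets: Sequence[ExternalCoordinateSet] = (),
    external_operons: Optional[Sequence[Operon]] = None,
    old_annotation: Optional[Sequence[AnnotationRecord]] = None,
    guide: Optional[str] = None,
) -> PipelineResult:
    """Run the full annotation pipeline over one or more samples."""
    if not samples:
        raise ValueError("at least one sample required")
    config = config or PipelineConfig()
    guide = guide or _pick_guide(samples)
    by_id = {s.sample_id: s for s in samples}
    if guide not in by_id:
        raise ValueError(f"guide sample {guide!r} not among samples")

    # 1) peak calling
    peak_sets: Dict[str, List[Peak]] = {}
    for sample in samples:
        peaks = call_peaks(sample, config)
        logger.info(
            "sample %s: %d candidate peaks (%d called, %d flagged)",
            sample.sample_id,
            len(peaks),
            sum(p.status == "called" for p in peaks),
            sum(p.status == "flagged" for p in peaks),
        )
        peak_sets[sample.sample_id] = peaks

    # 2) external evidence first, so it can rescue sample-private flagged peaks
    if external_sets:
        for peaks in peak_sets.values():
            external_verify(
                peaks, external_sets, config.search_distance, config.search_distance_0
            )

    # 3) cross-sample uniqueness, then reject whatever is still flagged
    unique_filter(peak_sets, config.unique_N, config.cross_sample_tolerance)
    for sample_id, peaks in peak_sets.items():
        finalize_statuses(peaks)

    # 4) randomisation-null FDR filter
    for sample_id, peaks in peak_sets.items():
        fdr_filter(
            peaks, by_id[sample_id], config.fdr_window, config.fdr_z, mode="analytic"
        )
        logger.info(
            "sample %s: %d surviving peaks",
            sample_id,
            sum(p.surviving for p in peaks),
        )

    # 5) operons from the guide sample (or supplied externally)
    guide_sample = by_id[guide]
    if external_operons is not None:
        operons = list(external_operons)
        logger.info("using %d externally supplied operons", len(operons))
    else:
        operons = build_operons(peak_sets[guide], guide_sample, config.operon_cutoff)

    results: Dict[str, SampleResult] = {}
    for sample in samples:
        peaks = peak_sets[sample.sample_id]
        # membership is per sample: reset before assigning this sample's peaks
        for operon in operons:
            operon.member_peaks = []
        unassigned = assign_peaks(peaks, operons)
        _, orphan_pairs = resolve_orphans(unassigned, operons)

        transcripts: List[Transcript] = []
        for operon in operons:
            transcripts.extend(
                enumerate_transcripts(operon, sample, config.density_threshold)
            )
        transcripts.extend(orphan_pair_transcripts(orphan_pairs))
        for t in transcripts:
            t.source_samples.add(sample.sample_id)

        # hybrid completion for peaks that ended up in no transcript
        if old_annotation is not None:
            used: set = set()
            for t in transcripts:
                used.add((t.strand, "start", t.five_prime))
                used.add((t.strand, "stop", t.three_prime))
            partnerless = [
                p
                for p in peaks
                if p.surviving and (p.strand, p.kind, p.position) not in used
            ]
            hybrids = make_hybrids(partnerless, old_annotation)
            for t in hybrids:
                t.source_samples.add(sample.sample_id)
            transcripts.extend(hybrids)

        assign_isoform_groups(transcripts)

        subrecords: Dict[int, List[AnnotationRecord]] = {}
        if old_annotation is not None:
            contained = transfer_features(transcripts, old_annotation)
            cds_transcripts = [
                t for t in transcripts if t.feature == CDS and id(t) in contained
            ]

            def srna_class_of(t: Transcript) -> str:
                return classify_srna(
                    t,
                    old_annotation,
                    partners=isoform_partners(t, transcripts),
                    operons=operons,
                    cds_transcripts=cds_transcripts,
                )

            for t in transcripts:
                if t.feature == CDS:
                    if id(t) in contained:
                        try:
                            subrecords[id(t)] = subcategorize_cds(t, contained[id(t)])
                        except CdsConsistencyError as exc:
                            logger.warning("demoting transcript: %s", exc)
                            t.feature = GENERIC
                    else:
                        # partial ORF overlap: a truncated transcript covering
                        # the start codon but not the stop codon is a putative
                        # sRNA; 3'-portion overlaps keep the CDS label
                        klass = srna_class_of(t)
                        if klass == PUTATIVE_SRNA:
                            t.feature = "putative_sRNA"
                            t.attributes["srna_class"] = klass
                elif t.feature in ("sRNA", NOVEL):
                    t.attributes["srna_class"] = srna_class_of(t)
        else:
            for t in transcripts:
                t.feature = t.feature or "transcript"

        logger.info(
            "sample %s: %d operon-derived transcripts", sample.sample_id, len(transcripts)
        )
        results[sample.sample_id] = SampleResult(
            sample=sample,
            peaks=peaks,
            transcripts=transcripts,
            subrecords=subrecords,
        )

    return PipelineResult(samples=results, operons=operons, guide=guide, config=config)


def coverage_report(
    peaks: Iterable[Peak], reference_operons: Sequence[Operon]
) -> Optional[float]:
    """Fraction of surviving peaks falling inside same-strand reference
    operons; None when there are no surviving peaks."""
    surviving = [p for p in peaks if p.surviving]
    if not surviving:
        return None
    inside = sum(
        1
        for p in surviving
        if any(o.contains(p.position, p.strand) for o in reference_operons)
    )
    return inside / len(surviving)


def read_density_report(sample: RendSample) -> float:
    """Genome-wide read density: non-zero values on all four tracks divided
    by the genome length."""
    nonzero = sum(len(track.counts) for track in sample.tracks.values())
    return nonzero / sample.genome_length


def _dedup_key(record: Gff3Record) -> Tuple:
    return (record.start, record.end, record.strand, record.feature)


def _sample_records(
    result: SampleResult, strict_phase: bool = False, subcategorised: bool = False
) -> List[Gff3Record]:
    records: List[Gff3Record] = []
    counter = 0
    for t in sorted(result.transcripts, key=lambda t: (t.left, t.right, t.strand)):
        counter += 1
        rid = f"{result.sample.sample_id}_t{counter:05d}"
        if subcategorised and id(t) in result.subrecords:
            for j, sub in enumerate(result.subrecords[id(t)], start=1):
                attributes = {"ID": f"{rid}.{j}", "Parent": rid}
                if sub.name:
                    attributes["Name"] = sub.name
                records.append(
                    Gff3Record(
                        seqid="genome",
                        source="rendannot",
                        feature=sub.feature,
                        start=sub.left,
                        end=sub.right,
                        score=".",
                        strand=sub.strand,
                        phase=".",
                        attributes=attributes,
                    )
                )
        else:
            records.append(
                transcript_record(t, rid, strict_phase=strict_phase)
            )
    return records


def write_products(
    result: PipelineResult,
    outdir,
    old_annotation: Optional[Sequence[AnnotationRecord]] = None,
    fmt: str = "gff3",
    output_all: bool = False,
    strict_phase: bool = False,
) -> List[Path]:
    """Write the pipeline's annotation products.

    Per sample: a transcript-configurations file and a subcategorised file
    (CDS transcripts tiled into UTRs and coding sequence).  Across
    samples: ``All_conditions`` (deduplicated union) and
    ``supplied_with_AA`` (union plus prior-annotation records for genes
    with no overlapping transcript).  With ``output_all`` a per-position
    z-score table is emitted per sample.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    suffix = "gtf" if fmt == "gtf" else "gff3"
    writer = write_gtf if fmt == "gtf" else write_gff3
    written: List[Path] = []

    union: List[Gff3Record] = []
    seen = set()
    for sample_id, sample_result in result.samples.items():
        configurations = _sample_records(sample_result, strict_phase)
        path = outdir / f"{sample_id}_transcripts.{suffix}"
        writer(configurations, path)
        written.append(path)
        sub = _sample_records(sample_result, strict_phase, subcategorised=True)
        path = outdir / f"{sample_id}_subcategorised.{suffix}"
        writer(sub, path)
        written.append(path)
        for record in configurations:
            key = _dedup_key(record)
            if key not in seen:
                seen.add(key)
                union.append(record)
        if output_all:
            table = pd.DataFrame(
                [
                    {
                        "position": p.position,
                        "strand": p.strand,
                        "kind": p.kind,
                        "value": p.value,
                        "z_large": p.z_large,
                        "z_small": p.z_small_win,
                        "status": p.status,
                        "evidence": ",".join(sorted(p.evidence)),
                    }
                    for p in sample_result.peaks
                ]
            )
            path = outdir / f"{sample_id}_zscores.tsv"
            table.to_csv(path, sep="\t", index=False)
            written.append(path)

    union.sort(key=lambda r: (r.start, r.end, r.strand, r.feature))
    path = outdir / f"All_conditions.{suffix}"
    writer(union, path)
    written.append(path)

    supplied = list(union)
    if old_annotation is not None:
        transcripts = result.all_transcripts
        for i, record in enumerate(old_annotation, start=1):
            covered = any(
                t.overlaps(record.left, record.right, record.strand)
                for t in transcripts
            )
            if not covered:
                attributes = {"ID": f"AA_{i:05d}"}
                if record.name:
                    attributes["Name"] = record.name
                supplied.append(
                    Gff3Record(
                        seqid="genome",
                        source="alternative_annotation",
                        feature=record.feature,
                        start=record.left,
                        end=record.right,
                        score=".",
                        strand=record.strand,
                        phase=".",
                        attributes=attributes,
                    )
                )
        supplied.sort(key=lambda r: (r.start, r.end, r.strand, r.feature))
    path = outdir / f"supplied_with_AA.{suffix}"
    writer(supplied, path)
    written.append(path)
    return written
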