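"""Feature transfer from an existing genome annotation.

Assembled transcripts are labelled against an older annotation (GFF3, e.g.
converted from GenBank): a transcript that fully contains at least one
coding sequence becomes a CDS transcript and inherits the gene names; a
transcript overlapping a single feature class inherits that class;
overlap with several distinct classes yields the generic label
"transcript"; and no overlap at all yields "novel_transcript".  Antisense
(opposite-strand) overlap counts as no overlap.  CDS transcripts are then
tiled into 5'UTR / CDS / 3'UTR sub-records, and non-coding transcripts are
subclassified into sRNA origin classes (UTR-derived, intergenic or
intragenic, independent with or without isoforms, putative sRNA).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import gffutils
from intervaltree import IntervalTree

from .operons import Operon
from .transcripts import Transcript

logger = logging.getLogger(__name__)

CDS = "CDS"
NOVEL = "novel_transcript"
GENERIC = "transcript"
FIVE_UTR = "five_prime_UTR"
THREE_UTR = "three_prime_UTR"

#: structural RNA classes that must never be re-labelled as sRNA
STRUCTURAL_RNA = frozenset({"rRNA", "tRNA", "tmRNA"})
#: record types ignored when transferring features (containers, not genes)
IGNORED_FEATURES = frozenset({"operon", "region", "gene", "source"})

# sRNA origin classes
FIVE_UTR_DERIVED = "five_utr_derived"
THREE_UTR_DERIVED = "three_utr_derived"
INTERGENIC = "intergenic"
INTRAGENIC = "intragenic"
INDEPENDENT_WITH_ISOFORM = "independent_with_isoform"
INDEPENDENT_WITHOUT_ISOFORM = "independent_without_isoform"
PUTATIVE_SRNA = "putative_srna"

SRNA_CLASSES = (
    FIVE_UTR_DERIVED,
    THREE_UTR_DERIVED,
    INTERGENIC,
    INTRAGENIC,
    INDEPENDENT_WITH_ISOFORM,
    INDEPENDENT_WITHOUT_ISOFORM,
    PUTATIVE_SRNA,
)


class CdsConsistencyError(ValueError):
    """A contained CDS extends beyond its transcript span."""


@dataclass
class AnnotationRecord:
    """One feature of an existing annotation."""

    left: int
    right: int
    strand: str
    feature: str
    name: str = ""
    attributes: Dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.left > self.right:
            raise ValueError("record left must not exceed right")
        if not self.feature:
            raise ValueError("feature must be non-empty")

    @property
    def length(self) -> int:
        return self.right - self.left + 1


def read_annotation(path) -> List[AnnotationRecord]:
    """Parse a GFF3 annotation into AnnotationRecords (gffutils line parser)."""
    records = []
    with open(path) as handle:
        for raw in handle:
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            feature = gffutils.feature.feature_from_line(line)
            attrs = {k: ",".join(v) for k, v in feature.attributes.items()}
            name = attrs.get("Name") or attrs.get("gene") or attrs.get("ID", "")
            records.append(
                AnnotationRecord(
                    left=feature.start,
                    right=feature.end,
                    strand=feature.strand,
                    feature=feature.featuretype,
                    name=name,
                    attributes=attrs,
                )
            )
    return records


def _record_tree(records: Iterable[AnnotationRecord]) -> Dict[str, IntervalTree]:
    trees: Dict[str, IntervalTree] = {"+": IntervalTree(), "-": IntervalTree()}
    for record in records:
        if record.feature in IGNORED_FEATURES:
            continue
        trees[record.strand][record.left : record.right + 1] = record
    return trees


def overlapping_records(
    transcript: Transcript, trees: Dict[str, IntervalTree]
) -> List[AnnotationRecord]:
    hits = trees[transcript.strand][transcript.left : transcript.right + 1]
    return sorted((iv.data for iv in hits), key=lambda r: (r.left, r.right))


def transfer_features(
    transcripts: Sequence[Transcript],
    old_annotation: Sequence[AnnotationRecord],
) -> Dict[int, List[AnnotationRecord]]:
    """Label every transcript from the old annotation (same-strand overlap).

    Returns a map from ``id(transcript)`` to the CDS records the transcript
    fully contains, for use by :func:`subcategorize_cds`.
    """
    trees = _record_tree(old_annotation)
    contained_map: Dict[int, List[AnnotationRecord]] = {}
    for transcript in transcripts:
        overlaps = overlapping_records(transcript, trees)
        contained_cds = [
            r
            for r in overlaps
            if r.feature == CDS
            and transcript.left <= r.left
            and r.right <= transcript.right
        ]
        if contained_cds:
            transcript.feature = CDS
            names = [r.name for r in contained_cds if r.name]
            if names:
                transcript.attributes["Name"] = ",".join(names)
            contained_map[id(transcript)] = contained_cds
            continue
        classes = sorted({r.feature for r in overlaps})
        if not classes:
            transcript.feature = NOVEL
        elif len(classes) == 1:
            transcript.feature = classes[0]
            names = [r.name for r in overlaps if r.name]
            if names:
                transcript.attributes["Name"] = ",".join(dict.fromkeys(names))
        else:
            transcript.feature = GENERIC
    return contained_map


def subcategorize_cds(
    transcript: Transcript,
    contained_cds: Sequence[AnnotationRecord],
) -> List[AnnotationRecord]:
    """Tile a CDS transcript into 5'UTR, CDS(s) and 3'UTR records.

    UTRs run from the transcript boundary to the outermost CDS edge on
    each side (in transcription orientation); zero-length UTRs are
    omitted.  Intercistronic gaps of polycistronic transcripts stay inside
    the CDS block.  A CDS reaching beyond the transcript raises
    :class:`CdsConsistencyError` (callers demote such transcripts to the
    generic label).
    """
    if not contained_cds:
        raise ValueError("subcategorize_cds needs at least one contained CDS")
    for record in contained_cds:
        if record.left < transcript.left or record.right > transcript.right:
            raise CdsConsistencyError(
                f"CDS {record.name or record.left} extends beyond transcript span"
            )
    ordered = sorted(contained_cds, key=lambda r: r.left)
    first_left = ordered[0].left
    last_right = ordered[-1].right
    out: List[AnnotationRecord] = []

    def utr(left: int, right: int, which: str) -> Optional[AnnotationRecord]:
        if left > right:
            return None
        return AnnotationRecord(
            left=left, right=right, strand=transcript.strand, feature=which,
            name=transcript.attributes.get("Name", ""),
        )

    if transcript.strand == "+":
        five = utr(transcript.left, first_left - 1, FIVE_UTR)
        three = utr(last_right + 1, transcript.right, THREE_UTR)
    else:
        five = utr(last_right + 1, transcript.right, FIVE_UTR)
        three = utr(transcript.left, first_left - 1, THREE_UTR)
    if five:
        out.append(five)
    out.extend(
        AnnotationRecord(
            left=r.left, right=r.right, strand=transcript.strand,
            feature=CDS, name=r.name, attributes=dict(r.attributes),
        )
        for r in ordered
    )
    if three:
        out.append(three)
    return out


def _cds_start_codon(record: AnnotationRecord) -> Tuple[int, int]:
    """Genomic span of the start codon of a CDS record."""
    if record.strand == "+":
        return record.left, min(record.left + 2, record.right)
    return max(record.right - 2, record.left), record.right


def _ends_before(transcript: Transcript, coordinate: int) -> bool:
    """True when the transcript's 3' end lies strictly upstream of
    ``coordinate`` in transcription direction."""
    if transcript.strand == "+":
        return transcript.three_prime < coordinate
    return transcript.three_prime > coordinate


def _begins_after(transcript: Transcript, coordinate: int) -> bool:
    if transcript.strand == "+":
        return transcript.five_prime > coordinate
    return transcript.five_prime < coordinate


def classify_srna(
    transcript: Transcript,
    old_annotation: Sequence[AnnotationRecord],
    partners: Sequence[Transcript] = (),
    operons: Sequence[Operon] = (),
    cds_transcripts: Sequence[Transcript] = (),
) -> str:
    """Assign one sRNA origin class to a non-coding transcript.

    ``partners`` are transcripts sharing a terminus with this one
    (isoforms); ``cds_transcripts`` are the CDS-labelled transcripts of the
    run, used to recognise UTR-derived species that share an mRNA
    terminus.  Classes, in decision order:

    * ``putative_srna`` — covers an annotated start codon but terminates
      before that gene's stop codon (may encode a truncated/alternative
      peptide);
    * ``five_utr_derived`` / ``three_utr_derived`` — shares an mRNA's 5'
      (resp. 3') terminus while staying clear of the coding region's far
      boundary;
    * ``intragenic`` / ``intergenic`` — inside an operon, within (resp.
      between) coding genes;
    * ``independent_with_isoform`` / ``independent_without_isoform`` —
      outside any coding context, split by the presence of isoform
      partners.
    """
    cds_records = [
        r
        for r in old_annotation
        if r.feature == CDS and r.strand == transcript.strand
    ]

    for record in cds_records:
        codon_left, codon_right = _cds_start_codon(record)
        covers_codon = (
            transcript.left <= codon_left and codon_right <= transcript.right
        )
        stop_coord = record.right if record.strand == "+" else record.left
        if covers_codon and _ends_before(transcript, stop_coord):
            return PUTATIVE_SRNA

    for mrna in cds_transcripts:
        if mrna.strand != transcript.strand:
            continue
        contained = [
            r for r in cds_records if mrna.left <= r.left and r.right <= mrna.right
        ]
        if not contained:
            continue
        if mrna.strand == "+":
            cds_stop = max(r.right for r in contained)
            cds_start = min(r.left for r in contained)
        else:
            cds_stop = min(r.left for r in contained)
            cds_start = max(r.right for r in contained)
        if transcript.five_prime == mrna.five_prime and _ends_before(
            transcript, cds_stop
        ):
            return FIVE_UTR_DERIVED
        if transcript.three_prime == mrna.three_prime and _begins_after(
            transcript, cds_start
        ):
            return THREE_UTR_DERIVED

    inside_operon = any(
        o.strand == transcript.strand
        and o.left <= transcript.left
        and transcript.right <= o.right
        for o in operons
    )
    if inside_operon:
        for record in cds_records:
            if record.left <= transcript.left and transcript.right <= record.right:
                return INTRAGENIC
        overlaps_cds = any(
            not (transcript.right < r.left or transcript.left > r.right)
            for r in cds_records
        )
        if not overlaps_cds:
            return INTERGENIC

    if partners:
        return INDEPENDENT_WITH_ISOFORM
    return INDEPENDENT_WITHOUT_ISOFORM
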