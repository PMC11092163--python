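"""GFF3/GTF emission and re-ingestion of pipeline products.

Hybrid annotations (one terminus borrowed from a prior annotation) are
marked with the value 0 in the phase column and carry a Note naming the
coordinate that has single-nucleotide resolution; all other rows use
phase '.'.  Because phase is ordinarily reserved for CDS rows, a strict
mode keeps the phase column '.' and confines the hybrid mark to the Note
attribute for downstream tools that validate GFF3 rigidly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Sequence

from .transcripts import Transcript

GFF3_HEADER = "##gff-version 3"

#: attribute keys emitted first, in this order; any others follow sorted
_ATTRIBUTE_ORDER = ("ID", "Name", "Note")

_ESCAPES = {
    "%": "%25",
    ";": "%3B",
    "=": "%3D",
    "&": "%26",
    ",": "%2C",
    "\t": "%09",
    "\n": "%0A",
}


def escape_attribute(value: str) -> str:
    for raw, enc in _ESCAPES.items():
        value = value.replace(raw, enc)
    return value


def unescape_attribute(value: str) -> str:
    for raw, enc in reversed(_ESCAPES.items()):
        value = value.replace(enc, raw)
    return value


@dataclass
class Gff3Record:
    """One GFF3 row."""

    seqid: str
    source: str
    feature: str
    start: int
    end: int
    score: str
    strand: str
    phase: str
    attributes: Dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError("start must not exceed end")
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"bad strand {self.strand!r}")

    def attribute_string(self) -> str:
        keys = [k for k in _ATTRIBUTE_ORDER if k in self.attributes]
        keys += sorted(k for k in self.attributes if k not in _ATTRIBUTE_ORDER)
        return ";".join(f"{k}={escape_attribute(self.attributes[k])}" for k in keys)

    def line(self) -> str:
        return "\t".join(
            [
                self.seqid,
                self.source,
                self.feature,
                str(self.start),
                str(self.end),
                self.score,
                self.strand,
                self.phase,
                self.attribute_string(),
            ]
        )


def write_gff3(records: Iterable[Gff3Record], path) -> None:
    with open(path, "w") as handle:
        handle.write(GFF3_HEADER + "\n")
        for record in records:
            handle.write(record.line() + "\n")


def read_gff3(path) -> List[Gff3Record]:
    records = []
    with open(path) as handle:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise ValueError(f"line {lineno}: expected 9 columns, got {len(cols)}")
            attributes = {}
            if cols[8] and cols[8] != ".":
                for token in cols[8].split(";"):
                    if not token:
                        continue
                    key, _, value = token.partition("=")
                    attributes[key] = unescape_attribute(value)
            records.append(
                Gff3Record(
                    seqid=cols[0],
                    source=cols[1],
                    feature=cols[2],
                    start=int(cols[3]),
                    end=int(cols[4]),
                    score=cols[5],
                    strand=cols[6],
                    phase=cols[7],
                    attributes=attributes,
                )
            )
    return records


def transcript_record(
    transcript: Transcript,
    record_id: str,
    seqid: str = "genome",
    source: str = "rendannot",
    strict_phase: bool = False,
) -> Gff3Record:
    """Render a Transcript as a GFF3 row (hybrid mark in the phase column
    unless ``strict_phase``)."""
    attributes = {"ID": record_id}
    attributes.update(transcript.attributes)
    if transcript.isoform_group is not None:
        attributes.setdefault("isoform_group", str(transcript.isoform_group))
    if transcript.source_samples:
        attributes.setdefault("samples", ",".join(sorted(transcript.source_samples)))
    phase = "."
    if transcript.hybrid and not strict_phase:
        phase = "0"
    return Gff3Record(
        seqid=seqid,
        source=source,
        feature=transcript.feature or "transcript",
        start=transcript.left,
        end=transcript.right,
        score=".",
        strand=transcript.strand,
        phase=phase,
        attributes=attributes,
    )


def write_gtf(records: Sequence[Gff3Record], path) -> None:
    """Write records as GTF: gene/transcript/exon triplets, one exon per
    transcript (bacterial, unspliced)."""
    with open(path, "w") as handle:
        for record in records:
            rid = record.attributes.get("ID", f"{record.feature}_{record.start}")
            gene_id = record.attributes.get("Name", rid)
            common = (
                f'gene_id "{gene_id}"; transcript_id "{rid}";'
            )
            for level in ("gene", "transcript", "exon"):
                handle.write(
                    "\t".join(
                        [
                            record.seqid,
                            record.source,
                            level,
                            str(record.start),
                            str(record.end),
                            record.score,
                            record.strand,
                            record.phase,
                            common,
                        ]
                    )
                    + "\n"
                )
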