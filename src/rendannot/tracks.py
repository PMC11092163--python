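"""Strand-specific end-count (wig) tracks for Rend-seq samples.

A Rend-seq sample is summarised by four genome-wide tracks counting read
termini per nucleotide: 5' ends and 3' ends on each strand.  Because true
transcript boundaries appear as single-nucleotide count spikes over a sparse
fragmentation background, tracks are modelled as sparse position -> count
maps; querying an absent position returns 0.

Coordinates are 1-based inclusive throughout (wig/GFF3 convention).  Counts
are stored as floats so that depth-normalised wig files are accepted
unchanged; zero-valued records are dropped on read.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterator, Mapping, Tuple

import numpy as np

FIVE_PRIME = "five_prime"
THREE_PRIME = "three_prime"
ENDS = (FIVE_PRIME, THREE_PRIME)
STRANDS = ("+", "-")

#: the four (strand, end) slots every sample must fill
TRACK_SLOTS: Tuple[Tuple[str, str], ...] = tuple(
    (strand, end) for strand in STRANDS for end in ENDS
)


class WigParseError(ValueError):
    """A wig body line could not be interpreted."""


class CoordinateError(ValueError):
    """A position lies outside [1, genome_length]."""


class ConfigurationError(ValueError):
    """A sample manifest is incomplete or inconsistent."""


@dataclass
class EndTrack:
    """One (strand, end-type) end-count vector over a genome.

    Parameters
    ----------
    strand : '+' or '-'
    end : 'five_prime' or 'three_prime'
    genome_length : int
        Chromosome length in nucleotides.
    counts : dict
        Sparse 1-based position -> count map; absent positions read as 0.
    """

    strand: str
    end: str
    genome_length: int
    counts: Dict[int, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.strand not in STRANDS:
            raise ValueError(f"strand must be one of {STRANDS}, got {self.strand!r}")
        if self.end not in ENDS:
            raise ValueError(f"end must be one of {ENDS}, got {self.end!r}")
        if self.genome_length < 1:
            raise ValueError("genome_length must be positive")
        for pos, value in self.counts.items():
            if not 1 <= pos <= self.genome_length:
                raise CoordinateError(
                    f"position {pos} outside [1, {self.genome_length}]"
                )
            if value < 0:
                raise ValueError(f"negative count {value} at position {pos}")

    def __getitem__(self, pos: int) -> float:
        return self.counts.get(pos, 0.0)

    def __len__(self) -> int:
        return len(self.counts)

    def positions(self) -> Iterator[int]:
        return iter(sorted(self.counts))

    def to_array(self) -> np.ndarray:
        """Dense float array of length genome_length + 1; index 0 unused."""
        arr = np.zeros(self.genome_length + 1)
        if self.counts:
            pos = np.fromiter(self.counts.keys(), dtype=np.int64, count=len(self.counts))
            val = np.fromiter(self.counts.values(), dtype=float, count=len(self.counts))
            arr[pos] = val
        return arr

    def total(self) -> float:
        return float(sum(self.counts.values()))


@dataclass
class RendSample:
    """One Rend-seq sample: four end-count tracks plus metadata."""

    sample_id: str
    condition: str
    genome_length: int
    tracks: Dict[Tuple[str, str], EndTrack]

    def __post_init__(self) -> None:
        missing = [slot for slot in TRACK_SLOTS if slot not in self.tracks]
        if missing:
            raise ConfigurationError(f"missing track slots: {missing}")
        for slot, track in self.tracks.items():
            if (track.strand, track.end) != slot:
                raise ConfigurationError(
                    f"track in slot {slot} labelled ({track.strand}, {track.end})"
                )
            if track.genome_length != self.genome_length:
                raise ConfigurationError(
                    f"track {slot} has genome_length {track.genome_length}, "
                    f"sample says {self.genome_length}"
                )

    def track(self, strand: str, end: str) -> EndTrack:
        return self.tracks[(strand, end)]


def _format_count(value: float) -> str:
    """Render a count; integral values print without a decimal point."""
    if float(value).is_integer():
        return str(int(value))
    return repr(float(value))


def read_end_track(
    path, strand: str, end: str, genome_length: int
) -> EndTrack:
    """Parse a wig file (variableStep or fixedStep body) into an EndTrack.

    Zero-valued records are dropped; positions outside the genome raise
    :class:`CoordinateError`; malformed lines raise :class:`WigParseError`
    naming the offending line number.
    """
    counts: Dict[int, float] = {}
    mode = None  # None | 'variable' | 'fixed'
    fixed_pos = 0
    fixed_step = 1
    with open(path) as handle:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            if line.startswith("variableStep"):
                mode = "variable"
                _check_span(line, lineno)
                continue
            if line.startswith("fixedStep"):
                mode = "fixed"
                fields = _header_fields(line, lineno)
                _check_span(line, lineno)
                try:
                    fixed_pos = int(fields["start"])
                except (KeyError, ValueError):
                    raise WigParseError(f"line {lineno}: fixedStep needs start=<int>")
                fixed_step = int(fields.get("step", 1))
                if fixed_step < 1:
                    raise WigParseError(f"line {lineno}: step must be >= 1")
                continue
            if mode is None:
                raise WigParseError(
                    f"line {lineno}: data before variableStep/fixedStep header"
                )
            parts = line.split()
            if mode == "variable":
                if len(parts) != 2:
                    raise WigParseError(
                        f"line {lineno}: expected 'position value', got {line!r}"
                    )
                try:
                    pos, value = int(parts[0]), float(parts[1])
                except ValueError:
                    raise WigParseError(f"line {lineno}: cannot parse {line!r}")
            else:
                if len(parts) != 1:
                    raise WigParseError(
                        f"line {lineno}: expected a single value, got {line!r}"
                    )
                try:
                    value = float(parts[0])
                except ValueError:
                    raise WigParseError(f"line {lineno}: cannot parse {line!r}")
                pos = fixed_pos
                fixed_pos += fixed_step
            if not 1 <= pos <= genome_length:
                raise CoordinateError(
                    f"line {lineno}: position {pos} outside [1, {genome_length}]"
                )
            if value != 0:
                counts[pos] = value
    return EndTrack(strand=strand, end=end, genome_length=genome_length, counts=counts)


def _header_fields(line: str, lineno: int) -> Dict[str, str]:
    fields = {}
    for token in line.split()[1:]:
        if "=" not in token:
            raise WigParseError(f"line {lineno}: malformed header token {token!r}")
        key, _, value = token.partition("=")
        fields[key] = value
    return fields


def _check_span(line: str, lineno: int) -> None:
    fields = _header_fields(line, lineno)
    if int(fields.get("span", 1)) != 1:
        raise WigParseError(f"line {lineno}: only span=1 wig files are supported")


def write_end_track(track: EndTrack, path, chrom: str = "genome") -> None:
    """Write an EndTrack as a variableStep wig file (sorted, sparse)."""
    with open(path, "w") as handle:
        handle.write("track type=wiggle_0\n")
        handle.write(f"variableStep chrom={chrom}\n")
        for pos in sorted(track.counts):
            handle.write(f"{pos} {_format_count(track.counts[pos])}\n")


def load_sample(
    manifest: Mapping[Tuple[str, str], "str | Path"],
    sample_id: str,
    condition: str,
    genome_length: int,
) -> RendSample:
    """Load the four wig files named in ``manifest`` into a RendSample.

    ``manifest`` maps each (strand, end) slot to a wig path; all four slots
    are required.
    """
    missing = [slot for slot in TRACK_SLOTS if slot not in manifest]
    if missing:
        raise ConfigurationError(f"manifest missing slots: {missing}")
    tracks = {
        (strand, end): read_end_track(manifest[(strand, end)], strand, end, genome_length)
        for strand, end in TRACK_SLOTS
    }
    return RendSample(
        sample_id=sample_id,
        condition=condition,
        genome_length=genome_length,
        tracks=tracks,
    )


def load_manifest(path) -> list:
    """Load RendSamples from a JSON manifest file.

    Layout::

        {"samples": [
            {"sample_id": "wt", "condition": "LB", "genome_length": 100000,
             "tracks": {"+": {"five_prime": "...wig", "three_prime": "...wig"},
                        "-": {"five_prime": "...wig", "three_prime": "...wig"}}},
            ...]}

    Relative wig paths are resolved against the manifest's directory.
    """
    path = Path(path)
    with open(path) as handle:
        manifest_data = json.load(handle)
    samples = []
    for entry in manifest_data["samples"]:
        mapping = {}
        for strand in STRANDS:
            for end in ENDS:
                try:
                    wig = entry["tracks"][strand][end]
                except KeyError:
                    raise ConfigurationError(
                        f"sample {entry.get('sample_id')}: missing track {strand}/{end}"
                    )
                wig = Path(wig)
                if not wig.is_absolute():
                    wig = path.parent / wig
                mapping[(strand, end)] = wig
        samples.append(
            load_sample(
                mapping,
                sample_id=entry["sample_id"],
                condition=entry.get("condition", ""),
                genome_length=int(entry["genome_length"]),
            )
        )
    return samples
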