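"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import math
from typing import Dict, Tuple

import numpy as np
import pytest

from rendannot.tracks import EndTrack, RendSample, TRACK_SLOTS


def make_track(
    counts: Dict[int, float],
    genome_length: int,
    strand: str = "+",
    end: str = "five_prime",
) -> EndTrack:
    return EndTrack(strand=strand, end=end, genome_length=genome_length, counts=dict(counts))


def make_sample(
    genome_length: int,
    counts: Dict[Tuple[str, str], Dict[int, float]] | None = None,
    sample_id: str = "s1",
    condition: str = "test",
) -> RendSample:
    counts = counts or {}
    tracks = {
        (strand, end): make_track(counts.get((strand, end), {}), genome_length, strand, end)
        for strand, end in TRACK_SLOTS
    }
    return RendSample(
        sample_id=sample_id, condition=condition, genome_length=genome_length, tracks=tracks
    )


def oracle_window(
    strand: str, pos: int, size: int, direction: str, genome_length: int
) -> list:
    """Explicit enumeration of the scoring-window positions (focal excluded)."""
    rightward = (direction == "downstream") == (strand == "+")
    if rightward:
        positions = range(pos + 1, pos + size + 1)
    else:
        positions = range(pos - size, pos)
    return [p for p in positions if 1 <= p <= genome_length]


def oracle_mean_sd(counts: Dict[int, float], positions) -> Tuple[float, float, int]:
    """Brute-force mean and population sd with absent positions as zeros."""
    values = [counts.get(p, 0.0) for p in positions]
    n = len(values)
    if n == 0:
        return 0.0, 0.0, 0
    mean = sum(values) / n
    var = sum((v - mean) ** 2 for v in values) / n
    return mean, math.sqrt(var), n


def oracle_z(
    counts: Dict[int, float],
    strand: str,
    pos: int,
    size: int,
    direction: str,
    genome_length: int,
    sd_floor: float = 1.0,
) -> float:
    positions = oracle_window(strand, pos, size, direction, genome_length)
    mean, sd, _ = oracle_mean_sd(counts, positions)
    return (counts.get(pos, 0.0) - mean) / max(sd, sd_floor)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240426)


@pytest.fixture
def empty_sample() -> RendSample:
    return make_sample(1000)
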