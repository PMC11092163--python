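"""Read density, operon segmentation and peak-to-operon assignment."""

from __future__ import annotations

import pytest

from rendannot.operons import (
    Operon,
    assign_peaks,
    build_operons,
    read_density,
    resolve_orphans,
)
from rendannot.peaks import CALLED, Peak

from conftest import make_sample


def _peak(position, kind, strand="+", value=50.0):
    return Peak(
        position=position, strand=strand, kind=kind, value=value,
        z_large=20.0, z_small_win=20.0, status=CALLED,
    )


def _dense_counts(a, b, value=2.0):
    return {p: value for p in range(a, b + 1)}


class TestReadDensity:
    def test_all_zero_region_is_zero(self, empty_sample):
        assert read_density(empty_sample, "+", 1, 100) == 0.0

    def test_mixed_counts_match_hand_count(self):
        sample = make_sample(
            100,
            {
                ("+", "five_prime"): {p: 1.0 for p in (11, 12, 13, 14)},
                ("+", "three_prime"): {p: 1.0 for p in (11, 13, 15, 17, 19, 20)},
            },
        )
        # 4 non-zero 5' + 6 non-zero 3' over a 10-nt region -> 10 / 20
        assert read_density(sample, "+", 11, 20) == pytest.approx(0.5)

    def test_saturated_region_is_one(self):
        sample = make_sample(
            50,
            {
                ("-", "five_prime"): _dense_counts(1, 50),
                ("-", "three_prime"): _dense_counts(1, 50),
            },
        )
        assert read_density(sample, "-", 1, 50) == 1.0

    def test_matches_counting_oracle_on_random_regions(self, rng):
        length = 2000
        five = {int(p): 1.0 for p in rng.choice(length, 600, replace=False) + 1}
        three = {int(p): 1.0 for p in rng.choice(length, 300, replace=False) + 1}
        sample = make_sample(length, {("+", "five_prime"): five, ("+", "three_prime"): three})
        for _ in range(100):
            a = int(rng.integers(1, length))
            b = int(rng.integers(a, length + 1))
            oracle = (
                sum(1 for p in range(a, b + 1) if p in five)
                + sum(1 for p in range(a, b + 1) if p in three)
            ) / (2 * (b - a + 1))
            assert read_density(sample, "+", a, b) == oracle


def _two_block_sample():
    """Two dense blocks 100-500 and 700-1100 separated by a bare gap."""
    counts5 = {**_dense_counts(100, 500), **_dense_counts(700, 1100)}
    counts3 = dict(counts5)
    return make_sample(
        1500,
        {("+", "five_prime"): counts5, ("+", "three_prime"): counts3},
    )


class TestBuildOperons:
    def test_single_covered_span_gives_one_operon(self):
        sample = make_sample(
            1000,
            {
                ("+", "five_prime"): _dense_counts(100, 500),
                ("+", "three_prime"): _dense_counts(100, 500),
            },
        )
        peaks = [_peak(100, "start"), _peak(500, "stop")]
        operons = build_operons(peaks, sample, 0.8)
        assert [(o.left, o.right) for o in operons] == [(100, 500)]
        assert operons[0].density > 0.8

    def test_zero_coverage_pair_gives_no_operon(self, empty_sample):
        peaks = [_peak(100, "start"), _peak(500, "stop")]
        assert build_operons(peaks, empty_sample, 0.8) == []

    def test_coverage_collapse_closes_operon_at_internal_stop(self):
        sample = _two_block_sample()
        peaks = [
            _peak(100, "start"),
            _peak(500, "stop"),
            _peak(700, "start"),
            _peak(1100, "stop"),
        ]
        operons = build_operons(peaks, sample, 0.8)
        assert [(o.left, o.right) for o in operons] == [(100, 500), (700, 1100)]

    def test_continuous_coverage_extends_across_internal_stop(self):
        counts = _dense_counts(100, 1100)
        sample = make_sample(
            1500,
            {("+", "five_prime"): counts, ("+", "three_prime"): dict(counts)},
        )
        peaks = [
            _peak(100, "start"),
            _peak(500, "stop"),
            _peak(520, "start"),
            _peak(1100, "stop"),
        ]
        operons = build_operons(peaks, sample, 0.8)
        assert [(o.left, o.right) for o in operons] == [(100, 1100)]

    def test_minus_strand_spans(self):
        sample = make_sample(
            1000,
            {
                ("-", "five_prime"): _dense_counts(100, 500),
                ("-", "three_prime"): _dense_counts(100, 500),
            },
        )
        peaks = [_peak(500, "start", strand="-"), _peak(100, "stop", strand="-")]
        operons = build_operons(peaks, sample, 0.8)
        assert [(o.left, o.right, o.strand) for o in operons] == [(100, 500, "-")]

    def test_spans_disjoint_per_strand(self):
        sample = _two_block_sample()
        peaks = [
            _peak(100, "start"), _peak(500, "stop"),
            _peak(700, "start"), _peak(1100, "stop"),
        ]
        operons = build_operons(peaks, sample, 0.8)
        for a in operons:
            for b in operons:
                if a is not b and a.strand == b.strand:
                    assert a.right < b.left or b.right < a.left


class TestAssignPeaks:
    def test_inside_span_assigned(self):
        operon = Operon(left=100, right=500, strand="+", density=0.9)
        peak = _peak(300, "start")
        unassigned = assign_peaks([peak], [operon])
        assert unassigned == []
        assert peak.operon is operon
        assert peak in operon.member_peaks

    def test_outside_and_opposite_strand_unassigned(self):
        operon = Operon(left=100, right=500, strand="+", density=0.9)
        outside = _peak(700, "start")
        antisense = _peak(300, "start", strand="-")
        unassigned = assign_peaks([outside, antisense], [operon])
        assert set(map(id, unassigned)) == {id(outside), id(antisense)}


class TestResolveOrphans:
    def test_lone_start_attaches_to_downstream_operon(self):
        operon = Operon(left=2000, right=3000, strand="+", density=0.9)
        start = _peak(1500, "start")
        assigned, pairs = resolve_orphans([start], [operon])
        assert pairs == []
        assert start.operon is operon

    def test_lone_stop_attaches_to_upstream_operon(self):
        operon = Operon(left=2000, right=3000, strand="+", density=0.9)
        stop = _peak(3500, "stop")
        assigned, pairs = resolve_orphans([stop], [operon])
        assert stop.operon is operon

    def test_orphan_pair_without_operon_in_between_forms_transcript(self):
        operon = Operon(left=50_000, right=60_000, strand="+", density=0.9)
        start, stop = _peak(10_000, "start"), _peak(10_400, "stop")
        assigned, pairs = resolve_orphans([start, stop], [operon])
        assert pairs == [(start, stop)]
        assert assigned == []

    def test_pair_spanning_an_operon_is_not_drawn(self):
        operon = Operon(left=10_100, right=10_300, strand="+", density=0.9)
        start, stop = _peak(10_000, "start"), _peak(10_400, "stop")
        assigned, pairs = resolve_orphans([start, stop], [operon])
        assert pairs == []
        assert start.operon is operon and stop.operon is operon

    def test_minus_strand_direction_respected(self):
        operon = Operon(left=2000, right=3000, strand="-", density=0.9)
        # on '-', downstream of a start means decreasing coordinates
        start = _peak(3500, "start", strand="-")
        stop = _peak(1500, "stop", strand="-")
        assigned, pairs = resolve_orphans([start, stop], [operon])
        assert pairs == []
        assert start.operon is operon and stop.operon is operon
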