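"""Dual-window z-scoring, peak calling and local-maximum pruning."""

from __future__ import annotations

import pytest
from hypothesis import given, settings, strategies as st

from rendannot.config import PipelineConfig
from rendannot.peaks import (
    CALLED,
    FLAGGED,
    Peak,
    call_peaks,
    prune_local_maxima,
    window_stats,
    z_score,
)

from conftest import make_sample, make_track, oracle_mean_sd, oracle_window, oracle_z


class TestWindowStats:
    def test_constant_track_has_zero_sd(self):
        track = make_track({p: 4.0 for p in range(1, 201)}, 200)
        mean, sd, n = window_stats(track, 100, 50, "downstream")
        assert (mean, sd, n) == (4.0, 0.0, 50)

    def test_sparse_window_matches_brute_force(self):
        # window holds [2, 2] + 48 zeros
        track = make_track({101: 2.0, 102: 2.0}, 500)
        mean, sd, n = window_stats(track, 100, 50, "downstream")
        positions = oracle_window("+", 100, 50, "downstream", 500)
        o_mean, o_sd, o_n = oracle_mean_sd(track.counts, positions)
        assert mean == pytest.approx(0.08)
        assert (mean, sd, n) == pytest.approx((o_mean, o_sd, o_n))

    def test_truncation_reported_via_n(self):
        track = make_track({}, 100)
        # only 10 in-genome positions downstream of 90
        _, _, n = window_stats(track, 90, 50, "downstream")
        assert n == 10
        assert n < 50 / 2

    def test_focal_position_excluded(self):
        track = make_track({100: 1000.0}, 500)
        mean, sd, _ = window_stats(track, 100, 50, "downstream")
        assert mean == 0.0 and sd == 0.0

    @pytest.mark.parametrize(
        "strand,direction,expected",
        [
            ("+", "downstream", list(range(101, 151))),
            ("+", "upstream", list(range(50, 100))),
            ("-", "downstream", list(range(50, 100))),
            ("-", "upstream", list(range(101, 151))),
        ],
    )
    def test_window_orientation_follows_transcription(self, strand, direction, expected):
        assert oracle_window(strand, 100, 50, direction, 500) == expected
        marker = {p: 1.0 for p in expected}
        track = make_track(marker, 500, strand=strand)
        mean, _, n = window_stats(track, 100, 50, direction)
        assert (mean, n) == (1.0, 50)


class TestZScore:
    def test_value_equal_to_mean_is_zero(self):
        assert z_score(3.0, 3.0, 2.0) == 0.0

    def test_direct_arithmetic(self):
        assert z_score(20.0, 1.0, 2.0) == pytest.approx(9.5)

    def test_floor_engages_on_flat_window(self):
        assert z_score(8.0, 0.0, 0.0, sd_floor=1.0) == 8.0


def _poisson_background_sample(rng, spike_pos=None, spike_value=100.0, length=2000):
    counts = {
        int(p): float(v)
        for p, v in enumerate(rng.poisson(1.0, length), start=1)
        if v > 0
    }
    if spike_pos is not None:
        counts[spike_pos] = spike_value
    return make_sample(length, {("+", "five_prime"): counts})


class TestCallPeaks:
    def test_all_zero_sample_yields_nothing(self, empty_sample):
        assert call_peaks(empty_sample) == []

    def test_single_spike_called_with_oracle_z(self, rng):
        sample = _poisson_background_sample(rng, spike_pos=1000)
        peaks = call_peaks(sample)
        starts = [p for p in peaks if p.position == 1000]
        assert len(starts) == 1
        peak = starts[0]
        assert peak.status == CALLED and peak.kind == "start"
        counts = sample.track("+", "five_prime").counts
        assert peak.z_large == pytest.approx(
            oracle_z(counts, "+", 1000, 50, "downstream", 2000), abs=1e-9
        )
        assert peak.z_large >= 7

    def test_band_peak_is_flagged_not_called(self):
        # large window holds a competing spike that drags z_large into the
        # 5-7 band; the small window is clean so z_small_win >= 5
        counts = {500: 10.0, 540: 12.0}
        counts.update({p: 1.0 for p in range(501, 526)})
        sample = make_sample(2000, {("+", "five_prime"): counts})
        peaks = call_peaks(sample)
        flagged = [p for p in peaks if p.position == 500]
        assert len(flagged) == 1
        peak = flagged[0]
        assert 5 <= peak.z_large < 7
        assert peak.z_small_win >= 5
        assert peak.status == FLAGGED

    def test_emitted_z_match_oracle_on_random_tracks(self, rng):
        config = PipelineConfig()
        for _ in range(30):
            length = 500
            sample_counts = {}
            for strand in "+-":
                for end in ("five_prime", "three_prime"):
                    vals = rng.poisson(0.8, length)
                    spikes = rng.choice(length, size=3, replace=False)
                    vals[spikes] += rng.poisson(30, size=3)
                    sample_counts[(strand, end)] = {
                        int(p + 1): float(v) for p, v in enumerate(vals) if v > 0
                    }
            sample = make_sample(length, sample_counts)
            for peak in call_peaks(sample, config):
                end = "five_prime" if peak.kind == "start" else "three_prime"
                direction = "downstream" if peak.kind == "start" else "upstream"
                counts = sample.track(peak.strand, end).counts
                assert peak.z_large == pytest.approx(
                    oracle_z(counts, peak.strand, peak.position, 50, direction, length),
                    abs=1e-9,
                )
                assert peak.z_small_win == pytest.approx(
                    oracle_z(counts, peak.strand, peak.position, 25, direction, length),
                    abs=1e-9,
                )

    def test_raising_thresholds_never_adds_calls(self, rng):
        sample = _poisson_background_sample(rng, spike_pos=700, spike_value=9.0)
        loose = {p.key for p in call_peaks(sample, PipelineConfig()) if p.status == CALLED}
        strict_cfg = PipelineConfig(z_start=9.0, z_stop=8.0)
        strict = {p.key for p in call_peaks(sample, strict_cfg) if p.status == CALLED}
        assert strict <= loose

    def test_strand_mirror_symmetry(self, rng):
        length = 1000
        counts = {
            int(p): float(v) for p, v in enumerate(rng.poisson(0.5, length), start=1) if v
        }
        counts[400] = 50.0
        fwd = make_sample(length, {("+", "five_prime"): counts})
        mirrored = {length + 1 - p: v for p, v in counts.items()}
        rev = make_sample(length, {("-", "five_prime"): mirrored})
        fwd_peaks = {(p.kind, p.position, p.status) for p in call_peaks(fwd)}
        rev_peaks = {(p.kind, length + 1 - p.position, p.status) for p in call_peaks(rev)}
        assert fwd_peaks == rev_peaks


def _peak(position, value, kind="start", strand="+", status=CALLED):
    return Peak(
        position=position, strand=strand, kind=kind, value=value,
        z_large=10.0, z_small_win=10.0, status=status,
    )


class TestPruning:
    def test_isolated_peak_unchanged(self):
        peaks = [_peak(100, 20.0)]
        assert prune_local_maxima(peaks, 5) == peaks

    def test_highest_within_radius_survives(self):
        kept = prune_local_maxima([_peak(100, 20.0), _peak(103, 10.0)], 5)
        assert [p.position for p in kept] == [100]

    def test_different_kinds_do_not_compete(self):
        kept = prune_local_maxima(
            [_peak(100, 20.0, kind="start"), _peak(102, 10.0, kind="stop")], 5
        )
        assert len(kept) == 2

    def test_equal_values_keep_transcript_extending_position(self):
        # starts: most upstream-in-transcription survives
        kept = prune_local_maxima([_peak(100, 5.0), _peak(103, 5.0)], 5)
        assert [p.position for p in kept] == [100]
        kept = prune_local_maxima(
            [_peak(100, 5.0, strand="-"), _peak(103, 5.0, strand="-")], 5
        )
        assert [p.position for p in kept] == [103]
        # stops: most downstream survives
        kept = prune_local_maxima(
            [_peak(100, 5.0, kind="stop"), _peak(103, 5.0, kind="stop")], 5
        )
        assert [p.position for p in kept] == [103]

    @settings(max_examples=200, deadline=None)
    @given(
        layout=st.lists(
            st.tuples(
                st.integers(min_value=1, max_value=300),
                st.integers(min_value=1, max_value=50),
                st.sampled_from(["start", "stop"]),
                st.sampled_from(["+", "-"]),
            ),
            max_size=30,
        )
    )
    def test_pruning_laws(self, layout):
        peaks = [_peak(p, float(v), kind=k, strand=s) for p, v, k, s in layout]
        kept = prune_local_maxima(peaks, 5)
        # no same-kind survivors within the radius
        for a in kept:
            for b in kept:
                if a is not b and (a.strand, a.kind) == (b.strand, b.kind):
                    assert abs(a.position - b.position) > 5
        # every survivor dominates the peaks it displaced
        for gone in peaks:
            if gone in kept:
                continue
            displacers = [
                k for k in kept
                if (k.strand, k.kind) == (gone.strand, gone.kind)
                and abs(k.position - gone.position) <= 5
            ]
            assert any(k.value >= gone.value for k in displacers)
        # idempotence
        assert prune_local_maxima(kept, 5) == kept
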