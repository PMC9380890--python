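import numpy as np
import pandas as pd
import pytest

from clef import (
    DetectionParams,
    QuietStats,
    detect_bites,
    detect_events,
    make_event_table,
    quiet_stats,
    select_sequences,
    summarize_session,
)

from conftest import make_trace
from oracles import brute_force_detect, sequence_partition_reference

FS = 2000.0


def quiet(mean=0.0, sd=1.0):
    return QuietStats(mean=mean, sd=sd, window=(0.0, 1.0))


def random_envelope(rng, n=4000, n_bursts=5):
    """Noisy baseline plus rectangular/Hann bursts of random size and span."""
    env = np.abs(rng.normal(0, 0.5, n))
    for _ in range(n_bursts):
        w = int(rng.integers(5, 200))
        s = int(rng.integers(0, n - w))
        if rng.random() < 0.5:
            env[s : s + w] += rng.uniform(2, 20)
        else:
            env[s : s + w] += rng.uniform(2, 20) * np.hanning(w)
    return env


class TestQuietStats:
    def test_constant_envelope(self):
        qs = quiet_stats(make_trace(np.full(1000, 3.0), fs=FS), window=(0.0, 0.5))
        assert (qs.mean, qs.sd) == (3.0, 0.0)

    def test_matches_direct_computation(self, rng):
        x = rng.normal(0, 1, 1000)
        qs = quiet_stats(make_trace(x, fs=1000.0), window=(0.0, 1.0))
        assert qs.mean == pytest.approx(x.mean(), abs=1e-12)
        assert qs.sd == pytest.approx(x.std(), abs=1e-12)

    def test_auto_finds_silent_second(self, rng):
        # 3 s of bursts, 1 s silent, 2 s of bursts
        x = np.abs(rng.normal(0, 5, 6000))
        x[3000:4000] = np.abs(rng.normal(0, 0.01, 1000))
        qs = quiet_stats(make_trace(x, fs=1000.0), window="auto")
        start, end = qs.window
        assert 2.9 <= start and end <= 4.1
        # exhaustive scan oracle: no 1-s window has lower RMS
        w = 1000
        rms = [np.mean(x[i : i + w] ** 2) for i in range(0, len(x) - w + 1, 100)]
        i0 = int(round(start * 1000.0))
        assert np.mean(x[i0 : i0 + w] ** 2) == pytest.approx(min(rms))

    def test_window_too_short_errors(self):
        with pytest.raises(ValueError):
            quiet_stats(make_trace(np.zeros(100), fs=1000.0), window=(0.0, 0.05))


class TestDetectEvents:
    def test_single_rectangular_burst(self, rng):
        sigma = 0.1
        env = np.abs(rng.normal(0, sigma, 2000))
        env[1000:1100] += 10 * sigma  # 50 ms burst at fs=2000
        qs = QuietStats(mean=float(env[:500].mean()), sd=float(env[:500].std()), window=(0, 0.25))
        tab = detect_events(make_trace(env, fs=FS), DetectionParams(), qs)
        assert len(tab) == 1
        assert tab.loc[0, "onset"] == pytest.approx(0.5, abs=0.005)
        assert tab.loc[0, "offset"] == pytest.approx(0.55, abs=0.005)

    def test_nine_ms_excursion_rejected_ten_ms_kept(self):
        for n, expected in ((18, 0), (20, 1)):  # 9 ms and 10 ms at 2 kHz
            env = np.zeros(1000)
            env[500 : 500 + n] = 10.0
            tab = detect_events(make_trace(env, fs=FS), DetectionParams(), quiet(0.0, 1.0))
            assert len(tab) == expected

    def test_envelope_equal_to_threshold_not_detected(self):
        env = np.full(1000, 2.0)  # threshold = 0 + 2*1 exactly
        tab = detect_events(make_trace(env, fs=FS), DetectionParams(), quiet(0.0, 1.0))
        assert len(tab) == 0

    def test_matches_brute_force_oracle(self, rng):
        params = DetectionParams()
        for _ in range(20):
            env = random_envelope(rng)
            qs = quiet(float(env[:1000].mean()), float(env[:1000].std()))
            tab = detect_events(make_trace(env, fs=FS), params, qs)
            ref = brute_force_detect(env, FS, qs.threshold(2.0), params.min_duration)
            assert len(tab) == len(ref)
            for (o, f), (_, row) in zip(ref, tab.iterrows()):
                assert row["onset"] == pytest.approx(o, abs=1e-12)
                assert row["offset"] == pytest.approx(f, abs=1e-12)

    def test_merge_gap_bridges_short_dropouts(self):
        env = np.zeros(1000)
        env[100:140] = 10.0
        env[144:180] = 10.0  # 2 ms gap
        p_nomerge = DetectionParams()
        p_merge = DetectionParams(merge_gap=0.003)
        qs = quiet(0.0, 1.0)
        assert len(detect_events(make_trace(env, fs=FS), p_nomerge, qs)) == 2
        merged = detect_events(make_trace(env, fs=FS), p_merge, qs)
        assert len(merged) == 1
        assert merged.loc[0, "offset"] - merged.loc[0, "onset"] == pytest.approx(0.040)

    def test_monotone_in_k_sd_and_min_duration(self, rng):
        env = random_envelope(rng, n_bursts=8)
        tr = make_trace(env, fs=FS)
        qs = quiet(float(env.mean()), float(env.std()))
        counts_k = [len(detect_events(tr, DetectionParams(k_sd=k), qs)) for k in (0.5, 1, 2, 3, 5)]
        assert counts_k == sorted(counts_k, reverse=True)
        counts_d = [
            len(detect_events(tr, DetectionParams(min_duration=d), qs))
            for d in (0.002, 0.005, 0.010, 0.030)
        ]
        assert counts_d == sorted(counts_d, reverse=True)

    def test_all_samples_above_threshold_within_events(self, rng):
        env = random_envelope(rng)
        qs = quiet(float(env.mean()), float(env.std()))
        tab = detect_events(make_trace(env, fs=FS), DetectionParams(), qs)
        thr = qs.threshold(2.0)
        for _, row in tab.iterrows():
            seg = env[int(row["onset"] * FS) : int(row["offset"] * FS)]
            assert (seg > thr).all()

    def test_auc_additive_across_silent_cut(self, rng):
        env = random_envelope(rng, n=4000, n_bursts=4)
        cut = 2000
        env[cut - 300 : cut + 300] = 0.0  # guarantee silence at the cut
        qs = quiet(0.05, 0.05)
        params = DetectionParams()
        whole = detect_events(make_trace(env, fs=FS), params, qs)
        left = detect_events(make_trace(env[:cut], fs=FS), params, qs)
        right = detect_events(make_trace(env[cut:], fs=FS, t0=cut / FS), params, qs)
        joined = pd.concat([left, right], ignore_index=True)
        assert len(joined) == len(whole)
        np.testing.assert_allclose(joined["auc"], whole["auc"], rtol=1e-9)
        np.testing.assert_allclose(joined["onset"], whole["onset"], atol=1e-12)


class TestDetectBites:
    def test_triangular_pulse_force_and_energy(self):
        # base 100 ms, peak 300 g over zero baseline (odd n samples the apex)
        n = int(0.1 * FS) + 1
        pulse = 300 * (1 - np.abs(np.linspace(-1, 1, n)))
        force = np.zeros(2000)
        force[500 : 500 + n] = pulse
        tab = detect_bites(make_trace(force, fs=FS, channel="force", units="g"),
                           DetectionParams(), quiet(0.0, 0.5))
        assert len(tab) == 1
        assert tab.loc[0, "peak_amplitude"] == pytest.approx(300.0)
        assert tab.loc[0, "auc"] == pytest.approx(15.0, rel=0.02)  # 0.5*0.1*300 g*s
        assert tab.loc[0, "channel"] == "force"

    def test_zero_force_empty_table(self):
        tab = detect_bites(make_trace(np.zeros(2000), fs=FS, channel="force"),
                           DetectionParams(), quiet(0.0, 1.0))
        assert len(tab) == 0

    def test_two_pulses_ordered(self):
        force = np.zeros(2000)
        n = int(0.05 * FS)
        force[400 : 400 + n] = 100.0
        force[800 : 800 + n] = 200.0
        tab = detect_bites(make_trace(force, fs=FS, channel="force"),
                           DetectionParams(), quiet(0.0, 1.0))
        assert len(tab) == 2
        assert tab.loc[0, "peak_amplitude"] == 100.0
        assert tab.loc[1, "peak_amplitude"] == 200.0


def bursts_at(peaks):
    return make_event_table(
        [
            {"onset": p - 0.02, "offset": p + 0.02, "peak_time": p, "peak_amplitude": 5.0, "auc": 1.0}
            for p in peaks
        ]
    )


class TestSequences:
    def test_four_bursts_never_a_sequence(self):
        assert select_sequences(bursts_at([0.1, 0.25, 0.4, 0.55])) == []

    def test_six_even_bursts_one_sequence(self):
        peaks = 1.0 + 0.150 * np.arange(6)
        seqs = select_sequences(bursts_at(peaks), max_cycle_gap=0.4)
        assert len(seqs) == 1
        assert seqs[0].n_cycles == 6
        np.testing.assert_allclose(seqs[0].interpeak_intervals, 0.150)
        assert len(seqs[0].interpeak_intervals) == seqs[0].n_cycles - 1

    def test_gap_splits_into_two_kept_runs(self):
        peaks = list(0.2 * np.arange(5)) + list(2.0 + 0.2 * np.arange(5))
        seqs = select_sequences(bursts_at(peaks))
        assert [s.n_cycles for s in seqs] == [5, 5]

    def test_matches_partition_oracle(self, rng):
        for _ in range(50):
            n = int(rng.integers(0, 12))
            peaks = np.cumsum(rng.uniform(0.05, 0.8, n))
            seqs = select_sequences(bursts_at(peaks), n_min=5, max_cycle_gap=0.4)
            ref = sequence_partition_reference(peaks, 5, 0.4)
            assert len(seqs) == len(ref)
            for s, r in zip(seqs, ref):
                np.testing.assert_allclose(s.events["peak_time"], peaks[r])

    def test_exhaustive_small_gap_patterns(self):
        # every close/far pattern for 7 bursts: runs of >=5 kept, of 4 never
        for mask in range(2**6):
            gaps = [0.2 if (mask >> i) & 1 else 1.0 for i in range(6)]
            peaks = np.cumsum([1.0] + gaps)
            seqs = select_sequences(bursts_at(peaks), n_min=5, max_cycle_gap=0.4)
            ref = sequence_partition_reference(peaks, 5, 0.4)
            assert [s.n_cycles for s in seqs] == [len(r) for r in ref]
            assert all(s.n_cycles >= 5 for s in seqs)


class TestSummaries:
    def bites_with(self, forces, energies=None):
        energies = energies if energies is not None else [10.0] * len(forces)
        return make_event_table(
            [
                {"onset": i * 1.0, "offset": i * 1.0 + 0.05, "peak_time": i * 1.0 + 0.02,
                 "peak_amplitude": f, "auc": e}
                for i, (f, e) in enumerate(zip(forces, energies))
            ],
            channel="force",
        )

    def test_counts_above_force_threshold(self):
        s = summarize_session(make_event_table(), self.bites_with([100.0, 450.0, 500.0]), [])
        assert s.n_force_above == 2
        assert s.max_force == 500.0
        assert s.n_bites == 3

    def test_histogram_counts_sum_to_n_bites(self, rng):
        forces = rng.uniform(0, 600, 1000)
        energies = rng.uniform(0, 80, 1000)
        s = summarize_session(make_event_table(), self.bites_with(forces, energies), [])
        assert s.force_histogram.sum() == 1000
        assert s.energy_histogram.sum() == 1000
        # direct count oracle on one bin
        lo, hi = s.force_bin_edges[2], s.force_bin_edges[3]
        assert s.force_histogram[2] == ((forces >= lo) & (forces < hi)).sum()
        assert np.allclose(np.diff(s.force_bin_edges), 50.0)
        assert np.allclose(np.diff(s.energy_bin_edges), 10.0)

    def test_sequence_means(self):
        peaks = 1.0 + 0.2 * np.arange(6)
        bursts = bursts_at(peaks)
        seqs = select_sequences(bursts, max_cycle_gap=0.4)
        s = summarize_session(bursts, make_event_table(channel="force"), seqs)
        assert s.mean_interpeak_interval == pytest.approx(0.2)
        assert s.mean_burst_duration == pytest.approx(0.04)
        assert s.n_sequence_bursts == 6

    def test_empty_inputs_flagged_not_zero(self):
        s = summarize_session(make_event_table(), make_event_table(channel="force"), [])
        assert s.n_bites == 0
        assert np.isnan(s.mean_interpeak_interval)
        assert np.isnan(s.max_force)
        assert s.force_histogram.sum() == 0
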