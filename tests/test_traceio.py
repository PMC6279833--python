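"""Trace serialization and optical-recording preprocessing."""

import numpy as np
import pytest

import cardioinverse as ci
from cardioinverse.trace import Trace
from cardioinverse.traceio import (
    RawRecording, median_filter3, preprocess_pair, read_trace_csv,
    segment_and_average, write_trace_csv,
)


class TestMedianFilter:
    def test_constant_series_unchanged(self):
        x = np.full(20, 3.3)
        assert np.array_equal(median_filter3(x), x)

    def test_single_sample_spike_removed(self):
        x = np.array([0.0, 0.0, 9.0, 0.0, 0.0])
        assert np.array_equal(median_filter3(x), np.zeros(5))

    def test_endpoints_pass_through(self):
        x = np.array([5.0, 1.0, 2.0, 1.0, 7.0])
        out = median_filter3(x)
        assert out[0] == 5.0 and out[-1] == 7.0

    def test_brute_force_oracle_on_random_series(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=200)
        out = median_filter3(x)
        for i in range(1, len(x) - 1):
            assert out[i] == np.median(x[i - 1:i + 2])


def one_beat(t, onset=100.0, width=60.0):
    return np.exp(-((t - onset) ** 2) / (2 * width ** 2))


def make_recording(n_beats=6, frame_rate=100.0, period=1000.0, noise=0.0,
                   jitter=0.0, seed=0, lead_in=0.5):
    rng = np.random.default_rng(seed)
    dt = 1000.0 / frame_rate
    t = np.arange(int((n_beats + lead_in) * period / dt)) * dt
    sig = np.zeros_like(t)
    for b in range(n_beats):
        onset = (b + lead_in) * period + rng.uniform(-jitter, jitter)
        sig += np.exp(-((t - onset - 150.0) ** 2) / (2 * 60.0 ** 2))
    if noise:
        sig = sig + rng.normal(0, noise, size=sig.shape)
    return RawRecording(t=t, signal=sig, channel="calcium", frame_rate=frame_rate)


def make_sharp_recording(n_beats=6, frame_rate=1000.0, period=1000.0, noise=0.0,
                         seed=0, lead_in=0.5):
    """Beats with a steep upstroke so max-dF/dt detection shrugs off noise."""
    rng = np.random.default_rng(seed)
    dt = 1000.0 / frame_rate
    t = np.arange(int((n_beats + lead_in) * period / dt)) * dt
    sig = np.zeros_like(t)
    for b in range(n_beats):
        from scipy.special import expit

        onset = (b + lead_in) * period
        local = t - onset
        sig += expit(local / 2.0) * np.exp(-np.maximum(local, 0.0) / 150.0)
    if noise:
        sig = sig + rng.normal(0, noise, size=sig.shape)
    return RawRecording(t=t, signal=sig, channel="calcium", frame_rate=frame_rate)


class TestSegmentAndAverage:
    def test_identical_beats_average_to_one_beat(self):
        rec = make_recording(n_beats=6)
        t, avg = segment_and_average(rec, 1000.0)
        assert len(t) == 100  # one period at 100 Hz
        # the averaged beat reproduces any single beat's shape
        single = make_recording(n_beats=1, lead_in=0.5)
        tt, ss = segment_and_average(make_recording(n_beats=6), 1000.0)
        assert np.allclose(avg, ss)

    def test_too_few_beats_raises(self):
        rec = make_recording(n_beats=3)
        with pytest.raises(ValueError, match="fewer"):
            segment_and_average(rec, 1000.0, n_beats=5)

    def test_jittered_beats_realign_to_the_common_shape(self):
        # at 1 kHz the max-dF/dt alignment resolves the jitter to the sample,
        # so the averaged beat reproduces the un-jittered shape
        clean = make_recording(n_beats=6, jitter=0.0, frame_rate=1000.0)
        t0, ref = segment_and_average(clean, 1000.0)
        jit = make_recording(n_beats=6, jitter=30.0, seed=4, frame_rate=1000.0)
        t1, avg = segment_and_average(jit, 1000.0)
        rms = np.sqrt(np.mean((avg - ref) ** 2)) / (ref.max() - ref.min())
        assert rms < 0.01

    def test_averaging_reduces_noise_like_sqrt_n(self):
        # sharp-upstroke beats at 1 kHz keep alignment exact under noise, so
        # the averaged residual follows the 1/sqrt(n) law of white noise;
        # the 3-point median filter shrinks the single-beat noise first, so
        # calibrate the numerator on filtered pure noise
        from cardioinverse.traceio import median_filter3

        n = 6
        sd = 0.05
        rng = np.random.default_rng(99)
        filtered_sd = np.std(median_filter3(rng.normal(0, sd, size=20000)))
        t0, clean = segment_and_average(
            make_sharp_recording(n_beats=n, frame_rate=1000.0), 1000.0)
        reps = []
        for seed in range(8):
            rec = make_sharp_recording(n_beats=n, noise=sd, seed=seed, frame_rate=1000.0)
            _, avg = segment_and_average(rec, 1000.0)
            # judge on the flat pre-upstroke baseline, where residual
            # sub-sample alignment error contributes nothing
            reps.append(np.std((avg - clean)[:80]))
        measured = np.mean(reps)
        expected = filtered_sd / np.sqrt(n)
        assert measured == pytest.approx(expected, rel=0.2)

    def test_idempotent_on_clean_averaged_beat(self):
        rec = make_recording(n_beats=6)
        t, avg = segment_and_average(rec, 1000.0)
        # feed the averaged beat back in as a 'recording' of repeated beats
        tiled = np.tile(avg, 6)
        rec2 = RawRecording(t=np.arange(len(tiled)) * 10.0, signal=tiled,
                            channel="calcium", frame_rate=100.0)
        t2, avg2 = segment_and_average(rec2, 1000.0)
        assert np.allclose(avg2, avg, atol=1e-12)


class TestTraceCsv:
    def test_roundtrip_is_lossless(self, tmp_path, baseline_trace):
        p = tmp_path / "trace.csv"
        meta = tmp_path / "trace.meta"
        write_trace_csv(baseline_trace, p, meta_path=meta)
        back = read_trace_csv(p, meta_path=meta)
        assert np.array_equal(back.t, baseline_trace.t)
        assert np.array_equal(back.v, baseline_trace.v)
        assert np.array_equal(back.ca, baseline_trace.ca)
        assert back.pacing_period == baseline_trace.pacing_period
        assert back.provenance == baseline_trace.provenance

    def test_missing_column_is_a_named_error(self, tmp_path):
        p = tmp_path / "bad.csv"
        p.write_text("time_ms,v\n0,1\n1,2\n")
        with pytest.raises(ValueError, match="ca"):
            read_trace_csv(p)

    def test_non_uniform_grid_rejected(self, tmp_path):
        p = tmp_path / "bad.csv"
        p.write_text("time_ms,v,ca\n0,1,1\n1,2,2\n3,3,3\n")
        with pytest.raises(ValueError, match="uniform"):
            read_trace_csv(p)

    def test_currents_roundtrip(self, tmp_path, base_model, base_p):
        from cardioinverse.models import EVAL_PROTOCOL

        tr = ci.simulate(base_model, base_p, EVAL_PROTOCOL, record_currents=True)
        p = tmp_path / "trace.csv"
        write_trace_csv(tr, p)
        back = read_trace_csv(p)
        assert set(back.currents) == set(tr.currents)
        assert np.array_equal(back.currents["I_Kr"], tr.currents["I_Kr"])


class TestPreprocessPair:
    def test_pair_becomes_measured_single_beat_trace(self):
        v = make_recording(n_beats=6, noise=0.005, seed=1)
        v.channel = "voltage"
        c = make_recording(n_beats=6, noise=0.005, seed=2)
        tr = preprocess_pair(v, c, 1000.0)
        assert tr.provenance == "measured"
        assert len(tr.t) == 100
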