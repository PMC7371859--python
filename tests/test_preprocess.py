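import numpy as np
import pytest

from entrain import montage
from entrain.core_io import Event, Recording, build_neighbors
from entrain.preprocess import (TrialSet, excise_ringing, interpolate_gaps,
                                preprocess, reject_artifacts,
                                remove_decay_components,
                                remove_ocular_components,
                                rereference_downsample, segment_trials)
from entrain.protocol import schedule_session
from entrain.synth import SynthConfig, generate_session


def _trial_segments(rec, trace):
    """Ground-truth trace cut into the same windows as segment_trials."""
    segs = []
    n = int(round(8.5 * rec.fs))
    for ev in rec.events_of("burst_offset"):
        start = int(round((ev.time - 3.5) * rec.fs))
        if 0 <= start and start + n <= rec.n_samples:
            segs.append(trace[start:start + n])
    return np.stack(segs)


def _projected_energy(data, template, window=None):
    """Energy of the per-channel least-squares projection onto a template."""
    if window is not None:
        data = data[..., window]
        template = template[window]
    denom = (template ** 2).sum()
    if denom == 0:
        return 0.0
    coef = (data * template).sum(axis=-1) / denom
    return float((coef ** 2).sum() * denom)


class TestSegmentTrials:
    def test_small_session_counts(self, clean_session, small_schedule):
        rec, _ = clean_session
        ts = segment_trials(rec)
        assert ts.conditions.count("rhythmic") == 6
        assert ts.conditions.count("arrhythmic") == 6

    def test_duration_exactly_8_5_s(self, clean_session):
        rec, _ = clean_session
        ts = segment_trials(rec)
        assert ts.n_samples / ts.fs == 8.5
        assert ts.times[0] == pytest.approx(-3.5)

    def test_out_of_bounds_burst_dropped(self):
        fs = 250.0
        events = [Event(5.0, "burst_offset", "rhythmic", 0),
                  Event(11.0, "burst_offset", "rhythmic", 1)]  # 1 s before end
        rec = Recording(np.zeros((2, int(12 * fs))), fs, ["a", "b"], events=events)
        with pytest.warns(UserWarning):
            ts = segment_trials(rec)
        assert ts.n_trials == 1

    def test_no_offsets_error(self):
        rec = Recording(np.zeros((1, 100)), 100.0, ["a"])
        with pytest.raises(ValueError):
            segment_trials(rec)


class TestExciseRinging:
    def _single_pulse_ts(self, fs=2500.0):
        n = int(8.5 * fs)
        events = [Event(2.0, "pulse", "rhythmic", 0),
                  Event(4.0, "burst_offset", "rhythmic", 0)]
        rec = Recording(np.zeros((1, int(10 * fs))), fs, ["Cz"], events=events)
        return segment_trials(rec)

    def test_33_samples_masked_at_2500hz(self):
        # oracle: brute-force enumeration of samples with trial time in
        # [-2.0 - 4 ms, -2.0 + 9 ms], endpoints inclusive
        ts = excise_ringing(self._single_pulse_ts())
        masked = (~ts.valid[0, 0]).sum()
        t = ts.times
        brute = ((t >= -2.0 - 0.004 - 1e-12) & (t <= -2.0 + 0.009 + 1e-12)).sum()
        assert masked == brute == 33

    def test_zero_pulses_no_change(self):
        fs = 250.0
        rec = Recording(np.zeros((1, int(10 * fs))), fs, ["Cz"],
                        events=[Event(4.0, "burst_offset", "rhythmic", 0)])
        ts = excise_ringing(segment_trials(rec))
        assert ts.valid.all()

    def test_overlapping_windows_merge(self):
        fs = 2500.0
        events = [Event(2.0, "pulse", "rhythmic", 0),
                  Event(2.01, "pulse", "rhythmic", 0),
                  Event(4.0, "burst_offset", "rhythmic", 0)]
        rec = Recording(np.zeros((1, int(10 * fs))), fs, ["Cz"], events=events)
        ts = excise_ringing(segment_trials(rec))
        invalid = np.flatnonzero(~ts.valid[0, 0])
        assert np.all(np.diff(invalid) == 1)  # one contiguous interval
        assert len(invalid) == int(0.023 * fs) + 1

    def test_data_untouched(self, artifact_session):
        rec, _ = artifact_session
        ts = segment_trials(rec)
        ts2 = excise_ringing(ts)
        assert np.array_equal(ts.data, ts2.data)


class TestDecayICA:
    def test_dominant_decay_rejected(self, small_schedule):
        cfg = SynthConfig(n_channels=16, fs=500, entrain_strength=3.0,
                          ringing_amp=400, decay_amp=100, blink_rate=0, seed=31)
        rec, gt = generate_session(cfg, small_schedule)
        ts = excise_ringing(segment_trials(rec))
        clean, dec = remove_decay_components(ts, seed=1)
        assert len(dec.rejected) >= 1
        # >80% decay-energy reduction in the 10..50 ms post-pulse windows
        decay_trials = _trial_segments(rec, gt.decay_trace)
        window = np.zeros(ts.n_samples, dtype=bool)
        for i in range(ts.n_trials):
            for tp in ts.pulse_times[i]:
                lo = int(round((tp + 0.010 + 3.5) * ts.fs))
                hi = int(round((tp + 0.050 + 3.5) * ts.fs))
                window[lo:hi] = True
        before = sum(_projected_energy(ts.data[i], decay_trials[i], window)
                     for i in range(ts.n_trials))
        after = sum(_projected_energy(clean.data[i], decay_trials[i], window)
                    for i in range(ts.n_trials))
        assert after < 0.2 * before

    def test_no_decay_none_rejected(self, clean_session):
        rec, _ = clean_session
        ts = excise_ringing(segment_trials(rec))
        _, dec = remove_decay_components(ts, seed=2)
        assert dec.rejected == []

    def test_unmixing_mixing_identity(self, clean_session):
        rec, _ = clean_session
        ts = excise_ringing(segment_trials(rec))
        _, dec = remove_decay_components(ts, n_components=15, seed=3)
        approx = dec.unmixing @ dec.mixing
        assert np.allclose(approx, np.eye(15), atol=1e-6)


class TestInterpolateGaps:
    def _gapped(self, signal, fs=500.0):
        n = len(signal)
        data = signal[None, None, :].copy()
        valid = np.ones((1, 1, n), dtype=bool)
        lo = n // 2
        valid[:, :, lo:lo + int(0.013 * fs) + 1] = False
        times = -3.5 + np.arange(n) / fs
        return TrialSet(data, fs, times, valid, ["rhythmic"],
                        [np.array([])], ["Cz"])

    def test_linear_ramp_exact(self):
        fs = 500.0
        ramp = np.linspace(0, 100, int(8.5 * fs))
        ts = interpolate_gaps(self._gapped(ramp, fs))
        assert np.max(np.abs(ts.data[0, 0] - ramp)) < 1e-9

    def test_sinusoid_error_bounded(self):
        # oracle: analytic 10 Hz sinusoid; 13 ms gap reconstruction < 5% amp
        fs = 500.0
        t = np.arange(int(8.5 * fs)) / fs
        sig = 50 * np.sin(2 * np.pi * 10 * t)
        ts = interpolate_gaps(self._gapped(sig, fs))
        assert np.max(np.abs(ts.data[0, 0] - sig)) < 0.05 * 50

    def test_no_gaps_identity(self):
        fs = 500.0
        rng = np.random.default_rng(0)
        sig = rng.normal(size=int(8.5 * fs))
        ts = self._gapped(sig, fs)
        ts.valid[:] = True
        out = interpolate_gaps(ts)
        assert np.array_equal(out.data[0, 0], sig)

    def test_mask_cleared(self):
        fs = 500.0
        ts = interpolate_gaps(self._gapped(np.ones(int(8.5 * fs)), fs))
        assert ts.valid.all()


class TestRereferenceDownsample:
    def test_zero_mean_across_channels(self, clean_session):
        rec, _ = clean_session
        ts = rereference_downsample(segment_trials(rec), target_fs=rec.fs)
        assert np.abs(ts.data.mean(axis=1)).max() < 1e-9

    def test_halves_sample_count(self):
        fs = 2500.0
        rec = Recording(np.random.default_rng(0).normal(size=(2, int(10 * fs))),
                        fs, ["a", "b"],
                        events=[Event(4.0, "burst_offset", "rhythmic", 0)])
        ts = segment_trials(rec)
        out = rereference_downsample(ts, target_fs=1250.0)
        assert out.n_samples == ts.n_samples // 2
        assert out.fs == 1250.0

    def test_sinusoid_amplitude_preserved(self):
        # filter-response oracle: 10 Hz is far below the anti-alias cutoff
        fs = 2500.0
        t = np.arange(int(10 * fs)) / fs
        sig = 40 * np.sin(2 * np.pi * 10 * t)
        rec = Recording(np.vstack([sig, -sig]), fs, ["a", "b"],
                        events=[Event(4.0, "burst_offset", "rhythmic", 0)])
        out = rereference_downsample(segment_trials(rec), target_fs=1250.0)
        mid = out.data[0, 0, 1000:-1000]
        assert abs(mid.max() - 40) < 0.4

    def test_non_integer_factor_error(self, clean_session):
        rec, _ = clean_session
        with pytest.raises(ValueError):
            rereference_downsample(segment_trials(rec), target_fs=333.0)


def _manual_trialset(rng, n_trials=8, fs=250.0, amp=10.0):
    """64-channel trials with realistic (spatially correlated) noise."""
    labels, pos = montage.standard_64()
    n = int(2.0 * fs)
    # deterministic common oscillation: stable inter-channel correlation
    # (like volume conduction) without trial-to-trial power co-fluctuation
    t = np.arange(n) / fs
    shared = np.sqrt(2) * np.sin(2 * np.pi * 10.0 * t)
    local = rng.standard_normal((n_trials, 64, n))
    data = amp * (0.8 * shared[None, None, :] + 0.6 * local)
    times = -3.5 + np.arange(n) / fs
    return TrialSet(data, fs, times, np.ones_like(data, dtype=bool),
                    ["rhythmic"] * n_trials, [np.array([])] * n_trials,
                    labels, pos)


class TestRejectArtifacts:
    def test_five_bad_channels_interpolated(self):
        rng = np.random.default_rng(1)
        ts = _manual_trialset(rng)
        nb = build_neighbors(ts.positions, channel_names=ts.channel_names)
        ts.data[0, :5] *= np.sqrt(10)  # 10x power on 5/64 channels
        out = reject_artifacts(ts, nb)
        assert out.n_trials == 8  # trial kept: 5/64 < 20%
        assert out.data[0, :5].std() < 2 * ts.data[1, :5].std()

    def test_many_bad_channels_rejects_trial(self):
        rng = np.random.default_rng(2)
        ts = _manual_trialset(rng)
        nb = build_neighbors(ts.positions, channel_names=ts.channel_names)
        ts.data[0, :20] *= 10  # 31% of channels corrupted
        out = reject_artifacts(ts, nb)
        assert out.n_trials == 7

    def test_high_std_channel_removed(self):
        rng = np.random.default_rng(3)
        ts = _manual_trialset(rng, amp=10.0)
        nb = build_neighbors(ts.positions, channel_names=ts.channel_names)
        noisy = ts.channel_names.index("C3")
        ts.data[:, noisy] = 40.0 * rng.standard_normal((ts.n_trials, ts.n_samples))
        out = reject_artifacts(ts, nb)
        assert "C3" in out.interpolated_channels
        assert any("C3" in line for line in out.log)

    def test_unusable_data_raises(self):
        rng = np.random.default_rng(4)
        ts = _manual_trialset(rng)
        nb = build_neighbors(ts.positions, channel_names=ts.channel_names)
        ts.data[:, :40] = 80.0 * rng.standard_normal(ts.data[:, :40].shape)
        with pytest.raises(RuntimeError, match="unusable"):
            reject_artifacts(ts, nb)


@pytest.fixture(scope="module")
def blinky():
    sched = schedule_session(10.0, 1, 6, 20, seed=41)
    cfg = SynthConfig(n_channels=16, fs=500, entrain_strength=5.0,
                      ringing_amp=0, decay_amp=0, blink_rate=10.0, seed=42)
    rec, gt = generate_session(cfg, sched)
    ts = rereference_downsample(segment_trials(rec), target_fs=rec.fs)
    return rec, gt, ts


class TestOcularICA:
    def test_blink_energy_reduced(self, blinky):
        rec, gt, ts = blinky
        out, dec = remove_ocular_components(ts, seed=5)
        assert len(dec.rejected) >= 1
        blink_trials = _trial_segments(rec, gt.blink_trace)
        frontal = ts.channel_index(montage.frontal_channels(ts.channel_names))
        before = sum(_projected_energy(ts.data[i][frontal], blink_trials[i])
                     for i in range(ts.n_trials))
        after = sum(_projected_energy(out.data[i][frontal], blink_trials[i])
                    for i in range(ts.n_trials))
        assert after < 0.2 * before

    def test_posterior_alpha_preserved(self, blinky):
        rec, gt, ts = blinky
        out, _ = remove_ocular_components(ts, seed=5)
        pidx = ts.channel_index(montage.posterior_channels(ts.channel_names))

        def alpha_power(x):
            f = np.fft.rfftfreq(x.shape[-1], 1 / ts.fs)
            p = np.abs(np.fft.rfft(x[:, pidx], axis=-1)) ** 2
            return p[..., (f >= 8) & (f <= 12)].sum()

        assert alpha_power(out.data) == pytest.approx(alpha_power(ts.data), rel=0.1)

    def test_no_blinks_none_rejected(self, clean_session):
        rec, _ = clean_session
        ts = rereference_downsample(segment_trials(rec), target_fs=rec.fs)
        _, dec = remove_ocular_components(ts, seed=6)
        assert dec.rejected == []


class TestFullCascade:
    def test_stage_order_logged(self, artifact_session):
        rec, _ = artifact_session
        ts = preprocess(rec, target_fs=rec.fs, ica_seed=7)
        stages = ["segment", "excise_ringing", "decay_ica", "interpolate",
                  "rereference_downsample", "reject", "ocular_ica"]
        hits = [next(i for i, line in enumerate(ts.log) if line.startswith(s))
                for s in stages]
        assert hits == sorted(hits)

    def test_identity_on_clean_data(self):
        # signal preservation relative to the re-referenced segmentation:
        # ICA and rejection stages must not distort posterior alpha by >10%.
        # Uses 24 trials so the IQR fence operates at a stable trial count.
        sched = schedule_session(10.0, 1, 12, 20, seed=81)
        cfg = SynthConfig(n_channels=16, fs=500, entrain_strength=10.0,
                          ringing_amp=0, decay_amp=0, blink_rate=0, seed=82)
        rec, _ = generate_session(cfg, sched)
        ts = preprocess(rec, target_fs=rec.fs, ica_seed=8)
        ref = rereference_downsample(segment_trials(rec), target_fs=rec.fs)
        keep = ts.trial_indices  # trials surviving rejection, matched in ref
        pidx = ts.channel_index(montage.posterior_channels(ts.channel_names))

        def alpha_power(x):
            f = np.fft.rfftfreq(x.shape[-1], 1 / ts.fs)
            p = np.abs(np.fft.rfft(x[:, pidx], axis=-1)) ** 2
            return p[..., (f >= 8) & (f <= 12)].sum()

        assert alpha_power(ts.data) == pytest.approx(
            alpha_power(ref.data[keep]), rel=0.1)
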