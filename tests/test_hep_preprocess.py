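import numpy as np
import pandas as pd
import pytest

from cardioaudio.containers import ContinuousRecording, EpochSet, Evoked
from cardioaudio.hep_preprocess import (cfa_correct, filter_continuous,
                                        hurst_exponent, interpolate_channels,
                                        make_epochs,
                                        remove_stationary_artifacts,
                                        rereference, robust_average,
                                        scan_artifacts)
from helpers import fbm_davies_harte

FS = 512.0


def make_recording(data, names=None, kinds=None):
    n = data.shape[0]
    return ContinuousRecording(
        data, FS, names or [f"E{i+1}" for i in range(n)],
        kinds or ["eeg"] * n)


def make_epochset(data, tmin=-0.1, lock="rpeak", meta=None):
    n_ep, n_ch, n_t = data.shape
    times = (np.arange(n_t) + round(tmin * FS)) / FS
    meta = meta if meta is not None else pd.DataFrame(
        {"trial": range(n_ep), "rpeak_latencies": [[] for _ in range(n_ep)]})
    return EpochSet(data, times, FS, [f"E{i+1}" for i in range(n_ch)],
                    lock, meta)


class TestFiltering:
    def test_passband_identity_and_zero_phase(self):
        t = np.arange(int(30 * FS)) / FS
        x = np.sin(2 * np.pi * 5 * t)
        rec = make_recording(x[None, :])
        y = filter_continuous(rec, 0.5, 40.0).data[0]
        mid = slice(int(5 * FS), int(25 * FS))
        assert np.abs(y[mid] - x[mid]).max() < 0.01

    def test_stopband_attenuation(self):
        t = np.arange(int(30 * FS)) / FS
        x = np.sin(2 * np.pi * 60 * t)
        y = filter_continuous(make_recording(x[None, :]), 0.5, 40.0).data[0]
        mid = slice(int(5 * FS), int(25 * FS))
        atten = 20 * np.log10(np.abs(x[mid]).max() / np.abs(y[mid]).max())
        assert atten >= 20

    def test_dc_removed(self):
        x = np.full((1, int(30 * FS)), 7.3)
        y = filter_continuous(make_recording(x), 0.5, 40.0).data[0]
        assert abs(y[int(5 * FS):int(25 * FS)].mean()) < 0.05

    def test_invalid_band_rejected(self):
        rec = make_recording(np.zeros((1, int(30 * FS))))
        with pytest.raises(ValueError):
            filter_continuous(rec, 40.0, 0.5)


class TestEpoching:
    def events(self, samples, kind="rpeak"):
        return pd.DataFrame({
            "sample": samples, "onset_s": np.asarray(samples) / FS,
            "kind": kind, "trial": range(len(samples)), "block": 0,
            "attention": "internal", "delay": "short", "omission_trial": 0})

    def test_sample_count_of_standard_window(self):
        rec = make_recording(np.zeros((2, int(20 * FS))))
        ep = make_epochs(rec, self.events([3000, 5000]), "rpeak", -0.3, 0.8)
        assert ep.data.shape == (2, 2, 563)       # floor(1.1 * 512)

    def test_edge_events_dropped(self):
        rec = make_recording(np.zeros((1, int(4 * FS))))
        ep = make_epochs(rec, self.events([51, 1024]), "rpeak", -0.3, 0.8)
        assert ep.n_epochs == 1

    def test_lock_time_is_event_onset(self):
        rec = make_recording(np.zeros((1, int(10 * FS))))
        rec.data[0, 2048] = 1.0
        ep = make_epochs(rec, self.events([2048], kind="omission"),
                         "omission", -0.1, 0.2)
        i0 = np.argmin(np.abs(ep.times))
        assert ep.times[i0] == 0.0
        assert ep.data[0, 0, i0] == 1.0

    def test_rpeak_latencies_recorded(self):
        rec = make_recording(np.zeros((1, int(10 * FS))))
        ev = pd.concat([self.events([2048], "omission"),
                        self.events([2000, 2100], "rpeak")])
        ep = make_epochs(rec, ev, "omission", -0.2, 0.2)
        lat = ep.metadata["rpeak_latencies"][0]
        assert np.allclose(lat, [(2000 - 2048) / FS, (2100 - 2048) / FS])

    def test_bad_window_rejected(self):
        rec = make_recording(np.zeros((1, int(4 * FS))))
        with pytest.raises(ValueError):
            make_epochs(rec, self.events([1000]), "rpeak", 0.5, 0.5)


class TestArtifactScan:
    def test_high_variance_channel_flagged(self, rng):
        x = rng.standard_normal((20, 32, 200))
        x[:, 5] *= 10.0
        rep = scan_artifacts("channels_raw", make_epochset(x))
        assert "E6" in rep.flagged

    def test_identical_channels_nothing_flagged(self):
        x = np.tile(np.sin(np.arange(200) / 7.0), (10, 8, 1))
        rep = scan_artifacts("channels_raw", make_epochset(x))
        assert rep.flagged == []

    def test_outlier_trial_flagged(self, rng):
        x = rng.standard_normal((30, 8, 200))
        x[4] *= 10.0
        rep = scan_artifacts("trials", make_epochset(x))
        assert 4 in rep.flagged

    def test_erp_stage_flags_noisy_channel(self, rng):
        x = rng.standard_normal((30, 16, 200)) * 0.1
        x[:, 3] += rng.standard_normal((30, 200)) * 5.0
        rep = scan_artifacts("channels_erp", make_epochset(x))
        assert "E4" in rep.flagged

    def test_flag_invariant_to_channel_order(self, rng):
        x = rng.standard_normal((15, 10, 150))
        x[:, 7] *= 8.0
        ep = make_epochset(x)
        rep = scan_artifacts("channels_raw", ep)
        perm = np.arange(10)[::-1]
        ep2 = make_epochset(x[:, perm])
        ep2.ch_names = [f"E{i+1}" for i in perm]
        rep2 = scan_artifacts("channels_raw", ep2)
        assert set(rep.flagged) == set(rep2.flagged)

    def test_too_few_trials_rejected(self, rng):
        with pytest.raises(ValueError):
            scan_artifacts("trials", make_epochset(rng.standard_normal((2, 8, 50))))


class TestHurst:
    @pytest.mark.parametrize("h", [0.3, 0.5, 0.7])
    def test_fbm_recovery(self, h, rng):
        x = fbm_davies_harte(10_000, h, rng)
        assert abs(hurst_exponent(x) - h) <= 0.1

    def test_linear_ramp_degenerate(self):
        with pytest.warns(UserWarning):
            out = hurst_exponent(np.arange(100, dtype=float))
        assert out == 1.0

    def test_short_input_rejected(self):
        with pytest.raises(ValueError):
            hurst_exponent(np.zeros(8))


class TestDecomposition:
    def _blinky_epochs(self, rng, layout, blink_amp=60.0):
        n_ep, n_ch, n_t = 40, layout.n_channels, 256
        x = rng.standard_normal((n_ep, n_ch, n_t))
        t = np.arange(n_t) / FS
        wave = np.exp(-0.5 * ((t - 0.2) / 0.05) ** 2) \
            - 0.35 * np.exp(-0.5 * ((t - 0.35) / 0.08) ** 2)
        fr = np.maximum(layout.pos[:, 1] - 0.05, 0)
        topo = fr / fr.max()
        blink_trials = rng.choice(n_ep, size=8, replace=False)
        for i in blink_trials:
            x[i] += blink_amp * topo[:, None] * wave[None, :]
        return make_epochset(x), topo, blink_trials

    def test_injected_blink_removed(self, rng, layout16):
        ep, topo, blink_trials = self._blinky_epochs(rng, layout16)
        frontal = np.flatnonzero(topo > 0.5)
        before = ep.data[blink_trials][:, frontal].var()
        clean, feats = remove_stationary_artifacts(ep, layout16, random_state=3)
        after = clean.data[blink_trials][:, frontal].var()
        assert feats["flagged"].any()
        assert after <= 0.2 * before

    def test_specific_without_artifacts(self, rng, layout16):
        x = rng.standard_normal((40, 16, 256))
        ep = make_epochset(x)
        clean, _ = remove_stationary_artifacts(ep, layout16, random_state=3)
        rms_change = np.sqrt(np.mean((clean.data - x) ** 2)) / x.std()
        assert rms_change < 0.05

    def test_disabled_classifier_is_identity(self, rng, layout16):
        x = rng.standard_normal((10, 16, 128))
        ep = make_epochset(x)
        clean, feats = remove_stationary_artifacts(ep, layout16, classifier=None)
        assert np.array_equal(clean.data, x)
        assert feats.empty


class TestInterpolation:
    def test_empty_bad_set_identity(self, rng, layout16):
        x = rng.standard_normal((5, 16, 64))
        ep = make_epochset(x)
        out = interpolate_channels(ep, layout16, [])
        assert np.array_equal(out.data, x)

    def test_smooth_field_reconstruction(self, layout16):
        # smooth dipolar-like potential over the scalp disc
        pos = layout16.pos
        t = np.linspace(0, 1, 64)
        field = (np.tanh(3 * pos[:, 0])[:, None]
                 * (1 + 0.5 * np.sin(2 * np.pi * 2 * t))[None, :]
                 + 0.4 * pos[:, 1][:, None])
        ep = make_epochset(field[None, :, :])
        out = interpolate_channels(ep, layout16, ["E5"])
        i = 4
        err = np.sqrt(np.mean((out.data[0, i] - field[i]) ** 2))
        assert err < 0.1 * np.sqrt(np.mean(field[i] ** 2))
        # untouched good channels
        others = [j for j in range(16) if j != i]
        assert np.array_equal(out.data[0, others], field[others])

    def test_all_bad_rejected(self, rng, layout16):
        ep = make_epochset(rng.standard_normal((2, 16, 32)))
        with pytest.raises(ValueError):
            interpolate_channels(ep, layout16, list(ep.ch_names))


class TestRereference:
    def test_average_reference_zero_mean_and_idempotent(self, rng):
        x = rng.standard_normal((4, 8, 100)) + 3.0
        ep = make_epochset(x)
        out = rereference(ep, "average")
        assert np.abs(out.data.mean(axis=1)).max() < 1e-10
        out2 = rereference(out, "average")
        assert np.allclose(out.data, out2.data)

    def test_missing_mastoids_named(self, rng):
        ep = make_epochset(rng.standard_normal((2, 4, 50)))
        with pytest.raises(ValueError, match="M1"):
            rereference(ep, "mastoids")

    def test_ecg_untouched_by_average(self, rng):
        x = rng.standard_normal((5, 100))
        rec = ContinuousRecording(x.copy()[None].repeat(1, 0).reshape(5, 100)
                                  if False else x.copy(), FS,
                                  ["E1", "E2", "E3", "E4", "ECG1"],
                                  ["eeg"] * 4 + ["ecg"])
        out = rereference(rec, "average")
        assert np.array_equal(out.data[4], x[4])
        assert not np.array_equal(out.data[0], x[0])


class TestCFACorrection:
    def _template(self, n_ch=4, n_t=154):
        times = (np.arange(n_t) - 51) / FS          # [-0.1, 0.2)
        data = np.outer(np.linspace(1, 2, n_ch),
                        np.exp(-0.5 * ((times - 0.02) / 0.01) ** 2)) * 20.0
        return Evoked(data, times, FS, [f"E{i+1}" for i in range(n_ch)],
                      "rest", 10)

    def test_zero_template_is_identity(self, rng):
        tmpl = self._template()
        tmpl.data[:] = 0.0
        x = rng.standard_normal((6, 4, 300))
        meta = pd.DataFrame({"trial": range(6),
                             "rpeak_latencies": [[0.05]] * 6})
        ep = make_epochset(x, tmin=-0.1, meta=meta)
        out = cfa_correct(ep, tmpl)
        assert np.array_equal(out.data, x)

    def test_artifact_removed_at_each_heartbeat(self, rng):
        tmpl = self._template()
        n_ep, n_t = 50, 600
        lat_lists = [[0.1, 0.55] for _ in range(n_ep)]
        noise = rng.standard_normal((n_ep, 4, n_t))
        x = noise.copy()
        times0 = -0.1
        for i, lats in enumerate(lat_lists):
            for lat in lats:
                start = int(round((lat + tmpl.times[0] - times0) * FS))
                x[i, :, start:start + tmpl.data.shape[1]] += tmpl.data
        meta = pd.DataFrame({"trial": range(n_ep),
                             "rpeak_latencies": lat_lists})
        ep = make_epochset(x, tmin=-0.1, meta=meta)
        out = cfa_correct(ep, tmpl)
        assert np.allclose(out.data, noise, atol=1e-10)

    def test_montage_mismatch_rejected(self, rng):
        tmpl = self._template(n_ch=3)
        ep = make_epochset(rng.standard_normal((2, 4, 300)))
        with pytest.raises(ValueError):
            cfa_correct(ep, tmpl)


class TestRobustAverage:
    def test_equals_mean_without_outliers(self, rng):
        # homogeneous sign-balanced noise: every deviation equals the MAD,
        # far below the 3 robust-SD Huber threshold, so all weights stay 1
        mu = rng.standard_normal((4, 563)) + 5.0
        amp = rng.uniform(0.5, 2.0, size=(4, 563))
        signs = np.ones((30, 1, 1)) * np.r_[np.ones(15), -np.ones(15)][:, None, None]
        signs = rng.permuted(np.broadcast_to(signs, (30, 4, 563)), axis=0)
        x = mu + signs * amp
        ep = make_epochset(x, tmin=-0.3)
        ev = robust_average(ep, lowpass_hz=None)
        assert np.allclose(ev.data, x.mean(axis=0), rtol=1e-6, atol=1e-9)
        assert np.all(ev.weights == 1.0)

    def test_bounded_influence_of_gross_outlier(self, rng):
        x = rng.standard_normal((30, 2, 563))
        clean_mean = x[1:].mean(axis=0)
        x[0, 0, 100] += 1000.0
        ep = make_epochset(x, tmin=-0.3)
        ev = robust_average(ep, lowpass_hz=None)
        assert abs(ev.data[0, 100] - clean_mean[0, 100]) < 3.0
        assert abs(x.mean(axis=0)[0, 100] - clean_mean[0, 100]) > 25.0

    def test_single_epoch_passthrough(self, rng):
        x = rng.standard_normal((1, 3, 563))
        ep = make_epochset(x, tmin=-0.3)
        ev = robust_average(ep, lowpass_hz=None)
        assert np.array_equal(ev.data, x[0])

    def test_lowpass_smooths(self, rng):
        x = rng.standard_normal((10, 2, 563))
        ep = make_epochset(x, tmin=-0.3)
        ev = robust_average(ep, lowpass_hz=20.0)
        raw = robust_average(ep, lowpass_hz=None)
        assert np.abs(np.diff(ev.data)).mean() < np.abs(np.diff(raw.data)).mean()
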