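"""Trial averaging, Morlet time-frequency maps, band power and rest RMS."""

import numpy as np
import pytest

import microsep as m
from microsep.recording import BASELINE_LEN, ConditionLabel, EpochSet
from microsep.sep import _band_power, band_power_map, morlet_tf
from microsep.synth import default_finger_centers


def _epochs_from_array(data, codes, pre):
    return EpochSet(data_uv=np.asarray(data, np.float32),
                    label_codes=codes, channel_ids=np.arange(data.shape[1]),
                    pre=pre)


class TestAverageEpochs:
    def test_mean_of_identical_trials_is_the_trial(self):
        trial = np.random.default_rng(0).normal(size=(1, 4, 100))
        ep = _epochs_from_array(np.repeat(trial, 2, axis=0), [2, 2], pre=10)
        avg = m.average_epochs(ep, 2)
        np.testing.assert_allclose(avg.mean_uv, trial[0], atol=1e-6)
        assert avg.n_averaged == 2

    def test_averaging_is_linear(self, small_epochs):
        avg = m.average_epochs(small_epochs, ConditionLabel("D2", 4))
        scaled = EpochSet(data_uv=3.0 * small_epochs.data_uv,
                          label_codes=small_epochs.label_codes,
                          channel_ids=small_epochs.channel_ids,
                          pre=small_epochs.pre)
        avg3 = m.average_epochs(scaled, ConditionLabel("D2", 4))
        np.testing.assert_allclose(avg3.mean_uv, 3.0 * avg.mean_uv,
                                   rtol=1e-4, atol=1e-4)

    def test_no_trials_raises(self, small_epochs):
        sub = small_epochs.select_trials(small_epochs.trials_of(0))
        with pytest.raises(ValueError):
            m.average_epochs(sub, 5)

    def test_averaged_rest_rms_shrinks_as_sqrt_n(self, geometry):
        """With purely independent noise the across-N average attenuates the
        rest-state RMS by 1/sqrt(N)."""
        cfg = m.SynthConfig(seed=3, n_trials_per_condition=16,
                            amp_peak_uv=0.0, early_amp_uv=(0.0,) * 5,
                            artifact_amp_uv=0.0, slow_noise_fraction=0.0)
        rec = m.generate_recording(cfg, geometry)
        ep = m.extract_epochs(rec, span=(BASELINE_LEN, 10))
        idx = ep.trials_of(0)
        single = np.sqrt(np.mean(ep.data_uv[idx, :, :BASELINE_LEN] ** 2))
        avg = ep.data_uv[idx, :, :BASELINE_LEN].mean(axis=0)
        # baseline correction couples the window mean; compare mean-zeroed RMS
        avg -= avg.mean(axis=1, keepdims=True)
        averaged = np.sqrt(np.mean(avg ** 2))
        assert averaged < 0.5 * single
        assert averaged == pytest.approx(single / np.sqrt(idx.size), rel=0.25)


class TestMorlet:
    def test_tone_burst_localizes_at_its_frequency(self):
        fs = m.FS_HZ
        n_pre, n_post = 600, 1200
        rng = np.random.default_rng(4)
        wave = 0.01 * rng.normal(size=n_pre + n_post)   # broadband floor
        t = np.arange(n_post) / fs
        wave[n_pre:] += np.sin(2 * np.pi * 100.0 * t)
        freqs = np.array([25.0, 50.0, 100.0, 200.0, 400.0])
        tf = morlet_tf(wave, fs=fs, freqs=freqs, pre=n_pre)
        post_power = tf.power[:, n_pre + 300:].mean(axis=1)
        assert freqs[np.argmax(post_power)] == 100.0

    def test_prestimulus_normalized_power_is_one(self):
        rng = np.random.default_rng(5)
        wave = rng.normal(size=2400)
        tf = morlet_tf(wave, fs=m.FS_HZ, pre=1200)
        np.testing.assert_allclose(tf.power[:, :1200].mean(axis=1), 1.0,
                                   atol=1e-9)

    def test_frequency_above_nyquist_rejected(self):
        with pytest.raises(ValueError):
            morlet_tf(np.zeros(100), fs=m.FS_HZ, freqs=np.array([4000.0]), pre=10)

    def test_synthetic_on_centre_channel_shows_slow_and_high_gamma(
            self, small_epochs, geometry):
        avg = m.average_epochs(small_epochs, ConditionLabel("D3", 4))
        centers = default_finger_centers(geometry)
        ch = np.flatnonzero(
            (geometry.pos_um == centers["D3"]).all(axis=1))[0]
        row = np.flatnonzero(avg.channel_ids == ch)[0]
        tf = morlet_tf(avg.mean_uv[row], fs=avg.fs_hz, pre=avg.pre)
        win = slice(avg.pre, avg.pre + 250)
        elev = tf.power[:, win].max(axis=1)
        slow = (tf.freqs_hz >= 40) & (tf.freqs_hz <= 50)
        hg = (tf.freqs_hz >= 80) & (tf.freqs_hz <= 200)
        assert elev[slow].max() > 10.0
        assert elev[hg].max() > 10.0


class TestBandPower:
    def test_zero_signal_zero_power(self):
        p = _band_power(np.zeros((4, 2000)), (80, 200), m.FS_HZ, (500, 1000),
                        method="filter")
        assert np.all(p == 0.0)

    def test_quadratic_amplitude_scaling(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=(3, 3000))
        for method in ("filter", "periodogram"):
            p1 = _band_power(x, (80, 200), m.FS_HZ, (500, 2500), method=method)
            p2 = _band_power(2.0 * x, (80, 200), m.FS_HZ, (500, 2500),
                             method=method)
            np.testing.assert_allclose(p2, 4.0 * p1, rtol=1e-9)

    def test_disjoint_bands_sum_to_total(self):
        """Parseval-style additivity of the periodogram estimator."""
        rng = np.random.default_rng(2)
        x = rng.normal(size=(2, 4096))
        edges = [10.0, 50.0, 200.0, 800.0, 3000.0]
        parts = sum(_band_power(x, (lo, hi), m.FS_HZ, (0, 4096),
                                method="periodogram")
                    for lo, hi in zip(edges[:-1], edges[1:]))
        total = _band_power(x, (edges[0], edges[-1]), m.FS_HZ, (0, 4096),
                            method="periodogram")
        np.testing.assert_allclose(parts, total, rtol=1e-9)

    def test_high_gamma_argmax_matches_raw_amplitude_argmax(self, small_epochs,
                                                            geometry):
        """The contact with the strongest 80-200 Hz power is the contact with
        the largest raw evoked amplitude (high-gamma and raw maps agree)."""
        for finger in ("D1", "D3", "D5"):
            avg = m.average_epochs(small_epochs, ConditionLabel(finger, 4))
            power = band_power_map(avg, band=(80, 200))
            win = avg.mean_uv[:, avg.pre + 50:avg.pre + 251]
            raw_best = int(avg.channel_ids[np.argmax(win.max(axis=1))])
            hg_best = int(power.idxmax())
            d = np.linalg.norm(geometry.pos_um[raw_best] - geometry.pos_um[hg_best])
            assert d <= geometry.pitch_um / 2

    def test_empty_window_rejected(self):
        with pytest.raises(ValueError):
            _band_power(np.zeros((1, 100)), (80, 200), m.FS_HZ, (50, 50),
                        method="filter")


class TestRestRms:
    def test_sine_segment_rms_is_known(self, geometry):
        """A unit sine across the rest segment has RMS 1/sqrt(2)."""
        n = 4000
        v = np.tile(np.sin(2 * np.pi * 50.0 * np.arange(n) / m.FS_HZ),
                    (96, 1)).astype(np.float32)
        rec = m.Recording(fs_hz=m.FS_HZ, voltage_uv=v, trigger_idx=[2000],
                          label_codes=[0], geometry=geometry)
        rms = m.rest_rms(rec)
        np.testing.assert_allclose(rms.values, 1 / np.sqrt(2), rtol=0.02)

    def test_zero_recording_zero_rms(self, geometry):
        v = np.zeros((96, 3000), np.float32)
        rec = m.Recording(fs_hz=m.FS_HZ, voltage_uv=v, trigger_idx=[2000],
                          label_codes=[0], geometry=geometry)
        assert np.all(m.rest_rms(rec).values == 0.0)

    def test_insufficient_prestim_data_rejected(self, geometry):
        v = np.zeros((96, 3000), np.float32)
        rec = m.Recording(fs_hz=m.FS_HZ, voltage_uv=v, trigger_idx=[100],
                          label_codes=[0], geometry=geometry)
        with pytest.raises(ValueError):
            m.rest_rms(rec)
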