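"""EEG front end: filter response, closed-form feature checks on
sinusoids and noise, windowing and preictal labelling."""

import numpy as np
import pytest

from alarmcal.eeg import (
    EEGRecord,
    bandpass_filter,
    dfa_exponent,
    extract_features,
    higuchi_fd,
    hjorth_complexity,
    hjorth_mobility,
    label_preictal,
)
from alarmcal.errors import InvalidInputError, InvalidParameterError

FS = 256.0


def _record(x, fs=FS, onsets=()):
    return EEGRecord(data=np.atleast_2d(x), sampling_rate=fs, seizure_onsets=onsets)


def _sine(freq, dur=30.0, fs=FS, amp=1.0):
    t = np.arange(int(dur * fs)) / fs
    return amp * np.sin(2 * np.pi * freq * t)


class TestBandpass:
    def test_in_band_tone_retained(self):
        x = _sine(10.0, dur=60.0)
        y = bandpass_filter(_record(x)).data[0]
        core = slice(len(x) // 4, -len(x) // 4)
        gain = np.sqrt(np.mean(y[core] ** 2) / np.mean(x[core] ** 2))
        assert gain >= 0.95

    def test_slow_drift_attenuated(self):
        x = _sine(0.1, dur=120.0)
        y = bandpass_filter(_record(x)).data[0]
        core = slice(len(x) // 4, -len(x) // 4)
        atten_db = 20 * np.log10(
            np.sqrt(np.mean(x[core] ** 2)) / max(np.sqrt(np.mean(y[core] ** 2)), 1e-300)
        )
        assert atten_db >= 20.0

    def test_dc_removed(self):
        x = np.full(int(60 * FS), 3.7)
        y = bandpass_filter(_record(x)).data[0]
        assert np.abs(y).max() < 1e-4 * x[0]  # > 80 dB suppression

    def test_length_preserved(self):
        x = _sine(5.0, dur=20.0)
        assert bandpass_filter(_record(x)).data.shape[1] == x.size

    def test_band_outside_nyquist_rejected(self):
        with pytest.raises(InvalidParameterError):
            bandpass_filter(_record(_sine(5.0)), low=0.5, high=200.0)


class TestDescriptors:
    def test_hjorth_mobility_sinusoid_closed_form(self):
        f = 10.0
        assert hjorth_mobility(_sine(f), FS) == pytest.approx(2 * np.pi * f, rel=0.02)

    def test_hjorth_complexity_sinusoid_near_one(self):
        assert hjorth_complexity(_sine(7.0)) == pytest.approx(1.0, abs=0.05)

    def test_dfa_white_noise(self, rng):
        x = rng.standard_normal(4096)
        assert abs(dfa_exponent(x) - 0.5) <= 0.15

    def test_dfa_random_walk_rougher_than_noise(self, rng):
        steps = rng.standard_normal(4096)
        assert dfa_exponent(np.cumsum(steps)) > dfa_exponent(steps) + 0.5

    def test_higuchi_white_noise(self, rng):
        x = rng.standard_normal(4096)
        assert abs(higuchi_fd(x) - 2.0) <= 0.15

    def test_higuchi_smooth_curve_near_one(self):
        assert higuchi_fd(_sine(1.0, dur=4.0)) == pytest.approx(1.0, abs=0.2)


class TestExtractFeatures:
    def test_alpha_tone_concentrates_in_alpha_band(self):
        fm = extract_features(_record(_sine(10.0)))
        row = fm.values[0, 0]
        names = list(fm.feature_names)
        assert row[names.index("alpha_power")] > 0.9
        for band in ("delta_power", "theta_power", "beta_power", "gamma_power"):
            assert row[names.index(band)] < 0.05

    def test_band_fractions_bounded(self, rng):
        fm = extract_features(_record(rng.standard_normal(int(30 * FS))))
        bands = fm.values[:, :, :5]
        assert (bands >= 0).all()
        assert (bands.sum(axis=-1) <= 1.0 + 1e-9).all()

    def test_window_count_formula(self, rng):
        for dur in (6.0, 7.4, 12.0, 31.5):
            x = rng.standard_normal(int(dur * FS))
            fm = extract_features(_record(x))
            assert fm.values.shape[0] == int((dur - 6.0) // 3.0) + 1

    def test_scale_free_features_amplitude_invariant(self, rng):
        x = rng.standard_normal(int(12 * FS))
        a = extract_features(_record(x))
        b = extract_features(_record(100.0 * x))
        names = list(a.feature_names)
        scale_free = [names.index(n) for n in
                      ("delta_power", "theta_power", "alpha_power", "beta_power",
                       "gamma_power", "spectral_entropy", "dfa", "hjorth_complexity",
                       "higuchi_fd")]
        np.testing.assert_allclose(a.values[..., scale_free], b.values[..., scale_free],
                                   rtol=1e-8, atol=1e-8)

    def test_zero_variance_window_flagged(self):
        x = np.zeros(int(9 * FS))
        fm = extract_features(_record(x))
        assert fm.degenerate.all()
        assert (fm.values == 0).all()

    def test_too_short_record_rejected(self):
        with pytest.raises(InvalidInputError):
            extract_features(_record(np.ones(int(2 * FS))))

    def test_feature_matrix_io(self, tmp_path, rng):
        fm = extract_features(_record(rng.standard_normal(int(9 * FS))))
        fm.save(tmp_path / "features.csv")
        assert (tmp_path / "features.csv").exists()
        assert (tmp_path / "features.csv.json").exists()


class TestPreictalLabels:
    def test_interval_arithmetic_on_bounds(self):
        # onset at 61 min; 3 s window step
        onset = 61 * 60.0
        starts = np.arange(0, 3700, 3.0)
        lab = label_preictal(3700.0, [onset], starts)
        in_window = (starts >= onset - 3600.0) & (starts < onset - 30.0)
        assert (lab.values == in_window.astype(int)).all()
        assert lab.values[starts.searchsorted(onset - 3600.0)] == 1

    def test_no_seizures_all_zero(self):
        lab = label_preictal(600.0, [], np.arange(0, 594, 3.0))
        assert not lab.values.any()

    def test_exclusion_window_before_onset(self):
        starts = np.array([0.0, 100.0, 189.0, 195.0])
        lab = label_preictal(200.0, [199.0], starts)
        # 10 s before onset lies inside the 30 s exclusion
        assert lab.values.tolist() == [1, 1, 0, 0]

    def test_early_onset_clipped_with_warning(self):
        with pytest.warns(UserWarning):
            label_preictal(100.0, [-5.0], np.arange(0, 90, 3.0))

    def test_onset_beyond_record_rejected(self):
        with pytest.raises(InvalidInputError):
            label_preictal(100.0, [150.0], np.arange(0, 90, 3.0))
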