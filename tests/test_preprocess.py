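"""Preprocessing chain: epoching, artefact mask, Welch, grouping, normalization."""

import numpy as np
import pandas as pd
import pytest

from somnidec.montage import synthetic_montage
from somnidec.preprocess import (
    aggregate_cell,
    detect_artefacts,
    epoch_and_label,
    interpolate_bad_channels,
    normalize_channels,
    prepare_features,
    process_night,
    sharpen_spectrum,
    spatial_average,
    welch_psd,
)
from somnidec.synthdata import (
    Hypnogram,
    SimConfig,
    inject_artefacts,
    stage_spectrum_template,
    synthesize_recording,
)


def _recording(n_groups=4, minutes=10, fs=500.0, seed=0, stage="S2"):
    montage = synthetic_montage(n_groups, electrodes_per_group=3, seed=1)
    cfg = SimConfig(n_subjects=2, sampling_rate=fs)
    hyp = Hypnogram(stages=[stage] * int(minutes * 2))
    tmpl = stage_spectrum_template(stage)
    spec = {stage: np.tile(tmpl, (montage.n_electrodes, 1))}
    return synthesize_recording(hyp, spec, cfg, seed=seed), hyp, montage


class TestEpoching:
    def test_seven_trials_per_epoch(self):
        rec, hyp, _ = _recording(minutes=1)
        t = epoch_and_label(rec, hyp)
        assert len(t) == 2 * 7                      # floor(30/4) per 30-s epoch
        assert np.allclose(np.diff(t.onset_s[:7]), 4.0)

    def test_segment_by_onset(self):
        hyp = Hypnogram(stages=["S2"] * 960)        # 480 min
        t = epoch_and_label(np.zeros((1, 1)), hyp)
        just_before = t[np.isclose(t.onset_s, 89.9 * 60, atol=4)]
        assert (just_before.segment == 1).all()
        assert set(t.segment.unique()) == {1, 2, 3, 4, 5, -1}
        assert (t[t.onset_s >= 450 * 60].segment == -1).all()   # partial 6th segment dropped


class TestWelch:
    def test_bin_grid(self):
        f, p = welch_psd(np.random.default_rng(0).normal(size=1000), fs=250.0)
        assert len(f) == 60
        assert np.allclose(np.diff(f), 0.5)
        assert f[0] == 0.5 and f[-1] == 30.0

    def test_sinusoid_peak_matches_dft_oracle(self):
        fs = 250.0
        t = np.arange(1000) / fs
        x = np.sin(2 * np.pi * 10.0 * t)
        f, p = welch_psd(x, fs)
        assert f[np.argmax(p)] == 10.0
        # independent oracle: plain DFT periodogram of the same trial
        spec = np.abs(np.fft.rfft(x)) ** 2
        fr = np.fft.rfftfreq(1000, 1 / fs)
        assert abs(fr[np.argmax(spec)] - 10.0) < 0.5

    def test_white_noise_flat(self):
        rng = np.random.default_rng(1)
        _, p = welch_psd(rng.normal(size=(100, 1000)), fs=250.0)
        mean = p.mean(axis=0)
        assert mean.max() / mean.min() < 2.0

    def test_invalid_arguments(self):
        x = np.zeros(1000)
        with pytest.raises(ValueError):
            welch_psd(x, fs=250.0, overlap=1.0)
        with pytest.raises(ValueError):
            welch_psd(np.zeros(100), fs=250.0)      # window longer than signal


class TestSpatialAverage:
    def test_group_mean_arithmetic(self):
        montage = synthetic_montage(2, electrodes_per_group=3, seed=0)
        psd = np.ones((5, montage.n_electrodes, 60))
        out = spatial_average(psd, montage)
        assert out.shape == (5, 2, 60)
        assert np.allclose(out, 1.0)
        psd[:, montage.membership[0][0], :] *= 2.0    # one member doubled
        out2 = spatial_average(psd, montage)
        size = len(montage.membership[0])
        assert np.allclose(out2[:, 0, :], 1.0 + 1.0 / size)

    def test_group_without_members_is_missing(self):
        montage = synthetic_montage(2, electrodes_per_group=3, seed=0)
        bad = np.zeros(montage.n_electrodes, bool)
        bad[montage.membership[0]] = True
        out = spatial_average(np.ones((2, montage.n_electrodes, 60)), montage, bad)
        assert np.isnan(out[:, 0, :]).all()
        assert np.isfinite(out[:, 1, :]).all()


class TestAggregation:
    def _table(self, n):
        return pd.DataFrame({
            "trial": np.arange(n), "onset_s": np.arange(n) * 4.0,
            "stage": ["S2"] * n, "segment": [1] * n,
        })

    def test_minimum_trial_inclusion(self):
        spectra = np.ones((39, 4, 60))
        mean, n = aggregate_cell(spectra, self._table(39), np.zeros(39, bool), "S2", 1)
        assert mean is None and n == 39             # 39 < 40 clean trials -> excluded
        spectra = np.ones((40, 4, 60))
        mean, n = aggregate_cell(spectra, self._table(40), np.zeros(40, bool), "S2", 1)
        assert np.allclose(mean, 1.0) and n == 40

    def test_mean_of_two_values(self):
        spectra = np.concatenate([np.full((20, 1, 60), 0.2), np.full((20, 1, 60), 0.4)])
        mean, _ = aggregate_cell(spectra, self._table(40), np.zeros(40, bool), "S2", 1)
        assert np.allclose(mean, 0.3)


class TestNormalizeSharpen:
    def test_minmax_example(self):
        assert np.allclose(normalize_channels(np.array([[2.0, 4.0, 6.0]])), [[0, 0.5, 1]])

    def test_endpoints_and_scale_invariance(self):
        rng = np.random.default_rng(2)
        x = rng.random((4, 60))
        n = normalize_channels(x)
        assert np.allclose(n.min(axis=1), 0) and np.allclose(n.max(axis=1), 1)
        assert np.allclose(normalize_channels(10 * x), n)

    def test_constant_channel_warns_and_zeros(self):
        with pytest.warns(UserWarning):
            out = normalize_channels(np.full((1, 60), 3.0))
        assert np.allclose(out, 0.0)

    def test_sharpen_closed_forms(self):
        assert np.allclose(sharpen_spectrum(np.full(60, 0.7)), 0.0)
        ramp = np.arange(60, dtype=float)
        assert np.allclose(sharpen_spectrum(ramp)[3:-3], 0.0)   # symmetric window cancels slope
        spike = np.zeros(60)
        spike[30] = 1.0
        out = sharpen_spectrum(spike)
        assert np.isclose(out[30], 1.0)
        assert np.isclose(out[29], -1.0 / 6.0) and np.isclose(out[31], -1.0 / 6.0)

    def test_sharpen_needs_enough_bins(self):
        with pytest.raises(ValueError):
            sharpen_spectrum(np.ones(5))

    def test_pipeline_order_is_not_commutative(self):
        rng = np.random.default_rng(3)
        x = rng.random((2, 60)) * 50
        a = sharpen_spectrum(normalize_channels(x))
        b = normalize_channels(sharpen_spectrum(x))
        assert not np.allclose(a, b)
        assert np.allclose(prepare_features(x), a)   # canonical order: normalize then sharpen


@pytest.fixture(scope="module")
def contaminated():
    rec, hyp, montage = _recording(n_groups=4, minutes=10, fs=500.0, seed=4)
    dirty, truth = inject_artefacts(
        rec, {"disconnect": 0.08, "jump": 0.04, "muscle": 0.08}, seed=5
    )
    trials = epoch_and_label(dirty, hyp)
    return rec, dirty, truth, trials, montage


class TestArtefactDetection:
    def test_clean_recording_low_false_positive(self, contaminated):
        rec, _, _, trials, _ = contaminated
        mask = detect_artefacts(rec, trials)
        assert mask.trial_channel.mean() < 0.01

    def test_dead_channel_marked_bad_whole(self, contaminated):
        _, dirty, truth, trials, _ = contaminated
        if not truth.bad_channels.any():
            pytest.skip("no disconnection drawn at this seed")
        mask = detect_artefacts(dirty, trials)
        assert np.all(mask.bad_channels[truth.bad_channels])

    def test_transient_sensitivity(self, contaminated):
        _, dirty, truth, trials, _ = contaminated
        mask = detect_artefacts(dirty, trials)
        inj = truth.trial_channel & ~truth.bad_channels[None, :]
        assert inj.sum() > 0
        sens = (mask.trial_channel & inj).sum() / inj.sum()
        assert sens > 0.9

    def test_low_rate_skips_muscle_with_warning(self):
        rec, hyp, _ = _recording(n_groups=2, minutes=2, fs=250.0)
        trials = epoch_and_label(rec, hyp)
        with pytest.warns(UserWarning, match="muscle"):
            detect_artefacts(rec, trials)

    def test_all_flagged_aborts(self):
        rec, hyp, _ = _recording(n_groups=2, minutes=2, fs=250.0)
        trials = epoch_and_label(rec, hyp)
        import warnings
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            with pytest.raises(RuntimeError):
                detect_artefacts(rec, trials, mad_k=0.0, channel_bad_fraction=1.1)


class TestInterpolation:
    def test_identical_neighbours_reconstruct(self):
        montage = synthetic_montage(2, electrodes_per_group=4, seed=0)
        rng = np.random.default_rng(0)
        common = rng.normal(size=500)
        from somnidec.synthdata import Recording
        sig = np.tile(common, (montage.n_electrodes, 1))
        rec = Recording(signal=sig.copy(), sampling_rate=100.0, subject_id=0,
                        night_index=0, condition="face")
        rec.signal[0] = 99.0
        bad = np.zeros(montage.n_electrodes, bool)
        bad[0] = True
        out, excluded = interpolate_bad_channels(rec, bad, montage)
        assert not excluded
        assert np.allclose(out.signal[0], common)

    def test_no_bad_channels_identity(self):
        montage = synthetic_montage(2, electrodes_per_group=3, seed=0)
        rec, _, _ = _recording(n_groups=2, minutes=1)
        out, _ = interpolate_bad_channels(rec, np.zeros(montage.n_electrodes, bool), montage)
        assert np.array_equal(out.signal, rec.signal)

    def test_interpolated_variance_bounded(self):
        rec, hyp, montage = _recording(n_groups=3, minutes=2)
        bad = np.zeros(montage.n_electrodes, bool)
        bad[1] = True
        out, excluded = interpolate_bad_channels(rec, bad, montage)
        if excluded:
            pytest.skip("channel isolated in this layout")
        d = np.linalg.norm(montage.electrode_pos - montage.electrode_pos[1], axis=1)
        nb = np.flatnonzero((d <= 2 * montage.radius) & ~bad & (d > 0))
        assert np.var(out.signal[1]) <= max(np.var(rec.signal[c]) for c in nb) + 1e-9


def test_process_night_shapes_and_inclusion():
    """Full raw chain on one 90-min segment: cells are (n_groups x 60), >= 40 trials."""
    import warnings

    rec, hyp, montage = _recording(n_groups=2, minutes=90, fs=250.0, seed=6)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)   # muscle band unrepresentable at 250 Hz
        cells = process_night(rec, hyp, montage, min_trials=40)
    assert ("S2", 1) in cells
    for (stage, seg), (mean, n) in cells.items():
        assert seg == 1
        assert mean.shape == (2, 60)
        assert n >= 40
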