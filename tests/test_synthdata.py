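"""Generator properties: hypnograms, templates, signatures, artefacts, behaviour."""

import numpy as np
import pandas as pd
import pytest

from somnidec.preprocess import welch_psd
from somnidec.synthdata import (
    BANDS,
    FREQS,
    Hypnogram,
    SimConfig,
    band_mask,
    embed_condition_signature,
    generate_behaviour,
    generate_hypnogram,
    inject_artefacts,
    simulate_cells,
    simulate_night_trials,
    stage_spectrum_template,
    synthesize_recording,
)


class TestHypnogram:
    def test_epoch_count_and_labels(self):
        h = generate_hypnogram(480, seed=1)
        assert len(h) == 960                      # 480 min / 30 s
        assert set(h.stages) <= {"W", "S1", "S2", "S3", "S4", "REM", "MT"}

    @pytest.mark.parametrize("seed", range(5))
    def test_single_cycle_contains_all_analysis_stages(self, seed):
        h = generate_hypnogram(90, seed=seed)
        for stage in ("S2", "S4", "REM"):
            assert stage in h.stages

    def test_every_full_segment_contains_s2_sws_rem(self):
        h = generate_hypnogram(480, seed=3)
        for seg in range(1, 6):
            stages = {h.stages[i] for i in range(len(h)) if h.segment_of_epoch(i) == seg}
            assert "S2" in stages and "REM" in stages
            assert stages & {"S3", "S4"}

    def test_deterministic(self):
        assert generate_hypnogram(120, seed=9).stages == generate_hypnogram(120, seed=9).stages

    def test_invalid_duration(self):
        with pytest.raises(ValueError):
            generate_hypnogram(0)
        with pytest.raises(ValueError):
            generate_hypnogram(90.25)

    def test_unknown_stage_label_rejected(self):
        with pytest.raises(ValueError):
            Hypnogram(stages=["S2", "XX"])


class TestTemplates:
    def test_deep_sleep_is_delta_dominant(self):
        t = stage_spectrum_template("S4")
        assert t[FREQS == 1.0] > t[FREQS == 20.0]

    def test_s2_has_spindle_peak(self):
        t = stage_spectrum_template("S2")
        m = (FREQS >= 11) & (FREQS <= 16)
        i = np.flatnonzero(m)[np.argmax(t[m])]
        assert t[i] > t[i - 2] and t[i] > t[i + 2]   # local maximum inside 11-16 Hz

    def test_rem_has_theta_bump(self):
        t = stage_spectrum_template("REM")
        flat = stage_spectrum_template("W")
        theta = band_mask("theta")
        assert (t[theta] / (60.0 / FREQS[theta] ** 1.3)).max() > 1.5

    def test_strictly_positive_and_deterministic(self):
        for st in ("W", "S1", "S2", "S3", "S4", "REM", "MT"):
            t = stage_spectrum_template(st)
            assert np.all(t > 0)
        a = stage_spectrum_template("S2", {b: 1.0 for b in BANDS})
        b = stage_spectrum_template("S2", {b: 1.0 for b in BANDS})
        assert np.array_equal(a, b)

    def test_unknown_stage(self):
        with pytest.raises(ValueError):
            stage_spectrum_template("S9")


class TestSignature:
    def setup_method(self):
        self.cfg = SimConfig(n_subjects=4, signature_cells=(("CP4", "spindle"),),
                             signature_segments=(2,), signature_stages=("S2",))
        tmpl = stage_spectrum_template("S2")
        self.spectra = {("S2", 1): np.tile(tmpl, (32, 1)), ("S2", 2): np.tile(tmpl, (32, 1))}

    def test_zero_amplitude_is_identity(self):
        out = embed_condition_signature(self.spectra, self.cfg, "face", amplitude=0.0)
        for k in self.spectra:
            assert np.array_equal(out[k], self.spectra[k])

    def test_face_house_ratio(self):
        face = embed_condition_signature(self.spectra, self.cfg, "face", amplitude=0.2)
        house = embed_condition_signature(self.spectra, self.cfg, "house", amplitude=0.2)
        gi = self.cfg.group_names.index("CP4")
        m = band_mask("spindle")
        ratio = face[("S2", 2)][gi, m] / house[("S2", 2)][gi, m]
        assert np.allclose(ratio, 1.2 / 0.8)

    def test_untouched_outside_signature_segments(self):
        face = embed_condition_signature(self.spectra, self.cfg, "face", amplitude=0.2)
        house = embed_condition_signature(self.spectra, self.cfg, "house", amplitude=0.2)
        assert np.array_equal(face[("S2", 1)], house[("S2", 1)])

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            embed_condition_signature(self.spectra, self.cfg, "face", amplitude=-0.1)
        with pytest.raises(ValueError):
            embed_condition_signature(self.spectra, self.cfg, "cat")


class TestRecordingSynthesis:
    def test_welch_spectrum_converges_to_template(self):
        cfg = SimConfig(n_subjects=2, sampling_rate=250.0)
        hyp = Hypnogram(stages=["S4"] * 12)          # 6 min of S4
        tmpl = stage_spectrum_template("S4")
        rec = synthesize_recording(hyp, {"S4": np.tile(tmpl, (2, 1))}, cfg, seed=0)
        f, p = welch_psd(rec.signal.astype(np.float64), 250.0)
        psd = p.mean(axis=0)
        assert np.abs(psd[f <= 4] / tmpl[f <= 4] - 1).mean() < 0.10
        assert np.abs(np.log(psd / tmpl)).mean() < 0.05   # spectral fidelity

    def test_deterministic_and_errors(self):
        cfg = SimConfig(n_subjects=2, sampling_rate=100.0)
        hyp = Hypnogram(stages=["S2"] * 2)
        spec = {"S2": np.tile(stage_spectrum_template("S2"), (2, 1))}
        a = synthesize_recording(hyp, spec, cfg, seed=4)
        b = synthesize_recording(hyp, spec, cfg, seed=4)
        assert np.array_equal(a.signal, b.signal)
        with pytest.raises(ValueError):
            synthesize_recording(Hypnogram(stages=[]), spec, cfg)
        with pytest.raises(ValueError):
            synthesize_recording(Hypnogram(stages=["REM"]), spec, cfg)


@pytest.fixture(scope="module")
def recording():
    cfg = SimConfig(n_subjects=2, sampling_rate=500.0)
    hyp = Hypnogram(stages=["S2"] * 10)
    spec = {"S2": np.tile(stage_spectrum_template("S2"), (8, 1))}
    return synthesize_recording(hyp, spec, cfg, seed=11)


class TestArtefacts:
    def test_zero_rates_identity(self, recording):
        out, truth = inject_artefacts(recording, {"disconnect": 0, "jump": 0, "muscle": 0}, seed=0)
        assert np.array_equal(out.signal, recording.signal)
        assert truth.trial_channel.sum() == 0

    def test_jump_rate_binomial(self):
        cfg = SimConfig(n_subjects=2, sampling_rate=100.0)
        hyp = Hypnogram(stages=["S2"] * 150)          # ~1050 trials
        spec = {"S2": np.tile(stage_spectrum_template("S2"), (2, 1))}
        rec = synthesize_recording(hyp, spec, cfg, seed=1)
        _, truth = inject_artefacts(rec, {"jump": 0.05}, seed=2)
        n = len(truth.kinds["jump"])
        n_trials = truth.trial_channel.shape[0]
        # ~rate * n_trials within 4 binomial SDs
        assert abs(n - 0.05 * n_trials) < 4 * np.sqrt(n_trials * 0.05 * 0.95)

    def test_muscle_burst_band_power(self, recording):
        out, truth = inject_artefacts(recording, {"muscle": 0.2}, seed=3)
        t, c = truth.kinds["muscle"][0]
        from somnidec.synthdata import trial_onsets
        on = trial_onsets(out.signal.shape[1], 500.0)
        f = np.fft.rfftfreq(2000, 1 / 500.0)
        band = (f >= 110) & (f <= 140)

        def bp(sig, o):
            return (np.abs(np.fft.rfft(sig[c, o: o + 2000].astype(float))) ** 2)[band].sum()

        clean_med = np.median([bp(recording.signal, o) for o in on[:40]])
        assert bp(out.signal, on[t]) > 5 * clean_med


class TestBehaviour:
    def _strengths(self, n, rng):
        return pd.DataFrame({
            "subject": np.repeat(np.arange(n), 2),
            "night": np.tile([0, 1], n),
            "strength": rng.uniform(0.1, 0.9, size=2 * n),
        })

    def test_counts_within_bounds(self):
        rng = np.random.default_rng(0)
        cfg = SimConfig(n_subjects=8)
        df = generate_behaviour(cfg, self._strengths(8, rng), seed=0)
        assert ((df.hits >= 0) & (df.hits <= df.n_old)).all()
        assert ((df.false_alarms >= 0) & (df.false_alarms <= df.n_new)).all()

    def test_link_strength_correlation(self):
        from somnidec.behavior import consolidation_table, spearman

        rng = np.random.default_rng(1)
        s = self._strengths(32, rng)                  # 64 nights
        cfg0 = SimConfig(n_subjects=32, behaviour_link=0.0, behaviour_noise_sd=0.3)
        rho0, _ = spearman(s.strength, consolidation_table(
            generate_behaviour(cfg0, s, seed=2)).consolidation)
        assert abs(rho0) < 0.3
        # strong link, tiny noise: recovery limited only by binomial count noise
        cfg1 = SimConfig(n_subjects=32, behaviour_link=3.0, behaviour_noise_sd=0.01)
        rho1, _ = spearman(s.strength, consolidation_table(
            generate_behaviour(cfg1, s, seed=2)).consolidation)
        assert rho1 > 0.8


class TestFeatureCohort:
    def test_bitwise_determinism(self):
        cfg = SimConfig(n_subjects=4, n_groups=4, n_bins=12, night_duration_min=180,
                        signature_cells=((2, "spindle"),), seed=5)
        a = simulate_cells(cfg)
        b = simulate_cells(cfg)
        for k in a.cells:
            assert np.array_equal(a.cells[k].X, b.cells[k].X)
        pd.testing.assert_frame_equal(a.behaviour, b.behaviour)

    def test_counterbalancing(self):
        coh = simulate_cells(SimConfig(n_subjects=10, n_groups=4, n_bins=12,
                                       signature_cells=((2, "spindle"),),
                                       night_duration_min=180, seed=6))
        for s in range(10):
            conds = {coh.conditions[(s, 0)], coh.conditions[(s, 1)]}
            assert conds == {"face", "house"}

    def test_trial_level_view_consistent_with_cells(self):
        cfg = SimConfig(n_subjects=3, n_groups=4, n_bins=12, night_duration_min=180,
                        signature_cells=((2, "spindle"),), seed=8)
        coh = simulate_cells(cfg)
        nt = simulate_night_trials(cfg, subject=1, night=0)
        assert nt.condition == coh.conditions[(1, 0)]
        # same hypnogram stream: stage counts agree with the cell trial counts
        assert nt.spectra.shape[1:] == (4, 12)
        assert np.all(nt.onsets[:-1] <= nt.onsets[1:])

    def test_invalid_config(self):
        with pytest.raises(ValueError):
            SimConfig(n_subjects=1)
        with pytest.raises(ValueError):
            SimConfig(signature_amplitude=-0.2)
        with pytest.raises(ValueError):
            SimConfig(artefact_rates={"jump": 1.4})
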