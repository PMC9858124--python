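"""Generator contracts: determinism, constructions, spectral fidelity."""

import dataclasses

import numpy as np
import pytest

import tremordetect as td
from tremordetect.config import SubjectParams
from tremordetect.labeling import band_peak_powers


def _params(freq=6.0, amp=5.0, depth=0.9, physio=10.0, snr=20.0):
    return SubjectParams(subject_id="S01", design_label="tremor",
                         tremor_freq=freq, tremor_amp_deg=amp,
                         tremor_depth=depth, physio_freq=physio, snr_db=snr)


class TestKinematicSimulation:
    def test_pure_sinusoid_construction(self, clean_cfg):
        """Noise/jitter-free patient stream is a pure sinusoid at f_t with
        amplitude A in the recovered flexion angle."""
        qs = td.simulate_kinematics(clean_cfg, "tremor",
                                    params=_params(freq=6.0, amp=5.0))
        ang = td.quaternions_to_wrist_angle(qs).angle
        assert ang.max() == pytest.approx(5.0, abs=0.02)
        assert ang.min() == pytest.approx(-5.0, abs=0.02)
        # all band-limited power concentrated at 6 Hz
        freqs = np.fft.rfftfreq(ang.size, d=1 / qs.fs)
        amp_spec = np.abs(np.fft.rfft(ang - ang.mean()))
        assert freqs[np.argmax(amp_spec)] == pytest.approx(6.0, abs=0.1)

    def test_healthy_zero_noise_identity(self, clean_cfg):
        """With drift, noise and physiological tremor off, hand and forearm
        streams coincide and the relative angle is identically zero."""
        qs = td.simulate_kinematics(clean_cfg, "no-tremor")
        np.testing.assert_allclose(qs.hand_q, qs.forearm_q, atol=1e-12)
        ang = td.quaternions_to_wrist_angle(qs).angle
        np.testing.assert_allclose(ang, 0.0, atol=1e-9)

    def test_determinism(self, small_cfg):
        a = td.simulate_kinematics(small_cfg, "tremor", "P01", trial=3)
        b = td.simulate_kinematics(small_cfg, "tremor", "P01", trial=3)
        np.testing.assert_array_equal(a.hand_q, b.hand_q)
        np.testing.assert_array_equal(a.forearm_q, b.forearm_q)

    def test_unit_quaternions(self, small_cfg):
        qs = td.simulate_kinematics(small_cfg, "tremor")
        qs.validate_norms(tol=1e-9)

    def test_anatomical_range_rejected(self):
        cfg = td.CohortConfig(tremor_amp_range_deg=(80.0, 89.0),
                              trial_duration=5.0)
        with pytest.raises(td.ConfigError):
            td.simulate_kinematics(cfg, "tremor",
                                   params=_params(amp=89.0, freq=5.0))

    def test_spectral_fidelity_band_power(self, clean_cfg):
        """>= 99% of band-limited power of the noise-free tremor angle lies
        within f_t +- 0.5 Hz."""
        qs = td.simulate_kinematics(clean_cfg, "tremor",
                                    params=_params(freq=6.5, amp=8.0))
        ang = td.quaternions_to_wrist_angle(qs).angle
        freqs = np.fft.rfftfreq(ang.size, d=1 / qs.fs)
        p = np.abs(np.fft.rfft(ang - ang.mean())) ** 2
        band = (freqs >= 1.0) & (freqs <= 24.0)
        near = band & (np.abs(freqs - 6.5) <= 0.5)
        assert p[near].sum() / p[band].sum() >= 0.99


class TestEmgSimulation:
    def test_determinism(self, small_cfg):
        a = td.simulate_emg(small_cfg, "tremor", "FCR", "P01", trial=1)
        b = td.simulate_emg(small_cfg, "tremor", "FCR", "P01", trial=1)
        np.testing.assert_array_equal(a.samples, b.samples)

    def test_no_modulation_no_band_peak(self, clean_cfg):
        """Zero modulation depth leaves no tremor-band envelope line above
        the noise floor."""
        rec = td.simulate_emg(clean_cfg, "tremor", "FCR",
                              params=_params(depth=0.0))
        env = td.emg_envelope(td.downsample_emg(rec))
        ws = td.segment_windows(env)
        peaks, _ = band_peak_powers(ws.windows, env.fs)
        # compare with a strongly modulated twin
        rec2 = td.simulate_emg(clean_cfg, "tremor", "ECR",
                               params=_params(depth=0.9))
        env2 = td.emg_envelope(td.downsample_emg(rec2))
        peaks2, _ = band_peak_powers(td.segment_windows(env2).windows, env2.fs)
        # the unmodulated envelope peak is noise floor only; a deep
        # modulation puts an order of magnitude more power in the band
        assert np.median(peaks2) > 10 * np.median(peaks)

    def test_envelope_peak_tracks_tremor_frequency(self, clean_cfg):
        """Tremor-class EMG at f_t = 5 Hz yields envelope periodogram peaks
        within 5 +- 1 Hz (generator -> preprocessing round trip)."""
        rec = td.simulate_emg(clean_cfg, "tremor", "FCR",
                              params=_params(freq=5.0, depth=0.9))
        env = td.emg_envelope(td.downsample_emg(rec))
        ws = td.segment_windows(env)
        _, pfreqs = band_peak_powers(ws.windows, env.fs)
        assert np.abs(np.median(pfreqs) - 5.0) <= 1.0

    def test_antiphase_channels(self, clean_cfg):
        """FCR and ECR burst trains alternate: their tremor-band envelopes
        are negatively correlated."""
        p = _params(freq=5.0, depth=0.9)
        fcr = td.simulate_emg(clean_cfg, "tremor", "FCR", params=p)
        ecr = td.simulate_emg(clean_cfg, "tremor", "ECR", params=p)
        e1 = td.emg_envelope(td.downsample_emg(fcr)).samples
        e2 = td.emg_envelope(td.downsample_emg(ecr)).samples
        r = np.corrcoef(e1, e2)[0, 1]
        assert r < -0.3

    def test_classes_have_comparable_total_power(self, small_cfg):
        pat = td.simulate_emg(small_cfg, "tremor", "FCR", "P01")
        hea = td.simulate_emg(small_cfg, "no-tremor", "FCR", "H01")
        ratio = np.var(pat.samples) / np.var(hea.samples)
        assert 0.5 < ratio < 2.0

    def test_carrier_band_rejected_config(self):
        cfg = td.CohortConfig(emg_carrier_band=(20.0, 1500.0))
        with pytest.raises(td.ConfigError):
            td.simulate_emg(cfg, "tremor", "FCR")


class TestCohort:
    def test_counts_single_trial(self):
        """12 patients + 11 healthy at one trial each -> 23 kinematic
        streams and 46 EMG recordings."""
        cfg = td.CohortConfig(n_patients=12, n_healthy=11, n_trials=1,
                              trial_duration=2.0, seed=5)
        cohort = td.generate_cohort(cfg)
        assert len(cohort.kinematic_streams) == 23
        assert len(cohort.emg_recordings) == 46
        labels = [r.params.design_label for r in cohort.recordings]
        assert labels.count("tremor") == 12

    def test_no_patients_all_no_tremor(self):
        cfg = td.CohortConfig(n_patients=0, n_healthy=2, n_trials=1,
                              trial_duration=2.0)
        cohort = td.generate_cohort(cfg)
        assert all(r.params.design_label == "no-tremor"
                   for r in cohort.recordings)

    def test_manifest_reproducible(self, small_cfg):
        a = td.generate_cohort(small_cfg)
        b = td.generate_cohort(small_cfg)
        assert a.manifest() == b.manifest()
        np.testing.assert_array_equal(a.recordings[0].emg_fcr.samples,
                                      b.recordings[0].emg_fcr.samples)

    def test_subject_params_logged(self, small_cfg):
        cohort = td.generate_cohort(small_cfg)
        man = cohort.manifest()
        assert len(man["subjects"]) == 4
        assert {"tremor_freq", "tremor_amp_deg"} <= set(man["subjects"][0])
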