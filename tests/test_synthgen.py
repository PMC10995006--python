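"""Generator: controllable band powers, planted effects, determinism."""

import numpy as np
import pytest

from n2oeeg.montage import BIOSEMI32_CHANNELS
from n2oeeg.spectra import DEFAULT_BANDS, band_power, estimate_spectrum
from n2oeeg.synthgen import (
    CohortConfig,
    EffectProfile,
    Recording,
    _channel_targets,
    generate_cohort,
    generate_recording,
    reject_artifact_epochs,
    synthesize_epoch,
)

BAND_NAMES = [b.name for b in DEFAULT_BANDS]


def estimated_band_powers(epochs: np.ndarray, fs: float = 256.0) -> np.ndarray:
    """Hann-periodogram band powers of a (n_epochs, n_ch, n_samp) stack."""
    spec = estimate_spectrum(epochs, fs)
    return band_power(spec).to_numpy()  # (4, n_ch)


class TestSynthesizeEpoch:
    def test_zero_targets_give_zero_epoch(self):
        epoch = synthesize_epoch(np.zeros((3, 4)), 256, 2, seed=1)
        assert epoch.shape == (3, 512)
        assert np.all(epoch == 0)

    def test_deterministic_given_seed(self):
        t = np.array([[40.0, 20.0, 25.0, 10.0]])
        a = synthesize_epoch(t, 256, 2, seed=7)
        b = synthesize_epoch(t, 256, 2, seed=7)
        assert np.array_equal(a, b)
        assert not np.array_equal(a, synthesize_epoch(t, 256, 2, seed=8))

    def test_band_powers_recovered_within_10pct(self):
        targets = np.array([[40.0, 20.0, 25.0, 10.0]])
        eps = np.stack(
            [synthesize_epoch(targets, 256, 2, seed=i)[0] for i in range(150)]
        )[:, None, :]
        est = estimated_band_powers(eps)[:, 0]
        assert np.all(np.abs(est / targets[0] - 1) < 0.10)

    def test_doubling_one_band_doubles_only_that_band(self):
        base = np.array([[10.0, 10.0, 10.0, 10.0]])
        doubled = base.copy()
        doubled[0, 0] *= 2  # delta
        est_base = estimated_band_powers(
            np.stack([synthesize_epoch(base, 256, 2, seed=i)[0] for i in range(200)])[:, None, :]
        )[:, 0]
        est_doubled = estimated_band_powers(
            np.stack([synthesize_epoch(doubled, 256, 2, seed=1000 + i)[0] for i in range(200)])[:, None, :]
        )[:, 0]
        ratio = est_doubled / est_base
        assert ratio[0] == pytest.approx(2.0, rel=0.10)
        # other bands move only by edge leakage, well below a doubling
        assert np.all(np.abs(ratio[1:] - 1.0) < 0.10)

    def test_white_noise_calibration_delta_beta_ratio_unity(self):
        # equal per-Hz power in every band: band powers are per-frequency
        # means, so the delta:beta ratio must be ~1 despite beta's width
        flat = np.full((1, 4), 15.0)
        eps = np.stack(
            [synthesize_epoch(flat, 256, 2, seed=i)[0] for i in range(300)]
        )[:, None, :]
        est = estimated_band_powers(eps)[:, 0]
        assert est[0] / est[3] == pytest.approx(1.0, abs=0.07)

    @pytest.mark.parametrize(
        "targets,fs,duration,match",
        [
            (-np.ones((1, 4)), 256, 2, "non-negative"),
            (np.ones((1, 4)), 256, 0, "positive"),
            (np.ones((1, 4)), 256, 0.3, "integer"),
        ],
    )
    def test_invalid_inputs_rejected(self, targets, fs, duration, match):
        with pytest.raises(ValueError, match=match):
            synthesize_epoch(targets, fs, duration, seed=0)


class TestEffectProfile:
    def test_dose_zero_multiplier_is_one_everywhere(self):
        profile = EffectProfile()
        for band in BAND_NAMES:
            for region in ("frontal", "lateral", "central", "occipital"):
                assert profile.dose_multiplier(band, region, 0) == 1.0

    def test_dose40_direction_frontal_delta_down_beta_up(self):
        profile = EffectProfile()
        assert profile.dose_multiplier("delta", "frontal", 40) == pytest.approx(0.6)
        assert profile.dose_multiplier("beta", "central", 40) == pytest.approx(1.5)
        assert profile.dose_multiplier("delta", "occipital", 40) == 1.0
        assert profile.dose_multiplier("alpha", "frontal", 40) == 1.0

    def test_log_linear_interpolation_in_dose(self):
        profile = EffectProfile()
        m20 = profile.dose_multiplier("delta", "frontal", 20)
        assert m20 == pytest.approx(0.6**0.5)
        assert 0.6 < m20 < 1.0

    def test_null_profile_has_no_dose_effect(self):
        null = EffectProfile().null()
        for dose in (20, 30, 40):
            assert null.dose_multiplier("delta", "frontal", dose) == 1.0
            assert null.dose_multiplier("beta", "central", dose) == 1.0

    def test_invalid_profiles_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            EffectProfile(baseline_band_power={"delta": -1.0})
        with pytest.raises(ValueError, match="positive"):
            EffectProfile(dose_effects={"delta": 0.0})
        with pytest.raises(ValueError, match="region"):
            EffectProfile(affected_regions=("parietal",))


class TestGenerateRecording:
    config = CohortConfig(conditions=(0, 40), n_epochs=3)

    def test_dose_zero_targets_equal_baseline_times_participant(self):
        effects = {"delta": 2.0, "theta": 0.5, "alpha": 1.0, "beta": 1.3}
        targets = _channel_targets(effects, 0, EffectProfile(), self.config, DEFAULT_BANDS)
        expected = np.array([40.0 * 2, 20.0 * 0.5, 25.0, 10.0 * 1.3])
        assert np.allclose(targets, expected[None, :])

    def test_dose40_shifts_frontal_targets_in_planted_direction(self):
        profile = EffectProfile()
        for mult in (0.4, 1.0, 2.7):
            effects = {b: mult for b in BAND_NAMES}
            t0 = _channel_targets(effects, 0, profile, self.config, DEFAULT_BANDS)
            t40 = _channel_targets(effects, 40, profile, self.config, DEFAULT_BANDS)
            fp1 = self.config.channel_labels.index("Fp1")
            oz = self.config.channel_labels.index("Oz")
            assert t40[fp1, 0] < t0[fp1, 0]  # frontal delta down
            assert t40[fp1, 3] > t0[fp1, 3]  # frontal beta up
            assert t40[oz, 0] == t0[oz, 0]  # occipital untouched

    def test_identical_seeds_identical_recordings(self):
        effects = {b: 1.0 for b in BAND_NAMES}
        a = generate_recording(effects, "P01", 40, EffectProfile(), self.config, seed=3)
        b = generate_recording(effects, "P01", 40, EffectProfile(), self.config, seed=3)
        assert np.array_equal(a.epochs, b.epochs)

    def test_unknown_condition_rejected(self):
        effects = {b: 1.0 for b in BAND_NAMES}
        with pytest.raises(ValueError, match="condition"):
            generate_recording(effects, "P01", 30, EffectProfile(), self.config, seed=0)

    def test_unmapped_channel_rejected(self):
        config = CohortConfig(conditions=(0, 40), channel_labels=("Fp1", "NoSuch"), n_epochs=2)
        effects = {b: 1.0 for b in BAND_NAMES}
        with pytest.raises(KeyError, match="NoSuch"):
            generate_recording(effects, "P01", 0, EffectProfile(), config, seed=0)


class TestGenerateCohort:
    def test_default_design_yields_48_recordings(self):
        config = CohortConfig(n_epochs=1, seed=0)
        recordings = generate_cohort(config)
        assert len(recordings) == 48
        keys = {(r.participant_id, r.condition) for r in recordings}
        assert len(keys) == 48

    def test_binary_design_yields_24_recordings(self):
        config = CohortConfig(conditions=(0, 40), n_epochs=1, seed=0)
        assert len(generate_cohort(config)) == 24

    def test_same_seed_bit_identical_cohorts(self):
        config = CohortConfig(conditions=(0, 40), n_participants=2, n_epochs=2, seed=5)
        a = generate_cohort(config)
        b = generate_cohort(config)
        for ra, rb in zip(a, b):
            assert ra.participant_id == rb.participant_id
            assert np.array_equal(ra.epochs, rb.epochs)

    def test_participant_multipliers_shared_across_conditions(self):
        # the same participant's dose-0 and dose-40 recordings must share
        # baseline structure: occipital (unaffected) band powers agree
        config = CohortConfig(conditions=(0, 40), n_participants=2, n_epochs=40, seed=2)
        recs = {(r.participant_id, r.condition): r for r in generate_cohort(config)}
        from n2oeeg.montage import default_region_map

        occ = [
            i for i, ch in enumerate(config.channel_labels)
            if default_region_map()[ch] == "occipital"
        ]
        for pid in ("P01", "P02"):
            p0 = estimated_band_powers(recs[(pid, 0)].epochs)[:, occ]
            p40 = estimated_band_powers(recs[(pid, 40)].epochs)[:, occ]
            ratio = (p40 / p0).mean(axis=1)  # average over 10 channels
            assert np.all(np.abs(ratio - 1) < 0.15)


class TestRejectArtifactEpochs:
    def _recording(self, epochs):
        return Recording("P01", 0, ("a", "b"), 256.0, epochs)

    def test_threshold_above_max_removes_nothing(self):
        rec = self._recording(np.random.default_rng(0).normal(0, 1, (5, 2, 64)))
        cleaned, n = reject_artifact_epochs(rec, amplitude_threshold=1e6)
        assert n == 0
        assert np.array_equal(cleaned.epochs, rec.epochs)

    def test_injected_spike_removes_exactly_that_epoch(self):
        epochs = np.random.default_rng(1).normal(0, 1, (6, 2, 64))
        epochs[3, 1, 10] = 10 * np.abs(epochs).max()
        rec = self._recording(epochs)
        cleaned, n = reject_artifact_epochs(rec, amplitude_threshold=np.abs(epochs).max() / 2)
        assert n == 1
        assert cleaned.n_epochs == 5
        # order of the survivors preserved
        assert np.array_equal(cleaned.epochs, epochs[[0, 1, 2, 4, 5]])

    def test_all_rejected_is_an_error_naming_the_recording(self):
        rec = self._recording(np.ones((3, 2, 64)))
        with pytest.raises(ValueError, match="P01"):
            reject_artifact_epochs(rec, amplitude_threshold=0.5)

    def test_nonpositive_threshold_rejected(self):
        rec = self._recording(np.ones((3, 2, 64)))
        with pytest.raises(ValueError, match="positive"):
            reject_artifact_epochs(rec, amplitude_threshold=0.0)


class TestCohortConfig:
    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            CohortConfig(n_participants=1)
        with pytest.raises(ValueError):
            CohortConfig(conditions=(0, 0, 40))
        with pytest.raises(ValueError):
            CohortConfig(fs=256, epoch_s=0.33)
        with pytest.raises(ValueError):
            CohortConfig(channel_labels=("Cz", "Cz"))

    def test_default_montage_is_biosemi32(self):
        assert CohortConfig().channel_labels == BIOSEMI32_CHANNELS
        assert CohortConfig().n_channels == 32
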