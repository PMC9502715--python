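"""Scene simulator: source synthesis, spatialization, mixing, reverberation."""

import numpy as np
import pytest

from spatialspeech.core import ArrayGeometry
from spatialspeech.scene import (
    SceneSpec,
    apply_reverb,
    build_scene,
    diffuse_noise,
    mix_at_snr,
    noise_gain_for_snr,
    reverb_tail,
    spatialize,
    synth_interferer,
    synth_speechlike,
)
from spatialspeech.signals import modulation_index, spectral_flatness

SR = 16000


class TestSources:
    def test_speechlike_length_and_finiteness(self):
        x = synth_speechlike(7.0, SR, seed=1)
        assert x.shape == (112000,)
        assert np.all(np.isfinite(x))
        assert np.sqrt(np.mean(x**2)) > 0

    def test_interferer_length(self):
        v = synth_interferer(1.0, SR, seed=3)
        assert v.shape == (16000,)
        assert np.all(np.isfinite(v))

    @pytest.mark.parametrize("synth", [synth_speechlike, synth_interferer])
    def test_seed_determinism(self, synth):
        a = synth(1.5, SR, seed=7)
        b = synth(1.5, SR, seed=7)
        np.testing.assert_array_equal(a, b)

    @pytest.mark.parametrize("synth", [synth_speechlike, synth_interferer])
    def test_nonpositive_duration_rejected(self, synth):
        with pytest.raises(ValueError):
            synth(0.0, SR, seed=1)

    @pytest.mark.parametrize("seed", [1, 2, 3, 4, 5])
    def test_speech_more_modulated_than_interferer(self, seed):
        # the modulation asymmetry is what makes the localized interferer
        # dominate the DOA statistics in speech pauses
        x = synth_speechlike(3.0, SR, seed)
        v = synth_interferer(3.0, SR, seed)
        assert modulation_index(x, SR) > modulation_index(v, SR)

    def test_interferer_spectrally_flatter(self):
        x = synth_speechlike(3.0, SR, seed=2)
        v = synth_interferer(3.0, SR, seed=2)
        assert spectral_flatness(v, SR) > spectral_flatness(x, SR)


class TestSpatialize:
    def test_frontal_source_symmetric_mics(self, geometry, rng):
        src = rng.standard_normal(SR)
        sig = spatialize(src, 0.0, geometry)
        # front-left (0) and front-right (3) are mirrored: zero delay at 0 deg
        xc = np.correlate(sig.samples[0], sig.samples[3], mode="full")
        assert xc.argmax() - (sig.n_samples - 1) == 0

    def test_delay_matches_geometry_prediction(self, rng):
        g2 = ArrayGeometry(np.array([[0, 0.09, 0], [0, -0.09, 0]]), SR)
        src = rng.standard_normal(SR)
        sig = spatialize(src, -30.0, g2)
        xc = np.correlate(sig.samples[0], sig.samples[1], mode="full")
        measured = xc.argmax() - (sig.n_samples - 1)
        predicted = (g2.delays(-30.0)[0] - g2.delays(-30.0)[1]) * SR
        assert abs(measured - predicted) <= 1.0

    def test_impulse_energy_preserved_without_shadow(self, geometry):
        src = np.zeros(2000)
        src[500] = 1.0
        sig = spatialize(src, 25.0, geometry, head_shadow=False)
        np.testing.assert_allclose(
            (sig.samples**2).sum(axis=1), 1.0, atol=1e-10
        )

    def test_empty_source_rejected(self, geometry):
        with pytest.raises(ValueError):
            spatialize(np.array([]), 0.0, geometry)


class TestDiffuseNoise:
    def test_channel_count(self, geometry):
        d = diffuse_noise(1.0, geometry, n_directions=19, seed=0)
        assert d.n_channels == geometry.n_mics

    def test_too_few_directions_rejected(self, geometry):
        with pytest.raises(ValueError):
            diffuse_noise(1.0, geometry, n_directions=1, seed=0)

    def test_coherence_decreases_with_frequency(self, geometry):
        from scipy.signal import coherence

        d = diffuse_noise(4.0, geometry, n_directions=19, seed=1)
        f, coh = coherence(d.samples[0], d.samples[3], fs=SR, nperseg=1024)
        low = coh[(f >= 150) & (f <= 400)].mean()
        high = coh[(f >= 3000) & (f <= 5000)].mean()
        assert low > high

    def test_no_dominant_sector_in_doa_map(self, geometry, doa_model):
        from spatialspeech.doa import average_map, probability_map

        d = diffuse_noise(2.0, geometry, n_directions=19, seed=2)
        prof = average_map(probability_map(d, doa_model))
        assert prof.values.max() < 0.9


class TestMixAtSnr:
    @pytest.fixture()
    def pair(self, geometry):
        tgt = spatialize(synth_speechlike(2.0, SR, 1), -30.0, geometry)
        noi = diffuse_noise(2.0, geometry, 19, seed=5)
        return tgt, noi

    def test_zero_db_achieved(self, pair):
        from spatialspeech.scene import _active_mask

        tgt, noi = pair
        mixed = mix_at_snr(tgt, noi, 0.0)
        added = mixed.samples[0] - tgt.samples[0]
        mask = _active_mask(tgt.samples[0], SR)
        snr = 10 * np.log10(
            np.mean(tgt.samples[0][mask] ** 2) / np.mean(added[mask] ** 2)
        )
        assert abs(snr) < 0.01

    def test_gain_ratio_follows_snr_difference(self, pair):
        tgt, noi = pair
        g_hi = noise_gain_for_snr(tgt, noi, 20.0)
        g_lo = noise_gain_for_snr(tgt, noi, -10.0)
        np.testing.assert_allclose(g_lo / g_hi, 10 ** (30 / 20), rtol=1e-10)

    def test_silent_noise_rejected(self, pair):
        from spatialspeech.core import MultichannelSignal

        tgt, noi = pair
        silent = MultichannelSignal(
            np.zeros_like(noi.samples), noi.sample_rate, noi.geometry
        )
        with pytest.raises(ValueError):
            mix_at_snr(tgt, silent, 0.0)


class TestReverb:
    def test_zero_t60_is_identity(self, geometry):
        sig = diffuse_noise(0.5, geometry, 19, seed=0)
        out = apply_reverb(sig, 0.0, seed=1)
        np.testing.assert_array_equal(out.samples, sig.samples)

    def test_negative_t60_rejected(self, geometry):
        sig = diffuse_noise(0.2, geometry, 19, seed=0)
        with pytest.raises(ValueError):
            apply_reverb(sig, -0.1, seed=1)

    @pytest.mark.parametrize("seed", [1, 2, 3])
    def test_schroeder_decay_hits_minus60_at_t60(self, seed):
        tail = reverb_tail(0.5, SR, seed)
        edc = np.cumsum(tail[::-1] ** 2)[::-1]
        edc_db = 10 * np.log10(edc / edc[0])
        t60_est = np.argmax(edc_db <= -60) / SR
        assert 0.45 <= t60_est <= 0.55

    def test_deterministic_under_seed(self, geometry):
        sig = diffuse_noise(0.5, geometry, 19, seed=0)
        a = apply_reverb(sig, 0.3, seed=9)
        b = apply_reverb(sig, 0.3, seed=9)
        np.testing.assert_array_equal(a.samples, b.samples)


class TestBuildScene:
    def test_ground_truth_passthrough(self, geometry):
        spec = SceneSpec(snr_db=20.0, seed=1, noise_kind="diffuse", duration_s=1.0)
        sig, truth = build_scene(spec, geometry)
        assert truth["target_sector"] == -30.0
        assert truth["interferer_sector"] is None
        assert sig.n_channels == 6

    def test_localized_truth_records_interferer(self, geometry):
        spec = SceneSpec(snr_db=0.0, seed=2, noise_kind="localized", duration_s=1.0)
        _, truth = build_scene(spec, geometry)
        assert truth["interferer_sector"] == 40.0

    def test_grid_enumeration_cardinality(self):
        n_utt = 3
        specs = [
            SceneSpec(snr_db=snr, seed=u, noise_kind=kind, room=room,
                      t60_s=0.5 if room == "reverberant" else 0.0)
            for room in ("anechoic", "reverberant")
            for kind in ("diffuse", "localized")
            for snr in range(-10, 21, 5)
            for u in range(n_utt)
        ]
        assert len(specs) == 2 * 2 * 7 * n_utt

    def test_scene_reproducible(self, geometry):
        spec = SceneSpec(snr_db=5.0, seed=42, noise_kind="localized", duration_s=1.0)
        a, _ = build_scene(spec, geometry)
        b, _ = build_scene(spec, geometry)
        np.testing.assert_array_equal(a.samples, b.samples)

    def test_spec_text_roundtrip(self):
        spec = SceneSpec(snr_db=-5.0, seed=3, noise_kind="localized",
                         room="reverberant", t60_s=0.4, duration_s=2.5)
        assert SceneSpec.from_text(spec.to_text()) == spec

    def test_invalid_specs_rejected(self):
        with pytest.raises(ValueError):
            SceneSpec(snr_db=0.0, seed=1, target_azimuth_deg=120.0)
        with pytest.raises(ValueError):
            SceneSpec(snr_db=0.0, seed=1, duration_s=-1.0)
        with pytest.raises(ValueError):
            SceneSpec(snr_db=0.0, seed=1, noise_kind="purple")
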