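"""Quality measures: M-Measure, matched phoneme filtering, inverse entropy."""

import numpy as np
import pytest

from spatialspeech.asqm import (
    EPSILON,
    MMConfig,
    inverse_entropy,
    learn_map_filters,
    m_measure,
    map_events,
)
from spatialspeech.posteriorgram import Posteriorgram, synth_posteriorgram


def _kl_bits(p, q):
    return float(np.sum(p * np.log2(p / q)))


def mm_bruteforce(probs, hop_s, delta_grid_ms, divergence="symmetric_kl",
                  eps=EPSILON):
    """Independent double-loop evaluation of the mean temporal distance."""
    P = np.maximum(probs, eps)
    P = P / P.sum(axis=1, keepdims=True)
    T = P.shape[0]
    values = []
    for dt_ms in delta_grid_ms:
        lag = int(round(dt_ms / (hop_s * 1000)))
        if lag < 1 or lag >= T:
            continue
        acc = 0.0
        for t in range(lag, T):
            a, b = P[t - lag], P[t]
            if divergence == "kl":
                acc += _kl_bits(a, b)
            else:
                acc += 0.5 * (_kl_bits(a, b) + _kl_bits(b, a))
        values.append(acc / (T - lag))
    return float(np.mean(values))


def entropy_bruteforce(probs):
    T, N = probs.shape
    acc = 0.0
    for t in range(T):
        for ph in range(N):
            p = probs[t, ph]
            if p > 0:
                acc += -p * np.log2(p)
    return acc / T


class TestMMeasure:
    def test_time_constant_posteriorgram_is_zero(self):
        pg = synth_posteriorgram(np.zeros(150, dtype=int), 0.0, 0.0, n_classes=6)
        assert m_measure(pg).value == 0.0

    def test_alternating_distributions_give_pairwise_divergence(self, rng):
        p = rng.dirichlet(np.ones(5))
        q = rng.dirichlet(np.ones(5))
        probs = np.array([p if t % 2 == 0 else q for t in range(200)])
        pg = Posteriorgram(probs, [f"c{i}" for i in range(5)])
        cfg = MMConfig(delta_grid_ms=(50, 150, 250))  # odd frame lags 5, 15, 25
        got = m_measure(pg, cfg).value
        # direct brute-force evaluation
        expect = mm_bruteforce(probs, 0.01, cfg.delta_grid_ms)
        np.testing.assert_allclose(got, expect, atol=1e-10)
        # with odd lags every term is the symmetrised divergence of (p, q)
        P = np.maximum(probs[:2], EPSILON)
        P /= P.sum(axis=1, keepdims=True)
        d_sym = 0.5 * (_kl_bits(P[0], P[1]) + _kl_bits(P[1], P[0]))
        np.testing.assert_allclose(got, d_sym, atol=1e-10)

    @pytest.mark.parametrize("divergence", ["kl", "symmetric_kl"])
    def test_matches_bruteforce_on_random_inputs(self, rng, divergence):
        for _ in range(10):
            probs = rng.dirichlet(np.ones(8), size=120)
            pg = Posteriorgram(probs, [f"c{i}" for i in range(8)])
            cfg = MMConfig(divergence=divergence)
            got = m_measure(pg, cfg).value
            expect = mm_bruteforce(probs, 0.01, cfg.delta_grid_ms, divergence)
            np.testing.assert_allclose(got, expect, atol=1e-10)

    def test_decreases_with_degradation(self, rng):
        labels = rng.integers(0, 10, size=300)
        values = [
            m_measure(synth_posteriorgram(labels, d, 0.0, n_classes=10)).value
            for d in (0.0, 0.3, 0.6, 0.9)
        ]
        assert all(np.diff(values) < 0)

    def test_short_utterance_restricts_grid_with_flag(self):
        pg = synth_posteriorgram(np.arange(30) % 3, 0.0, 0.0, n_classes=3)  # 300 ms
        res = m_measure(pg)
        assert res.diagnostics["skipped_delta_ms"]  # lags >= 300 ms dropped
        assert res.value > 0

    def test_too_short_for_any_lag_rejected(self):
        pg = synth_posteriorgram(np.arange(3) % 3, 0.0, 0.0, n_classes=3)
        with pytest.raises(ValueError):
            m_measure(pg)


def _runs_posteriorgram(n_classes=8, run=10, cycles=12):
    labels = np.repeat(np.tile(np.arange(n_classes), cycles), run)
    pg = synth_posteriorgram(labels, 0.0, 0.0, n_classes=n_classes)
    return pg, labels


class TestMapFiltering:
    def test_filters_from_rectangular_phones_are_rectangles(self):
        pg, labels = _runs_posteriorgram()
        fs = learn_map_filters([pg], [labels], support_frames=51)
        h = fs.filters["c0"]
        nz = np.flatnonzero(h > 1e-12)
        assert nz.size == 10  # matches the 10-frame activation
        np.testing.assert_allclose(h[nz], h[nz][0], atol=1e-12)

    def test_self_match_peak_is_one(self):
        pg, labels = _runs_posteriorgram()
        fs = learn_map_filters([pg], [labels], support_frames=51)
        for lab in fs.labels:
            avg = fs.filters[lab][::-1]  # reversed filter = average trace (scaled)
            peak = np.convolve(pg.probs[:, fs.labels.index(lab)], fs.filters[lab]).max()
            assert peak == pytest.approx(1.0, abs=1e-6)

    def test_deterministic_given_data(self):
        pg, labels = _runs_posteriorgram()
        a = learn_map_filters([pg], [labels], 51)
        b = learn_map_filters([pg], [labels], 51)
        for lab in a.labels:
            np.testing.assert_array_equal(a.filters[lab], b.filters[lab])

    def test_missing_class_rejected(self):
        pg, labels = _runs_posteriorgram(n_classes=8)
        wider = Posteriorgram(
            np.hstack([pg.probs, np.zeros((pg.n_frames, 1))]),
            pg.labels + ["ghost"],
        )
        with pytest.raises(ValueError, match="ghost"):
            learn_map_filters([wider], [labels], 51)

    def test_zero_activations_give_zero_events(self):
        pg, labels = _runs_posteriorgram()
        fs = learn_map_filters([pg], [labels], 51)
        silent = Posteriorgram(
            np.tile(np.eye(8)[0], (100, 1)), pg.labels
        )  # all mass on c0, constant
        res = map_events(
            Posteriorgram(np.tile(np.eye(8)[7], (100, 1)), pg.labels), fs
        )
        assert res.diagnostics["per_class_events"]["c0"] == 0

    def test_single_clean_activation_is_one_event(self):
        pg, labels = _runs_posteriorgram()
        fs = learn_map_filters([pg], [labels], 51)
        probs = np.zeros((80, 8))
        probs[:, 1] = 1.0  # background on c1
        probs[35:45, 0] = 1.0  # one clean 10-frame activation of c0
        probs[35:45, 1] = 0.0
        res = map_events(Posteriorgram(probs, pg.labels), fs)
        assert res.diagnostics["per_class_events"]["c0"] == 1

    def test_scaled_down_activation_misses_threshold(self):
        pg, labels = _runs_posteriorgram()
        fs = learn_map_filters([pg], [labels], 51)
        probs = np.zeros((80, 8))
        probs[:, 1] = 1.0
        probs[35:45, 0] = 0.4  # peak filter response 0.4 < 0.5
        probs[35:45, 1] = 0.6
        res = map_events(Posteriorgram(probs, pg.labels), fs)
        assert res.diagnostics["per_class_events"]["c0"] == 0

    def test_events_decrease_with_degradation(self):
        # variable-duration phone streams (not a rigid periodic pattern) so
        # the event count responds smoothly to the degradation level
        from spatialspeech.posteriorgram import PhonemeInventory, synth_phone_stream

        inv = PhonemeInventory()
        _, clean_labels = synth_phone_stream(inv, 30.0, seed=42)
        clean = synth_posteriorgram(clean_labels, 0.0, 0.0,
                                    class_labels=list(inv.labels))
        fs = learn_map_filters([clean], [clean_labels], 51)
        _, labels = synth_phone_stream(inv, 8.0, seed=43)
        counts = [
            map_events(
                synth_posteriorgram(labels, d, 200.0 * d,
                                    class_labels=list(inv.labels)), fs
            ).value
            for d in (0.0, 0.3, 0.6, 0.9)
        ]
        assert all(np.diff(counts) < 0)

    def test_filter_set_roundtrip(self, tmp_path):
        pg, labels = _runs_posteriorgram()
        fs = learn_map_filters([pg], [labels], 51)
        fs.save(tmp_path / "filters.npz")
        from spatialspeech.asqm import MatchedFilterSet

        back = MatchedFilterSet.load(tmp_path / "filters.npz")
        assert back.labels == fs.labels
        np.testing.assert_array_equal(back.filters["c3"], fs.filters["c3"])


class TestInverseEntropy:
    def test_one_hot_gives_zero_entropy(self):
        pg = synth_posteriorgram(np.arange(50) % 4, 0.0, 0.0, n_classes=4)
        res = inverse_entropy(pg)
        assert res.diagnostics["mean_entropy_bits"] == 0.0
        assert res.value == 0.0  # -H is maximal

    def test_uniform_gives_log2_n(self):
        pg = synth_posteriorgram(np.zeros(20, dtype=int), 1.0, 0.0, n_classes=16)
        assert inverse_entropy(pg).diagnostics["mean_entropy_bits"] == pytest.approx(
            4.0, abs=1e-12
        )

    def test_matches_bruteforce(self, rng):
        for _ in range(10):
            probs = rng.dirichlet(np.ones(12), size=60)
            pg = Posteriorgram(probs, [f"c{i}" for i in range(12)])
            got = inverse_entropy(pg).diagnostics["mean_entropy_bits"]
            np.testing.assert_allclose(got, entropy_bruteforce(probs), atol=1e-12)

    def test_reciprocal_mode_ranks_identically(self, rng):
        pgs = [
            Posteriorgram(rng.dirichlet(np.ones(6), size=40), [f"c{i}" for i in range(6)])
            for _ in range(5)
        ]
        neg = [inverse_entropy(p, "negative").value for p in pgs]
        rec = [inverse_entropy(p, "reciprocal").value for p in pgs]
        assert list(np.argsort(neg)) == list(np.argsort(rec))

    def test_unnormalized_rows_rejected(self):
        with pytest.raises(ValueError):
            Posteriorgram(np.full((4, 4), 0.3), list("abcd"))


class TestLabelPermutationInvariance:
    def test_all_measures_invariant(self, rng):
        labels = rng.integers(0, 8, size=250)
        pg = synth_posteriorgram(labels, 0.2, 30.0, n_classes=8)
        fs = learn_map_filters(
            [synth_posteriorgram(labels, 0.0, 0.0, n_classes=8)], [labels], 51
        )
        perm = rng.permutation(8)
        probs_p = pg.probs[:, perm]
        labels_p = [pg.labels[j] for j in perm]
        pg_p = Posteriorgram(probs_p, labels_p)
        np.testing.assert_allclose(
            m_measure(pg).value, m_measure(pg_p).value, atol=1e-12
        )
        np.testing.assert_allclose(
            inverse_entropy(pg).value, inverse_entropy(pg_p).value, atol=1e-12
        )
        assert map_events(pg, fs).value == map_events(pg_p, fs).value


class TestAsqmProfile:
    def test_identical_sector_signals_give_constant_profile(self, provider):
        from spatialspeech.asqm import asqm_profile
        from spatialspeech.scene import synth_speechlike

        wave = synth_speechlike(1.0, 16000, seed=2)
        signals = np.tile(wave, (3, 1))
        prof = asqm_profile(signals, np.array([-10.0, 0.0, 10.0]), provider, "MM")
        assert len(prof) == 3
        assert np.ptp(prof.values) < 1e-9

    def test_single_sector_rejected(self, provider):
        from spatialspeech.asqm import asqm_profile

        with pytest.raises(ValueError):
            asqm_profile(np.zeros((1, 16000)), np.array([0.0]), provider, "MM")
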