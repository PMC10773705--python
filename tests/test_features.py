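"""Feature inventory, spectral estimates, vector assembly, matrix construction."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from phonemebci import (
    BANDS,
    RawTrial,
    SimulationConfig,
    ValidationError,
    assemble_trial_vector,
    band_power,
    build_feature_matrix,
    extract_channel_features,
    feature_index,
    simulate_dataset,
    split_windows,
    welch_psd,
)
from phonemebci.features import (
    FEATURE_NAMES,
    N_FEATURES_PER_CHANNEL,
    N_FEATURES_PER_TRIAL,
    N_FEATURES_PER_WINDOW,
    sub_bands,
)

FS = 250.0


def test_inventory_structure():
    assert len(FEATURE_NAMES) == N_FEATURES_PER_CHANNEL == 35
    assert len(set(FEATURE_NAMES)) == 35
    # relative-power entries pair 1:1 with absolute-power entries
    absolutes = {n[len("pow_"):] for n in FEATURE_NAMES if n.startswith("pow_")}
    relatives = {n[len("rel_"):] for n in FEATURE_NAMES if n.startswith("rel_")}
    assert absolutes == relatives and len(absolutes) == 15


def test_band_scheme():
    assert BANDS["alpha"] == (8.0, 12.0)
    subs = sub_bands()
    assert len(subs) == 10
    assert subs["alpha_low"] == (8.0, 10.0)  # split at the arithmetic midpoint


class TestWelchAndBandPower:
    def test_pure_tone_total_power(self):
        t = np.arange(250) / FS
        for a in (1.0, 2.0):
            freqs, density = welch_psd(a * np.sin(2 * np.pi * 40.0 * t))
            total = band_power(freqs, density, (0.0, 125.0))
            assert total == pytest.approx(a * a / 2.0, rel=0.05)

    def test_zero_signal_zero_density(self):
        freqs, density = welch_psd(np.zeros(250))
        assert np.all(density == 0.0)

    def test_white_noise_density_flat(self, rng):
        x = rng.normal(size=(1000, 250))
        freqs, density = welch_psd(x)
        mean_density = density.mean(axis=0)
        inner = mean_density[(freqs >= 10) & (freqs <= 110)]
        assert inner.max() / inner.min() == pytest.approx(1.0, abs=0.15)

    def test_tone_power_lands_in_gamma(self):
        t = np.arange(250) / FS
        freqs, density = welch_psd(np.sin(2 * np.pi * 40.0 * t))
        total = band_power(freqs, density, (1.0, 100.0))
        gamma = band_power(freqs, density, BANDS["gamma"])
        delta = band_power(freqs, density, BANDS["delta"])
        assert gamma >= 0.95 * total
        assert delta < 0.01 * total

    def test_band_additivity(self, rng):
        freqs, density = welch_psd(rng.normal(size=250))
        tiles = [(1.0, 20.0), (20.0, 50.0), (50.0, 100.0)]
        total = band_power(freqs, density, (1.0, 100.0))
        assert sum(band_power(freqs, density, b) for b in tiles) == pytest.approx(
            total, rel=0.02
        )

    def test_empty_band_is_zero(self, rng):
        freqs, density = welch_psd(rng.normal(size=250))
        assert band_power(freqs, density, (2.5, 4.0)) == 0.0


class TestChannelFeatures:
    def test_zero_signal_all_features_zero(self):
        values = extract_channel_features(np.zeros(250))
        assert values.shape == (35,)
        assert np.all(values == 0.0)

    def test_pure_tone_closed_forms(self):
        t = np.arange(250) / FS
        values = extract_channel_features(np.sin(2 * np.pi * 10.0 * t))
        named = dict(zip(FEATURE_NAMES, values))
        assert named["mean"] == pytest.approx(0.0, abs=1e-12)
        assert named["rms"] == pytest.approx(1.0 / np.sqrt(2.0), rel=1e-6)
        # Hann leakage at the exact-bin tone splits power 1/4 : 1 : 1/4 over
        # 8/10/12 Hz; the 12 Hz bin falls in the 12-13 Hz band gap, so the
        # alpha share is exactly 5/6 of the total rather than 1.
        assert named["rel_alpha"] == pytest.approx(5.0 / 6.0, abs=0.02)
        assert named["rel_alpha"] == max(
            named[f"rel_{b}"] for b in ("delta", "theta", "alpha", "beta", "gamma")
        )

    def test_relative_powers_normalized(self, rng):
        values = extract_channel_features(rng.normal(size=250))
        named = dict(zip(FEATURE_NAMES, values))
        total_rel = sum(named[f"rel_{b}"] for b in ("delta", "theta", "alpha", "beta", "gamma"))
        assert total_rel <= 1.02

    @settings(max_examples=25, derandomize=True)
    @given(c=st.floats(0.01, 100.0))
    def test_scale_equivariance(self, c):
        rng = np.random.default_rng(7)
        x = rng.normal(size=250)
        base = extract_channel_features(x)
        scaled = extract_channel_features(c * x)
        named = dict(zip(FEATURE_NAMES, base))
        for i, name in enumerate(FEATURE_NAMES):
            if name in ("mean", "p99_95", "rms", "ptp"):
                assert scaled[i] == pytest.approx(c * base[i], rel=1e-9, abs=1e-12)
            elif name.startswith("pow_") or name == "total_power":
                assert scaled[i] == pytest.approx(c * c * base[i], rel=1e-9, abs=1e-12)
            else:
                assert scaled[i] == pytest.approx(base[i], rel=1e-9, abs=1e-12)

    def test_wrong_length_rejected(self):
        with pytest.raises(ValidationError):
            extract_channel_features(np.zeros(500))


class TestTrialVector:
    def test_lengths_and_ordering(self, rng):
        pair = split_windows(RawTrial(1, 1, 1, 1, rng.normal(size=(16, 500))))
        tf = assemble_trial_vector(pair)
        assert tf.vector.shape == (N_FEATURES_PER_TRIAL,) == (1120,)
        assert N_FEATURES_PER_WINDOW == 560
        index = feature_index()
        assert len(index) == 1120
        first = index.iloc[0]
        assert (first.window, first.channel, first.feature) == (1, "Fp1", "mean")
        # window-major: position 560 starts window 2 at Fp1
        row560 = index.iloc[560]
        assert (row560.window, row560.channel, row560.feature) == (2, "Fp1", "mean")
        # spot-check consistency: feature at a named position equals direct extraction
        from phonemebci.features import extract_channel_features

        col = index[(index.window == 2) & (index.channel == "F3") & (index.feature == "rms")].index[0]
        expected = extract_channel_features(pair.window2[3])  # F3 is montage row 3
        assert tf.vector[col] == expected[2]

    def test_rejected_pair_refused(self, rng):
        pair = split_windows(RawTrial(1, 1, 1, 1, rng.normal(size=(16, 480))))
        with pytest.raises(ValidationError):
            assemble_trial_vector(pair)


class TestFeatureMatrix:
    def test_full_participant_matrix_shape(self, null_matrix):
        n_rejected = len(null_matrix.rejections)
        assert null_matrix.X.shape == (660 - n_rejected, 1120)
        assert set(np.unique(null_matrix.labels)) == set(range(1, 45))
        assert np.all(null_matrix.participants == 1)

    def test_intersubject_pooling_is_additive(self, tmp_path):
        config = SimulationConfig(
            n_participants=2, n_sessions=1, trials_per_phoneme=2,
            effect_size=0.0, artifact_rate=0.0, seed=21,
        )
        manifest = simulate_dataset(config, tmp_path)
        pooled = build_feature_matrix(manifest, mode="intersubject")
        singles = [
            build_feature_matrix(manifest, mode="intrasubject", participant=p)
            for p in (1, 2)
        ]
        assert pooled.X.shape[0] == sum(m.X.shape[0] for m in singles)
        np.testing.assert_allclose(
            pooled.X, np.vstack([m.X for m in singles]), rtol=0, atol=0
        )

    def test_unknown_mode_rejected(self, null_dataset):
        _, manifest = null_dataset
        with pytest.raises(ValidationError):
            build_feature_matrix(manifest, mode="sideways")

    def test_gamma_effect_localized_to_f3_f7(self, effect_matrix):
        """Class-conditional gamma power separates classes on F3/F7, not O1/O2."""
        index = effect_matrix.index
        labels = effect_matrix.labels

        def between_within_ratio(channel):
            cols = index[
                (index.channel == channel)
                & index.feature.isin(["pow_gamma_low", "pow_gamma_high"])
            ].index
            vals = effect_matrix.X[:, cols]
            frame = pd.DataFrame(vals).groupby(labels)
            between = frame.mean().std(ddof=0).mean()
            within = frame.std(ddof=0).mean().mean()
            return between / within

        effect = min(between_within_ratio("F3"), between_within_ratio("F7"))
        control = max(between_within_ratio("O1"), between_within_ratio("O2"))
        assert effect / control > 3.0
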