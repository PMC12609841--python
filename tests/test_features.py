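"""Scattering transform and statistical descriptors against oracles."""

import math

import numpy as np
import pytest

from ecgfusion.ecg_io import EcgRecord, ValidationError
from ecgfusion.features import (
    ScatteringConfig,
    build_filter_bank,
    fuse_features,
    n_channels,
    scattering_transform,
    statistical_features,
)


class TestScatteringShape:
    def test_reference_shape_8527(self):
        """Default bank + frame grid reproduce the published (298, 504)."""
        rec = EcgRecord(np.random.default_rng(0).normal(size=8527), fs=300.0,
                        record_id="r")
        S = scattering_transform(rec, ScatteringConfig(), dtype=np.float32)
        assert S.values.shape == (298, 504)

    def test_channel_count_formula(self, tiny_scattering_config):
        cfg = tiny_scattering_config
        bank = build_filter_bank(cfg, 64)
        assert n_channels(cfg) == 1 + bank.xi1.size + len(bank.paths2)

    def test_channel_ordering(self, tiny_scattering_config):
        rec = EcgRecord(np.random.default_rng(1).normal(size=512), record_id="r")
        S = scattering_transform(rec, tiny_scattering_config)
        assert S.channel_index[0] == ("S0",)
        s1 = [c for c in S.channel_index if c[0] == "S1"]
        xi = [c[1] for c in s1]
        assert xi == sorted(xi, reverse=True)  # descending center frequency
        s2 = [c for c in S.channel_index if c[0] == "S2"]
        assert s2 == sorted(s2, key=lambda c: (-c[1], -c[2]))  # lexicographic

    def test_too_short_signal_rejected(self, tiny_scattering_config):
        rec = EcgRecord(np.ones(100), record_id="short")
        with pytest.raises(ValidationError):
            scattering_transform(rec, tiny_scattering_config)  # T=512 > 100


class TestScatteringValues:
    def test_zero_signal_gives_zeros(self, tiny_scattering_config):
        S = scattering_transform(EcgRecord(np.zeros(512), record_id="z"),
                                 tiny_scattering_config)
        assert np.max(np.abs(S.values)) < 1e-10

    def test_positive_homogeneity(self, tiny_scattering_config, rng):
        x = rng.normal(size=512)
        S1 = scattering_transform(EcgRecord(x, record_id="a"), tiny_scattering_config)
        S2 = scattering_transform(EcgRecord(2 * x, record_id="b"), tiny_scattering_config)
        np.testing.assert_allclose(S2.values, 2 * S1.values,
                                   rtol=1e-6, atol=1e-9)

    def test_orders_1_2_nonnegative(self, tiny_scattering_config, rng):
        for _ in range(5):
            x = rng.normal(size=512) * rng.uniform(0.1, 10)
            S = scattering_transform(EcgRecord(x, record_id="n"),
                                     tiny_scattering_config)
            assert S.values[:, 1:].min() >= -1e-9

    def test_order1_energy_concentrates_at_matching_filter(self):
        """A pure sine's order-1 energy peaks at the nearest-frequency channel,
        cross-checked with a direct time-domain convolution oracle."""
        cfg = ScatteringConfig(J=3, Q=2, T=512, n_frames=8, n_tail=0, j2_max=3)
        bank = build_filter_bank(cfg, 1024)
        n1 = bank.xi1.size
        assert n1 == 6
        alpha = 2.0 ** (1.0 / cfg.Q) - 1.0
        for target in range(n1):
            xi = bank.xi1[target]
            t = np.arange(512)
            x = np.sin(2 * np.pi * xi * t)
            S = scattering_transform(EcgRecord(x, record_id="s"), cfg)
            s1_energy = S.values[:, 1:1 + n1].mean(axis=0)
            assert int(np.argmax(s1_energy)) == target
            # oracle: analytic time-sampled Morlet, direct convolution
            oracle = []
            for xi_k in bank.xi1:
                sigma_f = alpha * xi_k
                sigma_t = 1.0 / (2 * np.pi * sigma_f)
                beta = np.exp(-(xi_k**2) / (2 * sigma_f**2))
                tt = np.arange(-512, 513)
                psi = (np.exp(2j * np.pi * xi_k * tt) - beta) \
                    * np.exp(-(tt**2) / (2 * sigma_t**2))
                psi /= np.abs(psi).sum()
                oracle.append(np.abs(np.convolve(x, psi, mode="same")).mean())
            assert int(np.argmax(oracle)) == target

    def test_shift_equivariance_on_frame_grid(self, rng):
        cfg = ScatteringConfig(J=3, Q=2, T=256, n_frames=16, n_tail=0, j2_max=3)
        x = rng.normal(size=512)
        hop = 512 // 16
        S = scattering_transform(EcgRecord(x, record_id="a"), cfg).values
        Sr = scattering_transform(EcgRecord(np.roll(x, hop), record_id="b"),
                                  cfg).values
        a, b = Sr[2:-2], S[1:-3]  # one-row shift, edges dropped
        assert np.linalg.norm(a - b) / np.linalg.norm(b) < 0.05


class TestStatisticalFeatures:
    def test_hand_computed_12345(self):
        sv = statistical_features(EcgRecord(np.array([1., 2, 3, 4, 5]),
                                            fs=300.0, record_id="r"))
        assert sv.mu == pytest.approx(3.0)
        assert sv.sigma == pytest.approx(math.sqrt(2.5))
        assert sv.gamma1 == pytest.approx(0.0, abs=1e-12)
        assert sv.gamma2 == pytest.approx(-1.912, abs=1e-3)

    def test_constant_signal_degenerate_convention(self):
        sv = statistical_features(EcgRecord(np.full(100, 3.0), fs=300.0,
                                            record_id="c"))
        assert (sv.mu, sv.sigma, sv.gamma1, sv.gamma2) == (3.0, 0.0, 0.0, 0.0)
        assert sv.p_band == pytest.approx(0.0, abs=1e-20)
        assert sv.degenerate

    def test_agrees_with_direct_summation_oracle(self, rng):
        """Mean/sigma/skew/kurtosis vs explicit loop summation, 1e-10."""
        for _ in range(10):
            x = rng.normal(size=100) * rng.uniform(0.5, 5)
            sv = statistical_features(EcgRecord(x, fs=300.0, record_id="o"))
            n = len(x)
            mu = math.fsum(x) / n
            sigma = math.sqrt(math.fsum((v - mu) ** 2 for v in x) / (n - 1))
            g1 = math.fsum(((v - mu) / sigma) ** 3 for v in x) / n
            g2 = math.fsum(((v - mu) / sigma) ** 4 for v in x) / n - 3
            assert sv.mu == pytest.approx(mu, abs=1e-10)
            assert sv.sigma == pytest.approx(sigma, abs=1e-10)
            assert sv.gamma1 == pytest.approx(g1, abs=1e-10)
            assert sv.gamma2 == pytest.approx(g2, abs=1e-10)

    def test_sine_band_power_and_kurtosis(self):
        """Unit 10 Hz sine: power A^2/2 = 0.5 (Parseval), excess kurtosis -1.5."""
        fs = 300.0
        t = np.arange(int(60 * fs)) / fs
        sv = statistical_features(EcgRecord(np.sin(2 * np.pi * 10 * t), fs=fs,
                                            record_id="s"))
        assert sv.p_band == pytest.approx(0.5, rel=0.05)
        assert sv.gamma2 == pytest.approx(-1.5, abs=0.01)

    def test_welch_within_5pct_of_periodogram(self, rng):
        import scipy.signal

        fs = 300.0
        t = np.arange(int(40 * fs)) / fs
        x = np.sin(2 * np.pi * 7 * t) + 0.5 * rng.normal(size=t.size)
        sv = statistical_features(EcgRecord(x, fs=fs, record_id="w"))
        freqs, psd = scipy.signal.periodogram(x, fs=fs)
        mask = (freqs >= 0.5) & (freqs <= 40.0)
        direct = np.trapezoid(psd[mask], freqs[mask])
        assert sv.p_band == pytest.approx(direct, rel=0.05)

    def test_invalid_band_rejected(self):
        with pytest.raises(ValidationError):
            statistical_features(EcgRecord(np.ones(10), fs=300.0, record_id="r"),
                                 band=(0.5, 200.0))


class TestFuseFeatures:
    def test_reference_509_channels(self):
        rec = EcgRecord(np.random.default_rng(2).normal(size=8527), fs=300.0,
                        record_id="r")
        S = scattering_transform(rec, ScatteringConfig(), dtype=np.float32)
        combined = fuse_features(S, statistical_features(rec))
        assert combined.shape == (298, 509)

    def test_concatenation_arithmetic_and_tiling(self, tiny_scattering_config, rng):
        rec = EcgRecord(rng.normal(size=512), fs=300.0, record_id="r")
        S = scattering_transform(rec, tiny_scattering_config)
        sv = statistical_features(rec)
        combined = fuse_features(S, sv)
        n_scat = S.values.shape[1]
        assert combined.shape == (S.values.shape[0], n_scat + 5)
        # the 5 statistic columns are constant across frames
        stat_block = combined.values[:, n_scat:]
        np.testing.assert_array_equal(stat_block, np.tile(sv.as_array(),
                                                          (S.values.shape[0], 1)))
        assert [c for c in combined.channel_index[-5:]] == [
            ("stat", "mu"), ("stat", "sigma"), ("stat", "gamma1"),
            ("stat", "gamma2"), ("stat", "p_band")]
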