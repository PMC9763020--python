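"""DWT de-noising: perfect reconstruction, universal threshold, soft
shrinkage, and sub-band extraction."""

import math

import numpy as np
import pytest
import scipy.signal
from hypothesis import given, settings
from hypothesis import strategies as st

from eegstress.errors import ConfigurationError, DomainError
from eegstress.wavelet import (
    RATE128_BAND_MAP,
    TABLE_BAND_MAP,
    WaveletConfig,
    decompose,
    denoise,
    extract_subbands,
    reconstruct,
    soft_threshold,
    universal_threshold,
)


class TestDecompose:
    def test_structure_eight_levels(self, rng):
        d = decompose(rng.normal(size=8064))
        assert d.levels == 8
        assert len(d.details) == 8
        assert d.original_length == 8064

    def test_zero_signal_gives_zero_coefficients(self):
        d = decompose(np.zeros(4096))
        assert not np.any(d.approximation)
        assert all(not np.any(c) for c in d.details)

    def test_depth_too_large_rejected(self, rng):
        with pytest.raises(ConfigurationError):
            decompose(rng.normal(size=64), WaveletConfig(levels=8))

    def test_perfect_reconstruction(self, rng):
        x = rng.normal(size=8064)
        assert np.abs(reconstruct(decompose(x)) - x).max() < 1e-8

    def test_batch_matches_per_signal(self, rng):
        X = rng.normal(size=(4, 2048))
        cfg = WaveletConfig(levels=5)
        batch = decompose(X, cfg)
        for i in range(4):
            single = decompose(X[i], cfg)
            assert np.allclose(batch.approximation[i], single.approximation)
            for b, s in zip(batch.details, single.details):
                assert np.allclose(b[i], s)


class TestUniversalThreshold:
    def test_known_values(self):
        assert universal_threshold(1) == 0.0
        assert universal_threshold(math.e) == pytest.approx(math.sqrt(2))
        # oracle: direct evaluation of sqrt(2 ln 8064)
        assert universal_threshold(8064) == pytest.approx(
            math.sqrt(2 * math.log(8064)), abs=1e-12
        )
        assert universal_threshold(8064) == pytest.approx(4.24150, abs=1e-5)

    def test_domain_error(self):
        with pytest.raises(DomainError):
            universal_threshold(0)


class TestSoftThreshold:
    def test_examples(self, rng):
        d = decompose(rng.normal(size=512), WaveletConfig(levels=2))
        d.details[0] = np.array([2.0, -0.3, 1.1])
        out = soft_threshold(d, 1.0)
        assert np.allclose(out.details[0], [1.0, 0.0, 0.1])

    def test_zero_threshold_is_identity(self, rng):
        d = decompose(rng.normal(size=512), WaveletConfig(levels=3))
        out = soft_threshold(d, 0.0)
        for a, b in zip(out.details, d.details):
            assert np.array_equal(a, b)
        assert np.array_equal(out.approximation, d.approximation)

    def test_large_threshold_zeroes_details(self, rng):
        d = decompose(rng.normal(size=512), WaveletConfig(levels=3))
        big = max(np.abs(c).max() for c in d.details) + 1
        out = soft_threshold(d, big)
        assert all(not np.any(c) for c in out.details)

    def test_negative_threshold_rejected(self, rng):
        d = decompose(rng.normal(size=512), WaveletConfig(levels=3))
        with pytest.raises(DomainError):
            soft_threshold(d, -0.1)

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(t=st.floats(0.0, 5.0), seed=st.integers(0, 1000))
    def test_shrinkage_bound(self, t, seed):
        """|output| <= max(|input| - t, 0) element-wise on every level."""
        d = decompose(
            np.random.default_rng(seed).normal(size=512),
            WaveletConfig(levels=3),
        )
        out = soft_threshold(d, t)
        for before, after in zip(d.details, out.details):
            assert np.all(
                np.abs(after) <= np.maximum(np.abs(before) - t, 0.0) + 1e-12
            )

    def test_thresholded_reconstruction_loses_energy(self, rng):
        x = rng.normal(size=2048)
        d = decompose(x, WaveletConfig(levels=4))
        y = reconstruct(soft_threshold(d, 1.0))
        assert np.sum(y**2) <= np.sum(x**2)


class TestDenoise:
    def test_spike_removal_improves_fidelity(self, rng):
        """De-noising reduces the worst-case deviation from the known clean
        signal when spikes are added (synthetic fixture with ground truth)."""
        t = np.arange(8064) / 128.0
        clean = 10.0 * np.sin(2 * np.pi * 6.0 * t)
        contaminated = clean + rng.normal(0, 1.0, clean.size)
        spikes = rng.choice(clean.size, 10, replace=False)
        contaminated[spikes] += 25.0
        out = denoise(contaminated)
        assert (
            np.abs(out - clean).max() < np.abs(contaminated - clean).max()
        )

    def test_sigma_scaled_mode_runs(self, rng):
        x = rng.normal(size=4096)
        cfg = WaveletConfig(threshold_mode="sigma_scaled")
        out = denoise(x, cfg)
        assert out.shape == x.shape
        # near-pure-noise input is shrunk towards zero
        assert np.sum(out**2) < np.sum(x**2)


class TestSubbands:
    def test_default_map_yields_five_named_bands(self, rng):
        bands = extract_subbands(decompose(rng.normal(size=8064)))
        assert set(bands) == {"gamma", "alpha", "beta", "theta", "delta"}
        assert all(v.shape == (8064,) for v in bands.values())

    def test_bands_sum_to_full_reconstruction(self, rng):
        """Linearity: single-coefficient-set reconstructions add up to the
        inverse transform of the whole decomposition (rate map covers every
        coefficient set exactly once)."""
        x = rng.normal(size=8064)
        d = decompose(
            x, WaveletConfig(band_map=dict(RATE128_BAND_MAP))
        )
        total = sum(extract_subbands(d).values())
        assert np.abs(total - reconstruct(d)).max() < 1e-8

    def test_pure_6hz_tone_lands_in_theta(self):
        """Sampling-rate-consistent map at 128 Hz: a 6 Hz sinusoid's energy
        concentrates in the theta (4-8 Hz) band; cross-checked against a
        periodogram band-power oracle on the extracted signals."""
        t = np.arange(8064) / 128.0
        x = np.sin(2 * np.pi * 6.0 * t)
        bands = extract_subbands(
            decompose(x, WaveletConfig(band_map=dict(RATE128_BAND_MAP)))
        )
        energies = {b: float(np.sum(v**2)) for b, v in bands.items()}
        assert max(energies, key=energies.get) == "theta"
        assert energies["theta"] > 0.8 * sum(energies.values())
        f, pxx = scipy.signal.periodogram(bands["theta"], fs=128.0)
        peak = f[np.argmax(pxx)]
        assert 4.0 <= peak <= 8.0

    def test_table_map_references_require_depth(self, rng):
        cfg = WaveletConfig(levels=6, band_map=dict(TABLE_BAND_MAP))
        with pytest.raises(ConfigurationError):
            extract_subbands(decompose(rng.normal(size=8064), cfg))
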