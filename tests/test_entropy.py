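"""Entropy estimators vs independent brute-force oracles and their
defining bounds/invariances."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ieegfocus import (
    EntropyParams,
    approximate_entropy,
    bispectrum,
    entropy_vector,
    permutation_entropy,
    phase_entropies,
    power_spectrum_probs,
    renyi_spectral,
    sample_entropy,
    shannon_spectral,
    tsallis_spectral,
)
from ieegfocus.entropy import ENTROPY_NAMES, UndefinedEntropyError

from .oracles import (
    ape_oracle,
    pe_oracle,
    renyi_oracle,
    sampen_oracle,
    shannon_oracle,
    spectral_probs_oracle,
    tsallis_oracle,
)


@pytest.fixture(scope="module")
def noise200():
    return np.random.default_rng(42).uniform(-1, 1, 200)


class TestApproximateEntropy:
    def test_constant_signal_is_zero(self):
        assert approximate_entropy(np.full(50, 3.7), r=0.1) == 0.0

    def test_matches_bruteforce_oracle(self, noise200):
        assert approximate_entropy(noise200) == pytest.approx(
            ape_oracle(noise200), abs=1e-10
        )

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_oracle_agreement_across_seeds(self, seed):
        x = np.random.default_rng(seed).standard_normal(150)
        assert approximate_entropy(x) == pytest.approx(ape_oracle(x), abs=1e-10)

    def test_periodic_below_shuffled(self):
        periodic = np.array([1.0, 2.0] * 50)
        shuffled = periodic.copy()
        np.random.default_rng(3).shuffle(shuffled)
        r = 0.2 * periodic.std()
        assert approximate_entropy(periodic, r=r) <= approximate_entropy(shuffled, r=r)

    def test_scale_invariance_with_relative_r(self, noise200):
        a = approximate_entropy(noise200)
        b = approximate_entropy(noise200 * 37.2)
        assert a == pytest.approx(b, rel=1e-9)

    def test_too_short_raises(self):
        with pytest.raises(ValueError):
            approximate_entropy(np.array([1.0, 2.0, 3.0]), d=2)

    def test_subsampling_matches_strided_signal(self, noise200):
        strided = noise200[::2]
        assert approximate_entropy(noise200, max_samples=100) == pytest.approx(
            approximate_entropy(strided), abs=1e-12
        )


class TestSampleEntropy:
    def test_constant_signal_is_zero(self):
        assert sample_entropy(np.full(50, 1.0), r=0.1) == 0.0

    def test_matches_bruteforce_oracle(self, noise200):
        assert sample_entropy(noise200) == pytest.approx(
            sampen_oracle(noise200), abs=1e-10
        )

    def test_sinusoid_below_shuffled(self):
        t = np.arange(400)
        sine = np.sin(2 * np.pi * t / 40)
        shuffled = sine.copy()
        np.random.default_rng(4).shuffle(shuffled)
        assert sample_entropy(sine) < sample_entropy(shuffled)

    def test_no_matches_is_undefined(self):
        # strictly exponential growth: no d+1 template pairs within tiny r
        x = 2.0 ** np.arange(12)
        with pytest.raises(UndefinedEntropyError):
            sample_entropy(x, r=1e-12)

    def test_scale_invariance_with_relative_r(self, noise200):
        assert sample_entropy(noise200) == pytest.approx(
            sample_entropy(noise200 * 0.01), rel=1e-9
        )


class TestPermutationEntropy:
    def test_monotone_ramp_is_zero(self):
        assert permutation_entropy(np.arange(100.0)) == 0.0

    def test_uniform_patterns_reach_log2_dfactorial(self):
        # sawtooth visiting all 6 patterns of d=3 equally often
        rng = np.random.default_rng(11)
        x = rng.standard_normal(5000)
        h = permutation_entropy(x)
        assert h <= np.log2(6) + 1e-12
        assert h > 2.5  # white noise approaches the bound

    def test_matches_counting_oracle(self):
        x = np.random.default_rng(5).standard_normal(500)
        assert permutation_entropy(x) == pytest.approx(pe_oracle(x), abs=1e-12)

    def test_monotone_transform_invariance(self):
        x = np.random.default_rng(6).standard_normal(300)
        assert permutation_entropy(np.exp(x)) == pytest.approx(
            permutation_entropy(x), abs=1e-12
        )

    def test_too_short_raises(self):
        with pytest.raises(ValueError):
            permutation_entropy(np.array([1.0, 2.0]), d=3)


class TestSpectralFamily:
    def test_bin_aligned_tone_concentrates(self):
        t = np.arange(256)
        x = np.sin(2 * np.pi * 8 * t / 256)
        p = power_spectrum_probs(x)
        assert p.max() >= 0.99
        assert p.sum() == pytest.approx(1.0, abs=1e-12)

    def test_two_tone_split(self):
        t = np.arange(256)
        x = np.sin(2 * np.pi * 8 * t / 256) + np.sin(2 * np.pi * 30 * t / 256)
        p = power_spectrum_probs(x)
        top = np.sort(p)[-2:]
        assert np.allclose(top, 0.5, atol=1e-6)

    def test_matches_dft_oracle(self):
        x = np.random.default_rng(7).standard_normal(64)
        p = power_spectrum_probs(x)
        np.testing.assert_allclose(p, spectral_probs_oracle(x), atol=1e-10)

    def test_zero_signal_raises(self):
        with pytest.raises(UndefinedEntropyError):
            power_spectrum_probs(np.zeros(64))

    def test_entropies_match_loop_oracles(self):
        p = np.random.default_rng(8).dirichlet(np.ones(40))
        assert shannon_spectral(p) == pytest.approx(shannon_oracle(p), abs=1e-12)
        assert renyi_spectral(p) == pytest.approx(renyi_oracle(p), abs=1e-12)
        assert tsallis_spectral(p) == pytest.approx(tsallis_oracle(p), abs=1e-12)

    def test_one_bin_distribution_gives_zero(self):
        p = np.zeros(10)
        p[3] = 1.0
        assert shannon_spectral(p) == 0.0
        assert renyi_spectral(p) == 0.0
        assert tsallis_spectral(p) == 0.0

    def test_uniform_closed_forms(self):
        F = 32
        p = np.full(F, 1 / F)
        assert shannon_spectral(p) == pytest.approx(np.log(F), abs=1e-12)
        assert renyi_spectral(p) == pytest.approx(np.log(F), abs=1e-12)
        assert tsallis_spectral(p) == pytest.approx(1 - 1 / F, abs=1e-12)

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(st.lists(st.floats(0.01, 10.0), min_size=2, max_size=50))
    def test_renyi_never_exceeds_shannon(self, weights):
        p = np.array(weights) / np.sum(weights)
        assert renyi_spectral(p) <= shannon_spectral(p) + 1e-10

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(st.lists(st.floats(0.01, 10.0), min_size=2, max_size=50))
    def test_tsallis_below_one(self, weights):
        p = np.array(weights) / np.sum(weights)
        assert 0.0 <= tsallis_spectral(p) < 1.0

    def test_alpha_q_of_one_rejected(self):
        p = np.full(4, 0.25)
        with pytest.raises(ValueError):
            renyi_spectral(p, alpha=1)
        with pytest.raises(ValueError):
            tsallis_spectral(p, q=1)


class TestBispectrum:
    def _coupled_triple(self, n, f1=0.12, f2=0.07, rng=None):
        """Quadratic phase coupling: components at f1, f2, f1+f2 with
        phi3 = phi1 + phi2, plus light noise."""
        rng = rng or np.random.default_rng(9)
        t = np.arange(n)
        p1, p2 = rng.uniform(0, 2 * np.pi, 2)
        x = (
            np.cos(2 * np.pi * f1 * t + p1)
            + np.cos(2 * np.pi * f2 * t + p2)
            + np.cos(2 * np.pi * (f1 + f2) * t + p1 + p2)
        )
        return x + 0.1 * rng.standard_normal(n)

    def test_peak_at_coupled_pair(self):
        nfft, epochs = 128, 64
        x = self._coupled_triple(nfft * epochs)
        b = bispectrum(x, epochs=epochs, nfft=nfft)
        f1_bin, f2_bin = round(0.12 * nfft), round(0.07 * nfft)
        mags = np.abs(b.values) * b.mask
        peak = np.unravel_index(np.argmax(mags), mags.shape)
        assert peak == (f1_bin, f2_bin)

    def test_noise_bispectrum_shrinks_with_epochs(self):
        rng = np.random.default_rng(10)
        x = rng.standard_normal(128 * 256)
        small = bispectrum(x, epochs=16, nfft=128)
        large = bispectrum(x, epochs=256, nfft=128)
        assert large.magnitudes.max() < small.magnitudes.max()

    def test_insufficient_length_raises(self):
        with pytest.raises(ValueError):
            bispectrum(np.ones(100), epochs=4, nfft=64)

    def test_phase_entropy_ordering_s2_le_s1(self):
        x = np.random.default_rng(11).standard_normal(128 * 32)
        s1, s2 = phase_entropies(bispectrum(x, epochs=32, nfft=128))
        assert 0 <= s2 <= s1

    def test_coupled_triple_lower_s1_than_noise(self):
        nfft, epochs = 128, 64
        x = self._coupled_triple(nfft * epochs)
        noise = np.random.default_rng(12).standard_normal(nfft * epochs)
        s1_sig, _ = phase_entropies(bispectrum(x, epochs=epochs, nfft=nfft))
        s1_noise, _ = phase_entropies(bispectrum(noise, epochs=epochs, nfft=nfft))
        assert s1_sig < s1_noise

    def test_zero_signal_phase_entropy_undefined(self):
        b = bispectrum(np.zeros(64 * 4), epochs=4, nfft=64)
        with pytest.raises(UndefinedEntropyError):
            phase_entropies(b)


class TestEntropyVector:
    def test_length_and_order(self):
        x = np.random.default_rng(13).standard_normal(2048)
        params = EntropyParams(bispec_epochs=8, bispec_nfft=256)
        v = entropy_vector(x, params)
        assert v.shape == (8,)
        assert ENTROPY_NAMES == ("ape", "pe", "sh", "sp", "ts", "s2", "s1", "ren")
        assert np.all(np.isfinite(v))

    def test_matches_standalone_estimators(self):
        x = np.random.default_rng(14).standard_normal(2048)
        params = EntropyParams(bispec_epochs=8, bispec_nfft=256)
        v = entropy_vector(x, params)
        assert v[0] == pytest.approx(approximate_entropy(x), abs=1e-12)
        assert v[3] == pytest.approx(sample_entropy(x), abs=1e-12)
        assert v[1] == pytest.approx(permutation_entropy(x), abs=1e-12)
        p = power_spectrum_probs(x)
        assert v[2] == pytest.approx(shannon_spectral(p), abs=1e-12)
        assert v[7] == pytest.approx(renyi_spectral(p), abs=1e-12)
        assert v[4] == pytest.approx(tsallis_spectral(p), abs=1e-12)

    def test_constant_signal_sentinels(self):
        with pytest.warns(UserWarning):
            v = entropy_vector(np.full(2048, 5.0))
        assert v[ENTROPY_NAMES.index("ape")] == 0.0
        assert v[ENTROPY_NAMES.index("sp")] == 0.0
        assert v[ENTROPY_NAMES.index("pe")] == 0.0
        assert np.isnan(v[ENTROPY_NAMES.index("sh")])

    def test_deterministic(self):
        x = np.random.default_rng(15).standard_normal(4096)
        params = EntropyParams(bispec_epochs=8, bispec_nfft=512)
        v1 = entropy_vector(x, params)
        v2 = entropy_vector(x.copy(), params)
        np.testing.assert_array_equal(v1, v2)
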