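import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dielmap import (
    HyperspectralStack,
    SkewedGaussianFit,
    SpectralAxis,
    Spectrum,
    fit_skewed_gaussian,
    mode_of_skew_gaussian,
    phase_modulus,
    phasor_image,
    phasor_transform,
)
from dielmap.spectra import (
    DegenerateSpectrumError,
    EmptySpectrumError,
    skew_gaussian,
)

from conftest import delta_spectrum


def phasor_oracle(intensities, n_channels, harmonic=1):
    """Independent direct-summation implementation of the transform."""
    g = s = total = 0.0
    for c, i in enumerate(intensities):
        angle = 2.0 * math.pi * harmonic * c / n_channels
        g += i * math.cos(angle)
        s += i * math.sin(angle)
        total += i
    return g / total, s / total


class TestSpectralAxis:
    def test_instrument_bandwidth(self, axis):
        assert axis.bandwidth == pytest.approx(9.75)

    def test_channel_centers(self, axis):
        centers = axis.channel_centers
        assert centers[0] == pytest.approx(416.0 + 9.75 / 2)
        assert centers[-1] == pytest.approx(728.0 - 9.75 / 2)
        assert len(centers) == 32

    @pytest.mark.parametrize(
        "lo,hi,n", [(728, 416, 32), (416, 416, 32), (416, 728, 1)]
    )
    def test_invalid_axis(self, lo, hi, n):
        with pytest.raises(ValueError):
            SpectralAxis(lo, hi, n)


class TestPhasorTransform:
    def test_delta_channel_zero(self, axis):
        p = phasor_transform(delta_spectrum(axis, 0))
        assert (p.G, p.S) == (1.0, 0.0)
        assert p.phase == 0.0
        assert p.modulus == pytest.approx(1.0)

    def test_delta_channel_eight(self, axis):
        p = phasor_transform(delta_spectrum(axis, 8))
        assert p.G == pytest.approx(0.0, abs=1e-15)
        assert p.S == pytest.approx(1.0)
        assert p.phase == pytest.approx(math.pi / 2)
        assert p.modulus == pytest.approx(1.0)

    def test_uniform_spectrum_nulls(self, axis):
        p = phasor_transform(Spectrum(axis, np.ones(32)))
        assert p.G == pytest.approx(0.0, abs=1e-14)
        assert p.S == pytest.approx(0.0, abs=1e-14)

    def test_fifty_fifty_mix_is_midpoint(self, axis):
        intens = np.zeros(32)
        intens[0] = intens[8] = 0.5
        p = phasor_transform(Spectrum(axis, intens))
        assert p.G == pytest.approx(0.5)
        assert p.S == pytest.approx(0.5)

    def test_empty_spectrum_raises(self, axis):
        with pytest.raises(EmptySpectrumError):
            phasor_transform(Spectrum(axis, np.zeros(32)))

    def test_bad_harmonic(self, axis):
        with pytest.raises(ValueError):
            phasor_transform(delta_spectrum(axis, 0), harmonic=0)

    def test_harmonic_two_delta(self, axis):
        # delta at c=8 with n=2 rotates twice as fast: angle pi
        p = phasor_transform(delta_spectrum(axis, 8), harmonic=2)
        assert p.phase == pytest.approx(math.pi)

    def test_oracle_equivalence_random(self, axis, rng):
        for _ in range(50):
            intens = rng.gamma(2.0, 50.0, size=32)
            p = phasor_transform(Spectrum(axis, intens))
            g, s = phasor_oracle(intens, 32)
            assert p.G == pytest.approx(g, abs=1e-12)
            assert p.S == pytest.approx(s, abs=1e-12)

    def test_linearity_equal_totals(self, axis, rng):
        for _ in range(20):
            a = rng.random(32)
            b = rng.random(32)
            a /= a.sum()
            b /= b.sum()
            w = rng.random()
            pa, pb = (
                phasor_transform(Spectrum(axis, v)) for v in (a, b)
            )
            pm = phasor_transform(Spectrum(axis, w * a + (1 - w) * b))
            assert pm.G == pytest.approx(w * pa.G + (1 - w) * pb.G, abs=1e-12)
            assert pm.S == pytest.approx(w * pa.S + (1 - w) * pb.S, abs=1e-12)

    def test_linearity_unequal_totals(self, axis, rng):
        a = rng.random(32) * 3.0
        b = rng.random(32) * 7.0
        pa, pb = (phasor_transform(Spectrum(axis, v)) for v in (a, b))
        pm = phasor_transform(Spectrum(axis, a + b))
        wa = a.sum() / (a.sum() + b.sum())
        assert pm.G == pytest.approx(wa * pa.G + (1 - wa) * pb.G, abs=1e-12)
        assert pm.S == pytest.approx(wa * pa.S + (1 - wa) * pb.S, abs=1e-12)

    @settings(max_examples=50, deadline=None)
    @given(
        data=st.lists(
            st.floats(0.0, 1e6, allow_nan=False), min_size=32, max_size=32
        )
    )
    def test_modulus_bound_property(self, data):
        intens = np.asarray(data)
        if intens.sum() <= 0:
            return
        p = phasor_transform(Spectrum(SpectralAxis(416, 728, 32), intens))
        assert p.modulus <= 1.0 + 1e-12

    def test_modulus_one_iff_single_channel(self, axis, rng):
        assert phasor_transform(delta_spectrum(axis, 13)).modulus == pytest.approx(1.0)
        spread = rng.random(32) + 0.1
        assert phasor_transform(Spectrum(axis, spread)).modulus < 1.0

    def test_shift_covariance(self, axis, rng):
        intens = rng.random(32)
        p0 = phasor_transform(Spectrum(axis, intens))
        for k in (1, 5, 17):
            pk = phasor_transform(Spectrum(axis, np.roll(intens, k)))
            rot = (p0.G + 1j * p0.S) * np.exp(2j * np.pi * k / 32)
            assert pk.G == pytest.approx(rot.real, abs=1e-12)
            assert pk.S == pytest.approx(rot.imag, abs=1e-12)

    def test_broadening_decreases_modulus(self, axis):
        lam = axis.channel_centers
        mods = []
        for sigma in (10.0, 20.0, 40.0, 80.0):
            intens = np.exp(-0.5 * ((lam - 560.0) / sigma) ** 2)
            mods.append(phasor_transform(Spectrum(axis, intens)).modulus)
        assert all(a > b for a, b in zip(mods, mods[1:]))


class TestPhaseModulus:
    @pytest.mark.parametrize(
        "g,s,phase,mod",
        [
            (0.0, 1.0, math.pi / 2, 1.0),
            (-1.0, 0.0, math.pi, 1.0),
            (0.5, 0.5, math.pi / 4, math.sqrt(2) / 2),
            (0.0, -1.0, 3 * math.pi / 2, 1.0),
        ],
    )
    def test_examples(self, g, s, phase, mod):
        ph, m = phase_modulus(g, s)
        assert ph == pytest.approx(phase)
        assert m == pytest.approx(mod)

    def test_origin_flagged(self):
        ph, m = phase_modulus(0.0, 0.0)
        assert math.isnan(ph)
        assert m == 0.0

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            phase_modulus(float("nan"), 0.0)


class TestPhasorImage:
    def test_uniform_delta_stack(self, axis):
        cube = np.zeros((2, 2, 32))
        cube[..., 0] = 7.0
        img = phasor_image(HyperspectralStack(axis, cube))
        assert np.allclose(img.G_map, 1.0)
        assert np.allclose(img.S_map, 0.0)
        assert img.valid_mask.all()

    def test_zero_pixel_masked(self, axis):
        cube = np.zeros((2, 2, 32))
        cube[0, 0, 3] = 1.0
        img = phasor_image(HyperspectralStack(axis, cube))
        assert img.valid_mask[0, 0]
        assert not img.valid_mask[1, 1]
        assert np.isnan(img.phase_map[1, 1])

    def test_matches_per_pixel_transform(self, axis, rng):
        cube = rng.random((3, 4, 32)) * 100
        stack = HyperspectralStack(axis, cube)
        img = phasor_image(stack)
        for r in range(3):
            for c in range(4):
                p = phasor_transform(stack.pixel_spectrum(r, c))
                assert img.G_map[r, c] == pytest.approx(p.G, abs=1e-12)
                assert img.S_map[r, c] == pytest.approx(p.S, abs=1e-12)

    def test_channel_mismatch_is_structural_error(self, axis):
        with pytest.raises(ValueError, match="channels"):
            HyperspectralStack(axis, np.zeros((2, 2, 31)))

    def test_two_phase_cluster_means(self, axis, forward_phase, calibration):
        # generated two-phase stack: cluster mean phases match the
        # forward-model phases within 3 standard errors
        from dielmap import Droplet, SceneSpec, generate_stack

        scene = SceneSpec(
            shape=(48, 48),
            droplets=[Droplet(center=(24, 24), radius=12, epsilon=10.0,
                              peak_counts=400.0)],
            background_epsilon=50.0,
            background_peak_counts=150.0,
            noise="poisson",
            seed=7,
        )
        stack, truth = generate_stack(scene, forward_phase, axis)
        img = phasor_image(stack)
        phases = img.phase_map
        for sel, eps in (
            (truth.labels == 1, 10.0),
            (truth.labels == 0, 50.0),
        ):
            vals = phases[sel & img.valid_mask]
            expected = calibration.phase(eps)
            sem = vals.std(ddof=1) / math.sqrt(vals.size)
            assert abs(vals.mean() - expected) < 3 * sem + 1e-4


class TestSkewedGaussianFit:
    def test_symmetric_recovery(self, axis):
        lam = axis.channel_centers
        sp = Spectrum(axis, skew_gaussian(lam, 1000.0, 540.0, 40.0, 0.0))
        fit = fit_skewed_gaussian(sp)
        assert fit.I0 == pytest.approx(1000.0, rel=1e-6)
        assert fit.mu == pytest.approx(540.0, rel=1e-6)
        assert fit.sigma == pytest.approx(40.0, rel=1e-6)
        assert abs(fit.gamma) < 1e-6
        assert fit.lambda_max == pytest.approx(540.0, abs=1e-6)

    def test_skewed_recovery(self, axis):
        lam = axis.channel_centers
        sp = Spectrum(axis, skew_gaussian(lam, 1000.0, 540.0, 40.0, 3.0))
        fit = fit_skewed_gaussian(sp)
        assert fit.mu == pytest.approx(540.0, rel=1e-4)
        assert fit.sigma == pytest.approx(40.0, rel=1e-4)
        assert fit.gamma == pytest.approx(3.0, rel=1e-4)

    def test_flat_spectrum_degenerate(self, axis):
        with pytest.raises(DegenerateSpectrumError):
            fit_skewed_gaussian(Spectrum(axis, np.full(32, 5.0)))

    def test_sparse_spectrum_degenerate(self, axis):
        intens = np.zeros(32)
        intens[[3, 7, 11]] = 10.0
        with pytest.raises(DegenerateSpectrumError):
            fit_skewed_gaussian(Spectrum(axis, intens))

    def test_poisson_lambda_max_recovery(self, axis, rng):
        # median |lambda_max error| under shot noise at ~1e2 peak counts
        # stays below one channel bandwidth (Monte-Carlo, reduced here;
        # the 200-seed version runs in the acceptance suite)
        lam = axis.channel_centers
        clean = skew_gaussian(lam, 1.0, 500.0, 40.0, 1.0)
        clean *= 100.0 / clean.max()
        truth = SkewedGaussianFit(I0=1.0, mu=500.0, sigma=40.0, gamma=1.0)
        true_mode = mode_of_skew_gaussian(truth)
        errs = []
        for _ in range(60):
            noisy = rng.poisson(clean).astype(float)
            fit = fit_skewed_gaussian(Spectrum(axis, noisy))
            errs.append(abs(fit.lambda_max - true_mode))
        assert np.median(errs) < axis.bandwidth


class TestModeOfSkewGaussian:
    def test_symmetric_mode_is_mu(self):
        fit = SkewedGaussianFit(I0=1.0, mu=540.0, sigma=40.0, gamma=0.0)
        assert mode_of_skew_gaussian(fit) == pytest.approx(540.0, abs=1e-6)

    def test_against_brute_force_grid(self):
        fit = SkewedGaussianFit(I0=1.0, mu=500.0, sigma=30.0, gamma=5.0)
        grid = np.arange(400.0, 620.0, 0.001)
        brute = grid[np.argmax(skew_gaussian(grid, 1.0, 500.0, 30.0, 5.0))]
        assert mode_of_skew_gaussian(fit) == pytest.approx(brute, abs=0.01)

    @pytest.mark.parametrize("gamma", [0.5, 1.0, 2.5, 7.0])
    def test_mirror_symmetry(self, gamma):
        plus = SkewedGaussianFit(I0=1.0, mu=500.0, sigma=30.0, gamma=gamma)
        minus = SkewedGaussianFit(I0=1.0, mu=500.0, sigma=30.0, gamma=-gamma)
        d_plus = mode_of_skew_gaussian(plus) - 500.0
        d_minus = mode_of_skew_gaussian(minus) - 500.0
        assert d_plus == pytest.approx(-d_minus, abs=1e-6)

    def test_invalid_sigma(self):
        with pytest.raises(ValueError):
            mode_of_skew_gaussian(
                SkewedGaussianFit(I0=1.0, mu=500.0, sigma=0.0, gamma=1.0)
            )
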