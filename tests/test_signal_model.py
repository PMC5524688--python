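"""Emission, IRF convolution and steady-state band-ratio tests."""
import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from geminate.dse_core import GridSpec, SolverConfig, solve_dse
from geminate.signal_model import (BandModel, EmissionCurve, IRF,
                                   SteadyStateSpectrum,
                                   UnderResolvedIRFError,
                                   UnidentifiableModelError,
                                   apply_excited_state_decay, convolve_irf,
                                   gaussian_irf, measure_ratio, synth_spectrum)

WL = np.arange(300.0, 560.0, 0.5)
BANDS = BandModel(roh_center=370.0, ro_center=420.0)


def _trace(k_pt=0.2, k_a=0.2, t_max=20.0):
    cfg = SolverConfig(4.0, 7.0, 9e-5, 3.0, k_pt, k_a)
    return solve_dse(cfg, GridSpec.auto(cfg, t_max, np.linspace(0.01, t_max, 200)))


class TestLifetimeWeighting:
    def test_infinite_lifetime_recovers_populations(self):
        tr = _trace()
        roh, ro = apply_excited_state_decay(tr, tau_roh=1e12, tau_ro=1e12)
        assert np.allclose(roh.intensity, tr.p_bound)
        assert np.allclose(ro.intensity, tr.separated_fraction)

    def test_initial_condition_fully_protonated(self):
        tr = _trace()
        roh, ro = apply_excited_state_decay(tr, 8.0, 10.0)
        # t=0 not on the grid; extrapolate from the first samples
        assert roh.intensity[0] == pytest.approx(1.0, abs=0.01)
        assert ro.intensity[0] == pytest.approx(0.0, abs=0.01)
        assert np.all(roh.intensity >= 0) and np.all(ro.intensity >= 0)
        assert roh.intensity[0] + ro.intensity[0] <= 1.0 + 1e-9

    def test_pure_radiative_decay_when_nothing_dissociates(self):
        tr = _trace(k_pt=0.0)
        roh, _ = apply_excited_state_decay(tr, tau_roh=5.0, tau_ro=10.0)
        i5 = np.interp(5.0, roh.times, roh.intensity)
        assert i5 == pytest.approx(np.exp(-1.0), rel=1e-4)

    def test_invalid_lifetimes(self):
        with pytest.raises(ValueError):
            apply_excited_state_decay(_trace(), -1.0, 10.0)


class TestIRF:
    def test_normalized_and_centered(self):
        irf = gaussian_irf(1.0, 2.0, 0.055, 3640)
        assert irf.weights.sum() == pytest.approx(1.0, abs=1e-9)
        centroid = float(np.sum(irf.times * irf.weights))
        assert centroid == pytest.approx(2.0, abs=0.055)
        # discrete FWHM within one channel of nominal
        half = irf.weights.max() / 2
        above = np.nonzero(irf.weights >= half)[0]
        width = irf.times[above[-1]] - irf.times[above[0]]
        # threshold crossing can truncate inward by up to one channel per side
        assert width == pytest.approx(1.0, abs=2 * 0.055)

    def test_under_resolved_rejected(self):
        with pytest.raises(UnderResolvedIRFError):
            gaussian_irf(0.05, 2.0, 0.055, 1000)


class TestConvolution:
    def test_delta_irf_is_identity(self):
        t = np.arange(200) * 0.1
        curve = EmissionCurve(times=t, intensity=np.exp(-t / 2.0))
        w = np.zeros(200)
        w[0] = 1.0
        delta = IRF(times=t, weights=w, fwhm=0.2, t0=0.0)
        out = convolve_irf(curve, delta)
        assert np.allclose(out.intensity, curve.intensity)

    def test_intensity_preserved(self):
        t = np.arange(1000) * 0.05
        curve = EmissionCurve(times=t, intensity=np.exp(-t / 2.0))
        irf = gaussian_irf(1.0, 2.0, 0.05, 1000)
        out = convolve_irf(curve, irf)
        assert out.intensity.sum() == pytest.approx(curve.intensity.sum(), rel=1e-6)

    def test_grid_mismatch_rejected(self):
        t = np.arange(100) * 0.1
        curve = EmissionCurve(times=t, intensity=np.ones(100))
        irf = gaussian_irf(1.0, 2.0, 0.05, 200)
        with pytest.raises(ValueError):
            convolve_irf(curve, irf)

    def test_fast_decay_peak_pinned_to_irf_peak(self):
        # a 0.1 ns decay through a 1 ns pulse peaks where the pulse does
        t = np.arange(2000) * 0.01
        curve = EmissionCurve(times=t, intensity=np.exp(-t / 0.1))
        irf = gaussian_irf(1.0, 5.0, 0.01, 2000)
        out = convolve_irf(curve, irf)
        t_peak = t[np.argmax(out.intensity)]
        assert abs(t_peak - 5.0) <= 0.2

    @given(alpha=st.floats(0.1, 5.0), beta=st.floats(0.1, 5.0))
    def test_linearity(self, alpha, beta):
        t = np.arange(500) * 0.05
        x = EmissionCurve(times=t, intensity=np.exp(-t / 1.5))
        y = EmissionCurve(times=t, intensity=np.exp(-t / 6.0))
        irf = gaussian_irf(0.8, 2.0, 0.05, 500)
        combo = EmissionCurve(times=t, intensity=alpha * x.intensity + beta * y.intensity)
        lhs = convolve_irf(combo, irf).intensity
        rhs = alpha * convolve_irf(x, irf).intensity + beta * convolve_irf(y, irf).intensity
        assert np.allclose(lhs, rhs, rtol=1e-10, atol=1e-12)


class TestSteadyState:
    @pytest.mark.parametrize("ratio", [0.70, 0.74, 4.9, 6.4, 6.5, 16.6, 18.2, 48.5])
    def test_round_trip_at_published_ratios(self, ratio):
        spectrum = synth_spectrum(ratio, BANDS, WL)
        assert measure_ratio(spectrum, BANDS) == pytest.approx(ratio, rel=0.01)

    def test_zero_ratio_single_band(self):
        spectrum = synth_spectrum(0.0, BANDS, WL)
        assert measure_ratio(spectrum, BANDS) == pytest.approx(0.0, abs=1e-12)
        apex = WL[np.argmax(spectrum.intensity)]
        assert apex == pytest.approx(BANDS.roh_center, abs=1.0)

    def test_bathochromic_shift_moves_only_the_ro_band(self):
        shifted = BANDS.shifted(5.0)
        s0 = synth_spectrum(50.0, BANDS, WL)
        s5 = synth_spectrum(50.0, shifted, WL)
        assert WL[np.argmax(s5.intensity)] - WL[np.argmax(s0.intensity)] == pytest.approx(5.0, abs=0.5)
        roh0 = synth_spectrum(0.0, BANDS, WL)
        roh5 = synth_spectrum(0.0, shifted, WL)
        assert np.allclose(roh0.intensity, roh5.intensity)

    @given(scale=st.floats(1e-3, 1e3), ratio=st.floats(0.01, 100.0))
    def test_scale_invariance(self, scale, ratio):
        spectrum = synth_spectrum(ratio, BANDS, WL)
        scaled = SteadyStateSpectrum(WL, spectrum.intensity * scale)
        assert measure_ratio(scaled, BANDS) == pytest.approx(
            measure_ratio(spectrum, BANDS), rel=1e-9)

    @pytest.mark.parametrize("ratio", [0.01, 0.5, 6.4, 48.5, 100.0])
    def test_round_trip_with_additive_noise(self, ratio):
        spectrum = synth_spectrum(ratio, BANDS, WL)
        rng = np.random.default_rng(12)
        # 1% proportional (shot-noise-like) perturbation of the spectrum
        noisy = np.clip(spectrum.intensity
                        * (1.0 + 0.01 * rng.normal(size=WL.size)), 0.0, None)
        measured = measure_ratio(SteadyStateSpectrum(WL, noisy), BANDS)
        assert measured == pytest.approx(ratio, rel=0.05)

    def test_matches_brute_force_amplitude_search(self):
        # exhaustive 2D grid search over band amplitudes as the oracle
        wl = np.linspace(320, 500, 50)
        spectrum = synth_spectrum(6.4, BANDS, wl)
        roh, ro = BANDS.basis(wl)
        best, best_sse = None, np.inf
        for a1 in np.linspace(0.5, 1.5, 101):
            for a2 in np.linspace(5.0, 8.0, 301):
                sse = float(np.sum((a1 * roh + a2 * ro - spectrum.intensity) ** 2))
                if sse < best_sse:
                    best, best_sse = a2 / a1, sse
        assert measure_ratio(spectrum, BANDS) == pytest.approx(best, rel=1e-3)

    def test_degenerate_bands_rejected(self):
        wl = np.arange(300.0, 560.0, 0.5)
        # force identical profiles via equal centers after shift
        bands = BandModel(roh_center=400.0, ro_center=401.0).shifted(-1.0)
        spectrum = synth_spectrum(1.0, BANDS, wl)
        with pytest.raises(UnidentifiableModelError):
            measure_ratio(spectrum, bands)

    def test_band_outside_grid_rejected(self):
        with pytest.raises(ValueError):
            synth_spectrum(1.0, BANDS, np.arange(430.0, 560.0, 0.5))
        with pytest.raises(ValueError):
            BandModel(roh_center=420.0, ro_center=380.0)
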