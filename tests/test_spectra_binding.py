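"""Spectral normalization/comparison and MST isotherm fitting."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.optimize import curve_fit

from cblpocket import synthetic
from cblpocket.spectra_binding import (
    NoBindingError,
    NormalizationError,
    Spectrum,
    ThermophoresisTrace,
    area_normalize,
    band_metrics,
    compare_spectra,
    fit_kd,
    fit_kd_from_traces,
    fnorm,
    stability_series,
)

COLD = (0.0, 4.0)
HOT = (15.0, 25.0)


class TestAreaNormalize:
    def test_idempotent_and_reverses_scaling(self):
        s = synthetic.hocbl_like_spectrum()
        n1 = area_normalize(s)
        n2 = area_normalize(n1)
        assert np.allclose(n1.absorbance, n2.absorbance, atol=1e-12)
        scaled = Spectrum(s.wavelength, 5.0 * s.absorbance)
        assert np.allclose(area_normalize(scaled).absorbance, n1.absorbance, atol=1e-12)

    def test_rectangular_pulse_analytic(self):
        w = np.arange(500.0, 521.0)
        a = np.where((w >= 505) & (w <= 515), 2.0, 0.0)
        n = area_normalize(Spectrum(w, a))
        # trapezoid area: 10 nm plateau (20) plus two 1 nm edge ramps (1 each)
        assert n.absorbance.max() == pytest.approx(2.0 / 22.0)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(scale=st.floats(min_value=1e-3, max_value=1e3))
    def test_normalization_scale_invariant(self, scale):
        """Any positive rescaling of the input leaves the normalized
        spectrum unchanged."""
        s = synthetic.gscbl_like_spectrum()
        n0 = area_normalize(s)
        n1 = area_normalize(Spectrum(s.wavelength, scale * s.absorbance))
        assert np.allclose(n0.absorbance, n1.absorbance, rtol=1e-9, atol=1e-12)

    def test_zero_area_rejected(self):
        w = np.arange(300.0, 401.0)
        with pytest.raises(NormalizationError):
            area_normalize(Spectrum(w, np.zeros_like(w)))


class TestBandMetrics:
    def test_single_gaussian_peak_position(self):
        s = synthetic.make_spectrum([(530.0, 1.0, 15.0)])
        m = band_metrics(s)
        assert m["alphabeta"]["position_nm"] == pytest.approx(530.0, abs=1.0)

    def test_known_red_shift_recovered(self):
        ref = synthetic.hocbl_like_spectrum()
        shifted = synthetic.gscbl_like_spectrum(red_shift=12.0)
        cmp_ = compare_spectra(ref, shifted)
        assert cmp_["alphabeta_shift_nm"] == pytest.approx(12.0, abs=1.0)

    def test_known_gamma_collapse_recovered(self):
        ref = synthetic.hocbl_like_spectrum()
        collapsed = synthetic.gscbl_like_spectrum(gamma_ratio=0.5)
        cmp_ = compare_spectra(ref, collapsed)
        assert cmp_["gamma_collapse_ratio"] == pytest.approx(0.5, abs=0.02)

    def test_comparison_scale_invariant(self):
        ref = synthetic.hocbl_like_spectrum()
        other = synthetic.gscbl_like_spectrum()
        big = Spectrum(other.wavelength, 37.0 * other.absorbance, other.label)
        a = compare_spectra(ref, other)
        b = compare_spectra(ref, big)
        assert a["gamma_collapse_ratio"] == pytest.approx(b["gamma_collapse_ratio"], abs=1e-12)

    def test_flat_window_flagged(self):
        w = np.arange(300.0, 701.0)
        s = Spectrum(w, np.ones_like(w))
        m = band_metrics(s, gamma_window=(340, 370))
        assert m["gamma"]["flat"] is True
        assert m["gamma"]["position_nm"] == pytest.approx(355.0)


class TestStability:
    def test_identical_series_zero_drift(self):
        ref = synthetic.gscbl_like_spectrum()
        series = [(float(t), synthetic.gscbl_like_spectrum()) for t in (0, 24, 48)]
        out = stability_series(ref, series)
        assert np.allclose(out["drifts"], 0.0, atol=1e-12)

    def test_decay_series_strictly_increasing_drift(self):
        """A mixture interpolating from the glutathionyl-like to the
        hydroxo-like spectrum drifts monotonically from the reference."""
        ref = synthetic.gscbl_like_spectrum()
        hoc = synthetic.hocbl_like_spectrum()
        series = []
        for i, frac in enumerate((0.0, 0.25, 0.5, 0.75, 1.0)):
            mix = Spectrum(ref.wavelength,
                           (1 - frac) * ref.absorbance + frac * hoc.absorbance)
            series.append((float(i * 24), mix))
        out = stability_series(ref, series)
        d = out["drifts"]
        assert all(b > a for a, b in zip(d, d[1:]))
        assert out["kendall_tau"] == pytest.approx(1.0)

    def test_stable_vs_decaying_tau(self):
        ref = synthetic.gscbl_like_spectrum()
        stable = [(float(t), synthetic.gscbl_like_spectrum(noise=1e-4, seed=t))
                  for t in (0, 24, 48, 72)]
        hoc = synthetic.hocbl_like_spectrum()
        decaying = [
            (float(i * 24),
             Spectrum(ref.wavelength,
                      (1 - f) * ref.absorbance + f * hoc.absorbance))
            for i, f in enumerate((0.0, 0.3, 0.6, 0.9))
        ]
        tau_stable = stability_series(ref, stable)["kendall_tau"]
        tau_decay = stability_series(ref, decaying)["kendall_tau"]
        assert tau_stable < tau_decay

    def test_too_few_timepoints(self):
        ref = synthetic.gscbl_like_spectrum()
        with pytest.raises(ValueError):
            stability_series(ref, [(0.0, ref)])


class TestFnorm:
    def test_constant_trace_is_1000(self):
        t = np.arange(0.0, 30.0, 0.25)
        tr = ThermophoresisTrace(t, np.full_like(t, 123.4), 1e-9)
        assert fnorm(tr, COLD, HOT) == pytest.approx(1000.0)

    def test_hot_cold_ratio_arithmetic(self):
        t = np.arange(0.0, 30.0, 0.25)
        f = np.where(t < 10.0, 1.0, 0.95)
        tr = ThermophoresisTrace(t, f, 1e-9)
        assert fnorm(tr, COLD, HOT) == pytest.approx(950.0)

    def test_synthetic_trace_matches_direct_arithmetic(self):
        tr = synthetic.make_mst_traces(kd=50e-9, probe=625e-12, noise=0.0)[8]
        t, f = tr.time, tr.fluorescence
        cold = f[(t >= COLD[0]) & (t <= COLD[1])].mean()
        hot = f[(t >= HOT[0]) & (t <= HOT[1])].mean()
        assert fnorm(tr, COLD, HOT) == pytest.approx(1000.0 * hot / cold, abs=1e-12)

    def test_window_validation(self):
        t = np.arange(0.0, 30.0, 0.25)
        tr = ThermophoresisTrace(t, np.ones_like(t), 0.0)
        with pytest.raises(ValueError):
            fnorm(tr, (0.0, 20.0), (15.0, 25.0))  # overlapping
        with pytest.raises(ValueError):
            fnorm(tr, (-5.0, 4.0), HOT)  # outside support


class TestFitKd:
    def test_noiseless_recovery_exact(self):
        conc, y = synthetic.make_mst_curve(kd=50e-9, probe=625e-12, noise=0.0)
        curve = fit_kd(conc, y, probe_conc=625e-12)
        assert curve.fitted_kd == pytest.approx(50e-9, rel=1e-6)
        assert curve.kd_is_lower_limit is False

    def test_noisy_recovery_within_factor(self):
        """Median recovered Kd over 100 seeds within 1.5× of truth at 5% noise."""
        kds = []
        for seed in range(100):
            conc, y = synthetic.make_mst_curve(kd=50e-9, probe=625e-12,
                                               noise=0.05, seed=seed)
            try:
                kds.append(fit_kd(conc, y, probe_conc=625e-12).fitted_kd)
            except NoBindingError:
                pass
        assert len(kds) >= 90
        med = float(np.median(kds))
        assert 50e-9 / 1.5 <= med <= 50e-9 * 1.5

    def test_probe_above_kd_flags_lower_limit(self):
        conc, y = synthetic.make_mst_curve(kd=100e-12, probe=625e-12, noise=0.0)
        curve = fit_kd(conc, y, probe_conc=625e-12)
        assert curve.kd_is_lower_limit is True

    def test_zero_amplitude_raises_no_binding(self):
        conc, y = synthetic.make_mst_curve(kd=50e-9, probe=625e-12,
                                           amplitude=0.0, noise=0.0)
        y = y + np.random.default_rng(0).normal(0, 0.5, y.shape)
        with pytest.raises(NoBindingError):
            fit_kd(conc, y, probe_conc=625e-12)

    def test_reduces_to_hyperbola_at_vanishing_probe(self):
        """With probe = Kd/1000 the depletion fit agrees with a plain
        hyperbolic-isotherm fit to 1%."""
        kd = 50e-9
        probe = kd / 1000.0
        conc, y = synthetic.make_mst_curve(kd=kd, probe=probe, noise=0.0)
        quad = fit_kd(conc, y, probe_conc=probe)

        def hyperbola(L, baseline, amplitude, log_kd):
            return baseline + amplitude * L / (L + 10.0**log_kd)

        popt, _ = curve_fit(hyperbola, conc, y, p0=[y[0], y[-1] - y[0], np.log10(kd)],
                            maxfev=10000)
        assert quad.fitted_kd == pytest.approx(10.0 ** popt[2], rel=0.01)

    def test_recovery_bias_small_when_probe_well_below_kd(self):
        """Median bias < 10% over 200 seeds for probe ≤ Kd/10, noise ≤ 2%."""
        kd = 50e-9
        kds = []
        for seed in range(200):
            conc, y = synthetic.make_mst_curve(kd=kd, probe=kd / 10.0,
                                               noise=0.02, seed=seed)
            kds.append(fit_kd(conc, y, probe_conc=kd / 10.0).fitted_kd)
        bias = abs(float(np.median(kds)) - kd) / kd
        assert bias < 0.10

    def test_input_validation(self):
        conc = np.array([1e-9, 2e-9, 4e-9, 8e-9, 16e-9])
        with pytest.raises(ValueError):
            fit_kd(conc, np.ones(5), probe_conc=1e-9)  # too few points
        conc16, y16 = synthetic.make_mst_curve(kd=1e-9, probe=1e-10)
        with pytest.raises(ValueError):
            fit_kd(conc16 * 0 + np.linspace(1e-9, 2e-9, 16), y16, probe_conc=1e-10)


def test_fit_from_traces_matches_curve_fit():
    traces = synthetic.make_mst_traces(kd=50e-9, probe=625e-12, noise=0.0)
    curve = fit_kd_from_traces(traces, probe_conc=625e-12,
                               cold_window=COLD, hot_window=HOT)
    assert curve.fitted_kd == pytest.approx(50e-9, rel=1e-5)
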