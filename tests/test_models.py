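"""Scan models and fits: closed-form values, symmetries, parameter recovery."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import optimize

from scopeqc import simulate as sim
from scopeqc.models import (
    ALPHA,
    DegenerateScanError,
    DispersionParams,
    PockelsParams,
    ScanSeries,
    _dispersion_model,
    _pockels_model,
    broadened_pulse_width,
    dispersion_fluorescence,
    fit_dispersion_scan,
    fit_pockels,
    pockels_transmission,
)

# ---------------------------------------------------------------------------
# forward models


class TestPockelsTransmission:
    @pytest.mark.parametrize(
        "v, expected",
        [(0.0, 0.0), (75.0, 100.0), (37.5, 50.0)],  # 0, V0/4, V0/8 at V0=300
    )
    def test_quarter_period_values(self, v, expected):
        p = PockelsParams(p0_mw=100.0, v0_v=300.0, phase_rad=0.0)
        assert pockels_transmission(v, p) == pytest.approx(expected, abs=1e-9)

    @settings(max_examples=60, derandomize=True, deadline=None)
    @given(
        p0=st.floats(1.0, 500.0),
        v0=st.floats(10.0, 1000.0),
        phase=st.floats(0.0, math.pi),
        v=st.floats(-2000.0, 2000.0),
    )
    def test_bounded_and_periodic(self, p0, v0, phase, v):
        p = PockelsParams(p0, v0, phase)
        val = float(pockels_transmission(v, p))
        assert -1e-9 <= val <= p0 * (1 + 1e-12)
        assert float(pockels_transmission(v + v0, p)) == pytest.approx(
            val, abs=p0 * 1e-9
        )


class TestDispersionFluorescence:
    def test_peak_at_minus_phi0(self):
        d = DispersionParams(2.0, 20000.0, 150.0)
        assert dispersion_fluorescence(-20000.0, d) == pytest.approx(2.0)

    def test_half_maximum_offset(self):
        d = DispersionParams(1.0, 20000.0, 150.0)
        x_half = math.sqrt(3.0) * 150.0**2 / math.sqrt(ALPHA)
        assert x_half == pytest.approx(14056.0, abs=1.0)
        for sign in (+1, -1):
            val = dispersion_fluorescence(-20000.0 + sign * x_half, d)
            assert val == pytest.approx(0.5, rel=1e-12)

    @settings(max_examples=60, derandomize=True, deadline=None)
    @given(
        phi0=st.floats(-30000.0, 30000.0),
        dtau=st.floats(50.0, 400.0),
        x=st.floats(0.0, 50000.0),
    )
    def test_symmetric_and_decreasing_around_peak(self, phi0, dtau, x):
        d = DispersionParams(1.0, phi0, dtau)
        left = float(dispersion_fluorescence(-phi0 - x, d))
        right = float(dispersion_fluorescence(-phi0 + x, d))
        assert left == pytest.approx(right, rel=1e-12)
        assert right <= 1.0 + 1e-12
        further = float(dispersion_fluorescence(-phi0 + x + 1000.0, d))
        assert further < right or x == 0.0 and further < 1.0


class TestBroadenedPulseWidth:
    def test_unbroadened_at_zero_gdd(self):
        assert broadened_pulse_width(110.0, 0.0) == 110.0

    @pytest.mark.parametrize("tau0, gdd", [(110.0, 20200.0), (150.0, 10000.0)])
    def test_matches_fourier_propagation(self, tau0, gdd):
        # independent oracle: FFT a chirped Gaussian field, measure the
        # intensity FWHM in the time domain
        sigma_field = tau0 / (2.0 * math.sqrt(2.0 * math.log(2.0))) * math.sqrt(2.0)
        n, dt = 1 << 16, 0.25
        t = (np.arange(n) - n / 2) * dt
        field = np.exp(-(t**2) / (2.0 * sigma_field**2))
        w = 2.0 * np.pi * np.fft.fftfreq(n, dt)
        spec = np.fft.fft(np.fft.ifftshift(field)) * np.exp(1j * 0.5 * gdd * w**2)
        intensity = np.abs(np.fft.fftshift(np.fft.ifft(spec))) ** 2
        half = intensity.max() / 2.0
        above = np.nonzero(intensity >= half)[0]
        fwhm_fft = (above[-1] - above[0]) * dt
        assert broadened_pulse_width(tau0, gdd) == pytest.approx(fwhm_fft, rel=5e-3)

    def test_inverse_width_reproduces_scan_response(self):
        # I(phi) with phi0=0 equals dtau0 / dtau(phi) up to normalization
        d = DispersionParams(1.0, 0.0, 150.0)
        for phi in (0.0, 5000.0, -20000.0, 40000.0):
            ratio = 150.0 / broadened_pulse_width(150.0, phi)
            assert float(dispersion_fluorescence(phi, d)) == pytest.approx(
                ratio, rel=1e-12
            )


# ---------------------------------------------------------------------------
# fitting


class TestFitPockels:
    TRUTH = PockelsParams(p0_mw=120.0, v0_v=300.0, phase_rad=0.4)

    def test_noiseless_recovery_to_machine_precision(self):
        scan = sim.simulate_pockels_scan(self.TRUTH, np.linspace(0, 400, 50))
        fit = fit_pockels(scan)
        assert fit.params.p0_mw == pytest.approx(120.0, rel=1e-6)
        assert fit.params.v0_v == pytest.approx(300.0, rel=1e-6)
        assert fit.params.phase_rad == pytest.approx(0.4, rel=1e-6)

    def test_noisy_recovery_within_three_stderr(self):
        rng = np.random.default_rng(42)
        v = np.linspace(0, 400, 81)
        power = pockels_transmission(v, self.TRUTH) * (
            1.0 + 0.02 * rng.normal(size=v.size)
        )
        fit = fit_pockels(ScanSeries(v, power))
        for attr, truth in [("p0_mw", 120.0), ("v0_v", 300.0), ("phase_rad", 0.4)]:
            est = getattr(fit.params, attr)
            assert abs(est - truth) <= 3.0 * fit.stderr[attr]

    def test_phase_normalized_to_half_period(self):
        truth = PockelsParams(120.0, 300.0, 3.5)  # equivalent phase 3.5 - pi
        scan = sim.simulate_pockels_scan(truth, np.linspace(0, 400, 60))
        fit = fit_pockels(scan)
        assert 0.0 <= fit.params.phase_rad < math.pi
        assert fit.params.phase_rad == pytest.approx(3.5 - math.pi, rel=1e-4)

    def test_constant_ordinate_rejected(self):
        scan = ScanSeries(np.linspace(0, 400, 30), np.full(30, 5.0))
        with pytest.raises(DegenerateScanError):
            fit_pockels(scan)

    def test_too_few_points_rejected(self):
        scan = ScanSeries(np.array([0.0, 1, 2, 3]), np.array([0.0, 1, 2, 1]))
        with pytest.raises(ValueError):
            fit_pockels(scan)

    def test_initialization_robust(self):
        scan = sim.simulate_pockels_scan(
            self.TRUTH, np.linspace(0, 400, 81), noise_sd=1.0, seed=7
        )
        fit = fit_pockels(scan)
        for factor in (0.8, 1.2):
            start = (120.0 * factor, 300.0 * factor, 0.4 * factor)
            alt, _ = optimize.curve_fit(
                _pockels_model, scan.abscissa, scan.ordinate, p0=start, maxfev=20000
            )
            assert alt[1] == pytest.approx(fit.params.v0_v, rel=1e-4)
            assert abs(alt[0]) == pytest.approx(fit.params.p0_mw, rel=1e-4)

    def test_bootstrap_agrees_with_jacobian_stderr(self):
        scan = sim.simulate_pockels_scan(
            self.TRUTH, np.linspace(0, 400, 81), noise_sd=2.4, seed=3
        )
        fit = fit_pockels(scan, n_bootstrap=200, seed=1)
        for name in ("p0_mw", "v0_v"):
            assert fit.bootstrap_stderr[name] == pytest.approx(
                fit.stderr[name], rel=0.5
            )


class TestFitDispersion:
    TRUTH = DispersionParams(i0=1.0, phi0_fs2=20000.0, delta_tau_fs=150.0)

    def test_noiseless_recovery_to_machine_precision(self):
        scan = sim.simulate_dispersion_scan(
            self.TRUTH, np.linspace(-45000, 5000, 41)
        )
        fit = fit_dispersion_scan(scan)
        assert fit.params.i0 == pytest.approx(1.0, rel=1e-6)
        assert fit.params.phi0_fs2 == pytest.approx(20000.0, rel=1e-6)
        assert fit.params.delta_tau_fs == pytest.approx(150.0, rel=1e-6)

    def test_mean_pulse_width_unbiased_under_noise(self):
        phi = np.linspace(-45000, 5000, 101)
        widths = []
        for s in range(100):
            scan = sim.simulate_dispersion_scan(
                self.TRUTH, phi, noise_sd=0.03, seed=5000 + s
            )
            widths.append(fit_dispersion_scan(scan).params.delta_tau_fs)
        assert np.mean(widths) == pytest.approx(150.0, rel=0.05)

    def test_peak_at_boundary_flagged(self):
        scan = sim.simulate_dispersion_scan(
            self.TRUTH, np.linspace(-20000, 5000, 41)
        )
        with pytest.warns(UserWarning, match="boundary"):
            fit = fit_dispersion_scan(scan)
        assert "peak_at_boundary" in fit.flags

    def test_initialization_robust(self):
        scan = sim.simulate_dispersion_scan(
            self.TRUTH, np.linspace(-45000, 5000, 101), noise_sd=0.01, seed=11
        )
        fit = fit_dispersion_scan(scan)
        for factor in (0.8, 1.2):
            start = (1.0 * factor, 20000.0 * factor, 150.0 * factor)
            alt, _ = optimize.curve_fit(
                _dispersion_model, scan.abscissa, scan.ordinate, p0=start, maxfev=20000
            )
            assert alt[1] == pytest.approx(fit.params.phi0_fs2, rel=1e-4)
            assert alt[2] == pytest.approx(fit.params.delta_tau_fs, rel=1e-4)

    def test_constant_ordinate_rejected(self):
        scan = ScanSeries(np.linspace(-1000, 1000, 20), np.ones(20))
        with pytest.raises(DegenerateScanError):
            fit_dispersion_scan(scan)


def test_scan_series_validation():
    with pytest.raises(ValueError):
        ScanSeries(np.arange(5.0), np.arange(4.0))
    with pytest.raises(ValueError):
        ScanSeries(np.array([0.0, np.nan]), np.array([1.0, 2.0]))
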