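"""Forward models and nonlinear fits for instrument scans.

Two scan types drive routine two-photon alignment:

* **Pockels-cell voltage scan** — transmitted power through an electro-optic
  modulator followed by a polarizer is sinusoidal-squared in the control
  voltage, ``P(V) = P0 · sin(2πV/V0 + ϕ)²``.

* **Dispersion (GDD) scan** — two-photon fluorescence at fixed average power
  varies with applied group-delay dispersion φ (fs²) as
  ``I(φ) = I0 · (1 + α(φ+φ0)²/Δτ⁴)^(−1/2)`` with ``α = 16·ln(2)²``, for a
  Gaussian pulse of transform-limited FWHM Δτ entering with intrinsic
  system dispersion φ0. Fitting a scan yields both the residual dispersion
  and the pulse width without an autocorrelator.

Fits are ordinary least squares (:func:`scipy.optimize.curve_fit`), with
deterministic documented initializers, Jacobian-based standard errors and an
optional seeded residual bootstrap.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize
from scipy.ndimage import gaussian_filter1d

__all__ = [
    "ALPHA",
    "PockelsParams",
    "DispersionParams",
    "ScanSeries",
    "FitResult",
    "pockels_transmission",
    "dispersion_fluorescence",
    "broadened_pulse_width",
    "fit_pockels",
    "fit_dispersion_scan",
    "DegenerateScanError",
    "FitConvergenceError",
]

#: Gaussian-pulse constant in the GDD response: 16·ln(2)².
ALPHA: float = 16.0 * math.log(2.0) ** 2


class DegenerateScanError(ValueError):
    """Raised when a scan carries no usable signal (e.g. constant ordinate)."""


class FitConvergenceError(RuntimeError):
    """Raised when the nonlinear least-squares fit fails to converge."""


@dataclass(frozen=True)
class PockelsParams:
    """Parameters of the sin² transmission curve.

    p0_mw: peak transmitted power (mW); v0_v: full-period voltage (V);
    phase_rad: phase offset, normalized to [0, π) by the sin² symmetry.
    """

    p0_mw: float
    v0_v: float
    phase_rad: float

    def __post_init__(self) -> None:
        if self.p0_mw <= 0 or self.v0_v <= 0:
            raise ValueError("p0_mw and v0_v must be > 0")

    def normalized(self) -> "PockelsParams":
        """Return an equivalent parameter set with phase in [0, π)."""
        return PockelsParams(self.p0_mw, self.v0_v, self.phase_rad % math.pi)


@dataclass(frozen=True)
class DispersionParams:
    """Parameters of the GDD-scan response.

    i0: peak fluorescence (a.u.); phi0_fs2: intrinsic system dispersion
    (fs²) — the peak sits at applied compensation φ = −φ0; delta_tau_fs:
    transform-limited pulse FWHM (fs).
    """

    i0: float
    phi0_fs2: float
    delta_tau_fs: float

    def __post_init__(self) -> None:
        if self.i0 <= 0 or self.delta_tau_fs <= 0:
            raise ValueError("i0 and delta_tau_fs must be > 0")


@dataclass(frozen=True)
class ScanSeries:
    """A measured abscissa/ordinate scan (volts→mW or fs²→a.u.)."""

    abscissa: np.ndarray
    ordinate: np.ndarray
    units: tuple[str, str] = ("", "")

    def __post_init__(self) -> None:
        object.__setattr__(self, "abscissa", np.asarray(self.abscissa, dtype=float))
        object.__setattr__(self, "ordinate", np.asarray(self.ordinate, dtype=float))
        if self.abscissa.shape != self.ordinate.shape or self.abscissa.ndim != 1:
            raise ValueError("abscissa and ordinate must be equal-length 1-D arrays")
        if not (np.isfinite(self.abscissa).all() and np.isfinite(self.ordinate).all()):
            raise ValueError("scan contains non-finite values")

    def __len__(self) -> int:
        return self.abscissa.size


@dataclass(frozen=True)
class FitResult:
    """A fitted model with per-parameter uncertainty and diagnostics."""

    params: PockelsParams | DispersionParams
    stderr: dict[str, float]
    rss: float
    n_points: int
    flags: tuple[str, ...] = ()
    bootstrap_stderr: dict[str, float] | None = None
    covariance: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if self.rss < 0:
            raise ValueError("rss must be >= 0")
        if any(v < 0 for v in self.stderr.values()):
            raise ValueError("stderr must be >= 0")


# ---------------------------------------------------------------------------
# forward models


def pockels_transmission(v, params: PockelsParams):
    """Transmitted power P0·sin(2πV/V0 + ϕ)² at control voltage ``v`` (V)."""
    v = np.asarray(v, dtype=float)
    return params.p0_mw * np.sin(2.0 * np.pi * v / params.v0_v + params.phase_rad) ** 2


def dispersion_fluorescence(phi, params: DispersionParams):
    """Fluorescence I0·(1 + α(φ+φ0)²/Δτ⁴)^(−1/2) at applied GDD ``phi`` (fs²)."""
    phi = np.asarray(phi, dtype=float)
    x = phi + params.phi0_fs2
    return params.i0 / np.sqrt(1.0 + ALPHA * x**2 / params.delta_tau_fs**4)


def broadened_pulse_width(delta_tau0_fs: float, gdd_fs2: float) -> float:
    """FWHM of a Gaussian pulse of width Δτ0 after acquiring GDD φ (fs²).

    Δτ(φ) = Δτ0·√(1 + (4·ln2·φ/Δτ0²)²); since (4·ln2)² = α, the inverse
    1/Δτ(φ) traces the same Lorentzian-like curve as the GDD-scan response.
    """
    if delta_tau0_fs <= 0:
        raise ValueError("delta_tau0_fs must be > 0")
    x = 4.0 * math.log(2.0) * gdd_fs2 / delta_tau0_fs**2
    return delta_tau0_fs * math.sqrt(1.0 + x * x)


# ---------------------------------------------------------------------------
# fitting helpers


def _check_scan(scan: ScanSeries, n_params: int) -> None:
    if len(scan) < n_params + 2:
        raise ValueError(
            f"scan has {len(scan)} points; need at least {n_params + 2} to fit "
            f"{n_params} parameters"
        )
    if np.ptp(scan.ordinate) == 0:
        raise DegenerateScanError("ordinate is constant; nothing to fit")


def _stderr_from_cov(pcov: np.ndarray, names: tuple[str, ...]) -> dict[str, float]:
    diag = np.diag(pcov)
    return {
        name: float(np.sqrt(d)) if np.isfinite(d) and d >= 0 else float("nan")
        for name, d in zip(names, diag)
    }


def _bootstrap(model, x, y, popt, n_boot: int, seed: int, bounds) -> np.ndarray:
    """Residual bootstrap: refit model on resampled residuals; returns sd per param."""
    rng = np.random.default_rng(seed)
    fitted = model(x, *popt)
    resid = y - fitted
    draws = []
    for _ in range(n_boot):
        y_star = fitted + rng.choice(resid, size=resid.size, replace=True)
        try:
            p_star, _ = optimize.curve_fit(
                model, x, y_star, p0=popt, bounds=bounds, maxfev=10000
            )
            draws.append(p_star)
        except RuntimeError:  # a resample may fail to converge; skip it
            continue
    if not draws:
        return np.full(len(popt), np.nan)
    return np.std(np.asarray(draws), axis=0, ddof=1)


# ---------------------------------------------------------------------------
# Pockels fit


def _pockels_model(v, p0, v0, phase):
    return p0 * np.sin(2.0 * np.pi * v / v0 + phase) ** 2


def _init_pockels(v: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """Documented initializer: amplitude from the max; period from the
    min→max distance of a smoothed scan, with a coarse (V0, ϕ) grid-search
    fallback; phase by 1-D grid search at 64 points."""
    p0 = float(np.max(y))
    span = float(np.ptp(v))
    y_smooth = gaussian_filter1d(y, sigma=max(1.0, len(y) / 50.0))
    v_min = v[int(np.argmin(y_smooth))]
    v_max = v[int(np.argmax(y_smooth))]
    v0 = 4.0 * abs(v_max - v_min)  # min→max is a quarter period of sin²... of P(V)

    candidates = [v0] if v0 > 0 else []
    candidates += list(np.linspace(span / 2.0, 4.0 * span, 12))
    phases = np.linspace(0.0, math.pi, 64, endpoint=False)
    best = (math.inf, span, 0.0)
    for v0_c in candidates:
        if v0_c <= 0:
            continue
        for ph in phases:
            sse = float(np.sum((y - _pockels_model(v, p0, v0_c, ph)) ** 2))
            if sse < best[0]:
                best = (sse, v0_c, ph)
    return p0, best[1], best[2]


def fit_pockels(
    scan: ScanSeries, n_bootstrap: int = 0, seed: int = 0
) -> FitResult:
    """Least-squares fit of the sin² transmission curve to a voltage scan.

    Requires at least 5 points spanning roughly half a period. Raises
    :class:`DegenerateScanError` on a constant ordinate and
    :class:`FitConvergenceError` if the optimizer does not converge.
    """
    _check_scan(scan, 3)
    v, y = scan.abscissa, scan.ordinate
    p0_init = _init_pockels(v, y)
    init_sse = float(np.sum((y - _pockels_model(v, *p0_init)) ** 2))
    bounds = ([0.0, 0.0, -2.0 * math.pi], [np.inf, np.inf, 2.0 * math.pi])
    try:
        popt, pcov = optimize.curve_fit(
            _pockels_model, v, y, p0=p0_init, bounds=bounds, maxfev=20000
        )
    except RuntimeError as exc:
        raise FitConvergenceError(f"Pockels fit did not converge: {exc}") from exc
    rss = float(np.sum((y - _pockels_model(v, *popt)) ** 2))
    if rss > init_sse * (1.0 + 1e-9):  # optimizer must not worsen the start
        raise FitConvergenceError("fit ended worse than its initialization")
    params = PockelsParams(float(popt[0]), float(popt[1]), float(popt[2])).normalized()
    names = ("p0_mw", "v0_v", "phase_rad")
    boot = None
    if n_bootstrap > 0:
        sds = _bootstrap(_pockels_model, v, y, popt, n_bootstrap, seed, bounds)
        boot = dict(zip(names, map(float, sds)))
    return FitResult(
        params=params,
        stderr=_stderr_from_cov(pcov, names),
        rss=rss,
        n_points=len(scan),
        bootstrap_stderr=boot,
        covariance=pcov,
    )


# ---------------------------------------------------------------------------
# dispersion fit


def _dispersion_model(phi, i0, phi0, dtau):
    return i0 / np.sqrt(1.0 + ALPHA * (phi + phi0) ** 2 / dtau**4)


def _init_dispersion(phi: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """Documented initializer: I0 from the max; φ0 from −argmax; Δτ from the
    observed half-max half-width via Δτ = (α·x_half²/3)^(1/4)."""
    i_peak = int(np.argmax(y))
    i0 = float(y[i_peak])
    phi0 = -float(phi[i_peak])
    half = i0 / 2.0
    # nearest abscissa where the ordinate first drops below half max
    below = np.nonzero(y < half)[0]
    if below.size:
        x_half = float(np.min(np.abs(phi[below] + phi0)))
    else:  # scan never reaches half max; fall back to the scan half-span
        x_half = float(np.ptp(phi)) / 2.0
    x_half = max(x_half, float(np.ptp(phi)) / max(len(phi) - 1, 1))
    dtau = (ALPHA * x_half**2 / 3.0) ** 0.25
    return i0, phi0, dtau


def fit_dispersion_scan(
    scan: ScanSeries, n_bootstrap: int = 0, seed: int = 0
) -> FitResult:
    """Least-squares fit of the GDD-scan response; Δτ is reported as FWHM in fs.

    The scan should bracket its maximum; a peak at either end is flagged
    (``"peak_at_boundary"``) with a warning, since φ0 is then an extrapolation.
    """
    _check_scan(scan, 3)
    phi, y = scan.abscissa, scan.ordinate
    order = np.argsort(phi)
    phi, y = phi[order], y[order]
    flags: list[str] = []
    if int(np.argmax(y)) in (0, len(y) - 1):
        warnings.warn(
            "dispersion scan peak at boundary; fitted phi0 is an extrapolation",
            stacklevel=2,
        )
        flags.append("peak_at_boundary")
    init = _init_dispersion(phi, y)
    bounds = ([0.0, -np.inf, 1e-6], [np.inf, np.inf, np.inf])
    try:
        popt, pcov = optimize.curve_fit(
            _dispersion_model, phi, y, p0=init, bounds=bounds, maxfev=20000
        )
    except RuntimeError as exc:
        raise FitConvergenceError(f"dispersion fit did not converge: {exc}") from exc
    rss = float(np.sum((y - _dispersion_model(phi, *popt)) ** 2))
    params = DispersionParams(float(popt[0]), float(popt[1]), float(popt[2]))
    names = ("i0", "phi0_fs2", "delta_tau_fs")
    boot = None
    if n_bootstrap > 0:
        sds = _bootstrap(_dispersion_model, phi, y, popt, n_bootstrap, seed, bounds)
        boot = dict(zip(names, map(float, sds)))
    return FitResult(
        params=params,
        stderr=_stderr_from_cov(pcov, names),
        rss=rss,
        n_points=len(scan),
        flags=tuple(flags),
        bootstrap_stderr=boot,
        covariance=pcov,
    )
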