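"""Rocking-scan reduction: mosaicity, peak integration, lattice indexing,
and full-hydration extrapolation of the D-spacing."""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit


@dataclass
class RockingFit:
    """Gauss+Lorentz mosaic fit of a rocking curve (angles in degrees)."""

    center: float
    sigma_gauss: float
    gamma_lorentz: float
    amp_gauss: float
    amp_lorentz: float
    background: float
    ok: bool
    message: str = ""
    covariance: np.ndarray | None = None


def _gauss_lorentz(omega, center, sigma_g, gamma_l, amp_g, amp_l, bg):
    g = amp_g * np.exp(-((omega - center) ** 2) / (2.0 * sigma_g**2))
    l = amp_l * gamma_l**2 / ((omega - center) ** 2 + gamma_l**2)
    return g + l + bg


def fit_rocking_curve(omega: np.ndarray, counts: np.ndarray,
                      monitor: float | None = None) -> RockingFit:
    """Fit a Gauss+Lorentz peak with constant background to a rocking scan.

    The narrow Gaussian width σ_G quantifies the mosaic spread of the
    aligned multilayers; the Lorentzian catches the diffuse tails. A scan
    with no significant peak is returned flagged (``ok=False``), never
    silently.
    """
    omega = np.asarray(omega, dtype=float)
    counts = np.asarray(counts, dtype=float)
    if omega.size < 10:
        raise ValueError("need at least 10 scan points")
    if np.any(np.diff(omega) <= 0):
        raise ValueError("omega must be strictly increasing")
    if np.any(counts < 0):
        raise ValueError("counts must be >= 0")
    if monitor:
        counts = counts / monitor

    bg0 = float(np.median(counts))
    amp0 = float(counts.max() - bg0)
    noise = float(np.std(counts - bg0))
    if amp0 <= 3.0 * max(noise, 1e-12) and amp0 <= 0.05 * max(bg0, 1e-12):
        return RockingFit(float(omega.mean()), 0.0, 0.0, 0.0, 0.0, bg0,
                          ok=False, message="no significant peak above background")
    c0 = float(omega[np.argmax(counts)])
    span = omega[-1] - omega[0]
    half = counts > bg0 + amp0 / 2
    fwhm0 = max(float(omega[half][-1] - omega[half][0]), span / 50) if half.any() else span / 10
    s0 = fwhm0 / 2.355
    p0 = [c0, s0, s0, 0.8 * amp0, 0.2 * amp0, bg0]
    try:
        popt, pcov = curve_fit(
            _gauss_lorentz, omega, counts, p0=p0,
            bounds=([omega[0], 1e-6, 1e-6, 0.0, 0.0, -np.inf],
                    [omega[-1], span, span, np.inf, np.inf, np.inf]),
            maxfev=20000)
    except RuntimeError as exc:
        return RockingFit(c0, s0, s0, amp0, 0.0, bg0, ok=False,
                          message=f"fit did not converge: {exc}")
    return RockingFit(center=float(popt[0]), sigma_gauss=float(popt[1]),
                      gamma_lorentz=float(popt[2]), amp_gauss=float(popt[3]),
                      amp_lorentz=float(popt[4]), background=float(popt[5]),
                      ok=True, covariance=pcov)


@dataclass
class PeakIntegral:
    intensity: float
    sigma: float
    center: float
    sigma_peak: float
    ok: bool
    message: str = ""


def _gauss_bg(x, center, sigma, amp, b0, b1):
    return amp * np.exp(-((x - center) ** 2) / (2.0 * sigma**2)) + b0 + b1 * (x - x.mean())


def integrate_peak(angle: np.ndarray, counts: np.ndarray,
                   monitor: float | None = None,
                   background: str = "linear") -> PeakIntegral:
    """Integrated intensity of one reflection by Gaussian-plus-background fit.

    I_h is the analytic Gaussian area amp·σ·√(2π) normalized to monitor
    counts when given; σ_I is propagated from the fit covariance. An
    amplitude consistent with zero yields intensity 0 with a flag.
    """
    if background not in ("constant", "linear"):
        raise ValueError("background must be 'constant' or 'linear'")
    x = np.asarray(angle, dtype=float)
    y = np.asarray(counts, dtype=float)
    if monitor:
        y = y / monitor
    bg0 = float(np.median(y))
    amp0 = float(y.max() - bg0)
    c0 = float(x[np.argmax(y)])
    span = float(x[-1] - x[0])
    half = y > bg0 + amp0 / 2
    fwhm0 = max(float(x[half][-1] - x[half][0]), span / 50) if half.any() else span / 10
    p0 = [c0, fwhm0 / 2.355, amp0, bg0, 0.0]
    fixed_slope = background == "constant"

    def model(x_, c, s, a, b0, b1):
        return _gauss_bg(x_, c, s, a, b0, 0.0 if fixed_slope else b1)

    try:
        popt, pcov = curve_fit(model, x, y, p0=p0, maxfev=20000,
                               bounds=([x[0], 1e-6, 0.0, -np.inf, -np.inf],
                                       [x[-1], span, np.inf, np.inf, np.inf]))
    except RuntimeError as exc:
        return PeakIntegral(0.0, math.inf, c0, 0.0, ok=False,
                            message=f"fit did not converge: {exc}")
    c, s, a = popt[0], popt[1], popt[2]
    var_a, var_s = pcov[2, 2], pcov[1, 1]
    cov_as = pcov[1, 2]
    area = a * s * math.sqrt(2.0 * math.pi)
    var_area = 2.0 * math.pi * (s**2 * var_a + a**2 * var_s + 2 * a * s * cov_as)
    sigma_area = math.sqrt(max(var_area, 0.0))
    floor = 1e-9 * max(float(np.max(np.abs(y))), 1.0)
    if a <= 2.0 * math.sqrt(max(var_a, 0.0)) or a < floor:
        return PeakIntegral(0.0, sigma_area, float(c), float(s), ok=False,
                            message="amplitude consistent with zero")
    return PeakIntegral(float(area), sigma_area, float(c), float(s), ok=True)


@dataclass
class LatticeFit:
    """Least-squares lamellar lattice constant from the Bragg equation."""

    D: float
    wavelength: float
    orders: np.ndarray
    residuals_deg: np.ndarray
    rms_deg: float
    relabeled: bool = False


def _fit_D(orders: np.ndarray, theta: np.ndarray, wavelength: float):
    # sin θ_h = h·λ/(2D): slope through the origin
    s = np.sin(theta)
    slope = float(np.dot(orders, s) / np.dot(orders, orders))
    D = wavelength / (2.0 * slope)
    pred = np.arcsin(np.clip(orders * wavelength / (2.0 * D), -1.0, 1.0))
    resid = np.degrees(theta - pred)
    return D, resid, float(np.sqrt(np.mean(resid**2)))


def index_and_fit_lattice(peaks: pd.DataFrame, wavelength: float,
                          rms_threshold_deg: float = 0.05,
                          max_start: int = 3) -> LatticeFit:
    """Lattice constant D from 2D·sinθ_h = hλ across all reflections.

    Uses the table's ``order_h`` labels when they satisfy the residual
    criterion; otherwise searches consecutive-integer labelings (starting at
    h = 1 upward — the lamellar first order is always present) and relabels
    if one passes. Residual RMS above threshold for all candidates raises an
    error naming the worst reflection.
    """
    if len(peaks) < 1:
        raise ValueError("need at least one reflection")
    theta = np.radians(np.asarray(peaks["two_theta_deg"], dtype=float) / 2.0)
    order = np.argsort(theta)
    theta = theta[order]
    n = len(theta)

    candidates = []
    if "order_h" in peaks.columns and peaks["order_h"].notna().all():
        given = np.asarray(peaks["order_h"], dtype=int)[order]
        candidates.append((given, False))
    for start in range(1, max_start + 1):
        candidates.append((np.arange(start, start + n), True))

    results = []
    for labels, relabeled in candidates:
        D, resid, rms = _fit_D(labels, theta, wavelength)
        results.append((rms, labels, D, resid, relabeled))
        if not relabeled and (rms <= rms_threshold_deg or n == 1):
            return LatticeFit(D, wavelength, labels, resid, rms, relabeled=False)
    rms, labels, D, resid, relabeled = min(results, key=lambda t: t[0])
    if rms > rms_threshold_deg and n > 1:
        worst = int(np.argmax(np.abs(resid)))
        raise ValueError(
            f"no consecutive order assignment fits the Bragg equation "
            f"(best RMS {rms:.4f}° > {rms_threshold_deg}°); worst reflection at "
            f"2θ = {math.degrees(2 * theta[worst]):.3f}°")
    if relabeled and n > 1:
        warnings.warn("input order labels inconsistent; reflections relabeled "
                      f"h = {labels[0]}..{labels[-1]}")
    return LatticeFit(D, wavelength, labels, resid, rms, relabeled=relabeled)


@dataclass
class HydrationFit:
    """Saturating-exponential extrapolation of D(t) to full hydration."""

    d_full: float
    ci95: float
    delta_d: float
    tau: float
    ok: bool
    message: str = ""


def extrapolate_full_hydration(times: np.ndarray, d_spacings: np.ndarray) -> HydrationFit:
    """Extrapolate the fully hydrated D-spacing from hydration kinetics.

    Fits D(t) = D_∞ − ΔD·exp(−t/τ) (ΔD may be negative for approach from
    above). A series that does not saturate within the observation window
    is flagged and the last value returned with a warning.
    """
    t = np.asarray(times, dtype=float)
    d = np.asarray(d_spacings, dtype=float)
    if t.size < 4:
        raise ValueError("need at least 4 time points")
    span = float(t[-1] - t[0])
    if np.ptp(d) < 1e-12:
        return HydrationFit(float(d[-1]), 0.0, 0.0, math.inf, ok=True,
                            message="constant series")

    def model(t_, d_inf, delta, tau):
        return d_inf - delta * np.exp(-t_ / tau)

    p0 = [float(d[-1]), float(d[-1] - d[0]), span / 3.0]
    try:
        popt, pcov = curve_fit(model, t, d, p0=p0, maxfev=20000,
                               bounds=([-np.inf, -np.inf, 1e-6],
                                       [np.inf, np.inf, 100.0 * span]))
    except RuntimeError:
        warnings.warn("hydration series did not fit a saturating exponential; "
                      "returning last observed D")
        return HydrationFit(float(d[-1]), math.nan, math.nan, math.nan, ok=False,
                            message="fit did not converge")
    d_inf, delta, tau = popt
    ci = 1.96 * math.sqrt(max(pcov[0, 0], 0.0))
    if tau > 2.0 * span:
        warnings.warn("hydration series is not saturating within the "
                      "observation window; returning last observed D")
        return HydrationFit(float(d[-1]), ci, float(delta), float(tau), ok=False,
                            message="non-saturating series")
    return HydrationFit(float(d_inf), ci, float(delta), float(tau), ok=True)
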