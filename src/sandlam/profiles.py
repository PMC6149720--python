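"""Fourier synthesis of NSLD profiles and extraction of D_HH, the water
distribution, and the Gibbs-surface bilayer thickness D_B.

The synthesis series for a centrosymmetric lamellar stack is

    ρ(z) = F0abs/D + (1/k)·(2/D)·Σ_{h=1}^{hmax} F_h·cos(2πhz/D)

with F0abs the forward-scattering value, k the absolute scale and F_h the
signed structure factors in relative units. Subtracting profiles measured
at different D2O/H2O contrasts isolates the water distribution; an
error-function fit to its flanks puts the Gibbs dividing surface at ±D_B/2.
"""

from __future__ import annotations

import itertools
import math
import warnings

import numpy as np
from scipy.optimize import curve_fit
from scipy.special import erf

from .models import ContrastSpec, NSLDProfile, StructureFactorSet, WaterProfile
from .synthetic import unit_cell_grid


def synthesize_profile(sf: StructureFactorSet, contrast_index: int,
                       grid_spacing: float = 0.5) -> NSLDProfile:
    """Evaluate the cosine synthesis series for one contrast of a set.

    The result is exactly even in z and its cell mean equals F0abs/D (the
    AC cosine terms average to zero over the period).
    """
    if sf.k is None or sf.f0abs is None:
        raise ValueError("structure-factor set must carry k and f0abs "
                         "(run absolute scaling first)")
    D = sf.D
    z = unit_cell_grid(D, grid_spacing)
    F = np.asarray(sf.F[contrast_index], dtype=float)
    h = np.arange(1, F.size + 1)
    series = F @ np.cos(2 * np.pi * np.outer(h, z) / D)
    series = 0.5 * (series + series[::-1])  # exact evenness to the last bit
    rho = sf.f0abs[contrast_index] / D + (2.0 / (sf.k * D)) * series
    return NSLDProfile(z=z, rho=rho, contrast=sf.contrasts[contrast_index],
                       D=D, hmax_used=F.size)


def _parabolic_peak(z: np.ndarray, y: np.ndarray, i: int) -> float:
    # 3-point parabolic interpolation through the discrete maximum
    if i == 0 or i == len(y) - 1:
        raise ValueError("maximum at grid boundary")
    denom = y[i - 1] - 2 * y[i] + y[i + 1]
    if denom == 0:
        return float(z[i])
    shift = 0.5 * (y[i - 1] - y[i + 1]) / denom
    return float(z[i] + shift * (z[i + 1] - z[i]))


def head_to_head(profile: NSLDProfile) -> float:
    """Head-to-head distance D_HH between the two headgroup maxima.

    Meaningful at the water-nulling contrast (~8% D2O), where the profile
    is a direct characteristic of the bilayer itself. Each maximum is
    located by 3-point parabolic interpolation; maxima at the cell boundary
    or absent (no interior peak away from z = 0) raise.
    """
    z, rho = profile.z, profile.rho
    peaks = []
    for side in (z > 0, z < 0):
        idx = np.flatnonzero(side)
        i_local = int(np.argmax(rho[idx]))
        i = idx[i_local]
        if i in (0, len(z) - 1):
            raise ValueError("headgroup maximum at grid boundary")
        if abs(z[i]) < 2 * profile.grid_spacing:
            raise ValueError("no headgroup maximum away from the bilayer center")
        peaks.append(_parabolic_peak(z, rho, i))
    return float(peaks[0] - peaks[1]) if peaks[0] > 0 else float(peaks[1] - peaks[0])


def water_distribution(profiles: list[NSLDProfile],
                       *,
                       plateau_frac: float = 0.1,
                       min_delta_nsld: float = 1e-3) -> WaterProfile:
    """Water distribution from pairwise NSLD-profile differences.

    For contrasts i, j: w(z) ≈ [ρ_i(z) − ρ_j(z)]/(ρ_w,i − ρ_w,j). Pairs
    with insufficient water-NSLD separation are skipped with a warning;
    the average over remaining pairs (weighted by Δρ_w²) is normalized so
    the interbilayer plateau (outer ``plateau_frac`` of the cell per side)
    equals 1. The normalization is truncation-consistent: the measured
    plateau mean is referenced to the plateau mean a unit error-function
    slab would show after the same Fourier truncation, so a finite number
    of orders does not bias the plateau towards its own ringing.
    """
    if len(profiles) < 2:
        raise ValueError("need profiles at >= 2 contrasts")
    z = profiles[0].z
    D = profiles[0].D
    for p in profiles[1:]:
        if p.z.shape != z.shape or not np.allclose(p.z, z) or p.D != D:
            raise ValueError("profiles must share grid and lattice constant")
    acc = np.zeros_like(z)
    wsum = 0.0
    for a, b in itertools.combinations(profiles, 2):
        d_nsld = a.contrast.water_nsld - b.contrast.water_nsld
        if abs(d_nsld) < min_delta_nsld:
            warnings.warn(
                f"contrasts {a.contrast.d2o_fraction} and {b.contrast.d2o_fraction} "
                "too close in water NSLD; pair skipped")
            continue
        acc += d_nsld**2 * ((a.rho - b.rho) / d_nsld)
        wsum += d_nsld**2
    if wsum == 0.0:
        raise ValueError("no usable contrast pair (water-NSLD differences too small)")
    w = acc / wsum
    plateau = np.abs(z) > (0.5 - plateau_frac) * D
    level = float(w[plateau].mean())
    if abs(level) < 1e-12:
        raise ValueError("water plateau level is zero; cannot normalize")
    w = w / level
    hmax = min((p.hmax_used for p in profiles if p.hmax_used), default=None)
    if hmax is not None:
        # reference the plateau to a unit erf slab truncated at the same hmax
        try:
            popt, _ = curve_fit(_erf_step, z[z >= 0], w[z >= 0],
                                p0=[0.35 * D, 2.0], maxfev=10000)
            z0, width = float(popt[0]), abs(float(popt[1]))
            h = np.arange(1, hmax + 1, dtype=float)
            coeffs = (-(D / (np.pi * h)) * np.sin(2 * np.pi * h * z0 / D)
                      * np.exp(-2.0 * (np.pi * h * width / D) ** 2))
            slab_mean = (D - 2.0 * z0) / D
            slab = slab_mean + (2.0 / D) * (
                coeffs @ np.cos(2 * np.pi * np.outer(h, z[plateau]) / D))
            ref = float(slab.mean())
            if 0.5 < ref < 1.5:
                w = w * ref
        except RuntimeError:
            pass
    return WaterProfile(z=z, water_probability=w, D=D)


def _erf_step(z, midpoint, width):
    return 0.5 * (1.0 + erf((z - midpoint) / (math.sqrt(2.0) * width)))


def gibbs_interface(water: WaterProfile) -> WaterProfile:
    """Locate the water/bilayer interface; fills the fit fields in place.

    Primary estimator: per-side error-function fit of w(z), midpoints
    averaged; D_B = 2·midpoint. The mean-position (integral, Gibbs) estimator
    z_G = D/2 − ∫₀^{D/2} w dz is computed as a cross-check and used as
    fallback when the fit does not converge (flagged by a warning).
    """
    z, w, D = water.z, water.water_probability, water.D
    half = z >= 0
    z_h, w_h = z[half], w[half]
    integral = float(np.trapezoid(w_h, z_h))
    z_mean = D / 2.0 - integral
    midpoints, widths = [], []
    for zz, ww in ((z_h, w_h), (-z[z <= 0][::-1], w[z <= 0][::-1])):
        try:
            popt, _ = curve_fit(_erf_step, zz, ww, p0=[z_mean, 2.0], maxfev=10000)
            midpoints.append(float(popt[0]))
            widths.append(abs(float(popt[1])))
        except RuntimeError:
            pass
    if midpoints:
        water.interface_midpoint = float(np.mean(midpoints))
        water.interface_width = float(np.mean(widths))
    else:
        warnings.warn("error-function fit failed; falling back to the "
                      "mean-position (Gibbs integral) estimator")
        water.interface_midpoint = z_mean
        water.interface_width = math.nan
    return water


def bilayer_thickness(water: WaterProfile) -> float:
    """D_B = 2 × fitted interface midpoint (runs the fit if needed)."""
    if water.interface_midpoint is None:
        gibbs_interface(water)
    return 2.0 * water.interface_midpoint


def mean_position_thickness(water: WaterProfile) -> float:
    """Alternative D_B from the Gibbs integral estimator (no fit)."""
    z, w = water.z, water.water_probability
    half = z >= 0
    return 2.0 * (water.D / 2.0 - float(np.trapezoid(w[half], z[half])))


def water_layer(D: float, D_B: float) -> float:
    """Interlamellar water thickness D_W = D − D_B."""
    if D < D_B:
        raise ValueError(f"D = {D} < D_B = {D_B}")
    return D - D_B
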