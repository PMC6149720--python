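"""Intensity corrections, structure-factor magnitudes, contrast-variation
phasing and absolute scaling.

For a monochromatic beam on an aligned lamellar stack the integrated
intensity of order h relates to the structure factor as

    ±|F_h| = ±( I_h / (L_f · A_c · F_c) )^(1/2)

with the Lorentz factor L_f = 1/sin 2θ_h, the slab absorption factor
A_c = [sin θ/(2μt)]·[1 − exp(−2μt/sin θ)] and the finite-sample flux
correction F_c = erf(l·sin θ/(8σ)) (2σ = beam width). For a centrosymmetric
bilayer the phases reduce to signs, fixed here by the linearity of the
signed F_h in the water scattering density across D2O/H2O contrasts.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import erf

from .models import CompositionConfig, ContrastSpec, InstrumentConfig

_SERIES_THRESHOLD = 1e-4  # switch A_c to its Taylor branch below this 2μt/sinθ


def lorentz_factor(theta: float) -> float:
    """Lorentz factor 1/sin(2θ) for θ in radians, θ ∈ (0, π/2)."""
    if not 0.0 < theta < math.pi / 2:
        raise ValueError("theta must be in (0, 90°) exclusive")
    return 1.0 / math.sin(2.0 * theta)


def absorption_factor(theta: float, mu: float, t: float) -> float:
    """Slab absorption factor A_c ∈ (0, 1]; μ in 1/cm, t in cm, θ in rad.

    A_c = (1 − e^−x)/x with x = 2μt/sin θ; evaluated by a Taylor series for
    small x so the μ → 0 limit is exact to better than 1e-8 relative.
    """
    if mu < 0 or t <= 0:
        raise ValueError("mu must be >= 0 and t > 0")
    if not 0.0 < theta <= math.pi / 2:
        raise ValueError("theta must be in (0, 90°]")
    x = 2.0 * mu * t / math.sin(theta)
    if x < _SERIES_THRESHOLD:
        return 1.0 - x / 2.0 + x * x / 6.0
    return (1.0 - math.exp(-x)) / x


def flux_factor(theta: float, l: float, sigma: float,
                beam_denominator: str = "8sigma") -> float:
    """Flux correction F_c = erf(l·sinθ / (8σ)) for l, σ in mm, θ in rad.

    ``beam_denominator='sqrt8_sigma'`` substitutes √8·σ for 8σ (the Gaussian
    beam convention); the printed 8σ form is the default.
    """
    if l <= 0 or sigma <= 0:
        raise ValueError("l and sigma must be positive")
    if beam_denominator == "8sigma":
        denom = 8.0 * sigma
    elif beam_denominator == "sqrt8_sigma":
        denom = math.sqrt(8.0) * sigma
    else:
        raise ValueError("beam_denominator must be '8sigma' or 'sqrt8_sigma'")
    return float(erf(l * math.sin(theta) / denom))


def structure_factor_magnitude(intensity: float, lf: float, ac: float, fc: float,
                               sigma_intensity: float = 0.0) -> tuple[float, float]:
    """|F_h| = √(I_h/(L_f·A_c·F_c)) with first-order error propagation.

    Returns (|F|, σ_F); σ_F is infinite for a zero intensity (degenerate
    relative uncertainty).
    """
    if intensity < 0:
        raise ValueError("intensity must be >= 0")
    if lf <= 0 or ac <= 0 or fc <= 0:
        raise ValueError("correction factors must be positive")
    corr = lf * ac * fc
    f = math.sqrt(intensity / corr)
    if f == 0.0:
        return 0.0, math.inf
    return f, sigma_intensity / (2.0 * f * corr)


def forward_scattering(composition: CompositionConfig, area: float,
                       contrast: ContrastSpec) -> float:
    """Forward-scattering value F0abs = (b_cell − ρ_w·V_cell)/A.

    ``b_cell``/``V_cell`` are the unit-cell totals (lipid plus the alcohol
    at mole ratio x; reduces to the single-lipid relation A·F0abs =
    b_l − ρ_w·V_l at x = 0). Units: ρ_w in 10⁻⁶ Å⁻², b in fm (converted via
    10·b), so F0abs is in 10⁻⁶ Å⁻¹ and F0abs/D is the NSLD profile offset.
    """
    if area <= 0:
        raise ValueError("area must be positive")
    return (10.0 * composition.b_total - contrast.water_nsld * composition.v_total) / area


# ---------------------------------------------------------------------------
# sign assignment by contrast variation
# ---------------------------------------------------------------------------

@dataclass
class SignAssignment:
    """Result of contrast-variation phasing.

    ``signs`` has shape (n_contrasts, hmax): the sign of F_h at every
    contrast (a signed F_h may legitimately cross zero between contrasts).
    ``slopes``/``intercepts`` are the per-order linear fits of signed F_h
    against the water NSLD. Orders whose fits are degenerate or ambiguous
    are listed in the flag fields rather than silently resolved.
    """

    signs: np.ndarray
    slopes: np.ndarray
    intercepts: np.ndarray
    residuals: np.ndarray
    indeterminate_orders: list[int] = field(default_factory=list)
    ambiguous_orders: list[int] = field(default_factory=list)
    low_leverage_orders: list[int] = field(default_factory=list)
    alternatives: dict[int, np.ndarray] = field(default_factory=dict)

    def signed(self, magnitudes: np.ndarray) -> np.ndarray:
        return self.signs * magnitudes


def _line_fit(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    A = np.column_stack([x, np.ones_like(x)])
    coef, *_ = np.linalg.lstsq(A, y, rcond=None)
    resid = float(np.sum((y - A @ coef) ** 2))
    return float(coef[0]), float(coef[1]), resid


def assign_signs(magnitudes: np.ndarray,
                 water_nslds: np.ndarray,
                 D: float,
                 *,
                 f0abs: np.ndarray | None = None,
                 plateau_frac: float = 0.1,
                 ambiguity_ratio: float = 1.5,
                 leverage_frac: float = 1e-3) -> SignAssignment:
    """Assign structure-factor signs from multi-contrast magnitudes.

    ``magnitudes``: (n_contrasts, hmax) array of |F_h| ordered like
    ``water_nslds``. For each order the relative signs across contrasts are
    chosen by exhaustive search for the pattern making signed F_h most
    linear in the water NSLD (F_h is exactly affine in ρ_w for a rigid
    bilayer). The remaining per-order overall flips are chosen
    exhaustively (≤ 2^hmax candidates) so that the slope vector dF_h/dρ_w —
    k times the Fourier coefficients of the water distribution — is best
    explained by an edge-localized error-function water slab; a positive
    slab amplitude (more water at the edge than the bilayer center) anchors
    the global sign, which also makes the headgroup maxima positive at the
    water-nulling contrast.

    When the per-contrast forward-scattering values ``f0abs`` are supplied,
    the Gibbs identity ∫w dz = ΔF0abs/Δρ_w pins the slab midpoint and the
    template search is confined to its neighbourhood; this breaks the
    midpoint/sign-pattern degeneracy of the slab family and is strongly
    recommended (the pipeline always passes it).
    """
    m = np.asarray(magnitudes, dtype=float)
    x = np.asarray(water_nslds, dtype=float)
    if m.ndim != 2 or m.shape[0] != x.size:
        raise ValueError("magnitudes must be (n_contrasts, hmax) matching water_nslds")
    nc, hmax = m.shape
    if nc < 2:
        raise ValueError("need magnitudes at >= 2 contrasts")

    scale = float(np.max(m)) or 1.0
    signs = np.ones((nc, hmax))
    slopes = np.zeros(hmax)
    intercepts = np.zeros(hmax)
    residuals = np.zeros(hmax)
    indeterminate, ambiguous, alternatives = [], [], {}

    for j in range(hmax):
        col = m[:, j]
        if np.all(col < 1e-12 * scale):
            indeterminate.append(j + 1)
            continue
        best = []
        for pat in itertools.product([1.0, -1.0], repeat=nc - 1):
            sig = np.concatenate([[1.0], pat])
            slope, icpt, resid = _line_fit(x, sig * col)
            best.append((resid, sig, slope, icpt))
        best.sort(key=lambda t: (t[0], tuple(t[1])))
        resid0, sig0, slope0, icpt0 = best[0]
        # runner-up with a genuinely different pattern (global flip is not
        # enumerated here, so any difference is a real alternative)
        for resid1, sig1, *_ in best[1:]:
            if not np.array_equal(sig1, sig0):
                if resid1 <= max(ambiguity_ratio * resid0, 1e-20 * scale**2):
                    ambiguous.append(j + 1)
                    alternatives[j + 1] = sig1
                break
        signs[:, j] = sig0
        slopes[j] = slope0
        intercepts[j] = icpt0
        residuals[j] = resid0

    # per-order flips: the slope vector dF_h/dρ_w is k times the cosine
    # coefficients of the water distribution, an edge-localized slab. Fit
    # every flip candidate against the analytic coefficients of an
    # error-function slab (grid over midpoint and width, closed-form
    # amplitude) and keep the candidate a slab explains best; a positive
    # slab amplitude (more water at the edge than the center) fixes the
    # global sign.
    max_slope = float(np.max(np.abs(slopes))) or 1.0
    low_leverage = [j + 1 for j in range(hmax)
                    if abs(slopes[j]) <= leverage_frac * max_slope
                    and (j + 1) not in indeterminate]
    active = [j for j in range(hmax) if (j + 1) not in indeterminate]

    h_idx = np.arange(1, hmax + 1, dtype=float)
    if f0abs is not None:
        f0 = np.asarray(f0abs, dtype=float)
        num = den = 0.0
        for i in range(nc):
            for j in range(i + 1, nc):
                dx = x[i] - x[j]
                if abs(dx) < 1e-3:
                    continue
                num += dx * dx * (f0[i] - f0[j]) / dx
                den += dx * dx
        if den > 0:
            z0_est = (D - num / den) / 2.0
            z0_est = min(max(z0_est, 0.05 * D), 0.49 * D)
            z0_grid = np.linspace(max(z0_est - 2.0, 0.05 * D),
                                  min(z0_est + 2.0, 0.49 * D), 81)
        else:
            z0_grid = np.linspace(0.05 * D, 0.49 * D, 240)
    else:
        z0_grid = np.linspace(0.05 * D, 0.49 * D, 240)
    sigma_grid = np.arange(0.25, 4.01, 0.25)
    templates = np.array([_erf_water_coefficients(h_idx, D, z0, s)
                          for z0 in z0_grid for s in sigma_grid])  # (n_templ, h)
    templ_norm2 = np.einsum("ij,ij->i", templates, templates)
    valid = templ_norm2 > 1e-12
    templates, templ_norm2 = templates[valid], templ_norm2[valid]

    from scipy.optimize import least_squares

    z0_lo, z0_hi = float(z0_grid[0]), float(z0_grid[-1])
    params = np.array([(z0, s) for z0 in z0_grid for s in sigma_grid])[valid]

    def slab_fit(slope_vec):
        # coarse grid (closed-form amplitude) then continuous refinement of
        # (amplitude, midpoint, width); the refinement matters because the
        # grid's residual floor can exceed the leverage of weak orders
        ss = float(slope_vec @ slope_vec)
        proj = templates @ slope_vec
        gain = proj**2 / templ_norm2
        best = int(np.argmax(gain))
        z0_0, s_0 = params[best]
        k_0 = float(proj[best] / templ_norm2[best])

        def resid(p):
            return p[0] * _erf_water_coefficients(h_idx, D, p[1], p[2]) - slope_vec

        try:
            sol = least_squares(resid, [k_0, z0_0, s_0],
                                bounds=([-np.inf, z0_lo, 0.05],
                                        [np.inf, z0_hi, 6.0]))
            return float(2.0 * sol.cost), float(sol.x[0])
        except Exception:
            return ss - float(gain[best]), float(proj[best])

    flips = np.ones(hmax)
    if active and np.any(slopes != 0.0):
        if len(active) <= 8:
            best_ssr, best_flips, best_proj = math.inf, np.ones(hmax), 1.0
            for pat in itertools.product([1.0, -1.0], repeat=max(len(active) - 1, 0)):
                f = np.ones(hmax)
                f[active[1:]] = pat
                ssr, proj = slab_fit(f * slopes)
                if ssr < best_ssr:
                    best_ssr, best_flips, best_proj = ssr, f, proj
            flips = best_flips
            proj = best_proj
        else:
            # deep series: greedy order-by-order refinement from the
            # all-positive start (lamellar data rarely exceed 8 orders)
            ssr, proj = slab_fit(flips * slopes)
            for j in active:
                trial = flips.copy()
                trial[j] *= -1.0
                t_ssr, t_proj = slab_fit(trial * slopes)
                if t_ssr < ssr:
                    flips, ssr, proj = trial, t_ssr, t_proj
        if proj < 0:  # slab amplitude k must be positive: global flip
            flips = -flips
    signs *= flips
    slopes *= flips
    intercepts *= flips
    for j1 in indeterminate:
        signs[:, j1 - 1] = 1.0

    return SignAssignment(signs=signs, slopes=slopes, intercepts=intercepts,
                          residuals=residuals,
                          indeterminate_orders=indeterminate,
                          ambiguous_orders=ambiguous,
                          low_leverage_orders=low_leverage,
                          alternatives=alternatives)


def _erf_water_coefficients(h: np.ndarray, D: float, z0: float, sigma: float) -> np.ndarray:
    # cosine coefficients of an error-function water slab: a sharp step at
    # ±z0 convolved with a Gaussian of width sigma
    return (-(D / (np.pi * h)) * np.sin(2 * np.pi * h * z0 / D)
            * np.exp(-2.0 * (np.pi * h * sigma / D) ** 2))


def absolute_scale(signed_F: np.ndarray,
                   water_nslds: np.ndarray,
                   f0abs: np.ndarray,
                   D: float,
                   *,
                   plateau_frac: float = 0.1,
                   min_delta_nsld: float = 1e-3,
                   method: str = "erf") -> float:
    """Absolute scaling factor k from the interbilayer water distribution.

    Between two contrasts the profile difference is Δρ(z) = ΔF0abs/D +
    (1/k)(2/D)Σ ΔF_h cos(2πhz/D) and must equal Δρ_w·w(z), a water
    distribution with unit interbilayer plateau. Two deterministic
    estimators:

    * ``method='plateau'``: k = ⟨(2/D)Σ ΔF_h cos⟩_plateau /
      (Δρ_w − ΔF0abs/D), averaged over contrast pairs weighted by Δρ_w²
      (slightly biased by series truncation on the plateau);
    * ``method='erf'`` (default): least-squares fit of the pair-averaged
      coefficients ΔF_h/Δρ_w = k·W_h(z0, σ_w) to the analytic Fourier
      coefficients of an error-function water slab — free of truncation
      bias. Initialized from the plateau estimate and the Gibbs identity
      ∫w dz = ΔF0abs/Δρ_w; falls back to the plateau estimate if the fit
      fails.
    """
    F = np.asarray(signed_F, dtype=float)
    x = np.asarray(water_nslds, dtype=float)
    f0 = np.asarray(f0abs, dtype=float)
    nc, hmax = F.shape
    if hmax < 2:
        raise ValueError("too few orders to identify the water plateau")
    if method not in ("erf", "plateau"):
        raise ValueError("method must be 'erf' or 'plateau'")

    z = np.linspace(-D / 2, D / 2, 1001)
    outer = np.abs(z) > (0.5 - plateau_frac) * D
    basis = np.cos(2 * np.pi * np.outer(np.arange(1, hmax + 1), z[outer]) / D)
    num = den = 0.0
    coeff_acc = np.zeros(hmax)
    water_integral_acc = 0.0
    n_pairs = 0
    for i in range(nc):
        for j in range(i + 1, nc):
            dx = x[i] - x[j]
            if abs(dx) < min_delta_nsld:
                continue
            target = dx - (f0[i] - f0[j]) / D
            s_plateau = float(((F[i] - F[j]) @ basis).mean()) * 2.0 / D
            w = dx * dx
            num += w * (s_plateau / target)
            den += w
            coeff_acc += w * (F[i] - F[j]) / dx
            water_integral_acc += w * (f0[i] - f0[j]) / dx
            n_pairs += 1
    if n_pairs == 0:
        raise ValueError("no contrast pair with sufficient water-NSLD leverage")
    k_plateau = num / den
    if method == "plateau" or hmax < 3:
        return k_plateau

    c = coeff_acc / den                       # ⟨ΔF_h/Δρ_w⟩ = k·W_h
    water_integral = water_integral_acc / den  # ∫w dz from the F0abs identity
    z0_init = max((D - water_integral) / 2.0, 0.05 * D)
    h = np.arange(1, hmax + 1, dtype=float)

    from scipy.optimize import curve_fit

    def model(h_, k, z0, sigma):
        return k * _erf_water_coefficients(h_, D, z0, sigma)

    try:
        popt, _ = curve_fit(model, h, c, p0=[k_plateau, z0_init, 2.0],
                            maxfev=20000)
    except RuntimeError:
        return k_plateau
    k_fit = float(popt[0])
    if k_fit <= 0 or not np.isfinite(k_fit):
        return k_plateau
    return k_fit


# ---------------------------------------------------------------------------
# table-level convenience
# ---------------------------------------------------------------------------

def magnitudes_from_table(table: pd.DataFrame,
                          instrument: InstrumentConfig) -> dict:
    """Reduce a multi-contrast peak table to |F_h| matrices.

    Returns dict with ``fractions``, ``water_nslds``, ``magnitudes`` and
    ``sigmas`` (n_contrasts × hmax, orders 1..hmax common to all contrasts),
    applying L_f, A_c and F_c at each reflection's measured angle.
    """
    fractions = sorted(table["contrast_d2o_fraction"].unique())
    common = None
    for frac in fractions:
        orders = set(table.loc[table["contrast_d2o_fraction"] == frac, "order_h"])
        common = orders if common is None else (common & orders)
    hmax = max(common)
    if set(range(1, hmax + 1)) - common:
        raise ValueError("orders 1..hmax must be present at every contrast")
    mags = np.zeros((len(fractions), hmax))
    sigs = np.zeros_like(mags)
    for i, frac in enumerate(fractions):
        sub = table[table["contrast_d2o_fraction"] == frac].set_index("order_h")
        mu = instrument.mu_for(frac)
        for h in range(1, hmax + 1):
            row = sub.loc[h]
            theta = math.radians(row["two_theta_deg"] / 2.0)
            lf = lorentz_factor(theta)
            ac = absorption_factor(theta, mu, instrument.sample_thickness_cm)
            fc = flux_factor(theta, instrument.sample_length_mm,
                             instrument.beam_sigma_mm, instrument.beam_denominator)
            mags[i, h - 1], sigs[i, h - 1] = structure_factor_magnitude(
                row["intensity"], lf, ac, fc, row["intensity_sigma"])
    return {
        "fractions": np.asarray(fractions),
        "water_nslds": np.array([ContrastSpec.from_d2o_fraction(f).water_nsld
                                 for f in fractions]),
        "magnitudes": mags,
        "sigmas": sigs,
    }
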