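"""Lateral and volumetric structural parameters derived from D_B.

The area per unit cell follows the Gibbs-interface volumetric identity:
the bilayer volume per unit cell (two lipids' worth per area A, i.e. one
lipid plus x alcohols per leaflet) exactly fills the slab of thickness D_B,
so A = 2(V_l + x·V_a)/D_B.
"""

from __future__ import annotations

from .models import BilayerStructure, VolumetricInputs
from .reduction import LatticeFit


def area_per_unit_cell(D_B: float, vol: VolumetricInputs) -> float:
    """A = 2·(V_lipid + x·V_alcohol)/D_B, Å² per unit cell.

    The unit cell comprises one lipid and ``x`` alcohol molecules (x = 0.3
    for the systems studied here); A·D_B = 2(V_l + x·V_a) holds exactly.
    """
    if D_B <= 0:
        raise ValueError("D_B must be positive")
    return 2.0 * (vol.v_lipid + vol.mole_ratio_x * vol.v_alcohol) / D_B


def interbilayer_waters(area: float, D_W: float, v_water: float) -> float:
    """Interlamellar water count per unit cell: n_W = A·D_W/(2·V_water).

    Half-slab convention: the water slab of thickness D_W is shared by the
    two adjacent bilayer surfaces, so each unit cell (one leaflet's lipid +
    alcohols) owns half the slab above it. Output headers must state this
    convention.
    """
    if area <= 0 or D_W < 0 or v_water <= 0:
        raise ValueError("area and v_water must be positive, D_W >= 0")
    return area * D_W / (2.0 * v_water)


def assemble_structure(lattice: LatticeFit | float,
                       D_B: float,
                       D_HH: float,
                       vol: VolumetricInputs,
                       tol: float = 1e-9) -> BilayerStructure:
    """Assemble and validate a per-sample structural record.

    Cross-identities checked at assembly: D = D_B + D_W (by construction),
    A·D_B = 2(V_l + x·V_a), and D_B ≤ D. Violations raise with the failing
    identity named.
    """
    D = lattice.D if isinstance(lattice, LatticeFit) else float(lattice)
    if D_B <= 0 or D_HH <= 0:
        raise ValueError("D_B and D_HH must be positive")
    if D_B > D:
        raise ValueError(f"identity violated: D_B = {D_B:.3f} > D = {D:.3f}")
    D_W = D - D_B
    A = area_per_unit_cell(D_B, vol)
    lhs = A * D_B
    rhs = 2.0 * (vol.v_lipid + vol.mole_ratio_x * vol.v_alcohol)
    if abs(lhs - rhs) > tol * rhs:
        raise ValueError(
            f"identity violated: A·D_B = {lhs:.6g} != 2(V_l + x·V_a) = {rhs:.6g}")
    n_w = interbilayer_waters(A, D_W, vol.v_water)
    return BilayerStructure(D=D, D_B=D_B, D_HH=D_HH, D_W=D_W, A=A, n_waters=n_w)
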