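"""Physical constants and literature-sourced molecular defaults.

Conventions used throughout the package:

* lengths in Å, thickness ``t`` in cm, sample length / beam widths in mm;
* coherent scattering lengths ``b`` in fm;
* molecular volumes ``V`` in Å³;
* neutron scattering length densities (NSLD) in 10⁻⁶ Å⁻², so that
  ``rho = 10 * b[fm] / V[Å³]``.

Bound coherent scattering lengths are the standard Sears tabulation.
Molecular volumes are literature-sourced defaults (group-contribution
estimates for the alcohols); every consumer of these values accepts
overrides, and output headers state the values used.
"""

from __future__ import annotations

# -- coherent scattering lengths, fm (Sears) ---------------------------------
B_H = -3.7390
B_D = 6.6710
B_C = 6.6460
B_N = 9.3600
B_O = 5.8030
B_P = 5.1300

B_H2O = 2.0 * B_H + B_O  # -1.675 fm
B_D2O = 2.0 * B_D + B_O  # 19.145 fm

#: molecular volume of water at 25 °C, Å³
V_WATER = 30.0

#: D2O mole fraction at which the water NSLD vanishes (~0.0804)
D2O_MATCH_FRACTION = -B_H2O / (B_D2O - B_H2O)

# -- lipid / alcohol defaults (literature-sourced, overridable) --------------

#: DOPC molecular volume in the fluid phase, Å³
V_DOPC = 1303.0

#: DOPC (C44H84NO8P) coherent scattering length, fm, from atomic values above
B_DOPC = 44 * B_C + 84 * B_H + B_N + 8 * B_O + B_P

# group-contribution volumes, Å³ (fluid alkyl chains at 25 °C)
V_CH2 = 26.9
V_CH3 = 54.3
V_OH = 13.0


def water_nsld(d2o_fraction: float, v_water: float = V_WATER) -> float:
    """NSLD of a D2O/H2O mixture, in 10⁻⁶ Å⁻².

    Linear in the D2O mole fraction; zero at :data:`D2O_MATCH_FRACTION`.
    """
    if not 0.0 <= d2o_fraction <= 1.0:
        raise ValueError(f"d2o_fraction must be in [0, 1], got {d2o_fraction}")
    b = d2o_fraction * B_D2O + (1.0 - d2o_fraction) * B_H2O
    return 10.0 * b / v_water


def alcohol_scattering_length(n_carbons: int) -> float:
    """Coherent scattering length of a linear alcohol CnH(2n+1)OH, fm."""
    if n_carbons < 1:
        raise ValueError("n_carbons must be >= 1")
    return n_carbons * B_C + (2 * n_carbons + 2) * B_H + B_O


def alcohol_volume(n_carbons: int) -> float:
    """Group-contribution molecular volume of CnOH, Å³ (fluid state)."""
    if n_carbons < 1:
        raise ValueError("n_carbons must be >= 1")
    return V_CH3 + (n_carbons - 1) * V_CH2 + V_OH
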