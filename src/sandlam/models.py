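"""Domain containers shared across the pipeline.

Tabular data (peak tables, rocking scans) travel as :class:`pandas.DataFrame`
with documented column names; everything else is a plain dataclass holding
numpy arrays. Angles are stored as 2θ in degrees at the I/O boundary and as
θ in radians internally.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import constants

# canonical peak-table columns (TSV dialect shared by the generator and the
# reduction stage)
PEAK_COLUMNS = [
    "contrast_d2o_fraction",
    "order_h",
    "two_theta_deg",
    "intensity",
    "intensity_sigma",
]

SCAN_COLUMNS = ["omega_deg", "counts", "monitor"]


@dataclass(frozen=True)
class ContrastSpec:
    """One D2O/H2O hydration contrast.

    ``water_nsld`` is in 10⁻⁶ Å⁻² and is strictly increasing in the D2O
    fraction; it vanishes at the contrast-match fraction (~8% D2O).
    """

    d2o_fraction: float
    water_nsld: float

    @classmethod
    def from_d2o_fraction(cls, d2o_fraction: float,
                          v_water: float = constants.V_WATER) -> "ContrastSpec":
        return cls(d2o_fraction, constants.water_nsld(d2o_fraction, v_water))


@dataclass(frozen=True)
class BilayerModel:
    """Parametric centrosymmetric fluid-bilayer NSLD model.

    The transbilayer profile is built from headgroup Gaussians at
    ``±headgroup_position``, a methyl-trough Gaussian at the center, a
    hydrocarbon plateau confined to the non-water region, and a
    complementary-error-function water profile whose midpoints sit at
    ``±interface_position`` (the Gibbs dividing surface, so the true
    bilayer thickness is ``D_B = 2·interface_position``).

    All NSLD amplitudes are in 10⁻⁶ Å⁻², all lengths in Å.
    """

    headgroup_position: float = 18.2
    headgroup_sigma: float = 3.0
    headgroup_amplitude: float = 2.2
    methyl_sigma: float = 3.0
    methyl_amplitude: float = -0.25
    interface_position: float = 19.5
    interface_width: float = 2.0
    lattice_D: float = 55.0
    chain_plateau: float = -0.35

    def __post_init__(self) -> None:
        for name in ("headgroup_sigma", "methyl_sigma", "interface_width",
                     "lattice_D"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not self.interface_position < self.lattice_D / 2:
            raise ValueError("interface_position must be < lattice_D/2")
        if not (self.headgroup_position
                < self.interface_position + 3 * self.interface_width):
            raise ValueError("headgroup must lie within the bilayer interface")


@dataclass(frozen=True)
class InstrumentConfig:
    """Diffractometer and sample geometry for the correction factors.

    ``mu`` may be a single linear absorption coefficient (1/cm) or a mapping
    from D2O fraction to μ — the coefficient depends on the D2O/H2O ratio in
    the interbilayer space.
    """

    wavelength: float = 4.5707          # Å
    sample_thickness_cm: float = 0.0005
    sample_length_mm: float = 65.0
    beam_sigma_mm: float = 1.25         # beam width = 2σ
    mu: float | Mapping[float, float] = 1.0
    beam_denominator: str = "8sigma"    # or "sqrt8_sigma"

    def __post_init__(self) -> None:
        for name in ("wavelength", "sample_thickness_cm", "sample_length_mm",
                     "beam_sigma_mm"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.beam_denominator not in ("8sigma", "sqrt8_sigma"):
            raise ValueError("beam_denominator must be '8sigma' or 'sqrt8_sigma'")

    def mu_for(self, d2o_fraction: float) -> float:
        if isinstance(self.mu, Mapping):
            try:
                return self.mu[d2o_fraction]
            except KeyError as exc:
                raise KeyError(
                    f"no absorption coefficient for contrast {d2o_fraction}"
                ) from exc
        return float(self.mu)


@dataclass(frozen=True)
class CompositionConfig:
    """Unit-cell composition: one lipid plus ``x`` alcohols.

    Scattering lengths in fm, volumes in Å³. Defaults are the DOPC + C12OH
    system at the 0.3 alcohol:lipid mole ratio.
    """

    b_lipid: float = constants.B_DOPC
    v_lipid: float = constants.V_DOPC
    b_alcohol: float = constants.alcohol_scattering_length(12)
    v_alcohol: float = constants.alcohol_volume(12)
    mole_ratio_x: float = 0.3
    v_water: float = constants.V_WATER

    def __post_init__(self) -> None:
        if self.v_lipid <= 0 or self.v_alcohol <= 0 or self.v_water <= 0:
            raise ValueError("volumes must be positive")
        if self.mole_ratio_x < 0:
            raise ValueError("mole_ratio_x must be >= 0")

    @property
    def b_total(self) -> float:
        return self.b_lipid + self.mole_ratio_x * self.b_alcohol

    @property
    def v_total(self) -> float:
        return self.v_lipid + self.mole_ratio_x * self.v_alcohol


@dataclass
class NSLDProfile:
    """ρ(z) on a uniform symmetric grid over one unit cell [−D/2, D/2]."""

    z: np.ndarray
    rho: np.ndarray
    contrast: ContrastSpec
    D: float
    hmax_used: int | None = None

    def __post_init__(self) -> None:
        self.z = np.asarray(self.z, dtype=float)
        self.rho = np.asarray(self.rho, dtype=float)
        if self.z.shape != self.rho.shape:
            raise ValueError("z and rho must have the same shape")

    @property
    def grid_spacing(self) -> float:
        return float(self.z[1] - self.z[0])

    @property
    def mean(self) -> float:
        """Cell average of ρ (trapezoid rule over the full period)."""
        return float(np.trapezoid(self.rho, self.z) / self.D)


@dataclass
class StructureFactorSet:
    """Signed structure factors for a contrast series sharing one lattice.

    ``F`` has shape (n_contrasts, hmax) in relative (count-derived) units;
    dividing by the absolute scale ``k`` puts them on the NSLD·Å scale of
    ``f0abs``.
    """

    D: float
    contrasts: Sequence[ContrastSpec]
    F: np.ndarray                      # (n_contrasts, hmax), signed, relative
    sigma_F: np.ndarray | None = None
    k: float | None = None
    f0abs: np.ndarray | None = None    # per contrast, absolute units
    diagnostics: dict = field(default_factory=dict)

    @property
    def hmax(self) -> int:
        return self.F.shape[1]

    @property
    def signs(self) -> np.ndarray:
        return np.where(self.F >= 0, 1, -1)


@dataclass
class WaterProfile:
    """Normalized transbilayer water probability from contrast differences."""

    z: np.ndarray
    water_probability: np.ndarray
    D: float
    interface_midpoint: float | None = None
    interface_width: float | None = None


@dataclass(frozen=True)
class VolumetricInputs:
    """Molecular volumes entering the lateral-area and water-count formulas."""

    v_lipid: float = constants.V_DOPC
    v_alcohol: float = constants.alcohol_volume(12)
    v_water: float = constants.V_WATER
    mole_ratio_x: float = 0.3

    def __post_init__(self) -> None:
        if min(self.v_lipid, self.v_alcohol, self.v_water) <= 0:
            raise ValueError("volumes must be positive")
        if self.mole_ratio_x < 0:
            raise ValueError("mole_ratio_x must be >= 0")


@dataclass
class BilayerStructure:
    """Per-sample structural scalars (all lengths Å, area Å²).

    Identities ``D = D_B + D_W`` and ``A·D_B = 2(V_l + x·V_a)`` are enforced
    at assembly. ``n_waters`` is the interlamellar water count per unit cell
    with the half-slab convention (one water slab shared by two bilayers).
    """

    D: float
    D_B: float
    D_HH: float
    D_W: float
    A: float
    n_waters: float


@dataclass
class ParticleFrame:
    """Labelled bead coordinates in an orthorhombic periodic box."""

    positions: np.ndarray          # (N, 3), Å
    labels: np.ndarray             # (N,), str
    resids: np.ndarray             # (N,), int
    box: np.ndarray                # (3,), Å

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.labels = np.asarray(self.labels)
        self.resids = np.asarray(self.resids, dtype=int)
        self.box = np.asarray(self.box, dtype=float)
        n = len(self.positions)
        if self.positions.ndim != 2 or self.positions.shape[1] != 3:
            raise ValueError("positions must be (N, 3)")
        if len(self.labels) != n or len(self.resids) != n:
            raise ValueError("labels/resids length mismatch")
        if self.box.shape != (3,) or np.any(self.box <= 0):
            raise ValueError("box must be 3 positive lengths")

    def select(self, labels) -> np.ndarray:
        """Boolean mask of beads whose label is in ``labels``."""
        wanted = {labels} if isinstance(labels, str) else set(labels)
        return np.isin(self.labels, sorted(wanted))


def validate_peak_table(df: pd.DataFrame) -> pd.DataFrame:
    """Check the canonical peak-table columns and basic invariants."""
    missing = [c for c in PEAK_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"peak table missing columns: {missing}")
    if (df["intensity"] < 0).any():
        raise ValueError("negative intensities in peak table")
    for frac, grp in df.groupby("contrast_d2o_fraction"):
        if grp["order_h"].duplicated().any():
            raise ValueError(f"duplicate orders at contrast {frac}")
    return df
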