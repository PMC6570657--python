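"""Membrane hydrodynamics and transducin-engagement stoichiometry.

The lateral mobility of a cylindrical inclusion of radius R in a membrane of
viscosity µ_m and thickness h, bathed in solvent of viscosity µ_w, follows
the Saffman–Delbrück relation

    D = kT / (4π µ_m h) · (ln(2/ε) − γ),   ε = 2 µ_w R / (µ_m h),

valid for small reduced radius ε. The Petrov–Schwille interpolation extends
it across all ε (large inclusions such as receptor clusters):

    D = kT / (4π µ_m h) · [ln(2/ε) − γ + 4ε/π − (ε²/2)·ln(2/ε)]
        / [1 − (ε³/π)·ln(2/ε) + c₁ε^{b₁}/(1 + c₂ε^{b₂})]

with c₁ = 0.73761, b₁ = 2.74819, c₂ = 0.52119, b₂ = 0.51465. The relation
is strictly decreasing in R, so a measured state diffusion coefficient maps
to a unique hydrodynamic radius by root finding.

The engagement model counts rhodopsin sequestered into slow Rh*₂–G_t
complexes: with one transducin per ``rhodopsins_per_gt`` rhodopsins and
``rhodopsins_per_complex`` rhodopsins per complex, the sequestered fraction
grows linearly with the photoisomerized fraction and saturates once every
transducin is engaged — at 20 % photoisomerization for the physiological
10:1 ratio and 2:1 complex.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

BOLTZMANN = 1.380649e-23  # J/K
EULER_GAMMA = 0.5772156649015329

_C1, _B1, _C2, _B2 = 0.73761, 2.74819, 0.52119, 0.51465

__all__ = [
    "SDParams",
    "StoichiometryParams",
    "sd_diffusion",
    "sd_diffusion_classical",
    "invert_sd",
    "gt_engagement",
    "saturation_isomerization",
    "poise_to_pa_s",
]


def poise_to_pa_s(viscosity_poise: float) -> float:
    """Convert a viscosity from Poise (CGS) to Pa·s (SI): 1 P = 0.1 Pa·s."""
    return 0.1 * viscosity_poise


@dataclass(frozen=True)
class SDParams:
    """Hydrodynamic parameters (SI units).

    Defaults: membrane viscosity 0.8 Pa·s (8 Poise), aqueous viscosity
    0.02 Pa·s (0.2 Poise), bilayer thickness 4 nm, T = 298 K. The solvent is
    assumed symmetric on both leaflets.
    """

    membrane_viscosity: float = 0.8
    aqueous_viscosity: float = 0.02
    membrane_thickness: float = 4e-9
    temperature: float = 298.0

    def __post_init__(self) -> None:
        for name in (
            "membrane_viscosity", "aqueous_viscosity",
            "membrane_thickness", "temperature",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.membrane_viscosity <= self.aqueous_viscosity:
            raise ValueError("membrane_viscosity must exceed aqueous_viscosity")

    def reduced_radius(self, radius_m: float) -> float:
        """ε = 2 µ_w R / (µ_m h), the reduced inclusion radius."""
        return (
            2.0 * self.aqueous_viscosity * radius_m
            / (self.membrane_viscosity * self.membrane_thickness)
        )

    @property
    def d_scale_um2_per_s(self) -> float:
        """kT/(4π µ_m h) in µm²/s."""
        return (
            BOLTZMANN * self.temperature
            / (4.0 * np.pi * self.membrane_viscosity * self.membrane_thickness)
        ) * 1e12


def sd_diffusion_classical(radius_m: float, params: SDParams | None = None) -> float:
    """Classical (small-ε) Saffman–Delbrück diffusion coefficient in µm²/s."""
    params = params or SDParams()
    if radius_m <= 0:
        raise ValueError("radius must be strictly positive")
    eps = params.reduced_radius(radius_m)
    return params.d_scale_um2_per_s * (np.log(2.0 / eps) - EULER_GAMMA)


def sd_diffusion(radius_m: float, params: SDParams | None = None) -> float:
    """Extended (Petrov–Schwille) Saffman–Delbrück coefficient in µm²/s.

    Valid for all inclusion radii; reduces to the classical logarithmic form
    as ε → 0 and is strictly decreasing in the radius.
    """
    params = params or SDParams()
    if radius_m <= 0:
        raise ValueError("radius must be strictly positive")
    eps = params.reduced_radius(radius_m)
    ln2e = np.log(2.0 / eps)
    num = ln2e - EULER_GAMMA + 4.0 * eps / np.pi - 0.5 * eps**2 * ln2e
    den = 1.0 - eps**3 / np.pi * ln2e + _C1 * eps**_B1 / (1.0 + _C2 * eps**_B2)
    return params.d_scale_um2_per_s * num / den


def invert_sd(
    d_um2_per_s: float,
    params: SDParams | None = None,
    radius_bracket: tuple[float, float] = (1e-10, 1e-5),
) -> float:
    """Hydrodynamic radius (m) whose extended-SD coefficient equals ``d``.

    Monotone root finding (Brent) to 1e-9 relative tolerance; raises if the
    requested coefficient lies outside the range attainable on the bracket.
    """
    params = params or SDParams()
    lo, hi = radius_bracket
    d_hi, d_lo = sd_diffusion(lo, params), sd_diffusion(hi, params)
    if not (d_lo < d_um2_per_s < d_hi):
        raise ValueError(
            f"D={d_um2_per_s} um^2/s outside attainable range "
            f"({d_lo:.3e}, {d_hi:.3e}) for radii in [{lo:.1e}, {hi:.1e}] m"
        )
    return brentq(
        lambda r: sd_diffusion(r, params) - d_um2_per_s, lo, hi,
        xtol=1e-18, rtol=1e-12, maxiter=200,
    )


@dataclass(frozen=True)
class StoichiometryParams:
    """Disc-membrane stoichiometry: rhodopsins per transducin (10:1) and
    rhodopsins per active complex (2:1 Rh*₂–G_t)."""

    rhodopsins_per_gt: float = 10.0
    rhodopsins_per_complex: int = 2

    def __post_init__(self) -> None:
        if self.rhodopsins_per_gt < 1 or self.rhodopsins_per_complex < 1:
            raise ValueError("stoichiometry ratios must be >= 1")


def gt_engagement(iso_fraction, stoich: StoichiometryParams | None = None):
    """Fraction of rhodopsin sequestered in Rh*₂–G_t complexes.

    Complex formation is transducin-limited: complexes per rhodopsin =
    min(1/rhodopsins_per_gt, iso_fraction/rhodopsins_per_complex); the
    sequestered fraction is rhodopsins_per_complex times that. Piecewise
    linear and saturating.
    """
    stoich = stoich or StoichiometryParams()
    iso = np.asarray(iso_fraction, dtype=float)
    if np.any((iso < 0) | (iso > 1)):
        raise ValueError("iso_fraction must lie in [0, 1]")
    complexes = np.minimum(
        1.0 / stoich.rhodopsins_per_gt, iso / stoich.rhodopsins_per_complex
    )
    out = stoich.rhodopsins_per_complex * complexes
    return float(out) if np.isscalar(iso_fraction) else out


def saturation_isomerization(stoich: StoichiometryParams | None = None) -> float:
    """Photoisomerized fraction at which transducin engagement saturates."""
    stoich = stoich or StoichiometryParams()
    return stoich.rhodopsins_per_complex / stoich.rhodopsins_per_gt
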