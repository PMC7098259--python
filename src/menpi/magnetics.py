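"""Nanoparticle magnetics: Langevin response, magnetoelectric shift, losses.

All magnetic quantities use CGS-Gaussian units (Oe, emu/cc, erg), matching the
conventions of the nanoparticle literature; electric fields enter in SI (V/m)
and are converted to V/cm only inside the magnetoelectric coupling.

Model summary
-------------
A superparamagnetic particle of moment ``m = M_S * V`` at temperature ``T``
has mean relative magnetization given by the Langevin function

    M_rel(H) = coth(xi) - 1/xi,   xi = m * H / (k_B * T).

A magnetoelectric nanoparticle (MEN) additionally shifts its magnetization
linearly with the local electric field through the isotropic ME coefficient
``alpha`` (G cm/V):

    dM = alpha * E[V/cm]     (emu/cc, using 1 G == 1 emu/cc),

so its relative magnetization is ``clip(L(xi) + dM / M_S, -1, 1)``.  A
conventional magnetic nanoparticle (MN) is the ``alpha = 0`` special case.
Hysteresis is ignored in the imaging response; the coercivity ``H_c`` enters
only the per-cycle dissipation estimate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np

from .errors import ConfigurationError, QuantumRegimeWarning

#: Boltzmann constant, erg/K (CGS).
K_B_ERG_PER_K = 1.38065e-16

#: 1 V/m = 0.01 V/cm.
_V_PER_M_TO_V_PER_CM = 1.0 / 100.0

_ERG_TO_J = 1.0e-7


@dataclass(frozen=True)
class ParticleSpec:
    """Physical description of one nanoparticle species.

    Parameters
    ----------
    diameter_nm : particle diameter (spherical), nm.
    m_s : saturation magnetization in ``m_s_unit`` (``"emu/cc"`` or ``"emu/g"``).
    alpha : isotropic magnetoelectric coefficient, G cm/V (0 for plain MNs).
    h_c : coercivity, Oe; used only for hysteresis-loss accounting.
    mass_density : material density, g/cc.
    temperature : microenvironment temperature, K.
    """

    diameter_nm: float = 50.0
    m_s: float = 10.0
    m_s_unit: str = "emu/cc"
    alpha: float = 0.1
    h_c: float = 100.0
    mass_density: float = 5.0
    temperature: float = 300.0

    def __post_init__(self) -> None:
        if self.diameter_nm <= 0:
            raise ConfigurationError("particle diameter must be positive")
        if self.m_s < 0 or self.alpha < 0 or self.h_c < 0:
            raise ConfigurationError("M_S, alpha and H_c must be non-negative")
        if self.temperature <= 0:
            raise ConfigurationError("temperature must be positive (K)")
        if self.mass_density <= 0:
            raise ConfigurationError("mass density must be positive (g/cc)")
        if self.m_s_unit not in ("emu/cc", "emu/g"):
            raise ConfigurationError(f"unknown M_S unit {self.m_s_unit!r}")

    @property
    def m_s_emu_cc(self) -> float:
        """Saturation magnetization in emu/cc regardless of the input unit."""
        if self.m_s_unit == "emu/cc":
            return self.m_s
        return self.m_s * self.mass_density

    @property
    def is_men(self) -> bool:
        return self.alpha > 0

    def as_mn(self) -> "ParticleSpec":
        """The magnetically equivalent conventional particle (alpha = 0)."""
        return replace(self, alpha=0.0)


#: Default 50-nm MEN: M_S = 10 emu/cc, alpha = 0.1 G cm/V, H_c = 100 Oe, 300 K.
MEN_DEFAULT = ParticleSpec()
#: Default 50-nm MN: M_S = 100 emu/cc, no ME coupling.
MN_DEFAULT = ParticleSpec(m_s=100.0, alpha=0.0)


@dataclass(frozen=True)
class MagnetizationState:
    """Relative magnetization and the ME-induced shift that produced it."""

    m_rel: float
    delta_m_emu_cc: float = 0.0

    def __post_init__(self) -> None:
        if abs(self.m_rel) > 1.0 + 1e-12:
            raise ValueError(f"|M_rel| must be <= 1, got {self.m_rel}")


def particle_volume_and_moment(spec: ParticleSpec) -> tuple[float, float]:
    """Sphere volume (cm^3) and saturation moment m = M_S * V (emu)."""
    d_cm = spec.diameter_nm * 1.0e-7
    volume = np.pi * d_cm**3 / 6.0
    return float(volume), float(spec.m_s_emu_cc * volume)


def langevin_mrel(h_oe, spec: ParticleSpec):
    """Langevin relative magnetization L(xi) = coth(xi) - 1/xi at field H (Oe).

    Vectorized over ``h_oe``; odd in H; numerically stable near zero via the
    series xi/3 - xi^3/45 for |xi| < 1e-3.
    """
    _, moment = particle_volume_and_moment(spec)
    h = np.asarray(h_oe, dtype=float)
    xi = moment * h / (K_B_ERG_PER_K * spec.temperature)
    small = np.abs(xi) < 1.0e-3
    xi_safe = np.where(small, 1.0, xi)
    with np.errstate(over="ignore"):
        full = 1.0 / np.tanh(xi_safe) - 1.0 / xi_safe
    series = xi / 3.0 - xi**3 / 45.0
    out = np.where(small, series, full)
    return out if out.ndim else float(out)


def me_magnetization_shift(e_v_per_m, spec: ParticleSpec):
    """ME-induced magnetization change dM = alpha * E (emu/cc), E in V/m.

    Linear and sign-preserving; returns an array matching ``e_v_per_m``.
    """
    e = np.asarray(e_v_per_m, dtype=float)
    out = spec.alpha * e * _V_PER_M_TO_V_PER_CM
    return out if out.ndim else float(out)


def me_moment_shift(e_v_per_m, spec: ParticleSpec):
    """Per-particle moment shift dm = alpha * E * V (emu); E in V/m."""
    volume, _ = particle_volume_and_moment(spec)
    return me_magnetization_shift(e_v_per_m, spec) * volume


def men_mrel(h_oe, e_v_per_m, spec: ParticleSpec):
    """Relative magnetization of a MEN: Langevin term plus the ME shift.

    ``clip(L(xi) + dM(E)/M_S, -1, 1)``.  Reduces exactly to the plain
    Langevin curve when ``alpha == 0`` or ``E == 0``.
    """
    e = np.asarray(e_v_per_m, dtype=float)
    if spec.m_s_emu_cc == 0:
        if np.any(e != 0) and spec.alpha > 0:
            raise ConfigurationError("M_S = 0 with a nonzero E field: dM/M_S undefined")
        return langevin_mrel(h_oe, spec)
    shift = me_magnetization_shift(e, spec) / spec.m_s_emu_cc
    out = np.clip(langevin_mrel(h_oe, spec) + shift, -1.0, 1.0)
    return out if np.ndim(out) else float(out)


def hysteresis_energy_per_cycle(
    spec: ParticleSpec,
    total_mass_g: float,
    loop_model: str = "rectangular",
) -> float:
    """Energy dissipated per M-H cycle (J) for a given administered mass.

    Order-of-magnitude estimator: the loop area is ``4 * H_c * M_S`` erg/cc
    for a rectangular loop or ``pi * H_c * M_S`` for an elliptical one,
    multiplied by the material volume ``mass / density``.
    """
    if total_mass_g < 0:
        raise ConfigurationError("total mass must be non-negative")
    area_factors = {"rectangular": 4.0, "elliptical": np.pi}
    if loop_model not in area_factors:
        raise ConfigurationError(
            f"unknown loop model {loop_model!r}; expected one of {sorted(area_factors)}"
        )
    volume_cc = total_mass_g / spec.mass_density
    energy_density_erg_cc = area_factors[loop_model] * spec.h_c * spec.m_s_emu_cc
    return float(energy_density_erg_cc * volume_cc * _ERG_TO_J)


def dipole_mean_field(number_density_per_cc, spec: ParticleSpec):
    """Nearest-neighbour axial dipole field 2 m / r^3 (Oe) at mean spacing r.

    ``r = density^(-1/3)``, so the field equals ``2 * m * density`` and grows
    linearly (hence monotonically) with density.  Below 5 nm spacing the
    quantum-interaction regime excluded from the model is entered and a
    :class:`~menpi.errors.QuantumRegimeWarning` is emitted.
    """
    density = np.asarray(number_density_per_cc, dtype=float)
    if np.any(density < 0):
        raise ConfigurationError("number density must be non-negative")
    _, moment = particle_volume_and_moment(spec)
    with np.errstate(divide="ignore"):
        spacing_cm = np.where(density > 0, density ** (-1.0 / 3.0), np.inf)
    if np.any(spacing_cm < 5.0e-7):
        warnings.warn(
            "mean inter-particle spacing below 5 nm: quantum-mechanical "
            "interactions are not modeled",
            QuantumRegimeWarning,
            stacklevel=2,
        )
    out = 2.0 * moment * density
    return out if out.ndim else float(out)


def mrel_curve(h_oe, e_values_v_per_m, spec: ParticleSpec):
    """Family of M_rel(H) curves, one per electric-field value.

    Returns a dict ``{E: M_rel array}`` suitable for CSV export.
    """
    return {float(e): np.asarray(men_mrel(h_oe, e, spec)) for e in e_values_v_per_m}
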