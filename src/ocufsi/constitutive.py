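"""Material laws for the outflow-tissue FSI model.

The tissue (JCT matrix, SC inner-wall endothelium, basement membrane) and the
scleral tether are nearly incompressible linear elastic solids.  The aqueous
humor is a Newtonian, weakly compressible fluid whose pressure follows a
Mie-Gruneisen equation of state with a cubic shock-velocity/particle-velocity
Hugoniot, the standard form used by explicit hydrocodes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

MMHG_TO_PA = 133.322


@dataclass(frozen=True)
class ElasticMaterial:
    """Isotropic linear elastic solid.

    Parameters
    ----------
    E : elastic modulus [Pa]
    nu : Poisson ratio (0 <= nu < 0.5; near 0.5 = nearly incompressible)
    rho : density [kg/m^3]
    """

    E: float
    nu: float
    rho: float

    def __post_init__(self) -> None:
        if self.E <= 0:
            raise ValueError(f"elastic modulus must be positive, got {self.E}")
        if not (0.0 <= self.nu < 0.5):
            raise ValueError(f"Poisson ratio must be in [0, 0.5), got {self.nu}")
        if self.rho <= 0:
            raise ValueError(f"density must be positive, got {self.rho}")

    @property
    def lam(self) -> float:
        """First Lame parameter lambda = E*nu / ((1+nu)(1-2nu)) [Pa]."""
        return self.E * self.nu / ((1.0 + self.nu) * (1.0 - 2.0 * self.nu))

    @property
    def shear_modulus(self) -> float:
        """Shear modulus G = E / (2(1+nu)) [Pa]."""
        return self.E / (2.0 * (1.0 + self.nu))

    @property
    def p_wave_modulus(self) -> float:
        """Dilatational (P-wave) modulus lambda + 2G [Pa]."""
        return self.lam + 2.0 * self.shear_modulus

    @property
    def dilatational_wave_speed(self) -> float:
        """sqrt((lambda + 2G)/rho) [m/s]; sets the explicit stable step."""
        return float(np.sqrt(self.p_wave_modulus / self.rho))


@dataclass(frozen=True)
class FluidMaterial:
    """Newtonian fluid with Mie-Gruneisen equation of state.

    ``C`` is the intercept of the shock-velocity/particle-velocity curve
    (the reference sound speed), ``S1..S3`` its cubic slope coefficients,
    ``gamma0`` the Gruneisen gamma and ``a`` its first-order volume
    correction.  Defaults are the aqueous-humor constants.
    """

    rho0: float = 1000.0
    mu_dyn: float = 0.7185e-3
    C: float = 1480.0
    S1: float = 2.56
    S2: float = -1.98
    S3: float = 0.226
    gamma0: float = 0.5
    a: float = 0.0

    def __post_init__(self) -> None:
        if self.rho0 <= 0:
            raise ValueError("reference density must be positive")
        if self.mu_dyn <= 0:
            raise ValueError("dynamic viscosity must be positive")
        if self.C <= 0:
            raise ValueError("EOS sound speed C must be positive")

    @property
    def bulk_modulus(self) -> float:
        """Acoustic-limit bulk modulus rho0*C^2 [Pa]."""
        return self.rho0 * self.C ** 2


@dataclass
class EOSState:
    """Thermodynamic state of a fluid parcel.

    V is the relative volume (initial volume of a closed parcel = 1),
    mu the compression 1/V - 1, E_int the internal energy per unit
    *initial* volume [Pa], and p the pressure [Pa].
    """

    V: float = 1.0
    E_int: float = 0.0
    p: float = 0.0

    @property
    def mu(self) -> float:
        return compression_from_relative_volume(self.V)


def compression_from_relative_volume(V):
    """Compression mu = 1/V - 1 from the relative volume V (> 0).

    mu = 0 at the reference state V = 1; mu > 0 in compression.
    """
    V = np.asarray(V, dtype=float)
    if np.any(V <= 0):
        raise ValueError("relative volume must be strictly positive")
    out = 1.0 / V - 1.0
    return float(out) if out.ndim == 0 else out


def relative_volume_from_compression(mu):
    """Inverse of :func:`compression_from_relative_volume`."""
    mu = np.asarray(mu, dtype=float)
    if np.any(mu <= -1):
        raise ValueError("compression must exceed -1")
    out = 1.0 / (1.0 + mu)
    return float(out) if out.ndim == 0 else out


def gruneisen_pressure(mu, E_int, fluid: FluidMaterial):
    """Mie-Gruneisen pressure [Pa] at compression ``mu`` and internal energy
    per initial volume ``E_int`` [Pa].

    Compression branch (mu >= 0): cubic shock-Hugoniot form

        p = rho0 C^2 mu [1 + (1 - gamma0/2) mu - (a/2) mu^2]
            / [1 - (S1-1) mu - S2 mu^2/(mu+1) - S3 mu^3/(mu+1)^2]^2
            + (gamma0 + a mu) E_int

    Expansion branch (mu < 0): linear, p = rho0 C^2 mu + (gamma0 + a mu) E_int.
    The two branches agree in value and slope at mu = 0 (acoustic limit with
    sound speed C).
    """
    mu = np.asarray(mu, dtype=float)
    E_int = np.asarray(E_int, dtype=float)
    if np.any(mu <= -1):
        raise ValueError("compression mu must exceed -1")
    g0, a = fluid.gamma0, fluid.a
    k0 = fluid.rho0 * fluid.C ** 2

    mu_c = np.maximum(mu, 0.0)
    denom = (1.0 - (fluid.S1 - 1.0) * mu_c
             - fluid.S2 * mu_c ** 2 / (mu_c + 1.0)
             - fluid.S3 * mu_c ** 3 / (mu_c + 1.0) ** 2)
    if np.any(np.abs(denom) < 1e-12):
        raise FloatingPointError("Gruneisen Hugoniot denominator is singular")
    num = k0 * mu_c * (1.0 + (1.0 - g0 / 2.0) * mu_c - (a / 2.0) * mu_c ** 2)
    p_comp = num / denom ** 2
    p_exp = k0 * mu
    p = np.where(mu >= 0.0, p_comp, p_exp) + (g0 + a * mu) * E_int
    return float(p) if p.ndim == 0 else p


def eos_pressure(state: EOSState, fluid: FluidMaterial) -> float:
    """Pressure of an :class:`EOSState` (convenience wrapper)."""
    return float(gruneisen_pressure(state.mu, state.E_int, fluid))


def cauchy_stress_small_strain(strain, mat: ElasticMaterial):
    """Linear isotropic Cauchy stress sigma = lambda tr(eps) I + 2 G eps.

    ``strain`` is a symmetric tensor of shape (..., d, d).
    """
    strain = np.asarray(strain, dtype=float)
    if strain.shape[-1] != strain.shape[-2]:
        raise ValueError("strain must be a square tensor")
    if not np.allclose(strain, np.swapaxes(strain, -1, -2), atol=1e-12):
        raise ValueError("strain tensor must be symmetric")
    d = strain.shape[-1]
    tr = np.trace(strain, axis1=-2, axis2=-1)
    eye = np.eye(d)
    return mat.lam * tr[..., None, None] * eye + 2.0 * mat.shear_modulus * strain


def viscous_deviatoric_stress(grad_v, mu_dyn: float):
    """Newtonian deviatoric stress tau = 2 mu dev(sym(grad v)); traceless.

    ``grad_v`` is a velocity-gradient tensor of shape (..., d, d); a rigid
    rotation (antisymmetric gradient) produces zero stress.
    """
    grad_v = np.asarray(grad_v, dtype=float)
    d = grad_v.shape[-1]
    D = 0.5 * (grad_v + np.swapaxes(grad_v, -1, -2))
    tr = np.trace(D, axis1=-2, axis2=-1)
    dev = D - (tr / d)[..., None, None] * np.eye(d)
    return 2.0 * mu_dyn * dev


#: Named material presets used throughout the package.
PRESETS = {
    # JCT / SC inner-wall endothelium with basement membrane, high-flow region
    "jct_high_flow": ElasticMaterial(E=3.05e3, nu=0.495, rho=700.0),
    "sclera": ElasticMaterial(E=2.54e6, nu=0.495, rho=1000.0),
    "aqueous_humor": FluidMaterial(),
}
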