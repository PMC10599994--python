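"""Spring-wing plant: inertia, thorax elasticity, transmission, drag.

The wing rotates in the stroke plane with angle phi, driven through a linear
transmission T (rad/m) by an antagonistic muscle pair working against a
linear thorax spring k (N/m).  The equation of motion is

    Fm/T = I phidd + Gamma |phid| phid + (k/T^2) phi  (+ c_lin phid),

with total rotational inertia I = Iw + Ia (wing mass plus aerodynamic added
mass) and a quasi-steady velocity-squared aerodynamic damping coefficient
Gamma.  The natural period of the undamped rotational system is
Tn = 2 pi sqrt(I / (k/T^2)).
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import yaml

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class WingMorphology:
    """Wing shape/mass parameters entering inertia and drag.

    R2_s, R2_m, R2_v are non-dimensional radii of the second moments of wing
    shape, mass, and added mass (each in (0, 1)); v_hat is the
    non-dimensional added mass of the wing pair; lcp the centre-of-pressure
    moment arm (m).
    """

    rho: float          # fluid density, kg/m^3
    CD_tilde: float     # mean drag coefficient
    Aw: float           # wing area, m^2
    R2_s: float
    R2_m: float
    R2_v: float
    Lw: float           # wing length, m
    mw: float           # wing mass, kg
    AR: float           # aspect ratio
    v_hat: float        # non-dimensional added mass
    lcp: float          # centre of pressure arm, m

    def __post_init__(self) -> None:
        for name in ("rho", "CD_tilde", "Aw", "Lw", "mw", "AR", "lcp"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("R2_s", "R2_m", "R2_v"):
            val = getattr(self, name)
            if not (0.0 < val < 1.0):
                raise ValueError(f"{name} must lie in (0, 1), got {val}")
        if self.v_hat < 0:
            raise ValueError("v_hat must be non-negative")


def added_mass(morph: WingMorphology) -> float:
    """Dimensional added mass v = 2 rho pi v_hat Lw^2 / AR^2.

    Implemented verbatim from the source derivation.  Note the expression as
    written carries units of kg/m rather than kg; compare the resulting
    inertia against any directly measured value before trusting it (a
    warning is raised at first use).
    """
    warnings.warn(
        "added-mass expression 2*rho*pi*v_hat*Lw^2/AR^2 is implemented "
        "verbatim; its dimensions are not those of a mass -- validate I "
        "against a measured inertia where possible",
        stacklevel=2,
    )
    return 2.0 * morph.rho * math.pi * morph.v_hat * morph.Lw**2 / morph.AR**2


def wing_inertia(morph: WingMorphology) -> tuple[float, float, float]:
    """Inertia components (Iw, Ia, I) from wing mass and added mass.

    Iw = R2_m^2 mw Lw^2 ; Ia = R2_v^2 v Lw^2 with the dimensional added
    mass v; I = Iw + Ia.
    """
    Iw = morph.R2_m**2 * morph.mw * morph.Lw**2
    if morph.v_hat == 0.0:
        Ia = 0.0
    else:
        Ia = morph.R2_v**2 * added_mass(morph) * morph.Lw**2
    return Iw, Ia, Iw + Ia


def drag_coefficient(morph: WingMorphology) -> float:
    """Quadratic aerodynamic damping Gamma (N m s^2).

    Gamma = (1/2) rho CD_tilde Aw R2_s^2 Lw^2 lcp, so the drag torque at
    angular velocity phid is Gamma |phid| phid.
    """
    return (
        0.5
        * morph.rho
        * morph.CD_tilde
        * morph.Aw
        * morph.R2_s**2
        * morph.Lw**2
        * morph.lcp
    )


def transmission_ratio(phi0: float, X0: float) -> float:
    """Transmission T = phi0/X0 (rad/m) from matched peak-to-peak amplitudes."""
    if phi0 <= 0 or X0 <= 0:
        raise ValueError("phi0 and X0 must be positive")
    return phi0 / X0


def natural_period(I: float, k_rot: float) -> float:
    """Undamped natural period Tn = 2 pi sqrt(I / k_rot).

    ``k_rot`` is the *rotational* stiffness (N m/rad).  A linear thorax
    stiffness k (N/m) must first be referred through the transmission as
    k/T^2; passing an obviously linear-scale stiffness is refused to guard
    against unit mistakes.
    """
    if I <= 0 or k_rot <= 0:
        raise ValueError("I and k_rot must be positive")
    return 2.0 * math.pi * math.sqrt(I / k_rot)


@dataclass(frozen=True)
class MechanicalPlant:
    """Spring-wing oscillator parameters.

    ``k`` is the linear thorax stiffness (N/m); the rotational stiffness
    k/T^2 is derived internally and used everywhere rotational dynamics are
    evaluated (including Tn).  ``c_lin`` is an opt-in linear viscous torque
    coefficient (N m s), default 0, emulating bearing/friction losses that
    the ideal model omits.
    """

    I: float            # total rotational inertia, kg m^2
    k: float            # linear thorax stiffness, N/m
    T: float            # transmission ratio, rad/m
    L: float            # muscle resting length, m
    Gamma: float        # quadratic damping coefficient, N m s^2
    Iw: float = 0.0
    Ia: float = 0.0
    c_lin: float = 0.0
    provenance: str = "unspecified"

    def __post_init__(self) -> None:
        for name in ("I", "k", "T", "L"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.Gamma < 0 or self.c_lin < 0:
            raise ValueError("Gamma and c_lin must be non-negative")

    @property
    def k_rot(self) -> float:
        """Rotational stiffness k/T^2 (N m/rad)."""
        return self.k / self.T**2

    @property
    def Tn(self) -> float:
        """Natural period 2 pi sqrt(I/(k/T^2)) (s)."""
        return natural_period(self.I, self.k_rot)


def plant_rhs(phi: float, phid: float, Fm: float, plant: MechanicalPlant) -> float:
    """Angular acceleration of the wing for muscle force Fm (N).

    phidd = (Fm/T - Gamma |phid| phid - (k/T^2) phi - c_lin phid) / I.
    """
    return (
        Fm / plant.T
        - plant.Gamma * abs(phid) * phid
        - plant.k_rot * phi
        - plant.c_lin * phid
    ) / plant.I


# ---------------------------------------------------------------------------
# Parameter files


def _load_params(name: str) -> dict:
    text = resources.files("springwing.params").joinpath(name).read_text()
    return yaml.safe_load(text)


def plant_from_params(params: dict) -> MechanicalPlant:
    """Build a plant from a unit-suffixed parameter mapping.

    Placeholder parameter sets (``provenance: placeholder``) are flagged with
    a logged warning so that downstream numbers are never mistaken for
    measured-table values.
    """
    provenance = params.get("provenance", "unspecified")
    if provenance != "measured":
        logger.warning(
            "plant '%s' uses %s parameter values; overwrite with measured "
            "table values for quantitative work",
            params.get("name", "?"),
            provenance,
        )
    return MechanicalPlant(
        I=params["I_kgm2"],
        k=params["k_Npm"],
        T=params["T_radpm"],
        L=params["L_m"],
        Gamma=params["Gamma_Nms2"],
        Iw=params.get("Iw_kgm2", 0.0),
        Ia=params.get("Ia_kgm2", 0.0),
        c_lin=params.get("c_lin_Nms", 0.0),
        provenance=provenance,
    )


def hawkmoth_plant() -> MechanicalPlant:
    """Placeholder M. sexta plant (see ``params/hawkmoth_placeholder.yaml``)."""
    return plant_from_params(_load_params("hawkmoth_placeholder.yaml"))


def hawkmoth_forcing_defaults() -> dict:
    """Synchronous drive defaults shipped with the hawkmoth plant."""
    p = _load_params("hawkmoth_placeholder.yaml")
    return {
        "Fs": p["Fs_N"],
        "fs": p["fs_Hz"],
        "Fa": p["Fa_N"],
        "t0": p["t0_s"],
        "kappa": p["kappa"],
        "phi0_target": math.radians(p["phi0_deg"]),
    }


def roboflapper_plant() -> MechanicalPlant:
    """Placeholder dynamically-scaled flapper (torsion spring + wing in water).

    The robot has a rotational torsion spring; its stiffness is stored here
    already referred to the rotational side with T = 1 rad/m, L = 1 m (all
    actuation scaling absorbed in the feedback gain, as in the hardware).
    """
    return plant_from_params(_load_params("roboflapper_placeholder.yaml"))
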