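"""Spin-system types and orientation-dependent frequency algebra.

All frequencies are cyclic (Hz), times are seconds, distances are
angstroms and angles are degrees at every public interface; radians are
used only inside trigonometric kernels.  The electron-nuclear hyperfine
coupling is treated as purely dipolar (point-dipole approximation),
appropriate for long through-space distances in nonconjugated systems.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import constants as _const

__all__ = [
    "PhysicalConstants",
    "CONSTANTS",
    "NucleusSpec",
    "F19",
    "H1",
    "SpinSystem",
    "CSTensor",
    "Orientation",
    "a_perp_from_distance",
    "dipolar_coupling",
    "cos_theta",
    "delta_eff",
    "larmor_shifted",
    "endor_frequencies",
]

_ALLOWED_S = (0.5, 1.5, 2.5, 3.5)


@dataclass(frozen=True)
class PhysicalConstants:
    """CODATA constants used by the dipolar-coupling formula.

    Attributes
    ----------
    mu0 : float
        Vacuum magnetic permeability (T m / A).
    muB : float
        Bohr magneton (J / T).
    muN : float
        Nuclear magneton (J / T).
    h : float
        Planck constant (J s).
    """

    mu0: float = _const.mu_0
    muB: float = _const.physical_constants["Bohr magneton"][0]
    muN: float = _const.physical_constants["nuclear magneton"][0]
    h: float = _const.h

    def __post_init__(self) -> None:
        for name in ("mu0", "muB", "muN", "h"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")


CONSTANTS = PhysicalConstants()


@dataclass(frozen=True)
class NucleusSpec:
    """A detected nucleus: isotope label, g-factor and reference Larmor frequency.

    ``larmor_ref`` is the unshifted Larmor frequency at the working field
    (Hz); orientation-dependent chemical shifts are applied on top of it.
    """

    label: str
    gn: float
    larmor_ref: float

    def __post_init__(self) -> None:
        if self.gn <= 0:
            raise ValueError("gn must be positive for the supported nuclei")
        if self.larmor_ref <= 0:
            raise ValueError("larmor_ref must be positive")


#: 19F at W-band (3.40 T); gn from the standard isotope tables.
F19 = NucleusSpec(label="19F", gn=5.2577, larmor_ref=136.4e6)
#: 1H at W-band (3.40 T).
H1 = NucleusSpec(label="1H", gn=5.5857, larmor_ref=144.9e6)


@dataclass(frozen=True)
class SpinSystem:
    """Electron spin coupled to a single detected nucleus.

    Defaults describe the Gd(III) central transition: S = 7/2 with an
    effective g-value of 1.992 (not the free-electron value).
    """

    nucleus: NucleusSpec
    r_GdF: float
    S: float = 3.5
    ge: float = 1.992

    def __post_init__(self) -> None:
        if self.S not in _ALLOWED_S:
            raise ValueError(f"S must be one of {_ALLOWED_S}, got {self.S}")
        if self.r_GdF <= 0:
            raise ValueError("r_GdF must be positive")
        if self.ge <= 0:
            raise ValueError("ge must be positive")

    @property
    def a_perp(self) -> float:
        """Perpendicular dipolar coupling |a_perp| in Hz."""
        return a_perp_from_distance(self.r_GdF, self.nucleus, self.ge)


@dataclass(frozen=True)
class CSTensor:
    """Anisotropic chemical-shift tensor and the electron-nucleus vector orientation.

    ``dxx, dyy, dzz`` are the principal values of the *anisotropic*
    (traceless) part of the shift tensor, in ppm.  ``gamma`` (polar) and
    ``rho`` (azimuthal) give the direction of the Gd-F vector in the
    tensor principal-axis frame, restricted to the canonical octant
    [0, 90] x [0, 90]: the quadratic orientation dependence makes the
    other octants equivalent.
    """

    dxx: float
    dyy: float
    dzz: float
    gamma: float
    rho: float

    def __post_init__(self) -> None:
        trace = self.dxx + self.dyy + self.dzz
        scale = max(abs(self.dxx), abs(self.dyy), abs(self.dzz), 1.0)
        if abs(trace) > 1e-9 * scale:
            raise ValueError(
                f"anisotropic shift tensor must be traceless, got trace {trace} ppm"
            )
        if not 0.0 <= self.gamma <= 90.0:
            raise ValueError("gamma must lie in [0, 90] degrees")
        if not 0.0 <= self.rho <= 90.0:
            raise ValueError("rho must lie in [0, 90] degrees")


@dataclass(frozen=True)
class Orientation:
    """Direction of the static field in the chemical-shift frame (degrees)."""

    xi: float
    phi: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.xi <= 180.0:
            raise ValueError("xi must lie in [0, 180] degrees")
        if not 0.0 <= self.phi < 360.0:
            raise ValueError("phi must lie in [0, 360) degrees")


def a_perp_from_distance(
    r: float, nucleus: NucleusSpec, ge: float = 1.992,
    constants: PhysicalConstants = CONSTANTS,
) -> float:
    """Perpendicular point-dipole hyperfine coupling |a_perp| in Hz.

    |a_perp| = mu0 * ge * muB * gn * muN / (4 pi h r^3) with r in angstrom.

    Parameters
    ----------
    r : float
        Electron-nucleus distance in angstrom (> 0).
    nucleus : NucleusSpec
        Supplies the nuclear g-factor.
    ge : float
        Electron g-value; defaults to the Gd(III) value 1.992.
    """
    if r <= 0:
        raise ValueError("distance must be positive")
    r_m = r * 1e-10
    c = constants
    return (c.mu0 * ge * c.muB * nucleus.gn * c.muN) / (
        4.0 * np.pi * c.h * r_m**3
    )


def dipolar_coupling(theta: float, a_perp: float):
    """Orientation-dependent dipolar splitting a(theta) = (3 cos^2 theta - 1) |a_perp|.

    ``theta`` is the angle (degrees) between the field and the
    electron-nucleus vector.  Accepts arrays.
    """
    a_perp = np.asarray(a_perp, dtype=float)
    if np.any(a_perp < 0):
        raise ValueError("a_perp must be non-negative")
    ct = np.cos(np.deg2rad(theta))
    return (3.0 * ct**2 - 1.0) * a_perp


def cos_theta(orientation: Orientation, gamma: float, rho: float) -> float:
    """Cosine of the angle between the field and the Gd-F unit vector.

    Both directions are expressed in the chemical-shift frame; the result
    is the dot product of the two unit vectors.
    """
    xi = np.deg2rad(orientation.xi)
    phi = np.deg2rad(orientation.phi)
    g = np.deg2rad(gamma)
    r = np.deg2rad(rho)
    value = (
        np.cos(r) * np.sin(g) * np.cos(phi) * np.sin(xi)
        + np.sin(r) * np.sin(g) * np.sin(phi) * np.sin(xi)
        + np.cos(g) * np.cos(xi)
    )
    return float(np.clip(value, -1.0, 1.0))


def delta_eff(orientation: Orientation, tensor: CSTensor) -> float:
    """Effective secular chemical shift (ppm) for a given field direction.

    Projects the traceless tensor onto the field direction using squared
    direction cosines:

        delta = dxx (cos phi sin xi)^2 + dyy (sin phi sin xi)^2 + dzz cos^2 xi
    """
    xi = np.deg2rad(orientation.xi)
    phi = np.deg2rad(orientation.phi)
    return float(
        tensor.dxx * (np.cos(phi) * np.sin(xi)) ** 2
        + tensor.dyy * (np.sin(phi) * np.sin(xi)) ** 2
        + tensor.dzz * np.cos(xi) ** 2
    )


def larmor_shifted(nu_ref: float, delta: float):
    """Larmor frequency shifted by a chemical shift ``delta`` in ppm."""
    if np.any(np.asarray(nu_ref) <= 0):
        raise ValueError("nu_ref must be positive")
    return nu_ref * (1.0 + np.asarray(delta) * 1e-6)


def endor_frequencies(nu_I, a):
    """Central-transition ENDOR doublet (nu_I - a/2, nu_I + a/2) in Hz.

    The pair is exactly symmetric about ``nu_I`` and split by ``a``.
    """
    nu_I = np.asarray(nu_I, dtype=float)
    if np.any(nu_I <= 0):
        raise ValueError("nu_I must be positive")
    a = np.asarray(a, dtype=float)
    return nu_I - 0.5 * a, nu_I + 0.5 * a
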