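"""Powder Mims-ENDOR forward simulation and nonlinear least-squares fitting.

The forward model accumulates the central-transition doublet
nu = nu_I(xi, phi) -/+ a(theta)/2 over a hemispheric orientation grid with
sin(xi) weighting, where a(theta) is the point-dipole coupling and
nu_I carries the optional chemical-shift anisotropy.  The stick powder
pattern is then convolved with a Gaussian of given FWHM and
max-normalized.  Fitting wraps :func:`scipy.optimize.least_squares`
with 1-sigma uncertainties from the residual-variance-scaled covariance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.ndimage import gaussian_filter1d
from scipy.optimize import least_squares

from endortools.spin_physics import CSTensor, SpinSystem, a_perp_from_distance

__all__ = [
    "AcquisitionParams",
    "Spectrum",
    "SpectrumFit",
    "mims_efficiency",
    "simulate_powder_spectrum",
    "fit_spectrum",
    "FIT_PARAM_NAMES",
]

_FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))

FIT_PARAM_NAMES = ("r_GdF", "gamma", "rho", "lw_fwhm", "amplitude")


@dataclass(frozen=True)
class AcquisitionParams:
    """Acquisition and simulation-grid settings.

    Parameters
    ----------
    tau : float
        Mims interpulse delay in seconds (> 0).
    nu_ref : float
        Reference nuclear Larmor frequency at the working field (Hz).
    lw_fwhm : float
        FWHM of the Gaussian convolution lineshape (Hz, >= 0); lumps RF
        excitation bandwidth and unresolved couplings.
    grid_xi, grid_phi : int
        Number of polar/azimuthal powder-grid nodes (>= 32 each).
    apply_mims_weighting : bool
        Weight each orientation by the Mims echo response.
    offset_bin : float
        Frequency-axis bin width (Hz) for auto-generated axes.
    offset_max : float or None
        Half-span of the auto-generated offset axis (Hz); None chooses a
        span covering the full powder pattern plus convolution tails.
    """

    tau: float = 2000e-9
    nu_ref: float = 136.4e6
    lw_fwhm: float = 15e3
    grid_xi: int = 181
    grid_phi: int = 361
    apply_mims_weighting: bool = True
    offset_bin: float = 500.0
    offset_max: float | None = None

    def __post_init__(self) -> None:
        if self.tau <= 0:
            raise ValueError("tau must be positive")
        if self.lw_fwhm < 0:
            raise ValueError("lw_fwhm must be non-negative")
        if self.grid_xi < 32 or self.grid_phi < 32:
            raise ValueError("powder grid sizes must be >= 32")
        if self.offset_bin <= 0:
            raise ValueError("offset_bin must be positive")


@dataclass
class Spectrum:
    """RF-offset spectrum: offsets nu - nu_I,0 (Hz) vs max-normalized intensity."""

    offsets: np.ndarray
    intensities: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.offsets = np.asarray(self.offsets, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.offsets.shape != self.intensities.shape:
            raise ValueError("offsets and intensities must have equal length")
        if self.offsets.ndim != 1 or len(self.offsets) < 2:
            raise ValueError("spectrum must be a 1-d array of >= 2 points")
        if np.any(np.diff(self.offsets) <= 0):
            raise ValueError("offsets must be strictly ascending")


@dataclass
class SpectrumFit:
    """Result of a powder-spectrum least-squares fit."""

    params: dict
    sigmas: dict
    residual_norm: float
    covariance: np.ndarray
    vary: tuple
    at_bound: tuple = ()
    success: bool = True
    message: str = ""


def mims_efficiency(a, tau: float):
    """Mims echo response 0.5 * (1 - cos(2 pi a tau)), in [0, 1].

    Vanishes exactly at the blind spots a * tau = 0, 1, 2, ...
    """
    if tau <= 0:
        raise ValueError("tau must be positive")
    return 0.5 * (1.0 - np.cos(2.0 * np.pi * np.asarray(a, dtype=float) * tau))


def _powder_grid(acq: AcquisitionParams):
    """Hemispheric (xi, phi) grid with solid-angle trapezoidal weights."""
    xi = np.linspace(0.0, np.pi / 2.0, acq.grid_xi)
    phi = np.linspace(0.0, 2.0 * np.pi, acq.grid_phi)

    def trapw(x):
        w = np.empty_like(x)
        w[1:-1] = 0.5 * (x[2:] - x[:-2])
        w[0] = 0.5 * (x[1] - x[0])
        w[-1] = 0.5 * (x[-1] - x[-2])
        return w

    w_xi = trapw(xi) * np.sin(xi)
    w_phi = trapw(phi)
    xi_g, phi_g = np.meshgrid(xi, phi, indexing="ij")
    weights = np.outer(w_xi, w_phi)
    return xi_g.ravel(), phi_g.ravel(), weights.ravel()


def _stick_contributions(
    system: SpinSystem, tensor: CSTensor | None, acq: AcquisitionParams
):
    """Offsets (Hz, relative to nu_ref) and weights of both doublet branches."""
    xi, phi, w = _powder_grid(acq)
    a_perp = system.a_perp

    if tensor is None:
        # No CS frame: theta is the polar angle itself, nu_I is constant.
        cos_t = np.cos(xi)
        nu_shift = np.zeros_like(xi)
    else:
        g = np.deg2rad(tensor.gamma)
        r = np.deg2rad(tensor.rho)
        sin_xi = np.sin(xi)
        cos_t = (
            np.cos(r) * np.sin(g) * np.cos(phi) * sin_xi
            + np.sin(r) * np.sin(g) * np.sin(phi) * sin_xi
            + np.cos(g) * np.cos(xi)
        )
        delta = (
            tensor.dxx * (np.cos(phi) * sin_xi) ** 2
            + tensor.dyy * (np.sin(phi) * sin_xi) ** 2
            + tensor.dzz * np.cos(xi) ** 2
        )
        nu_shift = acq.nu_ref * delta * 1e-6

    a = (3.0 * cos_t**2 - 1.0) * a_perp
    if acq.apply_mims_weighting:
        eff = mims_efficiency(a, acq.tau)
        if eff.max() < 1e-9:
            raise ValueError(
                "all orientations fall on Mims blind spots "
                "(a * tau is near-integer across the powder pattern)"
            )
        w = w * eff

    offsets = np.concatenate([nu_shift - 0.5 * a, nu_shift + 0.5 * a])
    weights = np.concatenate([w, w])
    return offsets, weights


def _deposit(offsets, weights, axis):
    """Linearly split each stick between its two neighbouring axis bins."""
    bin_w = axis[1] - axis[0]
    pos = (offsets - axis[0]) / bin_w
    idx = np.floor(pos).astype(int)
    frac = pos - idx
    hist = np.zeros(len(axis), dtype=float)
    ok = (idx >= 0) & (idx < len(axis) - 1)
    np.add.at(hist, idx[ok], weights[ok] * (1.0 - frac[ok]))
    np.add.at(hist, idx[ok] + 1, weights[ok] * frac[ok])
    # sticks exactly on the last node
    last = idx == len(axis) - 1
    edge = last & (frac < 1e-12)
    np.add.at(hist, idx[edge], weights[edge])
    return hist


def _default_axis(system: SpinSystem, tensor: CSTensor | None, acq: AcquisitionParams):
    a_perp = system.a_perp
    csa_span = 0.0
    if tensor is not None:
        csa_span = (
            max(abs(tensor.dxx), abs(tensor.dyy), abs(tensor.dzz))
            * acq.nu_ref
            * 1e-6
        )
    half = 1.1 * a_perp + csa_span + 4.0 * acq.lw_fwhm + 4.0 * acq.offset_bin
    if acq.offset_max is not None:
        half = acq.offset_max
    n = int(np.ceil(half / acq.offset_bin))
    return np.arange(-n, n + 1) * acq.offset_bin


def _simulate_on_axis(
    system: SpinSystem,
    tensor: CSTensor | None,
    acq: AcquisitionParams,
    axis: np.ndarray,
    normalize: bool = True,
):
    offsets, weights = _stick_contributions(system, tensor, acq)
    hist = _deposit(offsets, weights, axis)
    if acq.lw_fwhm > 0:
        bin_w = axis[1] - axis[0]
        sigma_bins = acq.lw_fwhm * _FWHM_TO_SIGMA / bin_w
        hist = gaussian_filter1d(hist, sigma_bins, mode="constant")
    peak = hist.max()
    if normalize:
        if peak <= 0:
            raise ValueError(
                "simulated spectrum is identically zero "
                "(all orientations fall on Mims blind spots)"
            )
        hist = hist / peak
    return hist


def simulate_powder_spectrum(
    system: SpinSystem,
    tensor: CSTensor | None,
    acq: AcquisitionParams,
    offsets: np.ndarray | None = None,
) -> Spectrum:
    """Simulate a powder ENDOR spectrum of the Gd(III) central transition.

    Parameters
    ----------
    system : SpinSystem
        Electron-nucleus pair; sets |a_perp| through the distance.
    tensor : CSTensor or None
        Anisotropic chemical-shift tensor; None disables CSA, giving a
        spectrum exactly symmetric about zero offset.
    acq : AcquisitionParams
        Delay, linewidth, grid and weighting settings.
    offsets : array, optional
        Frequency-offset axis (Hz) to evaluate on; auto-generated when
        omitted.

    Returns
    -------
    Spectrum
        Max-normalized intensities on the offset axis.
    """
    axis = _default_axis(system, tensor, acq) if offsets is None else np.asarray(
        offsets, dtype=float
    )
    if acq.lw_fwhm > 0 and acq.lw_fwhm < 2.0 * (axis[1] - axis[0]):
        warnings.warn(
            "offset bin width is coarse relative to lw_fwhm; "
            "increase the axis resolution",
            stacklevel=2,
        )
    intensities = _simulate_on_axis(system, tensor, acq, axis)
    meta = {
        "nucleus": system.nucleus.label,
        "tau_ns": acq.tau * 1e9,
        "nu_ref_mhz": acq.nu_ref * 1e-6,
        "r_GdF": system.r_GdF,
    }
    return Spectrum(offsets=axis, intensities=intensities, meta=meta)


_BOUNDS = {
    "r_GdF": (2.0, 60.0),
    "gamma": (0.0, 90.0),
    "rho": (0.0, 90.0),
    "lw_fwhm": (10.0, 1e6),
    "amplitude": (1e-6, 100.0),
}


def fit_spectrum(
    spectrum: Spectrum,
    system0: SpinSystem,
    tensor0: CSTensor | None,
    vary: set | tuple | list,
    acq: AcquisitionParams,
    max_nfev: int = 400,
) -> SpectrumFit:
    """Least-squares fit of the powder forward model to a spectrum.

    ``vary`` selects from ``{"r_GdF", "gamma", "rho", "lw_fwhm",
    "amplitude"}``; the remaining parameters are held at their values in
    ``system0`` / ``tensor0`` / ``acq``.  Angles are bounded to the
    canonical octant [0, 90] degrees.  Uncertainties are 1 sigma from the
    covariance matrix scaled by the residual variance.
    """
    requested = set(vary)
    unknown = requested - set(FIT_PARAM_NAMES)
    if unknown:
        raise ValueError(f"unknown fit parameters: {sorted(unknown)}")
    vary = tuple(v for v in FIT_PARAM_NAMES if v in requested)
    if not vary:
        raise ValueError("vary must select at least one parameter")
    if tensor0 is None and ({"gamma", "rho"} & set(vary)):
        raise ValueError("cannot vary CSA angles without a tensor")
    data = spectrum.intensities
    if np.ptp(data) == 0:
        raise ValueError("degenerate (flat) spectrum")
    axis = spectrum.offsets

    start = {
        "r_GdF": system0.r_GdF,
        "gamma": tensor0.gamma if tensor0 is not None else 0.0,
        "rho": tensor0.rho if tensor0 is not None else 0.0,
        "lw_fwhm": acq.lw_fwhm,
        "amplitude": 1.0,
    }
    x0 = np.array([start[name] for name in vary], dtype=float)
    lo = np.array([_BOUNDS[name][0] for name in vary])
    hi = np.array([_BOUNDS[name][1] for name in vary])

    def build(x):
        p = dict(start)
        p.update(dict(zip(vary, x)))
        system = replace(system0, r_GdF=p["r_GdF"])
        tensor = (
            None
            if tensor0 is None
            else replace(tensor0, gamma=p["gamma"], rho=p["rho"])
        )
        acq_i = replace(acq, lw_fwhm=p["lw_fwhm"])
        return p, system, tensor, acq_i

    def residuals(x):
        p, system, tensor, acq_i = build(x)
        model = _simulate_on_axis(system, tensor, acq_i, axis)
        return p["amplitude"] * model - data

    result = least_squares(
        residuals,
        x0,
        bounds=(lo, hi),
        method="trf",
        diff_step=1e-4,
        x_scale=np.maximum(np.abs(x0), 1.0),
        max_nfev=max_nfev,
    )
    if not result.success:
        raise RuntimeError(
            f"spectrum fit did not converge: {result.message}; "
            f"last iterate {dict(zip(vary, result.x))}"
        )

    p_best, _, _, _ = build(result.x)
    n, k = len(data), len(vary)
    dof = max(n - k, 1)
    s2 = 2.0 * result.cost / dof
    jtj = result.jac.T @ result.jac
    cov = s2 * np.linalg.pinv(jtj)
    sig = np.sqrt(np.clip(np.diag(cov), 0.0, np.inf))

    at_bound = tuple(
        name
        for name, xv, l, h in zip(vary, result.x, lo, hi)
        if np.isclose(xv, l, atol=1e-10) or np.isclose(xv, h, atol=1e-10)
    )
    params = {name: p_best[name] for name in FIT_PARAM_NAMES}
    sigmas = {name: float(s) for name, s in zip(vary, sig)}
    return SpectrumFit(
        params=params,
        sigmas=sigmas,
        residual_norm=float(np.sqrt(2.0 * result.cost)),
        covariance=cov,
        vary=vary,
        at_bound=at_bound,
        success=True,
        message=result.message,
    )
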