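"""Fitting of time-domain relaxation traces.

Covers stretched-exponential saturation/inversion recovery with
first-moment averaging of the rate distribution, mono- and
biexponential nuclear-spin-echo (NSE) decays, and the linear regression
of nuclear decoherence rates against electron spin-lattice rates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares
from scipy.special import gamma as gamma_fn

__all__ = [
    "Trace",
    "RecoveryFit",
    "NSEFit",
    "RateRegression",
    "fit_recovery",
    "mean_T1e",
    "fit_nse_mono",
    "fit_nse_biexp",
    "regress_rates",
]

_RECOVERY_KINDS = ("saturation", "inversion")
BETA_BOUNDS = (0.3, 1.5)
RATE_BOUNDS = (1.0, 1e7)  # Hz


@dataclass
class Trace:
    """A time-domain echo-intensity trace.

    ``t`` is the swept delay in seconds: the recovery wait time for
    ``kind`` in {"saturation", "inversion"} or the RF interpulse delay
    for ``kind`` == "nse".
    """

    t: np.ndarray
    I: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.I = np.asarray(self.I, dtype=float)
        if self.t.shape != self.I.shape or self.t.ndim != 1:
            raise ValueError("t and I must be 1-d arrays of equal length")
        if np.any(self.t < 0) or np.any(np.diff(self.t) <= 0):
            raise ValueError("t must be non-negative and strictly ascending")
        if self.meta.get("kind") not in (*_RECOVERY_KINDS, "nse"):
            raise ValueError("meta['kind'] must be saturation, inversion or nse")

    @property
    def kind(self) -> str:
        return self.meta["kind"]


@dataclass
class RecoveryFit:
    """Stretched-exponential recovery fit I = I0 (1 - A exp(-(t/T1e)^beta))."""

    I0: float
    A: float
    T1e: float
    beta: float
    T1e_bar: float
    sigmas: dict
    at_bound: tuple = ()
    residual_norm: float = 0.0


@dataclass
class NSEFit:
    """NSE decay fit; ``components`` is a list of (rate 1/T2n in Hz, fraction)."""

    components: list
    model: str
    window: tuple
    sigmas: dict
    I0: float = 1.0
    flagged: bool = False
    residual_norm: float = 0.0

    @property
    def rates(self) -> list:
        return [r for r, _ in self.components]

    @property
    def fractions(self) -> list:
        return [f for _, f in self.components]

    @property
    def T2n(self) -> float:
        """Dominant-component T2n (s); the single one for a mono fit."""
        rate, _ = max(self.components, key=lambda c: c[1])
        return 1.0 / rate


@dataclass
class RateRegression:
    """OLS summary of 1/T2n against 1/T1e-bar."""

    slope: float
    intercept: float
    r_squared: float
    n: int
    slope_sigma: float = float("nan")


def mean_T1e(T1e: float, beta: float) -> float:
    """First moment of exp(-(t/T1e)^beta): (T1e / beta) * Gamma(1 / beta)."""
    if T1e <= 0:
        raise ValueError("T1e must be positive")
    if beta <= 0:
        raise ValueError("beta must be positive")
    return (T1e / beta) * float(gamma_fn(1.0 / beta))


def _scaled_sigmas(result, names):
    n, k = len(result.fun), len(result.x)
    dof = max(n - k, 1)
    s2 = 2.0 * result.cost / dof
    cov = s2 * np.linalg.pinv(result.jac.T @ result.jac)
    sig = np.sqrt(np.clip(np.diag(cov), 0.0, np.inf))
    return {name: float(s) for name, s in zip(names, sig)}, cov


def fit_recovery(
    trace: Trace, fix_beta: float | None = None, weighting: str = "none"
) -> RecoveryFit:
    """Fit a saturation/inversion recovery trace with a stretched exponential.

    The model is I = I0 (1 - A exp(-(t/T1e)^beta)); A starts at 1.0 for
    saturation and 2.0 for inversion, both fitted freely.  ``fix_beta``
    pins the stretch exponent (e.g. 1.0 for a plain exponential).
    ``weighting`` selects the residual weights: "none" (homoscedastic)
    or "relative" (1/|I|, the maximum-likelihood choice when the noise
    is multiplicative, as in echo-train detection with signal-
    proportional scatter).  ``T1e_bar`` is filled with the first-moment
    mean of the fitted rate distribution.
    """
    if trace.kind not in _RECOVERY_KINDS:
        raise ValueError(f"recovery fit requires a recovery trace, got {trace.kind!r}")
    if weighting not in ("none", "relative"):
        raise ValueError("weighting must be 'none' or 'relative'")
    t, I = trace.t, trace.I
    if len(t) < 8:
        warnings.warn("fewer than 8 points; recovery fit may be unstable", stacklevel=2)
    if weighting == "relative":
        # floor avoids infinite weight at the zero crossing of inversion traces
        w = 1.0 / np.maximum(np.abs(I), 0.05 * np.abs(I).max())
    else:
        w = np.ones_like(I)

    I0_0 = I[-1] if I[-1] > 0 else max(I.max(), 1.0)
    A0 = 1.0 if trace.kind == "saturation" else 2.0
    # crude time-scale guess: delay where the recovery is ~63% complete
    frac = np.clip((I0_0 - I) / (I0_0 * A0), 1e-12, 1.0)
    above = np.nonzero(frac < np.exp(-1.0))[0]
    T0 = t[above[0]] if len(above) else t[len(t) // 2]
    T0 = max(T0, t[1] if len(t) > 1 else 1e-6)

    names = ("I0", "A", "T1e") if fix_beta is not None else ("I0", "A", "T1e", "beta")
    x0 = [I0_0, A0, T0] + ([] if fix_beta is not None else [0.9])
    lo = [1e-12 * I0_0, 0.05, 1e-9] + ([] if fix_beta is not None else [BETA_BOUNDS[0]])
    hi = [np.inf, 3.0, 100.0] + ([] if fix_beta is not None else [BETA_BOUNDS[1]])

    def model(x):
        I0, A, T1e = x[:3]
        beta = fix_beta if fix_beta is not None else x[3]
        return I0 * (1.0 - A * np.exp(-((t / T1e) ** beta)))

    result = least_squares(
        lambda x: w * (model(x) - I),
        x0,
        bounds=(lo, hi),
        x_scale=np.abs(x0),
        method="trf",
    )
    if not result.success:
        raise RuntimeError(f"recovery fit did not converge: {result.message}")

    I0, A, T1e = result.x[:3]
    beta = fix_beta if fix_beta is not None else float(result.x[3])
    sigmas, cov = _scaled_sigmas(result, names)

    if fix_beta is None:
        # delta-method propagation of (T1e, beta) uncertainty to the first moment
        eps = 1e-7
        g = np.zeros(len(names))
        g[2] = (mean_T1e(T1e * (1 + eps), beta) - mean_T1e(T1e * (1 - eps), beta)) / (
            2 * eps * T1e
        )
        g[3] = (mean_T1e(T1e, beta + eps) - mean_T1e(T1e, beta - eps)) / (2 * eps)
        sigmas["T1e_bar"] = float(np.sqrt(max(g @ cov @ g, 0.0)))
    else:
        sigmas["T1e_bar"] = sigmas["T1e"]

    at_bound = []
    if fix_beta is None and (
        np.isclose(beta, BETA_BOUNDS[0]) or np.isclose(beta, BETA_BOUNDS[1])
    ):
        at_bound.append("beta")

    if t[-1] < 2.0 * T1e:
        warnings.warn(
            "trace spans less than 2*T1e; fitted asymptote is extrapolated",
            stacklevel=2,
        )

    return RecoveryFit(
        I0=float(I0),
        A=float(A),
        T1e=float(T1e),
        beta=float(beta),
        T1e_bar=mean_T1e(float(T1e), float(beta)),
        sigmas=sigmas,
        at_bound=tuple(at_bound),
        residual_norm=float(np.sqrt(2.0 * result.cost)),
    )


def fit_nse_mono(trace: Trace, window_max: float = 200e-6) -> NSEFit:
    """Fit an NSE decay with I proportional to exp(-2 tau_RF / T2n).

    Only points with tau_RF <= ``window_max`` enter the fit (SNR limits
    restrict real measurements to the early decay region).
    """
    if trace.kind != "nse":
        raise ValueError("NSE fit requires kind == 'nse'")
    # small relative tolerance so a point sitting exactly on the window
    # edge is kept regardless of how the edge value was computed
    mask = trace.t <= window_max * (1.0 + 1e-9)
    t, I = trace.t[mask], trace.I[mask]
    if len(t) < 4:
        raise ValueError(f"only {len(t)} points in window <= {window_max:g} s; need 4")

    pos = I > 0
    if pos.sum() >= 2:
        slope = np.polyfit(t[pos], np.log(I[pos]), 1)[0]
    else:
        slope = -1.0
    if slope >= 0:
        raise ValueError("trace does not decay within the fit window")
    rate0 = float(np.clip(-slope / 2.0, *RATE_BOUNDS))
    I0_0 = max(I[0], 1e-12)

    def resid(x):
        return x[0] * np.exp(-2.0 * t * x[1]) - I

    result = least_squares(
        resid,
        [I0_0, rate0],
        bounds=([1e-12, RATE_BOUNDS[0]], [np.inf, RATE_BOUNDS[1]]),
        x_scale=[I0_0, rate0],
        method="trf",
    )
    if not result.success:
        raise RuntimeError(f"NSE fit did not converge: {result.message}")
    if result.x[1] <= 0:
        raise ValueError("non-decaying input: fitted rate is not positive")
    sigmas, _ = _scaled_sigmas(result, ("I0", "rate"))
    return NSEFit(
        components=[(float(result.x[1]), 1.0)],
        model="mono",
        window=(float(t[0]), float(window_max)),
        sigmas=sigmas,
        I0=float(result.x[0]),
        residual_norm=float(np.sqrt(2.0 * result.cost)),
    )


def fit_nse_biexp(trace: Trace, shared_rates: tuple | None = None) -> NSEFit:
    """Fit a two-population NSE decay.

    The model is I = I0 [f exp(-2 tau r_fast) + (1 - f) exp(-2 tau r_slow)]
    with rates in Hz.  When ``shared_rates`` = (r_fast, r_slow) is given,
    only I0 and the fast fraction f are fitted — the refit used to test
    whether conditions change populations rather than rates.
    """
    if trace.kind != "nse":
        raise ValueError("NSE fit requires kind == 'nse'")
    t, I = trace.t, trace.I
    if len(t) < 8:
        raise ValueError("biexponential fit needs >= 8 points")
    I0_0 = max(I[0], 1e-12)

    if shared_rates is not None:
        r_fast, r_slow = sorted(map(float, shared_rates), reverse=True)

        def resid(x):
            I0, f = x
            return (
                I0 * (f * np.exp(-2 * t * r_fast) + (1 - f) * np.exp(-2 * t * r_slow))
                - I
            )

        result = least_squares(
            resid, [I0_0, 0.5], bounds=([1e-12, 0.0], [np.inf, 1.0]), method="trf"
        )
        if not result.success:
            raise RuntimeError(f"biexponential refit failed: {result.message}")
        I0, f = result.x
        sigmas, _ = _scaled_sigmas(result, ("I0", "fraction_fast"))
    else:
        half = len(t) // 2
        tail = I[half:] > 0
        r_slow0 = 300.0
        if tail.sum() >= 2:
            s = np.polyfit(t[half:][tail], np.log(I[half:][tail]), 1)[0]
            if s < 0:
                r_slow0 = float(np.clip(-s / 2, *RATE_BOUNDS))
        r_fast0 = float(np.clip(50 * r_slow0, *RATE_BOUNDS))

        def resid(x):
            I0, f, rf, rs = x
            return I0 * (f * np.exp(-2 * t * rf) + (1 - f) * np.exp(-2 * t * rs)) - I

        result = least_squares(
            resid,
            [I0_0, 0.5, r_fast0, r_slow0],
            bounds=(
                [1e-12, 0.0, RATE_BOUNDS[0], RATE_BOUNDS[0]],
                [np.inf, 1.0, RATE_BOUNDS[1], RATE_BOUNDS[1]],
            ),
            x_scale=[I0_0, 1.0, r_fast0, r_slow0],
            method="trf",
        )
        if not result.success:
            raise RuntimeError(f"biexponential fit failed: {result.message}")
        I0, f, r_fast, r_slow = result.x
        if r_fast < r_slow:  # keep the fast component first
            r_fast, r_slow, f = r_slow, r_fast, 1.0 - f
        sigmas, _ = _scaled_sigmas(result, ("I0", "fraction_fast", "rate_fast", "rate_slow"))

    flagged = False
    if r_slow > 0 and r_fast / r_slow < 3.0:
        warnings.warn(
            "biexponential components are poorly separated (rate ratio < 3)",
            stacklevel=2,
        )
        flagged = True

    return NSEFit(
        components=[(float(r_fast), float(f)), (float(r_slow), float(1.0 - f))],
        model="biexp",
        window=(float(t[0]), float(t[-1])),
        sigmas=sigmas,
        I0=float(I0),
        flagged=flagged,
        residual_norm=float(np.sqrt(2.0 * result.cost)),
    )


def regress_rates(points, through_origin: bool = False) -> RateRegression:
    """Ordinary least squares of 1/T2n on 1/T1e-bar.

    ``points`` is a sequence of (1/T1e_bar, 1/T2n) pairs in Hz.  With
    ``through_origin`` the intercept is constrained to zero.
    """
    pts = np.asarray(list(points), dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 2:
        raise ValueError("need at least 2 (x, y) points")
    x, y = pts[:, 0], pts[:, 1]
    if np.any(pts <= 0):
        raise ValueError("all rates must be positive")
    if np.ptp(x) == 0:
        raise ValueError("degenerate abscissa: all 1/T1e_bar values equal")

    if through_origin:
        slope = float(x @ y / (x @ x))
        intercept = 0.0
        yhat = slope * x
        dof = len(x) - 1
        slope_var = ((y - yhat) @ (y - yhat) / max(dof, 1)) / (x @ x)
    else:
        X = np.column_stack([x, np.ones_like(x)])
        coef, *_ = np.linalg.lstsq(X, y, rcond=None)
        slope, intercept = float(coef[0]), float(coef[1])
        yhat = X @ coef
        dof = len(x) - 2
        s2 = (y - yhat) @ (y - yhat) / max(dof, 1)
        slope_var = s2 * np.linalg.pinv(X.T @ X)[0, 0]

    ss_res = float(((y - yhat) ** 2).sum())
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return RateRegression(
        slope=slope,
        intercept=intercept,
        r_squared=r2,
        n=len(x),
        slope_sigma=float(np.sqrt(max(slope_var, 0.0))),
    )
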