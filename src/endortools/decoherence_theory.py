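"""Limiting theories for nuclear decoherence near a paramagnetic center.

Two analytic limits are implemented: the Solomon-Bloembergen-Morgan
(SBM) expression, valid when the electron spin-lattice rate is fast
compared with the hyperfine coupling, and the slow-relaxation limit
T2n = 2 T1e, valid in the opposite extreme.  No analytic expression
exists for the intermediate regime; ``classify_regime`` reports where a
given parameter pair sits.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from endortools.spin_physics import (
    CONSTANTS,
    NucleusSpec,
    PhysicalConstants,
    a_perp_from_distance,
)

__all__ = [
    "TheoryPrediction",
    "sbm_t2n",
    "slow_limit_t2n",
    "classify_regime",
    "max_resolvable_distance",
    "endor_snr_scaling",
    "predict",
]


@dataclass(frozen=True)
class TheoryPrediction:
    """Both limiting T2n predictions plus a regime diagnostic."""

    t2n_sbm: float
    t2n_slow: float
    regime: str
    ratio: float  # a_perp * T1e, dimensionless


def sbm_t2n(a_perp: float, S: float, T1e: float, omega_I: float) -> float:
    """SBM transverse nuclear relaxation time (s), fast-electron limit.

    1/T2n = (2 pi a_perp)^2 / 15 * S (S + 1) * [4 T1e + 3 T1e / (1 + omega_I^2 T1e^2)]

    ``a_perp`` in Hz (cyclic units), ``omega_I`` in rad/s.  Terms in T2e
    are negligible in this regime and omitted.
    """
    if min(a_perp, S, T1e, omega_I) <= 0:
        raise ValueError("all inputs must be positive")
    bracket = 4.0 * T1e + 3.0 * T1e / (1.0 + omega_I**2 * T1e**2)
    rate = (2.0 * np.pi * a_perp) ** 2 / 15.0 * S * (S + 1.0) * bracket
    return 1.0 / rate


def slow_limit_t2n(T1e: float) -> float:
    """Slow-relaxation-limit prediction T2n = 2 T1e (s)."""
    if T1e <= 0:
        raise ValueError("T1e must be positive")
    return 2.0 * T1e


def classify_regime(a_perp: float, T1e: float, factor: float = 10.0) -> str:
    """Classify the decoherence regime from 1/T1e versus a_perp.

    Returns "fast" when 1/T1e > factor * a_perp (SBM applies), "slow"
    when 1/T1e < a_perp / factor (T2n = 2 T1e applies), otherwise
    "intermediate".  ``factor`` sets the order-of-magnitude margin.
    """
    if min(a_perp, T1e, factor) <= 0:
        raise ValueError("all inputs must be positive")
    rate = 1.0 / T1e
    if rate > factor * a_perp:
        return "fast"
    if rate < a_perp / factor:
        return "slow"
    return "intermediate"


def max_resolvable_distance(
    rate: float,
    nucleus: NucleusSpec,
    ge: float = 1.992,
    constants: PhysicalConstants = CONSTANTS,
) -> float:
    """Largest distance (angstrom) whose doublet splitting resolves ``rate``.

    Solves a_perp(r) = rate for r analytically: r = (K / rate)^(1/3)
    with K the point-dipole constant, i.e. the distance at which the
    perpendicular hyperfine coupling equals the decoherence-limited
    linewidth.
    """
    if rate <= 0:
        raise ValueError("rate must be positive")
    K = a_perp_from_distance(1.0, nucleus, ge, constants)  # Hz at 1 angstrom
    return float((K / rate) ** (1.0 / 3.0))


def endor_snr_scaling(r1: float, r2: float) -> float:
    """Relative ENDOR-efficiency penalty (r2/r1)^6 when moving from r1 to r2."""
    if r1 <= 0 or r2 <= 0:
        raise ValueError("distances must be positive")
    return float((r2 / r1) ** 6)


def predict(
    a_perp: float, S: float, T1e: float, omega_I: float, factor: float = 10.0
) -> TheoryPrediction:
    """Evaluate both limiting theories and classify the regime."""
    return TheoryPrediction(
        t2n_sbm=sbm_t2n(a_perp, S, T1e, omega_I),
        t2n_slow=slow_limit_t2n(T1e),
        regime=classify_regime(a_perp, T1e, factor),
        ratio=a_perp * T1e,
    )
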