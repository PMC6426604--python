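"""Pseudo-first-order kinetics of the betalamic acid + l-DOPA condensation.

With l-DOPA held in large excess the second-order condensation
v = k*[bet]*[DOPA] behaves first-order in betalamic acid with apparent
constant k_app = k*[DOPA], so the product accumulates as

    [dopax](t) = [bet]0 * (1 - exp(-k_app * t)),

with mass balance [bet]0 = [bet] + [dopax] at every time. Two estimators of
k_app are provided: a slope-based one from fixed-time endpoints at varying
[bet]0, and a nonlinear fit to a single time course. The endpoint slope s of
dopax on bet0 (through the origin) satisfies s = 1 - exp(-k_app*t) and is
inverted as k_app = -ln(1 - s)/t.

Units: k in 1/h/M, k_app in 1/h, [DOPA] in M, concentrations in uM, time in h.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

__all__ = [
    "CondensationScheme",
    "CondensationEndpointSet",
    "dopax_accumulation",
    "estimate_k",
    "time_course_k",
]


@dataclass(frozen=True)
class CondensationScheme:
    """Second-order condensation constant and its pseudo-first-order form."""

    k: float  # 1/h/M
    DOPA_conc: float  # M, held fixed
    slope: float | None = None  # endpoint regression slope, if estimated
    n: int | None = None  # number of points used, if estimated

    def __post_init__(self) -> None:
        if self.k <= 0:
            raise ValueError("k must be positive")
        if self.DOPA_conc <= 0:
            raise ValueError("DOPA concentration must be positive")

    @property
    def k_app(self) -> float:
        """Apparent first-order constant k*[DOPA], 1/h."""
        return self.k * self.DOPA_conc

    @classmethod
    def from_k_app(cls, k_app: float, DOPA_conc: float, **kw) -> "CondensationScheme":
        return cls(k=k_app / DOPA_conc, DOPA_conc=DOPA_conc, **kw)


@dataclass(frozen=True)
class CondensationEndpointSet:
    """Dopaxanthin formed at a fixed time t from varying initial [bet]0."""

    bet0: np.ndarray  # uM
    dopax_at_t: np.ndarray  # uM
    t: float  # h

    def __post_init__(self) -> None:
        b = np.asarray(self.bet0, dtype=float)
        d = np.asarray(self.dopax_at_t, dtype=float)
        object.__setattr__(self, "bet0", b)
        object.__setattr__(self, "dopax_at_t", d)
        if b.ndim != 1 or d.ndim != 1 or len(b) != len(d):
            raise ValueError("bet0 and dopax_at_t must be 1-D arrays of equal length")
        if len(b) < 3:
            raise ValueError("need at least 3 endpoints")
        if self.t <= 0:
            raise ValueError("t must be positive")
        if np.any(d < 0) or np.any(d > b * (1 + 1e-9)):
            raise ValueError("mass balance violated: need 0 <= dopax <= bet0")


def dopax_accumulation(bet0, scheme: CondensationScheme, t):
    """Dopaxanthin concentration (uM) at time t (h) from initial [bet]0 (uM)."""
    bet0 = np.asarray(bet0, dtype=float)
    t = np.asarray(t, dtype=float)
    if np.any(bet0 < 0):
        raise ValueError("bet0 must be non-negative")
    if np.any(t < 0):
        raise ValueError("time must be non-negative")
    return bet0 * (1.0 - np.exp(-scheme.k_app * t))


def residual_betalamic(bet0, scheme: CondensationScheme, t):
    """Betalamic acid remaining at time t: bet0 - dopax (mass balance)."""
    return np.asarray(bet0, dtype=float) - dopax_accumulation(bet0, scheme, t)


def estimate_k(endpoints: CondensationEndpointSet, DOPA_conc: float) -> CondensationScheme:
    """Slope-based estimator of the second-order constant.

    Regresses dopax on bet0 through the origin; the slope s = 1-exp(-k_app*t)
    is inverted to k_app and divided by the fixed [DOPA] (M) to give k.
    """
    if DOPA_conc <= 0:
        raise ValueError("DOPA concentration must be positive")
    b, d = endpoints.bet0, endpoints.dopax_at_t
    if len(np.unique(b)) != len(b):
        raise ValueError("bet0 values must be distinct")
    s = float(np.dot(b, d) / np.dot(b, b))  # through-origin least squares
    if s <= 0:
        raise ValueError("no reaction: slope <= 0")
    if s >= 1:
        raise ValueError("slope >= 1 is impossible under mass balance; check data")
    k_app = -math.log1p(-s) / endpoints.t
    return CondensationScheme.from_k_app(k_app, DOPA_conc, slope=s, n=len(b))


def time_course_k(
    times,
    dopax,
    bet0: float,
    DOPA_conc: float,
) -> CondensationScheme:
    """Nonlinear fit of bet0*(1-exp(-k_app*t)) to a dopaxanthin time course."""
    times = np.asarray(times, dtype=float)
    dopax = np.asarray(dopax, dtype=float)
    if len(times) < 5:
        raise ValueError("need at least 5 time points")
    if DOPA_conc <= 0:
        raise ValueError("DOPA concentration must be positive")
    if np.all(dopax <= 0):
        raise ValueError("no reaction: dopaxanthin never positive")

    def model(t, k_app):
        return bet0 * (1.0 - np.exp(-k_app * t))

    # crude guess from the last point, clamped away from total conversion
    frac = min(max(dopax[-1] / bet0, 1e-6), 1 - 1e-9)
    k0 = -math.log1p(-frac) / max(times[-1], 1e-12)
    try:
        popt, _ = curve_fit(model, times, dopax, p0=[k0], bounds=(0, np.inf), maxfev=20000)
    except RuntimeError as exc:  # pragma: no cover
        raise RuntimeError(f"time-course fit did not converge: {exc}") from exc
    k_app = float(popt[0])
    if k_app <= 0:
        raise ValueError("no reaction: fitted k_app <= 0")
    return CondensationScheme.from_k_app(k_app, DOPA_conc, n=len(times))
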