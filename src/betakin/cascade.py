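"""ODE model of the full enzymatic-chemical cascade.

Six species are tracked (all in uM internally; time in hours):

    DOPA --enzyme--> 4,5-seco-DOPA --k_cyc45--> betalamic acid
         \\--enzyme--> 2,3-seco-DOPA --k_cyc23--> muscaflavin
    betalamic acid + DOPA --k_cond--> dopaxanthin

The enzymatic step uses the saturation rate laws from
:mod:`betakin.kinetics` (substrate inhibition when Ki is finite, otherwise
Michaelis-Menten) with a branching fraction ``phi45`` splitting flux between
the 4,5- and 2,3-ring-cleavage products. Cyclizations are lumped first-order
steps; the condensation is second-order and consumes one free DOPA per
dopaxanthin, so the conserved quantity is

    [DOPA] + [s45] + [s23] + [bet] + [mus] + 2*[dopax] = [DOPA]0.

The enzyme can be switched off at ``t_enzyme_off`` (e.g. oxygen exhaustion);
integration is split at the switch so the solver never sees a discontinuity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import least_squares

__all__ = [
    "SPECIES",
    "CascadeParams",
    "TimeCourse",
    "CurveSummary",
    "cascade_rhs",
    "simulate",
    "lag_time",
    "fit_cascade",
    "conservation_error",
]

#: Canonical species order used in state vectors and time-course matrices.
SPECIES: tuple[str, ...] = ("DOPA", "seco45", "seco23", "betalamic", "muscaflavin", "dopaxanthin")

#: Free parameters fit_cascade may vary.
_FITTABLE = ("Vmax", "Km", "Ki", "phi45", "k_cyc45", "k_cyc23", "k_cond")


@dataclass(frozen=True)
class CascadeParams:
    """Cascade rate constants and initial condition.

    Vmax in uM/min and Km/Ki in mM (the assay convention); they are converted
    to uM and hours internally. k_cyc* in 1/h, k_cond in 1/h/M, DOPA0 in mM.
    ``enzyme_scale`` multiplies Vmax (aeration proxy); ``t_enzyme_off`` stops
    the enzymatic step after that many hours (None = always active).
    """

    Vmax: float = 5.26  # uM/min
    Km: float = 1.36  # mM
    Ki: float = math.inf  # mM
    phi45: float = 0.5
    k_cyc45: float = 0.05  # 1/h
    k_cyc23: float = 0.025  # 1/h
    k_cond: float = 189.0  # 1/h/M
    DOPA0: float = 2.5  # mM
    enzyme_scale: float = 1.0
    t_enzyme_off: float | None = 5.0  # h

    def __post_init__(self) -> None:
        for name in ("Vmax", "Km", "k_cyc45", "k_cyc23", "k_cond", "DOPA0"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.Ki <= 0:
            raise ValueError("Ki must be positive (or math.inf)")
        if not 0.0 <= self.phi45 <= 1.0:
            raise ValueError("phi45 must lie in [0, 1]")
        if self.enzyme_scale < 0:
            raise ValueError("enzyme_scale must be non-negative")
        if self.t_enzyme_off is not None and self.t_enzyme_off < 0:
            raise ValueError("t_enzyme_off must be non-negative")


@dataclass(frozen=True)
class TimeCourse:
    """Concentrations (uM) of cascade species on a strictly increasing time
    grid (h). ``data`` has shape (len(times), len(species))."""

    times: np.ndarray
    data: np.ndarray
    species: tuple[str, ...] = SPECIES

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        y = np.asarray(self.data, dtype=float)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "data", y)
        object.__setattr__(self, "species", tuple(self.species))
        if t.ndim != 1 or np.any(np.diff(t) <= 0):
            raise ValueError("times must be 1-D and strictly increasing")
        if y.shape != (len(t), len(self.species)):
            raise ValueError("data shape must be (n_times, n_species)")

    def __getitem__(self, name: str) -> np.ndarray:
        return self.data[:, self.species.index(name)]

    def normalized(self) -> "TimeCourse":
        """Each species scaled to its own maximum (zero-max species left as-is)."""
        maxima = self.data.max(axis=0)
        scale = np.where(maxima > 0, maxima, 1.0)
        return replace(self, data=self.data / scale)


@dataclass(frozen=True)
class CurveSummary:
    """Lag, peak and monotonicity summary of one species' time course.

    ``lag`` is the time-axis intercept of the tangent at the point of maximal
    rate (clipped at 0); None when undefined (flat curve). ``t_peak`` is the
    time of the discrete maximum, None for monotone curves.
    """

    lag: float | None
    t_peak: float | None
    peak_value: float | None
    monotone: bool


def _enzyme_rate(D: float, vmax_uM_h: float, Km_uM: float, Ki_uM: float) -> float:
    if D <= 0 or vmax_uM_h == 0:
        return 0.0
    denom = Km_uM + D * (1.0 + D / Ki_uM) if math.isfinite(Ki_uM) else Km_uM + D
    return vmax_uM_h * D / denom


def cascade_rhs(state, p: CascadeParams, enzyme_on: bool = True):
    """Time derivative of the six-species state (uM, h).

    Pure function of state; the enzyme switch is resolved by the caller.
    """
    D, s45, s23, bet, mus, dopax = state
    vmax = p.Vmax * 60.0 * p.enzyme_scale if enzyme_on else 0.0
    v_enz = _enzyme_rate(D, vmax, p.Km * 1e3, p.Ki * 1e3)
    v_cond = p.k_cond * 1e-6 * max(bet, 0.0) * max(D, 0.0)  # k_cond per uM
    return np.array([
        -v_enz - v_cond,
        p.phi45 * v_enz - p.k_cyc45 * s45,
        (1.0 - p.phi45) * v_enz - p.k_cyc23 * s23,
        p.k_cyc45 * s45 - v_cond,
        p.k_cyc23 * s23,
        v_cond,
    ])


def _integrate(p: CascadeParams, y0, t_span, t_eval, enzyme_on, rtol, atol):
    sol = solve_ivp(
        lambda t, y: cascade_rhs(y, p, enzyme_on=enzyme_on),
        t_span, y0, method="LSODA", t_eval=t_eval, rtol=rtol, atol=atol,
    )
    if not sol.success:  # pragma: no cover - solver diagnostics path
        raise RuntimeError(f"cascade integration failed: {sol.message}")
    return sol


def simulate(
    p: CascadeParams,
    times,
    rtol: float = 1e-8,
    atol: float = 1e-10,
) -> TimeCourse:
    """Integrate the cascade on the given time grid (hours).

    The initial state is pure DOPA at ``p.DOPA0`` (converted to uM). If
    ``t_enzyme_off`` falls inside the grid the integration is split there.
    """
    times = np.asarray(times, dtype=float)
    if times.ndim != 1 or len(times) < 2 or np.any(np.diff(times) <= 0):
        raise ValueError("times must be strictly increasing with span > 0")
    if times[0] < 0:
        raise ValueError("times must be non-negative")
    y0 = np.array([p.DOPA0 * 1e3, 0.0, 0.0, 0.0, 0.0, 0.0])

    t_off = p.t_enzyme_off
    if t_off is None or t_off >= times[-1]:
        sol = _integrate(p, y0, (times[0], times[-1]), times, True, rtol, atol)
        data = sol.y.T
    elif t_off <= times[0]:
        sol = _integrate(p, y0, (times[0], times[-1]), times, False, rtol, atol)
        data = sol.y.T
    else:
        before = times[times <= t_off]
        after = times[times > t_off]
        sol1 = _integrate(p, y0, (times[0], t_off), before, True, rtol, atol)
        # restart exactly at the switch with the phase-1 terminal state
        y_mid = _integrate(p, y0, (times[0], t_off), None, True, rtol, atol).y[:, -1]
        sol2 = _integrate(p, y_mid, (t_off, times[-1]), after, False, rtol, atol)
        data = np.vstack([sol1.y.T, sol2.y.T])
    return TimeCourse(times=times, data=np.clip(data, 0.0, None))


def conservation_error(course: TimeCourse) -> float:
    """Max relative drift of [DOPA]+[s45]+[s23]+[bet]+[mus]+2*[dopax]."""
    weights = np.array([2.0 if s == "dopaxanthin" else 1.0 for s in course.species])
    total = course.data @ weights
    return float(np.max(np.abs(total - total[0])) / total[0])


def lag_time(times, values, monotone_tol: float = 1e-9) -> CurveSummary:
    """Summarize a single-species curve: tangent-intercept lag, peak, monotonicity.

    The lag is where the tangent at the point of maximal (finite-difference)
    rate crosses the time axis, clipped at zero — the standard growth-curve
    construction. A flat (all-constant) curve has no defined lag.
    """
    times = np.asarray(times, dtype=float)
    values = np.asarray(values, dtype=float)
    if len(times) < 5:
        raise ValueError("need at least 5 points")
    if np.any(values < -1e-12):
        raise ValueError("values must be non-negative")

    diffs = np.diff(values)
    scale = max(np.max(np.abs(values)), 1.0)
    monotone = bool(np.all(diffs >= -monotone_tol * scale))

    if np.ptp(values) == 0:
        return CurveSummary(lag=None, t_peak=None, peak_value=None, monotone=monotone)

    rate = np.gradient(values, times)
    i = int(np.argmax(rate))
    lag = times[i] - values[i] / rate[i] if rate[i] > 0 else None
    if lag is not None:
        lag = max(lag, 0.0)

    i_max = int(np.argmax(values))
    if monotone or i_max == len(values) - 1:
        t_peak, peak_value = None, None
    else:
        t_peak, peak_value = float(times[i_max]), float(values[i_max])
    return CurveSummary(lag=lag, t_peak=t_peak, peak_value=peak_value, monotone=monotone)


def fit_cascade(
    course: TimeCourse,
    free: list[str],
    fixed: CascadeParams,
    rtol: float = 1e-8,
    atol: float = 1e-10,
) -> CascadeParams:
    """Least-squares fit of selected cascade parameters by repeated simulation.

    ``free`` names up to 4 parameters from Vmax/Km/Ki/phi45/k_cyc45/k_cyc23/
    k_cond to optimize; the rest are taken from ``fixed``. All observed
    species columns in ``course`` enter the objective. Raises when the
    objective is flat around the optimum (non-identifiable configuration).
    """
    if not free or len(free) > 4:
        raise ValueError("free must name 1-4 parameters")
    for name in free:
        if name not in _FITTABLE:
            raise ValueError(f"cannot fit parameter {name!r}")
    obs_idx = [SPECIES.index(s) for s in course.species]
    obs = course.data
    scale = max(obs.max(), 1.0)

    def unpack(x) -> CascadeParams:
        kw = dict(zip(free, np.abs(x)))
        if "phi45" in kw:
            kw["phi45"] = min(kw["phi45"], 1.0)
        return replace(fixed, **kw)

    def residuals(x):
        sim = simulate(unpack(x), course.times, rtol=rtol, atol=atol)
        return ((sim.data[:, obs_idx] - obs) / scale).ravel()

    x0 = np.array([getattr(fixed, name) for name in free], dtype=float)
    x0 = np.where(x0 > 0, x0, 0.1)
    result = least_squares(residuals, x0, method="lm", xtol=1e-12, ftol=1e-12)
    if not result.success:  # pragma: no cover
        raise RuntimeError(f"cascade fit did not converge: {result.message}")
    # flat-objective guard: perturbing each free parameter must move the fit
    base_cost = result.cost
    for j in range(len(free)):
        x_pert = result.x.copy()
        x_pert[j] *= 1.5
        x_pert[j] += 0.05
        pert_cost = 0.5 * np.sum(residuals(x_pert) ** 2)
        if pert_cost <= base_cost * (1 + 1e-9) + 1e-30:
            raise RuntimeError(f"non-identifiable configuration: flat objective in {free[j]}")
    return unpack(result.x)
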