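"""Saturation-curve models and nonlinear fitting for the dioxygenase.

Two rate laws are supported: classical Michaelis-Menten (MM) and the
canonical uncompetitive excess-substrate inhibition form (SI),

    v = Vmax * S / (Km + S * (1 + S/Ki)),

which reduces to MM as Ki -> infinity. Units follow the experimental
convention: substrate in mM, rates in uM/min. Conversions belong at I/O.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import curve_fit

__all__ = [
    "SaturationCurve",
    "KineticParams",
    "mm_rate",
    "si_rate",
    "fit_saturation",
    "derive_constants",
]


@dataclass(frozen=True)
class SaturationCurve:
    """Initial-rate saturation data: substrate (mM) vs rate (uM/min)."""

    substrate_conc: np.ndarray
    rate: np.ndarray
    substrate_name: str = "substrate"

    def __post_init__(self) -> None:
        s = np.asarray(self.substrate_conc, dtype=float)
        v = np.asarray(self.rate, dtype=float)
        object.__setattr__(self, "substrate_conc", s)
        object.__setattr__(self, "rate", v)
        if s.ndim != 1 or v.ndim != 1 or len(s) != len(v):
            raise ValueError("substrate and rate must be 1-D arrays of equal length")
        if len(s) < 4:
            raise ValueError("need at least 4 data points")
        if np.any(s <= 0):
            raise ValueError("substrate concentrations must be strictly positive")
        if np.any(np.diff(s) <= 0):
            raise ValueError("substrate concentrations must be strictly increasing")
        if np.any(v < 0):
            raise ValueError("rates must be non-negative")

    def __len__(self) -> int:
        return len(self.substrate_conc)


@dataclass(frozen=True)
class KineticParams:
    """Kinetic constants with optional standard errors.

    Km in mM, Vmax in uM/min, Ki in mM (``math.inf`` disables substrate
    inhibition), enzyme concentration in uM. ``kcat`` (1/min) and
    ``specificity`` (1/min/mM) are derived when the enzyme concentration is
    known.
    """

    Km: float
    Vmax: float
    Ki: float = math.inf
    enzyme_conc: float | None = None
    kcat: float | None = None
    specificity: float | None = None
    stderr: dict[str, float] = field(default_factory=dict)
    rss: float | None = None
    model: str = "MM"

    def __post_init__(self) -> None:
        if self.Km <= 0:
            raise ValueError("Km must be positive")
        if self.Vmax <= 0:
            raise ValueError("Vmax must be positive")
        if self.Ki <= 0:
            raise ValueError("Ki must be positive (or math.inf)")


def mm_rate(S, p: KineticParams):
    """Michaelis-Menten rate Vmax*S/(Km+S); vectorized over S (mM)."""
    S = np.asarray(S, dtype=float)
    if np.any(S < 0):
        raise ValueError("substrate concentration must be non-negative")
    return p.Vmax * S / (p.Km + S)


def si_rate(S, p: KineticParams):
    """Excess-substrate-inhibition rate Vmax*S/(Km + S*(1+S/Ki))."""
    S = np.asarray(S, dtype=float)
    if np.any(S < 0):
        raise ValueError("substrate concentration must be non-negative")
    if math.isinf(p.Ki):
        return mm_rate(S, p)
    return p.Vmax * S / (p.Km + S * (1.0 + S / p.Ki))


def _mm_model(S, Km, Vmax):
    return Vmax * S / (Km + S)


def _si_model(S, Km, Vmax, Ki):
    return Vmax * S / (Km + S * (1.0 + S / Ki))


def _initial_guesses(curve: SaturationCurve, model: str) -> list[float]:
    # Vmax0: max observed rate; Km0: S at half-Vmax0 (interpolated); Ki0: max S.
    s, v = curve.substrate_conc, curve.rate
    vmax0 = float(np.max(v))
    if vmax0 <= 0:
        raise ValueError("degenerate data: all rates are zero")
    half = vmax0 / 2.0
    km0 = float(np.interp(half, v, s)) if np.any(v >= half) else float(np.median(s))
    km0 = max(km0, float(s[0]) * 0.1)
    if model == "SI":
        return [km0, vmax0, float(s[-1])]
    return [km0, vmax0]


def fit_saturation(
    curve: SaturationCurve,
    model: str = "MM",
    weighting: str = "none",
) -> KineticParams:
    """Least-squares fit of a saturation curve.

    ``model`` is ``"MM"`` or ``"SI"``; ``weighting`` is ``"none"`` (ordinary
    least squares, the default) or ``"relative"`` (residuals scaled by the
    observed rate). Returns parameter estimates with asymptotic standard
    errors and the residual sum of squares.
    """
    model = model.upper()
    if model not in ("MM", "SI"):
        raise ValueError(f"unknown model {model!r}; expected 'MM' or 'SI'")
    if weighting not in ("none", "relative"):
        raise ValueError(f"unknown weighting {weighting!r}")
    if model == "SI" and len(curve) < 5:
        raise ValueError("SI fit requires at least 5 data points")
    if np.ptp(curve.rate) == 0:
        raise ValueError("degenerate data: constant rates")

    s, v = curve.substrate_conc, curve.rate
    p0 = _initial_guesses(curve, model)
    f = _mm_model if model == "MM" else _si_model
    sigma = None
    if weighting == "relative":
        sigma = np.where(v > 0, v, np.max(v))
    try:
        popt, pcov = curve_fit(
            f, s, v, p0=p0, sigma=sigma,
            bounds=(0, np.inf), maxfev=20000,
        )
    except RuntimeError as exc:  # pragma: no cover - pathological data
        raise RuntimeError(f"saturation fit did not converge: {exc}") from exc

    perr = np.sqrt(np.diag(pcov))
    residuals = v - f(s, *popt)
    rss = float(np.sum(residuals**2))
    names = ["Km", "Vmax"] + (["Ki"] if model == "SI" else [])
    stderr = {n: float(e) for n, e in zip(names, perr)}
    return KineticParams(
        Km=float(popt[0]),
        Vmax=float(popt[1]),
        Ki=float(popt[2]) if model == "SI" else math.inf,
        stderr=stderr,
        rss=rss,
        model=model,
    )


def derive_constants(p: KineticParams, enzyme_conc: float) -> KineticParams:
    """Derive kcat = Vmax/[E] and the specificity constant kcat/Km.

    ``enzyme_conc`` in uM; Vmax in uM/min gives kcat in 1/min. Uncertainties
    are propagated to first order assuming independent Km and Vmax errors.
    """
    if enzyme_conc <= 0:
        raise ValueError("enzyme concentration must be positive")
    kcat = p.Vmax / enzyme_conc
    specificity = kcat / p.Km
    stderr = dict(p.stderr)
    if "Vmax" in stderr:
        stderr["kcat"] = stderr["Vmax"] / enzyme_conc
        # relative errors add in quadrature for a ratio
        rel_v = stderr["Vmax"] / p.Vmax
        rel_k = stderr.get("Km", 0.0) / p.Km
        stderr["specificity"] = specificity * math.hypot(rel_v, rel_k)
    return replace(
        p,
        enzyme_conc=enzyme_conc,
        kcat=kcat,
        specificity=specificity,
        stderr=stderr,
    )
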