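"""Seeded synthetic-data generators for every pipeline input.

Noise is multiplicative Gaussian: value * (1 + eps), eps ~ N(0, cv^2)
truncated at -0.95 so generated concentrations stay positive. All generators
are pure functions of (truth, config): the same seed reproduces the output
bit for bit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .cascade import CascadeParams, TimeCourse, simulate
from .condensation import CondensationEndpointSet, CondensationScheme, dopax_accumulation
from .kinetics import KineticParams, SaturationCurve, mm_rate, si_rate

__all__ = [
    "GeneratorConfig",
    "gen_saturation",
    "gen_condensation",
    "gen_condensation_course",
    "gen_cascade",
]


def _default_substrate_grid() -> np.ndarray:
    # assay design: up to the 7.6 mM solubility limit
    return np.linspace(0.1, 7.6, 12)


def _default_bet0_grid() -> np.ndarray:
    return np.array([25.0, 50.0, 75.0, 100.0])


def _default_time_grid() -> np.ndarray:
    return np.linspace(0.0, 30.0, 61)


@dataclass(frozen=True)
class GeneratorConfig:
    """Seed, noise level and design grids shared by all generators."""

    seed: int = 0
    noise_cv: float = 0.05
    substrate_grid: np.ndarray = field(default_factory=_default_substrate_grid)
    bet0_grid: np.ndarray = field(default_factory=_default_bet0_grid)
    time_grid: np.ndarray = field(default_factory=_default_time_grid)
    endpoint_t: float = 12.0  # h, fixed endpoint sampling time
    normalize: bool = False  # per-species max-normalization of cascade output

    def __post_init__(self) -> None:
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be non-negative")
        for name in ("substrate_grid", "bet0_grid", "time_grid"):
            g = np.asarray(getattr(self, name), dtype=float)
            object.__setattr__(self, name, g)
            if len(g) >= 2 and np.any(np.diff(g) <= 0):
                raise ValueError(f"{name} must be strictly increasing")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


def _noisy(values: np.ndarray, rng: np.random.Generator, cv: float) -> np.ndarray:
    if cv == 0:
        return values.copy()
    eps = np.maximum(rng.normal(0.0, cv, size=values.shape), -0.95)
    return values * (1.0 + eps)


def gen_saturation(truth: KineticParams, cfg: GeneratorConfig) -> SaturationCurve:
    """Noisy saturation curve from MM (Ki infinite) or SI (Ki finite) truth."""
    s = cfg.substrate_grid
    model = mm_rate if math.isinf(truth.Ki) else si_rate
    v = np.asarray(model(s, truth), dtype=float)
    v = np.clip(_noisy(v, cfg.rng(), cfg.noise_cv), 0.0, None)
    return SaturationCurve(substrate_conc=s, rate=v)


def gen_condensation(truth: CondensationScheme, cfg: GeneratorConfig) -> CondensationEndpointSet:
    """Fixed-time condensation endpoints over the bet0 design grid."""
    bet0 = cfg.bet0_grid
    dopax = np.asarray(dopax_accumulation(bet0, truth, cfg.endpoint_t), dtype=float)
    dopax = _noisy(dopax, cfg.rng(), cfg.noise_cv)
    dopax = np.clip(dopax, 0.0, bet0)  # mass balance survives the noise
    return CondensationEndpointSet(bet0=bet0, dopax_at_t=dopax, t=cfg.endpoint_t)


def gen_condensation_course(
    truth: CondensationScheme,
    cfg: GeneratorConfig,
    bet0: float = 100.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Dopaxanthin time course (times_h, dopax_uM) at fixed initial bet0."""
    t = cfg.time_grid
    dopax = np.asarray(dopax_accumulation(bet0, truth, t), dtype=float)
    dopax = np.clip(_noisy(dopax, cfg.rng(), cfg.noise_cv), 0.0, bet0)
    return t, dopax


def gen_cascade(truth: CascadeParams, cfg: GeneratorConfig) -> TimeCourse:
    """Simulated cascade sampled on the time grid with per-species noise."""
    grid = cfg.time_grid
    if grid[0] < 0:
        raise ValueError("time grid must be non-negative")
    course = simulate(truth, grid)
    data = _noisy(course.data, cfg.rng(), cfg.noise_cv)
    data = np.clip(data, 0.0, None)
    out = TimeCourse(times=course.times, data=data, species=course.species)
    return out.normalized() if cfg.normalize else out
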