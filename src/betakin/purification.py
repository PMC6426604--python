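"""Purification-table arithmetic and absorbance-based quantification."""

from __future__ import annotations

from dataclasses import dataclass, replace

__all__ = ["PurificationStep", "derive_table", "beer_lambert_conc"]


@dataclass(frozen=True)
class PurificationStep:
    """One purification step with measured and derived quantities.

    Measured: volume (ml), protein_conc (mg/ml), activity (uM/min per assay)
    and optionally a directly determined specific activity (umol/min/mg).
    Derived by :func:`derive_table`: total protein (mg), total activity
    (activity x volume), purification fold and percent yield relative to the
    first step. ``fold``/``yield_pct`` are rounded for presentation;
    ``fold_exact``/``yield_exact`` keep full precision.
    """

    name: str
    volume: float
    protein_conc: float
    activity: float
    specific_activity: float | None = None
    total_protein: float | None = None
    total_activity: float | None = None
    fold: float | None = None
    yield_pct: float | None = None
    fold_exact: float | None = None
    yield_exact: float | None = None

    def __post_init__(self) -> None:
        if self.volume <= 0:
            raise ValueError("volume must be positive")
        if self.protein_conc < 0:
            raise ValueError("protein concentration must be non-negative")
        if self.activity < 0:
            raise ValueError("activity must be non-negative")


def derive_table(steps: list[PurificationStep]) -> list[PurificationStep]:
    """Fill in derived columns; the first step is the 100%/1.0-fold reference.

    total_protein = volume x protein_conc; total_activity = activity x volume;
    fold = specific activity over the reference's (1 decimal); yield = percent
    of reference total activity (integer). When a step has no directly given
    specific activity it is derived as total_activity / total_protein.
    """
    if not steps:
        raise ValueError("need at least one step")

    def spec_act(s: PurificationStep, total_act: float, total_prot: float) -> float:
        if s.specific_activity is not None:
            return s.specific_activity
        if total_prot <= 0:
            raise ValueError(f"step {s.name!r}: cannot derive specific activity")
        return total_act / total_prot

    ref = steps[0]
    ref_total_act = ref.activity * ref.volume
    if ref_total_act <= 0:
        raise ValueError("reference step has zero total activity")
    ref_spec = spec_act(ref, ref_total_act, ref.volume * ref.protein_conc)

    out = []
    for s in steps:
        total_prot = s.volume * s.protein_conc
        total_act = s.activity * s.volume
        sa = spec_act(s, total_act, total_prot)
        fold_exact = sa / ref_spec
        yield_exact = 100.0 * total_act / ref_total_act
        out.append(
            replace(
                s,
                specific_activity=sa,
                total_protein=total_prot,
                total_activity=total_act,
                fold_exact=fold_exact,
                yield_exact=yield_exact,
                fold=round(fold_exact, 1),
                yield_pct=float(round(yield_exact)),
            )
        )
    return out


def beer_lambert_conc(absorbance: float, epsilon: float = 24000.0, path: float = 1.0) -> float:
    """Concentration (uM) from absorbance via Beer-Lambert.

    ``epsilon`` in 1/M/cm (default: betalamic acid at 424 nm), ``path`` in cm.
    """
    if absorbance < 0:
        raise ValueError("absorbance must be non-negative")
    if epsilon <= 0:
        raise ValueError("epsilon must be positive")
    if path <= 0:
        raise ValueError("path length must be positive")
    return absorbance / (epsilon * path) * 1e6
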