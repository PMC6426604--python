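"""Exact-mass arithmetic: chemical formulas, tryptic digestion and
peptide-mass-fingerprint matching.

All masses are monoisotopic and expressed in daltons. Reported ion masses are
singly protonated ([M+H]+); multiply charged species are out of scope.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

__all__ = [
    "MONOISOTOPIC_MASS",
    "PROTON_MASS",
    "WATER_MASS",
    "RESIDUE_MASS",
    "CARBAMIDOMETHYL",
    "ChemicalFormula",
    "Peptide",
    "TrypticFragment",
    "MassMatch",
    "PMFResult",
    "parse_formula",
    "monoisotopic_mass",
    "protonated_mz",
    "ppm_error",
    "tryptic_digest",
    "peptide_mh",
    "pmf_match",
]

#: Monoisotopic atomic masses (Da) of the elements accepted in formulas.
MONOISOTOPIC_MASS: dict[str, float] = {
    "C": 12.000000,
    "H": 1.0078250319,
    "N": 14.0030740052,
    "O": 15.9949146221,
    "S": 31.97207069,
}

#: Mass of a proton (Da); added for [M+H]+ ions.
PROTON_MASS: float = 1.00727646

#: Monoisotopic mass of water, released/added at peptide bonds.
WATER_MASS: float = 2 * MONOISOTOPIC_MASS["H"] + MONOISOTOPIC_MASS["O"]

#: Monoisotopic residue masses (Da) of the 20 standard amino acids.
RESIDUE_MASS: dict[str, float] = {
    "G": 57.02146,
    "A": 71.03711,
    "S": 87.03203,
    "P": 97.05276,
    "V": 99.06841,
    "T": 101.04768,
    "C": 103.00919,
    "L": 113.08406,
    "I": 113.08406,
    "N": 114.04293,
    "D": 115.02694,
    "Q": 128.05858,
    "K": 128.09496,
    "E": 129.04259,
    "M": 131.04049,
    "H": 137.05891,
    "F": 147.06841,
    "R": 156.10111,
    "Y": 163.06333,
    "W": 186.07931,
}

#: Carbamidomethylation of cysteine (iodoacetamide alkylation), Da.
CARBAMIDOMETHYL: float = 57.02146

#: Default fixed modifications applied during digestion.
DEFAULT_FIXED_MODS: dict[str, float] = {"C": CARBAMIDOMETHYL}

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


@dataclass(frozen=True)
class ChemicalFormula:
    """Element -> count map for a neutral molecule.

    Only C, H, N, O and S are accepted; counts are non-negative and at least
    one element must be present.
    """

    counts: dict[str, int]

    def __post_init__(self) -> None:
        if not self.counts:
            raise ValueError("formula must contain at least one element")
        for element, count in self.counts.items():
            if element not in MONOISOTOPIC_MASS:
                raise ValueError(f"unknown element symbol: {element!r}")
            if not isinstance(count, int) or count < 0:
                raise ValueError(f"count for {element} must be a non-negative integer")

    def hill(self) -> str:
        """Canonical Hill-order string: C first, H second, then alphabetical."""
        order = ["C", "H"] + sorted(e for e in self.counts if e not in ("C", "H"))
        parts = []
        for element in order:
            n = self.counts.get(element, 0)
            if n == 0:
                continue
            parts.append(element if n == 1 else f"{element}{n}")
        return "".join(parts)

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.hill()


def parse_formula(text: str) -> ChemicalFormula:
    """Parse a formula string such as ``"C9H11NO6"`` (omitted count = 1)."""
    if not text or not text.strip():
        raise ValueError("empty formula string")
    text = text.strip()
    counts: dict[str, int] = {}
    pos = 0
    while pos < len(text):
        m = _FORMULA_TOKEN.match(text, pos)
        if m is None or m.start() != pos or not m.group(1):
            raise ValueError(f"malformed formula at position {pos}: {text!r}")
        element = m.group(1)
        if element not in MONOISOTOPIC_MASS:
            raise ValueError(f"unknown element symbol {element!r} in {text!r}")
        count = int(m.group(2)) if m.group(2) else 1
        counts[element] = counts.get(element, 0) + count
        pos = m.end()
    return ChemicalFormula(counts)


def monoisotopic_mass(formula: ChemicalFormula | str) -> float:
    """Monoisotopic mass (Da) of a neutral molecule."""
    if isinstance(formula, str):
        formula = parse_formula(formula)
    return sum(MONOISOTOPIC_MASS[e] * n for e, n in formula.counts.items())


def protonated_mz(formula: ChemicalFormula | str) -> float:
    """[M+H]+ m/z of a neutral molecule (singly charged)."""
    return monoisotopic_mass(formula) + PROTON_MASS


def ppm_error(experimental: float, theoretical: float) -> float:
    """Signed relative mass error in parts per million."""
    if theoretical <= 0:
        raise ValueError("theoretical mass must be positive")
    if experimental <= 0:
        raise ValueError("experimental mass must be positive")
    return (experimental - theoretical) / theoretical * 1e6


@dataclass(frozen=True)
class Peptide:
    """A peptide or protein sequence with optional fixed modifications.

    ``fixed_mods`` maps a residue code to a mass shift in Da applied to every
    occurrence of that residue.
    """

    sequence: str
    fixed_mods: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_FIXED_MODS))

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError("sequence must be non-empty")
        bad = set(self.sequence) - set(RESIDUE_MASS)
        if bad:
            raise ValueError(f"invalid residue code(s): {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class TrypticFragment:
    """A digestion product with its position in the parent sequence.

    ``start``/``end`` are 0-based half-open indices into the parent;
    ``missed`` counts internal uncleaved K/R sites.
    """

    peptide: Peptide
    start: int
    end: int
    missed: int

    @property
    def sequence(self) -> str:
        return self.peptide.sequence


@dataclass(frozen=True)
class MassMatch:
    """Pairing of an observed m/z with a theoretical one."""

    experimental_mz: float
    theoretical_mz: float | None
    fragment: TrypticFragment | None = None

    @property
    def matched(self) -> bool:
        return self.theoretical_mz is not None

    @property
    def delta_ppm(self) -> float | None:
        if self.theoretical_mz is None:
            return None
        return ppm_error(self.experimental_mz, self.theoretical_mz)


@dataclass(frozen=True)
class PMFResult:
    """Peptide-mass-fingerprint matching outcome."""

    matches: list[MassMatch]
    coverage: float  # fraction of parent residues covered by matched fragments

    @property
    def n_matched(self) -> int:
        return sum(1 for m in self.matches if m.matched)


def _cleavage_sites(sequence: str) -> list[int]:
    # Keil rule: cleave C-terminal of K or R unless the next residue is P.
    sites = []
    for i in range(len(sequence) - 1):
        if sequence[i] in "KR" and sequence[i + 1] != "P":
            sites.append(i + 1)
    return sites


def tryptic_digest(protein: Peptide | str, missed_cleavages: int = 0) -> list[TrypticFragment]:
    """In-silico trypsin digestion.

    Cleaves after K/R except before P. Returns every fragment with at most
    ``missed_cleavages`` internal uncleaved sites, ordered by (missed count,
    position). The 0-missed fragments partition the input sequence.
    """
    if missed_cleavages < 0:
        raise ValueError("missed_cleavages must be >= 0")
    if isinstance(protein, str):
        protein = Peptide(protein)
    seq = protein.sequence
    bounds = [0] + _cleavage_sites(seq) + [len(seq)]
    fragments: list[TrypticFragment] = []
    for missed in range(missed_cleavages + 1):
        for i in range(len(bounds) - 1 - missed):
            start, end = bounds[i], bounds[i + 1 + missed]
            fragments.append(
                TrypticFragment(
                    peptide=Peptide(seq[start:end], fixed_mods=protein.fixed_mods),
                    start=start,
                    end=end,
                    missed=missed,
                )
            )
    return fragments


def peptide_mh(peptide: Peptide | str) -> float:
    """Monoisotopic [M+H]+ m/z of a peptide: residues + water + proton + mods."""
    if isinstance(peptide, str):
        peptide = Peptide(peptide)
    mass = WATER_MASS + PROTON_MASS
    for residue in peptide.sequence:
        mass += RESIDUE_MASS[residue]
        mass += peptide.fixed_mods.get(residue, 0.0)
    return mass


def pmf_match(
    observed: list[float],
    protein: Peptide | str,
    tol_ppm: float = 50.0,
    missed_cleavages: int = 1,
) -> PMFResult:
    """Match observed [M+H]+ masses against an in-silico tryptic digest.

    Each observed mass is paired with the closest theoretical fragment within
    ``tol_ppm``; unmatched masses are flagged. Coverage is the fraction of
    parent residues spanned by at least one matched fragment.
    """
    if not observed:
        raise ValueError("observed mass list must be non-empty")
    if tol_ppm <= 0:
        raise ValueError("tol_ppm must be positive")
    if isinstance(protein, str):
        protein = Peptide(protein)
    fragments = tryptic_digest(protein, missed_cleavages)
    theoretical = [(peptide_mh(f.peptide), f) for f in fragments]

    matches: list[MassMatch] = []
    covered = [False] * len(protein.sequence)
    for mz in observed:
        best: tuple[float, TrypticFragment] | None = None
        for theo, frag in theoretical:
            if abs(ppm_error(mz, theo)) <= tol_ppm:
                if best is None or abs(mz - theo) < abs(mz - best[0]):
                    best = (theo, frag)
        if best is None:
            matches.append(MassMatch(experimental_mz=mz, theoretical_mz=None))
        else:
            theo, frag = best
            matches.append(MassMatch(experimental_mz=mz, theoretical_mz=theo, fragment=frag))
            for i in range(frag.start, frag.end):
                covered[i] = True
    coverage = sum(covered) / len(covered)
    return PMFResult(matches=matches, coverage=coverage)
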