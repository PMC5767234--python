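"""Elemental-formula arithmetic for isotope-labeling analysis.

Parsing Hill-notation formulas, monoisotopic masses for the adducts seen in
LC-MS metabolomics of small molecules ([M], [M+H]+, [M-H]-), mass-accuracy
errors in ppm, natural-abundance isotopologue (mass-shift) distributions, and
the correction matrix used to strip natural-isotope contributions from a
measured isotopologue ladder before quantifying tracer incorporation.

Mass shifts are aggregated by nominal shift (unit Da), which matches
unit-resolution isotopologue extraction on QTOF data; fine isotopic structure
is out of scope.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np

from .isotopes import ISOTOPES, PROTON_MASS, TRACER_ELEMENT

__all__ = [
    "ElementalFormula",
    "FormulaError",
    "parse_formula",
    "monoisotopic_mass",
    "ppm_error",
    "natural_isotopologue_distribution",
    "correction_matrix",
]

_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")

ADDUCTS = {"M": 0.0, "M+H": +PROTON_MASS, "M-H": -PROTON_MASS}


class FormulaError(ValueError):
    """Raised for malformed or unsupported elemental formulas."""


@dataclass(frozen=True)
class ElementalFormula:
    """An element -> count map, e.g. ``{"C": 18, "H": 14, "O": 5}``.

    All counts are non-negative and at least one element is present.  The
    carbon count defines the length (N+1) of any associated mass isotopomer
    distribution.
    """

    counts: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        clean = {el: int(n) for el, n in self.counts.items() if int(n) != 0}
        if not clean:
            raise FormulaError("formula must contain at least one atom")
        for el, n in clean.items():
            if el not in ISOTOPES:
                raise FormulaError(f"unknown element symbol {el!r}")
            if n < 0:
                raise FormulaError(f"negative count for element {el!r}")
        object.__setattr__(self, "counts", clean)

    @property
    def n_carbon(self) -> int:
        return self.counts.get("C", 0)

    def hill(self) -> str:
        """Canonical Hill-order string (C first, H second, rest alphabetical)."""
        parts = []
        for el in ["C", "H"] + sorted(set(self.counts) - {"C", "H"}):
            n = self.counts.get(el, 0)
            if n:
                parts.append(el + (str(n) if n > 1 else ""))
        return "".join(parts)

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.hill()


def parse_formula(text: str) -> ElementalFormula:
    """Parse a Hill-notation formula string like ``"C24H45NO9"``.

    Counts are optional (absent means 1).  Repeated element symbols
    accumulate.  Raises :class:`FormulaError` naming the offending token on
    unknown symbols or garbage input.
    """
    if not isinstance(text, str) or not text.strip():
        raise FormulaError("empty formula string")
    s = text.strip()
    counts: dict[str, int] = {}
    pos = 0
    while pos < len(s):
        m = _TOKEN.match(s, pos)
        if not m:
            raise FormulaError(f"unparsable token at {s[pos:]!r} in formula {text!r}")
        el, digits = m.groups()
        if el not in ISOTOPES:
            raise FormulaError(f"unknown element symbol {el!r} in formula {text!r}")
        counts[el] = counts.get(el, 0) + (int(digits) if digits else 1)
        pos = m.end()
    return ElementalFormula(counts)


def monoisotopic_mass(f: ElementalFormula, adduct: str = "M") -> float:
    """Monoisotopic mass in Da of a formula, optionally as [M+H]+ or [M-H]-.

    Uses the lightest isotope of each element; charged adducts add or remove
    a proton (proton-mass convention, electron mass included).
    """
    if adduct not in ADDUCTS:
        raise ValueError(
            f"unknown adduct {adduct!r}; supported adducts: {sorted(ADDUCTS)}"
        )
    mass = sum(ISOTOPES[el][0][0] * n for el, n in f.counts.items())
    return mass + ADDUCTS[adduct]


def ppm_error(observed: float, theoretical: float) -> float:
    """Signed relative mass error in parts per million."""
    if theoretical <= 0:
        raise ValueError("theoretical m/z must be positive")
    return 1e6 * (observed - theoretical) / theoretical


def _single_atom_shift_dist(el: str, exclude_tracer: bool) -> np.ndarray:
    """Nominal mass-shift distribution of one atom of element ``el``."""
    isos = ISOTOPES[el]
    base = round(isos[0][0])
    if el == TRACER_ELEMENT and exclude_tracer:
        return np.array([1.0])
    max_shift = round(isos[-1][0]) - base
    dist = np.zeros(max_shift + 1)
    for mass, ab in isos:
        dist[round(mass) - base] += ab
    return dist


def _convolve_power(dist: np.ndarray, n: int, trunc: int) -> np.ndarray:
    """n-fold self-convolution of ``dist`` truncated to ``trunc + 1`` entries.

    Exponentiation by squaring keeps this fast for large atom counts.
    """
    result = np.zeros(trunc + 1)
    result[0] = 1.0
    power = dist.copy()
    while n:
        if n & 1:
            result = np.convolve(result, power)[: trunc + 1]
        n >>= 1
        if n:
            power = np.convolve(power, power)[: trunc + 1]
    return result


def natural_isotopologue_distribution(
    f: ElementalFormula, max_shift: int, exclude_tracer: bool = False
) -> np.ndarray:
    """Probability of nominal mass shifts 0..max_shift from natural isotopes.

    Convolves the per-element multinomial isotope distributions of the
    formula.  With ``exclude_tracer`` set, carbon contributes no heavy-isotope
    terms (used when natural 13C is to be kept out of the correction).
    """
    if max_shift < 0:
        raise ValueError("max_shift must be >= 0")
    result = np.zeros(max_shift + 1)
    result[0] = 1.0
    for el, n in f.counts.items():
        dist = _single_atom_shift_dist(el, exclude_tracer)
        result = np.convolve(result, _convolve_power(dist, n, max_shift))[
            : max_shift + 1
        ]
    return result


@dataclass(frozen=True)
class CorrectionMatrix:
    """Natural-isotope correction matrix for an N-carbon molecule.

    Column j holds the theoretical nominal mass-shift distribution of a
    molecule carrying exactly j tracer 13C atoms, truncated to N+1 rows.
    Applying the inverse (or a non-negative solve) to a measured isotopologue
    ladder removes the natural-isotope contribution, leaving the tracer-only
    mass isotopomer distribution.
    """

    matrix: np.ndarray
    formula: ElementalFormula
    exclude_tracer: bool

    @property
    def n(self) -> int:
        return self.matrix.shape[0] - 1


def correction_matrix(
    f: ElementalFormula, exclude_tracer: bool = False
) -> CorrectionMatrix:
    """Build the (N+1)x(N+1) natural-abundance correction matrix.

    For column j, j carbons are fixed as 13C (a deterministic shift of j) and
    the remaining N-j carbons plus all heteroatoms contribute their natural
    mass-shift distribution.  With ``exclude_tracer`` the remaining carbons
    contribute no natural 13C.
    """
    n = f.n_carbon
    if n < 1:
        raise ValueError("correction matrix requires a formula with >= 1 carbon")
    hetero = {el: cnt for el, cnt in f.counts.items() if el != TRACER_ELEMENT}
    hetero_dist = (
        natural_isotopologue_distribution(ElementalFormula(hetero), n)
        if hetero
        else np.array([1.0] + [0.0] * n)
    )
    carbon_dist = _single_atom_shift_dist(TRACER_ELEMENT, exclude_tracer)
    mat = np.zeros((n + 1, n + 1))
    for j in range(n + 1):
        rest = _convolve_power(carbon_dist, n - j, n)
        col = np.convolve(rest, hetero_dist)[: n + 1]
        mat[j:, j] = col[: n + 1 - j]
    return CorrectionMatrix(matrix=mat, formula=f, exclude_tracer=exclude_tracer)
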