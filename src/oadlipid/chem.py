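"""Elemental formula arithmetic and monoisotopic mass/adduct m/z computation.

All masses are monoisotopic, in Da, from CODATA/IUPAC values pinned below.
Charged species are corrected by the electron mass, so that e.g. the
phosphocholine head-group ion C5H15NO4P+ evaluates to m/z 184.0733.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Mapping

# Monoisotopic masses (Da), IUPAC 2021 atomic mass evaluation.
ELEMENT_MASSES: dict[str, float] = {
    "H": 1.00782503207,
    "C": 12.0,
    "N": 14.0030740048,
    "O": 15.9949146196,
    "P": 30.97376163,
    "S": 31.97207100,
    "Na": 22.9897692809,
    "K": 38.96370668,
    "Cl": 34.96885268,
}

ELECTRON_MASS = 0.000548579909
PROTON_MASS = ELEMENT_MASSES["H"] - ELECTRON_MASS  # 1.00727645

#: Supported singly charged positive adducts: name -> mass added to the neutral.
#: The electron correction is folded in (adding H+ adds a proton, not an H atom).
ADDUCT_MASSES: dict[str, float] = {
    "[M+H]+": PROTON_MASS,
    "[M+NH4]+": ELEMENT_MASSES["N"] + 4 * ELEMENT_MASSES["H"] + PROTON_MASS,
    "[M+Na]+": ELEMENT_MASSES["Na"] - ELECTRON_MASS,
}

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


class FormulaError(ValueError):
    """Malformed formula string or invalid element arithmetic."""


def _parse_counts(text: str) -> dict[str, int]:
    counts: dict[str, int] = {}
    pos = 0
    while pos < len(text):
        m = _FORMULA_TOKEN.match(text, pos)
        if m is None or m.start() != pos or not m.group(1):
            raise FormulaError(f"cannot parse formula {text!r} at offset {pos}")
        sym, num = m.group(1), m.group(2)
        if sym not in ELEMENT_MASSES:
            raise FormulaError(f"unknown element symbol {sym!r} in {text!r}")
        counts[sym] = counts.get(sym, 0) + (int(num) if num else 1)
        pos = m.end()
    return counts


@dataclass(frozen=True)
class ElementalFormula:
    """An elemental composition with optional net charge.

    ``counts`` maps element symbol to a non-negative atom count; ``charge`` is
    the signed net charge (0 for a neutral molecule).
    """

    counts: Mapping[str, int] = field(default_factory=dict)
    charge: int = 0

    def __post_init__(self) -> None:
        clean = {}
        for sym, n in self.counts.items():
            if sym not in ELEMENT_MASSES:
                raise FormulaError(f"unknown element symbol {sym!r}")
            if n < 0:
                raise FormulaError(f"negative count for {sym}: {n}")
            if n > 0:
                clean[sym] = int(n)
        object.__setattr__(self, "counts", clean)

    @classmethod
    def parse(cls, text: str) -> "ElementalFormula":
        """Parse Hill-like notation, e.g. ``C5H15NO4P`` or ``C5H15NO4P+``."""
        text = text.strip()
        charge = 0
        while text and text[-1] in "+-":
            charge += 1 if text[-1] == "+" else -1
            text = text[:-1]
        return cls(_parse_counts(text), charge)

    def format(self) -> str:
        """Hill order: C, H, then other elements alphabetically."""
        parts = []
        for sym in ("C", "H"):
            n = self.counts.get(sym, 0)
            if n:
                parts.append(sym + (str(n) if n != 1 else ""))
        for sym in sorted(k for k in self.counts if k not in ("C", "H")):
            n = self.counts[sym]
            parts.append(sym + (str(n) if n != 1 else ""))
        sign = "+" * self.charge if self.charge > 0 else "-" * (-self.charge)
        return "".join(parts) + sign

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.format()

    def __add__(self, other: "ElementalFormula") -> "ElementalFormula":
        counts = dict(self.counts)
        for sym, n in other.counts.items():
            counts[sym] = counts.get(sym, 0) + n
        return ElementalFormula(counts, self.charge + other.charge)


@dataclass(frozen=True)
class FormulaDelta:
    """Net atoms gained (+) or lost (−) by a fragmentation event."""

    counts: Mapping[str, int] = field(default_factory=dict)

    @classmethod
    def parse(cls, text: str, sign: int = 1) -> "FormulaDelta":
        return cls({k: sign * v for k, v in _parse_counts(text).items()})

    def mass(self) -> float:
        return sum(ELEMENT_MASSES[sym] * n for sym, n in self.counts.items())

    def __neg__(self) -> "FormulaDelta":
        return FormulaDelta({k: -v for k, v in self.counts.items()})


def monoisotopic_mass(formula: ElementalFormula) -> float:
    """Monoisotopic mass in Da; charged species subtract charge × m_e."""
    mass = sum(ELEMENT_MASSES[sym] * n for sym, n in formula.counts.items())
    return mass - formula.charge * ELECTRON_MASS


def adduct_mz(neutral_mass: float, adduct: str) -> float:
    """m/z of a singly charged positive adduct of a neutral of given mass."""
    if adduct not in ADDUCT_MASSES:
        raise ValueError(
            f"unsupported adduct {adduct!r}; supported: {sorted(ADDUCT_MASSES)}"
        )
    return neutral_mass + ADDUCT_MASSES[adduct]


def apply_delta(formula: ElementalFormula, delta: FormulaDelta) -> ElementalFormula:
    """Element-wise sum; charge is preserved. Negative results are an error."""
    counts = dict(formula.counts)
    for sym, n in delta.counts.items():
        if sym not in ELEMENT_MASSES:
            raise FormulaError(f"unknown element symbol {sym!r}")
        new = counts.get(sym, 0) + n
        if new < 0:
            raise FormulaError(
                f"applying delta yields negative {sym} count ({new}) "
                f"on {formula.format()}"
            )
        counts[sym] = new
    return ElementalFormula(counts, formula.charge)


def ppm_error(observed_mz: float, theoretical_mz: float) -> float:
    """Signed mass error in parts per million."""
    if theoretical_mz <= 0:
        raise ValueError("theoretical_mz must be > 0")
    return (observed_mz - theoretical_mz) / theoretical_mz * 1e6
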