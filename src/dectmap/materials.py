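"""Chemical bookkeeping for staining solutions.

The staining agents in scope are an iodine solution (0.5% w/v I2 in absolute
ethanol, "I2E") and the clinical gadolinium agent Gadobutrol (marketed as
Gadovist, a 1.0 mmol/mL aqueous solution). These helpers exist to sanity-check
stated formulations; basis attenuation coefficients are always measured from
calibration phantoms, never computed from composition.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

from rdkit.Chem import GetPeriodicTable

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


def _known_symbols() -> frozenset[str]:
    pt = GetPeriodicTable()
    return frozenset(pt.GetElementSymbol(z) for z in range(1, 119))

#: Gadobutrol, C18H31GdN4O9 (the active agent of Gadovist).
GADOBUTROL = "C18H31GdN4O9"


@dataclass(frozen=True)
class MaterialFormula:
    """A molecular formula as an ordered list of (element symbol, count)."""

    elements: tuple[tuple[str, int], ...]

    def __post_init__(self) -> None:
        if not self.elements:
            raise ValueError("formula must contain at least one element")
        known = _known_symbols()
        for symbol, count in self.elements:
            if count < 1:
                raise ValueError(f"element count must be >= 1, got {symbol}{count}")
            if symbol not in known:
                raise ValueError(f"unknown element symbol: {symbol!r}")

    @classmethod
    def parse(cls, formula: str) -> "MaterialFormula":
        """Parse a Hill-style formula string such as ``"C18H31GdN4O9"``."""
        pos = 0
        elements: list[tuple[str, int]] = []
        for m in _FORMULA_TOKEN.finditer(formula):
            if m.start() != pos:
                raise ValueError(f"cannot parse formula {formula!r} at {pos}")
            if not m.group(0):
                break
            elements.append((m.group(1), int(m.group(2) or 1)))
            pos = m.end()
        if pos != len(formula) or not elements:
            raise ValueError(f"cannot parse formula {formula!r}")
        return cls(tuple(elements))


def _coerce(formula: MaterialFormula | str) -> MaterialFormula:
    if isinstance(formula, str):
        return MaterialFormula.parse(formula)
    return formula


def molar_mass(formula: MaterialFormula | str) -> float:
    """Molar mass in g/mol from standard (IUPAC) atomic weights."""
    formula = _coerce(formula)
    pt = GetPeriodicTable()
    return sum(pt.GetAtomicWeight(sym) * n for sym, n in formula.elements)


def mass_concentration(formula: MaterialFormula | str, molarity_mmol_per_ml: float) -> float:
    """Mass concentration in mg/mL of a solution of given molarity.

    Units: mmol/mL x g/mol = mg/mL. For Gadobutrol at 1.0 mmol/mL this
    reproduces the stated 604.72 mg/mL formulation of Gadovist.
    """
    if molarity_mmol_per_ml < 0:
        raise ValueError(f"molarity must be >= 0, got {molarity_mmol_per_ml}")
    return molarity_mmol_per_ml * molar_mass(formula)
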