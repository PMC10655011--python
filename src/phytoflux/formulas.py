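"""Elemental formulas: parsing, molecular weight, degree of reduction.

Formulas are plain Hill-style strings without parentheses, e.g. ``C6H12O6``
or ``C10H12N5O13P3``.  An empty string is a valid formula and denotes a
massless species (used for photons and electron-carrier pairs whose redox
state is tracked through explicit protons instead of formula changes).
"""

from __future__ import annotations

import re

__all__ = [
    "parse_formula",
    "format_formula",
    "molecular_weight",
    "degree_of_reduction",
    "FormulaError",
]

_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")

# Standard atomic weights (g/mol), 2021 IUPAC abridged values.
ATOMIC_WEIGHTS: dict[str, float] = {
    "H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999, "P": 30.974,
    "S": 32.06, "K": 39.098, "Ca": 40.078, "Mg": 24.305, "Fe": 55.845,
    "Cl": 35.45, "Na": 22.99, "Mn": 54.938, "Zn": 65.38, "Cu": 63.546,
    "Mo": 95.95, "Se": 78.971, "Co": 58.933,
}

# Degrees of reduction per atom relative to H2O/CO2/NH3/H3PO4/H2SO4
# references: C=4, H=1, O=-2, N=-3, P=5, S=6.  Metals contribute 0.
REDUCTION_DEGREES: dict[str, float] = {
    "C": 4.0, "H": 1.0, "O": -2.0, "N": -3.0, "P": 5.0, "S": 6.0,
}


class FormulaError(ValueError):
    """Raised when a formula string cannot be parsed."""


def parse_formula(formula: str) -> dict[str, int]:
    """Parse ``formula`` into an element -> count map.

    Raises :class:`FormulaError` on malformed input.  ``""`` parses to an
    empty map (a massless species); ``None`` is rejected.
    """
    if formula is None:
        raise FormulaError("formula is None")
    formula = formula.strip()
    counts: dict[str, int] = {}
    pos = 0
    while pos < len(formula):
        m = _TOKEN.match(formula, pos)
        if not m or m.start() != pos or not m.group(1):
            raise FormulaError(f"cannot parse formula {formula!r} at position {pos}")
        element = m.group(1)
        n = int(m.group(2)) if m.group(2) else 1
        if n < 0:
            raise FormulaError(f"negative count in {formula!r}")
        counts[element] = counts.get(element, 0) + n
        pos = m.end()
    return counts


def format_formula(counts: dict[str, float]) -> str:
    """Inverse of :func:`parse_formula` (Hill order: C, H, then alphabetical)."""
    def key(el: str):
        return {"C": "0", "H": "1"}.get(el, el)

    parts = []
    for el in sorted((e for e, c in counts.items() if c), key=key):
        c = counts[el]
        ci = int(round(c))
        shown = str(ci) if abs(c - ci) < 1e-9 else f"{c:g}"
        parts.append(el if shown == "1" else f"{el}{shown}")
    return "".join(parts)


def molecular_weight(formula: str) -> float:
    """Molecular weight in g/mol of a formula string."""
    counts = parse_formula(formula)
    try:
        return sum(ATOMIC_WEIGHTS[el] * n for el, n in counts.items())
    except KeyError as exc:  # pragma: no cover - guarded by curated weights
        raise FormulaError(f"no atomic weight for element {exc} in {formula!r}") from exc


def degree_of_reduction(formula: str) -> float:
    """Generalized degree of reduction (electrons available per molecule).

    Computed as sum over atoms of per-element degrees (C=4, H=1, O=-2,
    N=-3, P=5, S=6; metals 0).  Glucose C6H12O6 gives 24.
    """
    counts = parse_formula(formula)
    return sum(REDUCTION_DEGREES.get(el, 0.0) * n for el, n in counts.items())
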