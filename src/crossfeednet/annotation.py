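"""Accurate-mass annotation of negative-mode ions against a formula database.

Untargeted flow-injection mass spectrometry of culture supernatants yields
per-ion m/z values without chromatographic separation. Ions are putatively
annotated by matching the measured m/z against the singly deprotonated
([M - H]-) monoisotopic mass of every formula in a metabolite database,
within a user-set mass tolerance (default 0.003 Da). Compounds with
identical molecular formulas (e.g. leucine/isoleucine) are isobaric and are
all reported; this is a level-4 annotation by design.

The module also computes expected m/z of fully isotope-labeled species
(13C / 15N) for tracer experiments, where a tighter 0.001 Da tolerance is
customary.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np

from .masses import ISOTOPE_SHIFT, MONOISOTOPIC_MASS, PROTON_MASS

__all__ = [
    "FormulaRecord",
    "AnnotatedIon",
    "parse_formula",
    "format_formula",
    "neutral_mass",
    "mz_deprotonated",
    "labeled_mz",
    "annotate_ions",
]

_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


def parse_formula(formula: str) -> dict[str, int]:
    """Parse a Hill-style molecular formula into element counts.

    Parameters
    ----------
    formula : str
        Element symbols with optional integer counts, e.g. ``"C4H6O4"``.

    Returns
    -------
    dict mapping element symbol to count. Repeated symbols accumulate.

    Raises
    ------
    ValueError
        On empty input, malformed tokens, or unknown element symbols.
    """
    if not formula or not formula.strip():
        raise ValueError("empty molecular formula")
    formula = formula.strip()
    counts: dict[str, int] = {}
    pos = 0
    while pos < len(formula):
        m = _TOKEN.match(formula, pos)
        if m is None or m.start() != pos or not m.group(1):
            raise ValueError(f"malformed formula {formula!r} at position {pos}")
        symbol, digits = m.group(1), m.group(2)
        if symbol not in MONOISOTOPIC_MASS:
            raise ValueError(f"unknown element {symbol!r} in formula {formula!r}")
        n = int(digits) if digits else 1
        if n <= 0:
            raise ValueError(f"non-positive count for {symbol!r} in {formula!r}")
        counts[symbol] = counts.get(symbol, 0) + n
        pos = m.end()
    return counts


def format_formula(counts: dict[str, int]) -> str:
    """Render element counts in Hill order (C, H, then alphabetical)."""
    items = {el: n for el, n in counts.items() if n > 0}
    ordered: list[str] = []
    if "C" in items:
        ordered.append("C")
        if "H" in items:
            ordered.append("H")
        ordered.extend(sorted(el for el in items if el not in ("C", "H")))
    else:
        ordered.extend(sorted(items))
    return "".join(f"{el}{items[el] if items[el] != 1 else ''}" for el in ordered)


def neutral_mass(counts: dict[str, int]) -> float:
    """Monoisotopic neutral mass (Da) of a composition."""
    try:
        return sum(n * MONOISOTOPIC_MASS[el] for el, n in counts.items())
    except KeyError as exc:  # pragma: no cover - parse_formula already guards
        raise ValueError(f"unknown element {exc.args[0]!r}") from exc


def mz_deprotonated(counts: dict[str, int]) -> float:
    """m/z (Da) of the singly deprotonated ion [M - H]-."""
    return neutral_mass(counts) - PROTON_MASS


def labeled_mz(counts: dict[str, int], label: str, n_labeled: int) -> float:
    """Expected [M - H]- m/z with ``n_labeled`` heavy atoms of ``label``.

    ``label`` is the element symbol of the light isotope ("C" for 13C,
    "N" for 15N). ``n_labeled`` may not exceed that element's atom count.
    """
    if label not in ISOTOPE_SHIFT:
        raise ValueError(f"no isotope shift known for element {label!r}")
    if n_labeled < 0:
        raise ValueError("n_labeled must be non-negative")
    if n_labeled > counts.get(label, 0):
        raise ValueError(
            f"n_labeled={n_labeled} exceeds {label} count {counts.get(label, 0)}"
        )
    return mz_deprotonated(counts) + n_labeled * ISOTOPE_SHIFT[label]


@dataclass(frozen=True)
class FormulaRecord:
    """A database metabolite: identity, composition and compound class."""

    name: str
    formula: str
    element_counts: dict[str, int] = field(compare=False)
    neutral_mass: float = field(compare=False)
    compound_class: str = ""

    @classmethod
    def from_formula(
        cls, name: str, formula: str, compound_class: str = ""
    ) -> "FormulaRecord":
        counts = parse_formula(formula)
        return cls(
            name=name,
            formula=format_formula(counts),
            element_counts=counts,
            neutral_mass=neutral_mass(counts),
            compound_class=compound_class,
        )

    @property
    def mz_deprotonated(self) -> float:
        return self.neutral_mass - PROTON_MASS


@dataclass
class AnnotatedIon:
    """A measured m/z with all database candidates inside the tolerance.

    ``candidates`` is sorted by |mass error|, ties broken alphabetically
    by name so output is reproducible.
    """

    mz: float
    candidates: list[tuple[FormulaRecord, float]]
    tolerance: float


def annotate_ions(
    mz_list,
    database: list[FormulaRecord],
    tolerance: float = 0.003,
) -> list[AnnotatedIon]:
    """Annotate measured m/z values against a formula database.

    Every database entry whose [M - H]- mass lies within ``tolerance`` Da
    of a measured m/z is returned for that ion; entries sharing a formula
    (isobars) are all kept, since accurate mass alone cannot distinguish
    them.

    The candidate search is a binary search on the mass-sorted database,
    O((N + Q) log N) overall.
    """
    if tolerance <= 0:
        raise ValueError("tolerance must be positive")
    if not database:
        raise ValueError("empty formula database")

    order = sorted(range(len(database)), key=lambda i: database[i].mz_deprotonated)
    masses = np.array([database[i].mz_deprotonated for i in order])

    out: list[AnnotatedIon] = []
    for mz in mz_list:
        lo = int(np.searchsorted(masses, mz - tolerance, side="left"))
        hi = int(np.searchsorted(masses, mz + tolerance, side="right"))
        cands = []
        for j in range(lo, hi):
            rec = database[order[j]]
            err = mz - rec.mz_deprotonated
            if abs(err) <= tolerance:
                cands.append((rec, err))
        cands.sort(key=lambda c: (abs(c[1]), c[0].name))
        out.append(AnnotatedIon(mz=float(mz), candidates=cands, tolerance=tolerance))
    return out
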