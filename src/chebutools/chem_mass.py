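"""Elemental-formula and adduct m/z arithmetic for negative-mode tannin MS.

Monoisotopic masses, deprotonated/dimer/doubly-charged ion m/z, ppm errors
and the small catalog of mass differences (methylation, galloylation,
hexosylation, ...) that link homologous tannins.

Conventions
-----------
* Theoretical m/z of an anion is the plain monoisotopic mass of the
  tabulated ion formula divided by the charge magnitude.  No electron-mass
  correction is applied: deprotonated gallic acid C7H5O5(-) is reported at
  169.0137, which is the convention the reference ion tables use.
* Display rounding: m/z at 4 decimal places, ppm at 1 decimal place.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Sequence, Tuple

__all__ = [
    "ATOMIC_MASS",
    "ELECTRON_MASS",
    "PROTON_MASS",
    "ElementalFormula",
    "FormulaError",
    "IonSpecies",
    "ION_SPECIES",
    "MassDelta",
    "DEFAULT_MASS_DELTAS",
    "parse_formula",
    "monoisotopic_mass",
    "ion_mz",
    "neutral_mass",
    "expected_species_mz",
    "ppm_error",
    "annotate_mass_difference",
    "load_mass_delta_catalog",
]

# Most-abundant-isotope atomic masses, IUPAC/CIAAW 2021, in Da.
ATOMIC_MASS: Dict[str, float] = {
    "C": 12.0,
    "H": 1.00782503207,
    "O": 15.99491461956,
    "N": 14.0030740048,
    "S": 31.97207100,
}

#: mass of 1H (the "proton" removed on deprotonation keeps its electron in
#: the neutral-mass algebra used here, matching the no-electron convention)
PROTON_MASS: float = ATOMIC_MASS["H"]
ELECTRON_MASS: float = 0.000548579909  # exposed for completeness; unused by default

_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


class FormulaError(ValueError):
    """Raised for unparseable or chemically invalid formula strings."""


@dataclass(frozen=True)
class ElementalFormula:
    """An elemental composition, e.g. ``C7H5O5`` for deprotonated gallic acid.

    ``element_counts`` maps element symbol to a strictly positive count.
    Renders back to a canonical Hill-order string (C first, then H, then the
    rest alphabetically), so parsing round-trips losslessly.
    """

    element_counts: Tuple[Tuple[str, int], ...]

    def __post_init__(self) -> None:
        if not self.element_counts:
            raise FormulaError("formula must contain at least one atom")
        for element, count in self.element_counts:
            if element not in ATOMIC_MASS:
                raise FormulaError(f"unknown element symbol {element!r}")
            if count <= 0:
                raise FormulaError(f"non-positive count for element {element!r}")

    @classmethod
    def from_counts(cls, counts: Mapping[str, int]) -> "ElementalFormula":
        return cls(tuple(sorted(counts.items(), key=_hill_key)))

    @property
    def counts(self) -> Dict[str, int]:
        return dict(self.element_counts)

    @property
    def mass(self) -> float:
        return monoisotopic_mass(self)

    def __add__(self, other: "ElementalFormula") -> "ElementalFormula":
        merged = self.counts
        for element, count in other.element_counts:
            merged[element] = merged.get(element, 0) + count
        return ElementalFormula.from_counts(merged)

    def __str__(self) -> str:
        parts = []
        for element, count in self.element_counts:
            parts.append(element if count == 1 else f"{element}{count}")
        return "".join(parts)


def _hill_key(item: Tuple[str, int]) -> Tuple[int, str]:
    element = item[0]
    # Hill order: carbon, hydrogen, then alphabetical.
    return {"C": (0, ""), "H": (1, "")}.get(element, (2, element))


def parse_formula(text: str) -> ElementalFormula:
    """Parse ``"C7H5O5"``-style element/count strings.

    Counts default to 1.  Unknown symbols, explicit zero counts and empty
    strings raise :class:`FormulaError` naming the offending token.
    """
    if not text or not text.strip():
        raise FormulaError("empty formula string")
    text = text.strip()
    counts: Dict[str, int] = {}
    pos = 0
    while pos < len(text):
        match = _TOKEN.match(text, pos)
        if match is None or match.start() != pos or not match.group(1):
            raise FormulaError(f"cannot parse formula {text!r} at {text[pos:]!r}")
        element, digits = match.group(1), match.group(2)
        if element not in ATOMIC_MASS:
            raise FormulaError(f"unknown element symbol {element!r} in {text!r}")
        count = int(digits) if digits else 1
        if count == 0:
            raise FormulaError(f"zero count for element {element!r} in {text!r}")
        counts[element] = counts.get(element, 0) + count
        pos = match.end()
    return ElementalFormula.from_counts(counts)


def monoisotopic_mass(formula: ElementalFormula | str | Mapping[str, int]) -> float:
    """Monoisotopic (most-abundant isotope) mass in Da."""
    if isinstance(formula, str):
        formula = parse_formula(formula)
    elif isinstance(formula, Mapping):
        formula = ElementalFormula.from_counts(formula)
    return sum(ATOMIC_MASS[el] * n for el, n in formula.element_counts)


# ---------------------------------------------------------------------------
# Ion species
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class IonSpecies:
    """A negative-mode ion species built from ``n`` neutral molecules.

    ``delta_mass`` is the signed mass change applied to the ``n`` neutrals
    (e.g. −1.00783 Da for the removed hydrogen of [M−H]−).  m/z of the
    species for a neutral of mass M is ``(n*M + delta_mass) / z``.
    """

    label: str
    multimer_count: int
    charge_magnitude: int
    delta_mass: float

    def __post_init__(self) -> None:
        if self.multimer_count < 1:
            raise ValueError("multimer_count must be >= 1")
        if self.charge_magnitude < 1:
            raise ValueError("charge_magnitude must be >= 1")

    def mz_from_neutral(self, neutral_mass_da: float) -> float:
        return (self.multimer_count * neutral_mass_da + self.delta_mass) / self.charge_magnitude

    def neutral_from_mz(self, mz: float) -> float:
        return (mz * self.charge_magnitude - self.delta_mass) / self.multimer_count


_H = ATOMIC_MASS["H"]
_FORMIC = monoisotopic_mass("CH2O2")

#: The four species observed in the reference ion table.
ION_SPECIES: Dict[str, IonSpecies] = {
    "[M-H]-": IonSpecies("[M-H]-", 1, 1, -_H),
    "[2M-H]-": IonSpecies("[2M-H]-", 2, 1, -_H),
    "[M-2H]2-": IonSpecies("[M-2H]2-", 1, 2, -2.0 * _H),
    "[M+HCOOH-H]-": IonSpecies("[M+HCOOH-H]-", 1, 1, _FORMIC - _H),
}


def _resolve_species(species: IonSpecies | str) -> IonSpecies:
    if isinstance(species, str):
        key = species.replace("–", "-").replace("−", "-")
        try:
            return ION_SPECIES[key]
        except KeyError:
            raise KeyError(f"unknown ion species {species!r}; known: {sorted(ION_SPECIES)}")
    return species


def ion_mz(ion_formula: ElementalFormula | str, charge_magnitude: int = 1) -> float:
    """m/z of a tabulated *ion* formula (already deprotonated/adducted)."""
    if charge_magnitude == 0:
        raise ValueError("charge magnitude must be non-zero")
    return monoisotopic_mass(ion_formula) / abs(charge_magnitude)


def neutral_mass(observed_mz: float, species: IonSpecies | str) -> float:
    """Neutral monoisotopic mass implied by an observed species m/z."""
    return _resolve_species(species).neutral_from_mz(observed_mz)


def expected_species_mz(
    observed_mz: float,
    from_species: IonSpecies | str,
    to_species: IonSpecies | str,
) -> float:
    """Convert the observed m/z of one ion species of a molecule to another.

    E.g. chebulanin's [M−H]− at 651.0839 predicts its [2M−H]− dimer at
    1303.1756 (printed in networks as 1303.18).
    """
    neutral = _resolve_species(from_species).neutral_from_mz(observed_mz)
    return _resolve_species(to_species).mz_from_neutral(neutral)


def ppm_error(observed: float, theoretical: float) -> float:
    """Signed mass error in parts-per-million."""
    if theoretical <= 0:
        raise ValueError("theoretical m/z must be positive")
    return (observed - theoretical) / theoretical * 1e6


# ---------------------------------------------------------------------------
# Mass-difference (homolog) catalog
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MassDelta:
    """A named modification mass, e.g. methylation (+CH2, +14.0157 Da)."""

    name: str
    delta_mass: float
    max_multiplicity: int = 5


def _delta(name: str, formula: str, sign: int = 1, max_multiplicity: int = 5) -> MassDelta:
    return MassDelta(name, sign * monoisotopic_mass(formula), max_multiplicity)


#: Additions/losses recurring across the tannin homolog series: methyl
#: ladders of chebulic acid, galloylation/galloyl loss, hexosylation,
#: dehydration/decarboxylation and the ketene loss of galloyl glucoses.
DEFAULT_MASS_DELTAS: Tuple[MassDelta, ...] = (
    _delta("methylation", "CH2"),                      # +14.0157
    _delta("dehydration", "H2O", sign=-1),             # −18.0106
    _delta("decarboxylation", "CO2", sign=-1),         # −43.9898
    _delta("ketene loss", "C2H2O", sign=-1),           # −42.0106
    _delta("galloylation", "C7H4O4"),                  # +152.0110 (galloyl residue)
    _delta("gallate addition", "C7H6O5"),              # +170.0215 (gallic acid)
    _delta("hexosylation", "C6H10O5"),                 # +162.0528 (hexose residue)
)


def annotate_mass_difference(
    delta: float,
    catalog: Sequence[MassDelta] = DEFAULT_MASS_DELTAS,
    tol: float = 0.01,
) -> List[Tuple[MassDelta, int]]:
    """Explain a mass difference as k-fold applications of catalog entries.

    Returns every ``(modification, k)`` with ``k <= max_multiplicity`` and
    ``|k * delta_mass - delta| <= tol``, sorted by absolute residual.
    ``delta = 0`` (or nothing within tolerance) yields an empty list.
    """
    if tol <= 0:
        raise ValueError("tolerance must be positive")
    hypotheses: List[Tuple[float, MassDelta, int]] = []
    for entry in catalog:
        for k in range(1, entry.max_multiplicity + 1):
            residual = abs(k * entry.delta_mass - delta)
            if residual <= tol:
                hypotheses.append((residual, entry, k))
    hypotheses.sort(key=lambda item: (item[0], item[1].name, item[2]))
    return [(entry, k) for _, entry, k in hypotheses]


def load_mass_delta_catalog(path: str) -> List[MassDelta]:
    """Read a JSON catalog: ``[{"name", "delta_mass", "max_multiplicity"}]``."""
    with open(path) as handle:
        raw = json.load(handle)
    return [
        MassDelta(item["name"], float(item["delta_mass"]), int(item.get("max_multiplicity", 5)))
        for item in raw
    ]
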