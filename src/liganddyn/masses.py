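"""Molecular-formula mass engine with explicit isotope labels.

Formulas are Hill-style strings where a bracketed group pins an element
to one isotope: ``"C9H9N[15N]O5S"`` is nine carbons, nine hydrogens, one
nitrogen-14, one nitrogen-15, five oxygens, one sulfur.  Monoisotopic
masses use the most abundant isotope of each unlabeled element (masses
from the NIST table shipped with pyteomics); ions add one electron mass
per negative charge.
"""

from __future__ import annotations

import re
from collections import Counter

from pyteomics.mass import nist_mass

ELECTRON_MASS = nist_mass["e*"][0][0]  # Da
#: monoisotopic 2H minus 1H, the mass gained per H -> D exchange
DELTA_MASS_D_H = nist_mass["H"][2][0] - nist_mass["H"][1][0]
#: mass removed on deprotonation to the (M-H)- ion
PROTON_MASS = nist_mass["H"][1][0] - ELECTRON_MASS

_TOKEN = re.compile(r"\[(\d+)([A-Z][a-z]?)\](\d*)|([A-Z][a-z]?)(\d*)")

Composition = Counter  # keys: (element, isotope); isotope 0 = unspecified


def parse_formula(formula: str) -> Composition:
    """Parse a formula string into an (element, isotope) -> count map."""
    if not formula or not formula.strip():
        raise ValueError("empty molecular formula")
    comp: Composition = Counter()
    pos = 0
    for match in _TOKEN.finditer(formula):
        if match.start() != pos:
            raise ValueError(
                f"cannot parse formula {formula!r} at {formula[pos:]!r}")
        pos = match.end()
        if match.group(2):  # bracketed isotope
            isotope, element, count = (int(match.group(1)), match.group(2),
                                       match.group(3))
        else:
            isotope, element, count = 0, match.group(4), match.group(5)
        if element not in nist_mass:
            raise ValueError(f"unknown element symbol {element!r}")
        if isotope and isotope not in nist_mass[element]:
            raise ValueError(f"unknown isotope {isotope}{element}")
        n = int(count) if count else 1
        if n < 0:
            raise ValueError("negative atom count")
        comp[(element, isotope)] += n
    if pos != len(formula):
        raise ValueError(f"trailing junk in formula {formula!r}")
    if sum(comp.values()) == 0:
        raise ValueError("formula contains no atoms")
    return comp


def monoisotopic_mass(formula: str | Composition, charge: int = 0) -> float:
    """Monoisotopic mass (Da) of a formula, or m/|z| mass of its ion.

    Unlabeled elements contribute their most abundant isotope; bracketed
    isotopes override.  Electrons are added for negative charge and
    removed for positive charge (the charge carrier itself, e.g. the
    lost proton of an (M-H)- ion, must already be reflected in the
    formula's hydrogen count).
    """
    comp = parse_formula(formula) if isinstance(formula, str) else formula
    mass = 0.0
    for (element, isotope), count in comp.items():
        mass += nist_mass[element][isotope][0] * count
    return mass - charge * ELECTRON_MASS


def average_mass(formula: str | Composition) -> float:
    """Abundance-weighted average mass (Da) of a neutral formula.

    Bracketed isotopes contribute their exact isotopic mass.
    """
    comp = parse_formula(formula) if isinstance(formula, str) else formula
    mass = 0.0
    for (element, isotope), count in comp.items():
        if isotope:
            mass += nist_mass[element][isotope][0] * count
        else:
            avg = sum(m * ab for iso, (m, ab) in nist_mass[element].items()
                      if iso != 0)
            mass += avg * count
    return mass


def deprotonated_mz(formula: str | Composition) -> float:
    """Mass of the (M-H)- ion of a neutral formula, in Da."""
    return monoisotopic_mass(formula) - PROTON_MASS
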