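"""Molecular structure handling: parsing, canonical identity, mass arithmetic.

All m/z arithmetic in the package goes through this module. The ion mass
convention is ``m/z = neutral monoisotopic mass +/- proton mass`` with the
electron mass folded into the proton constant (1.00727646 Da), which keeps
the [M+H]+ / [M-H]- symmetry exact: their m/z values differ by exactly two
proton masses for every molecule.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from rdkit import Chem
from rdkit import RDLogger

RDLogger.DisableLog("rdApp.*")

#: NIST monoisotopic atomic masses (Da) for the supported organic subset
#: plus the alkali/halogen elements needed by the adduct table.
ELEMENT_MASSES: dict[str, float] = {
    "H": 1.00782503207,
    "C": 12.0,
    "N": 14.0030740048,
    "O": 15.9949146196,
    "P": 30.97376163,
    "S": 31.97207100,
    "F": 18.99840322,
    "Cl": 34.96885268,
    "Br": 78.9183371,
    "I": 126.904473,
    "Na": 22.9897692809,
    "K": 38.96370668,
}

#: Mass of a proton (Da); includes the electron-mass correction so that
#: ion m/z = neutral mass + PROTON_MASS for [M+H]+.
PROTON_MASS = 1.00727646
ELECTRON_MASS = 0.00054858

POSITIVE = "positive"
NEGATIVE = "negative"


class ChemError(ValueError):
    """Raised for unparsable, charged or otherwise unsupported input."""


@dataclass(frozen=True)
class AdductSpec:
    """An adduct type: a label, a mass delta added to the neutral mass,
    and the polarity it applies to."""

    name: str
    mass_delta: float
    polarity: str

    def __post_init__(self) -> None:
        if self.polarity not in (POSITIVE, NEGATIVE):
            raise ChemError(f"unknown polarity {self.polarity!r}")


def _cation(*elements: str) -> float:
    return sum(ELEMENT_MASSES[e] for e in elements) - ELECTRON_MASS


#: Built-in adduct table. Positive deltas are cation masses (atom set minus
#: one electron); [M+FA-H]- is the formate adduct (formic acid minus a proton).
DEFAULT_ADDUCTS: dict[str, AdductSpec] = {
    a.name: a
    for a in [
        AdductSpec("[M+H]+", PROTON_MASS, POSITIVE),
        AdductSpec("[M+Na]+", _cation("Na"), POSITIVE),
        AdductSpec("[M+K]+", _cation("K"), POSITIVE),
        AdductSpec("[M+NH4]+", _cation("N", "H", "H", "H", "H"), POSITIVE),
        AdductSpec("[M-H]-", -PROTON_MASS, NEGATIVE),
        AdductSpec("[M+Cl]-", ELEMENT_MASSES["Cl"] + ELECTRON_MASS, NEGATIVE),
        AdductSpec(
            "[M+FA-H]-",
            sum(ELEMENT_MASSES[e] for e in ("H", "C", "O", "O", "H")) - PROTON_MASS,
            NEGATIVE,
        ),
    ]
}

PROTONATION = {POSITIVE: DEFAULT_ADDUCTS["[M+H]+"], NEGATIVE: DEFAULT_ADDUCTS["[M-H]-"]}


def load_adduct_table(text: str) -> dict[str, AdductSpec]:
    """Parse a plain-text adduct table: ``name delta polarity`` per line,
    '#' comments allowed. Extends (and may override) the built-in table."""
    table = dict(DEFAULT_ADDUCTS)
    for lineno, line in enumerate(text.splitlines(), start=1):
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        parts = line.split()
        if len(parts) != 3:
            raise ChemError(f"adduct table line {lineno}: expected 'name delta polarity'")
        name, delta, pol = parts
        try:
            spec = AdductSpec(name, float(delta), pol)
        except ValueError as exc:
            raise ChemError(f"adduct table line {lineno}: {exc}") from exc
        table[name] = spec
    return table


@dataclass
class MoleculeStructure:
    """A neutral molecule: an RDKit mol with explicit hydrogens plus its
    canonical identity key and the original input text."""

    mol: Chem.Mol
    source: str
    canonical_key: str
    formula: dict[str, int] = field(default_factory=dict)

    @property
    def smiles(self) -> str:
        return self.canonical_key

    def __eq__(self, other: object) -> bool:
        return isinstance(other, MoleculeStructure) and self.canonical_key == other.canonical_key

    def __hash__(self) -> int:
        return hash(self.canonical_key)


def _formula_of(mol: Chem.Mol) -> dict[str, int]:
    counts: dict[str, int] = {}
    for atom in mol.GetAtoms():
        sym = atom.GetSymbol()
        counts[sym] = counts.get(sym, 0) + 1
        h = atom.GetTotalNumHs()
        if h:
            counts["H"] = counts.get("H", 0) + h
    return counts


def parse_structure(text: str) -> MoleculeStructure:
    """Parse a SMILES or InChI string into a neutral molecule.

    InChI is auto-detected by the ``InChI=`` prefix. The canonical key is
    the RDKit canonical SMILES, so equivalent encodings (including the
    InChI form) map to the same key. Charged species are rejected: the
    precursor must be a neutral molecule, ionization is applied downstream.
    """
    if not text or not text.strip():
        raise ChemError("empty structure string")
    text = text.strip()
    if text.startswith("InChI="):
        mol = Chem.MolFromInchi(text)
    else:
        mol = Chem.MolFromSmiles(text)
    if mol is None:
        raise ChemError(f"could not parse structure: {text!r}")
    if Chem.GetFormalCharge(mol) != 0:
        raise ChemError(f"neutral molecule required, got net charge "
                        f"{Chem.GetFormalCharge(mol):+d} for {text!r}")
    key = Chem.MolToSmiles(mol)
    molH = Chem.AddHs(mol)
    Chem.Kekulize(molH, clearAromaticFlags=False)
    return MoleculeStructure(mol=molH, source=text, canonical_key=key,
                             formula=_formula_of(molH))


def formula_mass(formula: dict[str, int]) -> float:
    """Monoisotopic mass of an elemental formula; unknown elements error."""
    total = 0.0
    for element, count in formula.items():
        if element not in ELEMENT_MASSES:
            raise ChemError(f"unsupported element: {element}")
        total += ELEMENT_MASSES[element] * count
    return total


def monoisotopic_mass(mol: MoleculeStructure) -> float:
    """Neutral monoisotopic mass (Da), hydrogens included."""
    return formula_mass(mol.formula)


def precursor_mz(mol: MoleculeStructure, adduct: AdductSpec) -> float:
    """m/z of the adduct ion of a neutral molecule."""
    return monoisotopic_mass(mol) + adduct.mass_delta


def formula_to_string(formula: dict[str, int]) -> str:
    """Hill-order formula string (C, H, then alphabetical)."""
    parts = []
    for element in ["C", "H"] + sorted(e for e in formula if e not in ("C", "H")):
        n = formula.get(element, 0)
        if n == 1:
            parts.append(element)
        elif n > 1:
            parts.append(f"{element}{n}")
    return "".join(parts) or "()"


def parse_formula(text: str) -> dict[str, int]:
    """Inverse of :func:`formula_to_string` for the supported elements."""
    import re

    if text == "()":
        return {}
    counts: dict[str, int] = {}
    pos = 0
    for m in re.finditer(r"([A-Z][a-z]?)(\d*)", text):
        if m.start() != pos or not m.group(1):
            break
        pos = m.end()
        counts[m.group(1)] = counts.get(m.group(1), 0) + int(m.group(2) or 1)
    if pos != len(text):
        raise ChemError(f"bad formula string: {text!r}")
    return counts
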