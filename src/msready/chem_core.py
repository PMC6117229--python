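"""Molecular-formula algebra, monoisotopic masses, adduct m/z and InChIKeys.

This module is the numerical and identifier foundation for the MS-Ready
toolkit: everything downstream (standardization, registry, search, export)
computes masses and formulas through the functions defined here so that a
formula printed anywhere in the package is guaranteed to be in canonical
Hill order and every mass is a most-abundant-isotope (monoisotopic) mass.

Conventions
-----------
* Formulas may have several dot-separated parts (salt/mixture records such
  as ``C31H42N3+.C2H3O2-``); each part may carry its own integer charge
  written as trailing sign characters (``-``, ``--`` or the ``2-`` dialect).
* Monoisotopic masses subtract ``charge x electron mass``, so the mass of a
  cation is slightly below the sum of its atomic masses.
* [M+H]+ and [M-H]- adducts add/subtract one *proton* mass (hydrogen atom
  minus electron), not a hydrogen-atom mass.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from typing import Dict, Iterable, List, Mapping, Optional, Tuple

from rdkit import Chem, RDLogger

RDLogger.DisableLog("rdApp.*")

__all__ = [
    "ELECTRON_MASS",
    "PROTON_MASS",
    "ElementMassTable",
    "FormulaError",
    "FormulaPart",
    "MolecularFormula",
    "MoleculeRecord",
    "AdductSpec",
    "parse_formula",
    "monoisotopic_mass",
    "adduct_mz",
    "formula_of",
    "inchikey",
    "first_block",
    "mol_from_record",
]

#: Electron rest mass in Da (CODATA).
ELECTRON_MASS = 0.00054857990946


class FormulaError(ValueError):
    """Raised for malformed molecular-formula text or unknown elements."""


class ElementMassTable:
    """Most-abundant-isotope exact masses keyed by element symbol.

    Loaded once from the bundled table; behaves like a read-only mapping.
    """

    def __init__(self, masses: Optional[Mapping[str, float]] = None):
        if masses is None:
            masses = _load_default_masses()
        self._masses: Dict[str, float] = dict(masses)
        self.electron_mass = ELECTRON_MASS
        self.proton_mass = self._masses["H"] - ELECTRON_MASS

    def __getitem__(self, symbol: str) -> float:
        try:
            return self._masses[symbol]
        except KeyError:
            raise FormulaError(f"unknown element symbol: {symbol!r}") from None

    def __contains__(self, symbol: str) -> bool:
        return symbol in self._masses

    def __iter__(self):
        return iter(self._masses)

    def __len__(self) -> int:
        return len(self._masses)


def _load_default_masses() -> Dict[str, float]:
    masses: Dict[str, float] = {}
    text = (
        resources.files("msready").joinpath("data/element_masses.tsv").read_text()
    )
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        symbol, mass = line.split("\t")
        masses[symbol] = float(mass)
    return masses


MASS_TABLE = ElementMassTable()

#: Proton mass in Da: hydrogen-atom mass minus the electron mass.
PROTON_MASS = MASS_TABLE.proton_mass


@dataclass(frozen=True)
class FormulaPart:
    """One connected part of a (possibly multi-part) molecular formula."""

    counts: Tuple[Tuple[str, int], ...]
    charge: int = 0

    def as_dict(self) -> Dict[str, int]:
        return dict(self.counts)

    @staticmethod
    def from_counts(counts: Mapping[str, int], charge: int = 0) -> "FormulaPart":
        items = tuple(sorted((el, int(n)) for el, n in counts.items() if n))
        for el, n in items:
            if n <= 0:
                raise FormulaError(f"non-positive count for {el}: {n}")
        return FormulaPart(items, charge)

    @property
    def hill(self) -> str:
        return _hill_text(self.as_dict()) + _charge_suffix(self.charge)


@dataclass(frozen=True)
class MolecularFormula:
    """An ordered list of formula parts with per-part and net charge."""

    parts: Tuple[FormulaPart, ...]

    @property
    def charge(self) -> int:
        return sum(p.charge for p in self.parts)

    @property
    def display(self) -> str:
        """Canonical dot-separated Hill-order text with trailing charge signs."""
        return ".".join(p.hill for p in self.parts)

    def merged(self) -> "MolecularFormula":
        """Collapse all parts into a single part (overall formula of a record)."""
        total: Dict[str, int] = {}
        for p in self.parts:
            for el, n in p.counts:
                total[el] = total.get(el, 0) + n
        return MolecularFormula((FormulaPart.from_counts(total, self.charge),))

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.display


def _hill_text(counts: Mapping[str, int]) -> str:
    """Hill order: C then H then alphabetical; without carbon, alphabetical."""
    if not counts:
        return ""
    symbols = list(counts)
    if "C" in counts:
        ordered = ["C"] + (["H"] if "H" in counts else [])
        ordered += sorted(s for s in symbols if s not in ("C", "H"))
    else:
        ordered = sorted(symbols)
    return "".join(
        f"{el}{counts[el]}" if counts[el] != 1 else el for el in ordered
    )


def _charge_suffix(charge: int) -> str:
    if charge == 0:
        return ""
    sign = "+" if charge > 0 else "-"
    return sign * abs(charge)


_TOKEN_RE = re.compile(r"([A-Z][a-z]?)(\d*)")
# trailing charge dialects, tried in order: "^2-" (caret-magnitude),
# "-2" (sign then magnitude), "--"/"+" (repeated signs). A bare trailing
# "2-" is ambiguous with an element count ("C2H3O2-") and is therefore
# read as count + single sign; use "^2-" or "-2" for multiple charges.
_CHARGE_CARET_RE = re.compile(r"\^(\d+)([+\-−‐])$")
_CHARGE_SIGNDIGIT_RE = re.compile(r"([+\-−‐])(\d+)$")
_CHARGE_SIGNS_RE = re.compile(r"([+\-−‐]+)$")


def _strip_charge(text: str) -> Tuple[str, int]:
    m = _CHARGE_CARET_RE.search(text)
    if m:
        sign = 1 if m.group(2) == "+" else -1
        return text[: m.start()], sign * int(m.group(1))
    m = _CHARGE_SIGNDIGIT_RE.search(text)
    if m:
        sign = 1 if m.group(1) == "+" else -1
        return text[: m.start()], sign * int(m.group(2))
    m = _CHARGE_SIGNS_RE.search(text)
    if m:
        signs = m.group(1)
        sign = 1 if signs[0] == "+" else -1
        if any((c == "+") != (sign > 0) for c in signs):
            raise FormulaError(f"mixed charge signs in {text!r}")
        return text[: m.start()], sign * len(signs)
    return text, 0


def _parse_part(text: str, masses: ElementMassTable) -> FormulaPart:
    text, charge = _strip_charge(text)
    if not text:
        raise FormulaError("empty formula part")
    counts: Dict[str, int] = {}
    pos = 0
    while pos < len(text):
        m = _TOKEN_RE.match(text, pos)
        if not m or m.start() != pos or not m.group(1):
            raise FormulaError(
                f"malformed formula near {text[pos:pos + 4]!r} in {text!r}"
            )
        symbol, digits = m.group(1), m.group(2)
        if symbol not in masses:
            # two-letter guesses like "Cl" vs "C" are resolved by the regex
            # greedily; reject anything not in the mass table outright.
            raise FormulaError(f"unknown element symbol {symbol!r} in {text!r}")
        n = int(digits) if digits else 1
        if n <= 0:
            raise FormulaError(f"zero count for {symbol} in {text!r}")
        counts[symbol] = counts.get(symbol, 0) + n
        pos = m.end()
    return FormulaPart.from_counts(counts, charge)


def parse_formula(
    text: str, masses: ElementMassTable = MASS_TABLE
) -> MolecularFormula:
    """Parse formula text such as ``C9H16ClN5``, ``C8F17O3S-`` or
    ``C31H42N3+.C2H3O2-`` into a :class:`MolecularFormula`.

    Dots separate parts; a trailing run of sign characters (ASCII or the
    Unicode minus) or a ``2-``-style suffix sets a part's charge.

    Raises
    ------
    FormulaError
        On empty input, unknown element symbols, or malformed counts; the
        message identifies the offending token.
    """
    if not isinstance(text, str) or not text.strip():
        raise FormulaError("empty formula")
    parts = tuple(
        _parse_part(chunk.strip(), masses)
        for chunk in text.replace("·", ".").split(".")
        if True
    )
    if any(not p.counts for p in parts):
        raise FormulaError(f"empty part in {text!r}")
    return MolecularFormula(parts)


def monoisotopic_mass(
    formula: MolecularFormula | str, masses: ElementMassTable = MASS_TABLE
) -> float:
    """Monoisotopic mass in Da: sum of most-abundant-isotope masses over all
    parts, corrected by ``-charge x electron mass`` per part."""
    if isinstance(formula, str):
        formula = parse_formula(formula, masses)
    total = 0.0
    for part in formula.parts:
        for el, n in part.counts:
            total += n * masses[el]
        total -= part.charge * masses.electron_mass
    return total


@dataclass(frozen=True)
class AdductSpec:
    """A pseudomolecular-ion species: M (intrinsic), M+H or M-H.

    ``M`` with charge +1/-1 models intrinsic ions (e.g. quaternary
    ammonium); charge 0 is the neutral molecule itself.
    """

    kind: str  # "M", "M+H", "M-H"
    charge: int = 0

    def __post_init__(self):
        if self.kind not in ("M", "M+H", "M-H"):
            raise ValueError(f"unsupported adduct kind {self.kind!r}")
        if self.kind == "M+H" and self.charge != 1:
            raise ValueError("M+H implies charge +1")
        if self.kind == "M-H" and self.charge != -1:
            raise ValueError("M-H implies charge -1")
        if self.kind == "M" and self.charge not in (-1, 0, 1):
            raise ValueError("multiply charged adducts are not supported")


def adduct_mz(
    formula: MolecularFormula | str,
    adduct: AdductSpec,
    masses: ElementMassTable = MASS_TABLE,
) -> float:
    """m/z of the given adduct of a neutral formula.

    M+H adds one proton mass; M-H subtracts one; an intrinsic ion M with
    charge q subtracts ``q x electron mass`` from the summed atomic masses.
    """
    if isinstance(formula, str):
        formula = parse_formula(formula, masses)
    neutral = monoisotopic_mass(formula, masses)
    if adduct.kind == "M+H":
        return neutral + masses.proton_mass
    if adduct.kind == "M-H":
        return neutral - masses.proton_mass
    return neutral - adduct.charge * masses.electron_mass


@dataclass
class MoleculeRecord:
    """One input structure (SMILES or molblock) with provenance identifiers."""

    structure: str
    identifier: str
    name: str = ""
    casrn: Optional[str] = None
    metadata: Dict[str, object] = field(default_factory=dict)

    def to_mol(self) -> Chem.Mol:
        return mol_from_record(self)


def mol_from_record(record: "MoleculeRecord") -> Chem.Mol:
    """Parse a record's structure text, trying SMILES then molblock."""
    text = record.structure
    mol = None
    if "\n" in text or "M  END" in text:
        mol = Chem.MolFromMolBlock(text, sanitize=True)
    else:
        mol = Chem.MolFromSmiles(text)
    if mol is None or mol.GetNumAtoms() == 0:
        raise ValueError(
            f"unparseable structure for record {record.identifier!r}"
        )
    return mol


def formula_of(
    mol: Chem.Mol, masses: ElementMassTable = MASS_TABLE
) -> MolecularFormula:
    """Hill-order formula of an RDKit molecule, one part per fragment.

    Implicit hydrogens are counted; per-part charge is the sum of the
    fragment's formal charges.
    """
    frags = Chem.GetMolFrags(mol, asMols=True, sanitizeFrags=False)
    parts: List[FormulaPart] = []
    for frag in frags:
        counts: Dict[str, int] = {}
        charge = 0
        for atom in frag.GetAtoms():
            sym = atom.GetSymbol()
            if sym not in masses:
                raise FormulaError(f"element {sym!r} not in the mass table")
            counts[sym] = counts.get(sym, 0) + 1
            nh = atom.GetTotalNumHs()
            if nh:
                counts["H"] = counts.get("H", 0) + nh
            charge += atom.GetFormalCharge()
        parts.append(FormulaPart.from_counts(counts, charge))
    # deterministic part order: heavy-atom count desc, then Hill text
    parts.sort(key=lambda p: (-sum(n for el, n in p.counts if el != "H"), p.hill))
    return MolecularFormula(tuple(parts))


_INCHIKEY_RE = re.compile(r"^[A-Z]{14}-[A-Z]{8}[A-Z]{2}-[A-Z]$")


def inchikey(structure: "MoleculeRecord | Chem.Mol | str") -> str:
    """Standard InChIKey (27 characters) of a structure.

    Accepts a :class:`MoleculeRecord`, an RDKit molecule, or SMILES text.
    Deterministic for identical structures; raises ``ValueError`` carrying
    the source identifier for unparseable records.
    """
    if isinstance(structure, MoleculeRecord):
        mol = mol_from_record(structure)
    elif isinstance(structure, Chem.Mol):
        mol = structure
    else:
        mol = Chem.MolFromSmiles(structure)
        if mol is None:
            raise ValueError(f"unparseable SMILES: {structure!r}")
    key = Chem.MolToInchiKey(mol)
    if not key:
        raise ValueError("InChIKey generation failed")
    return key


def first_block(key: str) -> str:
    """The 14-character connectivity-skeleton block of an InChIKey."""
    if not isinstance(key, str) or not _INCHIKEY_RE.match(key):
        raise ValueError(f"malformed InChIKey: {key!r}")
    return key.split("-", 1)[0]
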