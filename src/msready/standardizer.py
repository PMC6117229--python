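"""The MS-Ready structure-preparation pipeline.

A substance record (possibly a salt, mixture, or charged species) is turned
into zero or more standardized single-component structures suitable for
matching against HRMS-derived formulas and monoisotopic masses. The steps,
applied in order, are:

1. consistency checking (parse + valence sanitization),
2. separation into connected components and removal of inorganics,
3. removal of salts/counterions via an exclusion list,
4. tautomer/mesomer normalization to a canonical representation,
5. neutralization of charges and removal of stereochemistry,
6. aromatization and explicit-hydrogen bookkeeping for output,
7. deduplication of components by standard InChIKey.

Two modes are supported. ``msready`` retains mixture components (linked
back to their source substance) and organometallics with covalent
metal-carbon bonds. ``qsarready`` uses a larger exclusion list, discards
mixtures that still have more than one component after desalting, and
discards organometallics — the form needed for descriptor calculation
rather than mass-spectral matching.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Dict, FrozenSet, List, Optional, Sequence, Set, Tuple

import yaml
from rdkit import Chem
from rdkit.Chem import AllChem
from rdkit.Chem.MolStandardize import rdMolStandardize

from .chem_core import (
    MolecularFormula,
    MoleculeRecord,
    first_block,
    formula_of,
    inchikey,
    mol_from_record,
    monoisotopic_mass,
)

__all__ = [
    "METALS",
    "StandardizationConfig",
    "ComponentVerdict",
    "MSReadyResult",
    "TransformRule",
    "load_transform_rules",
    "load_exclusion_sdf",
    "check_consistency",
    "split_components",
    "classify_component",
    "apply_exclusion",
    "normalize_tautomer",
    "neutralize",
    "strip_stereo",
    "finalize",
    "standardize_substance",
    "exclusion_key",
]

# Alkali, alkaline-earth, transition, lanthanide/actinide and post-transition
# metals. B, Si, Ge, As, Sb, Te are treated as non-metals, matching common
# QSAR curation practice.
METALS: FrozenSet[str] = frozenset(
    """Li Na K Rb Cs Fr Be Mg Ca Sr Ba Ra
    Sc Ti V Cr Mn Fe Co Ni Cu Zn Y Zr Nb Mo Tc Ru Rh Pd Ag Cd
    Hf Ta W Re Os Ir Pt Au Hg
    Al Ga In Tl Sn Pb Bi Po
    La Ce Pr Nd Pm Sm Eu Gd Tb Dy Ho Er Tm Yb Lu
    Ac Th Pa U Np Pu Am Cm Bk Cf Es Fm Md No Lr""".split()
)


@dataclass(frozen=True)
class TransformRule:
    """One named, ordered tautomer/mesomer rewrite rule."""

    name: str
    smarts: str

    def reaction(self) -> AllChem.ChemicalReaction:
        rxn = AllChem.ReactionFromSmarts(self.smarts)
        if rxn is None:
            raise ValueError(f"bad transform SMARTS for rule {self.name!r}")
        return rxn


def load_transform_rules(path: Optional[str | Path] = None) -> Tuple[TransformRule, ...]:
    """Load the ordered transform-rule file (bundled default when *path* is None)."""
    if path is None:
        text = resources.files("msready").joinpath("data/transforms.txt").read_text()
    else:
        text = Path(path).read_text()
    rules = []
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        name, smarts = line.split("\t")
        rules.append(TransformRule(name, smarts))
    return tuple(rules)


def exclusion_key(mol: Chem.Mol) -> str:
    """Normalized InChIKey used for exclusion-list membership.

    The key is computed on the neutralized, stereochemistry-free form so
    that e.g. a benzoate entry also matches benzoic acid and vice versa.
    """
    work = Chem.Mol(mol)
    work.RemoveAllConformers()  # InChI would re-perceive stereo from 2D coords
    work, _ = _neutralize_mol(work)
    Chem.RemoveStereochemistry(work)
    return inchikey(work)


def load_exclusion_sdf(path: str | Path) -> Dict[str, str]:
    """Read an exclusion list from an SDF; returns normalized key -> label."""
    supplier = Chem.SDMolSupplier(str(path), sanitize=True, removeHs=True)
    entries: Dict[str, str] = {}
    for mol in supplier:
        if mol is None:
            continue
        label = (
            mol.GetProp("LABEL")
            if mol.HasProp("LABEL")
            else (mol.GetProp("_Name") if mol.HasProp("_Name") else "exclusion entry")
        )
        entries.setdefault(exclusion_key(mol), label)
    return entries


def _bundled_exclusion(mode: str) -> Dict[str, str]:
    fname = "exclusion_msready.sdf" if mode == "msready" else "exclusion_qsarready.sdf"
    with resources.as_file(
        resources.files("msready").joinpath("data").joinpath(fname)
    ) as p:
        return load_exclusion_sdf(p)


@dataclass
class StandardizationConfig:
    """Configuration of the preparation pipeline.

    Parameters
    ----------
    mode : {"msready", "qsarready"}
        Workflow variant; see the module docstring.
    exclusion : mapping of normalized InChIKey -> label
        Counterions/solvents removed from multi-component records. Defaults
        to the bundled list for the chosen mode.
    transform_rules : ordered tuple of TransformRule
        Tautomer/mesomer rewrites applied to a fixpoint.
    max_transform_iterations : int
        Cap on rule application passes per component (default 20).
    metals : set of element symbols treated as metals.
    """

    mode: str = "msready"
    exclusion: Optional[Dict[str, str]] = None
    transform_rules: Optional[Tuple[TransformRule, ...]] = None
    max_transform_iterations: int = 20
    metals: FrozenSet[str] = METALS

    def __post_init__(self):
        if self.mode not in ("msready", "qsarready"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.max_transform_iterations < 1:
            raise ValueError("max_transform_iterations must be >= 1")
        if self.exclusion is None:
            self.exclusion = _bundled_exclusion(self.mode)
        if self.transform_rules is None:
            self.transform_rules = load_transform_rules()

    @classmethod
    def from_yaml(cls, path: str | Path) -> "StandardizationConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        kwargs = {}
        if "mode" in data:
            kwargs["mode"] = data["mode"]
        if "max_transform_iterations" in data:
            kwargs["max_transform_iterations"] = int(data["max_transform_iterations"])
        if "exclusion_sdf" in data:
            kwargs["exclusion"] = load_exclusion_sdf(data["exclusion_sdf"])
        if "transform_file" in data:
            kwargs["transform_rules"] = load_transform_rules(data["transform_file"])
        if "metals" in data:
            kwargs["metals"] = frozenset(data["metals"])
        return cls(**kwargs)


@dataclass
class ComponentVerdict:
    """Classification outcome for one connected component."""

    component: MoleculeRecord
    component_class: str  # organic | inorganic | organometallic | excluded
    retained: bool
    reason: str = ""


@dataclass
class MSReadyResult:
    """Outcome of standardizing one substance record."""

    source_identifier: str
    components: List[MoleculeRecord] = field(default_factory=list)
    dropped: List[ComponentVerdict] = field(default_factory=list)
    status: str = "ok"  # ok | empty | error
    reason: str = ""

    @property
    def inchikeys(self) -> List[str]:
        return [c.metadata["inchikey"] for c in self.components]


# -- step 1: consistency ----------------------------------------------------


def check_consistency(record: MoleculeRecord) -> Chem.Mol:
    """Parse and sanitize a record; raises ``ValueError`` on valence or
    format problems, carrying the source identifier."""
    try:
        mol = mol_from_record(record)
    except Exception as exc:
        raise ValueError(f"{record.identifier}: {exc}") from exc
    try:
        Chem.SanitizeMol(mol)
    except Exception as exc:
        raise ValueError(
            f"{record.identifier}: sanitization failed ({exc})"
        ) from exc
    return mol


# -- step 2: split & classify ------------------------------------------------


def split_components(mol: Chem.Mol) -> List[Chem.Mol]:
    """Connected components in deterministic order: heavy-atom count
    descending, ties broken by canonical SMILES."""
    frags = list(Chem.GetMolFrags(mol, asMols=True, sanitizeFrags=True))
    frags.sort(key=lambda m: (-m.GetNumHeavyAtoms(), Chem.MolToSmiles(m)))
    return frags


_INORGANIC_CARBON_SMARTS = [
    # carbon only in CO/CO2/carbonate/cyanide-like environments
    Chem.MolFromSmarts("[C;$(C(=O)=O)]"),                       # CO2
    Chem.MolFromSmarts("[C;$([CX1]#[O+0,O+1])]"),               # CO
    Chem.MolFromSmarts("[C;$(C(=O)([OX2,OX1-])[OX2,OX1-])]"),   # carbonate/bicarbonate
    Chem.MolFromSmarts("[C;$([CH]#N),$([C-]#N),$(C(#N)[O,S;X1-,X2])]"),  # HCN/CN-/OCN/SCN
    Chem.MolFromSmarts("[C;X0,$([C-4])]"),                      # bare carbide
]


def _carbon_is_inorganic(mol: Chem.Mol) -> bool:
    carbons = {a.GetIdx() for a in mol.GetAtoms() if a.GetSymbol() == "C"}
    if not carbons:
        return True
    covered: Set[int] = set()
    for patt in _INORGANIC_CARBON_SMARTS:
        for match in mol.GetSubstructMatches(patt):
            covered.update(i for i in match if i in carbons)
    return carbons <= covered


def _has_metal_carbon_bond(mol: Chem.Mol, metals: FrozenSet[str]) -> bool:
    for bond in mol.GetBonds():
        a, b = bond.GetBeginAtom(), bond.GetEndAtom()
        syms = {a.GetSymbol(), b.GetSymbol()}
        if "C" in syms and syms & metals:
            return True
    return False


def classify_component(
    component: Chem.Mol,
    config: StandardizationConfig,
    record: Optional[MoleculeRecord] = None,
) -> ComponentVerdict:
    """Assign organic / inorganic / organometallic / excluded and decide
    retention under the configured mode.

    A component is *excluded* when the InChIKey of its neutralized,
    stereo-stripped form is on the exclusion list (the multi-component
    guard is applied later by :func:`apply_exclusion`). Organometallics
    (covalent metal-carbon bond) are retained in msready mode only.
    """
    rec = record or MoleculeRecord(Chem.MolToSmiles(component), "component")
    key = exclusion_key(component)
    if key in config.exclusion:
        return ComponentVerdict(
            rec, "excluded", False, reason=config.exclusion[key]
        )
    has_carbon = any(a.GetSymbol() == "C" for a in component.GetAtoms())
    if not has_carbon or _carbon_is_inorganic(component):
        return ComponentVerdict(rec, "inorganic", False, reason="no organic carbon")
    if _has_metal_carbon_bond(component, config.metals):
        retained = config.mode == "msready"
        return ComponentVerdict(
            rec,
            "organometallic",
            retained,
            reason="" if retained else "organometallic dropped in qsarready mode",
        )
    return ComponentVerdict(rec, "organic", True)


def apply_exclusion(
    components: Sequence[Chem.Mol],
    config: StandardizationConfig,
) -> Tuple[List[Chem.Mol], List[ComponentVerdict]]:
    """Drop inorganics, excluded counterions and (mode-dependent)
    organometallics from a component list.

    The exclusion list only fires for records with two or more components:
    a substance that *is* acetic acid must remain searchable even though
    acetate appears on a counterion list.
    """
    multi = len(components) > 1
    retained: List[Chem.Mol] = []
    dropped: List[ComponentVerdict] = []
    for comp in components:
        verdict = classify_component(comp, config)
        if verdict.component_class == "excluded" and not multi:
            retained.append(comp)  # single-component records are never desalted away
        elif verdict.retained:
            retained.append(comp)
        else:
            dropped.append(verdict)
    return retained, dropped


# -- step 4: tautomer / mesomer normalization --------------------------------

_TAUTOMER_CANONICALIZER = rdMolStandardize.TautomerEnumerator()


def _element_counts(mol: Chem.Mol) -> Dict[str, int]:
    counts: Dict[str, int] = {}
    for atom in mol.GetAtoms():
        counts[atom.GetSymbol()] = counts.get(atom.GetSymbol(), 0) + 1
        nh = atom.GetTotalNumHs()
        if nh:
            counts["H"] = counts.get("H", 0) + nh
    return counts


def normalize_tautomer(
    component: Chem.Mol, config: StandardizationConfig
) -> Tuple[Chem.Mol, str]:
    """Apply the ordered transform rules to a fixpoint, then the toolkit's
    canonical-tautomer tie-breaker. Returns (molecule, flag); the flag is
    empty or ``"max-iterations"`` when the rules did not converge.

    The molecular formula is conserved: a transform product with a
    different element count is rejected and the rule skipped.
    """
    work = Chem.Mol(component)
    before = _element_counts(work)
    flag = ""
    iterations = 0
    changed = True
    while changed and iterations < config.max_transform_iterations:
        changed = False
        iterations += 1
        for rule in config.transform_rules:
            rxn = rule.reaction()
            products = rxn.RunReactants((work,))
            if not products:
                continue
            candidate = products[0][0]
            try:
                Chem.SanitizeMol(candidate)
            except Exception:
                continue
            if _element_counts(candidate) != before:
                continue  # formula must be conserved; skip misfiring rule
            if Chem.MolToSmiles(candidate) == Chem.MolToSmiles(work):
                continue
            work = candidate
            changed = True
    if changed:
        flag = "max-iterations"
    # toolkit canonicalization as the final deterministic tie-break
    try:
        canon = _TAUTOMER_CANONICALIZER.Canonicalize(work)
        if canon is not None and _element_counts(canon) == before:
            work = canon
    except Exception:
        pass
    return work, flag


# -- step 5: neutralization & stereo removal ---------------------------------

_PROTONATABLE = {"O", "S", "N", "C", "P", "Se"}


def _neutralize_mol(mol: Chem.Mol) -> Tuple[Chem.Mol, bool]:
    """Add/remove protons to reach net charge 0 where chemically possible.

    Atoms participating in a charge-separated dipole (a formally charged
    atom bonded to an oppositely charged neighbour, as in nitro or azide
    groups) are left untouched. Returns (molecule, permanent_charge_flag).
    """
    work = Chem.RWMol(mol)
    for atom in work.GetAtoms():
        charge = atom.GetFormalCharge()
        if charge == 0:
            continue
        if any(
            n.GetFormalCharge() * charge < 0 for n in atom.GetNeighbors()
        ):
            continue  # ylide / charge-separated mesomer: keep as drawn
        if charge < 0 and atom.GetSymbol() in _PROTONATABLE:
            atom.SetFormalCharge(0)
            atom.SetNumExplicitHs(atom.GetTotalNumHs() + (-charge))
            atom.SetNoImplicit(True)
        elif charge > 0:
            hs = atom.GetTotalNumHs()
            remove = min(hs, charge)
            if remove:
                atom.SetFormalCharge(charge - remove)
                atom.SetNumExplicitHs(hs - remove)
                atom.SetNoImplicit(True)
    out = work.GetMol()
    Chem.SanitizeMol(out)
    permanent = Chem.GetFormalCharge(out) != 0
    return out, permanent


def neutralize(component: Chem.Mol) -> Tuple[Chem.Mol, bool]:
    """Neutralize protonatable/deprotonatable centres; permanently charged
    species (quaternary ammonium, stabilized carbenium, bare metal cations)
    keep their charge and are flagged ``True``."""
    return _neutralize_mol(component)


def strip_stereo(component: Chem.Mol) -> Chem.Mol:
    """Remove tetrahedral and double-bond stereo descriptors. Isotopic
    labels are retained (they shift the monoisotopic mass, which matters
    for MS matching); the InChIKey first block is unchanged."""
    work = Chem.Mol(component)
    work.RemoveAllConformers()  # 2D coords would let InChI re-perceive stereo
    Chem.RemoveStereochemistry(work)
    return work


# -- step 6: finalize ---------------------------------------------------------


def finalize(
    component: Chem.Mol,
    source_identifier: str = "",
    permanent_charge: bool = False,
    flag: str = "",
) -> MoleculeRecord:
    """Aromatize, compute formula/InChIKey/mass, and wrap into an
    output-ready :class:`MoleculeRecord` whose structure is the canonical
    aromatic SMILES. SDF emission adds explicit hydrogens separately."""
    Chem.SanitizeMol(component)
    formula = formula_of(component)
    key = inchikey(component)
    record = MoleculeRecord(
        structure=Chem.MolToSmiles(component),
        identifier=source_identifier or key,
        metadata={
            "formula": formula.display,
            "inchikey": key,
            "first_block": first_block(key),
            "monoisotopic_mass": monoisotopic_mass(formula),
            "permanent_charge": permanent_charge,
        },
    )
    if flag:
        record.metadata["flag"] = flag
    return record


# -- step 7 + composition -----------------------------------------------------


def standardize_substance(
    record: MoleculeRecord,
    config: Optional[StandardizationConfig] = None,
) -> MSReadyResult:
    """Run the full preparation pipeline on one substance record.

    Pipeline order: consistency -> split -> classify/exclusion ->
    per-component (tautomer -> neutralize -> strip stereo -> finalize) ->
    within-substance InChIKey dedup. In ``qsarready`` mode a record that
    still has more than one retained component is discarded as a mixture.
    """
    config = config or StandardizationConfig()
    result = MSReadyResult(source_identifier=record.identifier)
    try:
        mol = check_consistency(record)
    except ValueError as exc:
        result.status = "error"
        result.reason = str(exc)
        return result

    components = split_components(mol)
    retained, dropped = apply_exclusion(components, config)
    result.dropped.extend(dropped)

    finals: List[MoleculeRecord] = []
    seen: Set[str] = set()
    for comp in retained:
        comp, flag = normalize_tautomer(comp, config)
        comp, permanent = neutralize(comp)
        comp = strip_stereo(comp)
        out = finalize(
            comp,
            source_identifier=f"{record.identifier}",
            permanent_charge=permanent,
            flag=flag,
        )
        if out.metadata["inchikey"] in seen:
            continue
        seen.add(out.metadata["inchikey"])
        finals.append(out)

    if config.mode == "qsarready" and len(finals) > 1:
        for out in finals:
            result.dropped.append(
                ComponentVerdict(
                    out, "organic", False, reason="mixture discarded in qsarready mode"
                )
            )
        finals = []

    result.components = finals
    if not finals:
        if result.status != "error":
            result.status = "empty"
            if not result.reason:
                result.reason = "no retained components"
    return result
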