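"""Exact and MS-Ready searching by molecular formula and monoisotopic mass.

An *exact* formula search matches the overall (merged) formula of the
substance as registered, so a salt or mixture is only returned when the
query describes the whole record. An *MS-Ready* search matches the
formulas of the standardized single components and follows the mapping
table back to every substance containing that component — the neutral
form, all salt forms, and mixtures alike. Charged queries (e.g. the PFOS
sulfonate ``C8F17O3S-``) are neutralized by one hydrogen per unit charge
before MS-Ready matching.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Union

import pandas as pd

from .chem_core import (
    FormulaError,
    FormulaPart,
    MolecularFormula,
    monoisotopic_mass,
    parse_formula,
)
from .registry import Registry, SubstanceRecord

__all__ = [
    "SearchQuery",
    "SearchHit",
    "DEFAULT_PPM",
    "exact_formula_search",
    "msready_formula_search",
    "mass_search",
    "batch_search",
    "neutralize_formula",
]

#: Default mass tolerance in parts per million.
DEFAULT_PPM = 5.0


@dataclass(frozen=True)
class SearchQuery:
    kind: str                     # "formula" | "mass"
    value: Union[str, float]
    semantics: str = "msready"    # "msready" | "exact"
    ppm: Optional[float] = None
    mz_abs: Optional[float] = None

    def __post_init__(self):
        if self.kind not in ("formula", "mass"):
            raise ValueError(f"unknown query kind {self.kind!r}")
        if self.semantics not in ("msready", "exact"):
            raise ValueError(f"unknown semantics {self.semantics!r}")
        if self.kind == "mass":
            if float(self.value) <= 0:
                raise ValueError("mass must be positive")
            if self.ppm is not None and self.ppm <= 0:
                raise ValueError("ppm tolerance must be positive")
            if self.mz_abs is not None and self.mz_abs <= 0:
                raise ValueError("absolute tolerance must be positive")
        elif self.ppm is not None or self.mz_abs is not None:
            raise ValueError("formula queries carry no tolerance")


@dataclass
class SearchHit:
    """One (query, matched component, mapped substance) result row."""

    query: str
    found_by: str
    chemical_id: str          # matched individual component (CID)
    substance_id: str         # mapped substance (SID)
    substance_source_id: str
    substance_name: str
    substance_formula: str
    component_formula: str
    component_mass: float
    data_sources: int = 0


def neutralize_formula(formula: MolecularFormula) -> MolecularFormula:
    """Neutralize a charged query formula by adding one H per negative
    charge and removing one per positive charge (an anion observed in
    negative mode corresponds to the neutral acid)."""
    parts = []
    for part in formula.parts:
        q = part.charge
        if q == 0:
            parts.append(part)
            continue
        counts = part.as_dict()
        counts["H"] = counts.get("H", 0) - q
        if counts["H"] < 0:
            raise FormulaError(
                f"cannot neutralize {part.hill!r}: would need negative hydrogens"
            )
        parts.append(FormulaPart.from_counts(counts, 0))
    return MolecularFormula(tuple(parts))


def _as_formula(formula: Union[str, MolecularFormula]) -> MolecularFormula:
    return parse_formula(formula) if isinstance(formula, str) else formula


def _hit(
    query: str,
    found_by: str,
    chem,
    sub: SubstanceRecord,
) -> SearchHit:
    return SearchHit(
        query=query,
        found_by=found_by,
        chemical_id=chem.cid,
        substance_id=sub.sid,
        substance_source_id=sub.source_id,
        substance_name=sub.name,
        substance_formula=sub.formula_parts or sub.formula,
        component_formula=chem.formula,
        component_mass=chem.monoisotopic_mass,
        data_sources=sub.data_sources,
    )


def _rank(hits: List[SearchHit]) -> List[SearchHit]:
    hits.sort(key=lambda h: (-h.data_sources, h.substance_id, h.chemical_id))
    return hits


def exact_formula_search(
    registry: Registry, formula: Union[str, MolecularFormula]
) -> List[SearchHit]:
    """Substances whose overall merged formula equals the query exactly.

    The query must be neutral; mixtures where only a component matches are
    *not* returned.
    """
    f = _as_formula(formula)
    if f.charge != 0:
        raise FormulaError("exact formula search accepts neutral formulas only")
    target = f.merged().display
    hits: List[SearchHit] = []
    for sub in registry.substances():
        if sub.formula == target:
            chem = registry.chemical(registry._original_chemical_id(sub.sid))
            hits.append(_hit(target, "EXACT_FORMULA", chem, sub))
    return _rank(hits)


def msready_formula_search(
    registry: Registry, formula: Union[str, MolecularFormula]
) -> List[SearchHit]:
    """Substances linked to an MS-Ready component whose formula equals the
    (neutralized) query; single- and multi-component substances are both
    returned, ranked by data-source count descending."""
    f = neutralize_formula(_as_formula(formula))
    target = f.merged().display
    hits: List[SearchHit] = []
    seen = set()
    for chem in registry.chemicals(msready_only=True):
        if chem.formula != target:
            continue
        for sub in registry.substances_for_chemical(chem.cid):
            if (chem.cid, sub.sid) in seen:
                continue
            seen.add((chem.cid, sub.sid))
            hits.append(_hit(target, "MSREADY_FORMULA", chem, sub))
    return _rank(hits)


def mass_search(
    registry: Registry,
    mass: float,
    ppm: Optional[float] = DEFAULT_PPM,
    mz_abs: Optional[float] = None,
    semantics: str = "msready",
) -> List[SearchHit]:
    """Match monoisotopic masses within a ppm or absolute-Da window.

    ``msready`` semantics matches MS-Ready component masses; ``exact``
    matches the overall substance mass. ``found_by`` records the signed
    ppm deviation of each match.
    """
    if mass <= 0:
        raise ValueError("mass must be positive")
    if mz_abs is not None:
        if mz_abs <= 0:
            raise ValueError("absolute tolerance must be positive")
        window = mz_abs
    else:
        if ppm is None or ppm <= 0:
            raise ValueError("ppm tolerance must be positive")
        window = mass * ppm * 1e-6
    hits: List[SearchHit] = []
    if semantics == "msready":
        for chem in registry.chemicals(msready_only=True):
            dev = chem.monoisotopic_mass - mass
            if abs(dev) <= window:
                tag = f"MSREADY_MASS ({dev / mass * 1e6:+.2f} ppm)"
                for sub in registry.substances_for_chemical(chem.cid):
                    hits.append(_hit(f"{mass:.4f}", tag, chem, sub))
    elif semantics == "exact":
        for sub in registry.substances():
            dev = sub.monoisotopic_mass - mass
            if abs(dev) <= window:
                chem = registry.chemical(registry._original_chemical_id(sub.sid))
                tag = f"EXACT_MASS ({dev / mass * 1e6:+.2f} ppm)"
                hits.append(_hit(f"{mass:.4f}", tag, chem, sub))
    else:
        raise ValueError(f"unknown semantics {semantics!r}")
    return _rank(hits)


def run_query(registry: Registry, query: SearchQuery) -> List[SearchHit]:
    if query.kind == "mass":
        return mass_search(
            registry,
            float(query.value),
            ppm=query.ppm if query.ppm is not None else (
                None if query.mz_abs is not None else DEFAULT_PPM
            ),
            mz_abs=query.mz_abs,
            semantics=query.semantics,
        )
    if query.semantics == "exact":
        return exact_formula_search(registry, str(query.value))
    return msready_formula_search(registry, str(query.value))


def batch_search(
    registry: Registry,
    queries: Union[str, Path, Sequence[str]],
    semantics: str = "msready",
    ppm: float = DEFAULT_PPM,
) -> pd.DataFrame:
    """Run one query per input line, auto-detecting masses (lines that
    parse as a number) vs formulas. Returns a result table in stable input
    order with an ``INPUT`` column echoing each line verbatim; lines that
    fail to parse get a single row with the error in ``FOUND_BY``."""
    if isinstance(queries, (str, Path)):
        lines = Path(queries).read_text().splitlines()
    else:
        lines = list(queries)
    rows: List[Dict[str, object]] = []
    for line in lines:
        text = line.strip()
        if not text:
            continue
        try:
            try:
                mass = float(text)
                is_mass = True
            except ValueError:
                is_mass = False
            if is_mass:
                hits = mass_search(registry, mass, ppm=ppm, semantics=semantics)
            elif semantics == "exact":
                hits = exact_formula_search(registry, text)
            else:
                hits = msready_formula_search(registry, text)
        except (FormulaError, ValueError) as exc:
            rows.append({"INPUT": line, "FOUND_BY": f"ERROR: {exc}"})
            continue
        for h in hits:
            rows.append(
                {
                    "INPUT": line,
                    "FOUND_BY": h.found_by,
                    "CHEMICAL_ID": h.chemical_id,
                    "SUBSTANCE_ID": h.substance_source_id,
                    "SUBSTANCE_NAME": h.substance_name,
                    "SUBSTANCE_FORMULA": h.substance_formula,
                    "COMPONENT_FORMULA": h.component_formula,
                    "COMPONENT_MASS": round(h.component_mass, 4),
                    "DATA_SOURCES": h.data_sources,
                }
            )
        if not hits:
            rows.append({"INPUT": line, "FOUND_BY": "NO_MATCH"})
    columns = [
        "INPUT", "FOUND_BY", "CHEMICAL_ID", "SUBSTANCE_ID", "SUBSTANCE_NAME",
        "SUBSTANCE_FORMULA", "COMPONENT_FORMULA", "COMPONENT_MASS", "DATA_SOURCES",
    ]
    return pd.DataFrame(rows, columns=columns)
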