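"""Substance/chemical stores and the structure relationship mapping table.

A *substance* is a registered entry as supplied (possibly a salt or
mixture) with a surrogate ``SID``-prefixed identifier; a *chemical* is one
unique structure keyed by standard InChIKey with a ``CID``-prefixed
identifier. Three typed links connect them:

* ``has_structure``  — substance -> its original (full, multi-component) chemical
* ``component_of``   — MS-Ready component chemical -> substance
* ``msready_of``     — MS-Ready component chemical -> original chemical

Storage is a single-file embedded SQLite database (or in-memory), with a
flat-file SDF + TSV export that round-trips.
"""

from __future__ import annotations

import json
import logging
import sqlite3
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence, Union

import pandas as pd
from rdkit import Chem

from .chem_core import (
    MoleculeRecord,
    formula_of,
    inchikey,
    mol_from_record,
    monoisotopic_mass,
    parse_formula,
)
from .standardizer import MSReadyResult, StandardizationConfig, standardize_substance

logger = logging.getLogger(__name__)

__all__ = ["SubstanceRecord", "ChemicalRecord", "MappingEntry", "Registry"]


@dataclass
class SubstanceRecord:
    """A registered substance: the entity as supplied, plus metadata."""

    sid: str
    source_id: str
    name: str = ""
    casrn: Optional[str] = None
    formula: str = ""        # merged Hill formula of the full structure
    formula_parts: str = ""  # dot-separated per-component Hill formula
    monoisotopic_mass: float = 0.0
    metadata: Dict[str, object] = field(default_factory=dict)

    @property
    def data_sources(self) -> int:
        return int(self.metadata.get("data_sources", 0) or 0)


@dataclass
class ChemicalRecord:
    """One unique structure, keyed by standard InChIKey."""

    cid: str
    smiles: str
    inchikey: str
    formula: str
    monoisotopic_mass: float


@dataclass(frozen=True)
class MappingEntry:
    from_id: str
    to_id: str
    relation: str  # has_structure | component_of | msready_of


_SCHEMA = """
CREATE TABLE IF NOT EXISTS substances (
    sid TEXT PRIMARY KEY,
    source_id TEXT UNIQUE NOT NULL,
    name TEXT,
    casrn TEXT,
    formula TEXT,
    formula_parts TEXT,
    mass REAL,
    metadata TEXT
);
CREATE TABLE IF NOT EXISTS chemicals (
    cid TEXT PRIMARY KEY,
    smiles TEXT,
    inchikey TEXT UNIQUE NOT NULL,
    formula TEXT,
    mass REAL,
    msready INTEGER DEFAULT 0
);
CREATE TABLE IF NOT EXISTS mappings (
    from_id TEXT NOT NULL,
    to_id TEXT NOT NULL,
    relation TEXT NOT NULL,
    UNIQUE (from_id, to_id, relation)
);
CREATE TABLE IF NOT EXISTS unmapped (
    sid TEXT PRIMARY KEY,
    reason TEXT
);
CREATE INDEX IF NOT EXISTS idx_chem_formula ON chemicals (formula);
CREATE INDEX IF NOT EXISTS idx_map_rel ON mappings (relation, from_id, to_id);
"""


class Registry:
    """Embedded store for substances, chemicals and their typed links."""

    def __init__(self, path: Union[str, Path] = ":memory:"):
        self._conn = sqlite3.connect(str(path))
        self._conn.executescript(_SCHEMA)

    # -- id allocation -------------------------------------------------------

    def _next_id(self, table: str, prefix: str) -> str:
        row = self._conn.execute(f"SELECT COUNT(*) FROM {table}").fetchone()
        return f"{prefix}{row[0] + 1:07d}"

    # -- ingest ---------------------------------------------------------------

    def ingest_substances(
        self, source: Union[str, Path, Sequence[MoleculeRecord]]
    ) -> int:
        """Register substances (and their original chemicals, unified by
        InChIKey) from an SDF file, a SMILES/CSV table, or an in-memory
        record sequence. Returns the number registered; records without a
        usable identifier are skipped with a logged reason."""
        records = (
            list(source)
            if not isinstance(source, (str, Path))
            else _read_records(Path(source))
        )
        count = 0
        for rec in records:
            if not rec.identifier:
                logger.warning("skipping record without identifier")
                continue
            try:
                self.register_substance(rec)
            except ValueError as exc:
                logger.warning("skipping %s: %s", rec.identifier, exc)
                continue
            count += 1
        self._conn.commit()
        return count

    def register_substance(self, record: MoleculeRecord) -> SubstanceRecord:
        """Register one substance and its original structure."""
        existing = self._conn.execute(
            "SELECT sid FROM substances WHERE source_id = ?", (record.identifier,)
        ).fetchone()
        if existing:
            raise ValueError(f"duplicate substance identifier {record.identifier!r}")
        mol = mol_from_record(record)
        formula = formula_of(mol)
        merged = formula.merged().display
        sid = self._next_id("substances", "SID")
        self._conn.execute(
            "INSERT INTO substances VALUES (?,?,?,?,?,?,?,?)",
            (
                sid,
                record.identifier,
                record.name,
                record.casrn,
                merged,
                formula.display,
                monoisotopic_mass(formula),
                json.dumps(record.metadata, sort_keys=True),
            ),
        )
        cid = self._register_chemical(mol, msready=False)
        self._add_mapping(sid, cid, "has_structure")
        return self.substance(sid)

    def _register_chemical(self, mol: Chem.Mol, msready: bool) -> str:
        key = inchikey(mol)
        row = self._conn.execute(
            "SELECT cid, msready FROM chemicals WHERE inchikey = ?", (key,)
        ).fetchone()
        if row:
            if msready and not row[1]:
                self._conn.execute(
                    "UPDATE chemicals SET msready = 1 WHERE cid = ?", (row[0],)
                )
            return row[0]
        cid = self._next_id("chemicals", "CID")
        formula = formula_of(mol)
        self._conn.execute(
            "INSERT INTO chemicals VALUES (?,?,?,?,?,?)",
            (
                cid,
                Chem.MolToSmiles(mol),
                key,
                formula.display,
                monoisotopic_mass(formula),
                int(msready),
            ),
        )
        return cid

    # -- MS-Ready attachment ---------------------------------------------------

    def attach_msready(self, sid_or_source: str, result: MSReadyResult) -> List[MappingEntry]:
        """Register a standardization result's components and link them:
        ``component_of`` component -> substance and ``msready_of``
        component -> the substance's original chemical. Empty results are
        recorded as unmapped. Returns the new mapping entries."""
        sub = self._resolve_substance(sid_or_source)
        if sub is None:
            raise KeyError(f"unknown substance id {sid_or_source!r}")
        if result.status == "error":
            raise ValueError(
                f"cannot attach errored result for {result.source_identifier!r}"
            )
        original_cid = self._original_chemical_id(sub.sid)
        entries: List[MappingEntry] = []
        for comp in result.components:
            mol = Chem.MolFromSmiles(comp.structure)
            cid = self._register_chemical(mol, msready=True)
            for entry in (
                MappingEntry(cid, sub.sid, "component_of"),
                MappingEntry(cid, original_cid, "msready_of"),
            ):
                if self._add_mapping(entry.from_id, entry.to_id, entry.relation):
                    entries.append(entry)
        if not result.components:
            self._conn.execute(
                "INSERT OR REPLACE INTO unmapped VALUES (?,?)",
                (sub.sid, result.reason or result.status),
            )
        self._conn.commit()
        return entries

    def process_all(
        self, config: Optional[StandardizationConfig] = None
    ) -> Dict[str, MSReadyResult]:
        """Standardize every registered substance and attach the results."""
        config = config or StandardizationConfig()
        results: Dict[str, MSReadyResult] = {}
        for sub in self.substances():
            record = self._substance_record_input(sub)
            result = standardize_substance(record, config)
            results[sub.sid] = result
            if result.status != "error":
                self.attach_msready(sub.sid, result)
        return results

    def _substance_record_input(self, sub: SubstanceRecord) -> MoleculeRecord:
        cid = self._original_chemical_id(sub.sid)
        chem = self.chemical(cid)
        return MoleculeRecord(
            chem.smiles, sub.source_id, name=sub.name, casrn=sub.casrn,
            metadata=dict(sub.metadata),
        )

    # -- lookups ----------------------------------------------------------------

    def substance(self, sid: str) -> SubstanceRecord:
        row = self._conn.execute(
            "SELECT * FROM substances WHERE sid = ? OR source_id = ?", (sid, sid)
        ).fetchone()
        if row is None:
            raise KeyError(f"unknown substance id {sid!r}")
        return _substance_from_row(row)

    def _resolve_substance(self, sid: str) -> Optional[SubstanceRecord]:
        try:
            return self.substance(sid)
        except KeyError:
            return None

    def substances(self) -> List[SubstanceRecord]:
        rows = self._conn.execute("SELECT * FROM substances ORDER BY sid").fetchall()
        return [_substance_from_row(r) for r in rows]

    def chemical(self, cid: str) -> ChemicalRecord:
        row = self._conn.execute(
            "SELECT cid, smiles, inchikey, formula, mass FROM chemicals WHERE cid = ?",
            (cid,),
        ).fetchone()
        if row is None:
            raise KeyError(f"unknown chemical id {cid!r}")
        return ChemicalRecord(*row)

    def chemical_by_inchikey(self, key: str) -> Optional[ChemicalRecord]:
        row = self._conn.execute(
            "SELECT cid, smiles, inchikey, formula, mass FROM chemicals WHERE inchikey = ?",
            (key,),
        ).fetchone()
        return ChemicalRecord(*row) if row else None

    def chemicals(self, msready_only: bool = False) -> List[ChemicalRecord]:
        q = "SELECT cid, smiles, inchikey, formula, mass FROM chemicals"
        if msready_only:
            q += " WHERE msready = 1"
        return [ChemicalRecord(*r) for r in self._conn.execute(q + " ORDER BY cid")]

    def mappings(self, relation: Optional[str] = None) -> List[MappingEntry]:
        if relation:
            rows = self._conn.execute(
                "SELECT from_id, to_id, relation FROM mappings WHERE relation = ?",
                (relation,),
            )
        else:
            rows = self._conn.execute("SELECT from_id, to_id, relation FROM mappings")
        return [MappingEntry(*r) for r in rows]

    def unmapped(self) -> Dict[str, str]:
        return dict(self._conn.execute("SELECT sid, reason FROM unmapped"))

    def _original_chemical_id(self, sid: str) -> str:
        row = self._conn.execute(
            "SELECT to_id FROM mappings WHERE from_id = ? AND relation = 'has_structure'",
            (sid,),
        ).fetchone()
        if row is None:
            raise KeyError(f"substance {sid!r} has no original structure link")
        return row[0]

    def _add_mapping(self, from_id: str, to_id: str, relation: str) -> bool:
        cur = self._conn.execute(
            "INSERT OR IGNORE INTO mappings VALUES (?,?,?)", (from_id, to_id, relation)
        )
        return cur.rowcount > 0

    # -- traversal ---------------------------------------------------------------

    def substances_for_chemical(self, cid: str) -> List[SubstanceRecord]:
        """All substances linked to this chemical: directly via
        ``component_of``/``has_structure``, or through its ``msready_of``
        parent originals. Ordered by data-source count descending, then id."""
        self.chemical(cid)  # raise KeyError for unknown ids
        sids = set()
        for (sid,) in self._conn.execute(
            "SELECT to_id FROM mappings WHERE from_id = ? AND relation = 'component_of'",
            (cid,),
        ):
            sids.add(sid)
        for (sid,) in self._conn.execute(
            "SELECT from_id FROM mappings WHERE to_id = ? AND relation = 'has_structure'",
            (cid,),
        ):
            sids.add(sid)
        for (parent,) in self._conn.execute(
            "SELECT to_id FROM mappings WHERE from_id = ? AND relation = 'msready_of'",
            (cid,),
        ):
            for (sid,) in self._conn.execute(
                "SELECT from_id FROM mappings WHERE to_id = ? AND relation = 'has_structure'",
                (parent,),
            ):
                sids.add(sid)
        subs = [self.substance(s) for s in sids]
        subs.sort(key=lambda s: (-s.data_sources, s.sid))
        return subs

    def msready_components_for_substance(self, sid: str) -> List[ChemicalRecord]:
        sub = self.substance(sid)
        cids = [
            r[0]
            for r in self._conn.execute(
                "SELECT from_id FROM mappings WHERE to_id = ? AND relation = 'component_of'",
                (sub.sid,),
            )
        ]
        return [self.chemical(c) for c in sorted(cids)]

    # -- export / import ------------------------------------------------------------

    def export(self, directory: Union[str, Path]) -> None:
        """Write the registry to ``substances.sdf`` + ``mappings.tsv`` +
        ``chemicals.tsv`` in *directory*; re-ingesting yields identical
        id -> InChIKey mappings."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        writer = Chem.SDWriter(str(directory / "substances.sdf"))
        writer.SetKekulize(True)
        for sub in self.substances():
            chem = self.chemical(self._original_chemical_id(sub.sid))
            mol = Chem.MolFromSmiles(chem.smiles)
            mol.SetProp("_Name", sub.name or sub.source_id)
            mol.SetProp("SOURCE_ID", sub.source_id)
            mol.SetProp("PREFERRED_NAME", sub.name)
            if sub.casrn:
                mol.SetProp("CASRN", sub.casrn)
            mol.SetProp("METADATA", json.dumps(sub.metadata, sort_keys=True))
            writer.write(mol)
        writer.close()
        pd.DataFrame(
            [(m.from_id, m.to_id, m.relation) for m in self.mappings()],
            columns=["from_id", "to_id", "relation"],
        ).sort_values(["relation", "from_id", "to_id"]).to_csv(
            directory / "mappings.tsv", sep="\t", index=False
        )
        pd.DataFrame(
            [
                (c.cid, c.inchikey, c.formula, c.monoisotopic_mass, c.smiles)
                for c in self.chemicals()
            ],
            columns=["cid", "inchikey", "formula", "monoisotopic_mass", "smiles"],
        ).to_csv(directory / "chemicals.tsv", sep="\t", index=False)

    def id_to_inchikey(self) -> Dict[str, str]:
        return dict(self._conn.execute("SELECT cid, inchikey FROM chemicals"))

    def close(self) -> None:
        self._conn.close()


def _substance_from_row(row) -> SubstanceRecord:
    sid, source_id, name, casrn, formula, parts, mass, meta = row
    return SubstanceRecord(
        sid=sid,
        source_id=source_id,
        name=name or "",
        casrn=casrn,
        formula=formula,
        formula_parts=parts,
        monoisotopic_mass=mass,
        metadata=json.loads(meta) if meta else {},
    )


_ID_PROPS = ("SOURCE_ID", "DTXSID", "ID", "IDENTIFIER")


def _read_records(path: Path) -> List[MoleculeRecord]:
    """Read substance records from an SDF or a SMILES/CSV table."""
    if path.suffix.lower() in (".sdf", ".sd", ".mol"):
        return _read_sdf(path)
    return _read_table(path)


def _read_sdf(path: Path) -> List[MoleculeRecord]:
    records: List[MoleculeRecord] = []
    supplier = Chem.SDMolSupplier(str(path), sanitize=True, removeHs=True)
    for i, mol in enumerate(supplier):
        if mol is None:
            logger.warning("unparseable SDF record %d in %s", i, path)
            continue
        identifier = ""
        for prop in _ID_PROPS:
            if mol.HasProp(prop):
                identifier = mol.GetProp(prop)
                break
        if not identifier and mol.HasProp("_Name"):
            identifier = mol.GetProp("_Name")
        if not identifier:
            logger.warning("SDF record %d in %s has no identifier; skipped", i, path)
            continue
        metadata: Dict[str, object] = {}
        if mol.HasProp("METADATA"):
            try:
                metadata = json.loads(mol.GetProp("METADATA"))
            except json.JSONDecodeError:
                pass
        records.append(
            MoleculeRecord(
                structure=Chem.MolToSmiles(mol),
                identifier=identifier,
                name=mol.GetProp("PREFERRED_NAME") if mol.HasProp("PREFERRED_NAME") else (
                    mol.GetProp("_Name") if mol.HasProp("_Name") else ""
                ),
                casrn=mol.GetProp("CASRN") if mol.HasProp("CASRN") else None,
                metadata=metadata,
            )
        )
    return records


def _read_table(path: Path) -> List[MoleculeRecord]:
    sep = "\t" if path.suffix.lower() in (".tsv", ".txt", ".smi") else ","
    df = pd.read_csv(path, sep=sep)
    cols = {c.lower(): c for c in df.columns}
    smiles_col = cols.get("smiles")
    id_col = cols.get("identifier") or cols.get("id") or cols.get("source_id")
    if smiles_col is None or id_col is None:
        raise ValueError(f"{path} must have 'smiles' and 'identifier'/'id' columns")
    extra = [
        c for c in df.columns
        if c not in (smiles_col, id_col, cols.get("name"), cols.get("casrn"))
    ]
    records = []
    for _, row in df.iterrows():
        if pd.isna(row[id_col]):
            logger.warning("row without identifier in %s; skipped", path)
            continue
        meta = {
            c: (row[c] if not pd.isna(row[c]) else None) for c in extra
        }
        records.append(
            MoleculeRecord(
                structure=str(row[smiles_col]),
                identifier=str(row[id_col]),
                name=str(row[cols["name"]]) if "name" in cols and not pd.isna(row[cols["name"]]) else "",
                casrn=str(row[cols["casrn"]]) if "casrn" in cols and not pd.isna(row[cols["casrn"]]) else None,
                metadata=meta,
            )
        )
    return records
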