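"""MetFrag-compatible candidate file export and re-import.

The export carries one row per (query, component, substance) triple with
the 14 default columns in fixed order. Structural fields (formula, mass,
SMILES, InChI, InChIKey) describe the *component* chemical — the form
observed in the mass spectrometer — while the identifier fields describe
the *substance*, so a downstream fragmenter scores the observable
structure but reports the registered entity (salt, mixture, ...) it came
from. Optional numeric metadata columns can be appended for scoring.
"""

from __future__ import annotations

import csv
import io
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Union

from rdkit import Chem

from .registry import Registry
from .search import SearchHit

__all__ = ["DEFAULT_FIELDS", "export_metfrag", "read_metfrag"]

DEFAULT_FIELDS = (
    "INPUT",
    "FOUND_BY",
    "DTXCID_INDIVIDUAL_COMPONENT",
    "FORMULA_INDIVIDUAL_COMPONENT",
    "SMILES_INDIVIDUAL_COMPONENT",
    "MAPPED_DTXSID",
    "PREFERRED_NAME_DTXSID",
    "CASRN_DTXSID",
    "FORMULA_MAPPED_DTXSID",
    "SMILES_MAPPED_DTXSID",
    "MS_READY_SMILES",
    "INCHI_STRING_DTXCID",
    "INCHIKEY_DTXCID",
    "MONOISOTOPIC_MASS_DTXCID",
)


def _row_for_hit(
    hit: SearchHit, registry: Registry, metadata_fields: Sequence[str]
) -> Dict[str, str]:
    chem = registry.chemical(hit.chemical_id)
    sub = registry.substance(hit.substance_id)
    original = registry.chemical(registry._original_chemical_id(sub.sid))
    mol = Chem.MolFromSmiles(chem.smiles)
    inchi = Chem.MolToInchi(mol) if mol is not None else ""
    key = chem.inchikey
    row = {
        "INPUT": hit.query,
        "FOUND_BY": hit.found_by,
        "DTXCID_INDIVIDUAL_COMPONENT": chem.cid,
        "FORMULA_INDIVIDUAL_COMPONENT": chem.formula,
        "SMILES_INDIVIDUAL_COMPONENT": chem.smiles,
        "MAPPED_DTXSID": sub.source_id,
        "PREFERRED_NAME_DTXSID": sub.name,
        "CASRN_DTXSID": sub.casrn or "",
        "FORMULA_MAPPED_DTXSID": sub.formula_parts or sub.formula,
        "SMILES_MAPPED_DTXSID": original.smiles,
        "MS_READY_SMILES": chem.smiles,
        "INCHI_STRING_DTXCID": inchi,
        "INCHIKEY_DTXCID": key,
        "MONOISOTOPIC_MASS_DTXCID": f"{chem.monoisotopic_mass:.4f}",
    }
    for name in metadata_fields:
        value = sub.metadata.get(name)
        row[name] = "" if value is None else (
            f"{value:g}" if isinstance(value, float) else str(value)
        )
    return row


def export_metfrag(
    hits: Sequence[SearchHit],
    registry: Registry,
    path: Optional[Union[str, Path]] = None,
    metadata_fields: Sequence[str] = (),
    delimiter: str = ",",
) -> str:
    """Write hits as a MetFrag candidate file; returns the file text.

    *metadata_fields* are appended after the 14 default columns; an
    unknown field name raises ``KeyError`` listing the fields available on
    the hit substances. Output is byte-stable: UTF-8, LF line endings,
    minimal RFC-4180 quoting.
    """
    available = set()
    for hit in hits:
        available.update(registry.substance(hit.substance_id).metadata)
    unknown = [f for f in metadata_fields if f not in available]
    if unknown and hits:
        raise KeyError(
            f"unknown metadata field(s) {unknown}; available: {sorted(available)}"
        )
    header = list(DEFAULT_FIELDS) + list(metadata_fields)
    buf = io.StringIO()
    writer = csv.DictWriter(
        buf, fieldnames=header, delimiter=delimiter, lineterminator="\n"
    )
    writer.writeheader()
    for hit in hits:
        writer.writerow(_row_for_hit(hit, registry, metadata_fields))
    text = buf.getvalue()
    if path is not None:
        Path(path).write_bytes(text.encode("utf-8"))
    return text


def read_metfrag(
    source: Union[str, Path], delimiter: str = ","
) -> List[Dict[str, str]]:
    """Read a MetFrag candidate file back into row dictionaries.

    All 14 default columns must be present (any order for extras); a
    missing required column raises ``ValueError`` naming it.
    """
    text = str(source)
    if "\n" not in text:  # a path rather than file text
        text = Path(source).read_text(encoding="utf-8")
    reader = csv.DictReader(io.StringIO(text), delimiter=delimiter)
    fields = reader.fieldnames or []
    missing = [f for f in DEFAULT_FIELDS if f not in fields]
    if missing:
        raise ValueError(f"missing required column(s): {', '.join(missing)}")
    return [dict(row) for row in reader]
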