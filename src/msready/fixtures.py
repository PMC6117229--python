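"""Deterministic worked-example substance libraries.

Each library is a small, curated set of literature structures (embedded
SMILES, no downloads) engineered so that the behavioural claims the
package makes — mixture separation, salt stripping, exact vs MS-Ready
search counts, metadata ranking — can be exercised end to end.

The ``nicotine_family`` library is built so that, after MS-Ready
processing, a search for C10H14N2 finds all 8 substances, an exact
formula search finds the 5 single-component ones, and the nicotine
component itself is shared by 6 of the 8.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List

import pandas as pd
from rdkit import Chem

from .chem_core import MoleculeRecord

__all__ = ["FixtureLibrary", "FIXTURE_NAMES", "build_fixture", "write_fixture"]


@dataclass
class FixtureLibrary:
    name: str
    substances: List[MoleculeRecord] = field(default_factory=list)
    description: str = ""


_NICOTINE_S = "CN1CCC[C@H]1c1cccnc1"
_NICOTINE_R = "CN1CCC[C@@H]1c1cccnc1"
_NICOTINE_FLAT = "CN1CCCC1c1cccnc1"
_ANABASINE = "C1CCNC(C1)c1cccnc1"
_METANICOTINE = "CN/C=C/CCc1cccnc1"
_SALICYLIC = "OC(=O)c1ccccc1O"
_PFOS_ACID = "OS(=O)(=O)C(F)(F)C(F)(F)C(F)(F)C(F)(F)C(F)(F)C(F)(F)C(F)(F)C(F)(F)F"
_PFOS_ANION = "[O-]S(=O)(=O)C(F)(F)C(F)(F)C(F)(F)C(F)(F)C(F)(F)C(F)(F)C(F)(F)C(F)(F)F"
_PFOA = "OC(=O)C(F)(F)C(F)(F)C(F)(F)C(F)(F)C(F)(F)C(F)(F)C(F)(F)F"
_METHAPYRILENE = "CN(C)CCN(Cc1cccs1)c1ccccn1"
_FUMARIC = "OC(=O)/C=C/C(=O)O"
_RALOXIFENE = "Oc1ccc2c(c1)sc(-c1ccc(O)cc1)c2C(=O)c1ccc(OCCN2CCCCC2)cc1"
_NICARBAZIN = (
    "O=[N+]([O-])c1ccc(NC(=O)Nc2ccc([N+](=O)[O-])cc2)cc1.Cc1cc(C)nc(O)n1"
)

_TERBUTYLAZINE = "CCNc1nc(Cl)nc(NC(C)(C)C)n1"
_PROPAZINE = "CC(C)Nc1nc(Cl)nc(NC(C)C)n1"
_SEBUTYLAZINE = "CCNc1nc(Cl)nc(NC(C)CC)n1"
_SIMAZINE = "CCNc1nc(Cl)nc(NCC)n1"
_DET = "Nc1nc(Cl)nc(NC(C)(C)C)n1"  # desethylterbutylazine


def _sub(smiles, identifier, name, casrn=None, **metadata) -> MoleculeRecord:
    return MoleculeRecord(smiles, identifier, name=name, casrn=casrn, metadata=metadata)


def _nicotine_family() -> FixtureLibrary:
    subs = [
        _sub(_NICOTINE_S, "NIC001", "(S)-Nicotine", "54-11-5", data_sources=3880),
        _sub(_NICOTINE_R, "NIC002", "(R)-Nicotine", data_sources=120),
        _sub(_NICOTINE_FLAT, "NIC003", "Nicotine (unspecified stereo)", data_sources=540),
        _sub(_ANABASINE, "NIC004", "Anabasine", "494-52-0", data_sources=610),
        _sub(_METANICOTINE, "NIC005", "Metanicotine", data_sources=85),
        _sub(_NICOTINE_S + ".Cl", "NIC006", "Nicotine hydrochloride", data_sources=210),
        _sub(_NICOTINE_S + "." + _SALICYLIC, "NIC007", "Nicotine salicylate", data_sources=95),
        _sub(
            ".".join([_NICOTINE_S, _NICOTINE_S, "OS(O)(=O)=O"]),
            "NIC008",
            "Nicotine sulfate (2:1)",
            data_sources=160,
        ),
    ]
    return FixtureLibrary(
        "nicotine_family",
        subs,
        "3 stereo-forms + 2 constitutional isomers of C10H14N2 + 3 nicotine "
        "salts; MS-Ready search 8, exact search 5, nicotine component in 6",
    )


def _pfos_family() -> FixtureLibrary:
    subs = [
        _sub(_PFOS_ACID, "PFS001", "Perfluorooctanesulfonic acid", "1763-23-1",
             data_sources=940),
        _sub("[K+]." + _PFOS_ANION, "PFS002", "PFOS potassium salt", "2795-39-3",
             data_sources=410),
        _sub("[NH4+]." + _PFOS_ANION, "PFS003", "PFOS ammonium salt", data_sources=130),
        _sub(_PFOS_ACID + "." + _PFOA, "PFS004", "PFOS-PFOA mixture", data_sources=12),
    ]
    return FixtureLibrary(
        "pfos_family", subs,
        "neutral acid, two salts and one mixture, all sharing the C8HF17O3S MS-Ready form",
    )


def _nicarbazin() -> FixtureLibrary:
    return FixtureLibrary(
        "nicarbazin",
        [_sub(_NICARBAZIN, "NCZ001", "Nicarbazin", "330-95-0", data_sources=87)],
        "two-part substance separating into C13H10N4O5 and C6H8N2O components",
    )


def _methapyrilene() -> FixtureLibrary:
    subs = [
        _sub(_METHAPYRILENE, "MTP001", "Methapyrilene", "91-80-5", data_sources=320),
        _sub(
            ".".join([_METHAPYRILENE] * 3 + [_FUMARIC] * 2),
            "MTP002",
            "Methapyrilene fumarate (3:2)",
            "33032-12-1",
            data_sources=48,
        ),
    ]
    return FixtureLibrary(
        "methapyrilene", subs, "free base and its 3:2 fumarate salt",
    )


def _raloxifene() -> FixtureLibrary:
    return FixtureLibrary(
        "raloxifene",
        [_sub(_RALOXIFENE + ".Cl", "RAL001", "Raloxifene hydrochloride",
              "82640-04-8", data_sources=260)],
        "hydrochloride salt; HCl stripped by the exclusion list",
    )


def _triazines() -> FixtureLibrary:
    subs = [
        _sub(_TERBUTYLAZINE, "TRZ001", "Terbutylazine", "5915-41-3",
             data_sources=3880, pubmed_refs=410, norman=1, stoffident=1,
             toxcast_pct_active=31.0),
        _sub(_PROPAZINE, "TRZ002", "Propazine", "139-40-2",
             data_sources=1560, pubmed_refs=880, norman=1, stoffident=1,
             toxcast_pct_active=14.0),
        _sub(_SEBUTYLAZINE, "TRZ003", "Sebutylazine", "7286-69-3",
             data_sources=182, pubmed_refs=12, norman=0, stoffident=1,
             toxcast_pct_active=None),
        _sub(_SIMAZINE, "TRZ004", "Simazine", "122-34-9",
             data_sources=2620, pubmed_refs=2100, norman=1, stoffident=1,
             toxcast_pct_active=22.0),
        _sub(_DET, "TRZ005", "Desethylterbutylazine", "30125-63-4",
             data_sources=460, pubmed_refs=0, norman=1, stoffident=1,
             toxcast_pct_active=None),
        _sub(_SIMAZINE + ".Cl", "TRZ006", "Simazine hydrochloride",
             data_sources=25, pubmed_refs=0, norman=0, stoffident=0,
             toxcast_pct_active=None),
        _sub(_SIMAZINE + "." + _PROPAZINE, "TRZ007", "Simazine-propazine mixture",
             data_sources=4, pubmed_refs=0, norman=0, stoffident=0,
             toxcast_pct_active=None),
    ]
    return FixtureLibrary(
        "triazines",
        subs,
        "chlorotriazine herbicides with a metadata table (data sources, "
        "PubMed counts, list flags, ToxCast % active) plus simazine salt/mixture variants",
    )


def _salt_errors() -> FixtureLibrary:
    cation = (
        "CCN(CC)c1ccc([C+](c2ccc(N(CC)CC)cc2)c2ccc(N(CC)CC)cc2)cc1"
    )
    return FixtureLibrary(
        "salt_errors",
        [_sub("CC(=O)[O-]." + cation, "SLT001",
              "Tris[4-(diethylamino)phenyl]methylium acetate", data_sources=6)],
        "a permanently charged triarylmethylium dye salt; the cation keeps "
        "its +1 charge through neutralization and is flagged permanent",
    )


_BUILDERS = {
    "nicotine_family": _nicotine_family,
    "pfos_family": _pfos_family,
    "nicarbazin": _nicarbazin,
    "methapyrilene": _methapyrilene,
    "raloxifene": _raloxifene,
    "triazines": _triazines,
    "salt_errors": _salt_errors,
}

FIXTURE_NAMES = tuple(sorted(_BUILDERS))


def build_fixture(name: str) -> FixtureLibrary:
    """Build a named example library; raises ``KeyError`` listing the
    available choices for an unknown name."""
    try:
        builder = _BUILDERS[name]
    except KeyError:
        raise KeyError(
            f"unknown fixture {name!r}; choose from {', '.join(FIXTURE_NAMES)}"
        ) from None
    return builder()


def write_fixture(library: FixtureLibrary, directory: str | Path) -> Dict[str, Path]:
    """Write a library as ``<name>.sdf`` plus ``<name>_metadata.tsv``.

    Output is byte-stable: property order, float formatting and line
    endings are fixed, so re-running produces identical files.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    sdf_path = directory / f"{library.name}.sdf"
    tsv_path = directory / f"{library.name}_metadata.tsv"
    writer = Chem.SDWriter(str(sdf_path))
    writer.SetKekulize(True)
    for rec in library.substances:
        mol = Chem.MolFromSmiles(rec.structure)
        if mol is None:
            raise ValueError(f"fixture SMILES does not parse: {rec.structure}")
        mol.SetProp("_Name", rec.name)
        mol.SetProp("SOURCE_ID", rec.identifier)
        mol.SetProp("PREFERRED_NAME", rec.name)
        if rec.casrn:
            mol.SetProp("CASRN", rec.casrn)
        mol.SetProp("METADATA", json.dumps(rec.metadata, sort_keys=True))
        writer.write(mol)
    writer.close()

    meta_keys = sorted({k for rec in library.substances for k in rec.metadata})
    rows = []
    for rec in library.substances:
        row: Dict[str, object] = {"identifier": rec.identifier, "name": rec.name}
        for k in meta_keys:
            row[k] = rec.metadata.get(k)
        rows.append(row)
    pd.DataFrame(rows).to_csv(tsv_path, sep="\t", index=False, lineterminator="\n")
    return {"sdf": sdf_path, "tsv": tsv_path}
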