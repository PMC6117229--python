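"""The MS-Ready preparation pipeline on salts, mixtures and charged species.

Nicarbazin is a two-component substance whose parts dissociate in the
environment and are observed separately by HRMS; raloxifene hydrochloride
must lose its HCl before its mass can match anything; PFOS potassium salt
reduces to the neutral sulfonic acid the analyst's formula search expects.
"""

from msready import MoleculeRecord, StandardizationConfig, standardize_substance

SUBSTANCES = [
    MoleculeRecord(
        "O=[N+]([O-])c1ccc(NC(=O)Nc2ccc([N+](=O)[O-])cc2)cc1.Cc1cc(C)nc(O)n1",
        "NCZ001", name="Nicarbazin",
    ),
    MoleculeRecord(
        "Oc1ccc2c(c1)sc(-c1ccc(O)cc1)c2C(=O)c1ccc(OCCN2CCCCC2)cc1.Cl",
        "RAL001", name="Raloxifene hydrochloride",
    ),
    MoleculeRecord(
        "[K+].[O-]S(=O)(=O)C(F)(F)C(F)(F)C(F)(F)C(F)(F)C(F)(F)C(F)(F)C(F)(F)C(F)(F)F",
        "PFS002", name="PFOS potassium salt",
    ),
]

config = StandardizationConfig(mode="msready")
for record in SUBSTANCES:
    result = standardize_substance(record, config)
    print(f"{record.name} -> status {result.status}")
    for comp in result.components:
        print(f"  component {comp.metadata['formula']}"
              f"  mass {comp.metadata['monoisotopic_mass']:.4f}"
              f"  {comp.metadata['inchikey']}")
    for verdict in result.dropped:
        print(f"  dropped ({verdict.component_class}): {verdict.reason}")
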