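"""The MS-Ready / QSAR-Ready preparation pipeline, step by step and composed."""

import pytest
from rdkit import Chem

from msready.chem_core import MoleculeRecord, first_block, formula_of, inchikey
from msready.standardizer import (
    METALS,
    ComponentVerdict,
    StandardizationConfig,
    apply_exclusion,
    check_consistency,
    classify_component,
    exclusion_key,
    load_exclusion_sdf,
    load_transform_rules,
    neutralize,
    normalize_tautomer,
    split_components,
    standardize_substance,
    strip_stereo,
)

NICARBAZIN = "O=[N+]([O-])c1ccc(NC(=O)Nc2ccc([N+](=O)[O-])cc2)cc1.Cc1cc(C)nc(O)n1"
METHAPYRILENE = "CN(C)CCN(Cc1cccs1)c1ccccn1"
FUMARATE_SALT = ".".join([METHAPYRILENE] * 3 + ["OC(=O)/C=C/C(=O)O"] * 2)


def _mol(smi):
    return Chem.MolFromSmiles(smi)


class TestConsistency:
    def test_benzene_passes_unchanged(self):
        mol = check_consistency(MoleculeRecord("c1ccccc1", "S1"))
        assert Chem.MolToSmiles(mol) == "c1ccccc1"

    def test_pentavalent_carbon_rejected_with_identifier(self):
        with pytest.raises(ValueError, match="S2"):
            check_consistency(MoleculeRecord("C(C)(C)(C)(C)C1", "S2"))

    def test_hypervalent_nitro_is_accepted_and_normalized(self):
        mol = check_consistency(MoleculeRecord("CN(=O)=O", "S3"))
        assert Chem.GetFormalCharge(mol) == 0
        assert "[N+]" in Chem.MolToSmiles(mol)


class TestSplitComponents:
    def test_nicarbazin_gives_two_components(self):
        assert len(split_components(_mol(NICARBAZIN))) == 2

    def test_single_fragment_stays_single(self):
        assert len(split_components(_mol("CCO"))) == 1

    def test_order_is_heavy_atom_descending(self):
        frags = split_components(_mol("CC.c1ccccc1.[Na+]"))
        sizes = [f.GetNumHeavyAtoms() for f in frags]
        assert sizes == sorted(sizes, reverse=True)

    def test_methapyrilene_fumarate_has_two_distinct_components(self):
        frags = split_components(_mol(FUMARATE_SALT))
        assert len(frags) == 5  # 3 + 2 before dedup
        assert len({Chem.MolToSmiles(f) for f in frags}) == 2


class TestClassification:
    def test_sodium_cation_is_inorganic(self, msready_config):
        v = classify_component(_mol("[Na+]"), msready_config)
        # sodium is also on the counterion list; either way it is dropped
        assert v.component_class in ("inorganic", "excluded")
        assert not v.retained

    def test_carbonate_carbon_is_inorganic(self, msready_config):
        cfg = StandardizationConfig(exclusion={})
        v = classify_component(_mol("OC([O-])=O"), cfg)
        assert v.component_class == "inorganic"

    def test_tributyltin_retained_msready_dropped_qsarready(
        self, msready_config, qsarready_config
    ):
        tbt = _mol("CCCC[Sn](CCCC)CCCC")
        assert classify_component(tbt, msready_config).retained
        v = classify_component(tbt, qsarready_config)
        assert v.component_class == "organometallic" and not v.retained

    def test_ionic_metal_association_is_not_organometallic(self, msready_config):
        # disconnected potassium is a salt partner, not a metal-carbon bond
        frags = split_components(_mol("[K+].CC(=O)[O-]"))
        classes = {
            classify_component(f, StandardizationConfig(exclusion={})).component_class
            for f in frags
        }
        assert classes == {"inorganic", "organic"}

    def test_fumarate_excluded_qsarready_retained_msready(
        self, msready_config, qsarready_config
    ):
        fum = _mol("OC(=O)/C=C/C(=O)O")
        assert classify_component(fum, msready_config).component_class == "organic"
        v = classify_component(fum, qsarready_config)
        assert v.component_class == "excluded"
        assert v.reason  # carries the exclusion-list label

    def test_metal_set_excludes_boron_and_silicon(self):
        assert "B" not in METALS and "Si" not in METALS
        assert {"Na", "Fe", "Sn", "Hg"} <= METALS


class TestExclusion:
    def test_hydrochloride_salt_stripped(self, msready_config):
        frags = split_components(_mol("CN1CCC[C@H]1c1cccnc1.Cl"))
        kept, dropped = apply_exclusion(frags, msready_config)
        assert len(kept) == 1
        assert dropped[0].reason == "hydrochloric acid"

    def test_single_component_record_never_excluded(self, msready_config):
        kept, dropped = apply_exclusion([_mol("CC(=O)O")], msready_config)
        assert len(kept) == 1 and not dropped

    def test_salicylate_not_on_msready_list(self, msready_config):
        frags = split_components(_mol("CN1CCC[C@H]1c1cccnc1.OC(=O)c1ccccc1O"))
        kept, dropped = apply_exclusion(frags, msready_config)
        assert len(kept) == 2 and not dropped

    def test_exclusion_key_unifies_ion_and_parent_acid(self):
        assert exclusion_key(_mol("CC(=O)[O-]")) == exclusion_key(_mol("CC(=O)O"))

    def test_bundled_msready_subset_of_qsarready(
        self, msready_config, qsarready_config
    ):
        assert set(msready_config.exclusion) < set(qsarready_config.exclusion)

    def test_loader_reads_back_every_record(self, tmp_path):
        path = tmp_path / "excl.sdf"
        writer = Chem.SDWriter(str(path))
        for name, smi in [("a", "Cl"), ("b", "CC(=O)O"), ("c", "O")]:
            m = Chem.MolFromSmiles(smi)
            m.SetProp("_Name", name)
            m.SetProp("LABEL", name)
            writer.write(m)
        writer.close()
        entries = load_exclusion_sdf(path)
        assert len(entries) == 3
        assert set(entries.values()) == {"a", "b", "c"}


class TestTautomerMesomer:
    def test_enol_collapses_to_keto(self, msready_config):
        mol, flag = normalize_tautomer(_mol("C=CO"), msready_config)
        assert Chem.MolToSmiles(mol) == "CC=O"
        assert flag == ""

    def test_nitro_stays_charge_separated(self, msready_config):
        mol, _ = normalize_tautomer(_mol("C[N+](=O)[O-]"), msready_config)
        smi = Chem.MolToSmiles(mol)
        assert "[N+]" in smi and "[O-]" in smi

    def test_benzene_is_a_fixpoint(self, msready_config):
        mol, flag = normalize_tautomer(_mol("c1ccccc1"), msready_config)
        assert Chem.MolToSmiles(mol) == "c1ccccc1" and flag == ""

    @pytest.mark.parametrize(
        "smi",
        ["C=CO", "CC(=C)O", "C=CNC", "Cc1cc(C)nc(O)n1", "CN=[N+]=[N-]",
         METHAPYRILENE, "CCNc1nc(Cl)nc(NCC)n1"],
    )
    def test_formula_is_conserved(self, smi, msready_config):
        before = formula_of(_mol(smi)).merged().display
        mol, _ = normalize_tautomer(_mol(smi), msready_config)
        assert formula_of(mol).merged().display == before

    def test_rule_file_is_ordered_and_named(self):
        rules = load_transform_rules()
        names = [r.name for r in rules]
        assert "nitro_mesomer" in names and "enol_keto" in names


class TestNeutralize:
    def test_sulfonate_anion_becomes_neutral_acid(self):
        mol, permanent = neutralize(
            _mol("[O-]S(=O)(=O)C(F)(F)C(F)(F)C(F)(F)C(F)(F)C(F)(F)C(F)(F)C(F)(F)C(F)(F)F")
        )
        assert not permanent
        assert formula_of(mol).display == "C8HF17O3S"

    def test_carboxylate_gains_exactly_one_hydrogen(self):
        before = formula_of(_mol("CC(=O)[O-]"))
        mol, _ = neutralize(_mol("CC(=O)[O-]"))
        after = formula_of(mol)
        assert after.parts[0].as_dict()["H"] == before.parts[0].as_dict()["H"] + 1
        assert after.charge == 0

    def test_triarylmethylium_flagged_permanent(self):
        cation = "CCN(CC)c1ccc([C+](c2ccc(N(CC)CC)cc2)c2ccc(N(CC)CC)cc2)cc1"
        mol, permanent = neutralize(_mol(cation))
        assert permanent
        assert Chem.GetFormalCharge(mol) == 1

    def test_nitro_dipole_untouched(self):
        mol, permanent = neutralize(_mol("C[N+](=O)[O-]"))
        assert not permanent
        assert "[N+]" in Chem.MolToSmiles(mol)

    def test_ammonium_loses_proton(self):
        mol, permanent = neutralize(_mol("CC[NH+](C)C"))
        assert not permanent and Chem.GetFormalCharge(mol) == 0


class TestStripStereo:
    @pytest.mark.parametrize(
        "a,b",
        [
            ("CN1CCC[C@H]1c1cccnc1", "CN1CCC[C@@H]1c1cccnc1"),   # R/S pair
            ("OC(=O)/C=C/C(=O)O", "OC(=O)/C=C\\C(=O)O"),          # E/Z pair
        ],
    )
    def test_stereoisomers_converge(self, a, b):
        sa = Chem.MolToSmiles(strip_stereo(_mol(a)))
        sb = Chem.MolToSmiles(strip_stereo(_mol(b)))
        assert sa == sb
        assert "@" not in sa and "/" not in sa

    def test_first_block_is_preserved(self):
        for smi in ["CN1CCC[C@H]1c1cccnc1", "OC(=O)/C=C/C(=O)O", "C[C@H](N)C(=O)O"]:
            before = first_block(inchikey(smi))
            after = first_block(inchikey(strip_stereo(_mol(smi))))
            assert before == after

    def test_isotopes_are_retained(self):
        mol = strip_stereo(_mol("[13CH3][C@H](N)C(=O)O"))
        assert any(a.GetIsotope() == 13 for a in mol.GetAtoms())

    def test_achiral_molecule_unchanged(self):
        assert Chem.MolToSmiles(strip_stereo(_mol("CCO"))) == "CCO"


class TestStandardizeSubstance:
    def test_nicarbazin_two_linked_components(self, msready_config):
        result = standardize_substance(
            MoleculeRecord(NICARBAZIN, "NCZ"), msready_config
        )
        assert result.status == "ok"
        formulas = sorted(c.metadata["formula"] for c in result.components)
        assert formulas == ["C13H10N4O5", "C6H8N2O"]

    def test_sodium_chloride_is_empty(self, msready_config):
        result = standardize_substance(MoleculeRecord("[Na+].[Cl-]", "NACL"), msready_config)
        assert result.status == "empty"
        assert not result.components and len(result.dropped) == 2

    def test_fumarate_salt_msready_two_components_qsarready_desalted(
        self, msready_config, qsarready_config
    ):
        rec = MoleculeRecord(FUMARATE_SALT, "MTPF")
        ms = standardize_substance(rec, msready_config)
        qs = standardize_substance(rec, qsarready_config)
        assert [c.metadata["formula"] for c in ms.components] == ["C14H19N3S", "C4H4O4"]
        # fumarate is on the QSAR-Ready counterion list: the record is
        # desalted to the free base, not discarded as a mixture
        assert [c.metadata["formula"] for c in qs.components] == ["C14H19N3S"]

    def test_true_mixture_discarded_qsarready(self, qsarready_config):
        rec = MoleculeRecord(
            "CCNc1nc(Cl)nc(NCC)n1.CC(C)Nc1nc(Cl)nc(NC(C)C)n1", "MIX"
        )
        qs = standardize_substance(rec, qsarready_config)
        assert qs.status == "empty" and not qs.components
        assert all(
            d.reason == "mixture discarded in qsarready mode" for d in qs.dropped
        )

    def test_parse_failure_reports_error_status(self, msready_config):
        result = standardize_substance(MoleculeRecord("((((", "BAD"), msready_config)
        assert result.status == "error" and "BAD" in result.reason

    def test_duplicate_components_unified_by_inchikey(self, msready_config):
        rec = MoleculeRecord("CCc1ccccc1.CCc1ccccc1.c1ccccc1CC", "DUP")
        result = standardize_substance(rec, msready_config)
        assert len(result.components) == 1


class TestPipelineInvariants:
    @pytest.mark.parametrize(
        "smi",
        [
            NICARBAZIN,
            FUMARATE_SALT,
            "CN1CCC[C@H]1c1cccnc1.Cl",
            "[K+].[O-]S(=O)(=O)C(F)(F)C(F)(F)C(F)(F)C(F)(F)C(F)(F)C(F)(F)C(F)(F)C(F)(F)F",
            "CC(=O)[O-].CCN(CC)c1ccc([C+](c2ccc(N(CC)CC)cc2)c2ccc(N(CC)CC)cc2)cc1",
        ],
    )
    def test_msready_form_is_a_fixpoint(self, smi, msready_config):
        first = standardize_substance(MoleculeRecord(smi, "X"), msready_config)
        for comp in first.components:
            again = standardize_substance(
                MoleculeRecord(comp.structure, "Y"), msready_config
            )
            assert again.inchikeys == [comp.metadata["inchikey"]]

    def test_component_count_never_exceeds_split_count(self, msready_config):
        for smi in [NICARBAZIN, FUMARATE_SALT, "CCO", "[Na+].[Cl-]"]:
            mol = _mol(smi)
            result = standardize_substance(MoleculeRecord(smi, "X"), msready_config)
            assert len(result.components) <= len(split_components(mol))

    def test_qsarready_retained_subset_of_msready(
        self, msready_config, qsarready_config
    ):
        for smi in [NICARBAZIN, FUMARATE_SALT, "CCO", "CN1CCC[C@H]1c1cccnc1.Cl",
                    "CCCC[Sn](CCCC)CCCC"]:
            ms = set(
                standardize_substance(MoleculeRecord(smi, "X"), msready_config).inchikeys
            )
            qs = set(
                standardize_substance(MoleculeRecord(smi, "X"), qsarready_config).inchikeys
            )
            assert qs <= ms
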