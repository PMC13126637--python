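"""The 33-action catalog and the transformation operators."""

import numpy as np
import pytest
from rdkit import Chem

from molevolve import (
    ACTION_BY_NAME,
    ACTION_CATALOG,
    MoleculeRecord,
    N_ACTIONS,
    STOP_ACTION,
    apply_action,
    enumerate_applicable,
    random_mutate,
    reduce_chirality,
)


def act(name):
    return ACTION_BY_NAME[name].action_id


def run(smiles, name, seed=7, **kw):
    return apply_action(MoleculeRecord.from_smiles(smiles), act(name), seed, **kw)


class TestCatalog:
    def test_exactly_33_actions_one_stop(self):
        assert N_ACTIONS == 33
        stops = [a for a in ACTION_CATALOG if a.action_class == "control"]
        assert len(stops) == 1 and stops[0].name == "STOP"
        assert ACTION_CATALOG[STOP_ACTION].name == "STOP"
        assert len({a.name for a in ACTION_CATALOG}) == 33

    def test_parameter_flags(self):
        frag_needed = {a.name for a in ACTION_CATALOG if a.needs_core_fragment}
        deco_needed = {a.name for a in ACTION_CATALOG if a.needs_decoration}
        assert frag_needed == {"ADD_FRAG", "REPLACE_SIDECHAIN_CORE"}
        assert deco_needed == {"DECORATE_AROM", "REPLACE_DECOR_AROM"}

    def test_six_operator_classes(self):
        classes = {a.action_class for a in ACTION_CATALOG}
        assert classes == {"fragment", "functional_group", "ring", "reaction",
                           "bioisostere", "chain", "control"}


class TestApplyActionExamples:
    def test_decorate_benzene_with_fluorine(self):
        res = run("c1ccccc1", "DECORATE_AROM", decoration="F")
        assert res.status == "success"
        assert res.molecule.smiles == "Fc1ccccc1"

    def test_dehalogenate_restores_hydrogen(self):
        res = run("Fc1ccccc1", "DEHALOGENATE")
        assert res.status == "success"
        assert res.molecule.smiles == "c1ccccc1"

    def test_oxidize_primary_alcohol_to_aldehyde(self):
        res = run("CCO", "OXIDIZE_ALCOHOL")
        assert res.status == "success"
        assert res.molecule.smiles == "CC=O"

    def test_methane_has_no_ring_sidechain(self):
        res = run("C", "DELETE_RING_SIDECHAIN")
        assert res.status == "inapplicable"

    def test_stop_and_bad_ids_are_contract_violations(self):
        rec = MoleculeRecord.from_smiles("C")
        with pytest.raises(ValueError):
            apply_action(rec, STOP_ACTION, 0)
        with pytest.raises(ValueError):
            apply_action(rec, 99, 0)
        with pytest.raises(ValueError):
            apply_action(rec, act("DECORATE_AROM"), 0)  # missing decoration
        with pytest.raises(ValueError):
            apply_action(rec, act("ADD_FRAG"), 0)  # missing fragment

    def test_methylate_tertiary_amine_quaternizes(self):
        res = run("CN(C)C", "METHYLATE_AMINE")
        assert res.status == "success"
        assert res.molecule.smiles == "C[N+](C)(C)C"

    def test_deterministic_under_seed(self, records100):
        for rec in records100[:10]:
            a = apply_action(rec, act("HALOGENATE"), 123)
            b = apply_action(rec, act("HALOGENATE"), 123)
            assert a.status == b.status
            if a.status == "success":
                assert a.molecule.smiles == b.molecule.smiles

    def test_lineage_records_the_step(self):
        res = run("c1ccccc1", "DECORATE_AROM", decoration="Cl")
        assert res.molecule.lineage[-1][0] == "DECORATE_AROM"


class TestReduceChirality:
    def test_butanol_loses_its_stereocenter(self):
        res = reduce_chirality(MoleculeRecord.from_smiles("CC(O)CC"), 3)
        assert res.status == "success"
        assert res.molecule.stereocenter_count == 0

    def test_achiral_inapplicable(self):
        assert reduce_chirality(
            MoleculeRecord.from_smiles("CCO"), 0).status == "inapplicable"

    def test_strict_decrease_over_corpus(self, records100):
        chiral = [r for r in records100 if r.stereocenter_count >= 1]
        assert chiral
        for rec in chiral:
            res = reduce_chirality(rec, 17)
            if res.status == "success":
                assert res.molecule.stereocenter_count < rec.stereocenter_count
            assert res.attempts <= 20


class TestEnumerateApplicable:
    def test_methane(self):
        ids = enumerate_applicable(MoleculeRecord.from_smiles("C"))
        names = {ACTION_CATALOG[i].name for i in ids}
        assert {"ADD_FRAG", "HALOGENATE", "ADD_POLAR_GROUP"} <= names
        assert "SATURATE_RING" not in names
        assert "HYDROLYZE_ESTER" not in names

    def test_benzene(self):
        ids = enumerate_applicable(MoleculeRecord.from_smiles("c1ccccc1"))
        names = {ACTION_CATALOG[i].name for i in ids}
        assert {"DECORATE_AROM", "SATURATE_RING", "NITRATE"} <= names
        assert "DEMETHYLATE_AMINE" not in names

    def test_phenyl_acetate_ester_patterns(self):
        ids = enumerate_applicable(MoleculeRecord.from_smiles("CC(=O)Oc1ccccc1"))
        names = {ACTION_CATALOG[i].name for i in ids}
        assert {"HYDROLYZE_ESTER", "DEACETYLATE"} <= names

    def test_applicable_never_inapplicable(self, records100, library):
        """Consistency between the predicate and the executor."""
        rng = np.random.default_rng(0)
        for rec in records100[:30]:
            for aid in sorted(enumerate_applicable(rec)):
                spec = ACTION_CATALOG[aid]
                res = apply_action(
                    rec, aid, int(rng.integers(2 ** 31)),
                    core_fragment=library.sample_fragment(0)
                    if spec.needs_core_fragment else None,
                    decoration="Cl" if spec.needs_decoration else None,
                    library=library)
                assert res.status != "inapplicable", spec.name


class TestStructuralInvariants:
    def test_success_round_trips_canonical(self, records100):
        rng = np.random.default_rng(4)
        for rec in records100[:20]:
            for aid in sorted(enumerate_applicable(rec))[:8]:
                spec = ACTION_CATALOG[aid]
                res = apply_action(
                    rec, aid, int(rng.integers(2 ** 31)),
                    core_fragment="[*]CCO" if spec.needs_core_fragment else None,
                    decoration="F" if spec.needs_decoration else None)
                if res.status == "success":
                    assert (Chem.MolToSmiles(Chem.MolFromSmiles(
                        res.molecule.smiles)) == res.molecule.smiles)

    @pytest.mark.parametrize("deco", ["F", "Cl", "CF3", "NO2", "SO2CH3"])
    def test_decorate_then_delete_restores_input(self, deco):
        start = MoleculeRecord.from_smiles("Cc1ccccc1")
        dec = apply_action(start, act("DECORATE_AROM"), 5, decoration=deco)
        assert dec.status == "success"
        # the fresh decoration is the only one, so deletion must restore
        back = apply_action(dec.molecule, act("DELETE_DECOR_AROM"), 9)
        assert back.status == "success"
        assert back.molecule.smiles == start.smiles

    def test_ch2_linker_changes_heavy_count_by_one(self, records100):
        for rec in records100[:30]:
            ins = apply_action(rec, act("INSERT_CH2_LINKER"), 2)
            if ins.status == "success":
                assert ins.molecule.heavy_atom_count == rec.heavy_atom_count + 1
            dele = apply_action(rec, act("DELETE_CH2_LINKER"), 2)
            if dele.status == "success":
                assert dele.molecule.heavy_atom_count == rec.heavy_atom_count - 1

    @pytest.mark.parametrize("name", ["HALOGENATE", "NITRATE", "SULFONYLATE",
                                      "ADD_POLAR_GROUP",
                                      "ADD_LIPOPHILIC_GROUP"])
    def test_additive_actions_never_remove_atoms(self, records100, name):
        for rec in records100[:15]:
            res = apply_action(rec, act(name), 6)
            if res.status == "success":
                assert res.molecule.heavy_atom_count > rec.heavy_atom_count

    @pytest.mark.parametrize("name", ["DEHALOGENATE", "DELETE_DECOR_AROM",
                                      "DELETE_RING_SIDECHAIN", "DEACETYLATE",
                                      "DELETE_CH2_LINKER"])
    def test_deleting_actions_never_add_atoms(self, records100, name):
        for rec in records100[:15]:
            res = apply_action(rec, act(name), 6)
            if res.status == "success":
                assert res.molecule.heavy_atom_count < rec.heavy_atom_count

    def test_net_charge_preserved_except_quaternization(self, records100):
        rng = np.random.default_rng(8)
        for rec in records100[:15]:
            before = Chem.GetFormalCharge(rec.to_mol())
            for aid in sorted(enumerate_applicable(rec)):
                spec = ACTION_CATALOG[aid]
                if spec.needs_core_fragment or spec.needs_decoration:
                    continue
                res = apply_action(rec, aid, int(rng.integers(2 ** 31)))
                if res.status == "success":
                    after = Chem.GetFormalCharge(res.molecule.to_mol())
                    if spec.name == "METHYLATE_AMINE":
                        assert after - before in (0, 1)
                    else:
                        assert after == before


class TestRandomMutate:
    def test_zero_steps_rejected(self):
        with pytest.raises(ValueError):
            random_mutate(MoleculeRecord.from_smiles("C"), 0, 1)

    def test_deterministic(self, records100, library):
        rec = records100[0]
        a = random_mutate(rec, 3, 42, library=library)
        b = random_mutate(rec, 3, 42, library=library)
        assert a.smiles == b.smiles

    def test_sa_degrades_with_more_random_steps(self, records100, library):
        """Longer uniform-random trajectories hurt synthetic accessibility."""
        from molevolve.properties import sa_score

        subset = records100[:60]
        sa1 = np.mean([sa_score(random_mutate(r, 1, 100 + i, library=library))
                       for i, r in enumerate(subset)])
        sa9 = np.mean([sa_score(random_mutate(r, 9, 100 + i, library=library))
                       for i, r in enumerate(subset)])
        assert sa9 > sa1
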