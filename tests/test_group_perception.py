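"""Group perception: atom typing, neighbour-string grammar, specials."""
from collections import Counter

import pytest
from rdkit import Chem

from cpgroups.chem_model import Molecule, embed_3d, read_smiles
from cpgroups.group_perception import (
    ANGLE60,
    ANGLE90,
    ANGLE102,
    COHN,
    ENDOCYCLIC,
    HH_ACCEPTOR,
    PerceptionConfig,
    assign_atom_groups,
    count_special_groups,
    perceive,
    refine_hydroxy_groups,
)


def group_multiset(smiles: str) -> Counter:
    return perceive(read_smiles(smiles)).atom_group_counts


@pytest.mark.parametrize(
    "smiles,expected",
    [
        # worked string from the method description: ethanol C1
        ("CCO", {"C sp3|H3C": 1, "C sp3|H2CO": 1, "O(prim)|HC": 1}),
        # cyclic alcohol worked example
        ("OCC1CCCCC1",
         {"C sp3|H2C2": 5, "C sp3|HC3": 1, "C sp3|H2CO": 1, "O(prim)|HC": 1}),
        # glycine zwitterion
        ("[NH3+]CC([O-])=O",
         {"C sp3|H2CN(+)": 1, "C sp2|CO=O(-)": 1, "N(+) sp3|H3C": 1}),
        # N-ethylpyridinium cation: charged aromatic N typing
        ("CC[n+]1ccccc1.[Cl-]",
         {"N(+) aromatic|C:C2": 1, "C aromatic|H:C:N(+)": 2, "C aromatic|H:C2": 3,
          "C sp3|H2CN(+)": 1, "C sp3|H3C": 1}),
        # imidazolium resonance convention: + on C2, localized sp2 C4/C5,
        # alkyl substituents see neutral N
        ("CC[n+]1ccn(C)c1.[Br-]",
         {"C(+) aromatic|H:N2": 1, "N aromatic|C2:C(+)": 2, "C sp2|H=CN": 2,
          "C sp3|H2CN": 1, "C sp3|H3N": 1, "C sp3|H3C": 1}),
        # NTf2 anion grammar incl. floating charge suffix
        ("[N-](S(=O)(=O)C(F)(F)F)S(=O)(=O)C(F)(F)F.CC[n+]1ccccc1",
         {"N(-)|S2": 1, "S4|CN=O2(-)": 2, "C sp3|SF3": 2,
          "N(+) aromatic|C:C2": 1, "C aromatic|H:C:N(+)": 2, "C aromatic|H:C2": 3,
          "C sp3|H2CN(+)": 1, "C sp3|H3C": 1}),
        # ether/aromatic pi annotation
        ("COc1ccccc1",
         {"C sp3|H3O": 1, "O|C2(pi)": 1, "C aromatic|:C2O": 1, "C aromatic|H:C2": 5}),
        # sulfate-ester O carries no pi (hypervalent S neighbour does not count)
        ("COS([O-])(=O)=O.C[n+]1ccn(C)c1",
         {"C sp3|H3O": 1, "O|CS": 1, "S4|O2=O2(-)": 1,
          "C(+) aromatic|H:N2": 1, "N aromatic|C2:C(+)": 2, "C sp2|H=CN": 2,
          "C sp3|H3N": 2}),
        # indole perceived on its kekule structure
        ("c1ccc2[nH]ccc2c1",
         {"C aromatic|H:C2": 4, "C aromatic|:C2N": 1, "C aromatic|C:C2": 1,
          "N sp3|HC2(2pi)": 1, "C sp2|H=CN": 1, "C sp2|HC=C": 1}),
    ],
)
def test_group_multisets(smiles, expected):
    assert group_multiset(smiles) == Counter(expected)


@pytest.mark.parametrize(
    "smiles,otype",
    [
        ("CCCO", "O(prim)"),      # 1 C on carbinol carbon
        ("CO", "O(prim)"),        # methanol: treated as primary
        ("CC(C)O", "O(sec)"),
        ("CC(C)(C)O", "O(tert)"),
    ],
)
def test_hydroxy_refinement_classes(smiles, otype):
    counts = group_multiset(smiles)
    assert counts[f"{otype}|HC"] == 1


def test_phenol_and_acid_oxygen_not_refined():
    assert group_multiset("Oc1ccccc1")["O|HC(pi)"] == 1
    assert group_multiset("CC(O)=O")["O|HC(pi)"] == 1


def test_refinement_skipped_when_table_lacks_refined_types():
    mol = read_smiles("CCCO")
    groups = assign_atom_groups(mol)
    refined = refine_hydroxy_groups(groups, mol, table_keys={"O|HC"})
    types = [g.atom_type for _, g in refined]
    assert "O(prim)" not in types and "O" in types


def test_refinement_only_relabels_oxygens():
    mol = read_smiles("CC(C)O")
    before = assign_atom_groups(mol)
    after = refine_hydroxy_groups(before, mol)
    assert len(before) == len(after)
    changed = [(a, b) for (_, a), (_, b) in zip(before, after) if a != b]
    assert all(a.atom_type == "O" for a, _ in changed)


def test_backbone_completeness():
    for smiles in ["CCO", "CC(C)(C)O", "c1ccccc1", "CC[n+]1ccn(C)c1.[Br-]",
                   "CSCCC([NH3+])C([O-])=O", "FC(F)(F)S(=O)(=O)[O-].CC[n+]1ccccc1"]:
        mol = read_smiles(smiles)
        groups = assign_atom_groups(mol)
        n_backbone = sum(1 for a in mol.atoms if mol.degree(a.index) >= 2)
        assert len(groups) == n_backbone, smiles


def test_group_multiset_invariant_under_atom_renumbering():
    smiles = "CC(C)C1CCC(C)CC1O"
    ref = group_multiset(smiles)
    rd = Chem.MolFromSmiles(smiles)
    for seed in range(5):
        order = list(range(rd.GetNumAtoms()))
        import random
        random.Random(seed).shuffle(order)
        shuffled = Chem.MolToSmiles(Chem.RenumberAtoms(rd, order), canonical=False)
        assert group_multiset(shuffled) == ref


@pytest.mark.parametrize(
    "smiles,n_endocyclic",
    [
        ("OCC1CCCCC1", 6),
        ("C1C2CC3CC1CC(C2)C3", 12),   # adamantane: fused bonds counted once
        ("c1ccccc1", 0),              # aromatic bonds are not single
        ("C1CCC=CC1", 5),             # double ring bond excluded
        ("[O-]C(=O)C1CCC[NH2+]1", 5),
        ("c1ccc2[nH]ccc2c1", 0),      # localized heteroaromatic: still no endocyclic
    ],
)
def test_endocyclic_bond_counting(smiles, n_endocyclic):
    counts = count_special_groups(read_smiles(smiles))
    assert counts[ENDOCYCLIC] == n_endocyclic


def test_topological_angle_fallback():
    assert count_special_groups(read_smiles("C1CC1"))[ANGLE60] == 3
    assert count_special_groups(read_smiles("C1CCC1"))[ANGLE90] == 4
    hexa = count_special_groups(read_smiles("C1CCCCC1"))
    assert hexa[ANGLE60] == hexa[ANGLE90] == hexa[ANGLE102] == 0


def test_angle_bins_from_geometry():
    cp = count_special_groups(embed_3d(read_smiles("C1CC1", "cyclopropane")))
    assert cp[ANGLE60] == 3
    cb = count_special_groups(embed_3d(read_smiles("C1CCC1", "cyclobutane")))
    assert cb[ANGLE60] == 0 and cb[ANGLE90] == 4
    norbornane = count_special_groups(embed_3d(read_smiles("C1CC2CCC1C2")))
    assert norbornane[ANGLE102] > 0  # strained bicyclic: 90-102 degree angles


def test_cohn_flag_modes():
    diol = read_smiles("OCCCCO")
    assert count_special_groups(diol)[COHN] == 1
    assert count_special_groups(diol, PerceptionConfig(cohn_mode="per_oh"))[COHN] == 2
    mono = read_smiles("CCCO")
    assert count_special_groups(mono)[COHN] == 0
    with pytest.raises(ValueError):
        PerceptionConfig(cohn_mode="bogus")


def test_hh_acceptor_needs_geometry():
    glycol = read_smiles("OCCCCCO")
    assert count_special_groups(glycol)[HH_ACCEPTOR] == 0  # no coordinates


def test_every_fixture_string_occurs_in_a_table(fixture_set, liquid_table, solid_table):
    """Grammar round-trip: emitted keys on the fixture set are table keys."""
    tables = {"liquid": liquid_table, "solid": solid_table}
    novel = {}
    for rec in fixture_set:
        table = tables[rec.phase]
        gcv = perceive(rec.molecule(), table_keys=table.keys)
        for key in gcv.atom_group_counts:
            if key not in table:
                novel.setdefault(key, []).append(rec.name)
    assert not novel, f"novel group strings emitted: {novel}"
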