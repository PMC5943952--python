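"""Group perception: atom typing, neighbor strings, special groups."""

import random

import pytest

from atomgroups.groups import (
    GroupSignature,
    PerceptionError,
    atom_type,
    canonical_neighbor_string,
    detect_h_acceptor,
    detect_hydrocarbon_special,
    perceive,
    is_group_center,
)
from atomgroups.molgraph import HALOGENS, Bond, MolecularGraph, read_smiles


def find(mol, element, charge=None):
    for i, a in enumerate(mol.atoms):
        if a.element == element and (charge is None or a.charge == charge):
            return i
    raise AssertionError(f"no {element} in molecule")


class TestAtomType:
    def test_borate_center(self):
        mol = read_smiles("F[B-](F)(F)F")
        assert atom_type(mol, find(mol, "B")) == "B(-)"

    def test_imidazolium_c2(self):
        mol = read_smiles("Cc1[nH+]cc[nH]1")
        assert atom_type(mol, find(mol, "C", charge=1)) == "C(+) aromatic"

    def test_sulfonate_sulfur_hypervalent(self):
        mol = read_smiles("CS(=O)(=O)[O-]")
        assert atom_type(mol, find(mol, "S")) == "S4"

    def test_divalent_sulfur(self):
        mol = read_smiles("CSC")
        assert atom_type(mol, find(mol, "S")) == "S2"

    def test_halogen_center_is_contract_violation(self):
        mol = read_smiles("CCl")
        with pytest.raises(PerceptionError):
            atom_type(mol, find(mol, "Cl"))


class TestNeighborString:
    def test_pyridinium_nitrogen(self):
        mol = read_smiles("[nH+]1ccccc1")
        assert canonical_neighbor_string(mol, find(mol, "N", 1)) == "H:C2"

    def test_carboxyl_carbon(self):
        mol = read_smiles("CC(=O)O")
        idx = next(
            i for i in range(len(mol.atoms))
            if mol.atoms[i].element == "C" and "double" in mol.bond_orders(i)
        )
        assert canonical_neighbor_string(mol, idx) == "CO=O"

    def test_ester_oxygen_pi(self):
        mol = read_smiles("COC(C)=O")
        idx = next(
            i for i, a in enumerate(mol.atoms)
            if a.element == "O" and mol.heavy_degree(i) == 2
        )
        assert canonical_neighbor_string(mol, idx) == "C2(pi)"

    def test_phenol_oxygen_pi(self):
        mol = read_smiles("Oc1ccccc1")
        assert canonical_neighbor_string(mol, find(mol, "O")) == "HC(pi)"

    def test_iodine_written_as_j(self):
        mol = read_smiles("CCI")
        idx = next(
            i for i, a in enumerate(mol.atoms)
            if a.element == "C" and a.h_count == 2
        )
        assert canonical_neighbor_string(mol, idx) == "H2CJ"

    def test_net_charge_suffix_on_nitro(self):
        # charge rides the whole shell: CO=O(-) no matter which O is drawn charged
        mol = read_smiles("c1ccccc1[N+](=O)[O-]")
        assert canonical_neighbor_string(mol, find(mol, "N")) == "CO=O(-)"

    def test_hypervalent_sulfur_not_pi(self):
        # sulfonamide N sees aryl C as pi but SO2 sulfur as plain S
        mol = read_smiles("CNS(C)(=O)=O")
        idx = find(mol, "N")
        assert canonical_neighbor_string(mol, idx) == "HCS"


class TestCenters:
    @pytest.mark.parametrize("smiles,n_centers", [
        ("CC(C)=O", 3),      # acetone: carbonyl O is not a center
        ("CC#N", 2),         # nitrile N is not a center
        ("CS(=O)(=O)[O-]", 2),  # sulfonate: three O all terminal
        ("C=C", 2),          # terminal =CH2 is a center (has hydrogens)
    ])
    def test_terminal_multiply_bonded_atoms(self, smiles, n_centers):
        mol = read_smiles(smiles)
        assert perceive(mol).n_centers == n_centers

    def test_center_conservation(self, fixtures):
        # every fixture: sum of counts == number of group centers
        for f in fixtures.values():
            mol = f.molecule
            expected = sum(
                1 for i in range(len(mol.atoms)) if is_group_center(mol, i)
            )
            assert perceive(mol).n_centers == expected


class TestFixtureDecompositions:
    def test_all_fixtures_byte_exact(self, fixtures):
        for name, f in fixtures.items():
            got = perceive(f.molecule)
            assert got.counts == f.expected.counts, name
            assert got.special_counts == f.expected.special_counts, name

    def test_table1_signatures_present(self, fixtures, visc_table):
        # the nine worked ionic-liquid signatures must hit table rows exactly
        anchors = {
            "tetrafluoroborate": ("B(-)", "F4"),
            "pyridinium": ("C aromatic", "H:C:N(+)"),
            "2-methylimidazolium": ("C(+) aromatic", "C:N2"),
            "1-methylimidazolium": ("N aromatic", "C2:C(+)"),
            "1-methylpyridinium": ("N(+) aromatic", "C:C2"),
            "bis(trifluoromethanesulfonyl)amide": ("N(-)", "S2"),
            "tetramethylphosphonium": ("P(+)", "C4"),
            "hexafluorophosphate": ("P(-)", "F6"),
            "methylsulfonate": ("S4", "CO=O2(-)"),
        }
        for name, (atype, neigh) in anchors.items():
            sig = GroupSignature(atype, neigh)
            assert sig in perceive(fixtures[name].molecule).counts, name
            assert visc_table.get(sig) is not None, name


class TestPermutationInvariance:
    @staticmethod
    def permute(mol: MolecularGraph, perm):
        atoms = [None] * len(mol.atoms)
        for old, new in enumerate(perm):
            atoms[new] = mol.atoms[old]
        bonds = [Bond(perm[b.i], perm[b.j], b.order) for b in mol.bonds]
        return MolecularGraph(atoms, bonds, name=mol.name)

    def test_perceive_invariant_under_atom_reordering(self, fixtures):
        rng = random.Random(42)
        for f in fixtures.values():
            reference = perceive(f.molecule)
            for _ in range(3):
                perm = list(range(len(f.molecule.atoms)))
                rng.shuffle(perm)
                shuffled = self.permute(f.molecule, perm)
                assert perceive(shuffled).counts == reference.counts, f.name


class TestHydrocarbonSpecial:
    @pytest.mark.parametrize("smiles,expected", [
        ("CCCCCC", (6, 0)),       # n-hexane
        ("Cc1ccccc1", (0, 7)),    # toluene
        ("CCO", (0, 0)),          # heteroatom present
        ("C=CC", (0, 3)),         # propene
        ("C1CCCCC1", (6, 0)),     # cyclohexane
    ])
    def test_detect(self, smiles, expected):
        assert detect_hydrocarbon_special(read_smiles(smiles)) == expected


class TestHAcceptor:
    @pytest.mark.parametrize("smiles,expected", [
        ("O=Cc1ccccc1O", 1),   # salicylaldehyde: 6-membered O-H...O=C
        ("Oc1ccccc1", 0),      # phenol: no acceptor in range
        ("OCCO", 1),           # ethylene glycol: one 5-ring hydrogen bond
        ("OCCCCCCCO", 0),      # 1,7-diol: ring would be 9-membered
    ])
    def test_counts(self, smiles, expected):
        assert detect_h_acceptor(read_smiles(smiles)) == expected

    def test_off_by_default_in_perception(self):
        cv = perceive(read_smiles("OCCO"))
        assert cv.special_counts["h_acceptor"] == 0
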