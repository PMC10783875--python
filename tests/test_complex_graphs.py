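"""Structure parsing, featurization and distance-graph construction."""

import numpy as np
import pytest

from assaybind import complex_graphs as cg
from assaybind.complex_graphs import (
    AtomRecord,
    ComplexStructure,
    ResidueRecord,
    build_interaction_graph,
    build_ligand_graph,
    build_protein_graph,
    featurize_atom,
    parse_ligand,
    parse_protein,
    pocket_residues,
    rbf_expand,
)
from assaybind.synthetic_data import SyntheticConfig, make_complex, write_pdb, write_sdf

METHANE_SDF = """methane
  test

  5  4  0  0  0  0  0  0  0  0999 V2000
    0.0000    0.0000    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
    0.6300    0.6300    0.6300 H   0  0  0  0  0  0  0  0  0  0  0  0
   -0.6300   -0.6300    0.6300 H   0  0  0  0  0  0  0  0  0  0  0  0
   -0.6300    0.6300   -0.6300 H   0  0  0  0  0  0  0  0  0  0  0  0
    0.6300   -0.6300   -0.6300 H   0  0  0  0  0  0  0  0  0  0  0  0
  1  2  1  0
  1  3  1  0
  1  4  1  0
  1  5  1  0
M  END
$$$$
"""

TRIATOM_SDF = """triatom
  test

  3  2  0  0  0  0  0  0  0  0999 V2000
    1.2500    0.0000    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
    0.0000    1.5000    0.0000 O   0  0  0  0  0  0  0  0  0  0  0  0
    0.0000    0.0000    2.2500 N   0  0  0  0  0  0  0  0  0  0  0  0
  1  2  1  0
  2  3  2  0
M  END
$$$$
"""

TWO_RESIDUE_PDB = """ATOM      1  N   ALA A   1      -0.500   0.000   0.000  1.00  0.00           N
ATOM      2  CA  ALA A   1       1.000   2.000   3.000  1.00  0.00           C
ATOM      3  CA  GLY A   2       4.000   5.000   6.000  1.00  0.00           C
TER
END
"""

MISSING_CA_PDB = """ATOM      1  CA  ALA A   1       0.000   0.000   0.000  1.00  0.00           C
ATOM      2  N   GLY A   2       1.000   1.000   1.000  1.00  0.00           N
ATOM      3  CA  SER A   3       3.000   3.000   3.000  1.00  0.00           C
TER
END
"""


def brute_force_pairs(coords, cutoff):
    n = len(coords)
    return [
        (i, j)
        for i in range(n)
        for j in range(i + 1, n)
        if np.linalg.norm(coords[i] - coords[j]) < cutoff
    ]


def atoms_at(coords, element="C"):
    return [AtomRecord(index=i, element=element, coord=c) for i, c in enumerate(coords)]


def residues_at(coords, name="ALA"):
    return [
        ResidueRecord(index=i, residue_name=name, ca_coord=c)
        for i, c in enumerate(coords)
    ]


# -- parsers ----------------------------------------------------------------


class TestParsers:
    def test_hydrogens_dropped_by_default(self, tmp_path):
        path = tmp_path / "methane.sdf"
        path.write_text(METHANE_SDF)
        atoms = parse_ligand(path)
        assert len(atoms) == 1
        assert atoms[0].element == "C"
        assert len(parse_ligand(path, keep_hydrogens=True)) == 5

    def test_coordinates_read_verbatim(self, tmp_path):
        path = tmp_path / "tri.sdf"
        path.write_text(TRIATOM_SDF)
        atoms = parse_ligand(path)
        assert [a.element for a in atoms] == ["C", "O", "N"]
        np.testing.assert_allclose(atoms[0].coord, [1.25, 0.0, 0.0])
        np.testing.assert_allclose(atoms[2].coord, [0.0, 0.0, 2.25])

    def test_bond_orders_returned_on_request(self, tmp_path):
        path = tmp_path / "tri.sdf"
        path.write_text(TRIATOM_SDF)
        _, bonds = parse_ligand(path, with_bonds=True)
        assert bonds[frozenset((0, 1))] == "SINGLE"
        assert bonds[frozenset((1, 2))] == "DOUBLE"

    def test_pdb_residues_with_ca(self, tmp_path):
        path = tmp_path / "two.pdb"
        path.write_text(TWO_RESIDUE_PDB)
        res = parse_protein(path)
        assert [r.residue_name for r in res] == ["ALA", "GLY"]
        np.testing.assert_allclose(res[0].ca_coord, [1.0, 2.0, 3.0])
        np.testing.assert_allclose(res[1].ca_coord, [4.0, 5.0, 6.0])

    def test_residue_without_ca_skipped(self, tmp_path):
        path = tmp_path / "gap.pdb"
        path.write_text(MISSING_CA_PDB)
        res = parse_protein(path)
        assert [r.residue_name for r in res] == ["ALA", "SER"]

    def test_empty_structures_raise(self, tmp_path):
        pdb = tmp_path / "empty.pdb"
        pdb.write_text("END\n")
        with pytest.raises(cg.EmptyStructureError):
            parse_protein(pdb)

    def test_synthetic_write_then_read_round_trip(self, tmp_path):
        cfg = SyntheticConfig(seed=11)
        rng = np.random.default_rng(11)
        cs, _ = make_complex(cfg, rng)
        write_pdb(cs, tmp_path / "syn.pdb")
        write_sdf(cs, tmp_path / "syn.sdf")
        res = parse_protein(tmp_path / "syn.pdb")
        atoms = parse_ligand(tmp_path / "syn.sdf")
        assert len(res) == len(cs.protein)
        assert len(atoms) == len(cs.ligand)
        np.testing.assert_allclose(
            [r.ca_coord for r in res],
            [r.ca_coord for r in cs.protein],
            atol=1e-3,  # PDB prints 3 decimals
        )
        np.testing.assert_allclose(
            [a.coord for a in atoms],
            [a.coord for a in cs.ligand],
            atol=1e-4,  # SDF prints 4 decimals
        )
        assert [a.element for a in atoms] == [a.element for a in cs.ligand]
        assert [r.residue_name for r in res] == [r.residue_name for r in cs.protein]


# -- featurization ----------------------------------------------------------


class TestFeaturization:
    def test_element_one_hot_single_slot(self):
        v = featurize_atom("C")
        element_block = v[: len(cg.ELEMENTS) + 1]
        assert element_block.sum() == 1.0
        assert element_block[cg.ELEMENTS.index("C")] == 1.0

    def test_unknown_element_goes_to_other_slot(self):
        v = featurize_atom("Xx")
        element_block = v[: len(cg.ELEMENTS) + 1]
        assert element_block[-1] == 1.0
        assert element_block.sum() == 1.0

    def test_rbf_is_one_at_center(self):
        centers = np.linspace(0.0, 12.0, cg.N_RBF)
        v = rbf_expand(centers[3], 12.0)
        assert v[3] == pytest.approx(1.0)
        assert np.all(v <= 1.0)

    def test_feature_matrix_matches_independent_schema_evaluation(self):
        # independent re-evaluation: one-hot blocks sum to 1, lengths fixed
        cfg = SyntheticConfig(seed=3)
        rng = np.random.default_rng(3)
        cs, _ = make_complex(cfg, rng)
        A = np.array([a.features for a in cs.ligand])
        R = np.array([r.features for r in cs.protein])
        assert A.shape[1] == cg.ATOM_FEATURE_LENGTH
        assert R.shape[1] == cg.RESIDUE_FEATURE_LENGTH
        n_el = len(cg.ELEMENTS) + 1
        np.testing.assert_allclose(A[:, :n_el].sum(axis=1), 1.0)
        n_res = len(cg.STANDARD_RESIDUES) + 1
        np.testing.assert_allclose(R[:, :n_res].sum(axis=1), 1.0)
        # scalar residue props recomputed from the named amino acids
        for row, rec in zip(R, cs.protein):
            hydro, charge, mw = cg._RESIDUE_PROPS[rec.residue_name]
            np.testing.assert_allclose(row[n_res:], [hydro, charge, mw / 100.0])


# -- graph construction -----------------------------------------------------


class TestGraphConstruction:
    def test_default_cutoffs(self):
        atoms = atoms_at([np.zeros(3)])
        res = residues_at([np.zeros(3)])
        assert build_ligand_graph(atoms).cutoff == 5.0
        assert build_protein_graph(res).cutoff == 8.0
        assert build_interaction_graph(res, atoms).cutoff == 12.0

    def test_single_atom_no_edges(self):
        g = build_ligand_graph(atoms_at([np.zeros(3)]))
        assert len(g.nodes) == 1 and g.edges == []

    def test_collinear_atoms(self):
        coords = [np.array([x, 0.0, 0.0]) for x in (0.0, 3.0, 6.0)]
        g = build_ligand_graph(atoms_at(coords))
        assert g.edges == [(0, 1), (1, 2)]

    @pytest.mark.parametrize("d,expected", [(7.99, 1), (8.00, 0)])
    def test_protein_cutoff_strict_inequality(self, d, expected):
        res = residues_at([np.zeros(3), np.array([d, 0.0, 0.0])])
        assert len(build_protein_graph(res).edges) == expected

    @pytest.mark.parametrize("x,present", [(11.9, True), (12.0, False)])
    def test_interaction_boundary(self, x, present):
        res = residues_at([np.zeros(3)])
        atoms = atoms_at([np.array([x, 0.0, 0.0])])
        ig = build_interaction_graph(res, atoms)
        assert (len(ig.edges) == 1) is present

    def test_edge_sets_match_brute_force_oracle(self, rng):
        for _ in range(10):
            coords = rng.uniform(0, 10, size=(30, 3))
            g = build_ligand_graph(atoms_at(list(coords)))
            assert g.edges == brute_force_pairs(coords, 5.0)
            pg = build_protein_graph(residues_at(list(coords[:20])))
            assert pg.edges == brute_force_pairs(coords[:20], 8.0)
            ig = build_interaction_graph(
                residues_at(list(coords[:8])), atoms_at(list(coords[8:20]))
            )
            expected = [
                (i, j)
                for i in range(8)
                for j in range(12)
                if np.linalg.norm(coords[i] - coords[8 + j]) < 12.0
            ]
            assert ig.edges == expected

    def test_rigid_motion_leaves_edges_unchanged(self, rng):
        coords = rng.uniform(0, 12, size=(25, 3))
        from scipy.spatial.transform import Rotation

        R = Rotation.random(random_state=5).as_matrix()
        t = rng.uniform(-20, 20, 3)
        moved = coords @ R.T + t
        for builder, recs in (
            (build_ligand_graph, atoms_at),
            (build_protein_graph, residues_at),
        ):
            assert builder(recs(list(coords))).edges == builder(recs(list(moved))).edges

    def test_bipartite_indices_in_range(self, rng):
        coords = rng.uniform(0, 15, size=(20, 3))
        ig = build_interaction_graph(
            residues_at(list(coords[:8])), atoms_at(list(coords[8:]))
        )
        for i, j in ig.edges:
            assert 0 <= i < ig.residue_count
            assert 0 <= j < ig.atom_count

    def test_nonfinite_coordinate_rejected(self):
        with pytest.raises(ValueError):
            AtomRecord(index=0, element="C", coord=[np.nan, 0, 0])

    def test_pocket_truncation_keeps_contact_residues(self):
        res = residues_at([np.zeros(3), np.array([50.0, 0, 0])])
        atoms = atoms_at([np.array([1.0, 0, 0])])
        kept = pocket_residues(res, atoms)
        assert len(kept) == 1 and kept[0].index == 0

    def test_ligand_edge_features_include_bond_order(self):
        coords = [np.zeros(3), np.array([1.5, 0, 0])]
        bonds = {frozenset((0, 1)): "DOUBLE"}
        g = build_ligand_graph(atoms_at(coords), bonds=bonds)
        bond_block = g.edge_features[0][cg.N_RBF :]
        assert bond_block[cg.BOND_ORDERS.index("DOUBLE")] == 1.0

    def test_complex_requires_nonempty_parts(self):
        with pytest.raises(cg.EmptyStructureError):
            ComplexStructure(protein=[], ligand=atoms_at([np.zeros(3)]))
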