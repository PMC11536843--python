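"""Featurization: widths, pharmacophores, edges, invariances, ablation."""

import numpy as np
import pytest
from rdkit import Chem

from akscore2 import graphs, structio
from akscore2.graphs import (EDGE_DIM_COMPLEX, EDGE_DIM_COVALENT,
                             FeatureSchema, FeaturizationError, NODE_DIM,
                             build_covalent_edges, build_noncovalent_edges,
                             complex_graph, featurize_mol_nodes,
                             ligand_graph, perceive_pharmacophores,
                             pocket_graph)
from conftest import make_pose, random_rotation


class TestNodeFeatures:
    def test_width_is_73_for_any_atom(self, aspirin_pose, benzene_pose):
        for pose in (aspirin_pose, benzene_pose):
            x = featurize_mol_nodes(pose.mol, is_ligand=True)
            assert x.shape == (pose.n_atoms, NODE_DIM)

    def test_benzene_carbon_pharmacophores(self, benzene_pose):
        """Aromatic ring carbons are aromatic + ring + hydrophobic."""
        x = featurize_mol_nodes(benzene_pose.mol, is_ligand=True)
        schema = FeatureSchema()
        block = x[:, schema.node_slice("pharmacophore")]
        np.testing.assert_array_equal(
            block, np.tile([1, 1, 1, 0, 0, 0, 0], (6, 1)))

    def test_carboxylate_oxygens_acidic(self):
        pose = make_pose("CC(=O)O")
        pharm = perceive_pharmacophores(pose.mol)
        oxys = [i for i, a in enumerate(pose.mol.GetAtoms())
                if a.GetSymbol() == "O"]
        assert all(pharm[i, 5] == 1.0 for i in oxys)  # acidic column

    def test_amine_nitrogen_donor_and_basic(self):
        pose = make_pose("CCN")
        pharm = perceive_pharmacophores(pose.mol)
        n_idx = next(i for i, a in enumerate(pose.mol.GetAtoms())
                     if a.GetSymbol() == "N")
        assert pharm[n_idx, 3] == 1.0  # donor
        assert pharm[n_idx, 6] == 1.0  # basic

    def test_is_ligand_flag(self, benzene_pose):
        schema = FeatureSchema()
        xl = featurize_mol_nodes(benzene_pose.mol, is_ligand=True)
        xp = featurize_mol_nodes(benzene_pose.mol, is_ligand=False)
        sl = schema.node_slice("is_ligand")
        assert np.all(xl[:, sl] == 1.0) and np.all(xp[:, sl] == 0.0)

    def test_ablated_group_is_zero_filled_not_removed(self, benzene_pose):
        schema = FeatureSchema(ablated=frozenset({"pharmacophore"}))
        g = ligand_graph(benzene_pose, schema)
        assert g.node_features.shape[1] == NODE_DIM
        block = g.node_features[:, schema.node_slice("pharmacophore")]
        assert np.all(block == 0.0)
        # other groups untouched
        assert g.node_features[:, schema.node_slice("element")].sum() == 6

    def test_unknown_ablation_group_rejected(self):
        with pytest.raises(FeaturizationError, match="valid groups"):
            FeatureSchema(ablated=frozenset({"flavour"}))


class TestCovalentEdges:
    def test_ethane_single_bond(self):
        pose = make_pose("CC")
        ei, ef = build_covalent_edges(pose.mol, pose.coords)
        assert ei.shape == (2, 2)  # one bond, two directed arcs
        assert ef.shape == (2, EDGE_DIM_COVALENT)

    def test_benzene_aromatic_ring_edges(self, benzene_pose):
        ei, ef = build_covalent_edges(benzene_pose.mol, benzene_pose.coords)
        assert ei.shape[1] == 12  # 6 ring bonds as arc pairs
        schema = FeatureSchema()
        bond_type = ef[:, schema.edge_slice("bond_type")]
        assert np.all(bond_type[:, 3] == 1.0)  # aromatic slot
        assert np.all(ef[:, schema.edge_slice("bond_ring")] == 1.0)

    def test_atom_without_bonds_yields_no_edges(self):
        pose = make_pose("C")
        ei, ef = build_covalent_edges(pose.mol, pose.coords)
        assert ei.shape == (2, 0) and ef.shape == (0, EDGE_DIM_COVALENT)


class TestNonCovalentEdges:
    def _pair(self, d, pharm_p=None, pharm_l=None):
        pc = np.zeros((1, 3))
        lc = np.array([[d, 0.0, 0.0]])
        pp = np.zeros((1, 7)) if pharm_p is None else pharm_p
        pl = np.zeros((1, 7)) if pharm_l is None else pharm_l
        return build_noncovalent_edges(pc, lc, pp, pl)

    def test_below_cutoff_included(self):
        ei, ef = self._pair(7.9)
        assert ei.shape[1] == 2  # one undirected contact, two arcs

    def test_exact_cutoff_excluded(self):
        ei, ef = self._pair(8.0)
        assert ei.shape[1] == 0

    def test_distance_bin_and_pair_flags(self):
        hyd = np.array([[0, 0, 1.0, 0, 0, 0, 0]])
        ei, ef = self._pair(3.5, hyd, hyd)
        schema = FeatureSchema()
        bins = ef[0, schema.edge_slice("distance_bins")]
        assert bins[3] == 1.0 and bins.sum() == 1.0  # [3, 4) bin
        assert ef[0, schema.edge_slice("hydrophobic_pair")] == 1.0
        assert ef[0, schema.edge_slice("inverse_distance")] == \
            pytest.approx(1 / 3.5)
        assert ef[0, schema.edge_slice("donor_acceptor_pair")] == 0.0

    def test_donor_acceptor_either_orientation(self):
        don = np.array([[0, 0, 0, 1.0, 0, 0, 0]])
        acc = np.array([[0, 0, 0, 0, 1.0, 0, 0]])
        for pp, pl in ((don, acc), (acc, don)):
            _, ef = self._pair(3.0, pp, pl)
            schema = FeatureSchema()
            assert ef[0, schema.edge_slice("donor_acceptor_pair")] == 1.0

    def test_edge_count_monotone_in_cutoff(self, tiny_world):
        tid = tiny_world.target_ids[0]
        rec = tiny_world.natives[tid]
        pp = graphs.perceive_pharmacophores(graphs.pocket_to_mol(rec.pocket))
        pl = graphs.perceive_pharmacophores(rec.ligand.mol)
        counts = [build_noncovalent_edges(rec.pocket.coords,
                                          rec.ligand.coords, pp, pl,
                                          cutoff=c)[0].shape[1]
                  for c in (4.0, 5.0, 6.0, 7.0, 8.0)]
        assert counts == sorted(counts)


class TestComplexGraphs:
    def test_widths_and_partition(self, tiny_world):
        rec = tiny_world.natives[tiny_world.target_ids[0]]
        g = graphs.build_graphs(rec, mode="complex")
        assert g.node_features.shape[1] == NODE_DIM
        assert g.edge_features.shape[1] == EDGE_DIM_COMPLEX
        schema = FeatureSchema()
        cov = g.edge_features[:, schema.edge_slice("covalent_flag")].ravel() == 1
        # covalent edges have zero non-covalent block and vice versa
        nc_block_cols = slice(EDGE_DIM_COVALENT, EDGE_DIM_COMPLEX)
        assert np.all(g.edge_features[cov][:, nc_block_cols] == 0.0)
        assert np.all(g.edge_features[~cov][:, :EDGE_DIM_COVALENT] == 0.0)
        # non-covalent edges connect protein to ligand only
        src_orig = g.node_origin[g.edge_index[0][~cov]]
        dst_orig = g.node_origin[g.edge_index[1][~cov]]
        assert np.all(src_orig != dst_orig)

    def test_nondock_mode_keeps_partners_separate(self, tiny_world):
        rec = tiny_world.natives[tiny_world.target_ids[0]]
        pg, lg = graphs.build_graphs(rec, mode="nondock")
        assert pg.edge_features.shape[1] == EDGE_DIM_COVALENT
        assert lg.edge_features.shape[1] == EDGE_DIM_COVALENT
        assert np.all(pg.node_origin == 0) and np.all(lg.node_origin == 1)

    def test_rigid_transform_leaves_features_unchanged(self, tiny_world):
        """100 random rigid motions change no node or edge feature beyond
        float round-off."""
        rng = np.random.default_rng(9)
        rec = tiny_world.natives[tiny_world.target_ids[2]]
        base = graphs.build_graphs(rec, mode="complex")
        for _ in range(100):
            rot, t = random_rotation(rng), rng.normal(scale=30, size=3)
            pocket2 = structio.ProteinStructure([
                structio.Atom(a.element, a.name, a.res_id, a.res_name,
                              a.chain, rot @ a.coords + t)
                for a in rec.pocket.atoms])
            lig2 = rec.ligand.with_coords(rec.ligand.coords @ rot.T + t)
            rec2 = structio.ComplexRecord(
                rec.target_id, pocket2, lig2, rec.set_tag, rec.E_true,
                rec.R_true, rec.molecule_id, rec.pose_id)
            moved = graphs.build_graphs(rec2, mode="complex")
            np.testing.assert_allclose(moved.node_features,
                                       base.node_features, atol=1e-9)
            np.testing.assert_allclose(moved.edge_features,
                                       base.edge_features,
                                       rtol=1e-6, atol=1e-9)
            np.testing.assert_array_equal(moved.edge_index, base.edge_index)

    def test_atom_permutation_permutes_rows_consistently(self, aspirin_pose):
        rng = np.random.default_rng(4)
        perm = rng.permutation(aspirin_pose.n_atoms)
        mol2 = Chem.RenumberAtoms(aspirin_pose.mol,
                                  [int(i) for i in np.argsort(perm)])
        pose2 = structio.LigandPose(mol2)
        g1 = ligand_graph(aspirin_pose)
        g2 = ligand_graph(pose2)
        # row i of the permuted graph is row perm[i] of the original
        np.testing.assert_allclose(g2.node_features,
                                   g1.node_features[np.argsort(perm)],
                                   atol=1e-9)

    def test_serialization_roundtrip(self, tmp_path, tiny_world):
        rec = tiny_world.natives[tiny_world.target_ids[0]]
        schema = FeatureSchema(ablated=frozenset({"distance"}))
        g = graphs.build_graphs(rec, mode="complex", schema=schema)
        path = tmp_path / "graph.npz"
        g.save(path)
        back = graphs.MolecularGraph.load(path)
        np.testing.assert_array_equal(back.node_features, g.node_features)
        np.testing.assert_array_equal(back.edge_features, g.edge_features)
        assert back.schema.ablated == frozenset({"distance"})

    def test_featurizer_cache_matches_direct_build(self, tiny_world):
        fz = graphs.ComplexFeaturizer()
        for tid in tiny_world.target_ids[:2]:
            rec = tiny_world.natives[tid]
            direct = graphs.build_graphs(rec, mode="complex")
            cached = fz.complex_graph(rec)
            again = fz.complex_graph(rec)
            np.testing.assert_allclose(cached.node_features,
                                       direct.node_features, atol=1e-12)
            np.testing.assert_allclose(again.edge_features,
                                       cached.edge_features, atol=1e-12)
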