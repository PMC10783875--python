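"""Message passing, interaction fusion and read-out against dense oracles."""

import numpy as np
import pytest

from assaybind.autodiff import Tensor
from assaybind.complex_graphs import (
    AtomRecord,
    ComplexStructure,
    InteractionGraph,
    ResidueRecord,
    build_ligand_graph,
    featurize_interaction_edge,
)
from assaybind.encoder import (
    EncoderConfig,
    GNNConfig,
    InteractionEmbeddings,
    NoContactError,
    complex_tensors,
    encode_complex,
    encode_graph,
    fuse_interactions,
    graph_tensors,
    init_encoder_params,
    init_gnn_params,
    readout,
)

VARIANTS = ("GCN", "GIN", "GAT", "EGNN", "AttentiveFP")


def toy_graph(rng, n_nodes=5, n_feat=7, cutoff=5.0):
    coords = rng.uniform(0, 6, size=(n_nodes, 3))
    atoms = [
        AtomRecord(
            index=i,
            element="C",
            coord=coords[i],
            features=rng.standard_normal(23),
        )
        for i in range(n_nodes)
    ]
    return build_ligand_graph(atoms, cutoff=cutoff)


def leaky(x, slope=0.01):
    return np.where(x > 0, x, slope * x)


def dense_layer_oracle(variant, H, gt, params, p):
    """Independent dense re-evaluation of one message-passing layer."""
    n = H.shape[0]
    W = {k[len(p) + 1 :]: v.data for k, v in params.items() if k.startswith(p + ".")}
    msgs = np.zeros((n, W[list(W)[0]].shape[1] if variant == "GCN" else 0))
    if variant == "GCN":
        deg = np.bincount(gt.dst, minlength=n).astype(float) + 1.0
        d = W["msg.W"].shape[1]
        m = np.zeros((n, d))
        for s, t, e in zip(gt.src, gt.dst, gt.edge_attr):
            norm = 1.0 / np.sqrt(deg[s] * deg[t])
            m[t] += norm * (np.concatenate([H[s], e]) @ W["msg.W"] + W["msg.b"])
        return leaky(H @ W["self.W"] + W["self.b"] + m)
    if variant == "GIN":
        Z = H @ W["proj.W"] + W["proj.b"]
        d = Z.shape[1]
        m = np.zeros((n, d))
        for s, t, e in zip(gt.src, gt.dst, gt.edge_attr):
            m[t] += np.maximum(Z[s] + e @ W["edge.W"] + W["edge.b"], 0.0)
        agg = (1.0 + W["eps"]) * Z + m
        hid = leaky(agg @ W["mlp1.W"] + W["mlp1.b"])
        return leaky(hid @ W["mlp2.W"] + W["mlp2.b"])
    if variant == "GAT":
        Z = H @ W["proj.W"] + W["proj.b"]
        d = Z.shape[1]
        scores = np.full((n, len(gt.src)), -np.inf)
        per_edge = np.zeros(len(gt.src))
        for k, (s, t, e) in enumerate(zip(gt.src, gt.dst, gt.edge_attr)):
            ze = e @ W["edge.W"] + W["edge.b"]
            per_edge[k] = leaky(np.concatenate([Z[t], Z[s], ze]), 0.2) @ W["att"]
        m = np.zeros((n, d))
        for i in range(n):
            ks = [k for k in range(len(gt.src)) if gt.dst[k] == i]
            if not ks:
                continue
            ex = np.exp(per_edge[ks] - np.max(per_edge[ks]))
            alpha = ex / ex.sum()
            for a, k in zip(alpha, ks):
                m[i] += a * Z[gt.src[k]]
        return leaky(Z + m)
    if variant == "EGNN":
        Z = H @ W["proj.W"] + W["proj.b"]
        d = Z.shape[1]
        m = np.zeros((n, d))
        for s, t, e in zip(gt.src, gt.dst, gt.edge_attr):
            d2 = np.sum((gt.coords[s] - gt.coords[t]) ** 2)
            inp = np.concatenate([Z[t], Z[s], [d2], e])
            msg = leaky(leaky(inp @ W["msg1.W"] + W["msg1.b"]) @ W["msg2.W"] + W["msg2.b"])
            m[t] += msg
        return leaky(np.hstack([Z, m]) @ W["upd.W"] + W["upd.b"])
    if variant == "AttentiveFP":
        Z = H @ W["proj.W"] + W["proj.b"]
        d = Z.shape[1]
        nbr = np.zeros((len(gt.src), d))
        per_edge = np.zeros(len(gt.src))
        for k, (s, t, e) in enumerate(zip(gt.src, gt.dst, gt.edge_attr)):
            nbr[k] = leaky(np.concatenate([Z[s], e]) @ W["nbr.W"] + W["nbr.b"])
            per_edge[k] = leaky(np.concatenate([Z[t], nbr[k]]), 0.2) @ W["att"]
        m = np.zeros((n, d))
        for i in range(n):
            ks = [k for k in range(len(gt.src)) if gt.dst[k] == i]
            if not ks:
                continue
            ex = np.exp(per_edge[ks] - np.max(per_edge[ks]))
            alpha = ex / ex.sum()
            for a, k in zip(alpha, ks):
                m[i] += a * nbr[k]
        gate = 1.0 / (1.0 + np.exp(-(np.hstack([Z, m]) @ W["gate.W"] + W["gate.b"])))
        cand = np.tanh(m @ W["upd.W"] + W["upd.b"] + Z @ W["self.W"] + W["self.b"])
        return gate * cand + (1.0 - gate) * Z
    raise ValueError(variant)


class TestMessagePassing:
    @pytest.mark.parametrize("variant", VARIANTS)
    def test_two_layers_match_dense_oracle(self, variant, rng):
        graph = toy_graph(rng, n_nodes=6)
        gt = graph_tensors(graph)
        cfg = GNNConfig(variant=variant, n_layers=2, hidden_dim=5, dropout=0.0)
        params = init_gnn_params(cfg, 23, gt.edge_attr.shape[1], rng, "g")
        emb = encode_graph(gt, cfg, params, "g")
        H = gt.x
        expected_layers = []
        for layer in range(2):
            H = dense_layer_oracle(variant, H, gt, params, f"g.l{layer}")
            expected_layers.append(H)
        np.testing.assert_allclose(
            emb.final.data, expected_layers[0] + expected_layers[1], atol=1e-5
        )

    def test_jumping_knowledge_identity(self, rng):
        graph = toy_graph(rng)
        cfg = GNNConfig(n_layers=3, hidden_dim=4, dropout=0.0)
        gt = graph_tensors(graph)
        params = init_gnn_params(cfg, 23, gt.edge_attr.shape[1], rng, "g")
        emb = encode_graph(gt, cfg, params, "g")
        acc = sum(layer.data for layer in emb.per_layer)
        np.testing.assert_allclose(emb.final.data, acc, atol=1e-12)

    def test_isolated_node_gets_zero_message(self, rng):
        atom = AtomRecord(index=0, element="C", coord=np.zeros(3),
                          features=rng.standard_normal(23))
        graph = build_ligand_graph([atom])
        cfg = GNNConfig(variant="GIN", n_layers=1, hidden_dim=4, dropout=0.0)
        gt = graph_tensors(graph)
        params = init_gnn_params(cfg, 23, 21, rng, "g")
        emb = encode_graph(gt, cfg, params, "g")
        # oracle: zero aggregated message path through the GIN update
        W = {k: v.data for k, v in params.items()}
        z = atom.features @ W["g.l0.proj.W"] + W["g.l0.proj.b"]
        agg = (1.0 + W["g.l0.eps"]) * z
        hid = leaky(agg @ W["g.l0.mlp1.W"] + W["g.l0.mlp1.b"])
        expected = leaky(hid @ W["g.l0.mlp2.W"] + W["g.l0.mlp2.b"])
        np.testing.assert_allclose(emb.final.data[0], expected, atol=1e-10)

    @pytest.mark.parametrize("variant", VARIANTS)
    def test_permutation_equivariance(self, variant, rng):
        graph = toy_graph(rng, n_nodes=6)
        cfg = GNNConfig(variant=variant, n_layers=2, hidden_dim=4, dropout=0.0)
        gt = graph_tensors(graph)
        params = init_gnn_params(cfg, 23, gt.edge_attr.shape[1], rng, "g")
        out = encode_graph(gt, cfg, params, "g").final.data

        perm = rng.permutation(6)
        inv = np.argsort(perm)
        from assaybind.encoder import GraphTensors

        gt_p = GraphTensors(
            x=gt.x[perm],
            src=inv[gt.src],
            dst=inv[gt.dst],
            edge_attr=gt.edge_attr,
            coords=gt.coords[perm],
        )
        out_p = encode_graph(gt_p, cfg, params, "g").final.data
        np.testing.assert_allclose(out_p, out[perm], atol=1e-8)

    def test_feature_dim_mismatch_raises(self, rng):
        graph = toy_graph(rng)
        cfg = GNNConfig(n_layers=1, hidden_dim=4, dropout=0.0)
        params = init_gnn_params(cfg, 10, 21, rng, "g")  # wrong input dim
        with pytest.raises(ValueError, match="dim"):
            encode_graph(graph, cfg, params, "g")


class TestFusionAndReadout:
    def small_ig(self, rng, n_res=3, n_atoms=4, k_edges=5):
        edges = [(int(i), int(j)) for i, j in
                 zip(rng.integers(0, n_res, k_edges), rng.integers(0, n_atoms, k_edges))]
        edges = sorted(set(edges))
        feats = np.array([featurize_interaction_edge(rng.uniform(0, 12)) for _ in edges])
        return InteractionGraph(
            residue_count=n_res, atom_count=n_atoms, edges=edges, edge_features=feats
        )

    def test_fusion_matches_formula_oracle(self, rng):
        cfg = EncoderConfig(
            gnn=GNNConfig(hidden_dim=4, dropout=0.0), interaction_dim=6
        )
        from assaybind.encoder import init_fusion_params

        params = init_fusion_params(cfg, 4, 16, rng)
        hp = Tensor(rng.standard_normal((3, 4)))
        hl = Tensor(rng.standard_normal((4, 4)))
        ig = self.small_ig(rng)
        ie = fuse_interactions(hp, hl, ig, params)
        W = {k: v.data for k, v in params.items()}
        for row, (i, j) in zip(ie.embeddings.data, ig.edges):
            e = ig.edge_features[ig.edges.index((i, j))]
            fc = e @ W["fusion.fc.W"] + W["fusion.fc.b"]
            x = np.concatenate([hp.data[i], hl.data[j], fc])
            hid = leaky(x @ W["fusion.mlp1.W"] + W["fusion.mlp1.b"])
            expected = leaky(hid @ W["fusion.mlp2.W"] + W["fusion.mlp2.b"])
            np.testing.assert_allclose(row, expected, atol=1e-5)

    def test_fusion_output_aligned_with_edges(self, rng):
        cfg = EncoderConfig(gnn=GNNConfig(hidden_dim=4, dropout=0.0), interaction_dim=6)
        from assaybind.encoder import init_fusion_params

        params = init_fusion_params(cfg, 4, 16, rng)
        ig = self.small_ig(rng, k_edges=7)
        ie = fuse_interactions(
            Tensor(rng.standard_normal((3, 4))),
            Tensor(rng.standard_normal((4, 4))),
            ig,
            params,
        )
        assert ie.embeddings.shape[0] == len(ig.edges)
        assert ie.edges == ig.edges

    def test_empty_interaction_edges_raise_no_contact(self, rng):
        ig = InteractionGraph(
            residue_count=2, atom_count=2, edges=[], edge_features=np.zeros((0, 16))
        )
        with pytest.raises(NoContactError):
            fuse_interactions(
                Tensor(np.zeros((2, 4))), Tensor(np.zeros((2, 4))), ig, {}
            )

    def test_readout_formula_oracle(self, rng):
        h = rng.standard_normal((5, 6))
        w = rng.standard_normal(6)
        params = {"readout.w": Tensor(w)}
        ie = InteractionEmbeddings(embeddings=Tensor(h), edges=[(0, i) for i in range(5)])
        emb = readout(ie, params)
        att = np.tanh(h @ w)
        np.testing.assert_allclose(emb.o_sum.data, (att[:, None] * h).sum(axis=0), atol=1e-6)
        np.testing.assert_allclose(emb.o_max.data, h.max(axis=0), atol=1e-12)
        np.testing.assert_allclose(
            emb.vector.data, np.concatenate([emb.o_sum.data, emb.o_max.data])
        )
        np.testing.assert_allclose(emb.attention_weights, att)
        assert np.all(np.abs(emb.attention_weights) < 1.0)

    def test_readout_zero_attention_vector(self, rng):
        h = rng.standard_normal((4, 3))
        params = {"readout.w": Tensor(np.zeros(3))}
        ie = InteractionEmbeddings(embeddings=Tensor(h), edges=[(0, i) for i in range(4)])
        emb = readout(ie, params)
        np.testing.assert_allclose(emb.o_sum.data, np.zeros(3))
        np.testing.assert_allclose(emb.o_max.data, h.max(axis=0))

    def test_readout_single_edge(self, rng):
        h = rng.standard_normal((1, 3))
        w = rng.standard_normal(3)
        ie = InteractionEmbeddings(embeddings=Tensor(h), edges=[(0, 0)])
        emb = readout(ie, {"readout.w": Tensor(w)})
        np.testing.assert_allclose(emb.o_sum.data, np.tanh(h[0] @ w) * h[0])
        np.testing.assert_allclose(emb.o_max.data, h[0])

    def test_readout_permutation_invariant(self, rng):
        h = rng.standard_normal((6, 4))
        w = rng.standard_normal(4)
        perm = rng.permutation(6)
        ie1 = InteractionEmbeddings(embeddings=Tensor(h), edges=list(range(6)))
        ie2 = InteractionEmbeddings(embeddings=Tensor(h[perm]), edges=list(perm))
        o1 = readout(ie1, {"readout.w": Tensor(w)})
        o2 = readout(ie2, {"readout.w": Tensor(w)})
        np.testing.assert_allclose(o1.vector.data, o2.vector.data, atol=1e-12)


class TestEncodeComplex:
    def make_complex(self, rng, n_res=6, n_atoms=5):
        res = [
            ResidueRecord(index=i, residue_name="ALA", ca_coord=rng.uniform(0, 10, 3))
            for i in range(n_res)
        ]
        atoms = [
            AtomRecord(index=i, element="C", coord=rng.uniform(3, 8, 3))
            for i in range(n_atoms)
        ]
        return ComplexStructure(protein=res, ligand=atoms, protein_id="P", ligand_id="L")

    def test_eval_mode_deterministic(self, rng, tiny_model_cfg):
        cs = self.make_complex(rng)
        params = init_encoder_params(tiny_model_cfg.encoder, np.random.default_rng(0))
        o1 = encode_complex(cs, tiny_model_cfg.encoder, params)
        o2 = encode_complex(cs, tiny_model_cfg.encoder, params)
        np.testing.assert_array_equal(o1.vector.data, o2.vector.data)

    def test_rigid_rotation_invariance(self, rng, tiny_model_cfg):
        from scipy.spatial.transform import Rotation

        cs = self.make_complex(rng)
        R = Rotation.random(random_state=3).as_matrix()
        t = np.array([5.0, -2.0, 1.0])
        moved = ComplexStructure(
            protein=[
                ResidueRecord(r.index, r.residue_name, R @ r.ca_coord + t, r.features)
                for r in cs.protein
            ],
            ligand=[
                AtomRecord(a.index, a.element, R @ a.coord + t, a.features)
                for a in cs.ligand
            ],
            protein_id="P",
            ligand_id="L",
        )
        params = init_encoder_params(tiny_model_cfg.encoder, np.random.default_rng(0))
        o1 = encode_complex(cs, tiny_model_cfg.encoder, params)
        o2 = encode_complex(moved, tiny_model_cfg.encoder, params)
        np.testing.assert_allclose(o1.vector.data, o2.vector.data, atol=1e-6)

    def test_attention_weights_exposed_per_edge(self, rng, tiny_model_cfg):
        cs = self.make_complex(rng)
        ct = complex_tensors(cs, tiny_model_cfg.encoder)
        params = init_encoder_params(tiny_model_cfg.encoder, np.random.default_rng(0))
        o = encode_complex(ct, tiny_model_cfg.encoder, params)
        assert len(o.attention_weights) == len(ct.interaction.edges)
        assert o.edges == ct.interaction.edges

    def test_gradients_reach_all_parameter_groups(self, rng, tiny_model_cfg):
        cs = self.make_complex(rng)
        params = init_encoder_params(tiny_model_cfg.encoder, np.random.default_rng(0))
        o = encode_complex(cs, tiny_model_cfg.encoder, params)
        (o.vector**2).sum().backward()
        missing = [
            k for k, v in params.items() if v.grad is None or np.abs(v.grad).sum() == 0
        ]
        assert missing == []
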