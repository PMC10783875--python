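"""Independent dense re-evaluation of the full encoder pipeline (GIN).

Used as an end-to-end oracle: plain numpy loops over nodes and edges, no
shared code with the package's sparse message-passing path.
"""

import numpy as np

from assaybind.complex_graphs import build_complex_graphs


def _leaky(x, slope=0.01):
    return np.where(x > 0, x, slope * x)


def _gin_layer(H, src, dst, edge_attr, W, p):
    n = H.shape[0]
    Z = H @ W[f"{p}.proj.W"] + W[f"{p}.proj.b"]
    m = np.zeros_like(Z)
    for s, t, e in zip(src, dst, edge_attr):
        m[t] += np.maximum(Z[s] + e @ W[f"{p}.edge.W"] + W[f"{p}.edge.b"], 0.0)
    agg = (1.0 + W[f"{p}.eps"]) * Z + m
    hid = _leaky(agg @ W[f"{p}.mlp1.W"] + W[f"{p}.mlp1.b"])
    return _leaky(hid @ W[f"{p}.mlp2.W"] + W[f"{p}.mlp2.b"])


def _dense_gnn(x, edges, edge_features, W, prefix, n_layers):
    src = [i for i, j in edges] + [j for i, j in edges]
    dst = [j for i, j in edges] + [i for i, j in edges]
    attr = list(edge_features) + list(edge_features)
    H = x
    total = None
    for layer in range(n_layers):
        H = _gin_layer(H, src, dst, attr, W, f"{prefix}.l{layer}")
        total = H if total is None else total + H
    return total


def dense_encode_complex(cs, cfg, params):
    W = {k: v.data for k, v in params.items()}
    lg, pg, ig = build_complex_graphs(
        cs,
        ligand_cutoff=cfg.ligand_cutoff,
        protein_cutoff=cfg.protein_cutoff,
        interaction_cutoff=cfg.interaction_cutoff,
        pocket_only=cfg.pocket_only,
    )
    h_l = _dense_gnn(
        np.array([a.features for a in lg.nodes]),
        lg.edges, lg.edge_features, W, "ligand", cfg.gnn.n_layers,
    )
    h_p = _dense_gnn(
        np.array([r.features for r in pg.nodes]),
        pg.edges, pg.edge_features, W, "protein", cfg.gnn.n_layers,
    )
    hi = []
    for (i, j), e in zip(ig.edges, ig.edge_features):
        fc = e @ W["fusion.fc.W"] + W["fusion.fc.b"]
        x = np.concatenate([h_p[i], h_l[j], fc])
        hid = _leaky(x @ W["fusion.mlp1.W"] + W["fusion.mlp1.b"])
        hi.append(_leaky(hid @ W["fusion.mlp2.W"] + W["fusion.mlp2.b"]))
    hi = np.array(hi)
    att = np.tanh(hi @ W["readout.w"])
    o_sum = (att[:, None] * hi).sum(axis=0)
    o_max = hi.max(axis=0)
    return np.concatenate([o_sum, o_max])
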