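"""Shared bottom encoder: message passing, interaction fusion, read-out.

The encoder maps a protein-ligand complex to one fixed-length vector in
three stages:

1. *Encoding*: a GNN runs message passing over the ligand graph and the
   protein graph separately.  At layer l, messages M_l(h_i, h_j, e_ij) are
   aggregated over neighbors N(i) and an update U_l produces h_i^(l+1).
   The final node embedding is the jumping-knowledge sum over layers,
   h_i = sum_l h_i^(l).
2. *Interacting*: for each residue-atom contact edge (i, j) the interaction
   embedding is h^I_ij = MLP(h^P_i || h^L_j || FC(e^I_ij)).
3. *Read-out*: o_sum = sum_ij tanh(w . h^I_ij) h^I_ij, o_max = elementwise
   max over contact edges, and o = o_sum || o_max.

Five GNN variants are provided (GCN, GIN, GAT, EGNN, AttentiveFP-style
gated attention), all expressed in the same message-passing scheme; EGNN
uses squared pairwise distances, so its affinity output is invariant to
rigid motions rather than equivariant.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .autodiff import Tensor, concat, linear, segment_softmax, spmm
from . import complex_graphs as cg
from .complex_graphs import (
    ComplexStructure,
    InteractionGraph,
    LigandGraph,
    ProteinGraph,
    build_complex_graphs,
)

GNN_VARIANTS = ("GCN", "GIN", "GAT", "EGNN", "AttentiveFP")


class NoContactError(ValueError):
    """The complex has no residue-atom pair within the interaction cutoff."""


@dataclass
class GNNConfig:
    variant: str = "GIN"
    n_layers: int = 2
    hidden_dim: int = 32
    dropout: float = 0.1

    def __post_init__(self):
        if self.variant not in GNN_VARIANTS:
            raise ValueError(f"unknown GNN variant {self.variant!r}")
        if self.n_layers < 1 or self.hidden_dim < 1:
            raise ValueError("n_layers and hidden_dim must be >= 1")


@dataclass
class EncoderConfig:
    gnn: GNNConfig = field(default_factory=GNNConfig)
    interaction_dim: int = 32  # d_I: width of interaction embeddings
    ligand_cutoff: float = cg.LIGAND_CUTOFF
    protein_cutoff: float = cg.PROTEIN_CUTOFF
    interaction_cutoff: float = cg.INTERACTION_CUTOFF
    pocket_only: bool = True

    @property
    def output_dim(self) -> int:
        return 2 * self.interaction_dim  # o = o_sum || o_max


@dataclass
class NodeEmbeddings:
    """Final node embeddings plus the per-layer matrices they sum over."""

    final: Tensor  # (n_nodes, d): jumping-knowledge sum
    per_layer: list[Tensor]


@dataclass
class InteractionEmbeddings:
    """One embedding per interaction edge, aligned with the edge list."""

    embeddings: Tensor  # (n_edges, d_I)
    edges: list[tuple[int, int]]


@dataclass
class ComplexEmbedding:
    vector: Tensor  # (2 * d_I,)
    o_sum: Tensor
    o_max: Tensor
    attention_weights: np.ndarray  # tanh scores per edge, in (-1, 1)
    edges: list[tuple[int, int]]


# ---------------------------------------------------------------------------
# Parameter initialization
# ---------------------------------------------------------------------------


def _glorot(rng: np.random.Generator, n_in: int, n_out: int) -> np.ndarray:
    lim = np.sqrt(6.0 / (n_in + n_out))
    return rng.uniform(-lim, lim, size=(n_in, n_out))


def _linear_params(rng, name, n_in, n_out, params):
    params[f"{name}.W"] = Tensor(_glorot(rng, n_in, n_out), requires_grad=True)
    params[f"{name}.b"] = Tensor(np.zeros(n_out), requires_grad=True)


def _linear(x: Tensor, params, name) -> Tensor:
    return linear(x, params[f"{name}.W"], params[f"{name}.b"])


def init_gnn_params(
    cfg: GNNConfig, in_dim: int, edge_dim: int, rng: np.random.Generator, prefix: str
) -> dict[str, Tensor]:
    """Allocate the per-layer parameters for one GNN stack."""
    d = cfg.hidden_dim
    params: dict[str, Tensor] = {}
    for layer in range(cfg.n_layers):
        p = f"{prefix}.l{layer}"
        src = in_dim if layer == 0 else d
        if cfg.variant == "GCN":
            _linear_params(rng, f"{p}.msg", src + edge_dim, d, params)
            _linear_params(rng, f"{p}.self", src, d, params)
        elif cfg.variant == "GIN":
            _linear_params(rng, f"{p}.proj", src, d, params)
            _linear_params(rng, f"{p}.edge", edge_dim, d, params)
            _linear_params(rng, f"{p}.mlp1", d, d, params)
            _linear_params(rng, f"{p}.mlp2", d, d, params)
            params[f"{p}.eps"] = Tensor(np.zeros(1), requires_grad=True)
        elif cfg.variant == "GAT":
            _linear_params(rng, f"{p}.proj", src, d, params)
            _linear_params(rng, f"{p}.edge", edge_dim, d, params)
            params[f"{p}.att"] = Tensor(
                _glorot(rng, 3 * d, 1).ravel(), requires_grad=True
            )
        elif cfg.variant == "EGNN":
            _linear_params(rng, f"{p}.proj", src, d, params)
            _linear_params(rng, f"{p}.msg1", 2 * d + 1 + edge_dim, d, params)
            _linear_params(rng, f"{p}.msg2", d, d, params)
            _linear_params(rng, f"{p}.upd", 2 * d, d, params)
        elif cfg.variant == "AttentiveFP":
            _linear_params(rng, f"{p}.proj", src, d, params)
            _linear_params(rng, f"{p}.nbr", d + edge_dim, d, params)
            params[f"{p}.att"] = Tensor(
                _glorot(rng, 2 * d, 1).ravel(), requires_grad=True
            )
            _linear_params(rng, f"{p}.gate", 2 * d, d, params)
            _linear_params(rng, f"{p}.upd", d, d, params)
            _linear_params(rng, f"{p}.self", d, d, params)
    return params


def init_fusion_params(
    cfg: EncoderConfig, node_dim: int, edge_dim: int, rng: np.random.Generator
) -> dict[str, Tensor]:
    """Parameters of the interacting module (per-contact fusion) + read-out."""
    d_i = cfg.interaction_dim
    e_out = max(d_i // 2, 1)
    params: dict[str, Tensor] = {}
    _linear_params(rng, "fusion.fc", edge_dim, e_out, params)
    _linear_params(rng, "fusion.mlp1", 2 * node_dim + e_out, d_i, params)
    _linear_params(rng, "fusion.mlp2", d_i, d_i, params)
    params["readout.w"] = Tensor(
        rng.standard_normal(d_i) / np.sqrt(d_i), requires_grad=True
    )
    return params


def init_encoder_params(cfg: EncoderConfig, rng: np.random.Generator) -> dict[str, Tensor]:
    params = {}
    params.update(
        init_gnn_params(
            cfg.gnn, cg.ATOM_FEATURE_LENGTH, cg.LIGAND_EDGE_FEATURE_LENGTH, rng, "ligand"
        )
    )
    params.update(
        init_gnn_params(
            cfg.gnn, cg.RESIDUE_FEATURE_LENGTH, cg.PROTEIN_EDGE_FEATURE_LENGTH, rng, "protein"
        )
    )
    params.update(
        init_fusion_params(
            cfg, cfg.gnn.hidden_dim, cg.INTERACTION_EDGE_FEATURE_LENGTH, rng
        )
    )
    return params


# ---------------------------------------------------------------------------
# Graph tensors
# ---------------------------------------------------------------------------


@dataclass
class GraphTensors:
    """Dense arrays for one homogeneous graph, edges expanded to both
    directions for message passing."""

    x: np.ndarray  # (n, f) node features
    src: np.ndarray  # (2E,) message source nodes
    dst: np.ndarray  # (2E,) message target nodes
    edge_attr: np.ndarray  # (2E, fe)
    coords: np.ndarray  # (n, 3)
    _x_t: Tensor | None = None  # cached constant tensors
    _e_t: Tensor | None = None
    _ops: dict | None = None  # cached sparse gather/scatter operators

    @property
    def x_tensor(self) -> Tensor:
        if self._x_t is None:
            self._x_t = Tensor(self.x)
        return self._x_t

    @property
    def edge_tensor(self) -> Tensor:
        if self._e_t is None:
            self._e_t = Tensor(self.edge_attr)
        return self._e_t

    def sparse_ops(self) -> dict:
        """Selection matrices for src/dst gathers and their transposes
        (scatter-sums), built once per graph."""
        if self._ops is None:
            n = self.x.shape[0]
            g_src = _selection_matrix(self.src, n)
            g_dst = _selection_matrix(self.dst, n)
            self._ops = {
                "src": g_src, "srcT": g_src.T.tocsr(),
                "dst": g_dst, "dstT": g_dst.T.tocsr(),
            }
        return self._ops


def _selection_matrix(idx: np.ndarray, n_cols: int):
    """CSR matrix S with S @ x == x[idx]."""
    from scipy import sparse

    m = idx.size
    return sparse.csr_matrix(
        (np.ones(m), (np.arange(m), idx)), shape=(m, n_cols)
    )


def graph_tensors(graph: LigandGraph | ProteinGraph) -> GraphTensors:
    if isinstance(graph, LigandGraph):
        x = np.array([a.features for a in graph.nodes])
        coords = np.array([a.coord for a in graph.nodes])
    else:
        x = np.array([r.features for r in graph.nodes])
        coords = np.array([r.ca_coord for r in graph.nodes])
    if graph.edges:
        e = np.array(graph.edges, dtype=np.intp)
        src = np.concatenate([e[:, 0], e[:, 1]])
        dst = np.concatenate([e[:, 1], e[:, 0]])
        attr = np.concatenate([graph.edge_features, graph.edge_features])
    else:
        src = dst = np.zeros(0, dtype=np.intp)
        attr = np.zeros((0, graph.edge_features.shape[1] if graph.edge_features.size else 0))
    return GraphTensors(x=x, src=src, dst=dst, edge_attr=attr, coords=coords)


# ---------------------------------------------------------------------------
# Message-passing layers
# ---------------------------------------------------------------------------


def _dropout(h: Tensor, rate: float, rng: np.random.Generator | None) -> Tensor:
    if rng is None or rate <= 0.0:
        return h
    mask = (rng.random(h.shape) >= rate) / (1.0 - rate)
    return h * Tensor(mask)


def _layer_forward(
    variant: str,
    h: Tensor,
    gt: GraphTensors,
    params: dict[str, Tensor],
    p: str,
    n_nodes: int,
) -> Tensor:
    """One message-passing layer; isolated nodes receive the zero message."""
    e = gt.edge_tensor
    has_edges = gt.src.size > 0

    if variant == "GCN":
        deg = np.bincount(gt.dst, minlength=n_nodes).astype(float) + 1.0
        if has_edges:
            ops = gt.sparse_ops()
            norm = 1.0 / np.sqrt(deg[gt.src] * deg[gt.dst])
            msg_in = concat([spmm(ops["src"], ops["srcT"], h), e], axis=1)
            msg = _linear(msg_in, params, f"{p}.msg") * Tensor(norm[:, None])
            m = spmm(ops["dstT"], ops["dst"], msg)
        else:
            m = Tensor(np.zeros((n_nodes, params[f"{p}.msg.W"].shape[1])))
        return (_linear(h, params, f"{p}.self") + m).leaky_relu()

    if variant == "GIN":
        z = _linear(h, params, f"{p}.proj")
        if has_edges:
            ops = gt.sparse_ops()
            msg = (spmm(ops["src"], ops["srcT"], z) + _linear(e, params, f"{p}.edge")).relu()
            m = spmm(ops["dstT"], ops["dst"], msg)
        else:
            m = Tensor(np.zeros(z.shape))
        agg = z * (1.0 + params[f"{p}.eps"]) + m
        hid = _linear(agg, params, f"{p}.mlp1").leaky_relu()
        return _linear(hid, params, f"{p}.mlp2").leaky_relu()

    if variant == "GAT":
        z = _linear(h, params, f"{p}.proj")
        if has_edges:
            ops = gt.sparse_ops()
            ze = _linear(e, params, f"{p}.edge")
            zi = spmm(ops["dst"], ops["dstT"], z)
            zj = spmm(ops["src"], ops["srcT"], z)
            scores = (
                concat([zi, zj, ze], axis=1).leaky_relu(0.2) @ params[f"{p}.att"]
            )
            alpha = segment_softmax(scores, gt.dst, n_nodes)
            m = spmm(ops["dstT"], ops["dst"], zj * alpha.reshape(-1, 1))
        else:
            m = Tensor(np.zeros(z.shape))
        return (z + m).leaky_relu()

    if variant == "EGNN":
        z = _linear(h, params, f"{p}.proj")
        if has_edges:
            d2 = np.sum((gt.coords[gt.src] - gt.coords[gt.dst]) ** 2, axis=1)
            ops = gt.sparse_ops()
            msg_in = concat(
                [
                    spmm(ops["dst"], ops["dstT"], z),
                    spmm(ops["src"], ops["srcT"], z),
                    Tensor(d2[:, None]),
                    e,
                ],
                axis=1,
            )
            msg = _linear(
                _linear(msg_in, params, f"{p}.msg1").leaky_relu(), params, f"{p}.msg2"
            ).leaky_relu()
            m = spmm(ops["dstT"], ops["dst"], msg)
        else:
            m = Tensor(np.zeros(z.shape))
        return _linear(concat([z, m], axis=1), params, f"{p}.upd").leaky_relu()

    if variant == "AttentiveFP":
        z = _linear(h, params, f"{p}.proj")
        if has_edges:
            ops = gt.sparse_ops()
            nbr = _linear(
                concat([spmm(ops["src"], ops["srcT"], z), e], axis=1), params, f"{p}.nbr"
            ).leaky_relu()
            scores = (
                concat([spmm(ops["dst"], ops["dstT"], z), nbr], axis=1).leaky_relu(0.2)
                @ params[f"{p}.att"]
            )
            alpha = segment_softmax(scores, gt.dst, n_nodes)
            m = spmm(ops["dstT"], ops["dst"], nbr * alpha.reshape(-1, 1))
        else:
            m = Tensor(np.zeros(z.shape))
        gate = _linear(concat([z, m], axis=1), params, f"{p}.gate").sigmoid()
        cand = (_linear(m, params, f"{p}.upd") + _linear(z, params, f"{p}.self")).tanh()
        return gate * cand + (1.0 - gate) * z

    raise ValueError(f"unknown GNN variant {variant!r}")


def encode_graph(
    graph: LigandGraph | ProteinGraph | GraphTensors,
    cfg: GNNConfig,
    params: dict[str, Tensor],
    prefix: str,
    dropout_rng: np.random.Generator | None = None,
) -> NodeEmbeddings:
    """Run the full message-passing stack over one graph.

    Returns the jumping-knowledge sum of per-layer embeddings together with
    the retained per-layer matrices.  Pass ``dropout_rng`` only in training
    mode; evaluation is deterministic.
    """
    gt = graph if isinstance(graph, GraphTensors) else graph_tensors(graph)
    if gt.x.shape[1] != params[f"{prefix}.l0.proj.W" if cfg.variant != "GCN" else f"{prefix}.l0.self.W"].shape[0]:
        raise ValueError(
            f"node feature dim {gt.x.shape[1]} does not match encoder input dim"
        )
    n_nodes = gt.x.shape[0]
    h = gt.x_tensor
    per_layer: list[Tensor] = []
    for layer in range(cfg.n_layers):
        h = _layer_forward(cfg.variant, h, gt, params, f"{prefix}.l{layer}", n_nodes)
        h = _dropout(h, cfg.dropout, dropout_rng)
        per_layer.append(h)
    final = per_layer[0]
    for t in per_layer[1:]:
        final = final + t
    return NodeEmbeddings(final=final, per_layer=per_layer)


# ---------------------------------------------------------------------------
# Interacting module and read-out
# ---------------------------------------------------------------------------


def fuse_interactions(
    h_protein: NodeEmbeddings | Tensor,
    h_ligand: NodeEmbeddings | Tensor,
    ig: InteractionGraph,
    params: dict[str, Tensor],
) -> InteractionEmbeddings:
    """Per contact edge (i, j): MLP(h^P_i || h^L_j || FC(e^I_ij))."""
    if not ig.edges:
        raise NoContactError("interaction graph has no edges")
    hp = h_protein.final if isinstance(h_protein, NodeEmbeddings) else h_protein
    hl = h_ligand.final if isinstance(h_ligand, NodeEmbeddings) else h_ligand
    edges = getattr(ig, "_edge_array", None)
    if edges is None:
        edges = np.array(ig.edges, dtype=np.intp)
        ig._edge_array = edges
        ig._edge_tensor = Tensor(ig.edge_features)
        g_res = _selection_matrix(edges[:, 0], ig.residue_count)
        g_atom = _selection_matrix(edges[:, 1], ig.atom_count)
        ig._g_res, ig._g_res_T = g_res, g_res.T.tocsr()
        ig._g_atom, ig._g_atom_T = g_atom, g_atom.T.tocsr()
    fc = _linear(ig._edge_tensor, params, "fusion.fc")
    fused_in = concat(
        [
            spmm(ig._g_res, ig._g_res_T, hp),
            spmm(ig._g_atom, ig._g_atom_T, hl),
            fc,
        ],
        axis=1,
    )
    hid = _linear(fused_in, params, "fusion.mlp1").leaky_relu()
    out = _linear(hid, params, "fusion.mlp2").leaky_relu()
    return InteractionEmbeddings(embeddings=out, edges=ig.edges)


def readout(
    ie: InteractionEmbeddings, params: dict[str, Tensor]
) -> ComplexEmbedding:
    """Attention-weighted sum plus elementwise max over contact edges."""
    h = ie.embeddings
    if h.shape[0] < 1:
        raise ValueError("read-out needs at least one interaction embedding")
    scores = (h @ params["readout.w"]).tanh()  # (E,), in (-1, 1)
    o_sum = (h * scores.reshape(-1, 1)).sum(axis=0)
    o_max = h.max_rows()
    return ComplexEmbedding(
        vector=concat([o_sum, o_max], axis=0),
        o_sum=o_sum,
        o_max=o_max,
        attention_weights=scores.data.copy(),
        edges=ie.edges,
    )


# ---------------------------------------------------------------------------
# Whole-complex encoding
# ---------------------------------------------------------------------------


@dataclass
class ComplexTensors:
    """Pre-built tensors for one complex (graph construction amortized)."""

    ligand: GraphTensors
    protein: GraphTensors
    interaction: InteractionGraph


def complex_tensors(cs: ComplexStructure, cfg: EncoderConfig) -> ComplexTensors:
    lg, pg, ig = build_complex_graphs(
        cs,
        ligand_cutoff=cfg.ligand_cutoff,
        protein_cutoff=cfg.protein_cutoff,
        interaction_cutoff=cfg.interaction_cutoff,
        pocket_only=cfg.pocket_only,
    )
    if not ig.edges:
        raise NoContactError(
            f"complex {cs.protein_id}/{cs.ligand_id}: no residue-atom contact "
            f"within {cfg.interaction_cutoff} A"
        )
    return ComplexTensors(
        ligand=graph_tensors(lg), protein=graph_tensors(pg), interaction=ig
    )


def encode_complex(
    cs: ComplexStructure | ComplexTensors,
    cfg: EncoderConfig,
    params: dict[str, Tensor],
    dropout_rng: np.random.Generator | None = None,
) -> ComplexEmbedding:
    """Full encoder: graphs -> GNN x2 -> interaction fusion -> read-out.

    Deterministic in evaluation mode (no ``dropout_rng``).
    """
    ct = cs if isinstance(cs, ComplexTensors) else complex_tensors(cs, cfg)
    h_l = encode_graph(ct.ligand, cfg.gnn, params, "ligand", dropout_rng)
    h_p = encode_graph(ct.protein, cfg.gnn, params, "protein", dropout_rng)
    ie = fuse_interactions(h_p, h_l, ct.interaction, params)
    return readout(ie, params)
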