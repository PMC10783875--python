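"""Four task heads, label-type routing and the multi-task loss.

Tasks form a 2x2 grid: measurement family {IC50, K} x objective
{regression, ranking}.  All four heads sit on one shared encoder (hard
parameter sharing).  For a within-assay pair the regression head predicts
the pAff of the first ligand only, the ranking head classifies which of the
two raw nM values is larger, and the total loss is

    L_total = L_rank + lambda * L_reg.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field

import numpy as np

from .autodiff import Tensor, concat, linear, softplus
from .bioassay_data import BioassayPair, map_label_type, ranking_label, to_paffinity
from .encoder import (
    ComplexEmbedding,
    EncoderConfig,
    encode_complex,
    init_encoder_params,
)

TASKS = ("ic50_reg", "ic50_rank", "k_reg", "k_rank")
LAMBDA_GRID = (0.0, 0.01, 0.1, 0.3, 1.0)  # regression-weight ablation grid


class RoutingError(ValueError):
    pass


@dataclass
class ModelConfig:
    encoder: EncoderConfig = field(default_factory=EncoderConfig)
    lam: float = 0.1  # weight of the regression loss in the total loss
    enabled_tasks: tuple[str, ...] = TASKS
    head_dropout: float = 0.0

    def __post_init__(self):
        if self.lam < 0:
            raise ValueError("lambda must be >= 0")
        bad = set(self.enabled_tasks) - set(TASKS)
        if bad:
            raise ValueError(f"unknown tasks: {sorted(bad)}")

    def config_hash(self) -> str:
        blob = json.dumps(
            {
                "gnn": vars(self.encoder.gnn),
                "d_i": self.encoder.interaction_dim,
                "cutoffs": [
                    self.encoder.ligand_cutoff,
                    self.encoder.protein_cutoff,
                    self.encoder.interaction_cutoff,
                ],
                "pocket_only": self.encoder.pocket_only,
                "lam": self.lam,
                "tasks": sorted(self.enabled_tasks),
            },
            sort_keys=True,
        )
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


@dataclass
class LossBundle:
    """Per-batch losses; l_total = l_rank + lambda * l_reg exactly."""

    l_rank: Tensor
    l_reg: Tensor
    l_total: Tensor
    task_type: str = ""

    def as_floats(self) -> tuple[float, float, float]:
        return (
            self.l_rank.item(),
            self.l_reg.item(),
            self.l_total.item(),
        )


# ---------------------------------------------------------------------------
# Heads
# ---------------------------------------------------------------------------


def _head_params(rng, params, name, in_dim):
    hid = max(in_dim // 2, 1)
    lim1 = np.sqrt(6.0 / (in_dim + hid))
    lim2 = np.sqrt(6.0 / (hid + 1))
    params[f"{name}.l1.W"] = Tensor(
        rng.uniform(-lim1, lim1, (in_dim, hid)), requires_grad=True
    )
    params[f"{name}.l1.b"] = Tensor(np.zeros(hid), requires_grad=True)
    params[f"{name}.l2.W"] = Tensor(
        rng.uniform(-lim2, lim2, (hid, 1)), requires_grad=True
    )
    params[f"{name}.l2.b"] = Tensor(np.zeros(1), requires_grad=True)


def init_head_params(cfg: ModelConfig, rng: np.random.Generator) -> dict[str, Tensor]:
    d_o = cfg.encoder.output_dim
    params: dict[str, Tensor] = {}
    for task in ("IC50", "K"):
        _head_params(rng, params, f"head.{task}.Reg", d_o)
        _head_params(rng, params, f"head.{task}.Rank", 2 * d_o)
    return params


def _head_forward(params: dict[str, Tensor], name: str, x: Tensor) -> Tensor:
    # asinh compresses the dynamic range of the attention-sum read-out,
    # whose magnitude grows with the number of contact edges
    hid = linear(x.asinh(), params[f"{name}.l1.W"], params[f"{name}.l1.b"]).leaky_relu()
    return linear(hid, params[f"{name}.l2.W"], params[f"{name}.l2.b"])


class MultiTaskModel:
    """Shared encoder plus the four task heads and the loss weight lambda."""

    def __init__(self, cfg: ModelConfig, rng: np.random.Generator | int = 0):
        if isinstance(rng, (int, np.integer)):
            rng = np.random.default_rng(int(rng))
        self.cfg = cfg
        self.params: dict[str, Tensor] = init_encoder_params(cfg.encoder, rng)
        self.params.update(init_head_params(cfg, rng))

    # -- embeddings ---------------------------------------------------------

    def encode(self, cs, dropout_rng=None) -> ComplexEmbedding:
        return encode_complex(cs, self.cfg.encoder, self.params, dropout_rng)

    # -- heads --------------------------------------------------------------

    def predict_affinity(self, o, task_type: str) -> Tensor:
        """Scalar pAff prediction from the matching regression head only."""
        if task_type not in ("IC50", "K"):
            raise RoutingError(f"unknown task type {task_type!r}")
        vec = o.vector if isinstance(o, ComplexEmbedding) else o
        return _head_forward(self.params, f"head.{task_type}.Reg", vec)

    def predict_rank_logit(self, o1, o2, task_type: str) -> Tensor:
        if task_type not in ("IC50", "K"):
            raise RoutingError(f"unknown task type {task_type!r}")
        v1 = o1.vector if isinstance(o1, ComplexEmbedding) else o1
        v2 = o2.vector if isinstance(o2, ComplexEmbedding) else o2
        if v1.shape != v2.shape:
            raise ValueError("embeddings must have the same dimension")
        return _head_forward(
            self.params, f"head.{task_type}.Rank", concat([v1, v2], axis=0)
        )

    def predict_rank(self, o1, o2, task_type: str) -> Tensor:
        """P(value_1 > value_2) from the ranking head on the ordered
        concatenation o1 || o2.  Not symmetric by construction; training sees
        both orders through random pair ordering."""
        return self.predict_rank_logit(o1, o2, task_type).sigmoid()

    # -- parameter plumbing -------------------------------------------------

    def trainable(self) -> dict[str, Tensor]:
        return {k: v for k, v in self.params.items() if v.requires_grad}

    def zero_grad(self) -> None:
        for t in self.params.values():
            t.grad = None

    def state_arrays(self) -> dict[str, np.ndarray]:
        return {k: v.data.copy() for k, v in self.params.items()}

    def load_state_arrays(self, state: dict[str, np.ndarray]) -> None:
        for k, t in self.params.items():
            t.data = state[k].copy()
            t.grad = None


# ---------------------------------------------------------------------------
# Losses
# ---------------------------------------------------------------------------


def regression_loss(y_hat: Tensor, y: float | Tensor) -> Tensor:
    """Squared error on the pAff scale (batch averaging is done by callers)."""
    y = y if isinstance(y, Tensor) else Tensor(y)
    diff = (y_hat.sum() if y_hat.ndim else y_hat) - y
    return diff**2


def ranking_loss(logit: Tensor, label: int) -> Tensor:
    """Numerically stable binary cross-entropy on the head's logit.

    BCE(sigmoid(z), 1) = softplus(-z); BCE(sigmoid(z), 0) = softplus(z).
    """
    z = logit.sum() if logit.ndim else logit  # collapse (1,) outputs
    return softplus(-z) if label == 1 else softplus(z)


def multitask_loss(l_rank: Tensor, l_reg: Tensor, lam: float) -> Tensor:
    """Total pre-training loss: L_rank + lambda * L_reg."""
    if lam < 0:
        raise ValueError("lambda must be >= 0")
    return l_rank + lam * l_reg


def pair_loss(
    model: MultiTaskModel,
    pair: BioassayPair,
    dropout_rng: np.random.Generator | None = None,
) -> LossBundle:
    """Losses for one bioassay pair: encode both conformations, rank the raw
    values, regress the first ligand's pAff."""
    task = map_label_type(pair.measure_type)
    o1 = encode_complex(
        pair.conformation_a, model.cfg.encoder, model.params, dropout_rng
    )
    o2 = encode_complex(
        pair.conformation_b, model.cfg.encoder, model.params, dropout_rng
    )
    zero = Tensor(0.0)
    task_key = task.lower()
    if f"{task_key}_rank" in model.cfg.enabled_tasks:
        logit = model.predict_rank_logit(o1, o2, task)
        l_rank = ranking_loss(logit, ranking_label(pair))
    else:
        l_rank = zero
    if f"{task_key}_reg" in model.cfg.enabled_tasks:
        y_hat = model.predict_affinity(o1, task)
        l_reg = regression_loss(y_hat.sum(), to_paffinity(pair.value_a))
    else:
        l_reg = zero
    return LossBundle(
        l_rank=l_rank,
        l_reg=l_reg,
        l_total=multitask_loss(l_rank, l_reg, model.cfg.lam),
        task_type=task,
    )
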