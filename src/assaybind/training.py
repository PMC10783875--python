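"""Pre-training on bioassay pairs and downstream fine-tuning.

Optimization protocol: Adam with initial learning rate 1e-3 and L2
regularization factor 1e-6; the learning rate is scaled down by 0.6
whenever the epoch-mean training loss sets no new minimum for 10
consecutive epochs.  Dropout 0.1.  Batch size 256 for pre-training and 128
for fine-tuning; 100 pre-training epochs; fine-tuning runs up to 1000
epochs with early stopping after 70 epochs without validation improvement.
The desk-scale defaults in :func:`pretrain_config` / :func:`finetune_config`
keep this protocol but shrink the budgets; every field is overridable.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .autodiff import Tensor
from .bioassay_data import Bioassay, BioassayPair, sample_assay, sample_pair
from .encoder import ComplexTensors, NoContactError, complex_tensors
from .multitask_model import ModelConfig, MultiTaskModel, pair_loss, regression_loss

logger = logging.getLogger(__name__)


@dataclass
class TrainConfig:
    phase: str = "pretrain"  # or "finetune"
    learning_rate: float = 1e-3
    weight_decay: float = 1e-6  # L2 factor
    lr_decay: float = 0.6
    plateau_patience: int = 10
    dropout: float = 0.1
    batch_size: int = 256
    max_epochs: int = 100
    early_stop_patience: int = 70  # finetune only
    min_lr: float = 1e-6  # guard against degenerate schedules
    seed: int = 0

    def __post_init__(self):
        if self.phase not in ("pretrain", "finetune"):
            raise ValueError(f"unknown phase {self.phase!r}")
        for name in ("learning_rate", "lr_decay", "batch_size", "max_epochs"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


def pretrain_config(**overrides) -> TrainConfig:
    return replace(TrainConfig(phase="pretrain", batch_size=256, max_epochs=100), **overrides)


def finetune_config(**overrides) -> TrainConfig:
    return replace(
        TrainConfig(phase="finetune", batch_size=128, max_epochs=1000), **overrides
    )


# ---------------------------------------------------------------------------
# Optimizer and schedule
# ---------------------------------------------------------------------------


class Adam:
    """Adam with decoupled-from-nothing classic L2: grad += wd * param."""

    def __init__(self, params: dict[str, Tensor], lr: float, weight_decay: float = 0.0,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.weight_decay = weight_decay
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self.m = {k: np.zeros_like(v.data) for k, v in params.items()}
        self.v = {k: np.zeros_like(v.data) for k, v in params.items()}

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for k, p in self.params.items():
            if p.grad is None:
                continue
            g = p.grad + self.weight_decay * p.data
            self.m[k] = b1 * self.m[k] + (1 - b1) * g
            self.v[k] = b2 * self.v[k] + (1 - b2) * g * g
            m_hat = self.m[k] / (1 - b1**self.t)
            v_hat = self.v[k] / (1 - b2**self.t)
            p.data -= self.lr * m_hat / (np.sqrt(v_hat) + self.eps)


class PlateauSchedule:
    """Multiply lr by `factor` after `patience` epochs without a new loss
    minimum; the counter resets on any new minimum."""

    def __init__(self, optimizer: Adam, factor: float = 0.6, patience: int = 10,
                 min_lr: float = 1e-6):
        self.opt = optimizer
        self.factor = factor
        self.patience = patience
        self.min_lr = min_lr
        self.best = np.inf
        self.stale = 0

    def step(self, loss: float) -> bool:
        """Record an epoch loss; returns True if the lr was reduced."""
        if loss < self.best:
            self.best = loss
            self.stale = 0
            return False
        self.stale += 1
        if self.stale >= self.patience:
            self.opt.lr = max(self.opt.lr * self.factor, self.min_lr)
            self.stale = 0
            return True
        return False


# ---------------------------------------------------------------------------
# Pair stream
# ---------------------------------------------------------------------------


@dataclass
class PairStream:
    """Two-stage sampler over curated assays with pre-built complex tensors.

    ``conformations`` maps (assay_id, ligand_id) to a ComplexTensors (or a
    ComplexStructure; tensors are then built lazily and cached).  One epoch
    is defined as sum(n_i) sampled pairs.
    """

    assays: list[Bioassay]
    conformations: dict[tuple[str, str], object]
    model_cfg: ModelConfig | None = None
    _cache: dict = field(default_factory=dict)

    @property
    def epoch_size(self) -> int:
        return sum(a.size for a in self.assays)

    def _tensors(self, assay_id: str, ligand_id: str) -> ComplexTensors:
        key = (assay_id, ligand_id)
        if key not in self._cache:
            obj = self.conformations[key]
            if not isinstance(obj, ComplexTensors):
                obj = complex_tensors(obj, self.model_cfg.encoder)
            self._cache[key] = obj
        return self._cache[key]

    def sample(self, rng: np.random.Generator) -> BioassayPair:
        assay = sample_assay(self.assays, rng)
        pair = sample_pair(assay, rng)
        pair.conformation_a = self._tensors(assay.assay_id, pair.ligand_a)
        pair.conformation_b = self._tensors(assay.assay_id, pair.ligand_b)
        return pair


def filter_contactable(
    assays: list[Bioassay],
    conformations: dict[tuple[str, str], object],
    model_cfg: ModelConfig,
) -> tuple[list[Bioassay], dict[tuple[str, str], ComplexTensors], int]:
    """Drop complexes without any interaction edge (logged, not zero-padded);
    assays shrinking below two ligands are dropped as well."""
    tensors: dict[tuple[str, str], ComplexTensors] = {}
    skipped = 0
    kept_assays = []
    for assay in assays:
        kept_records = []
        for lig, val in assay.records:
            key = (assay.assay_id, lig)
            obj = conformations[key]
            try:
                ct = (
                    obj
                    if isinstance(obj, ComplexTensors)
                    else complex_tensors(obj, model_cfg.encoder)
                )
            except NoContactError:
                skipped += 1
                logger.info("skipping contact-free complex %s/%s", assay.assay_id, lig)
                continue
            tensors[key] = ct
            kept_records.append((lig, val))
        if len(kept_records) >= 2:
            kept_assays.append(
                Bioassay(assay.assay_id, assay.target_id, kept_records, assay.measure_type)
            )
    if skipped:
        logger.warning("excluded %d contact-free complexes", skipped)
    return kept_assays, tensors, skipped


# ---------------------------------------------------------------------------
# Checkpoints
# ---------------------------------------------------------------------------


@dataclass
class Checkpoint:
    state: dict[str, np.ndarray]
    config_hash: str
    epoch: int
    model_cfg: ModelConfig

    def save(self, path: str | Path) -> None:
        meta = {
            "config_hash": self.config_hash,
            "epoch": self.epoch,
            "gnn": vars(self.model_cfg.encoder.gnn),
            "interaction_dim": self.model_cfg.encoder.interaction_dim,
            "lam": self.model_cfg.lam,
            "enabled_tasks": list(self.model_cfg.enabled_tasks),
        }
        np.savez(
            path,
            __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
            **self.state,
        )

    @staticmethod
    def load(path: str | Path, model_cfg: ModelConfig) -> "Checkpoint":
        with np.load(path) as data:
            meta = json.loads(bytes(data["__meta__"]).decode())
            state = {k: data[k] for k in data.files if k != "__meta__"}
        ckpt = Checkpoint(
            state=state,
            config_hash=meta["config_hash"],
            epoch=meta["epoch"],
            model_cfg=model_cfg,
        )
        if model_cfg.config_hash() != meta["config_hash"]:
            raise ValueError(
                "checkpoint/config mismatch: checkpoint was written with hash "
                f"{meta['config_hash']}, current config hashes to {model_cfg.config_hash()}"
            )
        return ckpt


# ---------------------------------------------------------------------------
# Pre-training
# ---------------------------------------------------------------------------


@dataclass
class EpochLog:
    epoch: int
    l_total: float
    l_rank: float
    l_reg: float
    lr: float


def pretrain(
    model: MultiTaskModel,
    pair_stream: PairStream,
    cfg: TrainConfig,
    pairs_per_epoch: int | None = None,
) -> tuple[Checkpoint, list[EpochLog]]:
    """Pre-train the shared encoder and all enabled heads on sampled pairs.

    Returns the best checkpoint (lowest epoch-mean total loss) and the loss
    history.  With ``cfg.max_epochs == 0`` the returned parameters equal the
    initialization.
    """
    assert cfg.phase == "pretrain"
    rng = np.random.default_rng(cfg.seed)
    opt = Adam(model.trainable(), cfg.learning_rate, cfg.weight_decay)
    sched = PlateauSchedule(opt, cfg.lr_decay, cfg.plateau_patience, cfg.min_lr)
    n_pairs = pairs_per_epoch or pair_stream.epoch_size
    history: list[EpochLog] = []
    best_state = model.state_arrays()
    best_loss = np.inf
    for epoch in range(cfg.max_epochs):
        tot = trk = trg = 0.0
        n_done = 0
        while n_done < n_pairs:
            batch = min(cfg.batch_size, n_pairs - n_done)
            model.zero_grad()
            batch_loss = None
            sums = np.zeros(3)
            for _ in range(batch):
                pair = pair_stream.sample(rng)
                lb = pair_loss(model, pair, dropout_rng=rng if cfg.dropout > 0 else None)
                sums += lb.as_floats()
                batch_loss = lb.l_total if batch_loss is None else batch_loss + lb.l_total
            (batch_loss * (1.0 / batch)).backward()
            opt.step()
            trk += sums[0]
            trg += sums[1]
            tot += sums[2]
            n_done += batch
        epoch_loss = tot / n_pairs
        if not np.isfinite(epoch_loss):
            raise FloatingPointError(
                f"non-finite training loss at epoch {epoch}: {epoch_loss}"
            )
        history.append(
            EpochLog(epoch, epoch_loss, trk / n_pairs, trg / n_pairs, opt.lr)
        )
        if epoch_loss < best_loss:
            best_loss = epoch_loss
            best_state = model.state_arrays()
        sched.step(epoch_loss)
    ckpt = Checkpoint(
        state=best_state if cfg.max_epochs > 0 else model.state_arrays(),
        config_hash=model.cfg.config_hash(),
        epoch=len(history),
        model_cfg=model.cfg,
    )
    return ckpt, history


# ---------------------------------------------------------------------------
# Fine-tuning
# ---------------------------------------------------------------------------


@dataclass
class LabelledComplex:
    """A downstream sample: complex tensors, pAff label, measurement family."""

    tensors: ComplexTensors
    paff: float
    task_type: str  # "IC50" or "K"
    complex_id: str = ""


def transfer_from_checkpoint(
    ckpt: Checkpoint, model: MultiTaskModel
) -> MultiTaskModel:
    """Copy encoder and the two regression heads from a pre-training
    checkpoint; ranking heads keep their fresh initialization (they are
    discarded downstream)."""
    if ckpt.config_hash != model.cfg.config_hash():
        raise ValueError("checkpoint/config hash mismatch; refusing to transfer")
    for key, arr in ckpt.state.items():
        if key.startswith("head.") and ".Rank" in key:
            continue
        model.params[key].data = arr.copy()
        model.params[key].grad = None
    return model


def _eval_rmse(model: MultiTaskModel, data: list[LabelledComplex]) -> float:
    errs = [
        (model.predict_affinity(model.encode(s.tensors), s.task_type).item() - s.paff) ** 2
        for s in data
    ]
    return float(np.sqrt(np.mean(errs)))


def finetune(
    model: MultiTaskModel,
    train: list[LabelledComplex],
    val: list[LabelledComplex],
    cfg: TrainConfig,
) -> tuple[MultiTaskModel, list[dict]]:
    """Fine-tune encoder + regression heads on labelled complexes.

    Early stopping monitors validation RMSE; after ``early_stop_patience``
    epochs without improvement the best-epoch parameters are restored.
    """
    assert cfg.phase == "finetune"
    rng = np.random.default_rng(cfg.seed)
    trainable = {
        k: v for k, v in model.trainable().items() if ".Rank" not in k
    }
    opt = Adam(trainable, cfg.learning_rate, cfg.weight_decay)
    sched = PlateauSchedule(opt, cfg.lr_decay, cfg.plateau_patience, cfg.min_lr)
    best_val = np.inf
    best_state = model.state_arrays()
    stale = 0
    history: list[dict] = []
    for epoch in range(cfg.max_epochs):
        order = rng.permutation(len(train))
        total = 0.0
        for start in range(0, len(order), cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            model.zero_grad()
            batch_loss = None
            for i in idx:
                s = train[i]
                o = model.encode(s.tensors, dropout_rng=rng if cfg.dropout > 0 else None)
                loss = regression_loss(model.predict_affinity(o, s.task_type), s.paff)
                batch_loss = loss if batch_loss is None else batch_loss + loss
            (batch_loss * (1.0 / len(idx))).backward()
            opt.step()
            total += batch_loss.item()
        train_loss = total / len(train)
        val_rmse = _eval_rmse(model, val)
        history.append(
            {"epoch": epoch, "train_mse": train_loss, "val_rmse": val_rmse, "lr": opt.lr}
        )
        if val_rmse < best_val:
            best_val = val_rmse
            best_state = model.state_arrays()
            stale = 0
        else:
            stale += 1
            if stale >= cfg.early_stop_patience:
                break
        sched.step(train_loss)
    model.load_state_arrays(best_state)
    return model, history


def predict(model: MultiTaskModel, cs, task_type: str) -> float:
    """Deterministic pAff prediction for one complex (evaluation mode)."""
    o = model.encode(cs)  # no dropout rng: deterministic
    return model.predict_affinity(o, task_type).item()
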