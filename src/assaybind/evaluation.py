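"""Regression metrics and the ablation / transfer-benchmark harness.

Metrics follow the binding-affinity literature: RMSE, MAE, Pearson's R and
SD — the standard deviation of the residuals about the least-squares line
of the true values on the predictions (N-1 denominator), which measures
scatter after an affine recalibration and is therefore invariant to linear
transformations of the predictions.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .bioassay_data import (
    Bioassay,
    apply_chembl_filters,
    group_into_assays,
    map_label_type,
    ranking_label,
    sample_pair,
    to_paffinity,
)
from .multitask_model import TASKS, ModelConfig, MultiTaskModel
from .synthetic_data import SyntheticConfig, make_assay_collection
from .training import (
    LabelledComplex,
    PairStream,
    TrainConfig,
    filter_contactable,
    finetune,
    finetune_config,
    pretrain,
    pretrain_config,
)

logger = logging.getLogger(__name__)


@dataclass
class MetricReport:
    rmse: float
    mae: float
    sd: float
    r: float
    n: int
    extra: dict = field(default_factory=dict)

    def as_dict(self) -> dict:
        return {"rmse": self.rmse, "mae": self.mae, "sd": self.sd, "r": self.r, "n": self.n}


def compute_metrics(y: np.ndarray, y_hat: np.ndarray) -> MetricReport:
    """RMSE, MAE, Pearson R and residual SD about the y-on-y_hat line.

    With zero-variance predictions R and SD are undefined and reported as
    NaN with a warning.
    """
    y = np.asarray(y, dtype=float)
    y_hat = np.asarray(y_hat, dtype=float)
    if y.shape != y_hat.shape or y.ndim != 1 or y.size < 2:
        raise ValueError("y and y_hat must be equal-length vectors of length >= 2")
    if not (np.all(np.isfinite(y)) and np.all(np.isfinite(y_hat))):
        raise ValueError("metrics need finite inputs")
    rmse = float(np.sqrt(np.mean((y - y_hat) ** 2)))
    mae = float(np.mean(np.abs(y - y_hat)))
    if np.ptp(y_hat) == 0.0 or np.ptp(y) == 0.0:
        warnings.warn("zero-variance input: R and SD undefined", RuntimeWarning)
        return MetricReport(rmse=rmse, mae=mae, sd=float("nan"), r=float("nan"), n=y.size)
    r = float(np.corrcoef(y, y_hat)[0, 1])
    slope, icept = np.polyfit(y_hat, y, 1)
    resid = y - (slope * y_hat + icept)
    sd = float(np.sqrt(np.sum(resid**2) / (y.size - 1)))
    return MetricReport(rmse=rmse, mae=mae, sd=sd, r=r, n=y.size)


def summarize_reports(reports: list[MetricReport]) -> dict:
    """Mean (std) over repeated runs, the reporting convention for seeds."""
    out = {}
    for key in ("rmse", "mae", "sd", "r"):
        vals = np.array([getattr(rep, key) for rep in reports])
        out[key] = float(vals.mean())
        out[f"{key}_std"] = float(vals.std(ddof=1)) if len(vals) > 1 else 0.0
    out["n_runs"] = len(reports)
    return out


# ---------------------------------------------------------------------------
# Synthetic benchmark assembly
# ---------------------------------------------------------------------------


@dataclass
class SyntheticBenchmark:
    """A curated synthetic collection split into pre-training and held-out
    assays, with complex tensors pre-built."""

    train_stream: PairStream
    heldout_assays: list[Bioassay]
    heldout_tensors: dict
    n_skipped: int


def build_benchmark(
    syn_cfg: SyntheticConfig,
    model_cfg: ModelConfig,
    seed: int,
    heldout_fraction: float = 0.25,
) -> SyntheticBenchmark:
    """Generate, curate and split a synthetic collection (by whole assays)."""
    rng = np.random.default_rng(seed)
    records, complexes, _ = make_assay_collection(replace(syn_cfg, seed=seed), rng)
    survivors, report = apply_chembl_filters(records)
    assays = group_into_assays(survivors, report)
    assays, tensors, skipped = filter_contactable(
        assays, {k: v for k, v in complexes.items()}, model_cfg
    )
    n_held = max(1, int(round(heldout_fraction * len(assays))))
    order = rng.permutation(len(assays))
    held_idx = set(order[:n_held].tolist())
    held = [a for i, a in enumerate(assays) if i in held_idx]
    train = [a for i, a in enumerate(assays) if i not in held_idx]
    train_keys = {(a.assay_id, lig) for a in train for lig, _ in a.records}
    stream = PairStream(
        assays=train,
        conformations={k: v for k, v in tensors.items() if k in train_keys},
        model_cfg=model_cfg,
    )
    held_tensors = {
        (a.assay_id, lig): tensors[(a.assay_id, lig)] for a in held for lig, _ in a.records
    }
    return SyntheticBenchmark(
        train_stream=stream,
        heldout_assays=held,
        heldout_tensors=held_tensors,
        n_skipped=skipped,
    )


def ranking_accuracy(
    model: MultiTaskModel,
    assays: list[Bioassay],
    tensors: dict,
    rng: np.random.Generator,
    n_pairs: int = 200,
) -> float:
    """Within-assay pair-ranking accuracy of the matching ranking head."""
    embeddings: dict = {}

    def embed(assay_id, ligand_id):
        key = (assay_id, ligand_id)
        if key not in embeddings:
            embeddings[key] = model.encode(tensors[key])
        return embeddings[key]

    correct = 0
    sized = [a for a in assays if a.size >= 2]
    for _ in range(n_pairs):
        assay = sized[rng.integers(len(sized))]
        pair = sample_pair(assay, rng)
        o1 = embed(assay.assay_id, pair.ligand_a)
        o2 = embed(assay.assay_id, pair.ligand_b)
        p = model.predict_rank(o1, o2, map_label_type(pair.measure_type)).item()
        correct += int((p > 0.5) == bool(ranking_label(pair)))
    return correct / n_pairs


def make_labelled_complexes(
    syn_cfg: SyntheticConfig,
    model_cfg: ModelConfig,
    n: int,
    seed: int,
) -> list[LabelledComplex]:
    """Downstream-style labelled complexes: clean labels (no assay offset or
    type shift), measured pAff as target."""
    cfg = replace(
        syn_cfg,
        n_assays=max(1, n // max(syn_cfg.assay_size_range[0], 2)),
        assay_offset_sd=0.0,
        type_shift=0.0,
        seed=seed,
    )
    rng = np.random.default_rng(seed)
    records, complexes, _ = make_assay_collection(cfg, rng)
    assays = group_into_assays(records)
    assays, tensors, _ = filter_contactable(assays, complexes, model_cfg)
    out: list[LabelledComplex] = []
    for assay in assays:
        for lig, val in assay.records:
            out.append(
                LabelledComplex(
                    tensors=tensors[(assay.assay_id, lig)],
                    paff=to_paffinity(val),
                    task_type=map_label_type(assay.measure_type),
                    complex_id=f"{assay.assay_id}/{lig}",
                )
            )
            if len(out) == n:
                return out
    return out


# ---------------------------------------------------------------------------
# Transfer benchmark (pretrain vs from-scratch fine-tuning)
# ---------------------------------------------------------------------------


@dataclass
class TransferResult:
    seed: int
    ranking_accuracy: float
    rmse_pretrained: float
    rmse_scratch: float
    report_pretrained: MetricReport
    report_scratch: MetricReport


def pretrain_transfer_benchmark(
    seeds: list[int],
    syn_cfg: SyntheticConfig | None = None,
    model_cfg: ModelConfig | None = None,
    pre_cfg: TrainConfig | None = None,
    ft_cfg: TrainConfig | None = None,
    n_train: int = 60,
    n_val: int = 20,
    n_test: int = 20,
    pairs_per_epoch: int | None = None,
) -> list[TransferResult]:
    """Paired comparison of fine-tuning from a pre-trained encoder versus an
    identically initialized encoder trained from scratch, over seeds.

    Both arms share the model initialization, the downstream data and the
    fine-tuning schedule; only the starting encoder differs.
    """
    syn_cfg = syn_cfg or SyntheticConfig()
    model_cfg = model_cfg or ModelConfig()
    results: list[TransferResult] = []
    for seed in seeds:
        pre = pre_cfg or pretrain_config(max_epochs=25, batch_size=32, seed=seed)
        ft = ft_cfg or finetune_config(max_epochs=120, batch_size=32, seed=seed)
        bench = build_benchmark(syn_cfg, model_cfg, seed)
        model = MultiTaskModel(model_cfg, rng=seed)
        init_state = model.state_arrays()
        ckpt, _ = pretrain(model, bench.train_stream, pre, pairs_per_epoch)
        model.load_state_arrays(ckpt.state)
        acc = ranking_accuracy(
            model,
            bench.heldout_assays,
            bench.heldout_tensors,
            np.random.default_rng(seed + 10_000),
        )
        data = make_labelled_complexes(
            syn_cfg, model_cfg, n_train + n_val + n_test, seed + 20_000
        )
        train, val, test = (
            data[:n_train],
            data[n_train : n_train + n_val],
            data[n_train + n_val :],
        )

        def run_arm(start_state):
            arm = MultiTaskModel(model_cfg, rng=seed)
            arm.load_state_arrays(start_state)
            arm, _ = finetune(arm, train, val, ft)
            y = np.array([s.paff for s in test])
            y_hat = np.array(
                [
                    arm.predict_affinity(arm.encode(s.tensors), s.task_type).item()
                    for s in test
                ]
            )
            return compute_metrics(y, y_hat)

        rep_pre = run_arm(ckpt.state)
        rep_scratch = run_arm(init_state)
        results.append(
            TransferResult(
                seed=seed,
                ranking_accuracy=acc,
                rmse_pretrained=rep_pre.rmse,
                rmse_scratch=rep_scratch.rmse,
                report_pretrained=rep_pre,
                report_scratch=rep_scratch,
            )
        )
        logger.info(
            "seed %d: ranking acc %.3f, RMSE pretrained %.3f vs scratch %.3f",
            seed, acc, rep_pre.rmse, rep_scratch.rmse,
        )
    return results


# ---------------------------------------------------------------------------
# Ablation runners
# ---------------------------------------------------------------------------


def run_lambda_ablation(
    lam_grid: list[float],
    seeds: list[int],
    syn_cfg: SyntheticConfig | None = None,
    model_cfg: ModelConfig | None = None,
    pre_cfg: TrainConfig | None = None,
    pairs_per_epoch: int | None = None,
) -> pd.DataFrame:
    """Pre-train once per (lambda, seed) and report final losses plus
    held-out ranking accuracy; one row per run."""
    if not lam_grid:
        raise ValueError("lambda grid must be non-empty")
    syn_cfg = syn_cfg or SyntheticConfig()
    base_cfg = model_cfg or ModelConfig()
    rows = []
    for lam in lam_grid:
        cfg = replace(base_cfg, lam=lam)
        for seed in seeds:
            pre = pre_cfg or pretrain_config(max_epochs=10, batch_size=32, seed=seed)
            bench = build_benchmark(syn_cfg, cfg, seed)
            model = MultiTaskModel(cfg, rng=seed)
            ckpt, history = pretrain(model, bench.train_stream, pre, pairs_per_epoch)
            model.load_state_arrays(ckpt.state)
            acc = ranking_accuracy(
                model,
                bench.heldout_assays,
                bench.heldout_tensors,
                np.random.default_rng(seed + 10_000),
            )
            rows.append(
                {
                    "lambda": lam,
                    "seed": seed,
                    "final_l_total": history[-1].l_total,
                    "final_l_rank": history[-1].l_rank,
                    "final_l_reg": history[-1].l_reg,
                    "ranking_accuracy": acc,
                }
            )
    return pd.DataFrame(rows)


def run_task_ablation(
    task_subsets: list[tuple[str, ...]],
    seeds: list[int],
    syn_cfg: SyntheticConfig | None = None,
    model_cfg: ModelConfig | None = None,
    pre_cfg: TrainConfig | None = None,
    ft_cfg: TrainConfig | None = None,
    pairs_per_epoch: int | None = None,
) -> pd.DataFrame:
    """Pre-train with each task subset enabled, then fine-tune and report
    downstream test metrics; one row per (subset, seed)."""
    syn_cfg = syn_cfg or SyntheticConfig()
    base_cfg = model_cfg or ModelConfig()
    rows = []
    for subset in task_subsets:
        bad = set(subset) - set(TASKS)
        if bad:
            raise ValueError(f"unknown tasks {sorted(bad)}")
        cfg = replace(base_cfg, enabled_tasks=tuple(subset))
        results = pretrain_transfer_benchmark(
            list(seeds),
            syn_cfg=syn_cfg,
            model_cfg=cfg,
            pre_cfg=pre_cfg,
            ft_cfg=ft_cfg,
            pairs_per_epoch=pairs_per_epoch,
        )
        for res in results:
            rows.append(
                {
                    "tasks": "+".join(subset),
                    "seed": res.seed,
                    "ranking_accuracy": res.ranking_accuracy,
                    "rmse": res.rmse_pretrained,
                    "mae": res.report_pretrained.mae,
                    "sd": res.report_pretrained.sd,
                    "r": res.report_pretrained.r,
                }
            )
    return pd.DataFrame(rows)
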