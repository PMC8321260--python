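"""The three training pipelines, evaluation, and the freezing-depth ablation.

Pipeline I trains the U-Net directly on the target training set from random
initialization (standard supervised training, SST).  Pipeline II first
pre-trains on one or more source tissue classes and then fine-tunes on the
target.  Pipeline III meta-learns the initialization on the source classes
(interpolation method, MAML or Reptile) before the transfer.  The transfer
step itself is either SST or the staged layer-freezing plan.

Every run derives all of its randomness from ``(seed, run_index)`` through
independent named streams (data, init, meta, fine-tune), so arms that share
a seed see identical data and initializations and repeated runs are
bit-identical.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .meta_optim import MetaConfig, TaskPool, meta_train
from .metrics import ClassWeights, MetricsRecord, one_hot, precision_recall, weighted_dice
from .segmodel import (
    SegmentationObjective,
    UNet,
    UNetSpec,
    calibrate_bn_stats,
    fine_tune_layer_freezing,
    make_freeze_plan,
    train_supervised,
)
from .synthetic_tasks import augment, generate_pool, held_out_target, three_tissue_sources

__all__ = [
    "ExperimentConfig",
    "evaluate_model",
    "pipeline_I_sst",
    "pipeline_II_pretrain",
    "pipeline_III_meta",
    "run_pipeline",
    "ablate_freeze_depth",
    "run_transfer_benchmark",
]


@dataclass(frozen=True)
class ExperimentConfig:
    """Full description of one experiment (all arms derive from it)."""

    pipeline: str = "I"  # I | II | III
    method: str = "sst"  # sst | pretrain | ours | maml | reptile
    transfer: str = "sst"  # sst | layer_freezing
    freeze_depth: int = 2
    meta: MetaConfig = field(default_factory=MetaConfig)
    model: UNetSpec = field(default_factory=UNetSpec.tiny)
    n_runs: int = 5
    seed: int = 0
    epochs: int = 30  # total supervised epochs on the target set
    batch_size_supervised: int = 8
    meta_iterations: int = 200
    pretrain_epochs: int = 20
    image_size: int = 32
    n_source_per_class: int = 40
    n_target_train: int = 30
    n_target_test: int = 40
    use_augmentation: bool = True
    source_specs: tuple = field(default_factory=lambda: tuple(three_tissue_sources()))
    target_spec: object = field(default_factory=held_out_target)

    def __post_init__(self):
        if self.pipeline not in ("I", "II", "III"):
            raise ValueError(f"unknown pipeline {self.pipeline!r}")
        if self.pipeline == "III" and self.method not in ("ours", "maml", "reptile"):
            raise ValueError("pipeline III requires a meta method")
        if self.n_runs < 1:
            raise ValueError("n_runs must be >= 1")
        if self.transfer not in ("sst", "layer_freezing"):
            raise ValueError(f"unknown transfer {self.transfer!r}")


def _run_streams(seed: int, run: int) -> dict:
    """Independent named RNG streams for one run."""
    ss = np.random.SeedSequence([int(seed), int(run)])
    children = ss.spawn(5)
    names = ("source_data", "target_data", "init", "meta", "finetune")
    return {n: np.random.default_rng(c) for n, c in zip(names, children)}


def _pools(cfg: ExperimentConfig, streams: dict):
    source = generate_pool(
        cfg.source_specs, cfg.n_source_per_class, streams["source_data"], size=cfg.image_size
    )
    tr = streams["target_data"]
    target_train = [
        # target pool: a single held-out class
        ex
        for ex in generate_pool([cfg.target_spec], cfg.n_target_train, tr, size=cfg.image_size).examples
    ]
    target_test = generate_pool([cfg.target_spec], cfg.n_target_test, tr, size=cfg.image_size)
    return source, target_train, target_test


def evaluate_model(model: UNet, test_pool: TaskPool, w: ClassWeights | None = None) -> MetricsRecord:
    """Mean weighted DSC / precision / recall over a test pool.

    Predictions are binarized by per-pixel argmax before all three metrics,
    the reporting convention for hard segmentation tables.
    """
    if len(test_pool) == 0:
        raise ValueError("empty test pool")
    w = w or ClassWeights.binary()
    k = model.spec.n_classes
    dscs, precs, recs = [], [], []
    exs = test_pool.examples
    for start in range(0, len(exs), 16):
        chunk = exs[start : start + 16]
        x = np.stack([ex.image for ex in chunk])
        probs = model.predict(x)
        hard = probs.argmax(axis=1)
        for ex, h in zip(chunk, hard):
            gt = one_hot(ex.mask, k)
            dscs.append(weighted_dice(one_hot(h, k), gt, w))
            p, r = precision_recall(h, ex.mask)
            precs.append(p)
            recs.append(r)
    def _nanmean(vals):
        arr = np.asarray(vals, dtype=np.float64)
        ok = ~np.isnan(arr)
        return float(arr[ok].mean()) if ok.any() else float("nan")

    return MetricsRecord(
        dsc=float(np.mean(dscs)), precision=_nanmean(precs), recall=_nanmean(recs)
    )


def _transfer_and_eval(model: UNet, cfg: ExperimentConfig, target_train, target_test, rng) -> MetricsRecord:
    aug = augment if cfg.use_augmentation else None
    if cfg.transfer == "layer_freezing":
        per_stage = max(1, cfg.epochs // (cfg.freeze_depth + 1))
        plan = make_freeze_plan(
            cfg.freeze_depth, n_epochs_per_stage=per_stage,
            n_down_blocks=cfg.model.n_down_blocks,
        )
        fine_tune_layer_freezing(
            model, plan, target_train, rng,
            batch_size=cfg.batch_size_supervised, augment_fn=aug,
        )
    else:
        train_supervised(
            model, target_train, n_epochs=cfg.epochs, lr=1e-3, rng=rng,
            batch_size=cfg.batch_size_supervised, augment_fn=aug,
        )
    return evaluate_model(model, target_test)


def pipeline_I_sst(cfg: ExperimentConfig) -> list:
    """Random initialization, supervised training on the target set only."""
    records = []
    sst_cfg = replace(cfg, transfer="sst")
    for run in range(cfg.n_runs):
        streams = _run_streams(cfg.seed, run)
        _, target_train, target_test = _pools(cfg, streams)
        model = UNet(cfg.model, streams["init"])
        records.append(
            _transfer_and_eval(model, sst_cfg, target_train, target_test, streams["finetune"])
        )
    return records


def pipeline_II_pretrain(cfg: ExperimentConfig) -> list:
    """Supervised pre-training on the source pool, then target transfer."""
    records = []
    aug = augment if cfg.use_augmentation else None
    for run in range(cfg.n_runs):
        streams = _run_streams(cfg.seed, run)
        source, target_train, target_test = _pools(cfg, streams)
        model = UNet(cfg.model, streams["init"])
        if cfg.pretrain_epochs > 0:
            train_supervised(
                model, source.examples, n_epochs=cfg.pretrain_epochs, lr=1e-3,
                rng=streams["meta"], batch_size=cfg.batch_size_supervised, augment_fn=aug,
            )
        records.append(_transfer_and_eval(model, cfg, target_train, target_test, streams["finetune"]))
    return records


def pipeline_III_meta(cfg: ExperimentConfig) -> list:
    """Meta-learned initialization on source classes, then target transfer."""
    records = []
    for run in range(cfg.n_runs):
        streams = _run_streams(cfg.seed, run)
        source, target_train, target_test = _pools(cfg, streams)
        model = UNet(cfg.model, streams["init"])
        objective = SegmentationObjective(model)
        theta0 = model.get_flat()
        theta, _ = meta_train(
            theta0, source, cfg.method, cfg.meta, cfg.meta_iterations,
            streams["meta"], objective,
        )
        model.set_flat(theta)
        # meta-training never advances BN running statistics; re-estimate
        # them on the source pool before frozen-BN transfer
        calibrate_bn_stats(model, source.examples, streams["meta"])
        records.append(_transfer_and_eval(model, cfg, target_train, target_test, streams["finetune"]))
    return records


def run_pipeline(cfg: ExperimentConfig) -> list:
    """Dispatch on cfg.pipeline."""
    if cfg.pipeline == "I":
        return pipeline_I_sst(cfg)
    if cfg.pipeline == "II":
        return pipeline_II_pretrain(cfg)
    return pipeline_III_meta(cfg)


def ablate_freeze_depth(cfg: ExperimentConfig, depths) -> list:
    """Pipeline III at several initial freezing depths, matched seeds.

    Returns rows of (depth, mean_dsc, ci95_halfwidth) over cfg.n_runs runs.
    """
    from .metrics import run_statistics

    rows = []
    for depth in depths:
        dcfg = replace(cfg, pipeline="III", transfer="layer_freezing", freeze_depth=int(depth))
        recs = pipeline_III_meta(dcfg)
        dscs = [r.dsc for r in recs]
        if len(dscs) >= 2:
            mean, ci = run_statistics(dscs)
        else:
            mean, ci = float(dscs[0]), float("nan")
        rows.append({"depth": int(depth), "mean_dsc": mean, "ci95": ci})
    return rows


def run_transfer_benchmark(
    seed: int,
    n_runs: int = 5,
    meta_methods: tuple = ("ours", "maml", "reptile"),
    include_pretrain: bool = False,
    base_cfg: ExperimentConfig | None = None,
) -> dict:
    """The scaled-down synthetic transfer benchmark.

    Three source tissue classes, one held-out target class; each meta arm
    learns an initialization and transfers with the depth-2 layer-freezing
    plan; the baseline arm trains from random initialization.  All arms
    share per-run data and initializations through matched seed streams.
    Returns per-arm DSC lists plus full metric records.
    """
    cfg = base_cfg or ExperimentConfig(seed=seed, n_runs=n_runs)
    cfg = replace(cfg, seed=seed, n_runs=n_runs)
    out: dict = {"records": {}, "dsc": {}}

    arms: dict = {"sst": replace(cfg, pipeline="I", method="sst", transfer="sst")}
    if include_pretrain:
        arms["pretrain_multisource"] = replace(
            cfg, pipeline="II", method="pretrain", transfer="layer_freezing"
        )
    for m in meta_methods:
        arms[m] = replace(cfg, pipeline="III", method=m, transfer="layer_freezing")

    for name, acfg in arms.items():
        recs = run_pipeline(acfg)
        out["records"][name] = [r.as_dict() for r in recs]
        out["dsc"][name] = [r.dsc for r in recs]
    return out


_ARM_PIPELINE = {
    "sst": "I",
    "pretrain_multisource": "II",
    "ours": "III",
    "maml": "III",
    "reptile": "III",
}


def metrics_table(benchmark_out: dict) -> list:
    """Flatten benchmark output to rows: run_id, pipeline, method, metrics."""
    rows = []
    for method, recs in benchmark_out["records"].items():
        for run_id, rec in enumerate(recs):
            rows.append(
                {"run_id": run_id, "pipeline": _ARM_PIPELINE.get(method, "?"),
                 "method": method, **rec}
            )
    return rows
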