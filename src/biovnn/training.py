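"""Optimization schedule: Kaiming-initialized models trained by mini-batch
(default 2000) with a Rectified-Adam + Lookahead optimizer at learning rate
1e-3, early-stopped when the validation objective has not improved for two
consecutive epochs, with the best-validation checkpoint restored.

Training samples are all (training cell line, target gene) pairs; expression
is z-scored per fold with training-set statistics only.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .baselines import build_matched_fcn, randomize_hierarchy
from .data import (CohortDataset, FeatureMask, FoldSplit, apply_zscore,
                   assemble_batch, build_feature_masks, stratified_folds,
                   training_statistics)
from .errors import ConfigurationError
from .evaluation import EvaluationReport
from .model import compile_model
from .network import SparseNet
from .ontology import PathwayHierarchy

MODEL_KINDS = ("biovnn", "fcn", "random")


@dataclass
class TrainingConfig:
    batch_size: int = 2000
    learning_rate: float = 1e-3
    patience: int = 2
    max_epochs: int = 200
    optimizer: str = "ranger"          # RAdam + Lookahead; "adam" also supported
    seed: int = 0
    alpha: float = 0.3
    lam: float = 1.0
    dropout_p: float = 0.5
    mask_cap: int = 100
    n_folds: int = 5
    bn_max_samples: int = 20000
    lookahead_k: int = 6
    lookahead_alpha: float = 0.5

    def __post_init__(self) -> None:
        if self.patience < 1:
            raise ConfigurationError("patience must be >= 1")
        if self.batch_size < 1:
            raise ConfigurationError("batch size must be >= 1")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "TrainingConfig":
        import yaml
        with open(path) as fh:
            return cls(**(yaml.safe_load(fh) or {}))


@dataclass
class TrainingTrace:
    train_losses: list[float] = field(default_factory=list)
    val_losses: list[float] = field(default_factory=list)
    stopping_epoch: int = 0
    best_epoch: int = 0
    wall_time: float = 0.0
    checkpoint_path: str | None = None

    @property
    def best_val_loss(self) -> float:
        return min(self.val_losses)

    def to_jsonl(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for e, (tr, va) in enumerate(zip(self.train_losses, self.val_losses), 1):
                fh.write(json.dumps({"epoch": e, "train_loss": tr,
                                     "val_loss": va}) + "\n")


# ---------------------------------------------------------------------------
# optimizers (operate on dicts of arrays)


class Adam:
    def __init__(self, params: Mapping[str, np.ndarray], lr: float,
                 betas=(0.9, 0.999), eps: float = 1e-8):
        self.lr, (self.b1, self.b2), self.eps = lr, betas, eps
        self.t = 0
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}

    def step(self, params, grads) -> None:
        self.t += 1
        b1t, b2t = self.b1 ** self.t, self.b2 ** self.t
        for k in params:
            g = grads[k]
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            mhat = self.m[k] / (1 - b1t)
            vhat = self.v[k] / (1 - b2t)
            params[k] -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


class RAdam(Adam):
    """Rectified Adam: warms up the adaptive term by the variance-rectification
    factor, falling back to un-adapted momentum updates early on."""

    def step(self, params, grads) -> None:
        self.t += 1
        b1t, b2t = self.b1 ** self.t, self.b2 ** self.t
        rho_inf = 2.0 / (1.0 - self.b2) - 1.0
        rho_t = rho_inf - 2.0 * self.t * b2t / (1.0 - b2t)
        if rho_t > 4.0:
            r = np.sqrt(((rho_t - 4) * (rho_t - 2) * rho_inf)
                        / ((rho_inf - 4) * (rho_inf - 2) * rho_t))
        else:
            r = None
        for k in params:
            g = grads[k]
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            mhat = self.m[k] / (1 - b1t)
            if r is not None:
                vhat = np.sqrt(self.v[k] / (1 - b2t))
                params[k] -= self.lr * r * mhat / (vhat + self.eps)
            else:
                params[k] -= self.lr * mhat


class Lookahead:
    """Keeps slow weights; every k steps interpolates them toward the fast
    weights and resets the fast weights."""

    def __init__(self, inner, params, k: int = 6, alpha: float = 0.5):
        self.inner, self.k, self.alpha = inner, k, alpha
        self.step_count = 0
        self.slow = {key: v.copy() for key, v in params.items()}

    def step(self, params, grads) -> None:
        self.inner.step(params, grads)
        self.step_count += 1
        if self.step_count % self.k == 0:
            for key in params:
                self.slow[key] += self.alpha * (params[key] - self.slow[key])
                params[key] = self.slow[key].copy()


def make_optimizer(config: TrainingConfig, params) -> object:
    if config.optimizer == "ranger":
        return Lookahead(RAdam(params, config.learning_rate), params,
                         k=config.lookahead_k, alpha=config.lookahead_alpha)
    if config.optimizer == "radam":
        return RAdam(params, config.learning_rate)
    if config.optimizer == "adam":
        return Adam(params, config.learning_rate)
    raise ConfigurationError(f"unknown optimizer {config.optimizer!r}")


# ---------------------------------------------------------------------------
# single-fold training


def _pair_indices(line_ids: Sequence[str], dataset: CohortDataset
                  ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """All (cell line, target) pairs for the given lines, with labels."""
    positions = np.array([dataset.cell_lines.index(cl) for cl in line_ids])
    n = len(dataset.target_genes)
    li = np.repeat(positions, n)
    tj = np.tile(np.arange(n), len(positions))
    y = dataset.labels.to_numpy()[li, tj].astype(np.float64)
    return li, tj, y


def train(model: SparseNet,
          dataset: CohortDataset,
          fold: dict[str, list[str]],
          masks: FeatureMask,
          config: TrainingConfig | None = None) -> TrainingTrace:
    """Train one model on one fold's training lines, early-stopping on the
    validation objective (root + auxiliary cross-entropy, no regularizer)."""
    config = config or TrainingConfig()
    if set(fold["train"]) & set(fold["validation"]):
        raise ConfigurationError("train and validation cell lines overlap")
    t0 = time.time()
    rng = np.random.default_rng(config.seed)

    stats = training_statistics(dataset.expression, fold["train"])
    z = apply_zscore(dataset.expression, stats).to_numpy()
    n_targets = len(dataset.target_genes)

    tr_li, tr_tj, tr_y = _pair_indices(fold["train"], dataset)
    va_li, va_tj, va_y = _pair_indices(fold["validation"], dataset)
    n_pos, n_neg = tr_y.sum(), (1 - tr_y).sum()
    model.neg_weight = float(n_pos / n_neg) if n_neg > 0 else 1.0

    X_val = assemble_batch(z, va_li, va_tj, masks, n_targets)
    sub = rng.permutation(len(tr_li))[:config.bn_max_samples]
    X_bn = assemble_batch(z, tr_li[sub], tr_tj[sub], masks, n_targets)

    opt = make_optimizer(config, model.params)
    trace = TrainingTrace()
    best_state, best_val, since_best = None, np.inf, 0

    for epoch in range(1, config.max_epochs + 1):
        order = rng.permutation(len(tr_li))
        epoch_losses = []
        for start in range(0, len(order), config.batch_size):
            idx = order[start:start + config.batch_size]
            if len(idx) < 2:
                continue  # batch statistics need >= 2 samples
            X = assemble_batch(z, tr_li[idx], tr_tj[idx], masks, n_targets)
            drop = model.make_dropout_masks(len(idx), rng)
            loss, grads = model.loss_and_grad_manual(X, tr_y[idx], drop)
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"non-finite loss at epoch {epoch}, batch starting {start} "
                    f"(batch size {len(idx)})")
            opt.step(model.params, grads)
            epoch_losses.append(float(loss))
        model.update_bn_stats(X_bn)
        val_loss = model.loss(X_val, va_y, include_reg=False)
        trace.train_losses.append(float(np.mean(epoch_losses)))
        trace.val_losses.append(float(val_loss))

        if val_loss < best_val:
            best_val, best_state, since_best = val_loss, model.state_copy(), 0
            trace.best_epoch = epoch
        else:
            since_best += 1
            if since_best >= config.patience:
                break
    trace.stopping_epoch = epoch
    if best_state is not None:
        model.load_state(best_state)
    trace.wall_time = time.time() - t0
    return trace


# ---------------------------------------------------------------------------
# cross-validation driver


@dataclass
class FoldResult:
    fold: int
    net: SparseNet
    zscore_stats: tuple[np.ndarray, np.ndarray]
    trace: TrainingTrace
    predictions: pd.DataFrame


@dataclass
class CrossValidationResult:
    model_kind: str
    folds: list[FoldResult]
    masks: FeatureMask
    hierarchy: PathwayHierarchy
    split: FoldSplit

    @property
    def predictions(self) -> pd.DataFrame:
        return pd.concat([f.predictions for f in self.folds], ignore_index=True)

    @property
    def epochs_to_converge(self) -> list[int]:
        return [f.trace.stopping_epoch for f in self.folds]

    def fold_models(self) -> list[tuple[SparseNet, tuple]]:
        return [(f.net, f.zscore_stats) for f in self.folds]

    def report(self) -> EvaluationReport:
        return EvaluationReport.from_predictions(
            self.predictions,
            parameter_count=self.folds[0].net.count_parameters(),
            epochs_to_converge=self.epochs_to_converge,
        )


def build_model(model_kind: str,
                hierarchy: PathwayHierarchy,
                dataset: CohortDataset,
                config: TrainingConfig,
                seed: int) -> tuple[SparseNet, PathwayHierarchy]:
    """Compile the requested architecture; returns (net, mask hierarchy)."""
    if model_kind == "biovnn":
        net = compile_model(hierarchy, dataset.feature_genes,
                            dataset.target_genes, seed=seed,
                            alpha=config.alpha, lam=config.lam,
                            dropout_p=config.dropout_p)
        return net, hierarchy
    if model_kind == "fcn":
        net = build_matched_fcn(hierarchy, dataset.feature_genes,
                                dataset.target_genes, seed=seed,
                                alpha=config.alpha, lam=config.lam,
                                dropout_p=config.dropout_p)
        return net, hierarchy
    if model_kind == "random":
        randomized = randomize_hierarchy(
            hierarchy, 1.0, seed,
            feature_genes=dataset.feature_genes,
            target_genes=dataset.target_genes).hierarchy
        net = compile_model(randomized, dataset.feature_genes,
                            dataset.target_genes, seed=seed,
                            alpha=config.alpha, lam=config.lam,
                            dropout_p=config.dropout_p)
        return net, randomized
    raise ConfigurationError(f"unknown model kind {model_kind!r} "
                             f"(expected one of {MODEL_KINDS})")


def run_cross_validation(model_kind: str,
                         dataset: CohortDataset,
                         hierarchy: PathwayHierarchy,
                         config: TrainingConfig | None = None,
                         randomize_fraction: float | None = None
                         ) -> CrossValidationResult:
    """Five-fold cross-validation of one model kind; pooled test predictions
    cover every cell line exactly once."""
    if model_kind not in MODEL_KINDS:
        raise ConfigurationError(f"unknown model kind {model_kind!r} "
                                 f"(expected one of {MODEL_KINDS})")
    config = config or TrainingConfig()
    split = stratified_folds(dataset, n_folds=config.n_folds, seed=config.seed)

    if randomize_fraction is not None and model_kind == "biovnn":
        arch_hierarchy = randomize_hierarchy(
            hierarchy, randomize_fraction, config.seed,
            feature_genes=dataset.feature_genes,
            target_genes=dataset.target_genes).hierarchy
        model_kind_inner = "biovnn"
    else:
        arch_hierarchy = hierarchy
        model_kind_inner = model_kind

    fold_results = []
    for f, fold in enumerate(split):
        fr, masks = _train_fold(model_kind_inner, arch_hierarchy, hierarchy,
                                dataset, config, fold, f, randomize_fraction)
        fold_results.append(fr)
    return CrossValidationResult(model_kind=model_kind, folds=fold_results,
                                 masks=masks, hierarchy=arch_hierarchy,
                                 split=split)


def _train_fold(model_kind_inner: str,
                arch_hierarchy: PathwayHierarchy,
                hierarchy: PathwayHierarchy,
                dataset: CohortDataset,
                config: TrainingConfig,
                fold: dict[str, list[str]],
                f: int,
                randomize_fraction: float | None
                ) -> tuple[FoldResult, FeatureMask]:
    try:
        net, mask_hierarchy = build_model(
            model_kind_inner,
            arch_hierarchy if model_kind_inner != "random" else hierarchy,
            dataset, config, seed=config.seed * 1000 + f)
        masks = build_feature_masks(
            dataset.target_genes, mask_hierarchy, dataset.feature_genes,
            cap=config.mask_cap,
            allow_unmapped=(model_kind_inner == "random"
                            or randomize_fraction is not None))
        trace = train(net, dataset, fold, masks, config)

        stats = training_statistics(dataset.expression, fold["train"])
        z = apply_zscore(dataset.expression, stats).to_numpy()
        li, tj, y = _pair_indices(fold["test"], dataset)
        X = assemble_batch(z, li, tj, masks, len(dataset.target_genes))
        scores = net.predict(X)
    except Exception as exc:
        raise RuntimeError(f"fold {f} failed: {exc}") from exc
    return FoldResult(
        fold=f, net=net, zscore_stats=stats, trace=trace,
        predictions=pd.DataFrame({
            "cell_line": [dataset.cell_lines[i] for i in li],
            "target_gene": [dataset.target_genes[j] for j in tj],
            "score": scores,
            "label": y.astype(int),
            "fold": f,
        }),
    ), masks


def run_single_fold(model_kind: str,
                    dataset: CohortDataset,
                    hierarchy: PathwayHierarchy,
                    config: TrainingConfig | None = None,
                    fold_index: int = 0,
                    randomize_fraction: float | None = None
                    ) -> CrossValidationResult:
    """Train and test one fold of the 5-fold split only.

    This is the unit of the desk-scale experiments: where a claim is a
    comparison between models repeated over seeds, one fold per seed gives
    independent replicates at a fifth of the cost of full cross-validation.
    The returned result has a single entry in ``folds``."""
    config = config or TrainingConfig()
    split = stratified_folds(dataset, n_folds=config.n_folds, seed=config.seed)

    if randomize_fraction is not None and model_kind == "biovnn":
        arch_hierarchy = randomize_hierarchy(
            hierarchy, randomize_fraction, config.seed,
            feature_genes=dataset.feature_genes,
            target_genes=dataset.target_genes).hierarchy
    else:
        arch_hierarchy = hierarchy

    fold = split.assignments[fold_index]
    fr, masks = _train_fold(model_kind, arch_hierarchy, hierarchy, dataset,
                            config, fold, fold_index, randomize_fraction)
    return CrossValidationResult(model_kind=model_kind, folds=[fr],
                                 masks=masks, hierarchy=arch_hierarchy,
                                 split=split)


def randomization_decay(dataset: CohortDataset,
                        hierarchy: PathwayHierarchy,
                        fractions: Sequence[float] = (0.0, 0.25, 0.5, 0.75, 1.0),
                        config: TrainingConfig | None = None,
                        fold_index: int = 0) -> pd.DataFrame:
    """Performance decay under partial hierarchy randomization.

    Re-trains the model on one fold per fraction p of randomized gene
    memberships and reports test AUROC/AUPRC, the desk-scale analogue of the
    gradual-randomization experiment.  Architecture sizes (and hence the
    parameter count) are identical at every p."""
    rows = []
    for p in fractions:
        result = run_single_fold("biovnn", dataset, hierarchy, config,
                                 fold_index=fold_index, randomize_fraction=p)
        report = result.report()
        rows.append({"fraction": p, "auroc": report.auroc,
                     "auprc": report.auprc,
                     "epochs": result.folds[0].trace.stopping_epoch})
    return pd.DataFrame(rows)
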