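"""Metrics, cross-fold pooling and the time-stamped evaluation protocol.

Cross-validation predictions are pooled over the five test folds before
computing the overall AUROC/AUPRC; model comparisons use two-sided
Mann-Whitney-Wilcoxon tests over the five per-fold values (exact small-sample
p-values).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.metrics import average_precision_score, roc_auc_score

from .errors import UndefinedMetricError

logger = logging.getLogger(__name__)


def _check_binary(labels: np.ndarray) -> np.ndarray:
    labels = np.asarray(labels)
    if np.any((labels != 0) & (labels != 1)):
        raise ValueError("labels must be binary (0/1)")
    return labels


def auroc(scores: Sequence[float], labels: Sequence[int]) -> float:
    """Rank-based area under the ROC curve (ties handled by midrank)."""
    labels = _check_binary(labels)
    if labels.min() == labels.max():
        raise UndefinedMetricError("AUROC undefined: only one class present")
    return float(roc_auc_score(labels, np.asarray(scores, dtype=float)))


def auprc(scores: Sequence[float], labels: Sequence[int]) -> float:
    """Area under the precision-recall curve via step-wise interpolation
    (precision summed at each recall increment)."""
    labels = _check_binary(labels)
    if labels.sum() == 0:
        raise UndefinedMetricError("AUPRC undefined: no positive samples")
    return float(average_precision_score(labels, np.asarray(scores, dtype=float)))


@dataclass
class EvaluationReport:
    """Pooled predictions plus summary metrics for one model."""

    predictions: pd.DataFrame        # cell_line, target_gene, score, label, fold
    auroc: float
    auprc: float
    per_fold: list[dict] = field(default_factory=list)
    parameter_count: int | None = None
    epochs_to_converge: list[int] = field(default_factory=list)
    extras: dict = field(default_factory=dict)

    @classmethod
    def from_predictions(cls, predictions: pd.DataFrame, **kwargs
                         ) -> "EvaluationReport":
        per_fold = []
        for f, grp in predictions.groupby("fold"):
            entry = {"fold": int(f), "n": len(grp)}
            try:
                entry["auroc"] = auroc(grp["score"], grp["label"])
                entry["auprc"] = auprc(grp["score"], grp["label"])
            except UndefinedMetricError:
                entry["auroc"] = entry["auprc"] = float("nan")
            per_fold.append(entry)
        return cls(
            predictions=predictions,
            auroc=auroc(predictions["score"], predictions["label"]),
            auprc=auprc(predictions["score"], predictions["label"]),
            per_fold=per_fold,
            **kwargs,
        )

    def summary(self) -> dict:
        out = {
            "auroc": self.auroc,
            "auprc": self.auprc,
            "n_samples": int(len(self.predictions)),
            "per_fold": self.per_fold,
            "epochs_to_converge": self.epochs_to_converge,
        }
        if self.parameter_count is not None:
            out["parameter_count"] = int(self.parameter_count)
        out.update(self.extras)
        return out

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(self.summary(), fh, indent=2, default=float)

    def write_predictions(self, path: str | Path) -> None:
        self.predictions.to_csv(path, sep="\t", index=False)


def compare_per_fold(values_a: Sequence[float], values_b: Sequence[float],
                     alternative: str = "two-sided") -> float:
    """MWW test between two models' per-fold values (epochs or metrics)."""
    res = sps.mannwhitneyu(values_a, values_b, alternative=alternative,
                           method="exact")
    return float(res.pvalue)


def timestamp_evaluate(fold_models: list,
                       old_cohort,
                       new_expression: pd.DataFrame,
                       new_dependency: pd.DataFrame,
                       masks) -> EvaluationReport:
    """Train-on-old, test-on-new protocol.

    ``fold_models`` holds per-fold ``(net, zscore_stats)`` pairs from
    cross-validation on the old cohort.  The new cohort must consist of cell
    lines absent from the old cohort; its expression is z-scored with each
    fold's *old* training statistics.  Target genes missing from the new
    dependency matrix are skipped with a warning.
    """
    from .data import apply_zscore, assemble_batch  # local: avoid cycle

    overlap = sorted(set(old_cohort.cell_lines) & set(new_expression.index))
    if overlap:
        raise ValueError(
            f"new cohort shares {len(overlap)} cell lines with the old cohort: "
            f"{overlap[:10]}")
    missing_feats = [g for g in old_cohort.feature_genes
                     if g not in new_expression.columns]
    if missing_feats:
        raise ValueError(f"new expression lacks {len(missing_feats)} feature genes")
    targets = []
    for g in old_cohort.target_genes:
        if g in new_dependency.columns:
            targets.append(g)
        else:
            logger.warning("target gene %s absent from new dependency data; skipped", g)

    new_expr = new_expression[old_cohort.feature_genes]
    labels = (new_dependency[targets] >= 0.5).astype(int)
    m = len(new_expr)
    target_idx = np.array([old_cohort.target_genes.index(g) for g in targets])
    line_rep = np.repeat(np.arange(m), len(targets))
    targ_rep = np.tile(target_idx, m)
    y = labels.to_numpy().reshape(-1)

    rows = []
    per_fold = []
    for f, (net, stats) in enumerate(fold_models):
        z = apply_zscore(new_expr, stats).to_numpy()
        X = assemble_batch(z, line_rep, targ_rep, masks,
                           len(old_cohort.target_genes))
        scores = net.predict(X)
        per_fold.append({"fold": f, "auroc": auroc(scores, y),
                         "auprc": auprc(scores, y), "n": len(y)})
        rows.append(pd.DataFrame({
            "cell_line": np.asarray(new_expr.index)[line_rep],
            "target_gene": [old_cohort.target_genes[t] for t in targ_rep],
            "score": scores, "label": y, "fold": f,
        }))
    predictions = pd.concat(rows, ignore_index=True)
    report = EvaluationReport(
        predictions=predictions,
        auroc=float(np.mean([p["auroc"] for p in per_fold])),
        auprc=float(np.mean([p["auprc"] for p in per_fold])),
        per_fold=per_fold,
        extras={"n_new_cell_lines": m, "n_targets": len(targets)},
    )
    return report
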