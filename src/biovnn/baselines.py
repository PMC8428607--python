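"""Matched baselines: the dense network of identical depth/width, hierarchies
with partially or fully randomized gene memberships, and the expression-only
scorer.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .data import (CohortDataset, FoldSplit, apply_zscore, stratified_folds,
                   training_statistics)
from .errors import ConfigurationError, UndefinedMetricError
from .evaluation import EvaluationReport, auroc
from .model import block_output_size
from .network import BlockSpec, SparseNet
from .ontology import Pathway, PathwayHierarchy

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# matched fully connected network


def build_matched_fcn(hierarchy: PathwayHierarchy,
                      feature_genes: Sequence[str],
                      target_genes: Sequence[str],
                      seed: int = 0,
                      alpha: float = 0.3,
                      lam: float = 1.0,
                      dropout_p: float = 0.5) -> SparseNet:
    """Dense network with the same depth as the hierarchy and, per hidden
    layer, the same total neuron count as the pathway blocks of that level.

    It shares the Mish/BatchNorm/Dropout stack, per-layer auxiliary heads and
    the root output head, so it is a drop-in replacement in the training and
    evaluation code."""
    k, n = len(feature_genes), len(target_genes)
    widths = [0] * hierarchy.n_levels
    for pid, level in hierarchy.levels.items():
        widths[level - 1] += block_output_size(len(hierarchy.pathways[pid].genes))
    if any(w == 0 for w in widths):
        raise ConfigurationError("hierarchy has an empty level")

    specs = []
    for ell, width in enumerate(widths, start=1):
        name = f"L{ell}"
        if ell == 1:
            specs.append(BlockSpec(name=name, out_size=width, level=ell,
                                   x_indices=np.arange(k + n, dtype=np.int64)))
        else:
            specs.append(BlockSpec(name=name, out_size=width, level=ell,
                                   children=[f"L{ell - 1}"]))
    return SparseNet(specs, root=f"L{hierarchy.n_levels}", n_inputs=k + n,
                     alpha=alpha, lam=lam, dropout_p=dropout_p, seed=seed,
                     fingerprint_extra="fcn:" + hierarchy.fingerprint())


# ---------------------------------------------------------------------------
# randomized hierarchies


@dataclass
class RandomizedHierarchy:
    """A hierarchy with the same topology and per-pathway sizes as its base
    but with a fraction of gene memberships resampled from the gene pool."""

    base: PathwayHierarchy
    fraction: float
    seed: int
    hierarchy: PathwayHierarchy


def randomize_hierarchy(hierarchy: PathwayHierarchy,
                        fraction: float,
                        seed: int,
                        feature_genes: Sequence[str] | None = None,
                        target_genes: Sequence[str] | None = None
                        ) -> RandomizedHierarchy:
    """Resample a fraction of gene-pathway membership slots.

    A ``fraction`` of all membership slots, chosen uniformly, is refilled by
    genes drawn from the global pool — without replacement within a pathway
    (no duplicate members) and with replacement across pathways.  Pathway
    sizes and the parent-child topology are untouched; ``fraction=1``
    reproduces the fully random gene-group model.

    When the feature/target gene lists are given, a replacement gene is drawn
    from the same role category (feature-only, target-only, or both) as the
    gene it displaces, so the compiled model's leaf input sizes — hence its
    parameter count — are preserved exactly.
    """
    if not 0.0 <= fraction <= 1.0:
        raise ValueError("fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    pool = sorted(hierarchy.gene_universe())

    if feature_genes is not None or target_genes is not None:
        fset = {g.upper() for g in (feature_genes or [])}
        tset = {g.upper() for g in (target_genes or [])}

        def category(g: str) -> tuple[bool, bool]:
            return (g in fset, g in tset)
    else:
        def category(g: str) -> tuple[bool, bool]:
            return (True, True)

    pool_by_cat: dict[tuple[bool, bool], list[str]] = {}
    for g in pool:
        pool_by_cat.setdefault(category(g), []).append(g)

    ordered_ids = hierarchy.topological_order()
    slots = [(pid, g) for pid in ordered_ids
             for g in sorted(hierarchy.pathways[pid].genes)]
    n_swap = int(round(fraction * len(slots)))
    chosen = set(rng.choice(len(slots), size=n_swap, replace=False)) if n_swap else set()

    new_genes: dict[str, set[str]] = {pid: set() for pid in ordered_ids}
    swaps: dict[str, list[str]] = {pid: [] for pid in ordered_ids}
    for s, (pid, g) in enumerate(slots):
        if s in chosen:
            swaps[pid].append(g)
        else:
            new_genes[pid].add(g)
    for pid in ordered_ids:
        for old in swaps[pid]:
            cands = [g for g in pool_by_cat[category(old)]
                     if g not in new_genes[pid]]
            if not cands:
                new_genes[pid].add(old)  # pool exhausted: keep the gene
                continue
            new_genes[pid].add(cands[rng.integers(len(cands))])

    pathways = {
        pid: Pathway(id=pid, name=hierarchy.pathways[pid].name,
                     genes=new_genes[pid],
                     parents=set(hierarchy.pathways[pid].parents),
                     children=set(hierarchy.pathways[pid].children))
        for pid in ordered_ids
    }
    randomized = PathwayHierarchy(pathways=pathways, root=hierarchy.root,
                                  levels=dict(hierarchy.levels),
                                  n_levels=hierarchy.n_levels)
    return RandomizedHierarchy(base=hierarchy, fraction=fraction, seed=seed,
                               hierarchy=randomized)


# ---------------------------------------------------------------------------
# expression-only baseline


def expression_baseline(dataset: CohortDataset,
                        split: FoldSplit | None = None,
                        seed: int = 0) -> EvaluationReport:
    """Score each (cell line, target) pair by the target gene's own z-scored
    expression, sign chosen per fold by validation AUROC.

    Also reports the Pearson correlation between expression and dependency
    probability across all scorable pairs."""
    if split is None:
        split = stratified_folds(dataset, seed=seed)
    targets = [g for g in dataset.target_genes if g in dataset.expression.columns]
    skipped = set(dataset.target_genes) - set(targets)
    for g in sorted(skipped):
        logger.warning("target gene %s lacks expression data; excluded", g)
    if not targets:
        raise ConfigurationError("no target gene has expression data")

    rows = []
    for f, fold in enumerate(split):
        stats = training_statistics(dataset.expression, fold["train"])
        z = apply_zscore(dataset.expression, stats)

        def pairs(ids):
            s = -z.loc[ids, targets].to_numpy().reshape(-1)
            y = dataset.labels.loc[ids, targets].to_numpy().reshape(-1)
            return s, y

        val_s, val_y = pairs(fold["validation"])
        sign = 1.0
        try:
            if auroc(val_s, val_y) < 0.5:
                sign = -1.0
        except UndefinedMetricError:
            pass
        test_s, test_y = pairs(fold["test"])
        rows.append(pd.DataFrame({
            "cell_line": np.repeat(fold["test"], len(targets)),
            "target_gene": np.tile(targets, len(fold["test"])),
            "score": sign * test_s,
            "label": test_y,
            "fold": f,
        }))
    predictions = pd.concat(rows, ignore_index=True)

    expr = dataset.expression[targets].to_numpy().reshape(-1)
    dep = dataset.dependency[targets].to_numpy().reshape(-1)
    pearson = float(sps.pearsonr(expr, dep)[0]) if np.std(expr) > 0 else float("nan")
    return EvaluationReport.from_predictions(
        predictions, parameter_count=0,
        extras={"expression_dependency_pearson": pearson,
                "n_scorable_targets": len(targets)},
    )
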