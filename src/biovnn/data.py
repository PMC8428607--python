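"""Cohort assembly: feature/target gene selection, per-target feature masks,
z-scoring by training statistics and class/tissue-balanced fold splits.

Matrices follow the DepMap orientation: rows are cell lines, columns are
genes; expression is log2(TPM+1) and dependencies are probabilities in
[0, 1], binarized at 0.5 (a dependency >= 0.5 is a positive sample).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError, MaskError
from .ontology import PathwayHierarchy

DEPENDENT_THRESHOLD = 0.5
MASK_CAP = 100


# ---------------------------------------------------------------------------
# I/O helpers


def read_matrix(path: str | Path) -> pd.DataFrame:
    """Read a cell-line x gene matrix (CSV or TSV, first column = cell line id,
    header row = gene symbols)."""
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    df = pd.read_csv(path, sep=sep, index_col=0)
    df.columns = [str(c).strip().upper() for c in df.columns]
    df.index = [str(i).strip() for i in df.index]
    return df


def read_tissue_map(path: str | Path) -> dict[str, str]:
    """Two-column TSV: cell line id TAB tissue label."""
    df = pd.read_csv(path, sep="\t", header=None, names=["cell_line", "tissue"])
    return dict(zip(df["cell_line"].astype(str), df["tissue"].astype(str)))


def read_gene_list(path: str | Path) -> set[str]:
    with open(path) as fh:
        return {line.strip().upper() for line in fh if line.strip()}


# ---------------------------------------------------------------------------
# containers


@dataclass
class CohortDataset:
    """Expression features, binarized dependency labels and tissue labels for
    one cohort of cell lines."""

    expression: pd.DataFrame          # m x k, log2(TPM+1), feature genes only
    dependency: pd.DataFrame          # m x n, probabilities in [0, 1]
    tissues: dict[str, str]
    feature_genes: list[str]
    target_genes: list[str]
    labels: pd.DataFrame = field(init=False)  # m x n in {0, 1}

    def __post_init__(self) -> None:
        if self.expression.isna().any().any() or self.dependency.isna().any().any():
            raise ConfigurationError("NaN values in assembled cohort matrices")
        self.labels = (self.dependency >= DEPENDENT_THRESHOLD).astype(np.int8)

    @property
    def cell_lines(self) -> list[str]:
        return list(self.expression.index)

    @property
    def n_cell_lines(self) -> int:
        return len(self.expression)


@dataclass
class FeatureMask:
    """Per-target binary filters over the feature genes.

    ``matrix[j]`` keeps the feature genes sharing at least one pathway with
    target gene j, accumulated from the smallest pathway to the largest until
    ``cap`` genes are reached (smaller pathways represent tighter functional
    relationships)."""

    target_genes: list[str]
    feature_genes: list[str]
    matrix: np.ndarray                # n x k, uint8
    cap: int = MASK_CAP

    def vector(self, target_gene: str) -> np.ndarray:
        return self.matrix[self.target_genes.index(target_gene)]


@dataclass
class FoldSplit:
    """Five-fold cross-validation roles per cell line.

    ``folds[i]`` is the list of cell lines dealt to fold i; per evaluation
    fold f, ``test = folds[f]`` and the remaining lines are re-partitioned
    into train and validation at 4:1, giving the overall 3.2 : 0.8 : 1 ratio.
    """

    folds: list[list[str]]
    assignments: list[dict[str, list[str]]]  # per fold: train/validation/test

    @property
    def n_folds(self) -> int:
        return len(self.folds)

    def __iter__(self):
        return iter(self.assignments)


# ---------------------------------------------------------------------------
# gene selection


def filter_feature_genes(expression: pd.DataFrame,
                         ontology_genes: set[str],
                         min_value: float = 1.0,
                         min_fraction: float = 0.01) -> list[str]:
    """Feature genes: expressed above ``min_value`` in at least
    ``ceil(min_fraction * m)`` cell lines and present in the ontology."""
    m = len(expression)
    min_lines = math.ceil(min_fraction * m)
    ontology_genes = {g.upper() for g in ontology_genes}
    expressed = (expression.to_numpy() > min_value).sum(axis=0) >= min_lines
    genes = [g for g, ok in zip(expression.columns, expressed)
             if ok and g in ontology_genes]
    if not genes:
        raise ConfigurationError("no feature genes survive the expression filter")
    return genes


def select_target_genes(dependency: pd.DataFrame,
                        ontology_genes: set[str],
                        druggable: set[str] | None = None,
                        min_pos: int = 6,
                        min_neg: int = 6) -> list[str]:
    """Target genes: in the ontology (and the druggable list when given) with
    at least ``min_pos`` dependent and ``min_neg`` non-dependent cell lines.

    The positive/negative minima exclude genes that are nearly always (or
    never) essential, whose evaluation would be degenerate."""
    ontology_genes = {g.upper() for g in ontology_genes}
    labels = dependency.to_numpy() >= DEPENDENT_THRESHOLD
    n_pos = labels.sum(axis=0)
    n_neg = (~labels).sum(axis=0)
    out = []
    for idx, gene in enumerate(dependency.columns):
        if gene not in ontology_genes:
            continue
        if druggable is not None and gene not in druggable:
            continue
        if n_pos[idx] >= min_pos and n_neg[idx] >= min_neg:
            out.append(gene)
    if not out:
        raise ConfigurationError("no target genes survive selection")
    return out


# ---------------------------------------------------------------------------
# masks


def build_feature_mask(target_gene: str,
                       hierarchy: PathwayHierarchy,
                       feature_genes: Sequence[str],
                       cap: int = MASK_CAP) -> np.ndarray:
    """Binary vector over ``feature_genes`` for one target gene.

    Pathways containing the target are visited in ascending gene-count order
    (ties broken by pathway id); their feature-gene members accumulate until
    ``cap`` genes are selected.  If the cap is crossed mid-pathway, that
    pathway's new genes are added in sorted-symbol order up to the cap."""
    target_gene = target_gene.upper()
    pathway_ids = hierarchy.pathways_of_gene(target_gene)
    if not pathway_ids:
        raise MaskError(f"target gene {target_gene!r} belongs to no pathway")
    pathway_ids.sort(key=lambda pid: (len(hierarchy.pathways[pid].genes), pid))
    feature_set = {g: i for i, g in enumerate(feature_genes)}
    selected: set[str] = set()
    for pid in pathway_ids:
        members = hierarchy.pathways[pid].genes & feature_set.keys()
        new = sorted(members - selected)
        room = cap - len(selected)
        if room <= 0:
            break
        selected.update(new[:room])
    mask = np.zeros(len(feature_genes), dtype=np.uint8)
    for g in selected:
        mask[feature_set[g]] = 1
    return mask


def build_feature_masks(target_genes: Sequence[str],
                        hierarchy: PathwayHierarchy,
                        feature_genes: Sequence[str],
                        cap: int = MASK_CAP,
                        allow_unmapped: bool = False) -> FeatureMask:
    """Stack per-target masks into a FeatureMask.

    With ``allow_unmapped`` a target gene in no pathway gets an all-zero mask
    (its expression inputs vanish) instead of raising — used for randomized
    ontologies where shuffling can strand a target gene."""
    rows = []
    for g in target_genes:
        try:
            rows.append(build_feature_mask(g, hierarchy, feature_genes, cap))
        except MaskError:
            if not allow_unmapped:
                raise
            rows.append(np.zeros(len(feature_genes), dtype=np.uint8))
    return FeatureMask(list(target_genes), list(feature_genes),
                       np.stack(rows), cap)


# ---------------------------------------------------------------------------
# z-scoring and sample assembly


def zscore_by_training(expression: pd.DataFrame,
                       training_ids: Sequence[str]) -> pd.DataFrame:
    """Z-score every column using the mean/sd of the training rows only.

    Zero-variance genes map to 0 everywhere."""
    if len(training_ids) == 0:
        raise ConfigurationError("training set is empty")
    stats = training_statistics(expression, training_ids)
    return apply_zscore(expression, stats)


def training_statistics(expression: pd.DataFrame,
                        training_ids: Sequence[str]) -> tuple[np.ndarray, np.ndarray]:
    train = expression.loc[list(training_ids)].to_numpy(dtype=np.float64)
    mean = train.mean(axis=0)
    sd = train.std(axis=0)
    return mean, sd


def apply_zscore(expression: pd.DataFrame,
                 stats: tuple[np.ndarray, np.ndarray]) -> pd.DataFrame:
    mean, sd = stats
    safe_sd = np.where(sd > 0, sd, 1.0)
    z = (expression.to_numpy(dtype=np.float64) - mean) / safe_sd
    z[:, sd == 0] = 0.0
    return pd.DataFrame(z, index=expression.index, columns=expression.columns)


def assemble_sample(cell_line: str,
                    target_gene: str,
                    zscored: pd.DataFrame,
                    dataset: CohortDataset,
                    mask: FeatureMask) -> tuple[np.ndarray, int]:
    """Input vector (masked z-scored expression ++ deletion one-hot) and label
    for one (cell line, target gene) pair."""
    i = zscored.index.get_loc(cell_line)
    j = dataset.target_genes.index(target_gene)
    x = assemble_batch(zscored.to_numpy(), np.array([i]), np.array([j]), mask,
                       len(dataset.target_genes))[0]
    y = int(dataset.labels.loc[cell_line, target_gene])
    return x, y


def assemble_batch(zscored: np.ndarray,
                   line_idx: np.ndarray,
                   target_idx: np.ndarray,
                   mask: FeatureMask,
                   n_targets: int) -> np.ndarray:
    """Vectorized sample assembly for index arrays of equal length."""
    expr = zscored[line_idx] * mask.matrix[target_idx]
    onehot = np.zeros((len(target_idx), n_targets))
    onehot[np.arange(len(target_idx)), target_idx] = 1.0
    return np.concatenate([expr, onehot], axis=1)


# ---------------------------------------------------------------------------
# fold splits


def stratified_folds(dataset: CohortDataset,
                     n_folds: int = 5,
                     seed: int = 0) -> FoldSplit:
    """Class/tissue-balanced 5-fold split by cell line.

    Cell lines are grouped by tissue; within each tissue they are ordered by
    their positive-label fraction (with a seeded shuffle breaking ties) and
    dealt round-robin into folds, so folds inherit both the tissue mix and
    the class mix.  Per evaluation fold, the four remaining folds are
    re-partitioned 4:1 into train and validation by taking every fifth line,
    giving overall train : validation : test = 3.2 : 0.8 : 1."""
    lines = dataset.cell_lines
    if len(lines) < n_folds:
        raise ConfigurationError(f"{len(lines)} cell lines < {n_folds} folds")
    rng = np.random.default_rng(seed)
    pos_frac = dataset.labels.mean(axis=1)

    by_tissue: dict[str, list[str]] = {}
    for cl in lines:
        by_tissue.setdefault(dataset.tissues.get(cl, "all"), []).append(cl)

    folds: list[list[str]] = [[] for _ in range(n_folds)]
    cursor = 0
    for tissue in sorted(by_tissue):
        group = by_tissue[tissue]
        order = rng.permutation(len(group))
        group = [group[i] for i in order]
        # stable sort on binned class fraction: balances classes across folds
        # while the seeded shuffle above still varies order within bins
        group.sort(key=lambda cl: int(pos_frac[cl] * 10))
        for cl in group:
            folds[cursor % n_folds].append(cl)
            cursor += 1

    assignments = []
    for f in range(n_folds):
        test = list(folds[f])
        rest: list[str] = []
        for g in range(1, n_folds):
            rest.extend(folds[(f + g) % n_folds])
        validation = rest[::n_folds]  # every n-th line -> 1/5 of the rest
        val_set = set(validation)
        train = [cl for cl in rest if cl not in val_set]
        assignments.append({"train": train, "validation": validation, "test": test})
    return FoldSplit(folds=folds, assignments=assignments)


def fold_class_balance(dataset: CohortDataset, split: FoldSplit) -> list[float]:
    """Positive-label fraction of each test fold (diagnostic)."""
    return [float(dataset.labels.loc[fold].to_numpy().mean())
            for fold in split.folds]


# ---------------------------------------------------------------------------
# cohort assembly


def build_cohort(expression: pd.DataFrame,
                 dependency: pd.DataFrame,
                 tissues: Mapping[str, str] | None,
                 hierarchy: PathwayHierarchy,
                 druggable: set[str] | None = None,
                 min_pos: int = 6,
                 min_neg: int = 6) -> CohortDataset:
    """Apply the standard feature/target filters and align the matrices."""
    shared = [cl for cl in expression.index if cl in set(dependency.index)]
    if not shared:
        raise ConfigurationError("expression and dependency share no cell lines")
    expression = expression.loc[shared]
    dependency = dependency.loc[shared]
    universe = hierarchy.gene_universe()
    feature_genes = filter_feature_genes(expression, universe)
    target_genes = select_target_genes(dependency, universe, druggable,
                                       min_pos=min_pos, min_neg=min_neg)
    tissues = dict(tissues) if tissues else {cl: "all" for cl in shared}
    return CohortDataset(
        expression=expression[feature_genes],
        dependency=dependency[target_genes],
        tissues=tissues,
        feature_genes=list(feature_genes),
        target_genes=list(target_genes),
    )
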