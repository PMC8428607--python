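"""Interpretability analyses on trained networks.

Three questions are asked of a trained model, mirroring how a visible
network's hidden states are read as pathway states:

1. *Class separation* — for a target gene, do the neuron states of pathways
   containing that gene differ between dependent and non-dependent cell
   lines?  States are compressed by PCA; a two-sided Mann-Whitney-Wilcoxon
   (MWW) test on each of the first two components is combined by Fisher's
   method, and the separation score is -log10 of the combined p.
2. *Prediction explanation* — per cell line, the cohort-z-scored PC1 of each
   related pathway, ordered from leaves to root.
3. *Reaction-partner importance* — per (target gene, pathway), are the
   target's reaction partners weighted more heavily than other member genes?
   Importance of gene g for pathway t is the Euclidean norm of the column of
   t's (leaf) weight matrix reading g's masked-expression input, summed over
   the leaf blocks of t's subtree when t is interior.

A fourth analysis asks whether a *dense* model re-discovers pathways: its
first-layer per-gene weight vectors are PCA-compressed and k-means-clustered
(k = number of leaf-level pathways), and clusters are tested for
hypergeometric overlap with pathways against a size-matched random-group
null.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA
from statsmodels.stats.multitest import multipletests

from .data import CohortDataset, FeatureMask, assemble_batch
from .errors import DegenerateInputError, UndefinedMetricError
from .model import pathway_gene_input_columns
from .network import SparseNet
from .ontology import PathwayHierarchy, ReactionSet


def bh_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values."""
    pvalues = np.asarray(pvalues, dtype=float)
    if len(pvalues) == 0:
        return pvalues
    return multipletests(pvalues, method="fdr_bh")[1]


def hypergeom_tail(overlap: int, group_size: int, pathway_size: int,
                   universe: int) -> float:
    """P(X >= overlap) for the overlap of a random ``group_size`` draw with a
    ``pathway_size`` category in a universe of ``universe`` genes."""
    return float(sps.hypergeom.sf(overlap - 1, universe, pathway_size,
                                  group_size))


# ---------------------------------------------------------------------------
# neuron-state extraction


@dataclass
class NeuronStateRecord:
    cell_line: str
    target_gene: str
    pathway_id: str
    state: np.ndarray
    probability: float
    label: int


@dataclass
class StateExtraction:
    """Neuron states for every (cell line, pathway) at one target gene."""

    target_gene: str
    cell_lines: list[str]
    labels: np.ndarray
    probabilities: np.ndarray
    states: dict[str, np.ndarray]     # pathway id -> m x s_o

    def records(self) -> Iterable[NeuronStateRecord]:
        for pid, mat in self.states.items():
            for i, cl in enumerate(self.cell_lines):
                yield NeuronStateRecord(cl, self.target_gene, pid, mat[i],
                                        float(self.probabilities[i]),
                                        int(self.labels[i]))


def extract_states(net: SparseNet,
                   dataset: CohortDataset,
                   masks: FeatureMask,
                   target_gene: str,
                   zscored: np.ndarray) -> StateExtraction:
    """Inference-mode forward over every cell line for one target gene,
    collecting every block's output state.  Deterministic."""
    j = dataset.target_genes.index(target_gene)
    m = dataset.n_cell_lines
    X = assemble_batch(zscored, np.arange(m), np.full(m, j), masks,
                       len(dataset.target_genes))
    probs, states, _ = net.forward(X, collect_states=True)
    return StateExtraction(
        target_gene=target_gene,
        cell_lines=dataset.cell_lines,
        labels=dataset.labels[target_gene].to_numpy(),
        probabilities=np.asarray(probs),
        states={k: np.asarray(v) for k, v in states.items()},
    )


# ---------------------------------------------------------------------------
# class separation


def pathway_pca(states: np.ndarray) -> np.ndarray:
    """First two principal-component scores of one pathway's states
    (centered PCA over cell lines)."""
    states = np.asarray(states, dtype=float)
    if states.shape[0] < 3:
        raise DegenerateInputError("PCA needs at least 3 cell lines")
    if states.shape[1] < 2:
        raise DegenerateInputError("PCA needs state dimension >= 2")
    if np.allclose(states.var(axis=0), 0):
        raise DegenerateInputError("zero-variance states")
    return PCA(n_components=2).fit_transform(states)


@dataclass
class SeparationResult:
    pathway_id: str
    target_gene: str
    p_pc1: float
    p_pc2: float
    combined_p: float
    score: float                      # -log10(combined p)
    related: bool
    adjusted_p: float = float("nan")


def class_separation_test(pc_scores: np.ndarray, labels: np.ndarray,
                          pathway_id: str = "", target_gene: str = "",
                          related: bool = False) -> SeparationResult:
    """Two-sided MWW on PC1 and PC2 between classes, Fisher-combined."""
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2 or min((labels == 0).sum(),
                                         (labels == 1).sum()) < 2:
        raise UndefinedMetricError("both classes need >= 2 members")
    pos, neg = pc_scores[labels == 1], pc_scores[labels == 0]
    ps = []
    for c in (0, 1):
        ps.append(float(sps.mannwhitneyu(pos[:, c], neg[:, c],
                                         alternative="two-sided").pvalue))
    combined = float(sps.combine_pvalues(ps, method="fisher").pvalue)
    return SeparationResult(pathway_id, target_gene, ps[0], ps[1], combined,
                            -np.log10(max(combined, 1e-300)), related)


def separation_table(extraction: StateExtraction,
                     hierarchy: PathwayHierarchy) -> pd.DataFrame:
    """Class separation of every pathway for one target gene.

    Pathways whose states are constant across the cohort (their inputs were
    entirely masked) get a separation score of 0 (p = 1)."""
    target = extraction.target_gene
    related_ids = set(hierarchy.pathways_of_gene(target))
    rows = []
    for pid, states in extraction.states.items():
        if pid not in hierarchy.pathways:
            continue
        related = pid in related_ids
        try:
            pcs = pathway_pca(states)
            res = class_separation_test(pcs, extraction.labels, pid, target,
                                        related)
        except DegenerateInputError:
            res = SeparationResult(pid, target, 1.0, 1.0, 1.0, 0.0, related)
        rows.append(res)
    df = pd.DataFrame([r.__dict__ for r in rows])
    df["adjusted_p"] = bh_adjust(df["combined_p"])
    df["level"] = [hierarchy.levels[p] for p in df["pathway_id"]]
    return df.sort_values(["level", "pathway_id"]).reset_index(drop=True)


def related_vs_unrelated(sep: pd.DataFrame, min_related: int = 6) -> float:
    """One-sided MWW: are separation scores of related pathways (containing
    the target gene) larger than those of unrelated pathways?

    Returns the raw p-value; genes with fewer than ``min_related`` related
    pathways are skipped (raises)."""
    related = sep.loc[sep["related"], "score"]
    unrelated = sep.loc[~sep["related"], "score"]
    if len(related) < min_related:
        raise UndefinedMetricError(
            f"only {len(related)} related pathways (< {min_related}); skipped")
    if len(unrelated) == 0:
        raise UndefinedMetricError("no unrelated pathways")
    return float(sps.mannwhitneyu(related, unrelated,
                                  alternative="greater").pvalue)


def related_separation_analysis(net: SparseNet,
                                dataset: CohortDataset,
                                masks: FeatureMask,
                                hierarchy: PathwayHierarchy,
                                zscored: np.ndarray,
                                min_related: int = 6,
                                fdr: float = 0.1) -> pd.DataFrame:
    """Across target genes: related-vs-unrelated separation with BH control.

    Returns one row per analyzable gene with the raw and adjusted p and a
    significance flag at the given FDR."""
    rows = []
    for gene in dataset.target_genes:
        extraction = extract_states(net, dataset, masks, gene, zscored)
        sep = separation_table(extraction, hierarchy)
        try:
            p = related_vs_unrelated(sep, min_related=min_related)
        except UndefinedMetricError as exc:
            rows.append({"target_gene": gene, "p": np.nan,
                         "skipped": str(exc)})
            continue
        rows.append({"target_gene": gene, "p": p, "skipped": ""})
    df = pd.DataFrame(rows)
    tested = df["p"].notna()
    df["adjusted_p"] = np.nan
    if tested.any():
        df.loc[tested, "adjusted_p"] = bh_adjust(df.loc[tested, "p"])
    df["significant"] = df["adjusted_p"] < fdr
    return df


# ---------------------------------------------------------------------------
# per-prediction explanation


def explain_prediction(net: SparseNet,
                       dataset: CohortDataset,
                       masks: FeatureMask,
                       hierarchy: PathwayHierarchy,
                       zscored: np.ndarray,
                       cell_line: str,
                       target_gene: str) -> pd.DataFrame:
    """Pathway-state summary for one prediction: per related pathway, the
    PC1 score z-scored across the cohort, ordered leaves -> root."""
    if cell_line not in dataset.cell_lines:
        raise KeyError(f"unknown cell line {cell_line!r}")
    extraction = extract_states(net, dataset, masks, target_gene, zscored)
    i = dataset.cell_lines.index(cell_line)
    related = hierarchy.pathways_of_gene(target_gene)
    rows = []
    for pid in related:
        try:
            pc1 = pathway_pca(extraction.states[pid])[:, 0]
        except DegenerateInputError:
            continue
        sd = pc1.std()
        z = (pc1 - pc1.mean()) / sd if sd > 0 else np.zeros_like(pc1)
        rows.append({"pathway_id": pid, "level": hierarchy.levels[pid],
                     "state_z": float(z[i])})
    df = pd.DataFrame(rows).sort_values(["level", "pathway_id"])
    df.attrs["probability"] = float(extraction.probabilities[i])
    df.attrs["label"] = int(extraction.labels[i])
    return df.reset_index(drop=True)


def explanation_heatmap(df: pd.DataFrame, path: str) -> None:
    """Optional PNG rendering of an explanation table."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    fig, ax = plt.subplots(figsize=(4, max(2, 0.3 * len(df))))
    ax.imshow(df[["state_z"]].to_numpy(), aspect="auto", cmap="RdBu_r",
              vmin=-3, vmax=3)
    ax.set_yticks(range(len(df)), df["pathway_id"])
    ax.set_xticks([])
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


# ---------------------------------------------------------------------------
# feature importance & reaction enrichment


def feature_importance(net: SparseNet,
                       hierarchy: PathwayHierarchy,
                       feature_genes: Sequence[str],
                       target_gene: str,
                       pathway_id: str,
                       reactions: ReactionSet | None = None) -> pd.DataFrame:
    """Per-gene importance for one pathway: the L2 norm of the weight column
    reading each member gene's expression input, summed over the pathway's
    leaf blocks when the pathway is interior."""
    target_gene = target_gene.upper()
    if target_gene not in hierarchy.pathways[pathway_id].genes:
        raise ValueError(f"{target_gene} is not a member of {pathway_id}")
    leaf_blocks = [pid for pid in hierarchy.subtree(pathway_id)
                   if not hierarchy.pathways[pid].children]
    importance: dict[str, float] = {}
    for leaf in leaf_blocks:
        W = net.params[f"W:{leaf}"]
        for gene, col in pathway_gene_input_columns(net, leaf,
                                                    feature_genes).items():
            importance[gene] = importance.get(gene, 0.0) \
                + float(np.linalg.norm(W[:, col]))
    members = hierarchy.pathways[pathway_id].genes
    rows = [{"gene": g, "importance": v, "in_pathway": g in members}
            for g, v in sorted(importance.items())]
    df = pd.DataFrame(rows)
    if reactions is not None:
        partners = reactions.partners(target_gene)
        df["is_partner"] = df["gene"].isin(partners)
    df["target_gene"] = target_gene
    df["pathway_id"] = pathway_id
    return df


def partner_enrichment_test(table: pd.DataFrame,
                            min_group: int = 3) -> float:
    """One-sided MWW: do reaction partners of the target outweigh the other
    member genes of the pathway?  Requires both groups >= ``min_group``; the
    target gene itself is excluded."""
    t = table[table["in_pathway"] & (table["gene"] != table["target_gene"])]
    partners = t.loc[t["is_partner"], "importance"]
    others = t.loc[~t["is_partner"], "importance"]
    if len(partners) < min_group or len(others) < min_group:
        raise UndefinedMetricError(
            f"group sizes {len(partners)}/{len(others)} below {min_group}")
    return float(sps.mannwhitneyu(partners, others,
                                  alternative="greater").pvalue)


def reaction_enrichment(tables: Iterable[pd.DataFrame],
                        min_group: int = 3,
                        fdr: float = 0.1,
                        top_candidates: int = 3) -> pd.DataFrame:
    """Across (target gene, pathway) pairs: partner-vs-other importance with
    BH control; significant pairs also report the top-weighted non-partner
    genes as candidate novel reaction components."""
    rows = []
    for table in tables:
        gene = table["target_gene"].iloc[0]
        pid = table["pathway_id"].iloc[0]
        try:
            p = partner_enrichment_test(table, min_group=min_group)
        except UndefinedMetricError as exc:
            rows.append({"target_gene": gene, "pathway_id": pid, "p": np.nan,
                         "skipped": str(exc), "candidates": ""})
            continue
        t = table[table["in_pathway"] & ~table["is_partner"]
                  & (table["gene"] != gene)]
        cands = ",".join(t.sort_values("importance", ascending=False)
                         ["gene"].head(top_candidates))
        rows.append({"target_gene": gene, "pathway_id": pid, "p": p,
                     "skipped": "", "candidates": cands})
    df = pd.DataFrame(rows)
    tested = df["p"].notna()
    df["adjusted_p"] = np.nan
    if tested.any():
        df.loc[tested, "adjusted_p"] = bh_adjust(df.loc[tested, "p"])
    df["significant"] = df["adjusted_p"] < fdr
    return df


# ---------------------------------------------------------------------------
# dense-model pathway recovery


def cluster_pathway_overlap(clusters: dict[int, set[str]],
                            pathway_sets: dict[str, set[str]],
                            universe: set[str],
                            fdr: float = 0.1) -> pd.DataFrame:
    """Hypergeometric overlap of every (cluster, pathway) pair, BH-adjusted;
    a cluster is recovered if any pathway overlap survives the FDR."""
    rows = []
    M = len(universe)
    for cid, members in clusters.items():
        for pid, pset in pathway_sets.items():
            pset = pset & universe
            overlap = len(members & pset)
            rows.append({"cluster": cid, "pathway_id": pid,
                         "overlap": overlap,
                         "p": hypergeom_tail(overlap, len(members),
                                             len(pset), M)})
    df = pd.DataFrame(rows)
    df["adjusted_p"] = bh_adjust(df["p"])
    df["significant"] = df["adjusted_p"] < fdr
    return df


def fcn_weight_clustering(fcn: SparseNet,
                          hierarchy: PathwayHierarchy,
                          feature_genes: Sequence[str],
                          n_pcs: int = 50,
                          seed: int = 0,
                          n_null: int = 100,
                          fdr: float = 0.1) -> dict:
    """Do the dense model's first-layer weights re-discover pathways?

    Each feature gene's first-layer weight vector is PCA-compressed and
    k-means-clustered with k = the number of leaf-level pathways; clusters
    are tested for pathway overlap and the count of recovered clusters is
    compared to size-matched random gene groups."""
    feature_genes = list(feature_genes)
    first = fcn.specs[0]
    W = fcn.params[f"W:{first.name}"]           # width x (k + n)
    k = len(feature_genes)
    vectors = W[:, :k].T                        # per-gene weight vectors
    n_leaves = len([p for p, lvl in hierarchy.levels.items() if lvl == 1])
    if n_leaves > len(feature_genes):
        raise ValueError("k exceeds the number of genes")
    n_comp = min(n_pcs, min(vectors.shape) - 1) or 1
    compressed = PCA(n_components=n_comp,
                     random_state=seed).fit_transform(vectors)
    assignment = KMeans(n_clusters=n_leaves, random_state=seed,
                        n_init=4).fit_predict(compressed)
    clusters = {c: {feature_genes[i] for i in np.where(assignment == c)[0]}
                for c in range(n_leaves)}
    universe = set(feature_genes)
    leaf_sets = {pid: hierarchy.pathways[pid].genes
                 for pid, lvl in hierarchy.levels.items() if lvl == 1}

    overlap = cluster_pathway_overlap(clusters, leaf_sets, universe, fdr)
    n_sig = overlap.groupby("cluster")["significant"].any().sum()

    sizes = [len(c) for c in clusters.values()]
    rng = np.random.default_rng(seed)
    null_counts = []
    pool = sorted(universe)
    for _ in range(n_null):
        shuffled = list(rng.permutation(pool))
        rand_clusters, start = {}, 0
        for cid, size in enumerate(sizes):
            rand_clusters[cid] = set(shuffled[start:start + size])
            start += size
        ov = cluster_pathway_overlap(rand_clusters, leaf_sets, universe, fdr)
        null_counts.append(int(ov.groupby("cluster")["significant"].any().sum()))
    null_counts = np.asarray(null_counts)
    return {
        "n_clusters": n_leaves,
        "n_significant": int(n_sig),
        "null_mean": float(null_counts.mean()),
        "null_sd": float(null_counts.std()),
        "z_vs_null": float((n_sig - null_counts.mean())
                           / (null_counts.std() or 1.0)),
        "overlap_table": overlap,
    }
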