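"""Synthetic pathway hierarchies and cohorts with a planted, pathway-routed
dependency mechanism.

The generator mirrors the statistical structure the analyses assume: genes of
a pathway co-vary through a shared latent factor; per pathway a "reaction"
subset marks tighter functional partners; and each target gene's dependency
probability is a sigmoid function of the mean (standardized) expression of
its reaction partners inside one driver pathway.  The reaction partners
therefore carry the label signal that feature-importance analysis must
rediscover, and the driver branch carries the class-separation signal.

Expression is produced on a log2(TPM+1)-like scale — nonnegative and
right-skewed via a softplus of a Gaussian — so the expression filters have
nontrivial behavior.  Tissue labels come from clustering the latent factors,
exercising tissue-balanced fold splitting.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .data import CohortDataset, build_cohort
from .errors import ConfigurationError
from .ontology import (PathwayHierarchy, ReactionSet, build_hierarchy,
                       write_gmt, write_hierarchy, write_reactions)


@dataclass
class GeneratorConfig:
    n_genes: int = 200
    n_pathways: int = 30
    n_levels: int = 4
    pathway_size_range: tuple[int, int] = (5, 20)
    n_cell_lines: int = 300
    n_target_genes: int = 6
    target_extra_pathways: int = 4   # extra leaves each target gene is placed in
    beta: float = 2.0                # effect size of the planted mechanism
    label_noise: float = 0.5         # sd of the logit noise (0 = deterministic)
    prevalence: float = 0.3          # target positive-class fraction
    factor_loading: float = 0.5      # co-member latent correlation
    expression_scale: float = 1.0
    low_expression_fraction: float = 0.05
    reaction_fraction: tuple[float, float] = (0.3, 0.5)
    n_tissues: int = 4
    n_future_cell_lines: int = 0
    seed: int = 0


@dataclass
class SyntheticTruth:
    """What was planted: per target gene, its driver pathway and the reaction
    partners whose expression drives the dependency."""

    drivers: dict[str, str]
    partners: dict[str, list[str]]


@dataclass
class SyntheticCohort:
    hierarchy: PathwayHierarchy
    reactions: ReactionSet
    dataset: CohortDataset
    truth: SyntheticTruth
    config: GeneratorConfig
    future_dataset: CohortDataset | None = None
    gene_sets: dict[str, set[str]] = field(default_factory=dict)
    edges: set[tuple[str, str]] = field(default_factory=set)


# ---------------------------------------------------------------------------
# hierarchy


def _level_counts(n_pathways: int, n_levels: int) -> list[int]:
    """Pathways per level (index 0 = leaves), single root at the top, counts
    roughly halving per level."""
    if n_levels < 2:
        raise ConfigurationError("need at least two levels")
    if n_pathways < n_levels:
        raise ConfigurationError("need at least one pathway per level")
    weights = np.array([2.0 ** (n_levels - 1 - ell) for ell in range(1, n_levels)])
    rest = n_pathways - 1
    counts = np.maximum(1, np.floor(rest * weights / weights.sum()).astype(int))
    # fix rounding so the total matches, never dropping a level below 1
    while counts.sum() > rest:
        counts[np.argmax(counts)] -= 1
    while counts.sum() < rest:
        counts[0] += 1
    for ell in range(1, len(counts)):
        if counts[ell] > counts[ell - 1]:
            raise ConfigurationError("level sizes must not grow toward the root")
    return list(counts) + [1]


def generate_hierarchy(config: GeneratorConfig
                       ) -> tuple[PathwayHierarchy, ReactionSet, SyntheticTruth,
                                  dict[str, set[str]], set[tuple[str, str]]]:
    """Random layered DAG with gene memberships, reaction subsets and the
    planted target/driver assignment."""
    rng = np.random.default_rng(config.seed)
    lo, hi = config.pathway_size_range
    if lo < 2 or hi < lo:
        raise ConfigurationError("invalid pathway size range")
    counts = _level_counts(config.n_pathways, config.n_levels)
    n_leaves = counts[0]
    if n_leaves * hi < config.n_genes:
        raise ConfigurationError(
            f"{n_leaves} leaves of at most {hi} genes cannot cover "
            f"{config.n_genes} genes")

    genes = [f"G{idx:04d}" for idx in range(config.n_genes)]

    # leaf sizes within range, total at least n_genes so every gene has a home
    sizes = rng.integers(lo, hi + 1, size=n_leaves)
    while sizes.sum() < config.n_genes:
        grow = rng.integers(n_leaves)
        if sizes[grow] < hi:
            sizes[grow] += 1

    leaf_ids = [f"P1_{idx:03d}" for idx in range(n_leaves)]
    slot_owner = np.repeat(np.arange(n_leaves), sizes)
    rng.shuffle(slot_owner)
    shuffled = [str(g) for g in rng.permutation(genes)]
    leaf_genes: dict[str, set[str]] = {pid: set() for pid in leaf_ids}
    primary: dict[str, str] = {}
    for slot, owner in enumerate(slot_owner):
        pid = leaf_ids[owner]
        if slot < config.n_genes:
            g = shuffled[slot]
            leaf_genes[pid].add(g)
            primary[g] = pid
        else:  # overlap slots: duplicate membership of a random other gene
            cands = [g for g in genes if g not in leaf_genes[pid]]
            if cands:
                leaf_genes[pid].add(cands[rng.integers(len(cands))])

    # targets: one per driver leaf, then planted into extra leaves by swapping
    # out an existing member (sizes stay fixed)
    if config.n_target_genes > n_leaves:
        raise ConfigurationError("more target genes than leaf pathways")
    driver_leaves = [str(p) for p in rng.choice(leaf_ids,
                                                size=config.n_target_genes,
                                                replace=False)]
    drivers: dict[str, str] = {}
    for pid in driver_leaves:
        members = sorted(leaf_genes[pid] - set(drivers))
        target = str(members[rng.integers(len(members))])
        drivers[target] = pid
    for target, driver in drivers.items():
        others = [pid for pid in leaf_ids
                  if pid != driver and target not in leaf_genes[pid]]
        n_extra = min(config.target_extra_pathways, len(others))
        for pid in (str(p) for p in rng.choice(others, size=n_extra,
                                               replace=False)):
            swappable = sorted(leaf_genes[pid] - set(drivers))
            if swappable:
                leaf_genes[pid].discard(swappable[rng.integers(len(swappable))])
            leaf_genes[pid].add(target)

    # reaction subsets: 30-50% of each leaf's members; a driver leaf's
    # reaction always contains its target so partners are well defined
    frac_lo, frac_hi = config.reaction_fraction
    reactions: dict[str, set[str]] = {}
    partners: dict[str, list[str]] = {}
    for pid in leaf_ids:
        members = sorted(leaf_genes[pid])
        size = max(2, int(round(rng.uniform(frac_lo, frac_hi) * len(members))))
        chosen = set(rng.choice(members, size=min(size, len(members)),
                                replace=False))
        for target, driver in drivers.items():
            if pid == driver:
                chosen.add(target)
                while len(chosen) < 3:  # at least two partners
                    extra = [g for g in members if g not in chosen]
                    if not extra:
                        break
                    chosen.add(extra[rng.integers(len(extra))])
        reactions[f"RXN_{pid}"] = chosen
    for target, driver in drivers.items():
        partners[target] = sorted(reactions[f"RXN_{driver}"] - {target})

    # interior levels: group children under parents, genes = union of children
    gene_sets: dict[str, set[str]] = dict(leaf_genes)
    edges: set[tuple[str, str]] = set()
    below = leaf_ids
    for level in range(2, config.n_levels + 1):
        n_here = counts[level - 1]
        ids = [f"P{level}_{idx:03d}" for idx in range(n_here)]
        assignment = rng.integers(n_here, size=len(below))
        assignment[:n_here] = np.arange(n_here)  # every parent gets a child
        for child, parent_idx in zip(below, assignment):
            parent = ids[parent_idx]
            edges.add((child, parent))
        for idx, pid in enumerate(ids):
            gene_sets[pid] = set().union(
                *(gene_sets[c] for c, p in edges if p == pid))
        below = ids

    hierarchy = build_hierarchy(gene_sets, edges)
    truth = SyntheticTruth(drivers=drivers, partners=partners)
    return hierarchy, ReactionSet(reactions), truth, gene_sets, edges


# ---------------------------------------------------------------------------
# cohort


def _softplus(x: np.ndarray) -> np.ndarray:
    return np.maximum(x, 0.0) + np.log1p(np.exp(-np.abs(x)))


def generate_cohort(hierarchy: PathwayHierarchy,
                    reactions: ReactionSet,
                    truth: SyntheticTruth,
                    config: GeneratorConfig) -> SyntheticCohort:
    """Expression with pathway-correlated structure and dependency labels from
    the planted mechanism; optionally a second "future" cohort drawn from the
    same generative process with fresh cell lines."""
    if config.beta == 0 and config.n_target_genes:
        import warnings
        warnings.warn("beta=0 plants no signal; recovery analyses will be null")
    rng = np.random.default_rng(config.seed + 1)
    genes = sorted(hierarchy.gene_universe())
    leaf_ids = sorted(hierarchy.leaves())
    leaf_pos = {pid: i for i, pid in enumerate(leaf_ids)}

    # a gene's latent factor comes from its smallest containing leaf
    gene_leaf = {}
    for g in genes:
        containing = [pid for pid in leaf_ids
                      if g in hierarchy.pathways[pid].genes]
        containing.sort(key=lambda pid: (len(hierarchy.pathways[pid].genes), pid))
        gene_leaf[g] = containing[0]

    protected = set(truth.drivers)
    for plist in truth.partners.values():
        protected |= set(plist)
    unprotected = [g for g in genes if g not in protected]
    n_low = int(round(config.low_expression_fraction * len(genes)))
    low_genes = set(rng.choice(unprotected, size=min(n_low, len(unprotected)),
                               replace=False))
    mu = {g: (rng.normal(-2.0, 0.5) if g in low_genes else rng.normal(2.5, 1.0))
          for g in genes}

    def draw_cohort(m: int, prefix: str, cohort_rng: np.random.Generator):
        factors = cohort_rng.normal(size=(m, len(leaf_ids)))
        rho = config.factor_loading
        latent = np.empty((m, len(genes)))
        for gi, g in enumerate(genes):
            eps = cohort_rng.normal(size=m)
            latent[:, gi] = (np.sqrt(rho) * factors[:, leaf_pos[gene_leaf[g]]]
                             + np.sqrt(1.0 - rho) * eps)
        expr = _softplus(np.array([mu[g] for g in genes])
                         + config.expression_scale * latent)
        lines = [f"{prefix}{i:04d}" for i in range(m)]
        expression = pd.DataFrame(expr, index=lines, columns=genes)

        gene_idx = {g: i for i, g in enumerate(genes)}
        dep = {}
        for target in sorted(truth.drivers):
            cols = [gene_idx[g] for g in truth.partners[target]]
            signal = latent[:, cols].mean(axis=1)
            signal = (signal - signal.mean()) / (signal.std() or 1.0)
            threshold = np.quantile(signal, 1.0 - config.prevalence)
            logits = config.beta * (signal - threshold) \
                + config.label_noise * cohort_rng.normal(size=m)
            dep[target] = 1.0 / (1.0 + np.exp(-logits))
        dependency = pd.DataFrame(dep, index=lines)

        tissue_labels = KMeans(n_clusters=min(config.n_tissues, m),
                               random_state=config.seed, n_init=4
                               ).fit_predict(factors)
        tissues = {cl: f"tissue_{t}" for cl, t in zip(lines, tissue_labels)}
        return expression, dependency, tissues

    expression, dependency, tissues = draw_cohort(
        config.n_cell_lines, "CL", rng)
    dataset = build_cohort(expression, dependency, tissues, hierarchy)

    future = None
    if config.n_future_cell_lines:
        f_expr, f_dep, f_tissues = draw_cohort(
            config.n_future_cell_lines, "FUT",
            np.random.default_rng(config.seed + 2))
        future = CohortDataset(
            expression=f_expr[dataset.feature_genes],
            dependency=f_dep[dataset.target_genes],
            tissues=f_tissues,
            feature_genes=dataset.feature_genes,
            target_genes=dataset.target_genes,
        )
    return SyntheticCohort(hierarchy=hierarchy, reactions=reactions,
                           dataset=dataset, truth=truth, config=config,
                           future_dataset=future)


def generate(config: GeneratorConfig | None = None) -> SyntheticCohort:
    """One-call generator: hierarchy, reactions, planted truth and cohort."""
    config = config or GeneratorConfig()
    hierarchy, reactions, truth, gene_sets, edges = generate_hierarchy(config)
    cohort = generate_cohort(hierarchy, reactions, truth, config)
    cohort.gene_sets = gene_sets
    cohort.edges = edges
    return cohort


# ---------------------------------------------------------------------------
# on-disk fixture emission (CLI `simulate`)


def write_fixture(cohort: SyntheticCohort, outdir: str | Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_gmt(outdir / "pathways.gmt", cohort.gene_sets)
    write_hierarchy(outdir / "hierarchy.tsv", cohort.edges)
    write_reactions(outdir / "reactions.tsv", cohort.reactions)
    cohort.dataset.expression.to_csv(outdir / "expression.csv")
    cohort.dataset.dependency.to_csv(outdir / "dependency.csv")
    with open(outdir / "tissues.tsv", "w") as fh:
        for cl, t in cohort.dataset.tissues.items():
            fh.write(f"{cl}\t{t}\n")
    manifest = {
        "config": asdict(cohort.config),
        "drivers": cohort.truth.drivers,
        "partners": cohort.truth.partners,
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
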