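"""Compile a pathway hierarchy into the sparse visible neural network.

Each pathway becomes one block whose state size grows with the pathway's gene
count, ``s_o = max(10, ceil(0.3 * n_genes))`` — representations of larger
pathways are allotted more neurons, with a floor of 10 (pathways under 34
genes).  Leaf (childless) pathways read the masked-expression entries of
their member feature genes plus the deletion-status bits of their member
target genes; interior pathways read the concatenated states of their
children.  Connectivity strictly follows the hierarchy, so a gene outside a
pathway's subtree can never influence that pathway's state.
"""

from __future__ import annotations

import math
from typing import Sequence

import numpy as np

from .errors import ConfigurationError
from .network import BlockSpec, SparseNet, mish  # noqa: F401  (mish re-exported)
from .ontology import PathwayHierarchy

MIN_STATE_SIZE = 10
STATE_SIZE_FACTOR = 0.3


def block_output_size(n_genes: int) -> int:
    """State size of a pathway block: max(10, ceil(0.3 * n_genes))."""
    return max(MIN_STATE_SIZE, math.ceil(STATE_SIZE_FACTOR * n_genes))


def leaf_input_indices(pathway_genes: set[str],
                       feature_genes: Sequence[str],
                       target_genes: Sequence[str]) -> np.ndarray:
    """Input columns a leaf block reads: member feature genes' (masked)
    expression entries, then member target genes' deletion bits."""
    k = len(feature_genes)
    feat_pos = {g: i for i, g in enumerate(feature_genes)}
    targ_pos = {g: i for i, g in enumerate(target_genes)}
    idx = [feat_pos[g] for g in sorted(pathway_genes) if g in feat_pos]
    idx += [k + targ_pos[g] for g in sorted(pathway_genes) if g in targ_pos]
    return np.asarray(idx, dtype=np.int64)


def compile_model(hierarchy: PathwayHierarchy,
                  feature_genes: Sequence[str],
                  target_genes: Sequence[str],
                  seed: int = 0,
                  alpha: float = 0.3,
                  lam: float = 1.0,
                  dropout_p: float = 0.5) -> SparseNet:
    """Build the sparse network whose blocks mirror the pathway hierarchy."""
    if not hierarchy.pathways:
        raise ConfigurationError("empty hierarchy")
    feature_genes = [g.upper() for g in feature_genes]
    target_genes = [g.upper() for g in target_genes]
    k, n = len(feature_genes), len(target_genes)

    specs: list[BlockSpec] = []
    for pid in hierarchy.topological_order():
        p = hierarchy.pathways[pid]
        out_size = block_output_size(len(p.genes))
        if p.children:
            spec = BlockSpec(name=pid, out_size=out_size,
                             level=hierarchy.levels[pid],
                             children=sorted(p.children))
        else:
            idx = leaf_input_indices(p.genes, feature_genes, target_genes)
            if len(idx) == 0:
                raise ConfigurationError(
                    f"leaf pathway {pid!r} has no feature or target gene members")
            spec = BlockSpec(name=pid, out_size=out_size,
                             level=hierarchy.levels[pid], x_indices=idx)
        specs.append(spec)

    net = SparseNet(specs, root=hierarchy.root, n_inputs=k + n,
                    alpha=alpha, lam=lam, dropout_p=dropout_p, seed=seed,
                    fingerprint_extra="biovnn:" + hierarchy.fingerprint())
    return net


def pathway_gene_input_columns(net: SparseNet,
                               pathway_id: str,
                               feature_genes: Sequence[str]) -> dict[str, int]:
    """For a leaf block: map member feature gene -> column of W reading its
    expression entry (used by feature-importance analysis)."""
    spec = net.by_name[pathway_id]
    if not spec.reads_input:
        raise ValueError(f"{pathway_id!r} is not a leaf-level block")
    k = len(feature_genes)
    out = {}
    for col, xi in enumerate(spec.x_indices):
        if xi < k:
            out[feature_genes[xi]] = col
    return out
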