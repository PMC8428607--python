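"""Shared fixtures: a hand-checkable toy hierarchy and small synthetic cohorts.

The toy mirrors the canonical example diagram: four leaf pathways, two
mid-level parents, one of which is wrapped once more before reaching the
root, so levels 1..4 and a multi-level skip (P7 at level 2 feeding the level-4
root) are all exercised.
"""

import numpy as np
import pandas as pd
import pytest

from biovnn import synthetic
from biovnn.data import CohortDataset
from biovnn.model import compile_model
from biovnn.ontology import build_hierarchy


TOY_GENE_SETS = {
    "P1": {"G1", "G2", "G3", "G7"},
    "P2": {"G4", "G5"},
    "P3": {"G3", "G6"},
    "P4": {"G3", "G7"},
    "P7": {"G1", "G2", "G3", "G4", "G5", "G7"},
    "P6": {"G3", "G6", "G7"},
    "P5": {"G3", "G6", "G7"},
    "R": {"G1", "G2", "G3", "G4", "G5", "G6", "G7"},
}

TOY_EDGES = {
    ("P1", "P7"), ("P2", "P7"),
    ("P3", "P6"), ("P4", "P6"),
    ("P6", "P5"),
    ("P7", "R"), ("P5", "R"),
}

TOY_FEATURE_GENES = ["G1", "G2", "G3", "G4", "G5", "G6", "G7"]
TOY_TARGET_GENES = ["G2", "G5"]


@pytest.fixture(scope="session")
def toy_hierarchy():
    return build_hierarchy(TOY_GENE_SETS, TOY_EDGES)


@pytest.fixture()
def toy_net(toy_hierarchy):
    return compile_model(toy_hierarchy, TOY_FEATURE_GENES, TOY_TARGET_GENES,
                         seed=0)


def make_toy_dataset(m: int = 40, seed: int = 0) -> CohortDataset:
    """Random cohort over the toy genes with both label classes present."""
    rng = np.random.default_rng(seed)
    lines = [f"CL{i}" for i in range(m)]
    expr = pd.DataFrame(rng.normal(3.0, 1.0, size=(m, len(TOY_FEATURE_GENES))),
                        index=lines, columns=TOY_FEATURE_GENES)
    dep = pd.DataFrame(rng.uniform(0, 1, size=(m, len(TOY_TARGET_GENES))),
                       index=lines, columns=TOY_TARGET_GENES)
    # guarantee >= 6 positives and negatives per target
    dep.iloc[:8] = 0.9
    dep.iloc[8:16] = 0.1
    tissues = {cl: f"T{i % 2}" for i, cl in enumerate(lines)}
    return CohortDataset(expression=expr, dependency=dep, tissues=tissues,
                         feature_genes=TOY_FEATURE_GENES,
                         target_genes=TOY_TARGET_GENES)


@pytest.fixture(scope="session")
def toy_dataset():
    return make_toy_dataset()


# A reduced-size planted cohort for unit tests of training/interpretability
# plumbing (the acceptance tests use the generator defaults).
SMALL_CONFIG = synthetic.GeneratorConfig(
    n_genes=60, n_pathways=10, n_levels=3, n_cell_lines=80,
    n_target_genes=3, target_extra_pathways=2, seed=7)


@pytest.fixture(scope="session")
def small_cohort():
    return synthetic.generate(SMALL_CONFIG)
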