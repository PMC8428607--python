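"""Feature/target selection, masks, z-scoring, sample assembly and folds."""

import numpy as np
import pandas as pd
import pytest

from biovnn.data import (CohortDataset, apply_zscore, assemble_batch,
                         assemble_sample, build_cohort, build_feature_mask,
                         build_feature_masks, filter_feature_genes,
                         fold_class_balance, read_matrix, select_target_genes,
                         stratified_folds, training_statistics,
                         zscore_by_training)
from biovnn.errors import ConfigurationError, MaskError
from biovnn.ontology import build_hierarchy

from conftest import (TOY_FEATURE_GENES, TOY_TARGET_GENES, make_toy_dataset,
                      toy_hierarchy)


# ---------------------------------------------------------------------------
# i/o


def test_read_matrix_csv_and_tsv(tmp_path):
    csv = tmp_path / "m.csv"
    csv.write_text("id,braf,KRAS\nCL1,1.5,0\nCL2,2.5,3\n")
    df = read_matrix(csv)
    assert list(df.columns) == ["BRAF", "KRAS"]
    assert df.loc["CL2", "KRAS"] == 3.0

    tsv = tmp_path / "m.tsv"
    tsv.write_text("id\tG1\nCL1\t1.0\n")
    assert read_matrix(tsv).loc["CL1", "G1"] == 1.0


# ---------------------------------------------------------------------------
# gene selection


def test_filter_feature_genes_threshold():
    # 100 lines -> a gene must exceed 1.0 in at least ceil(0.01*100)=1 line
    m = 100
    expr = pd.DataFrame(0.0, index=[f"CL{i}" for i in range(m)],
                        columns=["G1", "G2", "G3"])
    expr.loc["CL0", "G1"] = 1.5          # passes
    expr.loc["CL0", "G2"] = 1.0          # not strictly above 1.0
    expr.loc["CL0", "G3"] = 5.0          # passes but not in ontology
    genes = filter_feature_genes(expr, {"G1", "G2"})
    assert genes == ["G1"]


def test_filter_feature_genes_fraction_scales():
    # 200 lines -> need ceil(2) = 2 lines above threshold
    m = 200
    expr = pd.DataFrame(0.0, index=[f"CL{i}" for i in range(m)],
                        columns=["G1", "G2"])
    expr.loc["CL0", "G1"] = 2.0
    expr.loc[["CL0", "CL1"], "G2"] = 2.0
    assert filter_feature_genes(expr, {"G1", "G2"}) == ["G2"]


def test_filter_feature_genes_empty_raises():
    expr = pd.DataFrame(0.0, index=["CL0"], columns=["G1"])
    with pytest.raises(ConfigurationError):
        filter_feature_genes(expr, {"G1"})


def test_select_target_genes_minimum_counts():
    m = 20
    dep = pd.DataFrame(0.0, index=[f"CL{i}" for i in range(m)],
                       columns=["OK", "FEWPOS", "FEWNEG", "OUT"])
    dep.iloc[:6, 0] = 0.9       # 6 pos, 14 neg -> kept
    dep.iloc[:5, 1] = 0.9       # 5 pos -> dropped
    dep.iloc[:15, 2] = 0.9      # 5 neg -> dropped
    dep.iloc[:10, 3] = 0.9      # fine but not in ontology
    out = select_target_genes(dep, {"OK", "FEWPOS", "FEWNEG"})
    assert out == ["OK"]


def test_select_target_genes_druggable_filter():
    dep = pd.DataFrame(0.0, index=[f"CL{i}" for i in range(20)],
                       columns=["A", "B"])
    dep.iloc[:8, :] = 0.9
    assert select_target_genes(dep, {"A", "B"}, druggable={"B"}) == ["B"]


# ---------------------------------------------------------------------------
# feature masks


def big_hierarchy(n_genes=150):
    genes = {f"G{i:03d}" for i in range(n_genes)}
    return build_hierarchy({"BIG": genes}, set()), sorted(genes)


def test_mask_cap_100():
    hier, genes = big_hierarchy(150)
    mask = build_feature_mask("G000", hier, genes)
    assert int(mask.sum()) == 100
    # truncation keeps the alphabetically first symbols of the pathway
    kept = {g for g, bit in zip(genes, mask) if bit}
    assert kept == set(sorted(genes)[:100])


def test_mask_exhaustion_below_cap():
    hier, genes = big_hierarchy(40)
    mask = build_feature_mask("G000", hier, genes)
    assert int(mask.sum()) == 40


def test_mask_smallest_pathway_first():
    sets = {
        "SMALL": {"T", "A", "B"},
        "BIG": {"T", "C", "D", "E", "F"},
        "TOP": {"T", "A", "B", "C", "D", "E", "F"},
    }
    hier = build_hierarchy(sets, {("SMALL", "TOP"), ("BIG", "TOP")})
    feature_genes = sorted(hier.gene_universe())
    mask = build_feature_mask("T", hier, feature_genes, cap=4)
    kept = {g for g, bit in zip(feature_genes, mask) if bit}
    # SMALL's members enter first; one slot remains for BIG's sorted genes
    assert {"A", "B", "T"} <= kept
    assert kept == {"A", "B", "T", "C"}


def test_mask_unmapped_target():
    hier, genes = big_hierarchy(10)
    with pytest.raises(MaskError):
        build_feature_mask("NOT_A_GENE", hier, genes)
    fm = build_feature_masks(["NOT_A_GENE"], hier, genes, allow_unmapped=True)
    assert fm.matrix.sum() == 0


def test_feature_masks_stacking(toy_hierarchy):
    fm = build_feature_masks(TOY_TARGET_GENES, toy_hierarchy,
                             TOY_FEATURE_GENES)
    assert fm.matrix.shape == (2, 7)
    # G2 sits in P1 (smallest containing pathway): G1,G2,G3,G7 selected first
    g2 = {g for g, bit in zip(TOY_FEATURE_GENES, fm.vector("G2")) if bit}
    assert {"G1", "G2", "G3", "G7"} <= g2


# ---------------------------------------------------------------------------
# z-scoring


def test_zscore_uses_training_stats_only():
    expr = pd.DataFrame({"G1": [1.0, 3.0, 100.0], "G2": [5.0, 5.0, 9.0]},
                        index=["A", "B", "C"])
    z = zscore_by_training(expr, ["A", "B"])
    # train mean 2, population sd 1 -> A=-1, B=1, C=98
    assert np.allclose(z["G1"], [-1.0, 1.0, 98.0])
    # zero variance in training -> all zeros
    assert np.allclose(z["G2"], 0.0)


def test_zscore_population_sd():
    expr = pd.DataFrame({"G1": [0.0, 2.0, 4.0, 6.0]},
                        index=list("ABCD"))
    mean, sd = training_statistics(expr, list("ABCD"))
    assert mean[0] == 3.0
    assert sd[0] == pytest.approx(np.sqrt(5.0))  # ddof=0


def test_zscore_empty_training_raises():
    expr = pd.DataFrame({"G1": [1.0]}, index=["A"])
    with pytest.raises(ConfigurationError):
        zscore_by_training(expr, [])


# ---------------------------------------------------------------------------
# sample assembly


def test_assemble_sample_layout(toy_hierarchy):
    ds = make_toy_dataset()
    fm = build_feature_masks(ds.target_genes, toy_hierarchy, ds.feature_genes)
    z = zscore_by_training(ds.expression, ds.cell_lines)
    x, y = assemble_sample("CL0", "G5", z, ds, fm)
    k = len(ds.feature_genes)
    assert x.shape == (k + len(ds.target_genes),)
    # one-hot marks G5 (index 1 of target genes)
    assert x[k] == 0.0 and x[k + 1] == 1.0
    # expression entries outside the mask are zeroed
    expected = z.loc["CL0"].to_numpy() * fm.vector("G5")
    assert np.allclose(x[:k], expected)
    assert y == int(ds.labels.loc["CL0", "G5"])


def test_assemble_batch_matches_single(toy_hierarchy):
    ds = make_toy_dataset()
    fm = build_feature_masks(ds.target_genes, toy_hierarchy, ds.feature_genes)
    z = zscore_by_training(ds.expression, ds.cell_lines)
    X = assemble_batch(z.to_numpy(), np.array([0, 3]), np.array([1, 0]), fm,
                       len(ds.target_genes))
    x0, _ = assemble_sample("CL0", "G5", z, ds, fm)
    x1, _ = assemble_sample("CL3", "G2", z, ds, fm)
    assert np.allclose(X[0], x0)
    assert np.allclose(X[1], x1)


# ---------------------------------------------------------------------------
# fold splits


def hundred_line_dataset(n_tissues=4, seed=0):
    rng = np.random.default_rng(seed)
    m = 100
    lines = [f"CL{i:03d}" for i in range(m)]
    expr = pd.DataFrame(rng.normal(2, 1, size=(m, 3)), index=lines,
                        columns=["G1", "G2", "G3"])
    dep = pd.DataFrame(rng.uniform(0, 1, size=(m, 2)), index=lines,
                       columns=["G1", "G2"])
    tissues = {cl: f"T{i % n_tissues}" for i, cl in enumerate(lines)}
    return CohortDataset(expression=expr, dependency=dep, tissues=tissues,
                         feature_genes=["G1", "G2", "G3"],
                         target_genes=["G1", "G2"])


def test_fold_ratios_on_100_lines():
    ds = hundred_line_dataset()
    split = stratified_folds(ds, seed=0)
    assert [len(f) for f in split.folds] == [20] * 5
    for a in split:
        assert len(a["test"]) == 20
        assert len(a["validation"]) == 16
        assert len(a["train"]) == 64
        assert not set(a["train"]) & set(a["validation"])
        assert not set(a["train"]) & set(a["test"])
        assert not set(a["validation"]) & set(a["test"])
    # every line is tested exactly once
    tested = [cl for a in split for cl in a["test"]]
    assert sorted(tested) == sorted(ds.cell_lines)


def test_small_tissue_spread_across_folds():
    ds = hundred_line_dataset()
    # add a 5-line tissue
    for i, cl in enumerate(ds.cell_lines[:5]):
        ds.tissues[cl] = "RARE"
    for cl in ds.cell_lines[5:]:
        ds.tissues[cl] = "COMMON"
    split = stratified_folds(ds, seed=3)
    rare = {cl for cl in ds.cell_lines if ds.tissues[cl] == "RARE"}
    counts = [len(rare & set(f)) for f in split.folds]
    assert counts == [1] * 5


def test_fold_class_balance_spread():
    # half the lines are fully dependent, half fully non-dependent: every
    # fold should receive close to half of each
    rng = np.random.default_rng(1)
    m = 100
    lines = [f"CL{i:03d}" for i in range(m)]
    expr = pd.DataFrame(rng.normal(2, 1, size=(m, 3)), index=lines,
                        columns=["G1", "G2", "G3"])
    dep = pd.DataFrame(0.1, index=lines, columns=["G1", "G2"])
    dep.iloc[:50] = 0.9
    tissues = {cl: f"T{i % 2}" for i, cl in enumerate(lines)}
    ds = CohortDataset(expression=expr, dependency=dep, tissues=tissues,
                       feature_genes=["G1", "G2", "G3"],
                       target_genes=["G1", "G2"])
    split = stratified_folds(ds, seed=0)
    balance = fold_class_balance(ds, split)
    assert max(balance) - min(balance) <= 0.1


def test_split_determinism():
    ds = hundred_line_dataset()
    s1 = stratified_folds(ds, seed=5)
    s2 = stratified_folds(ds, seed=5)
    s3 = stratified_folds(ds, seed=6)
    assert s1.folds == s2.folds
    assert s1.folds != s3.folds


def test_too_few_lines_raises():
    ds = make_toy_dataset(m=40)
    with pytest.raises(ConfigurationError):
        stratified_folds(ds, n_folds=41)


# ---------------------------------------------------------------------------
# cohort assembly


def test_build_cohort_aligns_and_filters(toy_hierarchy):
    rng = np.random.default_rng(0)
    lines = [f"CL{i}" for i in range(30)]
    expr = pd.DataFrame(rng.normal(3, 1, size=(30, 7)), index=lines,
                        columns=TOY_FEATURE_GENES)
    dep = pd.DataFrame(rng.uniform(0, 1, size=(31, 2)),
                       index=lines + ["EXTRA"], columns=["G2", "G5"])
    ds = build_cohort(expr, dep, None, toy_hierarchy)
    assert ds.cell_lines == lines            # intersection only
    assert set(ds.target_genes) <= {"G2", "G5"}
    assert set(ds.feature_genes) <= set(TOY_FEATURE_GENES)


def test_cohort_rejects_nan():
    expr = pd.DataFrame({"G1": [1.0, np.nan]}, index=["A", "B"])
    dep = pd.DataFrame({"G1": [0.9, 0.1]}, index=["A", "B"])
    with pytest.raises(ConfigurationError):
        CohortDataset(expression=expr, dependency=dep, tissues={},
                      feature_genes=["G1"], target_genes=["G1"])


def test_labels_binarized_at_half():
    expr = pd.DataFrame({"G1": [1.0, 2.0]}, index=["A", "B"])
    dep = pd.DataFrame({"G1": [0.5, 0.4999]}, index=["A", "B"])
    ds = CohortDataset(expression=expr, dependency=dep, tissues={},
                       feature_genes=["G1"], target_genes=["G1"])
    assert ds.labels["G1"].tolist() == [1, 0]
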