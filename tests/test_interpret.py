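"""Interpretability: multiple-testing and hypergeometric primitives against
closed-form oracles, PCA/separation machinery, feature importances and the
dense-model pathway-recovery analysis."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from biovnn.baselines import build_matched_fcn
from biovnn.data import apply_zscore, build_feature_masks, training_statistics
from biovnn.errors import DegenerateInputError, UndefinedMetricError
from biovnn.interpret import (bh_adjust, class_separation_test,
                              cluster_pathway_overlap, explain_prediction,
                              extract_states, fcn_weight_clustering,
                              feature_importance, hypergeom_tail,
                              partner_enrichment_test, pathway_pca,
                              reaction_enrichment,
                              related_separation_analysis,
                              related_vs_unrelated, separation_table)
from biovnn.model import compile_model
from biovnn.training import TrainingConfig, run_single_fold


# ---------------------------------------------------------------------------
# primitives against closed-form references


def manual_bh(pvalues):
    """Textbook Benjamini-Hochberg: sort, scale by m/rank, enforce
    monotonicity from the largest p downwards."""
    p = np.asarray(pvalues, dtype=float)
    m = len(p)
    order = np.argsort(p)
    scaled = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(scaled[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adjusted, 1.0)
    return out


def test_bh_adjust_matches_manual_reference():
    p = [0.001, 0.008, 0.039, 0.041, 0.042, 0.06, 0.074, 0.205, 0.5, 0.99]
    assert np.allclose(bh_adjust(p), manual_bh(p), atol=1e-12)
    # permutation invariance of the correspondence
    rng = np.random.default_rng(3)
    p2 = rng.uniform(size=25)
    assert np.allclose(bh_adjust(p2), manual_bh(p2), atol=1e-12)


def test_bh_adjust_edge_cases():
    assert len(bh_adjust([])) == 0
    assert bh_adjust([0.04])[0] == pytest.approx(0.04)
    # all-equal p-values stay equal
    assert np.allclose(bh_adjust([0.2, 0.2, 0.2]), 0.2)


def test_hypergeom_tail_matches_combinatorial_sum():
    """P(X >= 5) for a 10-gene group against a 10-gene pathway in a
    100-gene universe, summed directly from binomial coefficients."""
    overlap, group, pathway, universe = 5, 10, 10, 100
    expected = sum(math.comb(pathway, k) * math.comb(universe - pathway,
                                                     group - k)
                   for k in range(overlap, min(group, pathway) + 1)
                   ) / math.comb(universe, group)
    assert hypergeom_tail(overlap, group, pathway, universe) == \
        pytest.approx(expected, rel=1e-12)


def test_hypergeom_tail_degenerate_values():
    assert hypergeom_tail(0, 5, 5, 50) == pytest.approx(1.0)
    # overlap larger than either set is impossible
    assert hypergeom_tail(6, 5, 5, 50) == pytest.approx(0.0, abs=1e-15)


# ---------------------------------------------------------------------------
# PCA and class separation


def test_pathway_pca_matches_eigendecomposition():
    rng = np.random.default_rng(0)
    X = rng.normal(size=(12, 4))
    scores = pathway_pca(X)
    Xc = X - X.mean(axis=0)
    cov = Xc.T @ Xc / (len(X) - 1)
    evals, evecs = np.linalg.eigh(cov)
    # largest two eigenpairs; PCA scores match projections up to sign
    for c, idx in enumerate((-1, -2)):
        proj = Xc @ evecs[:, idx]
        assert np.allclose(np.abs(scores[:, c]), np.abs(proj), atol=1e-10)
        assert scores[:, c].var(ddof=1) == pytest.approx(evals[idx])


def test_pathway_pca_rejects_degenerate_input():
    with pytest.raises(DegenerateInputError):
        pathway_pca(np.ones((2, 4)))
    with pytest.raises(DegenerateInputError):
        pathway_pca(np.random.default_rng(0).normal(size=(5, 1)))
    with pytest.raises(DegenerateInputError):
        pathway_pca(np.ones((6, 4)))


def test_class_separation_fisher_combination():
    rng = np.random.default_rng(1)
    labels = np.array([1] * 10 + [0] * 10)
    pcs = rng.normal(size=(20, 2))
    pcs[labels == 1, 0] += 3.0          # PC1 separates strongly
    res = class_separation_test(pcs, labels, "P1", "G1", related=True)
    p1 = sps.mannwhitneyu(pcs[labels == 1, 0], pcs[labels == 0, 0],
                          alternative="two-sided").pvalue
    p2 = sps.mannwhitneyu(pcs[labels == 1, 1], pcs[labels == 0, 1],
                          alternative="two-sided").pvalue
    assert res.p_pc1 == pytest.approx(float(p1))
    assert res.p_pc2 == pytest.approx(float(p2))
    chi2 = -2 * (np.log(p1) + np.log(p2))
    assert res.combined_p == pytest.approx(float(sps.chi2.sf(chi2, 4)))
    assert res.score == pytest.approx(-np.log10(res.combined_p))
    assert res.p_pc1 < 0.01 and res.related


def test_class_separation_needs_both_classes():
    pcs = np.random.default_rng(0).normal(size=(6, 2))
    with pytest.raises(UndefinedMetricError):
        class_separation_test(pcs, np.ones(6))
    with pytest.raises(UndefinedMetricError):
        class_separation_test(pcs, np.array([1, 0, 0, 0, 0, 0]))


def test_related_vs_unrelated_on_constructed_frame():
    sep = pd.DataFrame({
        "related": [True] * 6 + [False] * 10,
        "score": [5.0, 4.0, 4.5, 3.8, 6.0, 5.5] + [0.5] * 10,
    })
    p = related_vs_unrelated(sep)
    expected = sps.mannwhitneyu(sep.loc[sep.related, "score"],
                                sep.loc[~sep.related, "score"],
                                alternative="greater").pvalue
    assert p == pytest.approx(float(expected))
    assert p < 0.01
    # too few related pathways -> undefined
    with pytest.raises(UndefinedMetricError, match="related"):
        related_vs_unrelated(sep[3:])
    with pytest.raises(UndefinedMetricError, match="unrelated"):
        related_vs_unrelated(sep[sep.related])


# ---------------------------------------------------------------------------
# analyses on a trained small-cohort model


@pytest.fixture(scope="module")
def trained_small(small_cohort):
    ds, hier = small_cohort.dataset, small_cohort.hierarchy
    cfg = TrainingConfig(batch_size=32, learning_rate=3e-3, patience=8,
                         max_epochs=40, lam=1e-3, seed=0)
    result = run_single_fold("biovnn", ds, hier, cfg)
    net = result.folds[0].net
    masks = build_feature_masks(ds.target_genes, hier, ds.feature_genes)
    stats = training_statistics(ds.expression,
                                result.split.assignments[0]["train"])
    zscored = apply_zscore(ds.expression, stats).to_numpy()
    return net, masks, zscored


def test_extract_states_shapes_and_determinism(small_cohort, trained_small):
    ds, hier = small_cohort.dataset, small_cohort.hierarchy
    net, masks, zscored = trained_small
    target = ds.target_genes[0]
    a = extract_states(net, ds, masks, target, zscored)
    b = extract_states(net, ds, masks, target, zscored)
    assert a.cell_lines == ds.cell_lines
    assert set(a.states) == set(hier.pathways)
    for pid, mat in a.states.items():
        assert mat.shape[0] == ds.n_cell_lines
        assert np.array_equal(mat, b.states[pid])
    assert len(list(a.records())) == len(a.states) * ds.n_cell_lines


def test_separation_table_structure(small_cohort, trained_small):
    ds, hier = small_cohort.dataset, small_cohort.hierarchy
    net, masks, zscored = trained_small
    target = ds.target_genes[0]
    sep = separation_table(extract_states(net, ds, masks, target, zscored),
                           hier)
    assert len(sep) == len(hier.pathways)
    assert sep["related"].sum() == len(hier.pathways_of_gene(target))
    # sorted leaves -> root and BH-adjusted p >= raw p
    assert sep["level"].is_monotonic_increasing
    assert (sep["adjusted_p"] >= sep["combined_p"] - 1e-12).all()


def test_related_separation_analysis_frame(small_cohort, trained_small):
    ds, hier = small_cohort.dataset, small_cohort.hierarchy
    net, masks, zscored = trained_small
    df = related_separation_analysis(net, ds, masks, hier, zscored,
                                     min_related=2)
    assert list(df["target_gene"]) == ds.target_genes
    tested = df["p"].notna()
    assert tested.any()
    assert np.allclose(df.loc[tested, "adjusted_p"],
                       bh_adjust(df.loc[tested, "p"]))
    # with an unreachable threshold every gene is skipped, none significant
    strict = related_separation_analysis(net, ds, masks, hier, zscored,
                                         min_related=10_000)
    assert strict["p"].isna().all()
    assert not strict["significant"].any()


def test_explain_prediction_structure(small_cohort, trained_small):
    ds, hier = small_cohort.dataset, small_cohort.hierarchy
    net, masks, zscored = trained_small
    target = ds.target_genes[0]
    cl = ds.cell_lines[0]
    df = explain_prediction(net, ds, masks, hier, zscored, cl, target)
    assert set(df["pathway_id"]) <= set(hier.pathways_of_gene(target))
    assert df["level"].is_monotonic_increasing
    assert np.isfinite(df["state_z"]).all()
    assert 0.0 <= df.attrs["probability"] <= 1.0
    assert df.attrs["label"] == int(ds.labels[target].loc[cl])
    with pytest.raises(KeyError):
        explain_prediction(net, ds, masks, hier, zscored, "NOPE", target)


def test_explanation_heatmap_writes_png(small_cohort, trained_small,
                                        tmp_path):
    from biovnn.interpret import explanation_heatmap
    ds, hier = small_cohort.dataset, small_cohort.hierarchy
    net, masks, zscored = trained_small
    df = explain_prediction(net, ds, masks, hier, zscored,
                            ds.cell_lines[0], ds.target_genes[0])
    out = tmp_path / "heat.png"
    explanation_heatmap(df, str(out))
    assert out.stat().st_size > 0


# ---------------------------------------------------------------------------
# feature importance and reaction enrichment


def test_feature_importance_structure(small_cohort):
    ds, hier = small_cohort.dataset, small_cohort.hierarchy
    truth, reactions = small_cohort.truth, small_cohort.reactions
    net = compile_model(hier, ds.feature_genes, ds.target_genes, seed=0)
    target = ds.target_genes[0]
    driver = truth.drivers[target]
    df = feature_importance(net, hier, ds.feature_genes, target, driver,
                            reactions=reactions)
    members = hier.pathways[driver].genes
    assert set(df.loc[df["in_pathway"], "gene"]) <= members
    assert (df["importance"] >= 0).all()
    planted = set(truth.partners[target]) & set(df["gene"])
    assert planted <= set(df.loc[df["is_partner"], "gene"])
    with pytest.raises(ValueError, match="not a member"):
        feature_importance(net, hier, ds.feature_genes, target,
                           [p for p in hier.pathways
                            if target not in hier.pathways[p].genes][0])


def make_importance_table(n_partners, n_others, shift, seed=0):
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n_partners):
        rows.append({"gene": f"P{i}", "importance": rng.normal(1 + shift, 1),
                     "in_pathway": True, "is_partner": True})
    for i in range(n_others):
        rows.append({"gene": f"O{i}", "importance": rng.normal(1, 1),
                     "in_pathway": True, "is_partner": False})
    rows.append({"gene": "TGT", "importance": 99.0, "in_pathway": True,
                 "is_partner": False})
    df = pd.DataFrame(rows)
    df["target_gene"] = "TGT"
    df["pathway_id"] = "PW"
    return df


def test_partner_enrichment_detects_two_sigma_shift():
    table = make_importance_table(28, 49, shift=2.0)
    assert partner_enrichment_test(table) < 1e-6
    null = make_importance_table(28, 49, shift=0.0, seed=1)
    assert partner_enrichment_test(null) > 0.05


def test_partner_enrichment_excludes_target_and_checks_groups():
    # the target's huge importance must not count towards "others"
    table = make_importance_table(5, 5, shift=2.0)
    with_target = partner_enrichment_test(table)
    without = partner_enrichment_test(table[table["gene"] != "TGT"])
    assert with_target == pytest.approx(without)
    with pytest.raises(UndefinedMetricError, match="group sizes"):
        partner_enrichment_test(make_importance_table(2, 10, shift=2.0))


def test_reaction_enrichment_frame():
    tables = [make_importance_table(10, 20, shift=2.5, seed=s)
              for s in range(3)]
    small = make_importance_table(2, 20, shift=2.5, seed=9)  # skipped
    df = reaction_enrichment(tables + [small], fdr=0.1)
    assert len(df) == 4
    tested = df["p"].notna()
    assert tested.sum() == 3
    assert df.loc[~tested, "skipped"].str.contains("group sizes").all()
    assert np.allclose(df.loc[tested, "adjusted_p"],
                       bh_adjust(df.loc[tested, "p"]))
    # candidate genes are non-partner members, never the target
    for cand in df.loc[df["significant"], "candidates"]:
        genes = cand.split(",")
        assert all(g.startswith("O") for g in genes)


# ---------------------------------------------------------------------------
# dense-model pathway recovery


def test_cluster_pathway_overlap_exact_case():
    universe = {f"G{i}" for i in range(20)}
    pathways = {"A": {f"G{i}" for i in range(5)},
                "B": {f"G{i}" for i in range(5, 10)}}
    clusters = {0: {f"G{i}" for i in range(5)},       # perfect overlap with A
                1: {f"G{i}" for i in range(10, 15)}}  # no overlap
    df = cluster_pathway_overlap(clusters, pathways, universe, fdr=0.1)
    row = df[(df["cluster"] == 0) & (df["pathway_id"] == "A")].iloc[0]
    assert row["overlap"] == 5
    assert row["p"] == pytest.approx(hypergeom_tail(5, 5, 5, 20))
    assert row["p"] == pytest.approx(1 / math.comb(20, 5))
    miss = df[(df["cluster"] == 1) & (df["pathway_id"] == "A")].iloc[0]
    assert miss["overlap"] == 0 and miss["p"] == pytest.approx(1.0)
    assert row["significant"] and not miss["significant"]


def primary_leaf(hier, gene):
    containing = [p for p in hier.leaves() if gene in hier.pathways[p].genes]
    containing.sort(key=lambda p: (len(hier.pathways[p].genes), p))
    return containing[0]


def test_fcn_weight_clustering_recovers_planted_pathways(small_cohort):
    """With first-layer weight vectors hand-set so same-pathway genes are
    nearly identical, k-means recovers the leaves and beats the random-group
    null decisively."""
    ds, hier = small_cohort.dataset, small_cohort.hierarchy
    fcn = build_matched_fcn(hier, ds.feature_genes, ds.target_genes, seed=0)
    leaves = sorted(hier.leaves())
    first = fcn.specs[0].name
    W = fcn.params[f"W:{first}"]
    rng = np.random.default_rng(0)
    for i, gene in enumerate(ds.feature_genes):
        vec = np.zeros(W.shape[0])
        vec[leaves.index(primary_leaf(hier, gene)) % W.shape[0]] = 5.0
        W[:, i] = vec + rng.normal(scale=0.01, size=W.shape[0])
    result = fcn_weight_clustering(fcn, hier, ds.feature_genes, seed=0,
                                   n_null=50)
    assert result["n_clusters"] == len(leaves)
    assert result["n_significant"] >= len(leaves) - 1
    assert result["z_vs_null"] > 3
    assert len(result["overlap_table"]) == len(leaves) ** 2


def test_fcn_weight_clustering_null_behaviour(small_cohort):
    """Freshly initialized (uninformative) weights recover no more pathway
    structure than random gene groups."""
    ds, hier = small_cohort.dataset, small_cohort.hierarchy
    fcn = build_matched_fcn(hier, ds.feature_genes, ds.target_genes, seed=3)
    result = fcn_weight_clustering(fcn, hier, ds.feature_genes, seed=1,
                                   n_null=50)
    bound = result["null_mean"] + 3 * max(result["null_sd"], 0.5)
    assert result["n_significant"] <= bound
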