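"""Normalization, PCA, clustering, typing, markers, and proportions."""

import warnings

import numpy as np
import pandas as pd
import pytest

from stromastage import sc_pipeline as sc
from tests.conftest import labeling_from, make_count_matrix, make_norm


# ---------------------------------------------------------------------------
# normalize
# ---------------------------------------------------------------------------

def test_normalize_hand_arithmetic():
    nm = make_norm(np.array([[1], [3]]))
    assert nm.values[0, 0] == pytest.approx(np.log1p(2500.0))
    assert nm.values[1, 0] == pytest.approx(np.log1p(7500.0))


def test_all_zero_cell_stays_zero_with_warning():
    with pytest.warns(UserWarning, match="zero depth"):
        nm = make_norm(np.array([[1, 0], [3, 0]]))
    assert np.all(nm.values[:, 1] == 0)


def test_depth_invariance_under_doubling():
    counts = np.array([[2, 4], [6, 12]])
    nm = make_norm(counts)
    assert np.allclose(nm.values[:, 0], nm.values[:, 1])


def test_normalize_requires_positive_scale():
    cm = make_count_matrix(np.ones((2, 2), dtype=int))
    with pytest.raises(ValueError):
        sc.normalize(cm, scale=0)


# ---------------------------------------------------------------------------
# pca_embed
# ---------------------------------------------------------------------------

def test_rank_one_data_pc1_explains_everything():
    rng = np.random.default_rng(0)
    load = rng.normal(size=10)
    score = rng.normal(size=50)
    nm = make_norm(np.zeros((10, 50), dtype=int))
    nm.values = np.abs(np.outer(load, score))
    emb, evr = sc.pca_embed(nm, n_pcs=3)
    assert evr[0] > 0.999


def test_pc1_matches_closed_form_eigenvector():
    # 2-gene correlated Gaussian: leading eigenvector of the correlation
    # matrix [[1, r], [r, 1]] is (1, 1)/sqrt(2)
    rng = np.random.default_rng(1)
    z = rng.multivariate_normal([0, 0], [[1.0, 0.8], [0.8, 1.0]], size=4000)
    nm = make_norm(np.zeros((2, 4000), dtype=int))
    nm.values = np.abs(z.T)  # abs keeps values >= 0; correlation persists
    zc = (nm.values - nm.values.mean(axis=1, keepdims=True))
    zc /= zc.std(axis=1, keepdims=True)
    corr = zc @ zc.T / zc.shape[1]
    w, v = np.linalg.eigh(corr)
    lead = v[:, np.argmax(w)]
    emb, _ = sc.pca_embed(nm, n_pcs=1)
    recon = np.linalg.lstsq(zc.T, emb[:, 0], rcond=None)[0]
    recon /= np.linalg.norm(recon)
    assert abs(np.dot(recon, lead)) > 0.999


def test_permuting_cells_permutes_embedding():
    rng = np.random.default_rng(2)
    nm = make_norm(rng.integers(0, 10, size=(20, 30)))
    emb, _ = sc.pca_embed(nm, n_pcs=4)
    perm = rng.permutation(30)
    nm2 = nm.subset_cells(np.ones(30, dtype=bool))
    nm2.values = nm.values[:, perm]
    nm2.cells = [nm.cells[i] for i in perm]
    emb2, _ = sc.pca_embed(nm2, n_pcs=4)
    assert np.allclose(emb2, emb[perm], atol=1e-8)


def test_pca_rejects_too_many_components():
    nm = make_norm(np.random.default_rng(0).integers(0, 5, size=(4, 6)))
    with pytest.raises(ValueError, match="n_pcs"):
        sc.pca_embed(nm, n_pcs=10)


# ---------------------------------------------------------------------------
# cluster_cells
# ---------------------------------------------------------------------------

def _blobs(rng, centers, n_per, sd=1.0):
    pts = np.vstack([
        rng.normal(c, sd, size=(n_per, len(c))) for c in centers
    ])
    labels = np.repeat(np.arange(len(centers)), n_per)
    return pts, labels


def test_two_far_blobs_two_clusters():
    rng = np.random.default_rng(3)
    x, truth = _blobs(rng, [np.zeros(5), np.full(5, 100.0)], 30)
    lab = sc.cluster_cells(x, k_neighbors=10, resolution=1.0, seed=0)
    assert lab.n_clusters == 2
    # and no detected cluster mixes the two blobs
    df = pd.crosstab(lab.labels, truth)
    assert (df > 0).sum(axis=1).max() == 1


def test_three_blob_recovery_ari():
    rng = np.random.default_rng(4)
    centers = [np.zeros(4), np.r_[20.0, 0, 0, 0], np.r_[0, 20.0, 0, 0]]
    x, truth = _blobs(rng, centers, 100)
    lab = sc.cluster_cells(x, k_neighbors=10, resolution=0.1, seed=1)
    from sklearn.metrics import adjusted_rand_score
    assert adjusted_rand_score(truth, lab.labels) >= 0.95


def test_resolution_to_zero_gives_single_cluster():
    # two touching blobs (connected SNN graph): the resolution -> 0
    # limit collapses everything into one community
    rng = np.random.default_rng(5)
    x, _ = _blobs(rng, [np.zeros(3), np.full(3, 2.0)], 40)
    lab = sc.cluster_cells(x, k_neighbors=10, resolution=0.001, seed=0)
    assert lab.n_clusters == 1


def test_k_neighbors_must_be_less_than_cells():
    x = np.random.default_rng(0).normal(size=(10, 3))
    with pytest.raises(ValueError, match="k_neighbors"):
        sc.cluster_cells(x, k_neighbors=10)


def test_clustering_deterministic_under_seed():
    rng = np.random.default_rng(6)
    x, _ = _blobs(rng, [np.zeros(3), np.full(3, 8.0)], 50)
    a = sc.cluster_cells(x, k_neighbors=10, seed=7)
    b = sc.cluster_cells(x, k_neighbors=10, seed=7)
    assert np.array_equal(a.labels, b.labels)


# ---------------------------------------------------------------------------
# merge_indistinct_clusters
# ---------------------------------------------------------------------------

def test_merge_collapses_split_of_homogeneous_population():
    rng = np.random.default_rng(7)
    counts = rng.poisson(rng.gamma(4.0, 5.0 / 4.0, size=(100, 300)))
    nm = make_norm(counts)
    emb, _ = sc.pca_embed(nm, n_pcs=5)
    # an arbitrary split of identical cells must merge back to one
    lab = labeling_from(np.repeat([0, 1], 150))
    merged = sc.merge_indistinct_clusters(nm, lab, emb)
    assert merged.n_clusters == 1


def test_merge_keeps_clusters_with_strong_markers():
    rng = np.random.default_rng(8)
    mu = np.full((60, 200), 3.0)
    mu[:10, 100:] *= 8.0  # ten 8-fold genes in the second half
    counts = rng.poisson(rng.gamma(4.0, mu / 4.0))
    nm = make_norm(counts)
    emb, _ = sc.pca_embed(nm, n_pcs=5)
    lab = labeling_from(np.repeat([0, 1], 100))
    merged = sc.merge_indistinct_clusters(nm, lab, emb)
    assert merged.n_clusters == 2


# ---------------------------------------------------------------------------
# assign_cell_types
# ---------------------------------------------------------------------------

def _typed_norm(rng):
    # three clusters: fibroblast-high, both-ductal-high, nothing-high
    genes = ["LUM", "DCN", "COL1A1", "AMBP", "CFTR", "CEACAM5", "MUC1",
             "OTHER1", "OTHER2"]
    mu = np.full((9, 150), 1.0)
    mu[0:3, :50] = 12.0  # fibro markers in cluster 0
    mu[3:7, 50:100] = 12.0  # both ductal marker sets in cluster 1
    counts = rng.poisson(mu)
    nm = make_norm(counts, genes=genes)
    labels = np.repeat([0, 1, 2], 50)
    return nm, labeling_from(labels)


def test_marker_based_type_assignment():
    nm, lab = _typed_norm(np.random.default_rng(9))
    marker_map = {
        "Fibroblast": ["LUM", "DCN", "COL1A1"],
        "Ductal cell 1": ["AMBP", "CFTR"],
        "Ductal cell 2": ["CEACAM5", "MUC1"],
    }
    types = sc.assign_cell_types(lab, nm, marker_map)
    assert types[0] == "Fibroblast"
    assert types[1] == "Ductal cell 1 + Ductal cell 2"
    assert types[2] == "others"


def test_assign_requires_marker_map():
    nm, lab = _typed_norm(np.random.default_rng(10))
    with pytest.raises(ValueError):
        sc.assign_cell_types(lab, nm, {})


# ---------------------------------------------------------------------------
# find_markers
# ---------------------------------------------------------------------------

def test_identical_gene_is_not_a_marker():
    rng = np.random.default_rng(11)
    counts = np.vstack([np.full(100, 5), rng.poisson(5.0, 100)]).astype(int)
    nm = make_norm(counts)
    lab = labeling_from(np.repeat([0, 1], 50))
    table = sc.find_markers(nm, lab, 0).set_index("gene")
    assert table.loc["G0", "log2fc"] == pytest.approx(0.0, abs=0.15)
    assert not table.loc["G0", "is_marker"]


def test_planted_fourfold_marker_detected():
    rng = np.random.default_rng(12)
    mu = np.full((30, 200), 2.0)
    mu[0, :100] = 8.0  # 4-fold in cluster 0
    counts = rng.poisson(rng.gamma(4.0, mu / 4.0))
    nm = make_norm(counts)
    lab = labeling_from(np.repeat([0, 1], 100))
    table = sc.find_markers(nm, lab, 0).set_index("gene")
    assert table.loc["G0", "is_marker"]
    assert table.loc["G0", "log2fc"] > 0.5
    assert table.loc["G0", "p_value"] < 0.05


def test_find_markers_needs_three_cells():
    nm = make_norm(np.ones((5, 10), dtype=int))
    lab = labeling_from([0, 0] + [1] * 8)
    with pytest.raises(ValueError, match="< 3"):
        sc.find_markers(nm, lab, 0)


# ---------------------------------------------------------------------------
# stage_proportions
# ---------------------------------------------------------------------------

def test_single_cluster_all_fractions_one():
    nm = make_norm(np.ones((3, 8), dtype=int))
    lab = labeling_from(np.zeros(8, dtype=int))
    props = sc.stage_proportions(lab, nm.cell_meta)
    assert np.allclose(props.to_numpy(), 1.0)


def test_columns_sum_to_one_and_empty_stage_warns():
    rng = np.random.default_rng(13)
    cm = make_count_matrix(rng.integers(0, 5, size=(3, 30)))
    cm.cell_meta["stage"] = ["IB"] * 15 + ["IIB"] * 15
    nm = sc.normalize(cm)
    lab = labeling_from(rng.integers(0, 3, size=30))
    props = sc.stage_proportions(lab, nm.cell_meta)
    assert np.allclose(props.sum(axis=0), 1.0)
    assert set(props.columns) == {"IB", "IIB"}


def test_planted_proportions_recovered_within_multinomial_error():
    rng = np.random.default_rng(14)
    p = np.array([0.5, 0.3, 0.2])
    n = 2000
    labels = rng.choice(3, size=n, p=p)
    cm = make_count_matrix(np.ones((2, n), dtype=int))
    nm = sc.normalize(cm)
    props = sc.stage_proportions(labeling_from(labels), nm.cell_meta)
    for k in range(3):
        se = np.sqrt(p[k] * (1 - p[k]) / n)
        assert abs(props.loc[k, "IB"] - p[k]) < 3 * se


# ---------------------------------------------------------------------------
# embed_2d
# ---------------------------------------------------------------------------

def test_embed_2d_deterministic_and_separates_blobs():
    rng = np.random.default_rng(15)
    x = np.vstack([rng.normal(0, 1, (60, 5)),
                   rng.normal(30, 1, (60, 5))])
    a = sc.embed_2d(x, seed=1, perplexity=15)
    b = sc.embed_2d(x, seed=1, perplexity=15)
    assert np.allclose(a, b)
    from sklearn.metrics import silhouette_score
    labels = np.repeat([0, 1], 60)
    assert silhouette_score(a, labels) > 0


def test_embed_2d_rejects_large_perplexity():
    x = np.random.default_rng(0).normal(size=(10, 3))
    with pytest.raises(ValueError, match="perplexity"):
        sc.embed_2d(x, perplexity=30)
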