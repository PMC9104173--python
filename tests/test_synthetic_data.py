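"""Generators: determinism, moment oracles, and planted-structure truth."""

import numpy as np
import pytest

from stromastage import synthetic_data as sd
from stromastage.invasion_assay import polygon_area
from stromastage.io_formats import GeneSet


def small_spec(seed=0, cells_per_patient=20, **kw):
    return sd.default_spec(seed=seed, cells_per_patient=cells_per_patient,
                           **kw)


# ---------------------------------------------------------------------------
# scRNA-seq counts
# ---------------------------------------------------------------------------

def test_identical_seed_identical_counts():
    a, _ = sd.generate_scrnaseq(small_spec(seed=3))
    b, _ = sd.generate_scrnaseq(small_spec(seed=3))
    assert np.array_equal(a.counts, b.counts)
    assert a.cells == b.cells


def test_different_seed_differs():
    a, _ = sd.generate_scrnaseq(small_spec(seed=3))
    b, _ = sd.generate_scrnaseq(small_spec(seed=4))
    assert not np.array_equal(a.counts, b.counts)


def test_gene_mean_matches_moment_oracle():
    # a background gene with no planted effects: empirical mean across
    # ~10,000 cells within 3 s.e. of its profile mean
    spec = small_spec(seed=5, cells_per_patient=290)  # ~10,150 cells
    spec.stage_trajectories = {}
    spec.cluster_geneset_boost = {}
    cm, truth = sd.generate_scrnaseq(spec)
    gene = "G0010"
    assert truth["genes"].loc[gene, "role"] == "background"
    mu = float(spec.cell_type_profiles.loc[gene].iloc[0])
    x = cm.counts[cm.gene_index(gene)].astype(float)
    # NB variance + lognormal size-factor inflation bounds the s.e.
    se = x.std(ddof=1) / np.sqrt(len(x))
    assert abs(x.mean() - mu) < 3 * se + 1e-9


def test_marker_fold_change_matches_moment_oracle():
    spec = small_spec(seed=6, cells_per_patient=150)
    cm, truth = sd.generate_scrnaseq(spec)
    sub = spec.fibro_subclusters[0]
    gene = sub.marker_genes[0]
    cells = truth["cells"]
    in_cl = (cells["fibro_subcluster"] == sub.cluster_id).to_numpy()
    fib_other = ((cells["cell_type"] == "Fibroblast")
                 & (cells["fibro_subcluster"] != sub.cluster_id)).to_numpy()
    x = cm.counts[cm.gene_index(gene)].astype(float)
    ratio = x[in_cl].mean() / x[fib_other].mean()
    expected = 2 ** sub.log2_effect
    se = ratio * np.sqrt(
        x[in_cl].var() / (x[in_cl].mean() ** 2 * in_cl.sum())
        + x[fib_other].var() / (x[fib_other].mean() ** 2 * fib_other.sum())
    )
    assert abs(ratio - expected) < 3 * se


def test_eli_pairwise_count_correlation_near_target():
    # ±0.1 of the requested r at ~3,000 cells, latent factor isolated
    spec = sd.default_spec(seed=7, cells_per_patient=86, eli_r=0.35)
    spec.stage_trajectories = {}
    spec.cluster_geneset_boost = {}
    cm, _ = sd.generate_scrnaseq(spec)
    rows = [cm.gene_index(g) for g in spec.eli_up.members]
    cc = np.corrcoef(cm.counts[rows].astype(float))
    iu = np.triu_indices(len(rows), 1)
    assert abs(cc[iu].mean() - 0.35) < 0.1


def test_empty_stage_rejected():
    spec = small_spec()
    spec.n_patients_per_stage["IIA"] = 0
    with pytest.raises(ValueError, match="no patients"):
        sd.generate_scrnaseq(spec)


def test_truth_tables_cover_cells_and_genes():
    spec = small_spec(seed=8)
    cm, truth = sd.generate_scrnaseq(spec)
    assert list(truth["cells"].index) == cm.cells
    assert list(truth["genes"].index) == cm.genes
    fib = truth["cells"]["cell_type"] == "Fibroblast"
    assert (truth["cells"].loc[fib, "fibro_subcluster"] >= 0).all()
    assert (truth["cells"].loc[~fib, "fibro_subcluster"] == -1).all()


# ---------------------------------------------------------------------------
# PPI
# ---------------------------------------------------------------------------

def test_ppi_full_density_gives_clique():
    eli = GeneSet("E", tuple("ABCDE"))
    g = sd.generate_ppi(20, eli, target_density=1.0, seed=0)
    sub = g.subgraph(eli.members)
    assert sub.number_of_edges() == 10  # K5


def test_ppi_background_density_matches_binomial_oracle():
    eli = GeneSet("E", tuple(f"E{i}" for i in range(10)))
    g = sd.generate_ppi(500, eli, target_density=0.3, seed=1,
                        background_p=0.01)
    bg = [n for n, d in g.nodes(data=True) if d["role"] == "background"]
    sub = g.subgraph(bg)
    n_pairs = len(bg) * (len(bg) - 1) // 2
    p_hat = sub.number_of_edges() / n_pairs
    se = np.sqrt(0.01 * 0.99 / n_pairs)
    assert abs(p_hat - 0.01) < 3 * se


def test_ppi_deterministic_and_infeasible_density():
    eli = GeneSet("E", tuple("ABCD"))
    g1 = sd.generate_ppi(30, eli, target_density=0.5, seed=2)
    g2 = sd.generate_ppi(30, eli, target_density=0.5, seed=2)
    assert sorted(g1.edges()) == sorted(g2.edges())
    with pytest.raises(ValueError, match="density"):
        sd.generate_ppi(30, eli, target_density=0.005, background_p=0.01)


# ---------------------------------------------------------------------------
# invasion series
# ---------------------------------------------------------------------------

def test_flat_front_constant_area():
    series, truth = sd.generate_invasion_series(
        n_forks=0, fork_depth_px=0, interface_len_px=500, noise_sd_px=0,
        n_timepoints=5, seed=0,
    )
    areas = [polygon_area(p) for p in series.polygons]
    assert np.allclose(areas, areas[0])
    assert len(truth["fork_positions"]) == 0


def test_single_fork_max_advance_equals_depth():
    series, truth = sd.generate_invasion_series(
        n_forks=1, fork_depth_px=50, interface_len_px=500, noise_sd_px=0,
        n_timepoints=5, seed=1,
    )
    top = series.polygons[-1][2:, 1]  # advance samples of the last frame
    assert top.max() == pytest.approx(50.0)


def test_delta_area_matches_trapezoid_oracle():
    series, truth = sd.generate_invasion_series(
        n_forks=3, fork_depth_px=40, interface_len_px=800, noise_sd_px=0,
        n_timepoints=4, seed=2,
    )
    a0 = polygon_area(series.polygons[0])
    a1 = polygon_area(series.polygons[-1])
    planted = truth["planted_profile"]
    assert a1 - a0 == pytest.approx(np.trapezoid(planted), abs=1.0)


def test_fork_spacing_honored_and_infeasible_rejected():
    _, truth = sd.generate_invasion_series(
        n_forks=5, fork_depth_px=30, interface_len_px=1500, noise_sd_px=0,
        seed=3,
    )
    assert np.all(np.diff(truth["fork_positions"]) >= 100)
    with pytest.raises(ValueError, match="spacing"):
        sd.generate_invasion_series(
            n_forks=10, fork_depth_px=30, interface_len_px=500,
            noise_sd_px=0, seed=0,
        )


# ---------------------------------------------------------------------------
# bulk cohort
# ---------------------------------------------------------------------------

def test_bulk_cohort_planted_direction():
    spec = small_spec(seed=9)
    counts, groups = sd.generate_bulk_cohort(spec, seed=9)
    n1 = counts.loc[:, (groups == "N1").to_numpy()]
    n0 = counts.loc[:, (groups == "N0").to_numpy()]
    dn = list(spec.eli_dn.members)
    ratio = n1.loc[dn].mean(axis=1) / n0.loc[dn].mean(axis=1)
    assert np.median(ratio) < 0.7  # planted 2^-0.8 ~ 0.57
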