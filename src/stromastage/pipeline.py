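"""End-to-end synthetic study: simulate, cluster, and run every analysis.

``run_all`` drives the whole fibroblast-centric workflow on synthetic
data from a single configuration: generate the cohort, cluster and type
all cells, re-cluster the fibroblast compartment, call subcluster
markers and stage proportions, score ligand-receptor interactions,
compute the ELI gene-set statistics (correlation test, GSEA on the
subcluster and bulk-cohort rankings, stage-pattern mining), extract the
ELI PPI subnetwork, and quantify the planted invasion assay. All module
seeds fan out from one root seed by fixed offsets; outputs are TSV.
"""

from __future__ import annotations

import dataclasses
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from sklearn.metrics import adjusted_rand_score

from stromastage import (
    enrichment,
    invasion_assay,
    ligand_receptor,
    ppi_network,
    sc_pipeline,
    synthetic_data,
)
from stromastage.io_formats import STAGES

logger = logging.getLogger("stromastage")


@dataclasses.dataclass
class PipelineConfig:
    """All pipeline parameters with their default study conditions."""

    seed: int = 0
    cells_per_patient: int = 143
    eli_r: float = 0.2
    n_pcs_all: int = 10
    n_pcs_fibro: int = 7
    k_neighbors: int = 20
    resolution: float = 1.0
    type_tau: float = 0.25
    marker_alpha: float = 0.05
    marker_min_log2fc: float = 0.5
    merge_min_log2fc: float = 1.0
    lr_n_fibro: int = 4
    lr_n_partner: int = 3
    lr_min_expr: float = 0.5
    lr_min_frac_ligand: float = 0.05
    lr_min_frac_receptor: float = 0.10
    gsea_n_perm: int = 1000
    eli_top_n: int = 100
    stem_n_profiles: int = 50
    stem_c: int = 2
    ppi_n_background: int = 500
    ppi_target_density: float = 0.30
    ppi_max_linker_path: int = 2
    smooth_window: int = 20
    peak_side: int = 40
    invasion_n_forks: int = 6
    invasion_fork_depth_px: float = 50.0
    invasion_perturbed_depth_px: float = 25.0
    invasion_interface_px: int = 2000
    invasion_noise_sd_px: float = 2.0
    bulk_n_n0: int = 29
    bulk_n_n1: int = 78
    run_embed_2d: bool = False

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(
            yaml.safe_dump(dataclasses.asdict(self), sort_keys=True)
        )


def _match_clusters(detected: np.ndarray, planted: np.ndarray
                    ) -> dict[int, int]:
    """Map each planted cluster to the detected cluster holding most of
    its cells."""
    mapping = {}
    for p in np.unique(planted):
        det, cnt = np.unique(detected[planted == p], return_counts=True)
        mapping[int(p)] = int(det[np.argmax(cnt)])
    return mapping


def _peak_f1(detected_pos: np.ndarray, true_pos: np.ndarray,
             tol: float = 20.0) -> tuple[float, float, float]:
    """Greedy one-to-one matching of called vs planted fork positions."""
    used = np.zeros(len(true_pos), dtype=bool)
    tp = 0
    for p in detected_pos:
        d = np.abs(true_pos - p)
        d[used] = np.inf
        if len(d) and d.min() <= tol:
            used[np.argmin(d)] = True
            tp += 1
    precision = tp / len(detected_pos) if len(detected_pos) else 0.0
    recall = tp / len(true_pos) if len(true_pos) else 1.0
    f1 = (
        2 * precision * recall / (precision + recall)
        if precision + recall else 0.0
    )
    return precision, recall, f1


def run_all(config: PipelineConfig, outdir: str | Path) -> dict:
    """Run the full synthetic study; returns the diagnostics dict.

    Writes one TSV per analysis stage plus a resolved-config snapshot
    and a manifest. On a stage failure the manifest records the stages
    completed so far before the exception propagates.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    config.to_yaml(outdir / "resolved_config.yaml")
    handler = logging.FileHandler(outdir / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)

    completed: list[str] = []
    diagnostics: dict[str, float] = {}

    def _tsv(df: pd.DataFrame, name: str, index: bool = False) -> None:
        df.to_csv(outdir / name, sep="\t", index=index)

    try:
        # --- simulate -----------------------------------------------------
        logger.info("simulating cohort (seed=%d)", config.seed)
        spec = synthetic_data.default_spec(
            seed=config.seed,
            cells_per_patient=config.cells_per_patient,
            eli_r=config.eli_r,
        )
        cm, truth = synthetic_data.generate_scrnaseq(spec)
        completed.append("simulate")

        # --- all-cell clustering and typing -------------------------------
        norm = sc_pipeline.normalize(cm)
        emb, _ = sc_pipeline.pca_embed(norm, n_pcs=config.n_pcs_all)
        labeling = sc_pipeline.cluster_cells(
            emb, k_neighbors=config.k_neighbors,
            resolution=config.resolution, seed=config.seed + 1,
        )
        labeling = sc_pipeline.merge_indistinct_clusters(
            norm, labeling, emb, min_log2fc=config.merge_min_log2fc,
        )
        type_map = sc_pipeline.assign_cell_types(
            labeling, norm, synthetic_data.CELL_TYPE_MARKERS,
            tau=config.type_tau,
        )
        cell_types = np.array([type_map[c] for c in labeling.labels])
        _tsv(
            pd.DataFrame(
                {
                    "barcode": norm.cells,
                    "cluster": labeling.labels,
                    "cell_type": cell_types,
                    "stage": norm.cell_meta["stage"].to_numpy(),
                }
            ),
            "cell_types.tsv",
        )
        true_types = truth["cells"]["cell_type"].to_numpy()
        diagnostics["type_accuracy"] = float(
            (cell_types == true_types).mean()
        )
        completed.append("cluster_all")

        # --- fibroblast subclustering --------------------------------------
        fib_mask = cell_types == "Fibroblast"
        fibro = norm.subset_cells(fib_mask)
        emb_f, _ = sc_pipeline.pca_embed(fibro, n_pcs=config.n_pcs_fibro)
        sub_labeling = sc_pipeline.cluster_cells(
            emb_f, k_neighbors=config.k_neighbors,
            resolution=config.resolution, seed=config.seed + 2,
        )
        sub_labeling = sc_pipeline.merge_indistinct_clusters(
            fibro, sub_labeling, emb_f,
            min_log2fc=config.merge_min_log2fc,
        )
        if config.run_embed_2d:
            xy = sc_pipeline.embed_2d(emb, seed=config.seed + 20)
            _tsv(
                pd.DataFrame(
                    {"barcode": norm.cells, "tsne1": xy[:, 0],
                     "tsne2": xy[:, 1]}
                ),
                "tsne_coordinates.tsv",
            )

        planted = truth["cells"]["fibro_subcluster"].to_numpy()[fib_mask]
        ok = planted >= 0  # cells that truly are fibroblasts
        diagnostics["fibro_subcluster_ari"] = float(
            adjusted_rand_score(planted[ok], sub_labeling.labels[ok])
        )
        logger.info("fibroblast subclusters: %d (ARI %.3f)",
                    sub_labeling.n_clusters,
                    diagnostics["fibro_subcluster_ari"])
        completed.append("subcluster_fibroblasts")

        # --- markers and stage proportions ---------------------------------
        marker_tables = [
            sc_pipeline.find_markers(
                fibro, sub_labeling, cid,
                min_log2fc=config.marker_min_log2fc,
                alpha=config.marker_alpha,
            )
            for cid in range(sub_labeling.n_clusters)
        ]
        markers = pd.concat(marker_tables, ignore_index=True)
        _tsv(markers, "fibro_markers.tsv")

        cluster_map = _match_clusters(sub_labeling.labels[ok], planted[ok])
        recalls = []
        for sc in spec.fibro_subclusters:
            det = cluster_map.get(sc.cluster_id)
            if det is None:
                continue
            tab = marker_tables[det].set_index("gene")
            hit = [
                g for g in sc.marker_genes
                if g in tab.index
                and tab.loc[g, "is_marker"] and tab.loc[g, "log2fc"] > 0
            ]
            recalls.append(len(hit) / len(sc.marker_genes))
        diagnostics["marker_recall"] = float(np.mean(recalls))

        props = sc_pipeline.stage_proportions(sub_labeling, fibro.cell_meta)
        _tsv(props.reset_index(), "fibro_stage_proportions.tsv")
        completed.append("markers_proportions")

        # --- ligand-receptor scoring ---------------------------------------
        lr_rows = []
        for receiver in sorted(set(cell_types) - {"Fibroblast"}):
            lr_rows.append(
                ligand_receptor.lr_strength(
                    norm, cell_types, spec.lr_pairs,
                    sender_type="Fibroblast", receiver_type=receiver,
                )
            )
        lr_table = pd.concat(lr_rows, ignore_index=True)
        _tsv(lr_table, "lr_scores.tsv")
        lr_top = ligand_receptor.select_top_interactions(
            lr_table, fibro_side="ligand",
            n_fibro=config.lr_n_fibro, n_partner=config.lr_n_partner,
            min_expr=config.lr_min_expr,
            min_frac_ligand=config.lr_min_frac_ligand,
            min_frac_receptor=config.lr_min_frac_receptor,
        )
        _tsv(lr_top, "lr_top_interactions.tsv")
        _tsv(
            ligand_receptor.category_strength(lr_table, min_ratio=0.09),
            "lr_categories.tsv",
        )
        completed.append("ligand_receptor")

        # --- ELI correlation test ------------------------------------------
        eli_up = spec.eli_up.top(config.eli_top_n)
        eli_dn = spec.eli_dn.top(config.eli_top_n)
        corr_rows = []
        for gs in (eli_up, eli_dn):
            res = enrichment.geneset_correlation_test(
                fibro, gs, seed=config.seed + 3
            )
            corr_rows.append(
                {
                    "gene_set": gs.name,
                    "mean_strength_in": res.mean_strength_in,
                    "mean_strength_out": res.mean_strength_out,
                    "t_statistic": res.t_statistic,
                    "p_value": res.p_value,
                    "n_pairs_in": res.n_pairs_in,
                    "n_pairs_out": res.n_pairs_out,
                }
            )
        corr_df = pd.DataFrame(corr_rows)
        _tsv(corr_df, "eli_correlation.tsv")
        diagnostics["eli_corr_t_up"] = float(corr_df["t_statistic"][0])
        diagnostics["eli_corr_p_up"] = float(corr_df["p_value"][0])
        completed.append("eli_correlation")

        # --- GSEA ----------------------------------------------------------
        gsea_rows = []
        # per fibroblast subcluster: ELI^up enrichment in its markers
        for cid in range(sub_labeling.n_clusters):
            ranked = enrichment.rank_by_log2fc(marker_tables[cid])
            res = enrichment.gsea(
                ranked, eli_up, n_perm=config.gsea_n_perm,
                seed=config.seed + 10 + cid,
            )
            gsea_rows.append(
                ("fibro_subcluster_" + str(cid), res.set_name, res.es,
                 res.nes, res.p_value, res.size,
                 ",".join(res.leading_edge[:10]))
            )
        # bulk cohort: lymph-node positive vs negative
        bulk, groups = synthetic_data.generate_bulk_cohort(
            spec, n_n0=config.bulk_n_n0, n_n1=config.bulk_n_n1,
            seed=config.seed + 4,
        )
        ranked_bulk = enrichment.rank_genes_two_group(bulk, groups, "N1")
        c4 = next(sc for sc in spec.fibro_subclusters if sc.cluster_id == 4)
        from stromastage.io_formats import GeneSet as _GS
        c4_set = _GS("CLUSTER4_MARKERS", c4.marker_genes)
        for gs in (eli_dn, c4_set):
            res = enrichment.gsea(
                ranked_bulk, gs, n_perm=config.gsea_n_perm,
                seed=config.seed + 5,
            )
            gsea_rows.append(
                ("bulk_N1_vs_N0", res.set_name, res.es, res.nes,
                 res.p_value, res.size, ",".join(res.leading_edge[:10]))
            )
        gsea_df = pd.DataFrame(
            gsea_rows,
            columns=["contrast", "gene_set", "ES", "NES", "p_value",
                     "size", "leading_edge_top10"],
        )
        _tsv(gsea_df, "gsea.tsv")
        # ELI^up enrichment in the detected analog of planted subcluster 4
        det4 = cluster_map.get(4)
        if det4 is not None:
            row = gsea_df[
                gsea_df["contrast"] == f"fibro_subcluster_{det4}"
            ].iloc[0]
            diagnostics["eli_up_es_cluster4"] = float(row["ES"])
            diagnostics["eli_up_p_cluster4"] = float(row["p_value"])
        bulk_dn = gsea_df[
            (gsea_df["contrast"] == "bulk_N1_vs_N0")
            & (gsea_df["gene_set"] == eli_dn.name)
        ].iloc[0]
        diagnostics["eli_dn_es_bulk"] = float(bulk_dn["ES"])
        completed.append("gsea")

        # --- stage-pattern mining ------------------------------------------
        stages = [s for s in STAGES if s in spec.n_patients_per_stage]
        pattern_rows = []
        for gs in (eli_dn, eli_up):
            sm = enrichment.stage_mean_matrix(
                fibro, list(gs.members), stages
            )
            res = enrichment.stage_pattern_mining(
                sm, n_profiles=config.stem_n_profiles, c=config.stem_c,
                seed=config.seed + 6,
            )
            for j in np.flatnonzero(res.p_bonferroni < 0.05):
                pattern_rows.append(
                    (gs.name, j,
                     "/".join(f"{v:g}" for v in res.profiles[j]),
                     int(res.counts[j]), float(res.expected[j]),
                     float(res.p_bonferroni[j]))
                )
            if gs.name == eli_dn.name:
                # planted pro-resistive cohort: rise to IIA then fall
                cohort = spec.stage_trajectories[
                    "dn_rise_then_fall"].genes
                modal = res.assignment.loc[list(cohort)].mode()[0]
                frac = float(
                    (res.assignment.loc[list(cohort)] == modal).mean()
                )
                diagnostics["stem_dn_cohort_modal_fraction"] = frac
                diagnostics["stem_dn_cohort_p_bonf"] = float(
                    res.p_bonferroni[modal]
                )
        _tsv(
            pd.DataFrame(
                pattern_rows,
                columns=["gene_set", "profile", "profile_shape",
                         "n_genes", "expected", "p_bonferroni"],
            ),
            "stage_patterns.tsv",
        )
        completed.append("stage_patterns")

        # --- PPI subnetwork -------------------------------------------------
        graph = synthetic_data.generate_ppi(
            config.ppi_n_background, eli_up,
            target_density=config.ppi_target_density,
            seed=config.seed + 7,
        )
        sub = ppi_network.extract_subnetwork(
            graph, eli_up, max_linker_path=config.ppi_max_linker_path
        )
        metrics = ppi_network.subnetwork_metrics(graph, sub)
        bg_nodes = [n for n, d in graph.nodes(data=True)
                    if d["role"] == "background"]
        metrics["background_density"] = ppi_network.density(
            graph.subgraph(bg_nodes)
        )
        _tsv(pd.DataFrame([metrics]), "ppi_metrics.tsv")
        _tsv(
            pd.DataFrame(
                sorted(
                    (n, d["role"]) for n, d in sub.nodes(data=True)
                ),
                columns=["gene", "role"],
            ),
            "ppi_subnetwork_nodes.tsv",
        )
        diagnostics["ppi_subnetwork_density"] = metrics[
            "subnetwork_density"]
        diagnostics["ppi_background_density"] = metrics[
            "background_density"]
        completed.append("ppi_subnetwork")

        # --- invasion assay --------------------------------------------------
        inv_rows = []
        peak_rows = []
        depths = {}
        for cond, depth in (
            ("control", config.invasion_fork_depth_px),
            ("perturbed", config.invasion_perturbed_depth_px),
        ):
            series, inv_truth = synthetic_data.generate_invasion_series(
                n_forks=config.invasion_n_forks,
                fork_depth_px=depth,
                interface_len_px=config.invasion_interface_px,
                noise_sd_px=config.invasion_noise_sd_px,
                seed=config.seed + (8 if cond == "control" else 9),
            )
            table, smoothed, peaks = invasion_assay.quantify_series(
                series, smooth_window=config.smooth_window,
                peak_side=config.peak_side,
            )
            table.insert(0, "condition", cond)
            inv_rows.append(table)
            for p, dpx in zip(peaks.positions, peaks.depths):
                peak_rows.append((cond, p, dpx))
            depths[cond] = peaks.depths
            if cond == "control":
                pr, rc, f1 = _peak_f1(
                    peaks.positions, inv_truth["fork_positions"]
                )
                diagnostics["peak_f1"] = f1
        comp = invasion_assay.compare_depths(
            depths["control"], depths["perturbed"]
        )
        diagnostics["invasion_depth_p"] = comp.p_value
        _tsv(pd.concat(inv_rows, ignore_index=True), "invasion_extent.tsv")
        _tsv(
            pd.DataFrame(peak_rows,
                         columns=["condition", "position_px", "depth_px"]),
            "invasion_peaks.tsv",
        )
        _tsv(
            pd.DataFrame(
                [
                    {
                        "u_statistic": comp.u_statistic,
                        "p_value": comp.p_value,
                        "method": comp.method,
                        "median_control": comp.median_a,
                        "median_perturbed": comp.median_b,
                    }
                ]
            ),
            "invasion_depth_comparison.tsv",
        )
        completed.append("invasion")

        _tsv(
            pd.DataFrame(
                sorted(diagnostics.items()), columns=["metric", "value"]
            ),
            "diagnostics.tsv",
        )
        completed.append("diagnostics")
    finally:
        pd.DataFrame({"stage": completed}).to_csv(
            outdir / "manifest.tsv", sep="\t", index=False
        )
        logger.removeHandler(handler)
        handler.close()
    return diagnostics
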