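"""Synthetic inputs with the statistical structure the analysis assumes.

The single-cell generator emulates a multi-patient pancreatic cohort:
stage-annotated negative-binomial counts over ~12 planted cell types, a
fibroblast compartment split into 8 subclusters whose proportions shift
across stages (homogeneous in normal pancreas and at stage IIA, diverse
at IB/IIB/III), invasibility gene sets (ELI^up / ELI^dn) whose members
share a per-cell latent factor inducing a target pairwise correlation,
and per-stage expression trajectories planted on gene cohorts. Companion
generators produce a PPI graph with an embedded dense ELI subnetwork, a
two-group bulk cohort (lymph-node positive vs negative), and invasion
front ROI series with planted forks. Every generator is deterministic
under a fixed seed and emits truth tables next to the data.
"""

from __future__ import annotations

import dataclasses
import math

import networkx as nx
import numpy as np
import pandas as pd

from stromastage.io_formats import STAGES, CountMatrix, GeneSet, LRPairTable
from stromastage.invasion_assay import InvasionSeries

# ---------------------------------------------------------------------------
# simulation specification
# ---------------------------------------------------------------------------


@dataclasses.dataclass
class FibroSubcluster:
    """One planted fibroblast subcluster.

    ``stage_proportions`` gives the share of fibroblasts of each stage
    that belong to this subcluster; across subclusters the shares of a
    stage sum to 1. ``log2_effect`` is the marker-gene fold change (log2)
    of this subcluster over the fibroblast baseline.
    """

    cluster_id: int
    marker_genes: tuple[str, ...]
    log2_effect: float
    stage_proportions: dict[str, float]


@dataclasses.dataclass
class StageTrajectory:
    """A per-stage mean-expression multiplier profile planted on genes."""

    genes: tuple[str, ...]
    multipliers: dict[str, float]  # stage -> multiplicative effect


@dataclasses.dataclass
class SimulationSpec:
    """Full description of the synthetic single-cell study."""

    n_patients_per_stage: dict[str, int]
    cells_per_patient: int
    genes: list[str]
    cell_type_profiles: pd.DataFrame  # genes x cell types, baseline means
    cell_type_proportions: dict[str, float]
    fibro_subclusters: list[FibroSubcluster]
    eli_up: GeneSet
    eli_dn: GeneSet
    eli_r: float  # target pairwise count correlation within each ELI set
    stage_trajectories: dict[str, StageTrajectory]
    cluster_geneset_boost: dict[int, tuple[str, float]]
    lr_pairs: LRPairTable
    nb_dispersion: float = 4.0
    library_size_sd: float = 0.25  # lognormal sigma of cell size factors
    seed: int = 0

    def validate(self) -> None:
        if not self.n_patients_per_stage:
            raise ValueError("no stages in simulation spec")
        for stage, n in self.n_patients_per_stage.items():
            if stage not in STAGES:
                raise ValueError(f"unknown stage {stage!r}")
            if n < 1:
                raise ValueError(f"stage {stage!r} has no patients")
        if not 0 <= self.eli_r < 1:
            raise ValueError("eli_r must be in [0, 1)")
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be positive")
        props = np.array(list(self.cell_type_proportions.values()))
        if abs(props.sum() - 1) > 1e-8 or (props < 0).any():
            raise ValueError("cell type proportions must be a distribution")
        for stage in self.n_patients_per_stage:
            tot = sum(
                sc.stage_proportions.get(stage, 0.0)
                for sc in self.fibro_subclusters
            )
            if abs(tot - 1) > 1e-8:
                raise ValueError(
                    f"fibroblast subcluster proportions at stage {stage!r} "
                    f"sum to {tot}, not 1"
                )
        for traj in self.stage_trajectories.values():
            for m in traj.multipliers.values():
                if not math.isfinite(m) or m < 0:
                    raise ValueError("trajectory multipliers must be finite, >= 0")
        genes = set(self.genes)
        for sc in self.fibro_subclusters:
            if not set(sc.marker_genes) <= genes:
                raise ValueError(
                    f"subcluster {sc.cluster_id} markers not all in gene list"
                )


# default gene content: real marker symbols for the planted biology,
# synthetic symbols (FSC*, ELIUP*, ELIDN*, G*) as padding/background.

CELL_TYPE_MARKERS: dict[str, list[str]] = {
    "Fibroblast": ["LUM", "DCN", "COL1A1", "COL3A1", "FN1", "SPARC"],
    "Stellate cell": ["RGS5", "ADIRF", "FABP4", "MYH11"],
    "Ductal cell 1": ["AMBP", "CFTR", "SLC4A4", "ANXA4"],
    "Ductal cell 2": ["CEACAM5", "CEACAM6", "MUC1", "TFF1"],
    "Endothelial cell": ["CDH5", "PECAM1", "VWF", "PLVAP"],
    "Acinar cell": ["CELA2A", "CELA3A", "CTRB2", "PNLIP"],
    "Macrophage": ["CD68", "CD14", "AIF1", "CSF1R"],
    "Endocrine cell": ["INS", "GCG", "SST", "CHGB"],
    "B cell": ["CD79A", "CD79B", "MS4A1", "IGHM"],
    "T cell": ["CD3D", "CD3E", "CD2", "TRAC"],
}

FIBRO_SUBCLUSTER_MARKERS: dict[int, list[str]] = {
    0: ["MATN3", "COMP", "ACTA2", "GJB2", "SLC6A6",
        "FSC0A", "FSC0B", "FSC0C", "FSC0D", "FSC0E"],
    1: ["AGT", "F2R", "TIMP1", "APOD",
        "FSC1A", "FSC1B", "FSC1C", "FSC1D", "FSC1E", "FSC1F"],
    2: ["DPT", "CLPS", "PRSS1", "CTRB1", "CPA1", "CPB1", "CFD", "PTN",
        "FSC2A", "FSC2B"],
    3: ["CTGF", "SFRP4", "C3", "IGF1", "SERPINE1", "SERPINE2",
        "FSC3A", "FSC3B", "FSC3C", "FSC3D"],
    4: ["MMP14", "COL10A1", "COL11A1", "COL12A1", "MMP2", "MMP11",
        "FSC4A", "FSC4B", "FSC4C", "FSC4D"],
    5: ["SPINK1", "SERPINA1", "KRT7", "KRT19", "RARRES2", "MMP7", "CTHRC1",
        "FSC5A", "FSC5B", "FSC5C"],
    6: ["SOD3", "GPX3",
        "FSC6A", "FSC6B", "FSC6C", "FSC6D", "FSC6E", "FSC6F", "FSC6G",
        "FSC6H"],
    7: ["TNC", "POSTN", "TGFBI", "CXCL8", "CXCL3", "IGFBP2",
        "FSC7A", "FSC7B", "FSC7C", "FSC7D"],
}

# pad the planted programs to realistic sizes: transcriptional programs
# distinguishing cell types and subtypes span dozens of genes, not the
# handful of canonical markers used for labeling.
for _i, (_t, _mk) in enumerate(sorted(CELL_TYPE_MARKERS.items())):
    _mk.extend(f"CT{_i}P{_j:02d}" for _j in range(1, 13 - len(_mk)))
for _cid, _mk in FIBRO_SUBCLUSTER_MARKERS.items():
    _mk.extend(f"FSC{_cid}P{_j:02d}" for _j in range(1, 21 - len(_mk)))

# share of each stage's fibroblasts per subcluster: homogeneous in normal
# pancreas (cluster 2) and at IIA (cluster 5), diverse at IB/IIB/III.
FIBRO_STAGE_PROPORTIONS: dict[int, dict[str, float]] = {
    0: {"Normal": 0.02, "IB": 0.08, "IIA": 0.02, "IIB": 0.20, "III": 0.18},
    1: {"Normal": 0.02, "IB": 0.17, "IIA": 0.02, "IIB": 0.15, "III": 0.14},
    2: {"Normal": 0.86, "IB": 0.15, "IIA": 0.06, "IIB": 0.03, "III": 0.04},
    3: {"Normal": 0.02, "IB": 0.17, "IIA": 0.02, "IIB": 0.17, "III": 0.16},
    4: {"Normal": 0.02, "IB": 0.05, "IIA": 0.02, "IIB": 0.18, "III": 0.17},
    5: {"Normal": 0.02, "IB": 0.12, "IIA": 0.80, "IIB": 0.04, "III": 0.06},
    6: {"Normal": 0.02, "IB": 0.16, "IIA": 0.02, "IIB": 0.10, "III": 0.12},
    7: {"Normal": 0.02, "IB": 0.10, "IIA": 0.04, "IIB": 0.13, "III": 0.13},
}

CELL_TYPE_PROPORTIONS: dict[str, float] = {
    "Fibroblast": 0.40,
    "Stellate cell": 0.06,
    "Ductal cell 1": 0.12,
    "Ductal cell 2": 0.10,
    "Endothelial cell": 0.06,
    "Acinar cell": 0.06,
    "Macrophage": 0.06,
    "Endocrine cell": 0.04,
    "B cell": 0.03,
    "T cell": 0.05,
    "others": 0.02,
}

ELI_UP_SEED_GENES = ["KLF5", "NFKB1", "HSPB8", "MAP7D1", "GMFB", "PSMD11"]
ELI_DN_SEED_GENES = [
    "RGS7", "MDFI", "DUSP8", "NPRL2", "ELMO3", "NTPCR",
    "WDR17", "WDR83", "COX10", "MSTO1", "CPT2", "MDH1B",
]

_LR_PLANTED = [
    # ligand (fibroblast), receptor (other type), category
    ("COL1A1", "ITGB1", "ECM-receptor interaction"),
    ("FN1", "ITGA5", "ECM-receptor interaction"),
    ("COL3A1", "DDR1", "ECM-receptor interaction"),
    ("DCN", "EGFR", "growth factor signaling"),
    ("IGF1", "IGF1R", "growth factor signaling"),
    ("CTGF", "LRP6", "growth factor signaling"),
    ("PTN", "PTPRZ1", "growth factor signaling"),
    ("TIMP1", "CD63", "protease regulation"),
    ("SERPINE1", "LRP1", "protease regulation"),
    ("B2M", "HFE", "immune signaling"),
    ("C3", "C3AR1", "immune signaling"),
    ("CXCL8", "CXCR2", "immune signaling"),
]


def default_spec(seed: int = 0, cells_per_patient: int = 143,
                 eli_r: float = 0.2) -> SimulationSpec:
    """Build the default study conditions.

    35 patients (11 normal, 24 tumor split 5/6/9/4 over IB/IIA/IIB/III),
    ~5,000 cells, 11 planted cell types with fibroblasts at 40%, 8
    fibroblast subclusters with 4-fold markers, 100-gene ELI^up/ELI^dn
    sets with within-set latent correlation, and three planted stage
    trajectories mirroring the profile shapes the analysis must recover.
    """
    rng = np.random.default_rng(seed + 104729)  # spec-construction stream

    eli_up_members = ELI_UP_SEED_GENES + [
        f"ELIUP{i:03d}" for i in range(len(ELI_UP_SEED_GENES) + 1, 101)
    ]
    eli_dn_members = ELI_DN_SEED_GENES + [
        f"ELIDN{i:03d}" for i in range(len(ELI_DN_SEED_GENES) + 1, 101)
    ]
    eli_up = GeneSet("ELI_UP", tuple(eli_up_members))
    eli_dn = GeneSet("ELI_DN", tuple(eli_dn_members))

    receptors = sorted({r for _, r, _ in _LR_PLANTED})
    genes: list[str] = []
    for markers in CELL_TYPE_MARKERS.values():
        genes.extend(markers)
    for markers in FIBRO_SUBCLUSTER_MARKERS.values():
        genes.extend(markers)
    genes.extend(eli_up.members)
    genes.extend(eli_dn.members)
    genes.extend(receptors)
    extra_ligands = sorted(
        {lig for lig, _, _ in _LR_PLANTED} - set(genes)
    )
    genes.extend(extra_ligands)
    genes.extend(f"G{i:04d}" for i in range(1, 1201 - len(genes)))

    types = list(CELL_TYPE_PROPORTIONS)
    base = np.exp(rng.normal(np.log(0.4), 0.8, size=len(genes)))
    base = np.clip(base, 0.05, 4.0)
    profiles = pd.DataFrame(
        np.tile(base[:, None], (1, len(types))), index=genes, columns=types
    )
    gi = {g: i for i, g in enumerate(genes)}
    for t, markers in CELL_TYPE_MARKERS.items():
        for m in markers:
            profiles.iloc[gi[m]] = 1.0  # flat modest baseline elsewhere
            profiles.loc[m, t] = 8.0
    for markers in FIBRO_SUBCLUSTER_MARKERS.values():
        for m in markers:
            profiles.loc[m, :] = np.minimum(profiles.loc[m, :], 1.5)
            profiles.loc[m, "Fibroblast"] = 1.5
    for g in list(eli_up.members) + list(eli_dn.members):
        profiles.loc[g, :] = 5.0
    for r in receptors:
        profiles.loc[r, :] = 0.8
        profiles.loc[r, "Ductal cell 1"] = 3.0
    profiles.loc["ITGB1", "Ductal cell 1"] = 8.0  # designated top LR pair
    for lig in extra_ligands:  # ubiquitous ligands (e.g. B2M)
        profiles.loc[lig, :] = 2.0
        profiles.loc[lig, "Fibroblast"] = 3.0

    subclusters = [
        FibroSubcluster(
            cluster_id=cid,
            marker_genes=tuple(FIBRO_SUBCLUSTER_MARKERS[cid]),
            log2_effect=2.5,
            stage_proportions=FIBRO_STAGE_PROPORTIONS[cid],
        )
        for cid in sorted(FIBRO_SUBCLUSTER_MARKERS)
    ]

    trajectories = {
        # pro-resistive cohort: rises while the tumor grows, collapses on
        # stromal trespass (IIA -> IIB)
        "dn_rise_then_fall": StageTrajectory(
            genes=tuple(eli_dn.members[:40]),
            multipliers={"Normal": 1.0, "IB": 1.5, "IIA": 2.2,
                         "IIB": 1.0, "III": 0.65},
        ),
        # pro-invasable cohort: up with tumorigenesis, sustained after
        "up_sustained_rise": StageTrajectory(
            genes=tuple(eli_up.members[6:46]),
            multipliers={"Normal": 1.0, "IB": 1.35, "IIA": 1.4,
                         "IIB": 1.45, "III": 1.45},
        ),
        # smaller cohort peaking at first lymph metastasis
        "up_peak_at_iib": StageTrajectory(
            genes=tuple(eli_up.members[46:66]),
            multipliers={"Normal": 1.0, "IB": 1.1, "IIA": 1.2,
                         "IIB": 1.45, "III": 1.05},
        ),
    }

    lr_table = LRPairTable(
        pd.DataFrame(_LR_PLANTED, columns=["ligand", "receptor", "category"])
    )

    return SimulationSpec(
        n_patients_per_stage={"Normal": 11, "IB": 5, "IIA": 6,
                              "IIB": 9, "III": 4},
        cells_per_patient=cells_per_patient,
        genes=genes,
        cell_type_profiles=profiles,
        cell_type_proportions=dict(CELL_TYPE_PROPORTIONS),
        fibro_subclusters=subclusters,
        eli_up=eli_up,
        eli_dn=eli_dn,
        eli_r=eli_r,
        stage_trajectories=trajectories,
        cluster_geneset_boost={4: ("ELI_UP", 0.75)},
        lr_pairs=lr_table,
        nb_dispersion=4.0,
        library_size_sd=0.25,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# single-cell counts
# ---------------------------------------------------------------------------

def _latent_sigma(r: float, mu: float, theta: float,
                  lib_sd: float) -> float:
    """Log-normal latent-factor sigma inducing count correlation ``r``.

    For two genes with equal mean ``mu`` and NB dispersion ``theta``
    sharing a multiplicative log-normal factor with mean 1 and
    log-variance s^2, the count correlation is
    A * mu^2 / (mu + mu^2 (A+1)/theta + mu^2 A) with A = e^{s^2} - 1.
    Solved for A in closed form; the cell size factor (also log-normal,
    shared by all genes) contributes part of A, so its share is removed.
    """
    if r <= 0:
        return 0.0
    denom = 1.0 - r * (1.0 + 1.0 / theta)
    if denom <= 0:
        raise ValueError(
            f"target correlation {r} infeasible at dispersion {theta}"
        )
    a_total = r * (1.0 / mu + 1.0 / theta) / denom
    a_latent = (1.0 + a_total) / math.exp(lib_sd ** 2) - 1.0
    if a_latent <= 0:
        return 0.0
    return math.sqrt(math.log1p(a_latent))


def generate_scrnaseq(
    spec: SimulationSpec,
) -> tuple[CountMatrix, dict[str, pd.DataFrame]]:
    """Draw a stage-annotated count matrix plus truth tables.

    Counts are negative binomial (gamma-Poisson) with gene-level
    dispersion around a mean that is the cell type's baseline profile
    scaled by a log-normal cell size factor, subcluster marker fold
    changes, per-stage trajectory multipliers (fibroblasts only) and the
    ELI latent factors. Identical seeds give byte-identical output.

    Returns
    -------
    (CountMatrix, truth) where ``truth`` holds ``cells`` (barcode ->
    planted type/subcluster) and ``genes`` (gene -> planted role).
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    genes = spec.genes
    gi = {g: k for k, g in enumerate(genes)}
    types = list(spec.cell_type_proportions)
    type_p = np.array([spec.cell_type_proportions[t] for t in types])

    barcodes: list[str] = []
    meta_rows = []
    cell_type_idx: list[int] = []
    subcluster: list[int] = []
    pat_no = 0
    for stage in [s for s in STAGES if s in spec.n_patients_per_stage]:
        sub_ids = [sc.cluster_id for sc in spec.fibro_subclusters]
        sub_p = np.array(
            [sc.stage_proportions.get(stage, 0.0)
             for sc in spec.fibro_subclusters]
        )
        for _ in range(spec.n_patients_per_stage[stage]):
            pat_no += 1
            patient = f"P{pat_no:02d}"
            tissue = "normal" if stage == "Normal" else "tumor"
            t_idx = rng.choice(len(types), size=spec.cells_per_patient,
                               p=type_p)
            for j, ti in enumerate(t_idx):
                bc = f"{patient}_C{j:04d}"
                barcodes.append(bc)
                cell_type_idx.append(int(ti))
                if types[ti] == "Fibroblast":
                    sc = int(rng.choice(sub_ids, p=sub_p))
                else:
                    sc = -1
                subcluster.append(sc)
                meta_rows.append((bc, patient, tissue, stage))

    n_cells = len(barcodes)
    n_genes = len(genes)
    cell_types = np.array([types[i] for i in cell_type_idx])
    subcluster_arr = np.array(subcluster)
    stage_arr = np.array([r[3] for r in meta_rows])

    # mean matrix: baseline per type, then planted multipliers
    log_mu = np.empty((n_genes, n_cells))
    prof = spec.cell_type_profiles.loc[genes].to_numpy()
    tcol = {t: k for k, t in enumerate(spec.cell_type_profiles.columns)}
    for t in types:
        mask = cell_types == t
        log_mu[:, mask] = np.log(prof[:, [tcol[t]]])

    fib = cell_types == "Fibroblast"
    for sc in spec.fibro_subclusters:
        mask = fib & (subcluster_arr == sc.cluster_id)
        if not mask.any():
            continue
        rows = [gi[g] for g in sc.marker_genes]
        log_mu[np.ix_(rows, np.flatnonzero(mask))] += (
            sc.log2_effect * math.log(2)
        )
    for cid, (set_name, log2fc) in spec.cluster_geneset_boost.items():
        gs = {spec.eli_up.name: spec.eli_up, spec.eli_dn.name: spec.eli_dn}[
            set_name
        ]
        mask = fib & (subcluster_arr == cid)
        if mask.any():
            rows = [gi[g] for g in gs.members if g in gi]
            log_mu[np.ix_(rows, np.flatnonzero(mask))] += log2fc * math.log(2)
    for traj in spec.stage_trajectories.values():
        rows = [gi[g] for g in traj.genes]
        for stage, mult in traj.multipliers.items():
            mask = fib & (stage_arr == stage)
            if mask.any() and mult != 1.0:
                log_mu[np.ix_(rows, np.flatnonzero(mask))] += math.log(mult)

    # shared latent factor per ELI set -> within-set count correlation
    for gs in (spec.eli_up, spec.eli_dn):
        rows = [gi[g] for g in gs.members if g in gi]
        mu_typ = float(np.median(np.exp(log_mu[rows]).mean(axis=1)))
        s = _latent_sigma(spec.eli_r, mu_typ, spec.nb_dispersion,
                          spec.library_size_sd)
        if s > 0:
            z = rng.standard_normal(n_cells)
            log_mu[rows] += s * z - s ** 2 / 2.0

    # log-normal size factors with mean 1
    sd = spec.library_size_sd
    size = np.exp(rng.normal(0.0, sd, size=n_cells) - sd ** 2 / 2.0)
    mu = np.exp(log_mu) * size

    theta = spec.nb_dispersion
    lam = rng.gamma(theta, mu / theta)
    counts = rng.poisson(lam).astype(np.int64)

    meta = pd.DataFrame(
        meta_rows, columns=["barcode", "patient_id", "tissue", "stage"]
    ).set_index("barcode")
    cm = CountMatrix(genes=list(genes), cells=barcodes, counts=counts,
                     cell_meta=meta)

    gene_role = pd.Series("background", index=genes, name="role")
    gene_owner = pd.Series("", index=genes, name="owner")
    for t, markers in CELL_TYPE_MARKERS.items():
        for m in markers:
            if m in gene_role.index:
                gene_role[m] = "type_marker"
                gene_owner[m] = t
    for sc in spec.fibro_subclusters:
        for m in sc.marker_genes:
            gene_role[m] = "subcluster_marker"
            gene_owner[m] = str(sc.cluster_id)
    for gs, role in ((spec.eli_up, "eli_up"), (spec.eli_dn, "eli_dn")):
        for m in gs.members:
            if m in gene_role.index:
                gene_role[m] = role
                gene_owner[m] = gs.name
    gene_traj = pd.Series("", index=genes, name="trajectory")
    for name, traj in spec.stage_trajectories.items():
        for g in traj.genes:
            gene_traj[g] = name

    truth = {
        "cells": pd.DataFrame(
            {
                "patient_id": meta["patient_id"],
                "stage": meta["stage"],
                "cell_type": pd.Series(cell_types, index=barcodes),
                "fibro_subcluster": pd.Series(subcluster_arr,
                                              index=barcodes),
            }
        ),
        "genes": pd.DataFrame(
            {"role": gene_role, "owner": gene_owner, "trajectory": gene_traj}
        ),
    }
    return cm, truth


# ---------------------------------------------------------------------------
# PPI graph with embedded dense ELI subnetwork
# ---------------------------------------------------------------------------

def generate_ppi(
    n_background: int,
    eli_set: GeneSet,
    target_density: float,
    seed: int = 0,
    background_p: float = 0.01,
    cross_p: float = 0.02,
) -> nx.Graph:
    """Erdos-Renyi background with a dense planted ELI subgraph.

    Background nodes are named ``BG0001``... and carry ``role`` =
    'background'; ELI genes carry ``role`` = 'seed'. The induced ELI
    subgraph gets exactly ``ceil(target_density * C(k, 2))`` edges, so
    its density is at least ``target_density``; sparse cross edges give
    the extraction step linker candidates.
    """
    if not background_p < target_density <= 1.0:
        raise ValueError(
            f"target density {target_density} must lie in "
            f"({background_p}, 1]"
        )
    rng = np.random.default_rng(seed)
    bg = [f"BG{i:04d}" for i in range(1, n_background + 1)]
    eli = list(eli_set.members)
    g = nx.Graph()
    g.add_nodes_from(bg, role="background")
    g.add_nodes_from(eli, role="seed")

    iu, ju = np.triu_indices(n_background, k=1)
    mask = rng.random(len(iu)) < background_p
    g.add_edges_from((bg[i], bg[j]) for i, j in zip(iu[mask], ju[mask]))

    k = len(eli)
    n_pairs = k * (k - 1) // 2
    m = math.ceil(target_density * n_pairs)
    chosen = rng.choice(n_pairs, size=m, replace=False)
    ie, je = np.triu_indices(k, k=1)
    g.add_edges_from((eli[ie[c]], eli[je[c]]) for c in sorted(chosen))

    cross = rng.random((k, n_background)) < cross_p
    g.add_edges_from(
        (eli[a], bg[b]) for a, b in zip(*np.nonzero(cross))
    )
    return g


# ---------------------------------------------------------------------------
# bulk two-group cohort (lymph-node N1 vs N0 stand-in)
# ---------------------------------------------------------------------------

def generate_bulk_cohort(
    spec: SimulationSpec,
    n_n0: int = 29,
    n_n1: int = 78,
    log2fc_dn: float = -0.8,
    log2fc_cluster4: float = 0.8,
    mean_scale: float = 20.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.Series]:
    """Bulk NB counts for lymph-node negative (N0) vs positive (N1) samples.

    ELI^dn genes are downregulated and the pro-invasable subcluster-4
    marker genes upregulated in N1, mirroring the direction the
    enrichment analyses must recover. Sample counts default to a
    quarter-scale cohort (the full study has 116 N0 / 312 N1 patients).
    """
    rng = np.random.default_rng(seed)
    genes = spec.genes
    base = spec.cell_type_profiles["Fibroblast"].loc[genes].to_numpy()
    base = base * mean_scale
    lfc = pd.Series(0.0, index=genes)
    for g in spec.eli_dn.members:
        lfc[g] = log2fc_dn
    c4 = next(sc for sc in spec.fibro_subclusters if sc.cluster_id == 4)
    for g in c4.marker_genes:
        lfc[g] = log2fc_cluster4

    groups = pd.Series(["N0"] * n_n0 + ["N1"] * n_n1,
                       index=[f"S{i:03d}" for i in range(n_n0 + n_n1)])
    mu = np.tile(base[:, None], (1, len(groups)))
    mu[:, (groups == "N1").to_numpy()] *= 2.0 ** lfc.to_numpy()[:, None]
    theta = 10.0  # bulk counts are much less dispersed than single cells
    counts = rng.poisson(rng.gamma(theta, mu / theta))
    return (
        pd.DataFrame(counts, index=genes, columns=groups.index),
        groups,
    )


# ---------------------------------------------------------------------------
# invasion front series with planted forks
# ---------------------------------------------------------------------------

def generate_invasion_series(
    n_forks: int,
    fork_depth_px: float,
    interface_len_px: int,
    noise_sd_px: float = 0.0,
    n_timepoints: int = 25,
    seed: int = 0,
    fork_halfwidth_px: float = 30.0,
    compartment_depth_px: float = 200.0,
    min_spacing_px: float = 100.0,
) -> tuple[InvasionSeries, dict]:
    """ROI polygon series with triangular invasive forks.

    The cancer compartment starts as a rectangle behind the interface
    (y in [-compartment_depth, 0], invasion advances in +y). Each fork is
    a triangular bump whose depth grows linearly in time to
    ``fork_depth_px`` at the final time point; pixel noise is additive
    Gaussian on the front position. Truth carries the planted fork
    positions, final depths, and the planted final advance profile.
    """
    margin = fork_halfwidth_px + 10.0
    if n_forks > 0:
        span = interface_len_px - 2 * margin
        if span < (n_forks - 1) * min_spacing_px:
            raise ValueError(
                f"{n_forks} forks with >= {min_spacing_px} px spacing do "
                f"not fit an interface of {interface_len_px} px"
            )
    rng = np.random.default_rng(seed)
    positions = []
    if n_forks > 0:
        # jittered even spacing preserves the minimum gap deterministically
        slots = np.linspace(margin, interface_len_px - margin, n_forks)
        gap = span / max(n_forks - 1, 1)
        jitter = (gap - min_spacing_px) / 2.0 if n_forks > 1 else span / 2.0
        jitter = max(jitter, 0.0)
        positions = np.round(
            slots + rng.uniform(-jitter, jitter, size=n_forks)
        ).astype(int)
        positions = np.clip(positions, margin, interface_len_px - margin)
        positions = np.sort(positions)

    x = np.arange(interface_len_px + 1, dtype=float)
    planted = np.zeros_like(x)
    for p in positions:
        planted += fork_depth_px * np.clip(
            1.0 - np.abs(x - p) / fork_halfwidth_px, 0.0, None
        )

    times = np.arange(n_timepoints, dtype=float)
    tmax = max(times[-1], 1.0)
    polygons = []
    d = compartment_depth_px
    length = float(interface_len_px)
    for t in times:
        adv = planted * (t / tmax)
        if noise_sd_px > 0:
            adv = adv + rng.normal(0.0, noise_sd_px, size=len(adv))
        top = np.column_stack([x[::-1], adv[::-1]])
        verts = np.vstack([[[0.0, -d], [length, -d]], top])
        polygons.append(verts)
    series = InvasionSeries(times=times, polygons=polygons,
                            interface_length=length)
    truth = {
        "fork_positions": np.asarray(positions, dtype=float),
        "fork_depths": np.full(len(positions), float(fork_depth_px)),
        "planted_profile": planted,
    }
    return series, truth
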