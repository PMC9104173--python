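"""Single-cell processing: normalization, embedding, clustering, typing,
marker calling, and stage-wise cluster proportions.

The processing mirrors the standard Seurat-style workflow: depth
normalization to a fixed scale with log1p, PCA on standardized genes
(top 10 components for all cells, top 7 when re-clustering fibroblasts),
Louvain community detection at resolution 1 on a shared-nearest-neighbor
graph, cell-type assignment from marker-gene score maxima, and
Wilcoxon rank-sum marker tests filtered at p < 0.05 and
|log2 fold change| > 0.5.
"""

from __future__ import annotations

import dataclasses
import warnings

import networkx as nx
import numpy as np
import pandas as pd
import scipy.stats
from sklearn.decomposition import PCA
from sklearn.neighbors import NearestNeighbors
from statsmodels.stats.multitest import multipletests

from stromastage.io_formats import CountMatrix

DUCTAL_TYPES = ("Ductal cell 1", "Ductal cell 2")
OTHERS_LABEL = "others"


@dataclasses.dataclass
class NormalizedMatrix:
    """log1p depth-normalized expression (genes x cells) plus metadata."""

    genes: list[str]
    cells: list[str]
    values: np.ndarray
    cell_meta: pd.DataFrame

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.genes), len(self.cells)):
            raise ValueError("values shape does not match genes x cells")
        if (self.values < 0).any():
            raise ValueError("normalized values must be non-negative")

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    def gene_index(self, symbol: str) -> int:
        return self.genes.index(symbol.upper())

    def subset_cells(self, mask: np.ndarray) -> "NormalizedMatrix":
        mask = np.asarray(mask)
        cells = [c for c, m in zip(self.cells, mask) if m]
        return NormalizedMatrix(
            genes=list(self.genes),
            cells=cells,
            values=self.values[:, mask],
            cell_meta=self.cell_meta.loc[cells],
        )


@dataclasses.dataclass
class ClusterLabeling:
    """Cluster assignment per cell with the parameters that produced it."""

    labels: np.ndarray  # dense non-negative ints, one per cell
    params: dict

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        uniq = np.unique(self.labels)
        if len(self.labels) and (
            uniq.min() != 0 or not np.array_equal(uniq,
                                                  np.arange(len(uniq)))
        ):
            raise ValueError("cluster ids must be dense from 0")

    @property
    def n_clusters(self) -> int:
        return int(self.labels.max()) + 1 if len(self.labels) else 0


def normalize(counts: CountMatrix, scale: float = 1e4) -> NormalizedMatrix:
    """Depth-normalize to ``scale`` counts per cell and log1p.

    value(g, c) = log(1 + scale * count(g, c) / depth(c)); cells with
    zero depth map to all-zero columns with a warning.
    """
    if scale <= 0:
        raise ValueError("scale must be positive")
    depth = counts.counts.sum(axis=0).astype(float)
    zero = depth == 0
    if zero.any():
        warnings.warn(
            f"{int(zero.sum())} cell(s) have zero depth; normalized to zeros"
        )
    depth[zero] = 1.0
    values = np.log1p(scale * counts.counts / depth)
    return NormalizedMatrix(
        genes=list(counts.genes),
        cells=list(counts.cells),
        values=values,
        cell_meta=counts.cell_meta.copy(),
    )


def pca_embed(norm: NormalizedMatrix, n_pcs: int = 10
              ) -> tuple[np.ndarray, np.ndarray]:
    """PCA embedding of cells on standardized genes.

    Genes are centered and scaled to unit variance; zero-variance genes
    are dropped. Components are ordered by explained variance with a
    deterministic sign convention (the largest-magnitude gene loading of
    each component is positive). Returns (embedding of shape
    (n_cells, n_pcs), explained variance ratio).
    """
    x = norm.values.T  # cells x genes
    mean = x.mean(axis=0)
    sd = x.std(axis=0)
    keep = sd > 0
    x = (x[:, keep] - mean[keep]) / sd[keep]
    n_pcs = int(n_pcs)
    if n_pcs > min(x.shape):
        raise ValueError(
            f"n_pcs={n_pcs} exceeds min(cells, informative genes)="
            f"{min(x.shape)}"
        )
    pca = PCA(n_components=n_pcs, svd_solver="full")
    emb = pca.fit_transform(x)
    # deterministic sign: flip so the largest |loading| is positive
    for k in range(n_pcs):
        load = pca.components_[k]
        if load[np.argmax(np.abs(load))] < 0:
            emb[:, k] = -emb[:, k]
    return emb, pca.explained_variance_ratio_


def _snn_graph(embedding: np.ndarray, k_neighbors: int) -> nx.Graph:
    """Shared-nearest-neighbor graph with Jaccard edge weights."""
    n = embedding.shape[0]
    nn = NearestNeighbors(n_neighbors=k_neighbors + 1).fit(embedding)
    _, idx = nn.kneighbors(embedding)
    neigh = [set(row[1:]) for row in idx]  # drop self
    g = nx.Graph()
    g.add_nodes_from(range(n))
    for i in range(n):
        for j in idx[i][1:]:
            j = int(j)
            a, b = (i, j) if i < j else (j, i)
            if g.has_edge(a, b):
                continue
            shared = len(neigh[i] & neigh[j])
            w = shared / (2 * k_neighbors - shared)
            if w > 0:
                g.add_edge(a, b, weight=w)
    return g


def cluster_cells(
    embedding: np.ndarray,
    k_neighbors: int = 20,
    resolution: float = 1.0,
    seed: int = 0,
) -> ClusterLabeling:
    """Louvain community detection on the SNN graph of the embedding.

    Cluster ids are relabeled dense from 0 in decreasing cluster size
    (ties broken by smallest member index), so a fixed seed yields
    identical labels.
    """
    n = embedding.shape[0]
    if k_neighbors >= n:
        raise ValueError(f"k_neighbors={k_neighbors} must be < n_cells={n}")
    g = _snn_graph(embedding, k_neighbors)
    comms = nx.community.louvain_communities(
        g, weight="weight", resolution=resolution, seed=seed
    )
    comms = sorted(comms, key=lambda c: (-len(c), min(c)))
    labels = np.empty(n, dtype=int)
    for cid, comm in enumerate(comms):
        labels[list(comm)] = cid
    return ClusterLabeling(
        labels=labels,
        params={"k_neighbors": k_neighbors, "resolution": resolution,
                "seed": seed},
    )


def assign_cell_types(
    labeling: ClusterLabeling,
    norm: NormalizedMatrix,
    marker_map: dict[str, list[str]],
    tau: float = 0.25,
) -> dict[int, str]:
    """Assign a biological identity to each cluster from marker scores.

    The marker score of a cluster for a type is the mean (over the
    cluster's cells and the type's markers) of gene-standardized
    expression. A cluster gets the highest-scoring type above ``tau``;
    clusters exceeding ``tau`` for both ductal marker sets get the
    combined ductal label; clusters below ``tau`` for every type are
    labeled 'others'.
    """
    if not marker_map:
        raise ValueError("marker map is empty")
    x = norm.values
    mean = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    z = (x - mean) / sd
    gene_idx = {g: i for i, g in enumerate(norm.genes)}

    result: dict[int, str] = {}
    for cid in range(labeling.n_clusters):
        cells = labeling.labels == cid
        scores = {}
        for ctype, markers in marker_map.items():
            rows = [gene_idx[m.upper()] for m in markers
                    if m.upper() in gene_idx]
            if not rows:
                scores[ctype] = -np.inf
                continue
            scores[ctype] = float(z[np.ix_(rows, np.flatnonzero(cells))]
                                  .mean())
        above = {t for t, s in scores.items() if s > tau}
        if set(DUCTAL_TYPES) <= above:
            result[cid] = " + ".join(DUCTAL_TYPES)
        elif above:
            result[cid] = max(above, key=lambda t: (scores[t], t))
        else:
            result[cid] = OTHERS_LABEL
    return result


def find_markers(
    norm: NormalizedMatrix,
    labeling: ClusterLabeling,
    cluster_id: int,
    min_log2fc: float = 0.5,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Marker table for one cluster against all other cells.

    Per gene: two-sided Wilcoxon rank-sum on normalized values, a log2
    fold change computed from expm1-means with pseudocount 1, the
    fractions of cells expressing (> 0) inside and outside, a
    Benjamini-Hochberg adjusted p, and the default marker flag using the
    raw-p cutoff (p < alpha and |log2fc| > min_log2fc).
    """
    mask = labeling.labels == cluster_id
    if mask.sum() < 3:
        raise ValueError(
            f"cluster {cluster_id} has {int(mask.sum())} cells (< 3)"
        )
    x_in = norm.values[:, mask]
    x_out = norm.values[:, ~mask]
    res = scipy.stats.mannwhitneyu(
        x_in, x_out, axis=1, alternative="two-sided", method="asymptotic"
    )
    p = np.asarray(res.pvalue)
    mean_in = np.expm1(x_in).mean(axis=1)
    mean_out = np.expm1(x_out).mean(axis=1)
    log2fc = np.log2((mean_in + 1.0) / (mean_out + 1.0))
    p_adj = multipletests(p, method="fdr_bh")[1]
    table = pd.DataFrame(
        {
            "gene": norm.genes,
            "cluster": cluster_id,
            "log2fc": log2fc,
            "p_value": p,
            "p_adjusted": p_adj,
            "frac_in": (x_in > 0).mean(axis=1),
            "frac_out": (x_out > 0).mean(axis=1),
        }
    )
    table["is_marker"] = (table["p_value"] < alpha) & (
        table["log2fc"].abs() > min_log2fc
    )
    return table.sort_values(
        ["p_value", "gene"], kind="mergesort"
    ).reset_index(drop=True)


def merge_indistinct_clusters(
    norm: NormalizedMatrix,
    labeling: ClusterLabeling,
    embedding: np.ndarray,
    min_log2fc: float = 1.0,
    alpha: float = 0.05,
) -> ClusterLabeling:
    """Merge cluster pairs that lack a strongly differential gene.

    Modularity optimization at a fixed resolution splits large
    homogeneous populations, and because the split is chosen from the
    data, the resulting pieces always show weak "markers" along the
    split axis (a selection effect). A split is kept only when it is
    supported by a substantial expression difference: some gene with
    two-sided Wilcoxon Benjamini-Hochberg-adjusted p < ``alpha`` and
    |log2fc| > ``min_log2fc`` (default 1, i.e. at least one twofold
    gene). Candidate pairs are visited in order of centroid distance in
    the embedding and the search repeats until no pair merges.
    Deterministic; subtypes separated only by sub-twofold shifts are
    deliberately collapsed.
    """
    labels = labeling.labels.copy()
    while True:
        ids = np.unique(labels)
        if len(ids) < 2:
            break
        centroids = {
            c: embedding[labels == c].mean(axis=0) for c in ids
        }
        pairs = sorted(
            (
                (np.linalg.norm(centroids[a] - centroids[b]), a, b)
                for i, a in enumerate(ids) for b in ids[i + 1:]
            ),
            key=lambda t: (t[0], t[1], t[2]),
        )
        merged = False
        for _, a, b in pairs:
            xa = norm.values[:, labels == a]
            xb = norm.values[:, labels == b]
            res = scipy.stats.mannwhitneyu(
                xa, xb, axis=1, alternative="two-sided",
                method="asymptotic",
            )
            l2 = np.log2(
                (np.expm1(xa).mean(axis=1) + 1.0)
                / (np.expm1(xb).mean(axis=1) + 1.0)
            )
            q = multipletests(np.asarray(res.pvalue), method="fdr_bh")[1]
            n_markers = int(((q < alpha) & (np.abs(l2) > min_log2fc)).sum())
            if n_markers == 0:
                labels[labels == b] = a
                merged = True
                break
        if not merged:
            break
    # relabel dense, largest first (ties by smallest member index)
    order = sorted(
        np.unique(labels),
        key=lambda c: (-(labels == c).sum(),
                       int(np.flatnonzero(labels == c)[0])),
    )
    remap = {c: k for k, c in enumerate(order)}
    new = np.array([remap[c] for c in labels])
    params = dict(labeling.params)
    params.update({"merge_alpha": alpha, "merge_min_log2fc": min_log2fc})
    return ClusterLabeling(labels=new, params=params)


def stage_proportions(
    labeling: ClusterLabeling, cell_meta: pd.DataFrame
) -> pd.DataFrame:
    """Fraction of each stage's cells per cluster (columns sum to 1).

    Stages with no cells are omitted with a warning.
    """
    stages = [s for s in pd.unique(cell_meta["stage"])]
    counts = pd.crosstab(labeling.labels, cell_meta["stage"].to_numpy())
    empty = [s for s in stages if s not in counts.columns
             or counts[s].sum() == 0]
    for s in empty:
        warnings.warn(f"stage {s!r} has no cells; omitted")
    counts = counts[[s for s in counts.columns if s not in empty]]
    frac = counts / counts.sum(axis=0)
    frac.index.name = "cluster"
    return frac


def embed_2d(embedding: np.ndarray, seed: int = 0,
             perplexity: float = 30.0) -> np.ndarray:
    """t-SNE layout of a PCA embedding (display only, seeded)."""
    from sklearn.manifold import TSNE

    n = embedding.shape[0]
    if n <= perplexity:
        raise ValueError(
            f"perplexity={perplexity} must be < n_cells={n}"
        )
    tsne = TSNE(
        n_components=2, perplexity=perplexity, random_state=seed,
        init="pca",
    )
    return tsne.fit_transform(embedding)
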