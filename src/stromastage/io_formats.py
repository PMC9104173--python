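"""Readers and writers for every external format the pipeline touches.

Formats are deliberately plain text: MatrixMarket (MTX) plus TSV
barcodes/features for sparse counts, CSV for dense counts, GMT for gene
sets, TSV for ligand-receptor pairs and PPI edge lists, and CSV polygon
traces for invasion-assay regions of interest. All gene symbols are
uppercased on ingest; duplicate symbols after uppercasing are rejected.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

from stromastage.invasion_assay import InvasionSeries

STAGES = ("Normal", "IB", "IIA", "IIB", "III")
"""Ordered disease stages: normal pancreas, then AJCC TNM-derived stages."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class CountMatrix:
    """Gene x cell integer count matrix with per-cell metadata.

    Parameters
    ----------
    genes : list of str
        Unique gene symbols (uppercased on construction).
    cells : list of str
        Unique cell barcodes.
    counts : ndarray of shape (n_genes, n_cells)
        Non-negative integer counts.
    cell_meta : DataFrame indexed by barcode
        Must carry ``patient_id``, ``tissue`` ({'normal', 'tumor'}) and
        ``stage`` (one of :data:`STAGES`) for every cell; ``cell_type``
        and ``cluster`` are optional annotations filled in downstream.
    """

    genes: list[str]
    cells: list[str]
    counts: np.ndarray
    cell_meta: pd.DataFrame

    def __post_init__(self) -> None:
        self.genes = [str(g).upper() for g in self.genes]
        if len(set(self.genes)) != len(self.genes):
            dup = pd.Series(self.genes)
            dup = dup[dup.duplicated()].iloc[0]
            raise ValueError(f"duplicate gene symbol after uppercasing: {dup!r}")
        if len(set(self.cells)) != len(self.cells):
            raise ValueError("cell barcodes are not unique")
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (len(self.genes), len(self.cells)):
            raise ValueError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.genes)} genes x {len(self.cells)} cells"
            )
        if not np.issubdtype(self.counts.dtype, np.integer):
            if not np.all(np.equal(np.mod(self.counts, 1), 0)):
                raise ValueError("counts contain non-integer entries")
            self.counts = self.counts.astype(np.int64)
        if (self.counts < 0).any():
            raise ValueError("counts contain negative entries")
        missing = [c for c in self.cells if c not in self.cell_meta.index]
        if missing:
            raise ValueError(f"metadata missing for barcode {missing[0]!r}")
        extra = [c for c in self.cell_meta.index if c not in set(self.cells)]
        if extra:
            raise ValueError(f"metadata barcode not in matrix: {extra[0]!r}")
        self.cell_meta = self.cell_meta.loc[self.cells].copy()
        for col in ("patient_id", "tissue", "stage"):
            if col not in self.cell_meta.columns:
                raise ValueError(f"cell metadata lacks required column {col!r}")
        if self.cell_meta["stage"].isna().any():
            bad = self.cell_meta.index[self.cell_meta["stage"].isna()][0]
            raise ValueError(f"stage label missing for cell {bad!r}")
        unknown = set(self.cell_meta["stage"]) - set(STAGES)
        if unknown:
            raise ValueError(f"unknown stage label(s): {sorted(unknown)}")

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    def gene_index(self, symbol: str) -> int:
        return self.genes.index(symbol.upper())


@dataclasses.dataclass(frozen=True)
class GeneSet:
    """A named, ordered gene set; order matters for top-N truncation."""

    name: str
    members: tuple[str, ...]

    def __post_init__(self) -> None:
        members = tuple(str(m).upper() for m in self.members)
        if not members:
            raise ValueError(f"gene set {self.name!r} is empty")
        if len(set(members)) != len(members):
            seen: set[str] = set()
            for m in members:
                if m in seen:
                    raise ValueError(
                        f"gene set {self.name!r} has duplicate member {m!r}"
                    )
                seen.add(m)
        object.__setattr__(self, "members", members)

    def top(self, n: int) -> "GeneSet":
        """First ``n`` members in the stored (rank) order."""
        return GeneSet(self.name, self.members[:n])

    def __len__(self) -> int:
        return len(self.members)

    def __contains__(self, gene: str) -> bool:
        return str(gene).upper() in set(self.members)


@dataclasses.dataclass
class LRPairTable:
    """Ligand-receptor pair annotation (Ramilowski-style)."""

    table: pd.DataFrame  # columns ligand, receptor, category (optional)

    def __post_init__(self) -> None:
        t = self.table.copy()
        for col in ("ligand", "receptor"):
            if col not in t.columns:
                raise ValueError(f"pair table lacks column {col!r}")
            t[col] = t[col].astype(str).str.upper()
        if "category" not in t.columns:
            t["category"] = ""
        if t.duplicated(subset=["ligand", "receptor"]).any():
            row = t[t.duplicated(subset=["ligand", "receptor"])].iloc[0]
            raise ValueError(
                f"duplicate pair ({row['ligand']}, {row['receptor']})"
            )
        self.table = t.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.table)


# ---------------------------------------------------------------------------
# counts
# ---------------------------------------------------------------------------

_META_COLS = ["patient_id", "tissue", "stage", "cell_type", "cluster"]


def read_counts(path: str | Path, format: str = "mtx+tsv") -> CountMatrix:
    """Read a count matrix directory in ``mtx+tsv`` or ``csv`` layout.

    ``mtx+tsv``: ``matrix.mtx`` (MatrixMarket, genes x cells, 1-based
    coordinates), ``features.tsv``, ``barcodes.tsv``, ``cell_meta.tsv``.
    ``csv``: ``counts.csv`` (genes as rows, barcodes as header) and
    ``cell_meta.tsv``.
    """
    path = Path(path)
    if format == "mtx+tsv":
        mat = scipy.io.mmread(path / "matrix.mtx")
        counts = np.asarray(
            mat.todense() if scipy.sparse.issparse(mat) else mat
        )
        genes = (path / "features.tsv").read_text().split()
        cells = (path / "barcodes.tsv").read_text().split()
    elif format == "csv":
        df = pd.read_csv(path / "counts.csv", index_col=0)
        counts = df.to_numpy()
        genes = [str(g) for g in df.index]
        cells = [str(c) for c in df.columns]
    else:
        raise ValueError(f"unknown counts format {format!r}")
    if not np.all(np.equal(np.mod(counts, 1), 0)):
        raise ValueError("counts contain non-integer entries")
    meta = pd.read_csv(path / "cell_meta.tsv", sep="\t", index_col=0)
    meta.index = meta.index.astype(str)
    return CountMatrix(genes=genes, cells=cells, counts=counts, cell_meta=meta)


def write_counts(cm: CountMatrix, path: str | Path,
                 format: str = "mtx+tsv") -> None:
    """Write a count matrix directory; inverse of :func:`read_counts`."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    if format == "mtx+tsv":
        scipy.io.mmwrite(
            path / "matrix.mtx", scipy.sparse.coo_matrix(cm.counts)
        )
        (path / "features.tsv").write_text("\n".join(cm.genes) + "\n")
        (path / "barcodes.tsv").write_text("\n".join(cm.cells) + "\n")
    elif format == "csv":
        pd.DataFrame(cm.counts, index=cm.genes, columns=cm.cells).to_csv(
            path / "counts.csv"
        )
    else:
        raise ValueError(f"unknown counts format {format!r}")
    meta = cm.cell_meta.copy()
    for col in _META_COLS:
        if col not in meta.columns:
            meta[col] = ""
    meta[_META_COLS].to_csv(path / "cell_meta.tsv", sep="\t")


# ---------------------------------------------------------------------------
# gene sets (GMT)
# ---------------------------------------------------------------------------

def read_gmt(path: str | Path) -> list[GeneSet]:
    """Parse a GMT file: name, description, then members, tab-separated.

    Member order is preserved exactly as written (the invasibility
    signatures are rank-ordered and truncated to their top 100).
    """
    sets = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ValueError(
                f"GMT line {lineno}: expected >= 3 tab-separated fields, "
                f"got {len(fields)}"
            )
        name, _desc, *members = fields
        members = [m for m in members if m]
        if len(set(m.upper() for m in members)) != len(members):
            raise ValueError(f"GMT line {lineno}: duplicate member in {name!r}")
        sets.append(GeneSet(name, tuple(members)))
    return sets


def write_gmt(sets: list[GeneSet], path: str | Path,
              description: str = "na") -> None:
    lines = [
        "\t".join([s.name, description, *s.members]) for s in sets
    ]
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# ligand-receptor pairs and PPI edges
# ---------------------------------------------------------------------------

def read_lr_pairs(path: str | Path) -> LRPairTable:
    """Read a TSV of ligand/receptor[/category] columns."""
    return LRPairTable(pd.read_csv(path, sep="\t"))


def write_lr_pairs(pairs: LRPairTable, path: str | Path) -> None:
    pairs.table.to_csv(path, sep="\t", index=False)


def read_ppi_edges(path: str | Path):
    """Read a TSV edge list (columns gene_a, gene_b) into an undirected
    simple graph. Self-loops are rejected; repeated edges collapse."""
    import networkx as nx

    df = pd.read_csv(path, sep="\t")
    g = nx.Graph()
    for a, b in zip(df["gene_a"].astype(str), df["gene_b"].astype(str)):
        a, b = a.upper(), b.upper()
        if a == b:
            raise ValueError(f"self-loop on {a!r}")
        g.add_edge(a, b)
    return g


def write_ppi_edges(graph, path: str | Path) -> None:
    rows = sorted(tuple(sorted(e)) for e in graph.edges())
    pd.DataFrame(rows, columns=["gene_a", "gene_b"]).to_csv(
        path, sep="\t", index=False
    )


# ---------------------------------------------------------------------------
# invasion-assay ROI traces
# ---------------------------------------------------------------------------

def read_roi_series(path: str | Path,
                    interface_length: float | None = None) -> InvasionSeries:
    """Read an ROI trace CSV with columns time_h, vertex_index, x_px, y_px.

    One closed polygon per time point, in pixel coordinates with the image
    convention (y increases downward). A polygon may repeat its first
    vertex as its last; the duplicate is dropped. Vertices are re-oriented
    counter-clockwise on ingest so the shoelace sign is deterministic.
    When ``interface_length`` is not given it defaults to the x-extent of
    the first polygon.
    """
    from shapely.geometry import Polygon
    from shapely.geometry.polygon import orient

    df = pd.read_csv(path)
    for col in ("time_h", "vertex_index", "x_px", "y_px"):
        if col not in df.columns:
            raise ValueError(f"ROI CSV lacks column {col!r}")
    dup = df.duplicated(subset=["time_h", "vertex_index"])
    if dup.any():
        t_bad = df.loc[dup, "time_h"].iloc[0]
        raise ValueError(f"duplicated time point {t_bad}")
    times = []
    polygons = []
    for t, grp in df.groupby("time_h", sort=False):
        grp = grp.sort_values("vertex_index")
        verts = grp[["x_px", "y_px"]].to_numpy(dtype=float)
        if len(verts) >= 4 and np.allclose(verts[0], verts[-1]):
            verts = verts[:-1]
        if len(verts) < 3:
            raise ValueError(f"polygon at t={t} has fewer than 3 vertices")
        poly = Polygon(verts)
        if not poly.is_simple or not poly.is_valid:
            raise ValueError(f"self-intersecting polygon at t={t}")
        poly = orient(poly, sign=1.0)  # counter-clockwise
        xy = np.asarray(poly.exterior.coords)[:-1]
        times.append(float(t))
        polygons.append(xy)
    times_arr = np.asarray(times, dtype=float)
    if not np.all(np.diff(times_arr) > 0):
        raise ValueError("time points are not strictly increasing")
    if interface_length is None:
        x0 = polygons[0][:, 0]
        interface_length = float(x0.max() - x0.min())
    return InvasionSeries(
        times=times_arr, polygons=polygons, interface_length=interface_length
    )


def write_roi_series(series: InvasionSeries, path: str | Path) -> None:
    rows = []
    for t, poly in zip(series.times, series.polygons):
        for i, (x, y) in enumerate(poly):
            rows.append((t, i, x, y))
    pd.DataFrame(
        rows, columns=["time_h", "vertex_index", "x_px", "y_px"]
    ).to_csv(path, index=False)
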