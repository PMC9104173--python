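"""Ligand-receptor interaction scoring between cell types.

The strength of an interaction between a sender and a receiver cell type
is the product

    S = E_L * E_R * f_L * f_R

of the mean ligand expression in senders (E_L), the mean receptor
expression in receivers (E_R), the fraction of senders expressing the
ligand (f_L), and the fraction of receivers expressing the receptor
(f_R). Expression values are log-normalized means over all cells of the
type; "expressing" means a strictly positive normalized value.
Reporting keeps the top 4 fibroblast-side genes and the top 3 cognate
partner genes per other cell type after expression/fraction cutoffs
(expression >= 0.5 with >= 5% of cells expressing on the ligand side,
>= 10% on the receptor side).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from stromastage.io_formats import LRPairTable
from stromastage.sc_pipeline import NormalizedMatrix

SCORE_COLUMNS = [
    "sender_type", "receiver_type", "ligand", "receptor", "category",
    "E_L", "E_R", "f_L", "f_R", "S", "ligand_missing", "receptor_missing",
]


def lr_strength(
    norm: NormalizedMatrix,
    cell_types: np.ndarray | pd.Series,
    pairs: LRPairTable,
    sender_type: str,
    receiver_type: str,
) -> pd.DataFrame:
    """Score every ligand-receptor pair between two cell types.

    ``cell_types`` assigns a type to each cell of ``norm``. Pair genes
    absent from the matrix score 0 and are flagged. Unknown sender or
    receiver types raise.
    """
    ctypes = np.asarray(cell_types)
    if len(ctypes) != norm.n_cells:
        raise ValueError("cell_types length does not match matrix")
    present = set(np.unique(ctypes))
    for t in (sender_type, receiver_type):
        if t not in present:
            raise ValueError(f"unknown cell type {t!r}")
    send = norm.values[:, ctypes == sender_type]
    recv = norm.values[:, ctypes == receiver_type]
    gene_idx = {g: i for i, g in enumerate(norm.genes)}

    rows = []
    for _, pair in pairs.table.iterrows():
        lig, rec, cat = pair["ligand"], pair["receptor"], pair["category"]
        li = gene_idx.get(lig)
        ri = gene_idx.get(rec)
        e_l = float(send[li].mean()) if li is not None else 0.0
        f_l = float((send[li] > 0).mean()) if li is not None else 0.0
        e_r = float(recv[ri].mean()) if ri is not None else 0.0
        f_r = float((recv[ri] > 0).mean()) if ri is not None else 0.0
        rows.append(
            (
                sender_type, receiver_type, lig, rec, cat,
                e_l, e_r, f_l, f_r, e_l * e_r * f_l * f_r,
                li is None, ri is None,
            )
        )
    return pd.DataFrame(rows, columns=SCORE_COLUMNS)


def select_top_interactions(
    table: pd.DataFrame,
    fibro_side: str = "ligand",
    n_fibro: int = 4,
    n_partner: int = 3,
    min_expr: float = 0.5,
    min_frac_ligand: float = 0.05,
    min_frac_receptor: float = 0.10,
) -> pd.DataFrame:
    """Filter and truncate an LR score table for reporting.

    ``fibro_side`` says which side of the pair the fibroblasts are on:
    'ligand' (fibroblasts send) filters on E_L/f_L, 'receptor'
    (fibroblasts receive) on E_R/f_R. After filtering, fibroblast-side
    genes are ranked by their expression and the top ``n_fibro`` kept;
    within each partner cell type the top ``n_partner`` cognate genes by
    expression are kept. Ties break lexicographically by gene symbol.
    """
    if table.empty:
        raise ValueError("LR score table is empty")
    t = table.copy()
    if fibro_side == "ligand":
        fib_gene, fib_e, fib_f, min_frac = "ligand", "E_L", "f_L", \
            min_frac_ligand
        partner_gene, partner_e = "receptor", "E_R"
        partner_col = "receiver_type"
    elif fibro_side == "receptor":
        fib_gene, fib_e, fib_f, min_frac = "receptor", "E_R", "f_R", \
            min_frac_receptor
        partner_gene, partner_e = "ligand", "E_L"
        partner_col = "sender_type"
    else:
        raise ValueError("fibro_side must be 'ligand' or 'receptor'")

    t = t[(t[fib_e] >= min_expr) & (t[fib_f] >= min_frac)]
    if t.empty:
        return t.reset_index(drop=True)

    # top fibroblast-side genes by expression, ties by symbol
    gene_rank = (
        t.groupby(fib_gene)[fib_e].max().sort_values(ascending=False)
    )
    ordered = sorted(
        gene_rank.index, key=lambda g: (-gene_rank[g], g)
    )
    keep_genes = set(ordered[:n_fibro])
    t = t[t[fib_gene].isin(keep_genes)]

    # per partner type, top cognate genes by expression
    out = []
    for (_, ptype), grp in t.groupby([fib_gene, partner_col], sort=True):
        grp = grp.sort_values(
            [partner_e, partner_gene], ascending=[False, True],
            kind="mergesort",
        )
        out.append(grp.head(n_partner))
    return (
        pd.concat(out)
        .sort_values(["S", fib_gene], ascending=[False, True],
                     kind="mergesort")
        .reset_index(drop=True)
    )


def category_strength(
    table: pd.DataFrame,
    min_ratio: float,
) -> pd.DataFrame:
    """Aggregate interaction strength per functional annotation category.

    For each (sender, receiver) pair of types, categories covering at
    least ``min_ratio`` of that pair-of-types' interactions are kept and
    their summed strength reported (the tabular stand-in for the chord
    diagram; the conventional cutoffs are >= 9% on the ligand side and
    >= 7% on the receptor side).
    """
    rows = []
    for (s, r), grp in table.groupby(["sender_type", "receiver_type"]):
        n_total = len(grp)
        for cat, sub in grp.groupby("category"):
            ratio = len(sub) / n_total
            if ratio >= min_ratio:
                rows.append((s, r, cat, len(sub), ratio, sub["S"].sum()))
    return pd.DataFrame(
        rows,
        columns=["sender_type", "receiver_type", "category",
                 "n_pairs", "ratio", "total_S"],
    )
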