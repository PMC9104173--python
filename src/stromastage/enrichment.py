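"""Gene-set statistics: preranked GSEA, the within-set correlation test,
over-representation analysis, and stage-trajectory pattern mining.

GSEA follows the weighted running-sum formulation used by preranked
fgsea: hits increment by |score|^p normalized to the set total, misses
decrement by 1/(N - |set|); the enrichment score (ES) is the extremum of
the running sum, the permutation p-value compares the observed ES with
same-sign gene-label permutation ES values, and the leading edge is the
set members at or before (after, for negative ES) the extremum.

The within-set correlation test asks whether invasibility-signature
genes co-vary more than the rest of the transcriptome: the strength of
every within-set gene pair (|Pearson r| across cells) is compared with
the strengths of all pairs of genes outside the set by a Welch t-test.

Pattern mining across ordered disease stages follows the short
time-series mining approach: candidate model profiles on an integer
grid of per-stage changes, collapsed to a maximally distinct panel,
genes assigned to the best-correlated profile, and per-profile
significance from the exact permutation null of stage order.
"""

from __future__ import annotations

import dataclasses
import itertools
import math

import numpy as np
import pandas as pd
import scipy.stats
from statsmodels.stats.multitest import multipletests

from stromastage.io_formats import GeneSet
from stromastage.sc_pipeline import NormalizedMatrix


# ---------------------------------------------------------------------------
# ranked lists
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class RankedList:
    """Genes ordered by a signed score, descending, no duplicates."""

    genes: list[str]
    scores: np.ndarray

    def __post_init__(self) -> None:
        self.genes = [str(g).upper() for g in self.genes]
        self.scores = np.asarray(self.scores, dtype=float)
        if len(self.genes) != len(self.scores):
            raise ValueError("genes and scores differ in length")
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("ranked list contains duplicate genes")
        if not np.all(np.isfinite(self.scores)):
            raise ValueError("ranked scores must be finite")
        if np.any(np.diff(self.scores) > 0):
            raise ValueError("scores must be in descending order")

    def __len__(self) -> int:
        return len(self.genes)


def rank_by_log2fc(marker_table: pd.DataFrame) -> RankedList:
    """Ranked list from a marker table, ordered by log2 fold change."""
    t = marker_table.sort_values(
        ["log2fc", "gene"], ascending=[False, True], kind="mergesort"
    )
    return RankedList(list(t["gene"]), t["log2fc"].to_numpy())


def rank_genes_two_group(
    counts: pd.DataFrame, groups: pd.Series, positive: str
) -> RankedList:
    """Rank genes of a bulk cohort by Welch t on log-CPM, ``positive``
    group vs the rest (positive scores mean higher in ``positive``)."""
    x = counts.to_numpy(dtype=float)
    cpm = np.log2(x / x.sum(axis=0, keepdims=True) * 1e6 + 1.0)
    mask = (groups.loc[counts.columns] == positive).to_numpy()
    a, b = cpm[:, mask], cpm[:, ~mask]
    t, _ = scipy.stats.ttest_ind(a, b, axis=1, equal_var=False)
    t = np.nan_to_num(t, nan=0.0)
    order = np.lexsort((counts.index, -t))
    return RankedList(
        [counts.index[i] for i in order], t[order]
    )


# ---------------------------------------------------------------------------
# GSEA
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class EnrichmentResult:
    """Enrichment score with its permutation calibration."""

    set_name: str
    es: float
    nes: float
    p_value: float
    n_perm: int
    size: int
    leading_edge: list[str]


def _es_from_positions(
    pos: np.ndarray, weights: np.ndarray, n_genes: int
) -> float:
    """ES given sorted 0-based hit positions and their |score|^p weights.

    The running sum attains its extrema only at hit positions (just
    after a hit) and just before hits; both candidate sets are evaluated
    in O(k).
    """
    k = len(pos)
    total = weights.sum()
    if total == 0:
        # degenerate all-zero weights: hits increment equally
        cum = np.arange(1, k + 1) / k
    else:
        cum = np.cumsum(weights) / total
    miss = (pos - np.arange(k)) / (n_genes - k)
    tops = cum - miss
    bottoms = np.concatenate([[0.0], cum[:-1]]) - miss
    top = tops.max()
    bottom = bottoms.min()
    # on an exact |max| == |min| tie the negative extremum wins
    return float(top if top > -bottom else bottom)


def gsea(
    ranked: RankedList,
    gene_set: GeneSet,
    weight_p: float = 1.0,
    n_perm: int = 1000,
    seed: int = 0,
) -> EnrichmentResult:
    """Preranked GSEA of one gene set with gene-label permutations.

    The p-value is sign-conditional: a positive observed ES is compared
    only with non-negative permutation ES values (and symmetrically for
    negative), with +1 smoothing, which keeps the null distribution of
    reported p-values uniform. NES is the ES divided by the mean |ES| of
    same-sign permutations.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    n = len(ranked)
    members = set(gene_set.members)
    hit_mask = np.array([g in members for g in ranked.genes])
    k = int(hit_mask.sum())
    if k == 0:
        raise ValueError(
            f"gene set {gene_set.name!r} has no genes in the ranked list"
        )
    if k == n:
        raise ValueError("gene set covers the entire ranked list")
    absw = np.abs(ranked.scores) ** weight_p
    pos = np.flatnonzero(hit_mask)
    es = _es_from_positions(pos, absw[pos], n)

    rng = np.random.default_rng(seed)
    perm_es = np.empty(n_perm)
    for i in range(n_perm):
        p = np.sort(rng.choice(n, size=k, replace=False))
        perm_es[i] = _es_from_positions(p, absw[p], n)

    if es >= 0:
        same = perm_es[perm_es >= 0]
        more = int((same >= es).sum())
    else:
        same = perm_es[perm_es <= 0]
        more = int((same <= es).sum())
    p_value = (more + 1) / (len(same) + 1)
    denom = np.abs(same).mean() if len(same) else np.nan
    nes = es / denom if denom and denom > 0 else np.nan

    # leading edge from the full running sum extremum
    running = np.where(
        hit_mask,
        absw / (absw[hit_mask].sum() or 1.0),
        -1.0 / (n - k),
    ).cumsum()
    if es > 0:
        peak = int(np.argmax(running))
        lead = [g for g, h in zip(ranked.genes[: peak + 1],
                                  hit_mask[: peak + 1]) if h]
    else:
        trough = int(np.argmin(running))
        lead = [g for g, h in zip(ranked.genes[trough:],
                                  hit_mask[trough:]) if h]
    return EnrichmentResult(
        set_name=gene_set.name, es=es, nes=float(nes),
        p_value=float(p_value), n_perm=n_perm, size=k, leading_edge=lead,
    )


# ---------------------------------------------------------------------------
# within-set correlation test
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class CorrelationTestResult:
    """Within-set vs background pairwise correlation-strength contrast."""

    mean_strength_in: float
    mean_strength_out: float
    mean_signed_in: float
    mean_signed_out: float
    t_statistic: float
    p_value: float
    n_pairs_in: int
    n_pairs_out: int


def _pair_strengths(values: np.ndarray) -> np.ndarray:
    """Upper-triangle Pearson correlations of rows (genes) across cells."""
    r = np.corrcoef(values)
    iu = np.triu_indices(len(values), k=1)
    return r[iu]


def geneset_correlation_test(
    norm: NormalizedMatrix,
    gene_set: GeneSet,
    cells: np.ndarray | None = None,
    max_background_pairs: int = 1_000_000,
    seed: int = 0,
) -> CorrelationTestResult:
    """Welch t-test of within-set vs outside-set correlation strengths.

    Strength is |Pearson r| of a gene pair across the chosen cells.
    Within-set pairs are compared against all pairs among genes outside
    the set (mixed pairs excluded); when the background exceeds
    ``max_background_pairs`` pairs, a uniform seeded subsample is used.
    Zero-variance genes are dropped from both sides.
    """
    values = norm.values if cells is None else norm.values[:, cells]
    members = set(gene_set.members)
    in_set = np.array([g in members for g in norm.genes])
    var = values.var(axis=1)
    informative = var > 1e-12  # guards float residue on constant genes
    in_rows = np.flatnonzero(in_set & informative)
    out_rows = np.flatnonzero(~in_set & informative)
    if len(in_rows) < 2:
        raise ValueError("need >= 2 set genes with variance > 0")
    if len(out_rows) < 2:
        raise ValueError("need >= 2 background genes with variance > 0")

    r_in = _pair_strengths(values[in_rows])

    n_out = len(out_rows)
    n_out_pairs = n_out * (n_out - 1) // 2
    if n_out_pairs <= max_background_pairs:
        r_out = _pair_strengths(values[out_rows])
    else:
        rng = np.random.default_rng(seed)
        flat = rng.choice(n_out_pairs, size=max_background_pairs,
                          replace=False)
        # flat index -> (i, j) in the upper triangle
        i = (
            n_out - 2
            - np.floor(
                (np.sqrt(4 * n_out * (n_out - 1) - 8 * flat - 7) - 1) / 2
            )
        ).astype(int)
        j = (
            flat + i + 1 - (i * (2 * n_out - i - 1)) // 2
        ).astype(int)
        x = values[out_rows]
        xc = x - x.mean(axis=1, keepdims=True)
        norms = np.sqrt((xc ** 2).sum(axis=1))
        r_out = (xc[i] * xc[j]).sum(axis=1) / (norms[i] * norms[j])

    s_in, s_out = np.abs(r_in), np.abs(r_out)
    t, p = scipy.stats.ttest_ind(s_in, s_out, equal_var=False)
    return CorrelationTestResult(
        mean_strength_in=float(s_in.mean()),
        mean_strength_out=float(s_out.mean()),
        mean_signed_in=float(r_in.mean()),
        mean_signed_out=float(r_out.mean()),
        t_statistic=float(t),
        p_value=float(p),
        n_pairs_in=len(r_in),
        n_pairs_out=len(r_out),
    )


# ---------------------------------------------------------------------------
# over-representation analysis
# ---------------------------------------------------------------------------

def ora(
    genes: list[str],
    annotation: dict[str, list[str]],
    universe: list[str],
) -> pd.DataFrame:
    """Hypergeometric over-representation of a query against terms.

    One-sided upper tail per term; fold enrichment is
    (overlap/query) / (term/universe), 0 for disjoint terms. BH-adjusted
    q values are reported alongside.
    """
    uni = {str(g).upper() for g in universe}
    query = {str(g).upper() for g in genes}
    if not query <= uni:
        missing = sorted(query - uni)[0]
        raise ValueError(f"query gene {missing!r} not in universe")
    m_univ = len(uni)
    n_query = len(query)
    rows = []
    for term, term_genes in annotation.items():
        tset = {str(g).upper() for g in term_genes} & uni
        k = len(query & tset)
        n_term = len(tset)
        p = scipy.stats.hypergeom.sf(k - 1, m_univ, n_term, n_query)
        fold = (
            (k / n_query) / (n_term / m_univ)
            if n_term and n_query and k else 0.0
        )
        rows.append((term, k, n_term, fold, p))
    out = pd.DataFrame(
        rows, columns=["term", "overlap", "term_size", "fold_enrichment",
                       "p_value"],
    )
    out["q_value"] = multipletests(out["p_value"], method="fdr_bh")[1] \
        if len(out) else []
    return out.sort_values(["p_value", "term"],
                           kind="mergesort").reset_index(drop=True)


# ---------------------------------------------------------------------------
# stage-trajectory pattern mining
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class StagePatternResult:
    """Model profiles over ordered stages and per-profile statistics."""

    stages: list[str]
    profiles: np.ndarray  # n_profiles x n_stages, first stage anchored at 0
    assignment: pd.Series  # gene -> profile index
    counts: np.ndarray  # observed genes per profile
    expected: np.ndarray  # permutation-null expected genes per profile
    p_values: np.ndarray  # binomial upper tail per profile
    p_bonferroni: np.ndarray


def _candidate_profiles(n_stages: int, c: int) -> np.ndarray:
    """All integer profiles starting at 0 with per-stage steps in
    [-c, c]."""
    steps = itertools.product(range(-c, c + 1), repeat=n_stages - 1)
    return np.array([np.concatenate([[0], np.cumsum(s)]) for s in steps],
                    dtype=float)


def _select_distinct(cands: np.ndarray, n_profiles: int) -> np.ndarray:
    """Greedy maximally distinct panel under correlation distance.

    The flat profile is kept first (constant genes need a home); each
    further pick maximizes its minimum distance (1 - Pearson r) to the
    panel, ties broken by candidate order.
    """
    def sim(a: np.ndarray, b: np.ndarray) -> float:
        sa, sb = a.std(), b.std()
        if sa == 0 and sb == 0:
            return 1.0
        if sa == 0 or sb == 0:
            return 0.0
        return float(np.corrcoef(a, b)[0, 1])

    flat = int(np.flatnonzero((cands == 0).all(axis=1))[0])
    chosen = [flat]
    dist = np.array([1.0 - sim(cands[flat], c) for c in cands])
    while len(chosen) < min(n_profiles, len(cands)):
        nxt = int(np.argmax(dist))
        if dist[nxt] <= 0:
            break
        chosen.append(nxt)
        d_new = np.array([1.0 - sim(cands[nxt], c) for c in cands])
        dist = np.minimum(dist, d_new)
    return cands[chosen]


def _assign_many(profiles: np.ndarray, x: np.ndarray) -> np.ndarray:
    """Best-correlated model profile per gene (rows of ``x``).

    Constant genes go to the flat profile (index 0); otherwise the
    profile maximizing Pearson correlation wins, ties to the lowest
    index. Requires the flat profile at index 0; all other profiles are
    non-constant by construction.
    """
    xc = x - x.mean(axis=1, keepdims=True)
    xn = np.sqrt((xc ** 2).sum(axis=1))
    constant = xn == 0
    p = profiles[1:]
    pc = p - p.mean(axis=1, keepdims=True)
    pn = np.sqrt((pc ** 2).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (xc @ pc.T) / np.outer(xn, pn)
    out = np.argmax(r, axis=1) + 1
    out[constant] = 0
    return out


def stage_pattern_mining(
    stage_means: pd.DataFrame,
    n_profiles: int = 50,
    c: int = 2,
    n_perm: int | None = None,
    seed: int = 0,
) -> StagePatternResult:
    """Assign genes to model stage profiles and test profile enrichment.

    ``stage_means`` is a genes x ordered-stages matrix of mean
    expression. Candidate profiles are enumerated on a c-step integer
    grid, collapsed to ``n_profiles`` maximally distinct ones, and each
    gene is assigned to its best-correlated profile after anchoring its
    first stage to 0. The null expectation per profile comes from
    permuting each gene's stage order (all S! orderings when S! <= 720,
    otherwise ``n_perm`` random permutations); per-profile p-values are
    binomial upper tails, Bonferroni-corrected across profiles.
    """
    stages = list(stage_means.columns)
    s = len(stages)
    if s < 3:
        raise ValueError("need >= 3 ordered stages")
    cands = _candidate_profiles(s, c)
    profiles = _select_distinct(cands, n_profiles)
    x = stage_means.to_numpy(dtype=float)
    n_genes = len(x)

    assignment = _assign_many(profiles, x)

    if math.factorial(s) <= 720:
        perms = list(itertools.permutations(range(s)))
    else:
        rng = np.random.default_rng(seed)
        perms = [tuple(rng.permutation(s)) for _ in range(n_perm or 300)]
    null_counts = np.zeros(len(profiles))
    for perm in perms:
        idx = _assign_many(profiles, x[:, list(perm)])
        null_counts += np.bincount(idx, minlength=len(profiles))
    expected_frac = null_counts / (n_genes * len(perms))
    expected = expected_frac * n_genes

    counts = np.bincount(assignment, minlength=len(profiles))
    p_values = np.array(
        [
            scipy.stats.binom.sf(counts[j] - 1, n_genes, expected_frac[j])
            if expected_frac[j] > 0 else (1.0 if counts[j] == 0 else 0.0)
            for j in range(len(profiles))
        ]
    )
    p_bonf = np.minimum(p_values * len(profiles), 1.0)
    return StagePatternResult(
        stages=stages,
        profiles=profiles,
        assignment=pd.Series(assignment, index=stage_means.index,
                             name="profile"),
        counts=counts,
        expected=expected,
        p_values=p_values,
        p_bonferroni=p_bonf,
    )


def stage_mean_matrix(
    norm: NormalizedMatrix, genes: list[str], stages: list[str]
) -> pd.DataFrame:
    """Mean normalized expression per stage for the given genes."""
    gene_rows = [norm.gene_index(g) for g in genes if g.upper()
                 in set(norm.genes)]
    names = [norm.genes[i] for i in gene_rows]
    stage_labels = norm.cell_meta["stage"].to_numpy()
    cols = {}
    for s in stages:
        mask = stage_labels == s
        if not mask.any():
            raise ValueError(f"stage {s!r} has no cells")
        cols[s] = norm.values[np.ix_(gene_rows, np.flatnonzero(mask))].mean(
            axis=1
        )
    return pd.DataFrame(cols, index=names)
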