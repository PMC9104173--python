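"""GSEA, within-set correlation test, ORA, and stage-pattern mining."""

import itertools

import numpy as np
import pandas as pd
import pytest
import scipy.stats

from stromastage import enrichment as en
from stromastage.io_formats import GeneSet
from tests.conftest import make_norm, nb_counts


def brute_force_es(genes, scores, members, weight_p=1.0):
    """Independent running-sum oracle: full walk, negative wins ties."""
    members = {m.upper() for m in members}
    hits = [g.upper() in members for g in genes]
    w = np.abs(np.asarray(scores, float)) ** weight_p
    total = sum(wi for wi, h in zip(w, hits) if h)
    n_miss = len(genes) - sum(hits)
    run, mx, mn = 0.0, 0.0, 0.0
    for i, h in enumerate(hits):
        run += w[i] / total if h else -1.0 / n_miss
        mx, mn = max(mx, run), min(mn, run)
    # structural |max| == |min| ties exist (e.g. a single hit exactly at
    # the midpoint); the negative extremum wins, judged with a float
    # tolerance since this walk accumulates rounding error
    if mx - (-mn) > 1e-9:
        return mx
    return mn


def _ranked(n, rng):
    scores = np.sort(rng.normal(size=n))[::-1]
    return en.RankedList([f"g{j}" for j in range(n)], scores)


# ---------------------------------------------------------------------------
# GSEA
# ---------------------------------------------------------------------------

def test_top_gene_set_has_es_one_bottom_minus_one():
    rl = en.RankedList(list("abcdefghij"), np.arange(10, 0, -1.0))
    top = en.gsea(rl, GeneSet("t", ("a",)), weight_p=0.0, n_perm=100)
    bottom = en.gsea(rl, GeneSet("b", ("j",)), weight_p=0.0, n_perm=100)
    assert top.es == pytest.approx(1.0)
    assert bottom.es == pytest.approx(-1.0)


def test_es_equals_brute_force_oracle_small_list():
    rng = np.random.default_rng(0)
    rl = _ranked(10, rng)
    gs = GeneSet("s", ("g1", "g4", "g9"))
    res = en.gsea(rl, gs, n_perm=100, seed=0)
    assert res.es == pytest.approx(
        brute_force_es(rl.genes, rl.scores, gs.members), abs=1e-12
    )


def test_empty_intersection_rejected():
    rl = en.RankedList(["a", "b"], [1.0, 0.5])
    with pytest.raises(ValueError, match="no genes"):
        en.gsea(rl, GeneSet("s", ("zzz",)), n_perm=100)


def test_leading_edge_subset_and_sign():
    rng = np.random.default_rng(1)
    rl = _ranked(50, rng)
    gs = GeneSet("s", tuple(f"g{i}" for i in range(0, 10)))  # top genes
    res = en.gsea(rl, gs, n_perm=200, seed=1)
    assert res.es > 0
    assert set(res.leading_edge) <= {m.upper() for m in gs.members}
    assert res.leading_edge  # nonempty at the extremum
    assert np.sign(res.nes) == np.sign(res.es)


def test_ranked_list_validation():
    with pytest.raises(ValueError, match="descending"):
        en.RankedList(["a", "b"], [0.1, 0.5])
    with pytest.raises(ValueError, match="duplicate"):
        en.RankedList(["a", "A"], [0.5, 0.1])


# ---------------------------------------------------------------------------
# correlation test
# ---------------------------------------------------------------------------

def test_identical_set_genes_have_strength_one():
    rng = np.random.default_rng(2)
    base = rng.poisson(5.0, 80)
    counts = np.vstack([base, base] + [rng.poisson(5.0, 80)
                                       for _ in range(20)])
    nm = make_norm(counts)
    gs = GeneSet("s", ("G0", "G1"))
    res = en.geneset_correlation_test(nm, gs)
    assert res.mean_strength_in == pytest.approx(1.0)


def test_background_subsampling_is_seeded():
    rng = np.random.default_rng(3)
    counts = nb_counts(rng, 5.0, 2.0, (80, 60))
    nm = make_norm(counts)
    gs = GeneSet("s", tuple(f"G{i}" for i in range(5)))
    a = en.geneset_correlation_test(nm, gs, max_background_pairs=100, seed=5)
    b = en.geneset_correlation_test(nm, gs, max_background_pairs=100, seed=5)
    assert a.mean_strength_out == b.mean_strength_out
    assert a.n_pairs_out == 100


def test_requires_two_variable_set_genes():
    counts = np.ones((5, 10), dtype=int)
    nm = make_norm(counts)
    with pytest.raises(ValueError, match="variance"):
        en.geneset_correlation_test(nm, GeneSet("s", ("G0", "G1")))


# ---------------------------------------------------------------------------
# ORA
# ---------------------------------------------------------------------------

def test_ora_two_by_two_matches_hypergeometric_tail():
    universe = [f"g{i}" for i in range(20)]
    query = universe[:5]
    term = universe[1:6]  # overlap 4
    out = en.ora(query, {"t": term}, universe).set_index("term")
    expect = scipy.stats.hypergeom.sf(3, 20, 5, 5)
    assert out.loc["t", "p_value"] == pytest.approx(expect, rel=1e-12)


def test_ora_exact_term_has_minimal_p_and_disjoint_zero_fold():
    universe = [f"g{i}" for i in range(30)]
    query = universe[:6]
    annotation = {
        "exact": query,
        "partial": universe[3:9],
        "disjoint": universe[10:16],
    }
    out = en.ora(query, annotation, universe).set_index("term")
    assert out["p_value"].idxmin() == "exact"
    assert out.loc["disjoint", "fold_enrichment"] == 0.0


def test_ora_exhaustive_small_universes():
    # all configurations on universes up to 10: p equals the closed form
    for m in (5, 8, 10):
        universe = [f"g{i}" for i in range(m)]
        for nq in (1, 3):
            for nt in (1, 4):
                for k in range(0, min(nq, nt) + 1):
                    query = universe[:nq]
                    term = query[:k] + universe[nq:nq + (nt - k)]
                    if len(term) != nt:
                        continue
                    out = en.ora(query, {"t": term}, universe)
                    expect = scipy.stats.hypergeom.sf(k - 1, m, nt, nq)
                    assert out["p_value"][0] == pytest.approx(
                        expect, rel=1e-12
                    )


def test_ora_query_outside_universe_rejected():
    with pytest.raises(ValueError, match="not in universe"):
        en.ora(["zzz"], {"t": ["a"]}, ["a", "b"])


# ---------------------------------------------------------------------------
# stage-pattern mining
# ---------------------------------------------------------------------------

STAGES5 = ["Normal", "IB", "IIA", "IIB", "III"]


def test_constant_gene_assigned_to_flat_profile():
    sm = pd.DataFrame(
        {s: [1.0, v] for s, v in zip(STAGES5, [0.0, 1.0, 2.0, 1.0, 0.0])},
        index=["flatgene", "bumpy"],
    )
    sm.loc["flatgene"] = 1.0
    res = en.stage_pattern_mining(sm, n_profiles=20)
    assert res.assignment["flatgene"] == 0
    assert np.all(res.profiles[0] == 0)


def test_planted_rise_to_iia_then_fall_cohort():
    rng = np.random.default_rng(4)
    shape = np.array([0.0, 0.5, 1.0, 0.1, -0.3])  # rise to IIA, then fall
    cohort = shape + rng.normal(0, 0.03, size=(40, 5))
    noise = rng.normal(0, 1.0, size=(60, 5))
    sm = pd.DataFrame(
        np.vstack([cohort, noise]), columns=STAGES5,
        index=[f"c{i}" for i in range(40)] + [f"n{i}" for i in range(60)],
    )
    res = en.stage_pattern_mining(sm, seed=0)
    cohort_assign = res.assignment.iloc[:40]
    modal = cohort_assign.mode()[0]
    assert (cohort_assign == modal).mean() >= 0.9
    assert res.p_bonferroni[modal] < 0.05
    prof = res.profiles[modal]
    assert prof.argmax() == 2  # peak at IIA


def test_permuted_stage_null_counts_within_three_se():
    rng = np.random.default_rng(5)
    sm = pd.DataFrame(
        rng.normal(size=(150, 5)), columns=STAGES5,
        index=[f"g{i}" for i in range(150)],
    )
    res = en.stage_pattern_mining(sm, seed=1)
    n = len(sm)
    for j in range(len(res.profiles)):
        f = res.expected[j] / n
        se = np.sqrt(max(f * (1 - f) / n, 1e-12)) * n
        assert abs(res.counts[j] - res.expected[j]) <= 3 * se + 1e-9


def test_needs_three_stages():
    sm = pd.DataFrame(np.ones((3, 2)), columns=["Normal", "IB"])
    with pytest.raises(ValueError, match=">= 3"):
        en.stage_pattern_mining(sm)


def test_gene_counts_partition():
    rng = np.random.default_rng(6)
    sm = pd.DataFrame(rng.normal(size=(30, 5)), columns=STAGES5)
    res = en.stage_pattern_mining(sm)
    assert res.counts.sum() == 30
    assert len(res.assignment) == 30


# ---------------------------------------------------------------------------
# bulk ranking
# ---------------------------------------------------------------------------

def test_rank_genes_two_group_orders_by_welch_t():
    rng = np.random.default_rng(7)
    counts = pd.DataFrame(
        rng.poisson(50, size=(30, 20)),
        index=[f"g{i}" for i in range(30)],
        columns=[f"s{i}" for i in range(20)],
    )
    counts.iloc[0, 10:] *= 5  # strongly up in the positive group
    groups = pd.Series(["A"] * 10 + ["B"] * 10, index=counts.columns)
    rl = en.rank_genes_two_group(counts, groups, positive="B")
    assert rl.genes[0] == "G0"
    assert np.all(np.diff(rl.scores) <= 0)
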