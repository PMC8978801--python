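"""Hypergeometric over-representation, BH FDR, seed pathways, candidates."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from statsmodels.stats.multitest import multipletests

import scznet as sz
from scznet.datasets import candidate_replay_fixture


def enumeration_pvalue(N, K, n, k):
    """Exact upper-tail probability by enumerating all C(N, n) draws."""
    marked = set(range(K))
    hits = total = 0
    for draw in itertools.combinations(range(N), n):
        total += 1
        if len(marked.intersection(draw)) >= k:
            hits += 1
    return hits / total


def test_hypergeom_small_worked_example():
    bg = [f"g{i}" for i in range(10)]
    pathway = bg[:4]
    query = bg[:3]  # k = 3 of n = 3
    p = sz.hypergeom_overrep(query, pathway, bg)
    assert p == pytest.approx(4 / 120, rel=1e-12)


def test_hypergeom_zero_overlap_gives_one():
    bg = [f"g{i}" for i in range(10)]
    assert sz.hypergeom_overrep(bg[5:8], bg[:3], bg) == pytest.approx(1.0)


def test_hypergeom_query_equals_background_gives_one():
    bg = [f"g{i}" for i in range(8)]
    assert sz.hypergeom_overrep(bg, bg[:5], bg) == pytest.approx(1.0)


def test_hypergeom_matches_enumeration_for_all_small_configs():
    """Exhaustive agreement with the draw-enumeration oracle, N <= 12."""
    for N in range(1, 13):
        bg = [f"g{i}" for i in range(N)]
        for K in range(0, N + 1):
            pathway = bg[:K]
            for n in range(0, N + 1):
                for k in range(0, min(n, K) + 1):
                    # query with exactly k pathway members
                    query = pathway[:k] + bg[K : K + (n - k)]
                    if len(query) != n:
                        continue
                    p = sz.hypergeom_overrep(query, pathway, bg)
                    expected = enumeration_pvalue(N, K, n, k)
                    assert math.isclose(p, expected, abs_tol=1e-12), (N, K, n, k)


def test_hypergeom_no_underflow_for_extreme_enrichment():
    """A complete 100-gene overlap in a 10,000-gene background has
    p = 1 / C(10000, 100) ~ 1e-242; the value must not underflow to 0."""
    bg = [f"g{i}" for i in range(10000)]
    p = sz.hypergeom_overrep(bg[:100], bg[:100], bg)
    log_expected = -(math.lgamma(10001) - math.lgamma(101) - math.lgamma(9901))
    assert p > 0.0
    assert math.log(p) == pytest.approx(log_expected, rel=1e-6)


def test_hypergeom_empty_background_rejected():
    with pytest.raises(ValueError):
        sz.hypergeom_overrep(["a"], ["a"], [])


# -- BH FDR ----------------------------------------------------------------

def test_bh_single_pvalue_unchanged():
    assert sz.bh_fdr([0.03]) == pytest.approx([0.03])


def test_bh_hand_computed_vector():
    q = sz.bh_fdr([0.01, 0.02, 0.03, 0.04])
    assert q == pytest.approx([0.04, 0.04, 0.04, 0.04])


def test_bh_preserves_input_order():
    q = sz.bh_fdr([0.04, 0.01])
    assert q[1] < q[0]


def test_bh_rejects_out_of_range():
    with pytest.raises(ValueError):
        sz.bh_fdr([0.5, 1.5])


@settings(deadline=None, derandomize=True)
@given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=40))
def test_bh_matches_statsmodels(pvals):
    q = sz.bh_fdr(pvals)
    _, q_ref, _, _ = multipletests(pvals, method="fdr_bh")
    assert np.allclose(q, q_ref, atol=1e-12)
    order = np.argsort(pvals, kind="stable")
    assert (np.diff(np.asarray(q)[order]) >= -1e-12).all()  # monotone in sorted p
    assert (q >= np.asarray(pvals) - 1e-12).all()


# -- seed pathways and candidates -----------------------------------------

def test_empty_set_a_yields_no_seed_pathways(knowledgebase):
    _, _, pathway_db, _ = knowledgebase
    res = sz.identify_seed_pathways(set(), pathway_db, {"G00001", "G00002"})
    assert len(res) == 0


def test_planted_disease_pathways_recovered_exactly(knowledgebase):
    pool, disease_db, pathway_db, _ = knowledgebase
    res = sz.identify_seed_pathways(disease_db, pathway_db, set(pool["gene"]))
    assert sorted(res["pathway"]) == sorted(
        pid for pid in pathway_db if pid.startswith("disease_")
    )
    assert (res["q"] <= 0.05).all()
    assert res["q"].is_monotonic_increasing


def test_adding_pathwayless_genes_never_decreases_p():
    bg = [f"g{i}" for i in range(50)] + ["extra1", "extra2", "extra3"]
    pathway = bg[:10]
    query = bg[:5] + bg[20:25]
    p0 = sz.hypergeom_overrep(query, pathway, bg)
    p1 = sz.hypergeom_overrep(query + ["extra1", "extra2"], pathway, bg)
    assert p1 >= p0


def test_candidate_assignment_on_curated_fixture():
    """The curated factor lists + five seed pathways give exactly the 18
    candidates, with the multi-pathway gene flagged three times."""
    fx = candidate_replay_fixture()
    res = sz.assign_candidates(
        fx["factor_membership"], fx["set_a"], fx["seed_pathways"],
        fx["pathway_db"], fx["background"],
    )
    assert len(res) == 18
    assert res["gene"].is_unique
    gnb2 = res.set_index("gene").loc["GNB2"]
    assert bool(gnb2["dopaminergic_synapse"])
    assert bool(gnb2["glutamatergic_synapse"])
    assert bool(gnb2["serotonergic_synapse"])
    assert not bool(gnb2["camp_signaling"])
    # every candidate: not in set A, member of each flagged pathway
    for row in res.itertuples(index=False):
        assert row.gene not in fx["set_a"]
        for pid in fx["seed_pathways"]:
            if getattr(row, pid):
                assert row.gene in fx["pathway_db"][pid]


def test_factor_hitting_no_seed_pathway_contributes_nothing():
    fx = candidate_replay_fixture()
    fx["factor_membership"][99] = {"ZZZ1", "ZZZ2"}
    fx["background"] |= {"ZZZ1", "ZZZ2"}
    res = sz.assign_candidates(
        fx["factor_membership"], fx["set_a"], fx["seed_pathways"],
        fx["pathway_db"], fx["background"],
    )
    assert not (res["factor"] == 99).any()
    assert len(res) == 18


def test_factor_overlapping_set_a_rejected():
    fx = candidate_replay_fixture()
    some_a = next(iter(fx["set_a"]))
    fx["factor_membership"][1].add(some_a)
    with pytest.raises(ValueError, match="set B"):
        sz.assign_candidates(
            fx["factor_membership"], fx["set_a"], fx["seed_pathways"],
            fx["pathway_db"], fx["background"],
        )
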