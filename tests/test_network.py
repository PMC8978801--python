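"""Network expansion, cross-region set algebra, hubs and evidence profiles."""

import networkx as nx
import numpy as np
import pandas as pd
import pytest

import scznet as sz
from scznet import network
from scznet.datasets import CAMP, load_hub_genes, region_edge_lists
from scznet.gene_pool import assemble_pool, EVIDENCE_TYPES


def edges_df(triples, region="R1"):
    return pd.DataFrame(
        [{"set_a_gene": a.upper(), "set_b_gene": b.upper(), "pathway": p,
          "region": region, "factor": 1} for a, b, p in triples]
    )


def test_interaction_db_is_symmetric_and_deduplicated():
    db = sz.InteractionDB([("a", "b"), ("B", "A"), ("a", "a"), ("b", "c")])
    assert len(db) == 2
    assert ("A", "B") in db and ("B", "A") in db
    assert ("A", "A") not in db
    assert db.partners("a") == {"B"}


def test_expand_network_hand_enumeration():
    interactions = sz.InteractionDB([("a1", "b1"), ("a1", "x"), ("b1", "b2")])
    edges = sz.expand_network(
        {"P": {"a1", "a2"}}, {1: {"b1", "b2"}}, interactions, region="R1"
    )
    assert len(edges) == 1
    row = edges.iloc[0]
    assert (row["set_a_gene"], row["set_b_gene"], row["pathway"]) == ("A1", "B1", "P")
    assert row["factor"] == 1


def test_expand_network_empty_selection_or_db():
    interactions = sz.InteractionDB([("a1", "b1")])
    assert len(sz.expand_network({"P": {"a1"}}, {}, interactions)) == 0
    empty = sz.InteractionDB()
    assert len(sz.expand_network({"P": {"a1"}}, {1: {"b1"}}, empty)) == 0


def test_set_b_gene_with_two_set_a_partners_yields_two_edges():
    interactions = sz.InteractionDB([("a1", "b1"), ("a2", "b1")])
    edges = sz.expand_network({"P": {"a1", "a2"}}, {1: {"b1"}}, interactions)
    assert len(edges) == 2


def test_intersect_identity_disjoint_and_symmetry():
    e1 = edges_df([("a", "b", "P"), ("a", "c", "P")], region="R1")
    e2 = edges_df([("a", "b", "P"), ("a", "c", "P")], region="R2")
    both = sz.intersect_regions(e1, e2)
    assert len(both) == 2
    assert {"factor_R1", "factor_R2"} <= set(both.columns)

    disjoint = sz.intersect_regions(e1, edges_df([("x", "y", "P")], region="R2"))
    assert len(disjoint) == 0

    swapped = sz.intersect_regions(e2, e1)
    assert set(map(tuple, swapped[network.EDGE_KEY].to_numpy())) == set(
        map(tuple, both[network.EDGE_KEY].to_numpy())
    )


def test_union_properties_and_inclusion_exclusion():
    e1 = edges_df([("a", "b", "P"), ("a", "c", "P")], region="R1")
    e2 = edges_df([("a", "b", "P"), ("x", "y", "Q")], region="R2")
    u = sz.union_networks([e1, e2])
    inter = sz.intersect_regions(e1, e2)
    assert len(u) == 3
    assert len(u) + len(inter) == 2 + 2
    self_union = sz.union_networks([e1, e1])
    assert len(self_union) == len(e1)
    shared = u.set_index(network.EDGE_KEY).loc[("A", "B", "P"), "regions"]
    assert shared == "R1,R2"


def test_curated_region_lists_share_103_edges():
    dlpfc, amygdala = region_edge_lists()
    assert len(dlpfc) == 294
    assert len(amygdala) == 216
    both = sz.intersect_regions(dlpfc, amygdala)
    assert len(both) == 103


def test_star_and_matching_hub_extraction():
    star = edges_df([("a1", "b1", "P"), ("a1", "b2", "P"), ("a1", "b3", "Q")])
    hubs = sz.extract_hubs(star)
    assert list(hubs["gene"]) == ["A1"]
    assert hubs.iloc[0]["degree"] == 3
    assert hubs.iloc[0]["pathways"] == "P;Q"

    matching = edges_df([("a1", "b1", "P"), ("a2", "b2", "P")])
    assert len(sz.extract_hubs(matching)) == 0


def test_rela_has_seven_camp_partners_in_curated_network():
    dlpfc, amygdala = region_edge_lists()
    both = sz.intersect_regions(dlpfc, amygdala)
    both["region"] = "both"
    both["factor"] = both["factor_DLPFC"]
    hubs = sz.extract_hubs(both[both["pathway"] == CAMP])
    rela = hubs.set_index("gene").loc["RELA"]
    assert rela["side"] == "A"
    assert rela["degree"] == 7


def test_hub_degree_ignores_region_labels():
    e = edges_df([("a1", "b1", "P"), ("a1", "b2", "P")], region="R1")
    swapped = e.copy()
    swapped["region"] = "R2"
    h1, h2 = sz.extract_hubs(e), sz.extract_hubs(swapped)
    pd.testing.assert_frame_equal(h1, h2)


def test_hub_evidence_annotation_and_missing_pool_warning(caplog):
    pool = assemble_pool({"gwas": ["A1"], "exome": ["A1", "B1", "B2"]})
    edges = edges_df([("a1", "b1", "P"), ("a1", "b2", "P"), ("zz", "b1", "P"),
                      ("zz", "b2", "P")])
    with caplog.at_level("WARNING"):
        hubs = sz.extract_hubs(edges, pool)
    assert "unknown" in caplog.text
    by_gene = hubs.set_index("gene")
    assert bool(by_gene.loc["A1", "gwas"]) and bool(by_gene.loc["A1", "exome"])
    assert not by_gene.loc["ZZ", list(EVIDENCE_TYPES)].any()


def test_evidence_profile_percentages():
    hubs = pd.DataFrame({
        "gene": ["h1", "h2", "h3", "h4"],
        "side": ["A"] * 4,
        "degree": [2] * 4,
        "pathways": ["P"] * 4,
        **{etype: [False] * 4 for etype in EVIDENCE_TYPES},
    })
    hubs.loc[0, "gwas"] = True
    hubs[list(EVIDENCE_TYPES)] = hubs[list(EVIDENCE_TYPES)].astype(bool)
    hubs["exome"] = True
    profile = sz.evidence_profile(hubs)
    assert profile.loc["A", "gwas"] == 25.0
    assert profile.loc["A", "exome"] == 100.0
    assert profile.loc["A", "cnv"] == 0.0
    assert "B" not in profile.index


def test_evidence_profile_on_curated_hub_table():
    hubs = load_hub_genes()
    assert len(hubs) == 52
    assert (hubs["side"] == "A").sum() == 22
    profile = sz.evidence_profile(hubs)
    # arithmetic cross-check against direct counting
    expected_a_gwas = round(100 * hubs.loc[hubs["side"] == "A", "gwas"].mean(), 1)
    assert profile.loc["A", "gwas"] == expected_a_gwas


def test_graph_exports_round_trip(tmp_path):
    edges = edges_df([("a1", "b1", "P"), ("a1", "b1", "Q"), ("a1", "b2", "P")])
    g = network.to_graph(edges)
    assert g.number_of_edges() == 2
    assert g.edges["A1", "B1"]["pathways"] == "P;Q"

    sif = tmp_path / "net.sif"
    network.write_sif(edges, sif)
    assert len(sif.read_text().splitlines()) == 3

    gml = tmp_path / "net.graphml"
    network.write_graphml(edges, gml)
    back = nx.read_graphml(gml)
    assert set(back.nodes) == {"A1", "B1", "B2"}


def test_expansion_edges_exist_in_interaction_db(pipeline_result, knowledgebase):
    _, _, _, interactions = knowledgebase
    for row in pipeline_result.edges.itertuples(index=False):
        assert (row.set_a_gene, row.set_b_gene) in interactions
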