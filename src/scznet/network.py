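"""Interaction-network expansion, cross-region comparison and hub profiling.

Seed pathways are expanded into networks by linking their set A members to
factor-selected set B genes through experimentally supported physical
interactions. Edge identity is the (set A gene, set B gene, pathway)
triple; networks from two brain regions can be intersected (edges found in
both) or unioned, and hub genes — nodes with at least two distinct
partners — are extracted and annotated with their evidence profile from
the gene pool.
"""

from __future__ import annotations

import logging
from typing import Iterable, Mapping, Sequence

import networkx as nx
import pandas as pd

from .gene_pool import EVIDENCE_TYPES, normalize_symbol

logger = logging.getLogger(__name__)

EDGE_KEY = ["set_a_gene", "set_b_gene", "pathway"]


class InteractionDB:
    """Undirected, deduplicated gene-gene interaction pairs.

    Self-interactions are dropped; lookup is symmetric, ``(a, b)`` and
    ``(b, a)`` are the same edge. Symbols are case-normalized on entry.
    """

    def __init__(self, pairs: Iterable[tuple[str, str]] = ()):  # noqa: D107
        self._pairs: set[frozenset] = set()
        self._partners: dict[str, set[str]] = {}
        for a, b in pairs:
            self.add(a, b)

    def add(self, a: str, b: str) -> None:
        a, b = normalize_symbol(a), normalize_symbol(b)
        if a == b:
            return
        self._pairs.add(frozenset((a, b)))
        self._partners.setdefault(a, set()).add(b)
        self._partners.setdefault(b, set()).add(a)

    def __contains__(self, pair: tuple[str, str]) -> bool:
        a, b = pair
        return frozenset((normalize_symbol(a), normalize_symbol(b))) in self._pairs

    def __len__(self) -> int:
        return len(self._pairs)

    def partners(self, gene: str) -> set[str]:
        return set(self._partners.get(normalize_symbol(gene), set()))

    def pairs(self) -> list[tuple[str, str]]:
        return sorted(tuple(sorted(p)) for p in self._pairs)


def expand_network(
    set_a_pathway_genes: Mapping[str, Iterable[str]],
    selected_set_b: Mapping[int, Iterable[str]],
    interactions: InteractionDB,
    region: str = "",
) -> pd.DataFrame:
    """Build expansion edges between pathway set A genes and selected set B genes.

    One edge is emitted per (set A gene, set B gene, pathway) triple whose
    gene pair is in the interaction database. Rows are ordered by pathway,
    then set A gene, then set B gene.
    """
    if len(interactions) == 0:
        logger.warning("empty interaction database: no edges can be built")
    gene_to_factor: dict[str, int] = {}
    for factor in sorted(selected_set_b):
        for g in selected_set_b[factor]:
            gene_to_factor[normalize_symbol(g)] = factor
    rows = []
    for pathway in sorted(set_a_pathway_genes):
        a_genes = sorted({normalize_symbol(g) for g in set_a_pathway_genes[pathway]})
        n_before = len(rows)
        for a in a_genes:
            hits = interactions.partners(a) & gene_to_factor.keys()
            for b in sorted(hits):
                rows.append({
                    "set_a_gene": a,
                    "set_b_gene": b,
                    "pathway": pathway,
                    "region": region,
                    "factor": gene_to_factor[b],
                })
        logger.info("pathway %s: %d expansion edges", pathway, len(rows) - n_before)
    return pd.DataFrame(rows, columns=[*EDGE_KEY, "region", "factor"])


def _region_tag(edges: pd.DataFrame, fallback: str) -> str:
    if "region" in edges.columns and len(edges) and edges["region"].iloc[0]:
        return str(edges["region"].iloc[0])
    return fallback


def intersect_regions(
    edges_r1: pd.DataFrame, edges_r2: pd.DataFrame
) -> pd.DataFrame:
    """Edges present in both regions, matched on the edge-identity triple.

    The result carries both regions' factor indices as
    ``factor_<region>`` columns and is symmetric in its inputs.
    """
    t1, t2 = _region_tag(edges_r1, "region1"), _region_tag(edges_r2, "region2")
    e1 = edges_r1.drop_duplicates(EDGE_KEY)[EDGE_KEY + ["factor"]]
    e2 = edges_r2.drop_duplicates(EDGE_KEY)[EDGE_KEY + ["factor"]]
    merged = e1.merge(e2, on=EDGE_KEY, suffixes=("_r1", "_r2"))
    merged = merged.rename(
        columns={"factor_r1": f"factor_{t1}", "factor_r2": f"factor_{t2}"}
    )
    return merged.sort_values(EDGE_KEY, kind="stable").reset_index(drop=True)


def union_networks(edge_lists: Sequence[pd.DataFrame]) -> pd.DataFrame:
    """Deduplicated union of edge lists; ``regions`` lists the contributors."""
    frames = []
    for edges in edge_lists:
        sub = edges.drop_duplicates(EDGE_KEY)[EDGE_KEY].copy()
        sub["region"] = _region_tag(edges, "")
        frames.append(sub)
    if not frames:
        return pd.DataFrame(columns=[*EDGE_KEY, "regions"])
    cat = pd.concat(frames, ignore_index=True)
    out = (
        cat.groupby(EDGE_KEY, as_index=False)
        .agg(regions=("region", lambda r: ",".join(sorted(set(filter(None, r))))))
        .sort_values(EDGE_KEY, kind="stable")
        .reset_index(drop=True)
    )
    return out


def extract_hubs(edges: pd.DataFrame, pool: pd.DataFrame | None = None) -> pd.DataFrame:
    """Hub genes: nodes with >= 2 distinct partners across the edge list.

    Degree counts unique partner genes over the whole (union) network, not
    per pathway. Hubs are annotated with their side (A or B), the seed
    pathways they touch, and — when a pool table is supplied — the gene's
    evidence flags; genes missing from the pool get ``unknown`` evidence
    with a warning. Sorted by descending degree, then symbol.
    """
    dedup = edges.drop_duplicates(EDGE_KEY)
    partners: dict[tuple[str, str], set[str]] = {}
    pathways: dict[tuple[str, str], set[str]] = {}
    for row in dedup.itertuples(index=False):
        a, b, p = row.set_a_gene, row.set_b_gene, row.pathway
        partners.setdefault((a, "A"), set()).add(b)
        partners.setdefault((b, "B"), set()).add(a)
        pathways.setdefault((a, "A"), set()).add(p)
        pathways.setdefault((b, "B"), set()).add(p)

    lookup = None
    if pool is not None:
        lookup = pool.set_index("gene")
    missing: list[str] = []
    rows = []
    for (gene, side), part in partners.items():
        if len(part) < 2:
            continue
        rec = {
            "gene": gene,
            "side": side,
            "degree": len(part),
            "pathways": ";".join(sorted(pathways[(gene, side)])),
        }
        if lookup is not None:
            if gene in lookup.index:
                for etype in EVIDENCE_TYPES:
                    rec[etype] = bool(lookup.loc[gene, etype])
                rec["brain_expression"] = lookup.loc[gene, "brain_expression"]
            else:
                missing.append(gene)
                rec.update({etype: False for etype in EVIDENCE_TYPES})
                rec["brain_expression"] = "unknown"
        rows.append(rec)
    if missing:
        logger.warning(
            "%d hub gene(s) not in the pool table, evidence marked unknown: %s",
            len(missing), missing[:5],
        )
    cols = ["gene", "side", "degree", "pathways"]
    if lookup is not None:
        cols += [*EVIDENCE_TYPES, "brain_expression"]
    out = pd.DataFrame(rows, columns=cols)
    if len(out):
        out = out.sort_values(
            ["degree", "gene"], ascending=[False, True], kind="stable"
        ).reset_index(drop=True)
    return out


def evidence_profile(hubs: pd.DataFrame) -> pd.DataFrame:
    """Per-side percentage of hub genes carrying each evidence flag.

    Returns one row per side present in ``hubs`` with one column per
    evidence type, rounded to one decimal place; sides with no hubs are
    omitted with a warning.
    """
    rows = {}
    for side in ("A", "B"):
        sub = hubs[hubs["side"] == side]
        if len(sub) == 0:
            logger.warning("no hub genes on side %s; omitted from profile", side)
            continue
        rows[side] = {
            etype: round(100.0 * sub[etype].astype(bool).mean(), 1)
            for etype in EVIDENCE_TYPES
        }
    out = pd.DataFrame.from_dict(rows, orient="index", columns=list(EVIDENCE_TYPES))
    out.index.name = "side"
    return out


# -- export ---------------------------------------------------------------

def to_graph(edges: pd.DataFrame) -> nx.Graph:
    """Undirected graph with ``pathways`` edge attributes and ``side`` nodes."""
    g = nx.Graph()
    for row in edges.drop_duplicates(EDGE_KEY).itertuples(index=False):
        g.add_node(row.set_a_gene, side="A")
        g.add_node(row.set_b_gene, side="B")
        if g.has_edge(row.set_a_gene, row.set_b_gene):
            prev = g.edges[row.set_a_gene, row.set_b_gene]["pathways"]
            joined = ";".join(sorted(set(prev.split(";")) | {row.pathway}))
            g.edges[row.set_a_gene, row.set_b_gene]["pathways"] = joined
        else:
            g.add_edge(row.set_a_gene, row.set_b_gene, pathways=row.pathway)
    return g


def write_sif(edges: pd.DataFrame, path) -> None:
    """Cytoscape SIF export: one ``source <pathway> target`` line per edge."""
    with open(path, "w") as fh:
        for row in edges.drop_duplicates(EDGE_KEY).itertuples(index=False):
            fh.write(f"{row.set_a_gene}\t{row.pathway}\t{row.set_b_gene}\n")


def write_graphml(edges: pd.DataFrame, path) -> None:
    """Cytoscape-importable GraphML export of the expansion network."""
    nx.write_graphml(to_graph(edges), path)
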