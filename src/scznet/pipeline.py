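"""End-to-end per-region pipeline: pool split -> QC -> RF -> factors ->
seed pathways -> candidates -> network expansion -> hubs."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import pandas as pd

from . import enrichment, expression_prep, gene_pool, network, prioritization
from .expression_prep import ExpressionMatrix
from .network import InteractionDB
from .prioritization import FactorModel

logger = logging.getLogger(__name__)


@dataclass
class RegionResult:
    """Everything one region's run produces, plus the gene-count funnel."""

    region: str
    set_a: set[str]
    set_b: set[str]
    qc_matrix: ExpressionMatrix
    importances: pd.Series
    rf_retained: set[str]
    factor_model: FactorModel
    assignment: dict[int, set[str]]
    seed_pathways: pd.DataFrame
    candidates: pd.DataFrame
    edges: pd.DataFrame
    hubs: pd.DataFrame
    funnel: dict[str, int] = field(default_factory=dict)


def run_region(
    matrix: ExpressionMatrix,
    pool: pd.DataFrame,
    disease_db: Iterable[str],
    pathway_db: Mapping[str, set],
    interactions: InteractionDB,
    *,
    fpkm_min: float = 1.0,
    r_max: float = 0.8,
    n_trees: int = 1000,
    variance_target: float = 0.70,
    max_factors: int = 30,
    loading_min: float = 0.3,
    fdr_max: float = 0.05,
    seed: int = 0,
) -> RegionResult:
    """Run the whole prioritization + expansion pipeline on one region.

    The matrix is restricted to pool genes, QC-filtered, and its set B part
    is pushed through random-forest importance filtering and factor
    analysis; seed pathways come from set A against the pool background,
    candidates from the factor-conditional enrichment, and the expansion
    network from the interaction database.
    """
    pool_genes = set(pool["gene"])
    set_a, set_b = gene_pool.split_sets(pool, disease_db)

    m = matrix.restrict_genes(pool_genes)
    m = expression_prep.filter_low_expression(m, threshold=fpkm_min)
    m = expression_prep.remove_collinear(m, r_threshold=r_max)
    n_qc = m.n_genes

    m_b = m.restrict_genes(set_b)
    importances = prioritization.rf_importance(m_b, n_trees=n_trees, seed=seed)
    retained = prioritization.drop_zero_importance(importances)

    m_rf = m_b.restrict_genes(retained)
    fm = prioritization.fit_factors(
        m_rf, variance_target=variance_target, max_factors=max_factors, seed=seed
    )
    assignment = prioritization.assign_genes_to_factors(fm, loading_min=loading_min)

    background = pool_genes
    seeds = enrichment.identify_seed_pathways(
        set_a, pathway_db, background, fdr_max=fdr_max
    )
    candidates = enrichment.assign_candidates(
        assignment, set_a, seeds, pathway_db, background, fdr_max=fdr_max
    )

    set_a_pathway_genes = {
        pid: set(pathway_db[pid]) & set_a for pid in seeds["pathway"]
    }
    edges = network.expand_network(
        set_a_pathway_genes, assignment, interactions, region=matrix.region
    )
    hubs = network.extract_hubs(edges, pool)

    funnel = {
        "pool": len(pool_genes),
        "set_b": len(set_b),
        "qc": n_qc,
        "qc_set_b": m_b.n_genes,
        "rf_retained": len(retained),
        "factor_assigned": sum(len(v) for v in assignment.values()),
    }
    logger.info("funnel %s: %s", matrix.region, funnel)
    return RegionResult(
        region=matrix.region,
        set_a=set_a,
        set_b=set_b,
        qc_matrix=m,
        importances=importances,
        rf_retained=retained,
        factor_model=fm,
        assignment=assignment,
        seed_pathways=seeds,
        candidates=candidates,
        edges=edges,
        hubs=hubs,
        funnel=funnel,
    )
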