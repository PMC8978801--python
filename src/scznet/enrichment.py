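"""Over-representation analysis with a custom background.

Pathway enrichment is tested with the one-sided (upper-tail) hypergeometric
test — for a query of n background genes of which k fall in a pathway that
covers K of the N background genes, p = P(X >= k), X ~ Hypergeom(N, K, n) —
followed by Benjamini-Hochberg FDR control across the pathway family.
Two stages use it: seed-pathway discovery (set A against the pool
background) and factor-conditional candidate assignment, where each
retained factor is pooled with set A and a factor gene becomes a candidate
if it is a member of a seed pathway that stays significant in that run.
"""

from __future__ import annotations

import logging
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

logger = logging.getLogger(__name__)

#: pathway-ID -> member gene symbols
PathwayDB = Mapping[str, frozenset]

ENRICHMENT_COLUMNS = ("pathway", "overlap", "query_size", "pathway_in_background",
                      "background_size", "p", "q")


def hypergeom_overrep(
    query: Iterable[str], pathway: Iterable[str], background: Iterable[str]
) -> float:
    """Upper-tail hypergeometric p-value for pathway over-representation.

    Query and pathway are intersected with the background before counting.
    The survival function is evaluated in log space by scipy, so extreme
    enrichments (p down to ~1e-300) do not underflow to hard zero
    prematurely.
    """
    bg = set(background)
    if not bg:
        raise ValueError("background must be non-empty")
    q = set(query) & bg
    path = set(pathway) & bg
    n_bg, n_path, n_query = len(bg), len(path), len(q)
    overlap = len(q & path)
    return float(min(1.0, hypergeom.sf(overlap - 1, n_bg, n_path, n_query)))


def bh_fdr(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, returned in the input order.

    q_(i) = min_{j >= i} p_(j) * m / j over the sorted p-values, capped at 1.
    """
    p = np.asarray(list(pvalues), dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum(1.0, np.minimum.accumulate(ranked[::-1])[::-1])
    q = np.empty(m)
    q[order] = q_sorted
    return q


def enrich(
    query: Iterable[str], db: PathwayDB, background: Iterable[str]
) -> pd.DataFrame:
    """Test ``query`` against every pathway in ``db``; BH family = whole db."""
    bg = set(background)
    if not bg:
        raise ValueError("background must be non-empty")
    q = set(query) & bg
    rows = []
    for pid in db:
        members = set(db[pid]) & bg
        rows.append({
            "pathway": pid,
            "overlap": len(q & members),
            "query_size": len(q),
            "pathway_in_background": len(members),
            "background_size": len(bg),
            "p": hypergeom_overrep(q, members, bg),
        })
    res = pd.DataFrame(rows, columns=[c for c in ENRICHMENT_COLUMNS if c != "q"])
    res["q"] = bh_fdr(res["p"]) if len(res) else []
    return res


def identify_seed_pathways(
    set_a: Iterable[str],
    db: PathwayDB,
    background: Iterable[str],
    fdr_max: float = 0.05,
) -> pd.DataFrame:
    """Pathways significantly over-represented in set A (q <= fdr_max).

    Returned sorted by ascending q (then p, then pathway ID); these are the
    disease-associated "seed" pathways that later stages expand.
    """
    set_a = set(set_a)
    outside = set_a - set(background)
    if outside:
        logger.warning(
            "%d set A gene(s) outside the background are dropped from the query",
            len(outside),
        )
    res = enrich(set_a, db, background)
    hits = res[res["q"] <= fdr_max].sort_values(
        ["q", "p", "pathway"], kind="stable"
    ).reset_index(drop=True)
    logger.info("seed pathways at FDR <= %g: %d of %d", fdr_max, len(hits), len(res))
    return hits


def assign_candidates(
    factor_membership: Mapping[int, Iterable[str]],
    set_a: Iterable[str],
    seed_pathways: Sequence[str] | pd.DataFrame,
    db: PathwayDB,
    background: Iterable[str],
    fdr_max: float = 0.05,
) -> pd.DataFrame:
    """Factor-conditional candidate-gene assignment.

    For every factor F, the union F ∪ set A is re-tested against the whole
    pathway db. For each seed pathway that remains at q <= ``fdr_max`` in
    that run, every gene of F that is a member of the pathway is promoted to
    a candidate with that pathway flagged. A gene reached through several
    pathways yields a single row with several flags.

    Returns a table with columns ``gene``, ``factor`` and one boolean column
    per seed pathway, sorted by factor then gene.
    """
    set_a = set(set_a)
    if isinstance(seed_pathways, pd.DataFrame):
        seed_ids = list(seed_pathways["pathway"])
    else:
        seed_ids = list(seed_pathways)

    flags: dict[tuple[str, int], dict[str, bool]] = {}
    for factor in sorted(factor_membership):
        fgenes = set(factor_membership[factor])
        clash = fgenes & set_a
        if clash:
            raise ValueError(
                f"factor {factor} overlaps set A (violates the set B "
                f"precondition): {sorted(clash)[:5]}"
            )
        if not fgenes:
            continue
        res = enrich(fgenes | set_a, db, background).set_index("pathway")
        for pid in seed_ids:
            if pid not in res.index or res.loc[pid, "q"] > fdr_max:
                continue
            for gene in fgenes & set(db[pid]):
                rec = flags.setdefault((gene, factor), {p: False for p in seed_ids})
                rec[pid] = True

    rows = [
        {"gene": gene, "factor": factor, **rec}
        for (gene, factor), rec in flags.items()
    ]
    out = pd.DataFrame(rows, columns=["gene", "factor", *seed_ids])
    if len(out):
        out = out.sort_values(["factor", "gene"], kind="stable").reset_index(drop=True)
    logger.info("candidate genes assigned: %d", len(out))
    return out


def restrict_background_to_universe(
    pool_genes: Iterable[str], db: PathwayDB
) -> set[str]:
    """Optional stricter background: pool genes covered by the pathway db."""
    universe = set().union(*map(set, db.values())) if db else set()
    return set(pool_genes) & universe
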