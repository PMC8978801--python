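"""Assembly of the multi-evidence gene pool and the set A / set B split.

The pool is the union of genes carrying at least one type of prior
schizophrenia evidence (GWAS hits, linkage regions, CNVs, differential
methylation, differential expression, exome mutations). Pool genes found in
a curated disease database form "set A" (already-known disease genes); the
remainder form "set B", the candidates the rest of the pipeline tries to
promote.
"""

from __future__ import annotations

import logging
from typing import Iterable, Mapping

import pandas as pd

logger = logging.getLogger(__name__)

EVIDENCE_TYPES = ("gwas", "linkage", "cnv", "methylation", "diff_expression", "exome")
BRAIN_LEVELS = ("high", "low", "unknown")

#: Column order of a gene-pool table.
POOL_COLUMNS = ("gene", *EVIDENCE_TYPES, "brain_expression", "in_disease_db")


class EmptyPoolError(ValueError):
    """Raised when the union of all evidence lists is empty."""


def normalize_symbol(symbol: str) -> str:
    """Official-symbol identity rule: uppercase, surrounding whitespace stripped."""
    return str(symbol).strip().upper()


def assemble_pool(
    evidence_lists: Mapping[str, Iterable[str]],
    brain_expression: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Merge per-evidence gene lists into one pool table.

    Parameters
    ----------
    evidence_lists : mapping
        Keys must be a subset of :data:`EVIDENCE_TYPES`; values are gene-symbol
        iterables. Symbols are case-normalized; duplicates within one list are
        collapsed with a warning.
    brain_expression : mapping, optional
        Gene -> ``"high"``/``"low"`` annotation; unannotated genes are
        ``"unknown"``. Conflicts cannot arise because the map is a
        pass-through.

    Returns
    -------
    pandas.DataFrame
        One row per distinct gene with boolean evidence flags
        (columns :data:`POOL_COLUMNS`); ``in_disease_db`` starts ``False``
        and is set by :func:`split_sets` callers via :func:`annotate_disease_db`.
    """
    unknown = set(evidence_lists) - set(EVIDENCE_TYPES)
    if unknown:
        raise ValueError(f"unknown evidence types: {sorted(unknown)}")

    membership: dict[str, set[str]] = {}
    for etype, raw in evidence_lists.items():
        symbols = [normalize_symbol(s) for s in raw if str(s).strip()]
        if len(symbols) != len(set(symbols)):
            n_dup = len(symbols) - len(set(symbols))
            logger.warning("%d duplicate symbol(s) in %s list collapsed", n_dup, etype)
        membership[etype] = set(symbols)
        logger.info("evidence list %s: %d genes", etype, len(membership[etype]))

    union = sorted(set().union(*membership.values())) if membership else []
    if not union:
        raise EmptyPoolError("union of evidence lists is empty")

    brain = {normalize_symbol(g): v for g, v in (brain_expression or {}).items()}
    table = pd.DataFrame({"gene": union})
    for etype in EVIDENCE_TYPES:
        table[etype] = table["gene"].isin(membership.get(etype, set()))
    table["brain_expression"] = [brain.get(g, "unknown") for g in union]
    table["in_disease_db"] = False
    logger.info("gene pool assembled: %d genes", len(table))
    return table


def split_sets(
    pool: pd.DataFrame, disease_db: Iterable[str]
) -> tuple[set[str], set[str]]:
    """Partition the pool into set A (in the disease DB) and set B (the rest).

    Disease-database genes absent from the pool are ignored with a warning;
    set A is by definition drawn from the pool only.
    """
    pool_genes = set(pool["gene"])
    db = {normalize_symbol(g) for g in disease_db}
    outside = db - pool_genes
    if outside:
        logger.warning(
            "%d disease-db gene(s) not in the pool are ignored (e.g. %s)",
            len(outside), sorted(outside)[:5],
        )
    set_a = pool_genes & db
    set_b = pool_genes - set_a
    logger.info("set A: %d genes; set B: %d genes", len(set_a), len(set_b))
    return set_a, set_b


def annotate_disease_db(pool: pd.DataFrame, disease_db: Iterable[str]) -> pd.DataFrame:
    """Return a copy of the pool table with ``in_disease_db`` filled in."""
    set_a, _ = split_sets(pool, disease_db)
    out = pool.copy()
    out["in_disease_db"] = out["gene"].isin(set_a)
    return out
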