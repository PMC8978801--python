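"""Quality control of FPKM expression matrices.

Two filters are applied before any machine-learning step: genes with low
average expression (mean FPKM below a threshold across all samples) are
dropped as noise, and collinear genes (pairs whose log-scale Pearson
correlation exceeds a threshold) are pruned greedily so the matrix handed
to the random forest carries no near-duplicate features.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Literal

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

CASE = "case"
CONTROL = "control"


class EmptyMatrixError(ValueError):
    """Raised when a filter removes every gene."""


@dataclass
class ExpressionMatrix:
    """FPKM-scale genes x samples matrix with case/control labels.

    Parameters
    ----------
    values : pandas.DataFrame
        Non-negative FPKM values, one row per gene symbol, one column per
        sample identifier.
    labels : pandas.Series
        Maps every sample identifier to ``"case"`` or ``"control"``.
    region : str
        Free-text tissue tag (e.g. ``"DLPFC"``, ``"amygdala"``).
    """

    values: pd.DataFrame
    labels: pd.Series
    region: str = ""

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            dupes = self.values.index[self.values.index.duplicated()].unique()
            raise ValueError(f"duplicate gene symbols: {list(dupes)[:5]}")
        if self.values.columns.has_duplicates:
            raise ValueError("duplicate sample identifiers")
        missing = [s for s in self.values.columns if s not in self.labels.index]
        if missing:
            raise ValueError(f"unlabelled samples: {missing[:5]}")
        bad = set(self.labels.loc[self.values.columns]) - {CASE, CONTROL}
        if bad:
            raise ValueError(f"labels must be 'case'/'control', got {sorted(bad)}")
        if (self.values.to_numpy() < 0).any():
            raise ValueError("FPKM values must be non-negative")
        self.labels = self.labels.loc[self.values.columns]

    # -- convenience -------------------------------------------------------
    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def log2(self) -> pd.DataFrame:
        """log2(FPKM + 1) transform used by QC, RF and factor analysis."""
        return np.log2(self.values + 1.0)

    def restrict_genes(self, genes: Iterable[str]) -> "ExpressionMatrix":
        """Subset to ``genes`` (input row order preserved)."""
        keep = set(genes)
        rows = [g for g in self.values.index if g in keep]
        if not rows:
            raise EmptyMatrixError("no genes left after restriction")
        return replace(self, values=self.values.loc[rows])


def filter_low_expression(
    m: ExpressionMatrix,
    threshold: float = 1.0,
    agg: Literal["mean", "median"] = "mean",
) -> ExpressionMatrix:
    """Drop genes whose aggregate FPKM across all samples falls below ``threshold``.

    The aggregate is the per-gene mean by default (``agg="median"`` is the
    alternative reading); samples are never removed and gene order is kept.
    """
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    stat = m.values.mean(axis=1) if agg == "mean" else m.values.median(axis=1)
    keep = stat[stat >= threshold].index
    if len(keep) == 0:
        raise EmptyMatrixError("low-expression filter removed every gene")
    logger.info(
        "low-expression filter (%s FPKM >= %g): %d -> %d genes",
        agg, threshold, m.n_genes, len(keep),
    )
    return m.restrict_genes(keep)


def remove_collinear(m: ExpressionMatrix, r_threshold: float = 0.8) -> ExpressionMatrix:
    """Greedily prune genes until no pair has |Pearson r| above ``r_threshold``.

    Correlations are computed on log2(FPKM + 1). Offending pairs are visited
    in descending |r| and the lower-variance member of each still-alive pair
    is dropped; an exact variance tie drops the lexicographically later
    symbol, making the procedure deterministic for a given input order.
    Constant genes have undefined correlation and are treated as r = 0 with
    every partner (with a warning).
    """
    if m.n_samples < 2:
        raise ValueError("need at least 2 samples to compute correlations")
    log = m.log2()
    arr = log.to_numpy()
    var = arr.var(axis=1, ddof=1)
    genes = np.asarray(m.genes)

    constant = arr.max(axis=1) == arr.min(axis=1)
    var[constant] = 0.0
    if constant.any():
        logger.warning(
            "%d constant gene(s) have undefined correlation, treated as r=0: %s",
            constant.sum(), list(genes[constant])[:5],
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(arr)
    corr = np.nan_to_num(corr, nan=0.0)
    np.fill_diagonal(corr, 0.0)

    iu, ju = np.triu_indices(len(genes), k=1)
    absr = np.abs(corr[iu, ju])
    mask = absr > r_threshold
    # descending |r|; equal-|r| ties ordered by symbol pair for determinism
    pairs = sorted(
        zip(absr[mask], iu[mask], ju[mask]),
        key=lambda t: (-t[0], genes[t[1]], genes[t[2]]),
    )

    removed: set[int] = set()
    for _, i, j in pairs:
        if i in removed or j in removed:
            continue
        if var[i] < var[j]:
            drop = i
        elif var[j] < var[i]:
            drop = j
        else:  # exact tie: drop the lexicographically later symbol
            drop = i if genes[i] > genes[j] else j
        removed.add(drop)
    keep = [g for idx, g in enumerate(genes) if idx not in removed]
    if not keep:
        raise EmptyMatrixError("collinearity filter removed every gene")
    if removed:
        logger.info(
            "collinearity filter (|r| > %g): removed %d of %d genes",
            r_threshold, len(removed), len(genes),
        )
    return m.restrict_genes(keep)
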