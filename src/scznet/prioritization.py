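"""Machine-learning gene prioritization: random-forest importance filtering
followed by factor analysis.

A random-forest classifier is fitted on case/control labels; its
impurity-based relative importances (which sum to 1 across genes) define
which genes carry any discriminative signal, and genes with exactly zero
importance are discarded. The surviving genes are then clustered by
maximum-likelihood factor analysis with varimax rotation on standardized
log2(FPKM+1) values: factors are ordered by explained variance and the
shortest prefix reaching the cumulative variance target (default 70%) is
retained. Each gene is finally assigned to the retained factor where it
loads most strongly, provided |loading| clears a minimum.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.decomposition import FactorAnalysis
from sklearn.ensemble import RandomForestClassifier

from .expression_prep import CASE, CONTROL, ExpressionMatrix

logger = logging.getLogger(__name__)


class DegenerateInputError(ValueError):
    """Raised when constant genes make standardization/factoring singular."""


def rf_importance(
    m: ExpressionMatrix,
    labels: pd.Series | None = None,
    n_trees: int = 1000,
    seed: int = 0,
) -> pd.Series:
    """Relative gene importances from a random forest on log2(FPKM+1).

    The impurity-based importances are already normalized so that they sum
    to 1 over genes; the run is fully reproducible for a fixed ``seed``.
    """
    labels = m.labels if labels is None else labels.loc[m.samples]
    y = labels.to_numpy()
    counts = pd.Series(y).value_counts()
    if set(counts.index) != {CASE, CONTROL} or counts.min() < 2:
        raise ValueError("need at least 2 samples in each of case and control")
    X = m.log2().to_numpy().T  # samples x genes
    forest = RandomForestClassifier(
        n_estimators=n_trees, random_state=seed, n_jobs=1
    )
    forest.fit(X, y)
    imp = pd.Series(forest.feature_importances_, index=m.genes, name="importance")
    total = imp.sum()
    if total == 0:
        logger.warning("all RF importances are zero (no informative split found)")
    return imp


def drop_zero_importance(importances: pd.Series) -> set[str]:
    """Genes with strictly positive relative importance."""
    kept = set(importances[importances > 0].index)
    if not kept:
        logger.warning("zero-importance filter removed every gene")
    logger.info("RF filter: %d of %d genes retained", len(kept), len(importances))
    return kept


@dataclass
class FactorModel:
    """Rotated factor solution over the RF-retained genes.

    ``loadings`` is genes x factors (factor columns are 1-based ranks after
    ordering by explained variance); ``explained_variance`` holds each
    factor's share of the total (standardized) variance; ``retained_factors``
    is the prefix reaching ``variance_target``; ``assignment`` maps retained
    factors to their member genes once :func:`assign_genes_to_factors` ran.
    """

    loadings: pd.DataFrame
    explained_variance: pd.Series
    retained_factors: list[int]
    variance_target: float
    assignment: dict[int, set[str]] = field(default_factory=dict)

    @property
    def cumulative_variance(self) -> pd.Series:
        return self.explained_variance.cumsum()


def varimax(loadings: np.ndarray, tol: float = 1e-8, max_iter: int = 200) -> np.ndarray:
    """Orthogonal varimax rotation of a genes x factors loading matrix."""
    n, k = loadings.shape
    if k < 2:
        return loadings.copy()
    rotation = np.eye(k)
    objective = 0.0
    for _ in range(max_iter):
        rotated = loadings @ rotation
        target = rotated ** 3 - rotated * (rotated ** 2).sum(axis=0) / n
        u, s, vt = np.linalg.svd(loadings.T @ target)
        rotation = u @ vt
        new_objective = s.sum()
        if new_objective <= objective * (1 + tol):
            break
        objective = new_objective
    return loadings @ rotation


def fit_factors(
    m: ExpressionMatrix,
    variance_target: float = 0.70,
    max_factors: int = 30,
    seed: int = 0,
    max_iter: int = 2000,
) -> FactorModel:
    """Factor analysis of standardized log2(FPKM+1) with varimax rotation.

    The model is fitted unrotated, factors are ordered by their
    explained-variance proportion (sum of squared loadings over the number
    of genes) and the retained set is the shortest non-empty prefix whose
    cumulative proportion reaches ``variance_target`` — or all factors when
    the target is never reached, mirroring how a cumulative-variance curve
    is cut at a chosen height. Only the retained block is then
    varimax-rotated (rotating before selection would let varimax split a
    dominant general factor across components); rotated factors are
    re-ordered by their rotated variance share and renumbered 1..r.
    """
    if m.n_samples < 3:
        raise ValueError("factor analysis needs at least 3 samples")
    if m.n_genes < 2:
        raise ValueError("factor analysis needs at least 2 genes")
    log = m.log2()
    mu = log.mean(axis=1)
    sd = log.std(axis=1, ddof=1)
    # min == max is the robust constancy test (std accumulates float error)
    dead = log.index[(log.max(axis=1) - log.min(axis=1)) == 0]
    if len(dead):
        raise DegenerateInputError(
            f"constant gene(s) cannot be standardized: {list(dead)[:10]}"
        )
    z = log.sub(mu, axis=0).div(sd, axis=0)
    n_comp = min(m.n_samples - 1, m.n_genes, max_factors)
    fa = FactorAnalysis(n_components=n_comp, random_state=seed, max_iter=max_iter)
    try:
        fa.fit(z.to_numpy().T)  # samples x genes
    except np.linalg.LinAlgError as err:  # pragma: no cover - rare
        raise DegenerateInputError(f"factor analysis failed: {err}") from err

    raw = pd.DataFrame(fa.components_.T, index=m.genes)
    share = (raw ** 2).sum(axis=0) / m.n_genes
    order = share.sort_values(ascending=False, kind="stable").index
    raw, share = raw[order], share[order]

    cum = share.cumsum().to_numpy()
    above = np.nonzero(cum >= variance_target)[0]
    n_keep = int(above[0]) + 1 if len(above) else n_comp
    n_keep = max(1, n_keep)

    rotated = varimax(raw.iloc[:, :n_keep].to_numpy())
    rot_share = (rotated ** 2).sum(axis=0) / m.n_genes
    rot_order = np.argsort(-rot_share, kind="stable")
    blocks = np.hstack([rotated[:, rot_order], raw.iloc[:, n_keep:].to_numpy()])
    loadings = pd.DataFrame(blocks, index=m.genes, columns=range(1, n_comp + 1))
    ev = pd.Series(
        np.concatenate([rot_share[rot_order], share.iloc[n_keep:].to_numpy()]),
        index=range(1, n_comp + 1),
    )
    retained = list(range(1, n_keep + 1))
    logger.info(
        "factor analysis: %d factors fitted, %d retained (cumulative %.1f%% of "
        "variance, target %.0f%%)",
        n_comp, n_keep, 100 * cum[n_keep - 1], 100 * variance_target,
    )
    return FactorModel(
        loadings=loadings,
        explained_variance=ev,
        retained_factors=retained,
        variance_target=variance_target,
    )


def assign_genes_to_factors(
    fm: FactorModel, loading_min: float = 0.3
) -> dict[int, set[str]]:
    """Assign each gene to the retained factor where |loading| is maximal.

    Genes whose best |loading| is below ``loading_min`` stay unassigned;
    exact ties go to the lower factor index. The result is also stored on
    ``fm.assignment``.
    """
    sub = fm.loadings[fm.retained_factors].abs()
    assignment: dict[int, set[str]] = {f: set() for f in fm.retained_factors}
    best = sub.idxmax(axis=1)  # first (lowest) column wins ties
    strength = sub.max(axis=1)
    for gene in sub.index:
        if strength[gene] >= loading_min:
            assignment[int(best[gene])].add(gene)
    n_assigned = sum(len(v) for v in assignment.values())
    logger.info(
        "factor assignment: %d of %d genes assigned (|loading| >= %g)",
        n_assigned, len(sub), loading_min,
    )
    fm.assignment = assignment
    return assignment
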