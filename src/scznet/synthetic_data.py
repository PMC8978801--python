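"""Synthetic expression data and knowledgebase with planted ground truth.

The generator emulates the study design the pipeline targets: positive,
skewed FPKM-like case/control expression matrices with latent-factor
structure (a subset of factors carries a case/control mean shift), and a
consistent knowledgebase — an evidence gene pool containing a disease-db
subset, a pathway collection in which a few pathways are strongly enriched
for disease-db genes, and an interaction set — with known planted candidate
genes and hub genes, so that every downstream stage can be tested for
ground-truth recovery without any external download.

Expression model, per gene g in factor k and sample s:

    x_gs = exp(b_g + lambda_g * F_ks + eps_gs)

with base b_g ~ N(fpkm_location, fpkm_scale^2), loading lambda_g ~
U(0.5, 1), factor score F_ks ~ N(+/- effect_size/2, 1) (sign by
case/control status for informative factors, mean 0 otherwise) and noise
eps_gs ~ N(0, noise_sd^2). Genes outside any factor are independent
log-normal noise of comparable total variance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd

from .expression_prep import CASE, CONTROL, ExpressionMatrix
from .gene_pool import BRAIN_LEVELS, EVIDENCE_TYPES, POOL_COLUMNS
from .network import InteractionDB

logger = logging.getLogger(__name__)

#: Marginal per-gene evidence rates, matching the composition of a
#: ~6,000-gene multi-evidence pool (counts 460/223/392/1,890/683/3,540).
EVIDENCE_RATES = {
    "gwas": 460 / 5948,
    "linkage": 223 / 5948,
    "cnv": 392 / 5948,
    "methylation": 1890 / 5948,
    "diff_expression": 683 / 5948,
    "exome": 3540 / 5948,
}

_LOADING_LOW, _LOADING_HIGH = 0.5, 1.0


class ConfigurationError(ValueError):
    """Invalid simulation/knowledgebase configuration."""


def _gene_symbols(n: int) -> list[str]:
    return [f"G{i:05d}" for i in range(1, n + 1)]


@dataclass(frozen=True)
class SimulationConfig:
    """Study-design parameters of the synthetic expression matrix.

    Defaults describe the standard desk-scale recovery scenario: 2,000
    genes over 60 cases + 60 controls, five latent factors of 40 genes of
    which two are informative with a standardized shift of 1.0.
    """

    n_genes: int = 2000
    n_cases: int = 60
    n_controls: int = 60
    n_factors: int = 5
    genes_per_factor: int = 40
    n_informative_factors: int = 2
    effect_size: float = 1.0
    noise_sd: float = 0.7
    fpkm_location: float = 1.5
    fpkm_scale: float = 0.6
    seed: int = 0
    region: str = "DLPFC"

    def __post_init__(self) -> None:
        counts = {
            "n_genes": self.n_genes, "n_cases": self.n_cases,
            "n_controls": self.n_controls, "n_factors": self.n_factors,
            "genes_per_factor": self.genes_per_factor,
            "n_informative_factors": self.n_informative_factors,
        }
        for name, value in counts.items():
            if value <= 0:
                raise ConfigurationError(f"{name} must be > 0, got {value}")
        if self.n_informative_factors > self.n_factors:
            raise ConfigurationError("n_informative_factors exceeds n_factors")
        if self.n_factors * self.genes_per_factor > self.n_genes:
            raise ConfigurationError("factor genes exceed n_genes")
        if self.effect_size < 0:
            raise ConfigurationError("effect_size must be >= 0")
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be >= 0")


@dataclass(frozen=True)
class KnowledgebaseConfig:
    """Shape of the synthetic evidence pool, pathway db and interactions."""

    pool_size: int = 2600
    disease_db_size: int = 234
    n_pathways: int = 15
    pathway_size: int = 40
    n_interactions: int = 300
    planted_candidates: int = 8
    planted_hubs: int = 4
    n_disease_pathways: int = 5
    disease_fraction: float = 0.7
    seed: int = 0

    def __post_init__(self) -> None:
        if self.disease_db_size > self.pool_size:
            raise ConfigurationError("disease_db_size exceeds pool_size")
        if self.n_disease_pathways > self.n_pathways:
            raise ConfigurationError("n_disease_pathways exceeds n_pathways")
        if self.planted_hubs > self.planted_candidates:
            raise ConfigurationError("planted_hubs exceeds planted_candidates")
        for name in ("pool_size", "n_pathways", "pathway_size", "n_interactions",
                     "planted_candidates"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be > 0")
        slots = self.n_disease_pathways * (
            self.pathway_size - int(self.disease_fraction * self.pathway_size)
        )
        if self.planted_candidates > slots:
            raise ConfigurationError(
                f"planted_candidates={self.planted_candidates} exceeds the "
                f"{slots} non-disease slots in the disease pathways"
            )


@dataclass
class GroundTruth:
    """Planted signal: which genes are informative, candidates and hubs."""

    informative_genes: set[str] = field(default_factory=set)
    planted_candidate_genes: set[str] = field(default_factory=set)
    planted_hub_genes: set[str] = field(default_factory=set)
    factor_membership: dict[int, set[str]] = field(default_factory=dict)


def generate_expression(config: SimulationConfig) -> tuple[ExpressionMatrix, GroundTruth]:
    """Simulate a positive FPKM-scale matrix with planted factor structure."""
    rng = np.random.default_rng(config.seed)
    genes = _gene_symbols(config.n_genes)
    n_samples = config.n_cases + config.n_controls
    samples = [f"CASE_{i:03d}" for i in range(1, config.n_cases + 1)] + [
        f"CTRL_{i:03d}" for i in range(1, config.n_controls + 1)
    ]
    labels = pd.Series(
        [CASE] * config.n_cases + [CONTROL] * config.n_controls, index=samples
    )
    is_case = np.array([1.0] * config.n_cases + [0.0] * config.n_controls)

    base = rng.normal(config.fpkm_location, config.fpkm_scale, size=config.n_genes)
    log_x = np.empty((config.n_genes, n_samples))

    membership: dict[int, set[str]] = {}
    informative: set[str] = set()
    row = 0
    for k in range(1, config.n_factors + 1):
        block = genes[row : row + config.genes_per_factor]
        membership[k] = set(block)
        shift = config.effect_size if k <= config.n_informative_factors else 0.0
        if shift:
            informative |= set(block)
        scores = rng.normal(0.0, 1.0, size=n_samples) + shift * (is_case - 0.5)
        lam = rng.uniform(_LOADING_LOW, _LOADING_HIGH, size=len(block))
        eps = rng.normal(0.0, config.noise_sd, size=(len(block), n_samples))
        log_x[row : row + len(block)] = (
            base[row : row + len(block), None] + lam[:, None] * scores[None, :] + eps
        )
        row += len(block)

    # remaining genes: independent noise of comparable total variance
    n_rest = config.n_genes - row
    if n_rest:
        rest_sd = np.sqrt(config.noise_sd ** 2
                          + (_LOADING_LOW ** 2 + _LOADING_HIGH ** 2) / 2)
        log_x[row:] = base[row:, None] + rng.normal(
            0.0, rest_sd, size=(n_rest, n_samples)
        )

    values = pd.DataFrame(np.exp(log_x), index=genes, columns=samples)
    matrix = ExpressionMatrix(values=values, labels=labels, region=config.region)
    truth = GroundTruth(informative_genes=informative, factor_membership=membership)
    logger.info(
        "simulated %d x %d matrix (%d informative genes in %d of %d factors)",
        config.n_genes, n_samples, len(informative),
        config.n_informative_factors, config.n_factors,
    )
    return matrix, truth


def generate_knowledgebase(
    config: KnowledgebaseConfig,
    truth: GroundTruth,
    expressed_genes: Iterable[str] | None = None,
) -> tuple[pd.DataFrame, set[str], dict[str, set[str]], InteractionDB]:
    """Build a pool table, disease-db set, pathway db and interaction set.

    The planted candidate genes (sampled from the informative-factor genes)
    are written into disease-enriched pathways; the first ``planted_hubs``
    of them additionally receive two interaction edges to distinct
    disease-db members of one of their pathways, making them recoverable
    hubs. ``truth.planted_candidate_genes`` and ``truth.planted_hub_genes``
    are filled in place.

    When ``expressed_genes`` (the genes of the companion expression matrix)
    is given, non-planted pathway members are drawn from the pool genes
    outside the matrix — mirroring real pathway databases, most of whose
    members are not expressed in any one tissue — so the only pathway
    members the factor stage can select are the planted candidates.
    """
    rng = np.random.default_rng(config.seed)
    pool_genes = _gene_symbols(config.pool_size)
    pool_set = set(pool_genes)

    factor_genes = set().union(*truth.factor_membership.values()) \
        if truth.factor_membership else set()
    stray = (factor_genes | truth.informative_genes) - pool_set
    if stray:
        raise ConfigurationError(
            f"ground-truth genes outside the pool (pool_size too small?): "
            f"{sorted(stray)[:5]}"
        )

    # disease db avoids the simulated factor blocks so the planted factor
    # structure lives entirely in set B
    eligible = sorted(pool_set - factor_genes)
    if len(eligible) < config.disease_db_size:
        raise ConfigurationError("pool too small for the requested disease db")
    disease_db = {str(g) for g in rng.choice(eligible, size=config.disease_db_size,
                                             replace=False)}

    informative = sorted(truth.informative_genes)
    if len(informative) < config.planted_candidates:
        raise ConfigurationError("fewer informative genes than planted candidates")
    planted = [str(g) for g in rng.choice(informative, size=config.planted_candidates,
                                          replace=False)]
    hubs = planted[: config.planted_hubs]

    n_disease_members = int(config.disease_fraction * config.pathway_size)
    neutral = sorted(pool_set - disease_db - factor_genes)
    if expressed_genes is not None:
        unexpressed = sorted(set(neutral) - set(expressed_genes))
        # pathways may overlap, so one pathway's worth of symbols suffices
        if len(unexpressed) >= config.pathway_size:
            neutral = unexpressed
        else:
            logger.warning(
                "too few unexpressed pool genes; pathway filler may include "
                "expressed genes"
            )
    pathway_db: dict[str, set[str]] = {}
    disease_ids = [f"disease_pathway_{i:02d}"
                   for i in range(1, config.n_disease_pathways + 1)]
    for i, pid in enumerate(disease_ids):
        members = {str(g) for g in rng.choice(sorted(disease_db),
                                              size=n_disease_members, replace=False)}
        members |= set(planted[i :: config.n_disease_pathways])
        n_fill = config.pathway_size - len(members)
        if n_fill > 0:
            members |= {str(g) for g in rng.choice(neutral, size=n_fill,
                                                   replace=False)}
        pathway_db[pid] = members
    for i in range(1, config.n_pathways - config.n_disease_pathways + 1):
        pathway_db[f"background_pathway_{i:02d}"] = {
            str(g) for g in rng.choice(neutral,
                                       size=min(config.pathway_size, len(neutral)),
                                       replace=False)
        }

    # interactions: anchor every planted candidate to its disease pathway's
    # set A members; hubs get two distinct partners
    interactions = InteractionDB()
    for i, gene in enumerate(planted):
        pid = disease_ids[i % config.n_disease_pathways]
        anchors = sorted(pathway_db[pid] & disease_db)
        n_edges = 2 if gene in hubs else 1
        for partner in rng.choice(anchors, size=n_edges, replace=False):
            interactions.add(partner, gene)
    while len(interactions) < config.n_interactions:
        a, b = rng.choice(pool_genes, size=2, replace=False)
        interactions.add(a, b)

    # evidence flags: independent Bernoulli per type; every pool gene keeps
    # at least one flag (a rate-weighted flag is forced on for all-false rows)
    flags = {
        etype: rng.random(config.pool_size) < rate
        for etype, rate in EVIDENCE_RATES.items()
    }
    none = ~np.logical_or.reduce(list(flags.values()))
    if none.any():
        rates = np.array([EVIDENCE_RATES[e] for e in EVIDENCE_TYPES])
        picks = rng.choice(len(EVIDENCE_TYPES), size=int(none.sum()),
                           p=rates / rates.sum())
        for idx, pick in zip(np.where(none)[0], picks):
            flags[EVIDENCE_TYPES[pick]][idx] = True

    table = pd.DataFrame({"gene": pool_genes})
    for etype in EVIDENCE_TYPES:
        table[etype] = flags[etype]
    table["brain_expression"] = rng.choice(
        BRAIN_LEVELS, size=config.pool_size, p=[0.7, 0.2, 0.1]
    )
    table["in_disease_db"] = table["gene"].isin(disease_db)
    table = table[list(POOL_COLUMNS)]

    truth.planted_candidate_genes = set(planted)
    truth.planted_hub_genes = set(hubs)
    logger.info(
        "knowledgebase: %d pool genes, %d disease-db, %d pathways, %d "
        "interactions; planted %d candidates (%d hubs)",
        config.pool_size, config.disease_db_size, len(pathway_db),
        len(interactions), len(planted), len(hubs),
    )
    return table, disease_db, pathway_db, interactions
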