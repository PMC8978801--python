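"""Packaged reference data and deterministic replay fixtures.

Three small curated tables ship with the package: the 18 schizophrenia
candidate genes with their factor and seed-pathway flags, the 103
interaction edges shared between the DLPFC and amygdala expansion
networks, and the 52 hub genes (22 from set A, 30 from set B) with their
evidence profiles. The fixture builders below wrap these tables into
complete, fully deterministic inputs (set A, pathway db, background,
per-region edge lists) so the candidate-assignment and cross-region
stages can be replayed end to end without external downloads.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

DOPAMINERGIC = "dopaminergic_synapse"
NEUROACTIVE = "neuroactive_ligand_receptor"
GLUTAMATERGIC = "glutamatergic_synapse"
CAMP = "camp_signaling"
SEROTONERGIC = "serotonergic_synapse"

#: The five seed pathways, in their enrichment order.
SEED_PATHWAYS = [DOPAMINERGIC, NEUROACTIVE, GLUTAMATERGIC, CAMP, SEROTONERGIC]

#: Number of set A genes inside each seed pathway.
SET_A_PATHWAY_SIZES = {
    DOPAMINERGIC: 35,
    NEUROACTIVE: 49,
    GLUTAMATERGIC: 26,
    CAMP: 34,
    SEROTONERGIC: 24,
}

SET_A_SIZE = 534
POOL_SIZE = 5948

#: Per-region expansion-network sizes (unique edges; 103 are shared).
REGION_EDGE_TOTALS = {"DLPFC": 294, "amygdala": 216}


def _read(name: str) -> pd.DataFrame:
    with resources.files("scznet.data").joinpath(name).open() as fh:
        return pd.read_csv(fh, sep="\t")


def load_candidate_genes() -> pd.DataFrame:
    """18 candidate genes: gene, factor, Y/- flag per seed pathway."""
    return _read("candidate_genes.tsv")


def load_cross_region_edges() -> pd.DataFrame:
    """103 expansion edges found in both brain regions, with both factor
    indices per set B gene."""
    return _read("cross_region_edges.tsv")


def load_hub_genes() -> pd.DataFrame:
    """52 hub genes with side, pathway membership and evidence flags."""
    df = _read("hub_genes.tsv")
    for col in ("gwas", "linkage", "cnv", "methylation", "diff_expression", "exome"):
        df[col] = df[col].astype(bool)
    return df


def _synthetic_set_a() -> list[str]:
    """Synthetic stand-in symbols for the 534 known disease genes."""
    return [f"SCZA{i:04d}" for i in range(1, SET_A_SIZE + 1)]


def candidate_replay_fixture() -> dict:
    """Deterministic inputs that replay the candidate-assignment stage.

    The factor gene lists and gene->pathway memberships come from the
    curated candidate table; set A and the non-candidate pathway members
    are synthetic stand-in symbols (the real disease-db and pathway-release
    gene lists are not distributed), sized to the published pathway
    composition. Returns a dict with ``factor_membership``, ``set_a``,
    ``pathway_db``, ``background`` and ``seed_pathways``.
    """
    table = load_candidate_genes()
    set_a = _synthetic_set_a()

    pathway_db: dict[str, set[str]] = {}
    offset = 0
    for pid in SEED_PATHWAYS:
        n_a = SET_A_PATHWAY_SIZES[pid]
        members = set(set_a[offset : offset + n_a])
        offset += n_a
        members |= set(table.loc[table[pid] == "Y", "gene"])
        pathway_db[pid] = members

    factor_membership: dict[int, set[str]] = {}
    for factor, sub in table.groupby("factor"):
        genes = set(sub["gene"])
        # a few factor genes outside every pathway: they must contribute
        # no candidates
        genes |= {f"F{factor}NULL{j}" for j in range(1, 4)}
        factor_membership[int(factor)] = genes

    background = set(set_a)
    for members in factor_membership.values():
        background |= members
    n_fill = POOL_SIZE - len(background)
    background |= {f"POOL{i:04d}" for i in range(1, n_fill + 1)}

    return {
        "factor_membership": factor_membership,
        "set_a": set(set_a),
        "pathway_db": pathway_db,
        "background": background,
        "seed_pathways": list(SEED_PATHWAYS),
    }


def region_edge_lists() -> tuple[pd.DataFrame, pd.DataFrame]:
    """Reconstruct the DLPFC and amygdala expansion-edge lists.

    Both lists contain the 103 shared edges (with their region-specific
    factor indices); synthetic region-unique filler edges pad each list to
    its published total (294 DLPFC, 216 amygdala), so intersecting the two
    recovers exactly the shared edges.
    """
    shared = load_cross_region_edges()

    def regional(tag: str, factor_col: str, prefix: str) -> pd.DataFrame:
        df = shared[["set_a_gene", "set_b_gene", "pathway"]].copy()
        df["region"] = tag
        df["factor"] = shared[factor_col]
        n_extra = REGION_EDGE_TOTALS[tag] - len(df)
        extra = pd.DataFrame({
            "set_a_gene": [f"{prefix}A{i:04d}" for i in range(1, n_extra + 1)],
            "set_b_gene": [f"{prefix}B{i:04d}" for i in range(1, n_extra + 1)],
            "pathway": [SEED_PATHWAYS[i % len(SEED_PATHWAYS)] for i in range(n_extra)],
            "region": tag,
            "factor": 1,
        })
        return pd.concat([df, extra], ignore_index=True)

    dlpfc = regional("DLPFC", "factor_dlpfc", "DL")
    amygdala = regional("amygdala", "factor_amygdala", "AM")
    return dlpfc, amygdala


def pool_split_fixture() -> tuple[pd.DataFrame, set[str]]:
    """A 5,948-gene pool with a 534-gene disease db, built from six
    overlapping synthetic evidence lists whose sizes mirror the published
    per-evidence counts (460 GWAS / 223 linkage / 392 CNV / 3,540 exome /
    1,890 methylation / 683 differential expression)."""
    from .gene_pool import assemble_pool

    symbols = [f"P{i:04d}" for i in range(1, POOL_SIZE + 1)]
    lists = {
        "gwas": symbols[0:460],
        "linkage": symbols[460:683],
        "cnv": symbols[683:1075],
        "exome": symbols[1075:4615],
        "methylation": symbols[4615:5948] + symbols[0:557],
        "diff_expression": symbols[0:683],
    }
    pool = assemble_pool(lists)
    disease_db = set(symbols[3::11][:SET_A_SIZE])
    return pool, disease_db
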