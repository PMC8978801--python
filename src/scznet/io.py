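"""Readers and writers for the plain-text formats the pipeline exchanges.

Expression matrices and labels travel as TSV, gene lists as one-symbol-per-
line text (or the first column of a TSV), pathway collections as GMT, and
interactions as two-column TSV (BioGRID TAB exports are accepted by naming
the two symbol columns).
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from gseapy.parser import read_gmt as _read_gmt

from .expression_prep import ExpressionMatrix
from .gene_pool import normalize_symbol
from .network import InteractionDB


# -- expression ------------------------------------------------------------

def read_expression(
    matrix_path, labels_path, region: str = ""
) -> ExpressionMatrix:
    """Load a genes x samples TSV plus a sample->label TSV."""
    values = pd.read_csv(matrix_path, sep="\t", index_col=0)
    labels_df = pd.read_csv(labels_path, sep="\t", index_col=0)
    labels = labels_df.iloc[:, 0].astype(str)
    return ExpressionMatrix(values=values, labels=labels, region=region)


def write_expression(m: ExpressionMatrix, matrix_path, labels_path) -> None:
    m.values.to_csv(matrix_path, sep="\t")
    m.labels.rename("label").to_frame().rename_axis("sample").to_csv(
        labels_path, sep="\t"
    )


# -- gene lists ------------------------------------------------------------

def read_gene_list(path) -> list[str]:
    """One symbol per line, or the first column of a TSV (header ignored
    when it does not look like a symbol list of one column)."""
    symbols = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        symbols.append(normalize_symbol(line.split("\t")[0]))
    return symbols


def write_gene_list(genes: Iterable[str], path) -> None:
    Path(path).write_text("".join(f"{g}\n" for g in sorted(set(genes))))


# -- pathways (GMT) --------------------------------------------------------

def read_pathway_gmt(path) -> dict[str, set[str]]:
    """GMT file -> pathway-ID -> member-symbol set (empty sets rejected)."""
    raw = _read_gmt(str(path))
    db = {pid: {normalize_symbol(g) for g in genes} for pid, genes in raw.items()}
    empty = [pid for pid, members in db.items() if not members]
    if empty:
        raise ValueError(f"pathway(s) with no members: {empty[:5]}")
    return db


def write_pathway_gmt(db: Mapping[str, Iterable[str]], path) -> None:
    with open(path, "w") as fh:
        for pid in db:
            members = "\t".join(sorted(set(db[pid])))
            fh.write(f"{pid}\tna\t{members}\n")


# -- interactions ----------------------------------------------------------

def read_interactions(
    path, col_a: str | int = 0, col_b: str | int = 1
) -> InteractionDB:
    """Two-column interaction TSV; pass BioGRID TAB column names (e.g.
    ``"Official Symbol Interactor A"``) through ``col_a``/``col_b``."""
    table = pd.read_csv(path, sep="\t")
    a = table[col_a] if isinstance(col_a, str) else table.iloc[:, col_a]
    b = table[col_b] if isinstance(col_b, str) else table.iloc[:, col_b]
    return InteractionDB(zip(a.astype(str), b.astype(str)))


def write_interactions(db: InteractionDB, path) -> None:
    pd.DataFrame(db.pairs(), columns=["gene_a", "gene_b"]).to_csv(
        path, sep="\t", index=False
    )
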