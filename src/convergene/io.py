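"""Tab-separated I/O for every typed table in the pipeline.

All tabular files are TSV with a header row.  Gene and sample identifiers
are case-preserved and matched case-sensitively.  Expression matrices
have genes in rows (first column the gene id) and sample ids as the
header; phenotypes are a two-column (sample, phenotype) file.
"""

from __future__ import annotations

import logging
from pathlib import Path

import networkx as nx
import pandas as pd

from .synthdata import ExpressionStudy

logger = logging.getLogger(__name__)


def write_expression_tsv(
    study: ExpressionStudy, expr_path: str | Path, pheno_path: str | Path
) -> None:
    """Write an expression matrix and its phenotype file."""
    out = study.values.copy()
    out.index.name = "gene"
    out.to_csv(expr_path, sep="\t")
    pheno = study.phenotype.rename("phenotype").to_frame()
    pheno.index.name = "sample"
    pheno.to_csv(pheno_path, sep="\t")


def read_expression_tsv(
    expr_path: str | Path, pheno_path: str | Path, dataset_name: str | None = None
) -> ExpressionStudy:
    """Read an expression study, dropping samples with missing values.

    Every sample column must appear in the phenotype file.  Samples with
    any missing expression value are removed (the count is logged), then
    the study is validated (both classes present, unique ids).
    """
    values = pd.read_csv(expr_path, sep="\t", index_col=0)
    if not values.index.is_unique:
        dupes = values.index[values.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate gene ids in {expr_path}: {dupes}")
    pheno = pd.read_csv(pheno_path, sep="\t", index_col=0)["phenotype"]
    missing = [s for s in values.columns if s not in pheno.index]
    if missing:
        raise ValueError(f"samples missing from phenotype file: {missing}")
    values.index.name = None
    values.columns.name = None
    incomplete = values.columns[values.isna().any(axis=0)]
    if len(incomplete):
        logger.info(
            "dropping %d sample(s) with missing values: %s",
            len(incomplete),
            list(incomplete),
        )
        values = values.drop(columns=incomplete)
    pheno = pheno.loc[values.columns]
    return ExpressionStudy(
        values=values,
        phenotype=pheno,
        dataset_name=dataset_name or Path(expr_path).stem,
    )


def write_table(frame: pd.DataFrame, path: str | Path, index: bool = False) -> None:
    """Write any typed table as TSV."""
    frame.to_csv(path, sep="\t", index=index)


def read_evidence_table(path: str | Path) -> pd.DataFrame:
    """Read an evidence TSV in the CFG schema.

    Required columns: gene, eqtl_count, gwas_count, ppi_partners,
    early_deg, abeta_r, abeta_sig, tau_r, tau_sig.  "-" marks an empty
    partner set; "NA" a missing count or flag.
    """
    frame = pd.read_csv(path, sep="\t", dtype={"eqtl_count": str, "gwas_count": str})
    required = {
        "gene", "eqtl_count", "gwas_count", "ppi_partners",
        "early_deg", "abeta_r", "abeta_sig", "tau_r", "tau_sig",
    }
    missing = required - set(frame.columns)
    if missing:
        raise ValueError(f"{path}: missing evidence columns {sorted(missing)}")
    return frame


def read_edge_list(path: str | Path) -> nx.Graph:
    """Read a two-column undirected edge list; deduplicated, symmetrized.

    Self-loops are rejected with the offending line number.
    """
    graph = nx.Graph()
    with open(path) as fh:
        header = fh.readline()
        if not header:
            return graph
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 2:
                raise ValueError(f"{path}:{lineno}: expected two columns")
            u, v = fields[0], fields[1]
            if u == v:
                raise ValueError(f"{path}:{lineno}: self-loop on {u}")
            graph.add_edge(u, v)
    return graph


def write_edge_list(graph: nx.Graph, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("gene_a\tgene_b\n")
        for u, v in sorted(tuple(sorted(e)) for e in graph.edges):
            fh.write(f"{u}\t{v}\n")


def read_gene_list(path: str | Path) -> list[str]:
    """One gene per line (blank lines skipped)."""
    with open(path) as fh:
        return [line.strip() for line in fh if line.strip()]
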