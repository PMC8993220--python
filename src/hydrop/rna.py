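"""UMI-collapsed gene counting and RNA QC filters.

The counting contract is defined on a post-alignment assignment table —
one row per sequenced read with its corrected cell barcode, UMI and
assigned gene — so it stays independent of any particular aligner's
barcode-geometry parameters.  A transcript count is the number of distinct
UMIs observed per (barcode, gene) among mapped records; UMI collapse is
exact-match (no 1-mismatch UMI network), which is simple and deterministic.

Cell/gene filtering follows the droplet-snRNA convention of capping
detected genes (ambient/doublet guard) and mitochondrial UMI fraction
(damaged-nucleus guard), then dropping genes seen in too few remaining
cells.  The order — cells first, then genes — is fixed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

__all__ = [
    "GeneAssignment",
    "CountMatrix",
    "build_count_matrix",
    "filter_cells_genes",
    "sequencing_efficiency",
    "per_cell_summary",
]

ASSIGNMENT_COLUMNS = ["barcode", "umi", "gene_id", "mapped_ok"]


@dataclass(frozen=True)
class GeneAssignment:
    """One read's barcode/UMI/gene assignment (an aligner's output contract)."""

    barcode: str
    umi: str
    gene_id: str
    mapped_ok: bool = True


@dataclass
class CountMatrix:
    """Sparse UMI count matrix, cells x genes.

    ``matrix[i, j]`` is the number of distinct UMIs for barcode
    ``barcodes[i]`` and gene ``genes[j]``; the grand total equals the
    number of distinct mapped (barcode, gene, umi) triples, exactly.
    """

    matrix: sp.csr_matrix
    barcodes: pd.Index
    genes: pd.Index
    n_dropped_empty_umi: int = 0

    @property
    def total_umis(self) -> int:
        return int(self.matrix.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.matrix.toarray(), index=self.barcodes, columns=self.genes
        )

    def write_mtx(self, prefix) -> None:
        """Write MatrixMarket (genes x cells, the conventional orientation)
        plus ``<prefix>barcodes.tsv`` and ``<prefix>features.tsv``."""
        import scipy.io as sio

        sio.mmwrite(f"{prefix}matrix.mtx", self.matrix.T.tocoo())
        pd.Series(self.barcodes).to_csv(
            f"{prefix}barcodes.tsv", sep="\t", index=False, header=False
        )
        pd.Series(self.genes).to_csv(
            f"{prefix}features.tsv", sep="\t", index=False, header=False
        )

    @classmethod
    def read_mtx(cls, prefix) -> "CountMatrix":
        import scipy.io as sio

        mat = sp.csr_matrix(sio.mmread(f"{prefix}matrix.mtx").T)
        barcodes = pd.Index(
            pd.read_csv(f"{prefix}barcodes.tsv", sep="\t", header=None)[0]
        )
        genes = pd.Index(pd.read_csv(f"{prefix}features.tsv", sep="\t", header=None)[0])
        return cls(mat, barcodes, genes)


def _as_frame(assignments) -> pd.DataFrame:
    if isinstance(assignments, pd.DataFrame):
        df = assignments.copy()
        if "mapped_ok" not in df.columns:
            df["mapped_ok"] = True
        missing = set(ASSIGNMENT_COLUMNS) - set(df.columns)
        if missing:
            raise ValueError(f"assignment table missing columns {sorted(missing)}")
        return df
    rows = [(a.barcode, a.umi, a.gene_id, a.mapped_ok) for a in assignments]
    return pd.DataFrame(rows, columns=ASSIGNMENT_COLUMNS)


def build_count_matrix(assignments) -> CountMatrix:
    """Collapse mapped read assignments to per-(barcode, gene) distinct-UMI
    counts.  Mapped records with an empty UMI are dropped and tallied in
    ``n_dropped_empty_umi``."""
    df = _as_frame(assignments)
    df = df[df["mapped_ok"].astype(bool)]
    empty_umi = df["umi"].isna() | (df["umi"] == "")
    n_dropped = int(empty_umi.sum())
    df = df[~empty_umi]
    triples = df[["barcode", "gene_id", "umi"]].drop_duplicates()
    counts = (
        triples.groupby(["barcode", "gene_id"], sort=True, observed=True)
        .size()
        .reset_index(name="n")
    )
    barcodes = pd.Index(np.sort(df["barcode"].unique()), name="barcode")
    genes = pd.Index(np.sort(df["gene_id"].unique()), name="gene")
    mat = sp.coo_matrix(
        (
            counts["n"].to_numpy(),
            (
                barcodes.get_indexer(counts["barcode"]),
                genes.get_indexer(counts["gene_id"]),
            ),
        ),
        shape=(len(barcodes), len(genes)),
        dtype=np.int64,
    ).tocsr()
    return CountMatrix(mat, barcodes, genes, n_dropped)


def filter_cells_genes(
    cm: CountMatrix,
    max_genes: int = 4000,
    max_mito_fraction: float = 0.01,
    min_cells_per_gene: int = 3,
    mito_genes: set[str] | None = None,
    mito_prefix: str | None = None,
) -> CountMatrix:
    """Apply the cell caps, then the gene floor.

    Cells are kept when detected genes <= ``max_genes`` AND mitochondrial
    UMI fraction <= ``max_mito_fraction`` (both inclusive; a cell with 4001
    genes is removed).  Genes are then kept when expressed (count > 0) in
    >= ``min_cells_per_gene`` of the remaining cells.  Mitochondrial genes
    come from an explicit ``mito_genes`` set and/or a gene-name
    ``mito_prefix`` (e.g. ``"mt-"``); with neither, the mito fraction is 0
    for every cell.
    """
    mito_mask = np.zeros(len(cm.genes), dtype=bool)
    if mito_genes:
        mito_mask |= cm.genes.isin(sorted(mito_genes))
    if mito_prefix:
        mito_mask |= np.asarray(cm.genes.str.lower().str.startswith(mito_prefix.lower()))

    genes_per_cell = np.asarray((cm.matrix > 0).sum(axis=1)).ravel()
    umis_per_cell = np.asarray(cm.matrix.sum(axis=1)).ravel()
    mito_umis = np.asarray(cm.matrix[:, mito_mask].sum(axis=1)).ravel()
    with np.errstate(invalid="ignore"):
        mito_frac = np.where(umis_per_cell > 0, mito_umis / umis_per_cell, 0.0)
    keep_cells = (genes_per_cell <= max_genes) & (mito_frac <= max_mito_fraction)

    sub = cm.matrix[keep_cells]
    cells_per_gene = np.asarray((sub > 0).sum(axis=0)).ravel()
    keep_genes = cells_per_gene >= min_cells_per_gene
    return CountMatrix(
        sub[:, keep_genes].tocsr(),
        cm.barcodes[keep_cells],
        cm.genes[keep_genes],
        cm.n_dropped_empty_umi,
    )


def sequencing_efficiency(total_reads: int, cm: CountMatrix) -> float:
    """Fraction of all sequenced reads that end up as UMI-counted mapped
    transcripts: total matrix UMIs / total reads."""
    if total_reads <= 0:
        raise ValueError("total_reads must be positive")
    total_umis = cm.total_umis
    if total_umis > total_reads:
        raise ValueError(
            f"matrix holds {total_umis} UMIs but only {total_reads} reads were sequenced"
        )
    return total_umis / total_reads


def per_cell_summary(cm: CountMatrix) -> tuple[pd.DataFrame, dict]:
    """Per-barcode UMI and detected-gene counts, plus their medians.

    All-zero cells are flagged (``empty=True``) and excluded from the
    medians.
    """
    umis = np.asarray(cm.matrix.sum(axis=1)).ravel()
    genes = np.asarray((cm.matrix > 0).sum(axis=1)).ravel()
    df = pd.DataFrame(
        {"n_umis": umis, "n_genes": genes, "empty": umis == 0}, index=cm.barcodes
    )
    nonempty = df[~df["empty"]]
    medians = {
        "median_umis": float(nonempty["n_umis"].median()) if len(nonempty) else float("nan"),
        "median_genes": float(nonempty["n_genes"].median()) if len(nonempty) else float("nan"),
    }
    return df, medians
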