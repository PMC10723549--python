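"""Readers and writers for the plain-text formats the pipeline exchanges.

Count matrices travel as 10x-style MTX triplets (``matrix.mtx`` +
``features.tsv`` + ``barcodes.tsv``, genes as rows), cell annotations and
truth labels as TSV, per-cell marker intensities as CSV, and gene sets as
GMT.  All formats are uncompressed text so fixtures stay inspectable.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace

import anndata as ad
import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

__all__ = [
    "CountMatrix",
    "read_mtx_triplet",
    "write_mtx_triplet",
    "read_annotations",
    "write_annotations",
    "read_gmt",
    "write_gmt",
    "read_pair_table",
    "bundled_pairs",
]


@dataclass
class CountMatrix:
    """Sparse genes x cells UMI count matrix with identifiers.

    ``values`` follows the 10x convention of genes as rows.  Use
    :meth:`to_anndata` to obtain the cells x genes view the analysis
    modules operate on.
    """

    values: sp.spmatrix
    gene_symbols: list[str] = field(repr=False)
    barcodes: list[str] = field(repr=False)
    sample_id: str = "sample"

    def __post_init__(self) -> None:
        self.values = sp.csc_matrix(self.values)
        n_genes, n_cells = self.values.shape
        if n_genes != len(self.gene_symbols):
            raise ValueError(
                f"matrix has {n_genes} rows but {len(self.gene_symbols)} gene symbols"
            )
        if n_cells != len(self.barcodes):
            raise ValueError(
                f"matrix has {n_cells} columns but {len(self.barcodes)} barcodes"
            )
        if len(set(self.barcodes)) != len(self.barcodes):
            raise ValueError("duplicate barcodes in count matrix")

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_cells(self) -> int:
        return self.values.shape[1]

    def to_anndata(self) -> ad.AnnData:
        """Cells x genes AnnData view of the counts."""
        adata = ad.AnnData(
            X=sp.csr_matrix(self.values.T),
            obs=pd.DataFrame(index=pd.Index(self.barcodes, name="barcode")),
            var=pd.DataFrame(index=pd.Index(self.gene_symbols, name="gene")),
        )
        adata.obs["sample_id"] = self.sample_id
        return adata

    def copy(self) -> "CountMatrix":
        return replace(
            self,
            values=self.values.copy(),
            gene_symbols=list(self.gene_symbols),
            barcodes=list(self.barcodes),
        )


def write_mtx_triplet(counts: CountMatrix, out_dir: str | os.PathLike) -> None:
    """Write ``matrix.mtx``, ``features.tsv`` and ``barcodes.tsv``."""
    os.makedirs(out_dir, exist_ok=True)
    scipy.io.mmwrite(
        os.path.join(out_dir, "matrix.mtx"), sp.coo_matrix(counts.values)
    )
    pd.Series(counts.gene_symbols).to_csv(
        os.path.join(out_dir, "features.tsv"), sep="\t", index=False, header=False
    )
    pd.Series(counts.barcodes).to_csv(
        os.path.join(out_dir, "barcodes.tsv"), sep="\t", index=False, header=False
    )


def read_mtx_triplet(in_dir: str | os.PathLike, sample_id: str = "sample") -> CountMatrix:
    values = sp.csc_matrix(scipy.io.mmread(os.path.join(in_dir, "matrix.mtx")))
    genes = pd.read_csv(
        os.path.join(in_dir, "features.tsv"), sep="\t", header=None
    )[0].tolist()
    barcodes = pd.read_csv(
        os.path.join(in_dir, "barcodes.tsv"), sep="\t", header=None
    )[0].tolist()
    return CountMatrix(values, genes, barcodes, sample_id)


TRUTH_COLUMNS = [
    "barcode",
    "population",
    "sample_id",
    "mixture_lambda",
    "parent_1",
    "parent_2",
]


def write_annotations(truth: pd.DataFrame, path: str | os.PathLike) -> None:
    truth.to_csv(path, sep="\t", index=False)


def read_annotations(path: str | os.PathLike) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def read_gmt(path: str | os.PathLike) -> dict[str, list[str]]:
    """Parse a GMT file into ``{set_name: member_genes}``.

    Column 2 (the description) is discarded; blank lines are skipped.
    """
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3 or not parts[0]:
                continue
            sets[parts[0]] = [g for g in parts[2:] if g]
    return sets


def write_gmt(sets: dict[str, list[str]], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for name, genes in sets.items():
            fh.write("\t".join([name, "na", *genes]) + "\n")


def read_pair_table(path: str | os.PathLike) -> pd.DataFrame:
    """Ligand-receptor pair table with columns ``ligand`` and ``receptor``."""
    table = pd.read_csv(path)
    missing = {"ligand", "receptor"} - set(table.columns)
    if missing:
        raise ValueError(f"pair table missing columns: {sorted(missing)}")
    return table


def bundled_pairs() -> pd.DataFrame:
    """The small built-in ligand-receptor table (well-known metastasis axes)."""
    from importlib.resources import files

    with files("hybridsc.data").joinpath("lr_pairs.csv").open() as fh:
        return pd.read_csv(fh)
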