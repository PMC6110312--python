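"""Matrix I/O, count preprocessing and run configuration.

Expression matrices travel either as TSV (cells in rows, genes in columns,
first column the cell id) or as MatrixMarket triplets in the genes-by-cells
orientation used by droplet pipelines, with plain-text side files for gene
and cell ids; in memory they are always cells-by-genes
(:class:`~mirkinet.synthetic_data.ExpressionMatrix`).

Preprocessing follows the UMI-count conventions: per-cell scaling to one
million counts, a small pseudocount per gene (with a larger one for the
reporter/proxy gene so its zeros stay visible on log axes), and removal of
genes whose across-cell mean falls below an expression floor.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse
import yaml

from .inference import InferenceConfig
from .synthetic_data import BenchmarkSpec, ExpressionMatrix

logger = logging.getLogger("mirkinet")

__all__ = [
    "MatrixFormatError",
    "RunConfig",
    "read_expression_matrix",
    "write_expression_matrix",
    "normalize_cpm",
    "filter_low_expression",
    "collapse_genes",
]


class MatrixFormatError(ValueError):
    """The on-disk matrix or its side files are inconsistent."""


def _attach_proxy(
    values: np.ndarray,
    cell_ids: np.ndarray,
    gene_ids: np.ndarray,
    proxy_gene: str | None,
    proxy_file,
) -> tuple[np.ndarray, str | None]:
    if proxy_gene is not None:
        hits = np.flatnonzero(gene_ids == proxy_gene)
        if hits.size != 1:
            raise MatrixFormatError(f"proxy gene {proxy_gene!r} not found (or duplicated)")
        return values[:, hits[0]].astype(float), proxy_gene
    if proxy_file is not None:
        side = pd.read_csv(proxy_file, sep="\t", index_col=0)
        try:
            proxy = side.iloc[:, 0].loc[[str(c) for c in cell_ids]].to_numpy(float)
        except KeyError as exc:
            raise MatrixFormatError(f"cell {exc.args[0]!r} missing from proxy file") from exc
        return proxy, None
    raise MatrixFormatError("a proxy gene or a per-cell proxy file is required")


def read_expression_matrix(
    path,
    fmt: str = "tsv",
    proxy_gene: str | None = None,
    proxy_file=None,
    genes_file=None,
    cells_file=None,
    target_genes=None,
) -> ExpressionMatrix:
    """Read a cells-by-genes expression matrix.

    ``fmt="tsv"``: cells in rows (first column the cell id), genes in
    columns.  ``fmt="mtx"``: MatrixMarket triplets, genes-by-cells, with
    one-id-per-line side files (defaults: ``<stem>.genes.tsv`` and
    ``<stem>.barcodes.tsv`` next to the matrix).  The per-cell proxy comes
    from a designated gene column or a two-column (cell id, value) TSV.
    """
    path = Path(path)
    if fmt == "tsv":
        df = pd.read_csv(path, sep="\t", index_col=0)
        values = df.to_numpy(float)
        cell_ids = df.index.to_numpy(str)
        gene_ids = df.columns.to_numpy(str)
    elif fmt == "mtx":
        genes_file = genes_file or path.with_suffix("").with_suffix(".genes.tsv")
        cells_file = cells_file or path.with_suffix("").with_suffix(".barcodes.tsv")
        mat = scipy.io.mmread(path)
        values = np.asarray(mat.todense() if scipy.sparse.issparse(mat) else mat, dtype=float).T
        gene_ids = pd.read_csv(genes_file, sep="\t", header=None)[0].to_numpy(str)
        cell_ids = pd.read_csv(cells_file, sep="\t", header=None)[0].to_numpy(str)
        if values.shape != (cell_ids.size, gene_ids.size):
            raise MatrixFormatError(
                f"matrix shape {values.shape} does not match side files "
                f"({cell_ids.size} cells, {gene_ids.size} genes)"
            )
    else:
        raise MatrixFormatError(f"unknown format {fmt!r}")
    if np.any(values < 0):
        raise MatrixFormatError("negative values in expression matrix")
    proxy, pgene = _attach_proxy(values, cell_ids, gene_ids, proxy_gene, proxy_file)
    target_mask = None
    if target_genes is not None:
        target_mask = np.isin(gene_ids, np.asarray(list(target_genes), dtype=str))
    return ExpressionMatrix(
        values=values,
        cell_ids=cell_ids,
        gene_ids=gene_ids,
        proxy=proxy,
        target_mask=target_mask,
        proxy_gene=pgene,
    )


def write_expression_matrix(matrix: ExpressionMatrix, path, fmt: str = "tsv") -> None:
    """Write a matrix as TSV or MatrixMarket triplets with side files.

    Unless the proxy is one of the genes, a ``<stem>.cells.tsv`` file with
    (cell id, proxy) is written alongside.
    """
    path = Path(path)
    if fmt == "tsv":
        df = pd.DataFrame(matrix.values, index=matrix.cell_ids, columns=matrix.gene_ids)
        df.index.name = "cell_id"
        df.to_csv(path, sep="\t")
    elif fmt == "mtx":
        scipy.io.mmwrite(path, scipy.sparse.coo_matrix(matrix.values.T))
        stem = path.with_suffix("")
        pd.Series(matrix.gene_ids).to_csv(stem.with_suffix(".genes.tsv"), sep="\t", header=False, index=False)
        pd.Series(matrix.cell_ids).to_csv(stem.with_suffix(".barcodes.tsv"), sep="\t", header=False, index=False)
    else:
        raise MatrixFormatError(f"unknown format {fmt!r}")
    if matrix.proxy_gene is None:
        side = pd.DataFrame({"cell_id": matrix.cell_ids, "proxy": matrix.proxy})
        side.to_csv(Path(path).with_suffix("").with_suffix(".cells.tsv"), sep="\t", index=False)


def normalize_cpm(
    matrix: ExpressionMatrix,
    gene_pseudocount: float = 0.001,
    proxy_pseudocount: float = 1.0,
) -> ExpressionMatrix:
    """Counts-per-million normalization with pseudocounts.

    Each cell is scaled to one million total counts; every gene then
    receives ``gene_pseudocount``, except the designated proxy gene which
    receives ``proxy_pseudocount`` instead (so a zero-count reporter maps
    to exactly that value).  Cells with zero total count are dropped with
    a warning.
    """
    totals = matrix.values.sum(axis=1)
    keep = totals > 0
    if not keep.all():
        logger.warning("normalize_cpm: dropping %d zero-total cells", int((~keep).sum()))
    values = matrix.values[keep] / totals[keep, None] * 1e6
    values = values + gene_pseudocount
    proxy = matrix.proxy[keep]
    if matrix.proxy_gene is not None:
        col = int(np.flatnonzero(matrix.gene_ids == matrix.proxy_gene)[0])
        values[:, col] += proxy_pseudocount - gene_pseudocount
        proxy = values[:, col]
    return ExpressionMatrix(
        values=values,
        cell_ids=matrix.cell_ids[keep],
        gene_ids=matrix.gene_ids,
        proxy=proxy,
        target_mask=matrix.target_mask,
        zero_proxy=matrix.zero_proxy[keep],
        proxy_gene=matrix.proxy_gene,
    )


def filter_low_expression(matrix: ExpressionMatrix, min_mean: float = 7.0) -> ExpressionMatrix:
    """Drop genes whose across-cell mean expression is below ``min_mean``.

    The comparison is strict (a gene at exactly the floor is retained);
    the proxy gene is always exempt.  An empty result warns, it does not
    raise.
    """
    means = matrix.values.mean(axis=0)
    keep = means >= min_mean
    if matrix.proxy_gene is not None:
        keep |= matrix.gene_ids == matrix.proxy_gene
    if not keep.any():
        logger.warning("filter_low_expression: no genes left at min_mean=%g", min_mean)
    return ExpressionMatrix(
        values=matrix.values[:, keep],
        cell_ids=matrix.cell_ids,
        gene_ids=matrix.gene_ids[keep],
        proxy=matrix.proxy,
        target_mask=matrix.target_mask[keep],
        zero_proxy=matrix.zero_proxy,
        proxy_gene=matrix.proxy_gene,
    )


def collapse_genes(matrix: ExpressionMatrix, mapping: dict | pd.Series) -> ExpressionMatrix:
    """Sum counts of gene entries mapping to the same identifier.

    Entries absent from ``mapping`` pass through under their own id (so an
    empty mapping is the identity).  Intended for collapsing transcript or
    Ensembl entries to one gene-level id.
    """
    mapping = dict(mapping)
    new_ids = [mapping.get(str(g), str(g)) for g in matrix.gene_ids]
    frame = pd.DataFrame(matrix.values, columns=new_ids)
    collapsed = frame.T.groupby(level=0, sort=False).sum().T
    target = pd.Series(matrix.target_mask, index=new_ids).groupby(level=0, sort=False).any()
    proxy_gene = mapping.get(matrix.proxy_gene, matrix.proxy_gene) if matrix.proxy_gene else None
    return ExpressionMatrix(
        values=collapsed.to_numpy(float),
        cell_ids=matrix.cell_ids,
        gene_ids=collapsed.columns.to_numpy(str),
        proxy=matrix.proxy,
        target_mask=target.to_numpy(bool),
        zero_proxy=matrix.zero_proxy,
        proxy_gene=proxy_gene,
    )


@dataclass
class RunConfig:
    """Every pipeline threshold plus seed and paths, serializable to YAML.

    Written alongside each output for provenance; re-running from the
    saved file reproduces the outputs bit-identically.
    """

    seed: int = 0
    benchmark: dict = field(default_factory=dict)
    inference: dict = field(default_factory=dict)
    preprocessing: dict = field(default_factory=dict)
    paths: dict = field(default_factory=dict)

    def benchmark_spec(self) -> BenchmarkSpec:
        kwargs = dict(self.benchmark)
        kwargs.setdefault("seed", self.seed)
        return BenchmarkSpec(**kwargs)

    def inference_config(self) -> InferenceConfig:
        return InferenceConfig(**self.inference)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2)
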