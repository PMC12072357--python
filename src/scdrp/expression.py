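"""Loading, validation, preprocessing and gene-space alignment of
bulk and single-cell expression matrices.

Conventions
-----------
Samples are rows, genes are columns, everywhere.  Dense CSV/TSV files
carry sample ids in the first column and gene names in the header; a
``transpose`` flag accommodates gene-major files.  Matrix Market files
travel with ``<stem>.rows.txt`` / ``<stem>.cols.txt`` name sidecars.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

logger = logging.getLogger(__name__)

DOMAINS = ("bulk", "sc")


@dataclass
class PreprocessConfig:
    """Preprocessing knobs.

    n_hvg: number of highly variable genes retained as model features.
    target_library_size: per-sample count sum after library-size scaling.
    """

    n_hvg: int = 2500
    target_library_size: float = 1e4
    log_transform: bool = True
    standardize_per_gene: bool = True

    def __post_init__(self):
        if self.n_hvg < 1:
            raise ValueError("n_hvg must be >= 1")
        if self.target_library_size <= 0:
            raise ValueError("target_library_size must be positive")


@dataclass
class ExpressionMatrix:
    """A samples x genes expression matrix tagged with its domain.

    ``stages`` records which preprocessing steps have been applied, in
    order; a raw matrix has an empty tuple.
    """

    values: np.ndarray
    gene_names: list[str]
    sample_ids: list[str]
    domain: str
    stages: tuple[str, ...] = field(default=())

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        self.gene_names = list(map(str, self.gene_names))
        self.sample_ids = list(map(str, self.sample_ids))
        if self.domain not in DOMAINS:
            raise ValueError(f"domain must be one of {DOMAINS}, got {self.domain!r}")
        n, g = self.values.shape
        if len(self.sample_ids) != n:
            raise ValueError(f"{len(self.sample_ids)} sample ids for {n} rows")
        if len(self.gene_names) != g:
            raise ValueError(f"{len(self.gene_names)} gene names for {g} columns")
        for label, names in (("sample", self.sample_ids), ("gene", self.gene_names)):
            if len(set(names)) != len(names):
                dupes = sorted({x for x in names if names.count(x) > 1})[:5]
                raise ValueError(f"duplicate {label} names: {dupes}")
        if np.isnan(self.values).any():
            raise ValueError("expression matrix contains NaN")
        if not self.stages and (self.values < 0).any():
            i, j = np.argwhere(self.values < 0)[0]
            raise ValueError(
                f"negative value at sample {self.sample_ids[i]!r}, "
                f"gene {self.gene_names[j]!r}"
            )

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]

    def subset_genes(self, genes: list[str]) -> "ExpressionMatrix":
        """Restrict to `genes` in the given order."""
        idx = {g: i for i, g in enumerate(self.gene_names)}
        missing = [g for g in genes if g not in idx]
        if missing:
            raise KeyError(f"genes not present: {missing[:5]}")
        cols = [idx[g] for g in genes]
        return replace(self, values=self.values[:, cols], gene_names=list(genes))

    def to_csv(self, path: str | Path, sep: str = ",") -> None:
        df = pd.DataFrame(self.values, index=self.sample_ids, columns=self.gene_names)
        df.to_csv(path, sep=sep, index_label="sample_id")


def load_expression(
    path: str | Path,
    format: str = "dense_csv",
    domain: str = "bulk",
    transpose: bool = False,
) -> ExpressionMatrix:
    """Load an expression matrix from disk.

    Parameters
    ----------
    format
        ``dense_csv``, ``dense_tsv``, or ``mtx_triplet`` (Matrix Market
        coordinate file plus ``.rows.txt`` / ``.cols.txt`` sidecars).
    transpose
        Set when the file is gene-major (genes as rows).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format in ("dense_csv", "dense_tsv"):
        sep = "," if format == "dense_csv" else "\t"
        df = pd.read_csv(path, sep=sep, index_col=0)
        values = df.to_numpy(dtype=np.float64)
        row_names = df.index.astype(str).tolist()
        col_names = df.columns.astype(str).tolist()
    elif format == "mtx_triplet":
        rows_file = path.with_suffix(path.suffix + ".rows.txt")
        cols_file = path.with_suffix(path.suffix + ".cols.txt")
        if path.suffix == ".mtx":
            rows_file = path.with_suffix(".rows.txt")
            cols_file = path.with_suffix(".cols.txt")
        for f in (rows_file, cols_file):
            if not f.exists():
                raise FileNotFoundError(f"missing name sidecar {f}")
        mat = scipy.io.mmread(path)
        values = np.asarray(
            mat.todense() if scipy.sparse.issparse(mat) else mat, dtype=np.float64
        )
        row_names = rows_file.read_text().split()
        col_names = cols_file.read_text().split()
        if len(row_names) != values.shape[0] or len(col_names) != values.shape[1]:
            raise ValueError(
                f"matrix shape {values.shape} does not match name files "
                f"({len(row_names)} rows, {len(col_names)} cols)"
            )
    else:
        raise ValueError(f"unknown format {format!r}")
    if transpose:
        values = values.T
        row_names, col_names = col_names, row_names
    return ExpressionMatrix(
        values=values, gene_names=col_names, sample_ids=row_names, domain=domain
    )


def preprocess(x: ExpressionMatrix, cfg: PreprocessConfig) -> ExpressionMatrix:
    """Library-size scale, log1p, and (optionally) standardize per gene.

    Standardization statistics are fitted within ``x``'s own domain so
    that gross platform scale differences are removed before the shared
    encoder sees either domain.  Raises if ``x`` was already processed.
    """
    if x.stages:
        raise ValueError(f"matrix already preprocessed (stages={x.stages})")
    lib = x.values.sum(axis=1)
    zero = np.flatnonzero(lib == 0)
    if zero.size:
        bad = [x.sample_ids[i] for i in zero[:10]]
        raise ValueError(f"all-zero samples (library size 0): {bad}")
    values = x.values * (cfg.target_library_size / lib)[:, None]
    stages = ["libsize"]
    if cfg.log_transform:
        values = np.log1p(values)
        stages.append("log1p")
    out = replace(x, values=values, stages=tuple(stages))
    if cfg.standardize_per_gene:
        out = standardize_genes(out)
    return out


def standardize_genes(x: ExpressionMatrix) -> ExpressionMatrix:
    """Zero-mean, unit-variance per gene, fitted within this matrix.

    Kept separate from `preprocess` because HVG selection must see
    log-scale variances, i.e. run before standardization.
    """
    if "standardize" in x.stages:
        raise ValueError("matrix already standardized")
    mu = x.values.mean(axis=0)
    sd = x.values.std(axis=0)
    sd[sd == 0] = 1.0  # constant genes pass through centred
    return replace(
        x, values=(x.values - mu) / sd, stages=(*x.stages, "standardize")
    )


def select_hvg(x: ExpressionMatrix, n_hvg: int) -> list[str]:
    """The `n_hvg` genes with highest variance of log1p-normalized values.

    Deterministic: ties are broken by gene name, lexicographically.
    Expects a matrix that has been through the log transform (variance on
    a raw count scale is dominated by library size).
    """
    if "log1p" not in x.stages:
        raise ValueError("select_hvg expects a log-transformed matrix")
    if n_hvg > x.n_genes:
        raise ValueError(f"n_hvg={n_hvg} exceeds gene count {x.n_genes}")
    var = x.values.var(axis=0)
    order = sorted(range(x.n_genes), key=lambda j: (-var[j], x.gene_names[j]))
    return [x.gene_names[j] for j in order[:n_hvg]]


def align_gene_space(
    bulk: ExpressionMatrix, sc: ExpressionMatrix, hvg: list[str]
) -> tuple[ExpressionMatrix, ExpressionMatrix, list[str]]:
    """Restrict both domains to ``hvg ∩ bulk genes``, in hvg order."""
    bulk_set = set(bulk.gene_names)
    shared = [g for g in hvg if g in bulk_set]
    if not shared:
        raise ValueError("empty intersection between HVG list and bulk genes")
    logger.info(
        "aligned gene space: %d of %d HVGs present in bulk", len(shared), len(hvg)
    )
    return bulk.subset_genes(shared), sc.subset_genes(shared), shared
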