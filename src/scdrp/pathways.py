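"""Gene-set (GMT) parsing and pathway-mask construction.

The mask is the binary pathway x gene matrix that both defines the
shared-latent dimensionality and gates the sparse decoder: latent
dimension *i* may reconstruct gene *j* only where ``mask[i, j] == 1``.
A handful of unconstrained all-ones "free" rows (default 5) are appended
so the model can capture signal outside the annotated pathways.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import scipy.io
import scipy.sparse

logger = logging.getLogger(__name__)


@dataclass
class GeneSet:
    name: str
    description: str
    genes: list[str]


@dataclass
class GeneSetCollection:
    sets: list[GeneSet]

    def __post_init__(self):
        names = [s.name for s in self.sets]
        if len(set(names)) != len(names):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise ValueError(f"duplicate pathway names: {dupes[:5]}")
        for s in self.sets:
            if not s.genes:
                raise ValueError(f"gene set {s.name!r} is empty")

    def __len__(self) -> int:
        return len(self.sets)

    def to_gmt(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for s in self.sets:
                fh.write("\t".join([s.name, s.description, *s.genes]) + "\n")


@dataclass
class PathwayMask:
    """Binary (pathways + free rows) x genes mask.

    matrix: uint8 array; constrained rows first, free (all-ones) rows last.
    pathway_names: names of the constrained rows only.
    """

    matrix: np.ndarray
    pathway_names: list[str]
    n_free: int
    gene_names: list[str]
    min_genes: int

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=np.uint8)
        if not np.isin(self.matrix, (0, 1)).all():
            raise ValueError("mask entries must be 0/1")
        if self.matrix.shape != (self.n_rows, len(self.gene_names)):
            raise ValueError("mask shape inconsistent with names")
        if self.n_free and not (self.matrix[-self.n_free :] == 1).all():
            raise ValueError("free rows must be all ones")

    @property
    def n_rows(self) -> int:
        return len(self.pathway_names) + self.n_free

    @property
    def row_names(self) -> list[str]:
        return self.pathway_names + [f"FREE_{i + 1}" for i in range(self.n_free)]

    def save(self, stem: str | Path) -> None:
        """Persist as `<stem>.mtx` plus a JSON sidecar `<stem>.json`."""
        stem = Path(stem)
        scipy.io.mmwrite(str(stem.with_suffix(".mtx")), scipy.sparse.coo_matrix(self.matrix))
        meta = {
            "pathway_names": self.pathway_names,
            "n_free": self.n_free,
            "min_genes": self.min_genes,
            "gene_names": self.gene_names,
        }
        stem.with_suffix(".json").write_text(json.dumps(meta))

    @classmethod
    def load(cls, stem: str | Path) -> "PathwayMask":
        stem = Path(stem)
        meta = json.loads(stem.with_suffix(".json").read_text())
        mat = scipy.io.mmread(str(stem.with_suffix(".mtx")))
        if scipy.sparse.issparse(mat):
            mat = mat.todense()
        return cls(matrix=np.asarray(mat), **meta)


def parse_gmt(path: str | Path) -> GeneSetCollection:
    """Parse a GMT file: ``name<TAB>description<TAB>gene...`` per line.

    File order is preserved; duplicate genes within a set are dropped
    with a warning.
    """
    path = Path(path)
    sets: list[GeneSet] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path}:{lineno}: expected name, description and >=1 gene, "
                    f"got {len(fields)} fields"
                )
            name, desc, *genes = fields
            genes = [g for g in genes if g]
            unique = list(dict.fromkeys(genes))
            if len(unique) != len(genes):
                warnings.warn(
                    f"{path}:{lineno}: duplicate genes in set {name!r} deduplicated",
                    stacklevel=2,
                )
            sets.append(GeneSet(name=name, description=desc, genes=unique))
    return GeneSetCollection(sets=sets)


def build_mask(
    sets: GeneSetCollection,
    gene_space: list[str],
    min_genes: int = 10,
    n_free: int = 5,
) -> PathwayMask:
    """Build the pathway mask over the aligned model gene space.

    Each set is restricted to `gene_space` first; sets with fewer than
    `min_genes` surviving genes are dropped (their rows would be almost
    entirely zero and starve the sparse decoder).  `n_free` all-ones rows
    are appended after the constrained rows.
    """
    if not gene_space:
        raise ValueError("gene_space is empty")
    if min_genes < 1:
        raise ValueError("min_genes must be >= 1")
    if n_free < 0:
        raise ValueError("n_free must be >= 0")
    col = {g: j for j, g in enumerate(gene_space)}
    rows, names = [], []
    for s in sets.sets:
        hits = [col[g] for g in s.genes if g in col]
        if len(hits) < min_genes:
            continue
        row = np.zeros(len(gene_space), dtype=np.uint8)
        row[hits] = 1
        rows.append(row)
        names.append(s.name)
    if not rows:
        raise ValueError(
            f"no pathway retains >= {min_genes} genes in the model gene space; "
            "lower min_genes"
        )
    logger.info("mask: retained %d/%d pathways, %d free rows", len(rows), len(sets), n_free)
    matrix = np.vstack(rows + [np.ones((n_free, len(gene_space)), dtype=np.uint8)]
                       if n_free else rows)
    return PathwayMask(
        matrix=matrix,
        pathway_names=names,
        n_free=n_free,
        gene_names=list(gene_space),
        min_genes=min_genes,
    )
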