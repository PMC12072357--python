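"""Drug-response binarization and single-cell label filtering.

Bulk cell lines carry continuous dose-response AUC values (lower =
more sensitive).  Training labels come from an extreme-value split:
the lowest-AUC fraction ``k`` is labeled sensitive (1), the highest-AUC
fraction resistant (0), and the ambiguous middle is left unlabeled.

Single-cell test labels start from treatment group (control = sensitive,
treated = resistant) and are then cleaned: control cells sitting in
treated-dominated clusters are presumed intrinsically resistant and
excluded, and clusters of normal (non-tumor) cells flagged by marker
genes are excluded wholesale.  Clustering itself is an input, not
something this module computes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .expression import ExpressionMatrix


@dataclass
class DrugResponseTable:
    """Per-cell-line continuous response values for one drug."""

    drug_name: str
    entries: pd.DataFrame  # columns: cell_line_id, auc[, ic50]

    def __post_init__(self):
        df = pd.DataFrame(self.entries)
        if "cell_line_id" not in df or "auc" not in df:
            raise ValueError("entries needs columns 'cell_line_id' and 'auc'")
        df["cell_line_id"] = df["cell_line_id"].astype(str)
        if df["cell_line_id"].duplicated().any():
            dupes = df.loc[df["cell_line_id"].duplicated(), "cell_line_id"].tolist()
            raise ValueError(f"duplicate cell line ids: {dupes[:5]}")
        if df["auc"].isna().any():
            raise ValueError("auc missing for some cell lines")
        self.entries = df.reset_index(drop=True)

    @classmethod
    def from_csv(cls, path, drug_name: str | None = None) -> "DrugResponseTable":
        df = pd.read_csv(path)
        if drug_name is not None and "drug" in df:
            df = df[df["drug"] == drug_name]
        name = drug_name or (str(df["drug"].iloc[0]) if "drug" in df else "drug")
        return cls(drug_name=name, entries=df.drop(columns=["drug"], errors="ignore"))


@dataclass
class BinaryLabels:
    """1 = sensitive, 0 = resistant; ids outside both tails are unlabeled."""

    labels: dict[str, int]
    unlabeled: list[str] = field(default_factory=list)

    def __post_init__(self):
        if set(self.labels.values()) - {0, 1}:
            raise ValueError("labels must be 0/1")
        overlap = set(self.labels) & set(self.unlabeled)
        if overlap:
            raise ValueError(f"ids both labeled and unlabeled: {sorted(overlap)[:5]}")


@dataclass
class CellFilterInputs:
    cluster_of: dict[str, object]
    group_of: dict[str, str]  # values: control | treated
    normal_markers: list[str] = field(default_factory=list)
    marker_score_threshold: float = 1.0

    def __post_init__(self):
        if set(self.cluster_of) != set(self.group_of):
            raise ValueError("cluster and group maps must cover the same cells")
        bad = set(self.group_of.values()) - {"control", "treated"}
        if bad:
            raise ValueError(f"unknown treatment groups: {sorted(bad)}")


def extreme_value_labels(table: DrugResponseTable, k: float) -> BinaryLabels:
    """Extreme-value binarization of AUC with tail fraction ``k``.

    Ranks by AUC ascending; the first floor(k*n) ids become sensitive
    (y=1), the last floor(k*n) resistant (y=0).  Ties are broken by
    cell-line id so the split is deterministic.
    """
    if not (0.0 < k < 0.5):
        raise ValueError(f"k must be in (0, 0.5), got {k}")
    df = table.entries
    n = len(df)
    m = int(np.floor(k * n))
    if m < 1:
        raise ValueError(f"floor(k*n) = 0 for k={k}, n={n}: no labels possible")
    order = df.sort_values(["auc", "cell_line_id"], kind="mergesort")
    ids = order["cell_line_id"].tolist()
    labels = {i: 1 for i in ids[:m]}
    labels.update({i: 0 for i in ids[-m:]})
    return BinaryLabels(labels=labels, unlabeled=ids[m : n - m])


def filter_control_resistant(
    cells: CellFilterInputs, majority_threshold: float = 0.5
) -> list[str]:
    """Control cells in treated-dominated clusters, flagged for exclusion.

    A cluster is "treated-like" when its treated fraction exceeds
    `majority_threshold`; control cells inside such clusters look
    transcriptionally like treated survivors, i.e. intrinsically
    resistant, and must not be used as sensitive examples.
    """
    if not cells.cluster_of:
        raise ValueError("empty cluster map")
    df = pd.DataFrame(
        {
            "cell": list(cells.cluster_of),
            "cluster": list(cells.cluster_of.values()),
            "treated": [cells.group_of[c] == "treated" for c in cells.cluster_of],
        }
    )
    frac = df.groupby("cluster")["treated"].mean()
    treated_like = set(frac.index[frac > majority_threshold])
    mask = df["cluster"].isin(treated_like) & ~df["treated"]
    return sorted(df.loc[mask, "cell"])


def filter_normal_cells(x: ExpressionMatrix, cells: CellFilterInputs) -> list[str]:
    """Cells in clusters whose mean marker-gene expression exceeds the
    threshold — taken to be normal (non-tumor) subpopulations and
    excluded wholesale."""
    present = [g for g in cells.normal_markers if g in x.gene_names]
    if not present:
        raise ValueError("no marker genes present in the expression matrix")
    sub = x.subset_genes(present)
    score = pd.Series(sub.values.mean(axis=1), index=sub.sample_ids)
    clusters = pd.Series({c: cells.cluster_of[c] for c in sub.sample_ids})
    cluster_score = score.groupby(clusters).mean()
    normal = set(cluster_score.index[cluster_score > cells.marker_score_threshold])
    return sorted(c for c, cl in cells.cluster_of.items() if cl in normal)
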