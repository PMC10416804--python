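"""Count-matrix QC, normalization and hierarchical clustering.

Plate-based (SMART-Seq-style) single-cell libraries fail often enough that a
simple, interpretable per-cell filter is valuable: a panel of housekeeping
genes is expected to be well detected in every viable cell, so a cell where
more than 30% of panel genes have fewer than 10 raw counts is called a failed
library and excluded.  Downstream, counts are size-factor normalized
(median-of-ratios) and log-transformed — a documented stand-in for DESeq2's
variance-stabilizing transform, used for clustering only — and cells are
clustered by Ward-linkage agglomeration on Euclidean distances.  A
dendrogram-based rule flags outlier cells whose merge height is far above the
rest of the tree.
"""

from __future__ import annotations

import importlib.resources
import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.io import mmread, mmwrite
from scipy.sparse import csr_matrix

__all__ = [
    "default_housekeeping_panel",
    "drop_zero_genes",
    "housekeeping_qc",
    "apply_qc",
    "normalize_for_clustering",
    "ward_cluster",
    "flag_outliers",
    "Dendrogram",
    "read_counts_csv",
    "write_counts_csv",
    "read_counts_mtx",
    "write_counts_mtx",
]


def default_housekeeping_panel() -> list[str]:
    """The 22-gene housekeeping panel shipped with the package.

    A standard human housekeeping set (β-actin, GAPDH, ribosomal and
    metabolic housekeepers); override by passing your own gene list to
    :func:`housekeeping_qc`.
    """
    text = importlib.resources.files("spheroquant.data").joinpath(
        "housekeeping_panel.txt").read_text()
    return [line.strip() for line in text.splitlines()
            if line.strip() and not line.startswith("#")]


def _check_counts(m: pd.DataFrame) -> None:
    if not m.index.is_unique or not m.columns.is_unique:
        raise ValueError("gene and cell ids must be unique")
    if (np.asarray(m) < 0).any():
        raise ValueError("counts must be non-negative")


def drop_zero_genes(m: pd.DataFrame) -> pd.DataFrame:
    """Remove genes with zero detected reads across all cells."""
    _check_counts(m)
    return m.loc[m.sum(axis=1) > 0]


def housekeeping_qc(m: pd.DataFrame, panel: list[str], min_count: int = 10,
                    max_low_fraction: float = 0.30) -> pd.DataFrame:
    """Per-cell housekeeping QC report.

    A panel gene is "low" in a cell when its raw count is *strictly below*
    ``min_count``; a cell is excluded when *strictly more than*
    ``max_low_fraction`` of panel genes are low (so with a 22-gene panel and
    the 30% default, 7 low genes excludes and 6 retains).

    Returns a DataFrame indexed by cell with columns ``n_housekeeping_low``,
    ``fraction_low``, ``excluded`` and ``reason``.  All panel genes must be
    present in the matrix.
    """
    _check_counts(m)
    panel = list(panel)
    if not panel:
        raise ValueError("housekeeping panel is empty")
    if len(set(panel)) != len(panel):
        raise ValueError("housekeeping panel contains duplicate genes")
    missing = [g for g in panel if g not in m.index]
    if missing:
        raise KeyError(f"panel genes missing from the count matrix: {missing}")

    sub = m.loc[panel]
    n_low = (sub < min_count).sum(axis=0)
    frac = n_low / len(panel)
    excluded = frac > max_low_fraction
    report = pd.DataFrame(
        {
            "n_housekeeping_low": n_low.astype(int),
            "fraction_low": frac.astype(float),
            "excluded": excluded.astype(bool),
        }
    )
    report.index.name = "cell"
    report["reason"] = [
        (f"{n}/{len(panel)} housekeeping genes below {min_count} raw counts "
         f"(> {max_low_fraction:.0%})") if exc else ""
        for n, exc in zip(report["n_housekeeping_low"], report["excluded"])
    ]
    return report


def apply_qc(m: pd.DataFrame, report: pd.DataFrame) -> pd.DataFrame:
    """Drop the cells a QC report marks as excluded."""
    keep = report.index[~report["excluded"]]
    return m[[c for c in m.columns if c in set(keep)]]


def normalize_for_clustering(m: pd.DataFrame) -> pd.DataFrame:
    """Median-of-ratios size factors, then log2(count / size_factor + 1).

    The per-cell size factor is the median, over genes expressed in every
    cell, of the ratio of the cell's count to the gene's geometric mean
    across cells.  If no gene is expressed in all cells, library-size
    factors (scaled to geometric mean 1) are used instead, with a warning.
    This transform stabilizes depth differences for clustering; it is not a
    variance-stabilizing transform in the DESeq2 sense.
    """
    _check_counts(m)
    if m.shape[1] < 2:
        raise ValueError("need at least 2 cells to normalize")
    counts = np.asarray(m, dtype=float)
    expressed_everywhere = (counts > 0).all(axis=1)
    if expressed_everywhere.any():
        log_sub = np.log(counts[expressed_everywhere])
        log_geomean = log_sub.mean(axis=1, keepdims=True)
        size_factors = np.exp(np.median(log_sub - log_geomean, axis=0))
    else:
        warnings.warn(
            "no gene expressed in all cells; falling back to library-size factors",
            stacklevel=2,
        )
        lib = counts.sum(axis=0)
        if (lib == 0).any():
            raise ValueError("cannot normalize: some cells have zero total counts")
        size_factors = lib / np.exp(np.mean(np.log(lib)))
    transformed = np.log2(counts / size_factors + 1.0)
    return pd.DataFrame(transformed, index=m.index, columns=m.columns)


@dataclass
class Dendrogram:
    """Agglomerative merge tree over cells.

    ``merges`` is a scipy-style linkage matrix: row i merges clusters
    ``(left, right)`` at ``height`` into cluster ``n_leaves + i`` of size
    ``size``.  Heights follow the convention in which two singletons merge at
    their Euclidean distance.
    """

    merges: np.ndarray  # (n-1, 4): left, right, height, size
    leaves: list[str]

    def __post_init__(self) -> None:
        self.merges = np.asarray(self.merges, dtype=float)
        n = len(self.leaves)
        if self.merges.shape != (n - 1, 4):
            raise ValueError("merge list must have n-1 rows of (left, right, height, size)")

    @property
    def n_leaves(self) -> int:
        return len(self.leaves)

    @property
    def heights(self) -> np.ndarray:
        return self.merges[:, 2]

    def cut(self, n_clusters: int) -> pd.Series:
        """Flat cluster labels from cutting the tree into ``n_clusters`` groups."""
        labels = fcluster(self.merges, t=n_clusters, criterion="maxclust")
        return pd.Series(labels, index=self.leaves, name="cluster")

    def leaf_merge_heights(self) -> pd.Series:
        """Height at which each leaf (as a singleton) first merges into the tree."""
        n = self.n_leaves
        heights = np.empty(n)
        for left, right, height, _ in self.merges:
            for node in (int(left), int(right)):
                if node < n:
                    heights[node] = height
        return pd.Series(heights, index=self.leaves, name="merge_height")

    # -- serialization -------------------------------------------------------

    def _node_dict(self, node: int) -> dict:
        n = self.n_leaves
        if node < n:
            return {"leaf": self.leaves[node]}
        left, right, height, size = self.merges[node - n]
        return {
            "height": float(height),
            "size": int(size),
            "children": [self._node_dict(int(left)), self._node_dict(int(right))],
        }

    def to_dict(self) -> dict:
        return self._node_dict(2 * self.n_leaves - 2)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))

    def to_newick(self) -> str:
        """Newick string with branch lengths derived from merge heights."""
        n = self.n_leaves

        def height_of(node: int) -> float:
            return 0.0 if node < n else float(self.merges[node - n][2])

        def render(node: int, parent_height: float) -> str:
            length = parent_height - height_of(node)
            if node < n:
                return f"{self.leaves[node]}:{length:g}"
            left, right, height, _ = self.merges[node - n]
            inner = ",".join(
                render(int(child), float(height)) for child in (left, right)
            )
            return f"({inner}):{length:g}"

        root = 2 * n - 2
        left, right, height, _ = self.merges[root - n]
        inner = ",".join(render(int(child), float(height)) for child in (left, right))
        return f"({inner});"


def ward_cluster(transformed: pd.DataFrame, metric: str = "euclidean") -> Dendrogram:
    """Ward-linkage agglomerative clustering of cells (columns).

    Each merge joins the pair of clusters whose union minimizes the increase
    in within-cluster sum of squares (Lance–Williams recurrence); merge
    heights are scaled so two singletons merge at their Euclidean distance.
    """
    if metric != "euclidean":
        raise ValueError("Ward linkage requires the Euclidean metric")
    if transformed.shape[1] < 2:
        raise ValueError("need at least 2 cells to cluster")
    if not transformed.columns.is_unique:
        raise ValueError("duplicate cell ids")
    X = np.asarray(transformed, dtype=float).T  # cells × genes
    if not np.isfinite(X).all():
        raise ValueError("transformed matrix contains non-finite values")
    Z = linkage(X, method="ward", metric="euclidean")
    return Dendrogram(Z, list(transformed.columns))


def flag_outliers(d: Dendrogram, factor: float = 3.0) -> list[str]:
    """Cells that join the tree as singletons at an anomalous height.

    A leaf is flagged when the height of the merge at which it (still a
    singleton) joins the tree exceeds ``factor`` × the median merge height.
    ``factor = inf`` disables flagging.
    """
    if factor <= 0:
        raise ValueError("factor must be positive")
    if not np.isfinite(factor):
        return []
    median_height = float(np.median(d.heights))
    leaf_heights = d.leaf_merge_heights()
    return [str(c) for c in leaf_heights.index[leaf_heights > factor * median_height]]


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_counts_csv(path: str | Path, sep: str | None = None,
                    cells_in_rows: bool = False) -> pd.DataFrame:
    """Read a genes × cells count table from CSV/TSV (orientation flippable)."""
    path = Path(path)
    if sep is None:
        sep = "\t" if path.suffix.lower() in (".tsv", ".txt") else ","
    m = pd.read_csv(path, sep=sep, index_col=0)
    if cells_in_rows:
        m = m.T
    m.index.name, m.columns.name = "gene", "cell"
    return m


def write_counts_csv(m: pd.DataFrame, path: str | Path) -> None:
    m.to_csv(path)


def read_counts_mtx(directory: str | Path) -> pd.DataFrame:
    """Read an MTX triplet directory (matrix.mtx, genes.txt, cells.txt)."""
    directory = Path(directory)
    mat = mmread(directory / "matrix.mtx").toarray().astype(np.int64)
    genes = (directory / "genes.txt").read_text().splitlines()
    cells = (directory / "cells.txt").read_text().splitlines()
    return pd.DataFrame(mat, index=pd.Index(genes, name="gene"),
                        columns=pd.Index(cells, name="cell"))


def write_counts_mtx(m: pd.DataFrame, directory: str | Path) -> None:
    """Write a genes × cells matrix as an MTX triplet directory."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    mmwrite(directory / "matrix.mtx", csr_matrix(np.asarray(m)))
    (directory / "genes.txt").write_text("\n".join(map(str, m.index)) + "\n")
    (directory / "cells.txt").write_text("\n".join(map(str, m.columns)) + "\n")
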