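"""Integration, variable-gene selection, Ward clustering, representatives.

The matching step of the pipeline: purified patient profiles are integrated
with cell-line profiles, batch-corrected, reduced to the most variable
genes among the patient samples, and clustered agglomeratively with Ward's
minimum-variance criterion.  Cutting the tree at ``k`` primary clusters
groups patients with the cell lines that transcriptomically resemble them;
one representative (non-excluded) cell line is then chosen per cluster by
proximity to the cluster's patient centroid.  Marker-set z-score signatures
(e.g. AR activity, neuroendocrine differentiation) characterize the
clusters phenotypically.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch

from .datatypes import ExpressionMatrix, ROLE_CELL_LINE, ROLE_PATIENT

__all__ = [
    "Dendrogram",
    "ClusterAssignment",
    "select_variable_genes",
    "ward_cluster",
    "cut_primary_clusters",
    "assign_representatives",
    "signature_score",
]

logger = logging.getLogger(__name__)

_VAR_FLOOR = 1e-8


@dataclass
class Dendrogram:
    """Ward merge tree over samples.

    ``linkage`` is the scipy linkage matrix (heights on scipy's Ward scale,
    the square root of twice the within-cluster sum-of-squares increase).
    ``merges`` exposes the merge list with heights on the dSSE scale: the
    increase in within-cluster sum of squares caused by each merge, which
    for two singletons at Euclidean distance d equals d**2 / 2.
    """

    linkage: np.ndarray
    leaf_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        n = len(self.leaf_ids)
        if self.linkage.shape != (n - 1, 4):
            raise ValueError("linkage must have n-1 rows for n leaves")

    @property
    def n_leaves(self) -> int:
        return len(self.leaf_ids)

    @property
    def merges(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "node_a": self.linkage[:, 0].astype(int),
                "node_b": self.linkage[:, 1].astype(int),
                "merge_height": self.linkage[:, 2] ** 2 / 2.0,
                "cluster_size": self.linkage[:, 3].astype(int),
            }
        )

    def to_newick(self) -> str:
        """Newick export with branch lengths from dSSE merge heights."""
        tree = sch.to_tree(self.linkage)
        heights = {}

        def _height(node) -> float:
            if node.is_leaf():
                return 0.0
            return node.dist**2 / 2.0

        def _fmt(node, parent_height: float) -> str:
            h = _height(node)
            length = max(parent_height - h, 0.0)
            if node.is_leaf():
                return f"{self.leaf_ids[node.id]}:{length:.6g}"
            left = _fmt(node.left, h)
            right = _fmt(node.right, h)
            return f"({left},{right}):{length:.6g}"

        root_h = _height(tree)
        return f"({_fmt(tree.left, root_h)},{_fmt(tree.right, root_h)});"


@dataclass
class ClusterAssignment:
    """Sample-to-cluster labels with per-cluster representative lines.

    ``labels`` maps each sample to a cluster id in 1..k (ordered by first
    appearance along the sample index).  ``representatives`` maps cluster id
    to the selected cell line, or ``None`` for clusters without an eligible
    line.  ``excluded_present`` records lines that were members of a cluster
    but barred from selection.  ``scores`` optionally holds per-cluster mean
    signature scores.
    """

    labels: pd.Series
    representatives: dict[int, str | None] = field(default_factory=dict)
    excluded_present: dict[int, list[str]] = field(default_factory=dict)
    scores: pd.DataFrame | None = None

    @property
    def k(self) -> int:
        return int(self.labels.nunique())

    def cluster_members(self, cluster: int) -> pd.Index:
        return self.labels.index[self.labels == cluster]

    def to_frame(self) -> pd.DataFrame:
        df = self.labels.rename("cluster").to_frame()
        df["representative"] = df["cluster"].map(
            {c: (r if r is not None else "unrepresented") for c, r in self.representatives.items()}
        )
        return df


def select_variable_genes(matrix: ExpressionMatrix, k: int = 5000) -> pd.Index:
    """Top-k genes by expression variance across the patient samples.

    Variability is measured over patient samples only — cell-line-specific
    variation must not drive the gene selection.  ``k`` is capped at the
    gene count; ties are broken by input gene order.
    """
    if k <= 0:
        raise ValueError("k must be positive")
    patients = matrix.patient_samples()
    if not len(patients):
        raise ValueError("matrix contains no patient samples")
    variances = matrix.values[patients].var(axis=1, ddof=1).to_numpy()
    k = min(k, matrix.n_genes)
    # stable argsort on negated variance keeps input order among ties
    order = np.argsort(-variances, kind="stable")[:k]
    return matrix.gene_ids[np.sort(order)]


def ward_cluster(matrix: ExpressionMatrix) -> Dendrogram:
    """Agglomerative clustering with Ward's minimum-variance criterion.

    Samples are points in Euclidean space over the (log2) expression of the
    selected genes; each merge minimizes the increase in within-cluster sum
    of squares, computed through the Lance-Williams recurrence.
    """
    if matrix.n_samples < 2:
        raise ValueError("at least two samples required")
    X = matrix.values.to_numpy().T
    if not np.isfinite(X).all():
        raise ValueError("non-finite values in expression matrix")
    Z = sch.linkage(X, method="ward")
    return Dendrogram(linkage=Z, leaf_ids=tuple(matrix.sample_ids))


def cut_primary_clusters(dendrogram: Dendrogram, k: int) -> pd.Series:
    """Cut the tree into exactly k clusters by removing the k-1 top merges.

    Returns per-sample labels 1..k, numbered by first appearance along the
    leaf order.
    """
    n = dendrogram.n_leaves
    if not 1 <= k <= n:
        raise ValueError(f"k must lie in [1, {n}]")
    raw = sch.fcluster(dendrogram.linkage, t=k, criterion="maxclust")
    if len(np.unique(raw)) != k:
        # maxclust can return fewer clusters only with tied heights; force
        # an exact cut at the (k-1)-th largest merge height in that case
        heights = np.sort(dendrogram.linkage[:, 2])
        threshold = heights[n - 1 - k] if k < n else 0.0
        raw = sch.fcluster(dendrogram.linkage, t=threshold, criterion="distance")
    relabel: dict[int, int] = {}
    labels = []
    for r in raw:
        if r not in relabel:
            relabel[r] = len(relabel) + 1
        labels.append(relabel[r])
    return pd.Series(labels, index=list(dendrogram.leaf_ids), name="cluster")


def assign_representatives(
    labels: pd.Series,
    matrix: ExpressionMatrix,
    excludable_lines: Iterable[str] = (),
) -> ClusterAssignment:
    """Pick one representative cell line per primary cluster.

    Among the cluster's non-excluded cell-line members, the line closest
    (Euclidean, on the clustering genes) to the centroid of the cluster's
    patient samples is selected.  Clusters without an eligible line are
    marked unrepresented; excluded lines present in a cluster are reported.
    """
    excludable = set(excludable_lines)
    roles = matrix.sample_role
    assignment = ClusterAssignment(labels=labels.copy())
    X = matrix.values

    for cluster in sorted(labels.unique()):
        members = labels.index[labels == cluster]
        lines = [s for s in members if roles[s] == ROLE_CELL_LINE]
        patients = [s for s in members if roles[s] == ROLE_PATIENT]
        excluded_here = sorted(set(lines) & excludable)
        if excluded_here:
            assignment.excluded_present[int(cluster)] = excluded_here
            logger.info(
                "cluster %d: excluded line(s) present but not selectable: %s",
                cluster, excluded_here,
            )
        eligible = [s for s in lines if s not in excludable]
        if not eligible:
            assignment.representatives[int(cluster)] = None
            continue
        if patients:
            centroid = X[patients].mean(axis=1)
            dists = {line: float(np.linalg.norm(X[line] - centroid)) for line in eligible}
            best = min(sorted(dists), key=dists.get)
        else:
            best = sorted(eligible)[0]
        assignment.representatives[int(cluster)] = best
    return assignment


def signature_score(
    matrix: ExpressionMatrix, marker_genes: Sequence[str]
) -> pd.Series:
    """Per-sample signature score: mean marker z-score.

    Each gene is standardized across all samples (variance floor for
    degenerate genes, giving constant genes a z of zero); the score is the
    mean over the markers present in the matrix.
    """
    present = pd.Index(marker_genes).intersection(matrix.gene_ids)
    if present.empty:
        raise ValueError("no marker genes overlap the expression matrix")
    sub = matrix.values.loc[present]
    mu = sub.mean(axis=1)
    sd = sub.std(axis=1, ddof=0)
    sd = sd.where(sd**2 >= _VAR_FLOOR, np.inf)  # constant gene -> z = 0
    z = sub.sub(mu, axis=0).div(sd, axis=0)
    return z.mean(axis=0).rename("score")
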