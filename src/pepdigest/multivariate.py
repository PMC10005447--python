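"""Multivariate discrimination of digest samples.

Two feature spaces are used to compare (substrate, time) samples in a
holistic way:

* residue space — one column per mature residue position of every reference
  protein, cell = sum of intensities of all peptides overlapping that
  position in that sample (the input to PCA);
* peptide space — one column per peptide sequence, cell = summed intensity
  in that sample, with an occupancy filter keeping peptides present in at
  least ``min_presence`` time points (the input to hierarchical clustering).

PCA is computed by singular value decomposition of the (optionally centred
and scaled) feature matrix; agglomerative clustering is delegated to
scipy's linkage with a deterministic leaf ordering and Newick export.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist, squareform

from .peptide_mapping import ConfigError, PeptideObservation
from .profiling import profile_matrix
from .reference_proteome import ProteinRecord

logger = logging.getLogger(__name__)

DISTANCES = ("euclidean", "correlation")
LINKAGES = ("ward", "average", "complete", "single")


@dataclass
class PCAResult:
    """Scores, loadings and explained-variance ratios of a PCA."""

    scores: pd.DataFrame        # samples x components
    loadings: pd.DataFrame      # features x components
    explained_ratio: np.ndarray

    @property
    def n_components(self) -> int:
        return self.scores.shape[1]


@dataclass
class ClusterResult:
    """Agglomerative clustering of the rows of a feature matrix."""

    merge_tree: np.ndarray      # scipy linkage matrix
    leaf_order: list[int]
    row_keys: list
    distance_metric: str
    linkage_method: str

    def cut(self, n_clusters: int) -> np.ndarray:
        """Flat cluster labels from cutting the tree into ``n_clusters``."""
        return hierarchy.fcluster(self.merge_tree, n_clusters, criterion="maxclust")

    def to_newick(self) -> str:
        """Newick string with branch lengths derived from merge heights."""
        tree = hierarchy.to_tree(self.merge_tree)

        def build(node, parent_height):
            length = parent_height - node.dist
            if node.is_leaf():
                label = str(self.row_keys[node.id]).replace(" ", "_").replace(",", "|")
                for ch in "():;":
                    label = label.replace(ch, "")
                return f"{label}:{length:g}"
            left = build(node.left, node.dist)
            right = build(node.right, node.dist)
            return f"({left},{right}):{length:g}"

        left = build(tree.left, tree.dist)
        right = build(tree.right, tree.dist)
        return f"({left},{right});"


def residue_feature_matrix(
    observations: Iterable[PeptideObservation],
    proteins: Sequence[ProteinRecord],
    mode: str = "intensity_sum",
) -> pd.DataFrame:
    """Samples x residue-positions matrix over all reference proteins.

    Rows are (substrate, time_min) samples; columns are ``protein:pos``
    labels covering every residue of every protein, in protein input order.
    Equals the horizontal concatenation of per-protein profile matrices.
    """
    obs = list(observations)
    blocks = [profile_matrix(obs, protein, mode) for protein in proteins]
    return pd.concat(blocks, axis=1)


def peptide_feature_matrix(
    observations: Iterable[PeptideObservation],
    min_presence: int = 2,
    scope: str = "within_substrate",
) -> pd.DataFrame:
    """Samples x peptide-sequences intensity matrix with an occupancy filter.

    A peptide column is kept when the sequence occurs (intensity > 0) in at
    least ``min_presence`` distinct time points — within a single substrate
    (default) or anywhere in the experiment (``scope='overall'``).  Cells are
    intensities summed over animals; absent peptides are 0.
    """
    if min_presence < 1:
        raise ConfigError("min_presence must be >= 1")
    if scope not in ("within_substrate", "overall"):
        raise ConfigError(f"unknown presence scope {scope!r}")
    obs = list(observations)
    presence: dict[str, set] = {}
    for o in obs:
        if o.intensity > 0:
            key = o.time_min if scope == "overall" else (o.substrate, o.time_min)
            presence.setdefault(o.sequence, set()).add(key)

    def n_times(seq: str) -> int:
        marks = presence.get(seq, set())
        if scope == "overall":
            return len(marks)
        by_substrate: dict[str, int] = {}
        for substrate, _time in marks:
            by_substrate[substrate] = by_substrate.get(substrate, 0) + 1
        return max(by_substrate.values(), default=0)

    kept = sorted({o.sequence for o in obs if n_times(o.sequence) >= min_presence})
    keys = sorted({(o.substrate, o.time_min) for o in obs})
    index = pd.MultiIndex.from_tuples(keys, names=["substrate", "time_min"])
    matrix = pd.DataFrame(0.0, index=index, columns=kept)
    col_of = {seq: j for j, seq in enumerate(kept)}
    row_of = {key: i for i, key in enumerate(keys)}
    values = matrix.to_numpy()
    for o in obs:
        j = col_of.get(o.sequence)
        if j is not None:
            values[row_of[(o.substrate, o.time_min)], j] += o.intensity
    return pd.DataFrame(values, index=index, columns=kept)


def pca(matrix: pd.DataFrame, center: bool = True, scale: bool = False) -> PCAResult:
    """Principal component analysis of a samples x features matrix.

    Columns are mean-centred by default; unit-variance scaling is off by
    default because MS intensity shares one scale across residue features.
    Zero-variance columns are dropped (with a log entry) when scaling.
    Components carry a deterministic sign: the largest-magnitude loading
    entry of each component is positive.  ``explained_ratio`` sums to 1 over
    the returned components.
    """
    if matrix.shape[0] < 2:
        raise ValueError("PCA requires at least 2 samples (rows)")
    X = matrix.to_numpy(dtype=float)
    columns = list(matrix.columns)
    if scale:
        std = X.std(axis=0, ddof=1)
        keep = std > 0
        if not keep.all():
            dropped = [c for c, k in zip(columns, keep) if not k]
            logger.info("dropping %d zero-variance column(s) under scaling", len(dropped))
            X = X[:, keep]
            std = std[keep]
            columns = [c for c, k in zip(columns, keep) if k]
        X = X / std
    if center:
        X = X - X.mean(axis=0)

    U, S, Vt = np.linalg.svd(X, full_matrices=False)
    # deterministic sign: largest-|loading| entry of each component positive
    for j in range(Vt.shape[0]):
        pivot = np.argmax(np.abs(Vt[j]))
        if Vt[j, pivot] < 0:
            Vt[j] *= -1
            U[:, j] *= -1
    total = (S**2).sum()
    explained = S**2 / total if total > 0 else np.zeros_like(S)
    comp_labels = [f"PC{j + 1}" for j in range(len(S))]
    scores = pd.DataFrame(U * S, index=matrix.index, columns=comp_labels)
    loadings = pd.DataFrame(Vt.T, index=columns, columns=comp_labels)
    return PCAResult(scores=scores, loadings=loadings, explained_ratio=explained)


def _condensed_distance(X: np.ndarray, metric: str) -> np.ndarray:
    if metric == "euclidean":
        return pdist(X, metric="euclidean")
    if metric == "correlation":
        with np.errstate(invalid="ignore", divide="ignore"):
            dist = pdist(X, metric="correlation")
        if np.isnan(dist).any():
            # zero-variance rows: distance 0 to an identical row, else maximal
            square = squareform(dist)
            n = X.shape[0]
            for i in range(n):
                for j in range(i + 1, n):
                    if np.isnan(square[i, j]):
                        square[i, j] = square[j, i] = 0.0 if np.array_equal(X[i], X[j]) else 1.0
            dist = squareform(square)
        return dist
    raise ConfigError(f"unknown distance metric {metric!r} (choose from {DISTANCES})")


def hierarchical_cluster(
    matrix: pd.DataFrame,
    distance: str = "euclidean",
    linkage: str = "ward",
    log_transform: bool = True,
) -> ClusterResult:
    """Agglomerative clustering of the rows of a feature matrix.

    MS intensities span decades, so values are log10(1+x)-transformed by
    default before computing distances.  Defaults are Euclidean distance
    with Ward linkage; correlation distance and average/complete/single
    linkage are available.  Leaf order is deterministic: at every internal
    node the child subtrees are visited smaller-first, ties broken by the
    smallest leaf index they contain.
    """
    if matrix.shape[0] < 2:
        raise ValueError("clustering requires at least 2 rows")
    if linkage not in LINKAGES:
        raise ConfigError(f"unknown linkage {linkage!r} (choose from {LINKAGES})")
    if linkage == "ward" and distance != "euclidean":
        raise ConfigError("ward linkage requires euclidean distance")
    X = matrix.to_numpy(dtype=float)
    if log_transform:
        if (X < 0).any():
            raise ValueError("log transform requires non-negative values")
        X = np.log10(1.0 + X)
    dist = _condensed_distance(X, distance)
    Z = hierarchy.linkage(dist, method=linkage)
    return ClusterResult(
        merge_tree=Z,
        leaf_order=_leaf_order(Z),
        row_keys=list(matrix.index),
        distance_metric=distance,
        linkage_method=linkage,
    )


def _leaf_order(Z: np.ndarray) -> list[int]:
    n = Z.shape[0] + 1
    children = {n + i: (int(Z[i, 0]), int(Z[i, 1])) for i in range(Z.shape[0])}

    def stats(node: int) -> tuple[int, int]:
        if node < n:
            return 1, node
        left, right = children[node]
        ls, lm = stats(left)
        rs, rm = stats(right)
        return ls + rs, min(lm, rm)

    order: list[int] = []

    def walk(node: int) -> None:
        if node < n:
            order.append(node)
            return
        left, right = children[node]
        first, second = sorted((left, right), key=stats)
        walk(first)
        walk(second)

    walk(2 * n - 2)
    return order
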