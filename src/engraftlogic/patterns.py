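"""Direction-pattern classification and hierarchical clustering of targets.

Every target gene is DE in both BM and MPB, so its pair of directions
falls into exactly one of four classes: concordantly up in G0
(UP_G0_BOTH), concordantly up in G1 (UP_G1_BOTH), or one of the two
discordant ("aberrant") patterns.  The concordant union is the subset
carried forward for functional interpretation.  Expression profiles of
the targets are clustered agglomeratively with average linkage on
Euclidean distances between log2, per-feature mean-centered profiles.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from engraftlogic.matrix import ExpressionMatrix

PATTERN_CLASSES = ("UP_G0_BOTH", "UP_G1_BOTH", "BM_G0_MPB_G1", "BM_G1_MPB_G0")

_PATTERN_BY_DIRECTIONS = {
    ("up_G0", "up_G0"): "UP_G0_BOTH",
    ("up_G1", "up_G1"): "UP_G1_BOTH",
    ("up_G0", "up_G1"): "BM_G0_MPB_G1",
    ("up_G1", "up_G0"): "BM_G1_MPB_G0",
}


def classify_patterns(targets: pd.DataFrame) -> tuple[pd.Series, dict[str, int]]:
    """Assign each target its cross-tissue direction pattern.

    ``targets`` is the table from ``identify_targets`` (needs
    direction_BM / direction_MPB).  Returns (per-feature class Series,
    class->count dict over all four classes).  The assignment is
    exhaustive and mutually exclusive; counts sum to len(targets).
    """
    for col in ("direction_BM", "direction_MPB"):
        missing = targets.index[targets[col].isna()] if col in targets else targets.index
        if col not in targets or len(missing):
            feat = missing[0] if len(missing) else "?"
            raise ValueError(f"missing {col} for feature {feat!r}")
    classes = pd.Series(
        [
            _PATTERN_BY_DIRECTIONS[(bm, mpb)]
            for bm, mpb in zip(targets["direction_BM"], targets["direction_MPB"])
        ],
        index=targets.index,
        name="pattern_class",
    )
    counts = {c: int((classes == c).sum()) for c in PATTERN_CLASSES}
    return classes, counts


def concordant_subset(classes: pd.Series) -> list[str]:
    """Targets with the same direction in BM and MPB (UP_G0_BOTH ∪ UP_G1_BOTH)."""
    mask = classes.isin(["UP_G0_BOTH", "UP_G1_BOTH"])
    return list(classes.index[mask])


def profile_matrix(matrix: ExpressionMatrix, features) -> pd.DataFrame:
    """Log2, per-feature mean-centered expression profiles for clustering."""
    sub = np.log2(matrix.values.loc[list(features)])
    return sub.sub(sub.mean(axis=1), axis=0)


def hcluster(profiles: pd.DataFrame) -> tuple[np.ndarray, list[str]]:
    """Average-linkage agglomerative clustering on Euclidean distances.

    Rows of ``profiles`` are feature profiles.  Rows are sorted by feature
    id first so distance ties resolve lexicographically and the tree is
    deterministic.  Returns (scipy linkage matrix, leaf feature ids in
    linkage order).  Merge heights are non-decreasing (average linkage is
    monotone).
    """
    if profiles.shape[0] < 2:
        raise ValueError("clustering needs at least 2 features")
    if not np.isfinite(profiles.to_numpy()).all():
        raise ValueError("non-finite values in clustering input")
    profiles = profiles.sort_index(kind="stable")
    dist = pdist(profiles.to_numpy(), metric="euclidean")
    linkage = hierarchy.linkage(dist, method="average")
    return linkage, list(profiles.index)


def linkage_to_newick(linkage: np.ndarray, leaf_names: list[str]) -> str:
    """Serialize a linkage matrix as a Newick string with branch lengths.

    Branch lengths are the height differences between a node's merge
    height and its parent's, so root-to-leaf path lengths equal merge
    heights.
    """
    tree = hierarchy.to_tree(linkage)

    def walk(node, parent_height: float) -> str:
        if node.is_leaf():
            return f"{leaf_names[node.id]}:{parent_height:.6g}"
        left = walk(node.left, node.dist)
        right = walk(node.right, node.dist)
        return f"({left},{right}):{parent_height - node.dist:.6g}"

    left = walk(tree.left, tree.dist)
    right = walk(tree.right, tree.dist)
    return f"({left},{right});"


def cut_clusters(linkage: np.ndarray, leaf_names: list[str], k: int) -> pd.Series:
    """Flat cluster labels from cutting the tree into ``k`` groups."""
    labels = hierarchy.fcluster(linkage, t=k, criterion="maxclust")
    return pd.Series(labels, index=leaf_names, name="cluster")
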