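"""Hierarchical clustering of profiles from the pairwise similarity matrix.

Profiles are clustered agglomeratively on the dissimilarity ``1 - I-index``.
Merge heights therefore live in [0, 1]. Trees are exported as Newick with the
ultrametric convention that a node's height is half its merge distance, so the
path length between two leaves equals their cophenetic distance (a two-leaf
tree merging at height h reads ``(A:h/2,B:h/2);``).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .overlap import SimilarityMatrix
from .profiles import ValidationError

__all__ = ["ClusterTree", "cluster_profiles", "export_newick"]

_LINKAGES = ("average", "complete", "single")


@dataclass
class ClusterTree:
    """Agglomerative merge structure over profile labels.

    ``linkage_matrix`` is in scipy's standard (n-1, 4) format with heights on
    the ``1 - similarity`` scale; ``labels`` are in the (lexicographically
    sorted) input order used for the merge.
    """

    labels: list[str]
    linkage_matrix: np.ndarray

    def __post_init__(self) -> None:
        Z = np.asarray(self.linkage_matrix, dtype=float)
        self.linkage_matrix = Z
        n = len(self.labels)
        if Z.shape != (n - 1, 4):
            raise ValidationError("linkage matrix shape does not match label count")
        heights = Z[:, 2]
        if np.any(np.diff(heights) < -1e-12):
            raise ValidationError("merge heights must be non-decreasing root-ward")
        if np.any(heights < -1e-12) or np.any(heights > 1 + 1e-9):
            raise ValidationError("heights must lie in [0, 1] on the 1 - similarity scale")

    def cut(self, n_clusters: int) -> dict[str, int]:
        """Flat cluster assignment at the given number of clades."""
        assign = hierarchy.fcluster(self.linkage_matrix, n_clusters, criterion="maxclust")
        return dict(zip(self.labels, (int(a) for a in assign)))

    def newick(self) -> str:
        """Newick string with branch lengths from merge heights (see module doc)."""
        root = hierarchy.to_tree(self.linkage_matrix)

        def height(node) -> float:
            return 0.0 if node.is_leaf() else node.dist / 2.0

        def render(node, parent_h: float) -> str:
            bl = max(parent_h - height(node), 0.0)
            if node.is_leaf():
                return f"{_escape(self.labels[node.id])}:{bl:.10g}"
            left = render(node.left, height(node))
            right = render(node.right, height(node))
            return f"({left},{right}):{bl:.10g}"

        h = height(root)
        left = render(root.left, h)
        right = render(root.right, h)
        return f"({left},{right});"


def _escape(label: str) -> str:
    # Newick reserves these characters; quote labels containing them.
    if any(ch in label for ch in "(),:;' \t"):
        return "'" + label.replace("'", "''") + "'"
    return label


def cluster_profiles(sm: SimilarityMatrix, linkage: str = "average") -> ClusterTree:
    """Agglomerate profiles on distance ``1 - similarity``.

    Rows are pre-sorted by label so the result is deterministic and invariant
    to the input ordering (ties between equal distances resolve by label
    order).
    """
    if linkage not in _LINKAGES:
        raise ValidationError(f"linkage must be one of {_LINKAGES}")
    order = np.argsort(np.asarray(sm.labels, dtype=object))
    labels = [sm.labels[i] for i in order]
    D = 1.0 - sm.values[np.ix_(order, order)]
    np.fill_diagonal(D, 0.0)
    D = np.clip((D + D.T) / 2.0, 0.0, 1.0)  # symmetrise away float fuzz
    condensed = squareform(D, checks=False)
    Z = hierarchy.linkage(condensed, method=linkage)
    Z[:, 2] = np.clip(Z[:, 2], 0.0, 1.0)
    return ClusterTree(labels=labels, linkage_matrix=Z)


def export_newick(tree: ClusterTree, path: str | Path) -> Path:
    """Write the tree as a Newick file (re-parseable, branch lengths kept)."""
    path = Path(path)
    path.write_text(tree.newick() + "\n")
    return path


def control_purity(tree: ClusterTree, control_labels: set[str], n_clusters: int = 2) -> float:
    """Fraction of controls inside the control-majority clade at a flat cut.

    Used for the cohort-separation readout: with strongly diverging cases,
    nearly all controls should fall in one clade of the 2-clade cut.
    """
    assign = tree.cut(n_clusters)
    ctrl = [lbl for lbl in tree.labels if lbl in control_labels]
    if not ctrl:
        raise ValidationError("no control labels present in the tree")
    clades = [assign[lbl] for lbl in ctrl]
    majority = max(set(clades), key=clades.count)
    return clades.count(majority) / len(ctrl)
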