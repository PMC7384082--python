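"""Phylogenetic covariance from an ultrametric tree.

Under Brownian trait evolution, the covariance between two tips is
proportional to the depth of their most recent common ancestor, so the
species relatedness matrix A has ``A[i, j] = depth(MRCA(i, j)) /
height``.  Trees are scaled to unit height (the time calibration is
relative, not absolute), which makes heritable variance components
directly comparable to residual ones and gives ``diag(A) = 1``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import dendropy
import numpy as np

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PhyloCovariance:
    """Relatedness matrix A (unit tree height) with its inverse."""

    taxa: tuple
    A: np.ndarray
    A_inv: np.ndarray

    @property
    def n(self) -> int:
        return len(self.taxa)


def read_tree(path_or_string, schema: str = "newick") -> dendropy.Tree:
    """Read a tree from a Newick file path or literal string."""
    s = str(path_or_string)
    if s.lstrip().startswith("("):
        return dendropy.Tree.get(data=s, schema=schema)
    return dendropy.Tree.get(path=s, schema=schema)


def prune_tree(tree: dendropy.Tree, keep) -> dendropy.Tree:
    """Induced subtree on the labels in ``keep``.

    Degree-2 internal nodes created by pruning are suppressed with
    their branch lengths summed (dendropy's default behaviour).
    Raises ``KeyError`` listing labels absent from the tree, and
    ``ValueError`` for fewer than two kept taxa.
    """
    keep = list(dict.fromkeys(keep))
    if len(keep) < 2:
        raise ValueError("fewer than 2 taxa to keep")
    labels = {t.label for t in tree.taxon_namespace}
    missing = [k for k in keep if k not in labels]
    if missing:
        raise KeyError(f"labels absent from tree: {missing}")
    pruned = tree.clone(depth=1)
    pruned.retain_taxa_with_labels(keep)
    return pruned


def _tip_depths(tree: dendropy.Tree) -> dict:
    tree.calc_node_root_distances(return_leaf_distances_only=False)
    return {leaf.taxon.label: leaf.root_distance for leaf in tree.leaf_node_iter()}


def phylo_covariance(tree: dendropy.Tree, jitter: float = 1e-10) -> PhyloCovariance:
    """Relatedness matrix for the tips of a rooted tree.

    Shared path length from the root is computed as ``(depth_i +
    depth_j - d_ij) / 2`` where ``d_ij`` is the patristic distance --
    exactly the MRCA depth on any rooted tree.  The matrix is scaled
    by the maximum tip depth; a spread of tip depths beyond 1% of the
    height (a non-ultrametric tree) only triggers a warning.  The
    inverse falls back to a jittered solve when ill-conditioned.
    """
    tree = tree.clone(depth=1)
    depths = _tip_depths(tree)
    taxa = tuple(sorted(depths))
    n = len(taxa)
    if n < 2:
        raise ValueError("need at least 2 tips")
    depth_vec = np.array([depths[t] for t in taxa])
    height = float(depth_vec.max())
    if height <= 0:
        raise ValueError("tree has zero height")
    if (depth_vec.max() - depth_vec.min()) / height > 0.01:
        logger.warning("tree is not ultrametric (tip-depth spread %.3g of "
                       "height); scaling by max depth anyway",
                       (depth_vec.max() - depth_vec.min()) / height)
    pdm = tree.phylogenetic_distance_matrix()
    taxon_by_label = {t.label: t for t in tree.taxon_namespace}
    A = np.empty((n, n))
    for i, li in enumerate(taxa):
        A[i, i] = depth_vec[i]
        for j in range(i + 1, n):
            d = pdm.patristic_distance(taxon_by_label[li],
                                       taxon_by_label[taxa[j]])
            A[i, j] = A[j, i] = (depth_vec[i] + depth_vec[j] - d) / 2.0
    A /= height
    try:
        A_inv = np.linalg.inv(A)
        cond_bad = not np.all(np.isfinite(A_inv))
    except np.linalg.LinAlgError:
        cond_bad = True
    if cond_bad or np.linalg.cond(A) > 1e12:
        logger.warning("relatedness matrix ill-conditioned; "
                       "adding %.0e diagonal jitter", jitter)
        A_inv = np.linalg.inv(A + jitter * np.eye(n))
    return PhyloCovariance(taxa=taxa, A=A, A_inv=A_inv)
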