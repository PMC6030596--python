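"""Tree handling: newick parsing, pruning, and the shared-ancestry
correlation matrix used by the phylogenetic random effect.

The correlation between two tips is the branch length shared on their
root-to-tip paths (root-to-MRCA depth), divided by the maximum
root-to-tip depth.  For an ultrametric tree this is the standard
Brownian-motion correlation structure.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import dendropy
import numpy as np

from .data_model import normalize_species

__all__ = [
    "PhyloTree",
    "PhyloCorrelation",
    "NewickError",
    "read_newick",
    "parse_newick",
    "prune_tree",
    "tree_to_correlation",
]

#: Diagonal ridge added before any factorization of a near-singular A.
RIDGE = 1e-8


class NewickError(ValueError):
    """Malformed or unusable newick input."""


@dataclass
class PhyloTree:
    """A rooted tree with branch lengths, tip labels normalized."""

    tree: dendropy.Tree

    @property
    def tips(self) -> list[str]:
        return [leaf.taxon.label for leaf in self.tree.leaf_node_iter()]

    def __len__(self) -> int:
        return len(self.tree.leaf_nodes())

    def as_newick(self) -> str:
        return self.tree.as_string(schema="newick", suppress_rooting=True).strip()


def _validate(tree: dendropy.Tree) -> PhyloTree:
    labels = []
    for leaf in tree.leaf_node_iter():
        if leaf.taxon is None or not leaf.taxon.label:
            raise NewickError("tree contains an unlabelled tip")
        leaf.taxon.label = normalize_species(leaf.taxon.label)
        labels.append(leaf.taxon.label)
    dupes = sorted({l for l in labels if labels.count(l) > 1})
    if dupes:
        raise NewickError(f"duplicate tip label(s) after normalization: {', '.join(dupes)}")
    for edge in tree.preorder_edge_iter():
        if edge.head_node is tree.seed_node:
            continue
        if edge.length is None:
            raise NewickError("tree has edges without branch lengths")
        if edge.length < 0:
            raise NewickError(f"negative branch length {edge.length}")
    return PhyloTree(tree)


def parse_newick(newick: str) -> PhyloTree:
    """Parse a newick string (one tree, branch lengths required)."""
    if ";" not in newick:
        raise NewickError(
            f"malformed newick (no terminating ';'): parse stopped at offset {len(newick)}"
        )
    try:
        tree = dendropy.Tree.get(
            data=newick,
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises several error types
        raise NewickError(f"malformed newick: {exc}") from exc
    return _validate(tree)


def read_newick(path) -> PhyloTree:
    """Read a single-tree newick file."""
    with open(path, "r", encoding="utf-8") as fh:
        return parse_newick(fh.read())


def prune_tree(ptree: PhyloTree, keep: list[str]) -> PhyloTree:
    """Prune to ``keep`` (normalized species names), preserving all
    pairwise path lengths among retained tips.

    Degree-2 internal nodes created by pruning are collapsed with their
    edge lengths summed (dendropy does this on taxon retention).
    """
    keep_norm = [normalize_species(k) for k in keep]
    have = set(ptree.tips)
    unmatched = sorted(set(keep_norm) - have)
    if unmatched:
        raise ValueError(f"species not in tree: {', '.join(unmatched)}")
    clone = dendropy.Tree(ptree.tree)
    clone.retain_taxa_with_labels(keep_norm)
    return PhyloTree(clone)


@dataclass
class PhyloCorrelation:
    """Tip-ordered phylogenetic correlation matrix A (unit diagonal)."""

    tip_order: list[str]
    A: np.ndarray

    def index_of(self, species: str) -> int:
        return self.tip_order.index(normalize_species(species))

    def submatrix(self, species: list[str]) -> "PhyloCorrelation":
        idx = [self.index_of(s) for s in species]
        return PhyloCorrelation(
            tip_order=[self.tip_order[i] for i in idx],
            A=self.A[np.ix_(idx, idx)].copy(),
        )


def tree_to_correlation(ptree: PhyloTree) -> PhyloCorrelation:
    """Build the correlation matrix from root-to-MRCA shared path lengths.

    A[i, j] = depth(MRCA(i, j)) / max root-to-tip depth; the diagonal is
    forced to exactly 1 afterwards (only relevant for non-ultrametric
    input, where a warning records the largest pre-adjustment deviation).
    """
    tree = ptree.tree
    tips = ptree.tips
    n = len(tips)
    if n < 2:
        raise ValueError("tree must have at least 2 tips")

    # root-to-tip depths
    depth_of: dict = {}
    for node in tree.preorder_node_iter():
        parent = node.parent_node
        edge = node.edge.length if node.parent_node is not None else 0.0
        depth_of[node] = (depth_of[parent] if parent is not None else 0.0) + (edge or 0.0)
    tip_nodes = list(tree.leaf_node_iter())
    tip_depth = np.array([depth_of[nd] for nd in tip_nodes])
    max_depth = float(tip_depth.max())
    if max_depth <= 0:
        raise ValueError("zero-depth tree: all root-to-tip path lengths are 0")

    # patristic distances give MRCA depth: d(root,i)+d(root,j)-d(i,j) = 2*depth(MRCA)
    pdm = tree.phylogenetic_distance_matrix()
    A = np.zeros((n, n))
    taxa = [nd.taxon for nd in tip_nodes]
    for i in range(n):
        A[i, i] = tip_depth[i]
        for j in range(i + 1, n):
            dij = pdm.patristic_distance(taxa[i], taxa[j])
            A[i, j] = A[j, i] = 0.5 * (tip_depth[i] + tip_depth[j] - dij)
    A /= max_depth

    diag_dev = float(np.max(np.abs(np.diag(A) - 1.0)))
    if diag_dev > 1e-9:
        warnings.warn(
            f"non-ultrametric tree: forcing unit diagonal "
            f"(max pre-adjustment deviation {diag_dev:.3g})",
            stacklevel=2,
        )
    np.fill_diagonal(A, 1.0)
    return PhyloCorrelation(tip_order=list(tips), A=A)


def correlation_inverse(corr: PhyloCorrelation) -> np.ndarray:
    """Inverse of A with a small diagonal ridge for numerical safety."""
    A = corr.A + RIDGE * np.eye(len(corr.tip_order))
    L = np.linalg.cholesky(A)
    inv_L = np.linalg.inv(L)
    return inv_L.T @ inv_L
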