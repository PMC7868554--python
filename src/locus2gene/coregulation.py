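"""Co-regulation clustering of prioritized genes.

Each gene is described by its loading profile across a large set of
co-regulation components (principal components of cross-tissue expression).
Pairwise Pearson correlations of these profiles, Fisher-transformed to Z
scores, give a gene x gene similarity matrix; Ward hierarchical clustering
of the Z-score rows (Euclidean distance) cut at k clusters recovers groups
of genes with shared regulatory programs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy

logger = logging.getLogger(__name__)


@dataclass
class CoregZMatrix:
    """Symmetric gene x gene Fisher-Z correlation matrix."""

    z: pd.DataFrame
    n_components: int

    @property
    def genes(self) -> list[str]:
        return list(self.z.index)

    def z_cap(self) -> float:
        return float(np.arctanh(1 - 1e-12) * np.sqrt(self.n_components - 3))


def profile_correlate(genes: list[str], component_matrix: pd.DataFrame) -> CoregZMatrix:
    """Fisher-Z similarity of gene loading profiles.

    Z = atanh(r) * sqrt(n_components - 3) for the Pearson r between two
    genes' component-loading vectors; |r| = 1 (including the diagonal) is
    capped at atanh(1 - 1e-12) * sqrt(n - 3) to stay finite.  Genes with a
    constant profile have undefined correlations and are excluded with a log
    line.
    """
    missing = [g for g in genes if g not in component_matrix.index]
    if missing:
        raise ValueError(f"genes absent from component matrix: {missing[:5]}")
    n_comp = component_matrix.shape[1]
    if n_comp < 5:
        raise ValueError("need at least 5 components for a stable Fisher transform")
    X = component_matrix.loc[genes].to_numpy(float)
    sds = X.std(axis=1)
    constant = sds == 0
    if constant.any():
        dropped = [g for g, c in zip(genes, constant) if c]
        logger.warning("profile_correlate: excluding constant-profile genes %s", dropped)
        genes = [g for g, c in zip(genes, constant) if not c]
        X = X[~constant]
    r = np.corrcoef(X)
    r = np.clip(r, -(1 - 1e-12), 1 - 1e-12)
    z = np.arctanh(r) * np.sqrt(n_comp - 3)
    cap = float(np.arctanh(1 - 1e-12) * np.sqrt(n_comp - 3))
    np.fill_diagonal(z, cap)
    z = (z + z.T) / 2.0
    return CoregZMatrix(z=pd.DataFrame(z, index=genes, columns=genes), n_components=n_comp)


def cluster_genes(
    zmat: CoregZMatrix, k: int = 4
) -> tuple[dict[str, int], np.ndarray, str]:
    """Ward clustering of the Z-score rows cut to exactly k clusters.

    Returns (gene -> 1-based cluster label, linkage matrix, Newick string of
    the dendrogram).  Labels are renumbered so cluster 1 contains the
    lexicographically first gene id, making the output invariant to the
    input order of genes.
    """
    genes = sorted(zmat.genes)
    if k > len(genes):
        raise ValueError(f"k = {k} exceeds {len(genes)} genes")
    X = zmat.z.loc[genes, genes].to_numpy(float)
    linkage = hierarchy.linkage(X, method="ward")
    raw = hierarchy.fcluster(linkage, t=k, criterion="maxclust")
    # deterministic relabeling by first gene id in each raw cluster
    first_gene: dict[int, str] = {}
    for g, lab in zip(genes, raw):
        first_gene.setdefault(int(lab), g)
    order = sorted(first_gene, key=lambda lab: first_gene[lab])
    relabel = {old: new + 1 for new, old in enumerate(order)}
    labels = {g: relabel[int(lab)] for g, lab in zip(genes, raw)}
    newick = linkage_to_newick(linkage, genes)
    return labels, linkage, newick


def linkage_to_newick(linkage: np.ndarray, leaf_names: list[str]) -> str:
    """Render a SciPy linkage matrix as a Newick tree with branch lengths."""
    tree = hierarchy.to_tree(linkage)

    def walk(node, parent_dist: float) -> str:
        length = max(parent_dist - node.dist, 0.0)
        if node.is_leaf():
            return f"{leaf_names[node.id]}:{length:.6g}"
        left = walk(node.left, node.dist)
        right = walk(node.right, node.dist)
        return f"({left},{right}):{length:.6g}"

    return walk(tree, tree.dist) + ";"
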