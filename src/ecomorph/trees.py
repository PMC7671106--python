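"""Phylogeny handling: Newick I/O, validation, covariance structure, contrasts.

Thin layer over :mod:`dendropy`.  Trees are rooted with branch lengths in
arbitrary units; tip labels must match the species keys of the trait tables
they are analysed with (mismatches are pruned/dropped with a logged warning,
never silently).
"""

from __future__ import annotations

import logging
from typing import Iterable

import dendropy
import numpy as np

__all__ = [
    "TreeValidationError",
    "load_tree",
    "parse_tree",
    "validate_tree",
    "tip_labels",
    "reconcile",
    "vcv_matrix",
    "pic_contrasts",
    "pic_rate_matrix",
]

log = logging.getLogger(__name__)


class TreeValidationError(ValueError):
    """Raised for unrooted, mislabelled, or non-positive-branch trees."""


def parse_tree(newick: str) -> dendropy.Tree:
    try:
        tree = dendropy.Tree.get(data=newick, schema="newick")
    except Exception as err:
        raise TreeValidationError(str(err)) from err
    validate_tree(tree)
    return tree


def load_tree(path) -> dendropy.Tree:
    try:
        tree = dendropy.Tree.get(path=str(path), schema="newick")
    except FileNotFoundError:
        raise
    except Exception as err:
        raise TreeValidationError(str(err)) from err
    validate_tree(tree)
    return tree


def validate_tree(tree: dendropy.Tree) -> None:
    labels = tip_labels(tree)
    if len(labels) != len(set(labels)):
        raise TreeValidationError("duplicate tip labels")
    for edge in tree.preorder_edge_iter():
        if edge.tail_node is None:
            continue
        if edge.length is None or edge.length <= 0:
            head = edge.head_node
            name = head.taxon.label if head.taxon else "<internal>"
            raise TreeValidationError(
                f"edge above {name} has non-positive or missing length"
            )


def tip_labels(tree: dendropy.Tree) -> list[str]:
    return [leaf.taxon.label for leaf in tree.leaf_node_iter()]


def reconcile(tree: dendropy.Tree, species: Iterable[str]) -> tuple[dendropy.Tree, list[str]]:
    """Prune tree tips absent from ``species``; report species absent from the tree.

    Returns the pruned tree (a clone; the input is untouched) and the list of
    species that the caller must drop because the tree lacks them.  Both
    directions are logged.
    """
    species = set(species)
    labels = set(tip_labels(tree))
    extra_tips = sorted(labels - species)
    missing = sorted(species - labels)
    pruned = tree.clone(depth=1)
    if extra_tips:
        log.warning("pruning %d tree tips absent from the trait table: %s",
                    len(extra_tips), extra_tips)
        pruned.retain_taxa_with_labels(sorted(labels & species))
    if missing:
        log.warning("dropping %d species absent from the tree: %s",
                    len(missing), missing)
    return pruned, missing


def vcv_matrix(tree: dendropy.Tree, order: list[str] | None = None) -> tuple[np.ndarray, list[str]]:
    """Brownian-motion covariance of tip values: shared root-to-tip path lengths.

    Returns (C, labels) with C[i, j] the path length from the root to the most
    recent common ancestor of tips i and j.
    """
    leaves = list(tree.leaf_node_iter())
    labels = [l.taxon.label for l in leaves]
    if order is not None:
        lut = {lab: leaf for lab, leaf in zip(labels, leaves)}
        leaves = [lut[lab] for lab in order]
        labels = list(order)
    # depth of every node
    depth: dict = {}
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            depth[node] = 0.0
        else:
            depth[node] = depth[node.parent_node] + node.edge.length
    pdm = tree.phylogenetic_distance_matrix()
    n = len(leaves)
    C = np.zeros((n, n))
    for i, li in enumerate(leaves):
        C[i, i] = depth[li]
        for j in range(i + 1, n):
            lj = leaves[j]
            dij = pdm.patristic_distance(li.taxon, lj.taxon)
            # cov = (depth_i + depth_j - distance) / 2 = depth of the MRCA
            C[i, j] = C[j, i] = 0.5 * (depth[li] + depth[lj] - dij)
    return C, labels


def pic_contrasts(tree: dendropy.Tree, values: dict[str, np.ndarray]) -> np.ndarray:
    """Standardized phylogenetically independent contrasts.

    ``values`` maps tip label -> 1-D trait vector (p characters).  Returns an
    (n-1) x p array of contrasts standardized by their expected standard
    deviation, computed with the classic pruning recursion.
    """
    work = tree.clone(depth=1)
    xs: dict = {}
    vs: dict = {}
    for leaf in work.leaf_node_iter():
        xs[leaf] = np.asarray(values[leaf.taxon.label], dtype=float)
        vs[leaf] = 0.0
    contrasts = []
    for node in work.postorder_node_iter():
        if node.is_leaf():
            continue
        children = node.child_nodes()
        if len(children) == 1:  # unifurcation: pass through
            (c,) = children
            xs[node] = xs[c]
            vs[node] = vs[c] + c.edge.length
            continue
        # reduce multifurcations pairwise in child order
        x, v = xs[children[0]], vs[children[0]] + children[0].edge.length
        for c in children[1:]:
            xc, vc = xs[c], vs[c] + c.edge.length
            contrasts.append((x - xc) / np.sqrt(v + vc))
            x = (x / v + xc / vc) / (1 / v + 1 / vc)
            v = 1 / (1 / v + 1 / vc)
        xs[node] = x
        vs[node] = v
    return np.asarray(contrasts)


def pic_rate_matrix(tree: dendropy.Tree, values: dict[str, np.ndarray]) -> np.ndarray:
    """Evolutionary rate (covariance) matrix estimated from independent contrasts.

    R = U'U / m for the m x p matrix U of standardized contrasts; this is the
    ML estimator of the Brownian rate matrix under the contrasts construction.
    """
    u = pic_contrasts(tree, values)
    if u.ndim == 1:
        u = u[:, None]
    return (u.T @ u) / u.shape[0]
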