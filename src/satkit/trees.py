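"""Time-calibrated taxon trees: parsing, node ages, MRCA age queries.

Newick handling is delegated to dendropy; this module layers the dating
semantics on top: every node carries an age in million years (MY), leaves are
at age 0, and parent ages are never younger than child ages.

Two dialects are supported (declared, not guessed):

* ``branch_lengths`` — branch lengths are in MY and the tree is ultrametric;
  node ages are reconstructed from leaf depths.
* ``node_labels`` — internal-node labels carry the node age directly.
"""

from __future__ import annotations

from pathlib import Path

import dendropy


class DatedTree:
    """A dendropy tree annotated with a node age (MY) per node."""

    def __init__(self, tree: dendropy.Tree, ages: dict[dendropy.Node, float]):
        self.tree = tree
        self.ages = ages

    @property
    def taxa(self) -> list[str]:
        return [leaf.taxon.label for leaf in self.tree.leaf_node_iter()]

    @property
    def root_age(self) -> float:
        return self.ages[self.tree.seed_node]

    def node_age(self, node: dendropy.Node) -> float:
        return self.ages[node]

    def mrca(self, taxa: list[str]) -> dendropy.Node:
        known = set(self.taxa)
        missing = sorted(set(taxa) - known)
        if missing:
            raise KeyError(f"taxa not in tree: {missing}")
        if len(set(taxa)) == 1:
            (label,) = set(taxa)
            return self.tree.find_node_with_taxon_label(label)
        return self.tree.mrca(taxon_labels=list(set(taxa)))

    def mrca_age(self, taxa: list[str]) -> float:
        return self.ages[self.mrca(taxa)]

    def pairwise_age(self, a: str, b: str) -> float:
        return self.mrca_age([a, b])


def _ages_from_branch_lengths(tree: dendropy.Tree, tolerance: float) -> dict:
    depths = {}

    def walk(node, depth):
        depths[node] = depth
        for child in node.child_nodes():
            walk(child, depth + (child.edge.length or 0.0))

    walk(tree.seed_node, 0.0)
    leaf_depths = [depths[l] for l in tree.leaf_node_iter()]
    max_depth = max(leaf_depths)
    tol = max(tolerance, tolerance * max_depth)
    if max_depth - min(leaf_depths) > tol:
        raise ValueError(
            "tree is not ultrametric under the branch_lengths dialect: "
            f"leaf depths range {min(leaf_depths):g}..{max_depth:g} MY"
        )
    ages = {}
    for node in tree.preorder_node_iter():
        age = max_depth - depths[node]
        ages[node] = 0.0 if node.is_leaf() else age
    return ages


def _ages_from_node_labels(tree: dendropy.Tree) -> dict:
    ages = {}
    for node in tree.preorder_node_iter():
        if node.is_leaf():
            ages[node] = 0.0
        else:
            if node.label is None:
                raise ValueError("internal node without an age label under node_labels dialect")
            ages[node] = float(node.label)
    for node in tree.preorder_node_iter():
        for child in node.child_nodes():
            if ages[node] < ages[child]:
                raise ValueError(
                    f"parent age {ages[node]} MY younger than child age {ages[child]} MY"
                )
    return ages


def read_newick_dated(
    path: str | Path,
    dialect: str = "branch_lengths",
    tolerance: float = 1e-6,
) -> DatedTree:
    """Read a dated Newick tree; see module docstring for the two dialects."""
    tree = dendropy.Tree.get(path=str(path), schema="newick", preserve_underscores=True)
    return date_tree(tree, dialect=dialect, tolerance=tolerance)


def dated_tree_from_string(
    newick: str, dialect: str = "branch_lengths", tolerance: float = 1e-6
) -> DatedTree:
    tree = dendropy.Tree.get(data=newick, schema="newick", preserve_underscores=True)
    return date_tree(tree, dialect=dialect, tolerance=tolerance)


def date_tree(tree: dendropy.Tree, dialect: str = "branch_lengths", tolerance: float = 1e-6) -> DatedTree:
    tree.is_rooted = True  # a dated tree is rooted by construction
    if dialect == "branch_lengths":
        ages = _ages_from_branch_lengths(tree, tolerance)
    elif dialect == "node_labels":
        ages = _ages_from_node_labels(tree)
    else:
        raise ValueError(f"unknown tree dialect: {dialect!r}")
    return DatedTree(tree, ages)
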