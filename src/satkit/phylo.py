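"""Monomer phylogenetics: subsampling, K2P distance matrices, neighbor
joining, and bootstrap supports.

Neighbor joining is the in-repo, exactly-testable tree builder: on additive
distance matrices the reconstructed tree's path-length matrix reproduces the
input exactly (branch lengths are deliberately not clamped at zero, so that
property holds to machine precision). Supports come from column-resampled
bootstrap replicates of a supplied multiple sequence alignment.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import dendropy
import numpy as np

from satkit.alignment import global_align
from satkit.divergence import encode, k2p_distance

logger = logging.getLogger("satkit")


def subsample_monomers(monomers: list, n: int = 100, rng_seed: int | np.random.Generator = 0) -> list:
    """Uniform subsample without replacement; everything if fewer than n."""
    if n <= 0:
        raise ValueError("subsample size must be positive")
    if len(monomers) <= n:
        return list(monomers)
    rng = rng_seed if isinstance(rng_seed, np.random.Generator) else np.random.default_rng(rng_seed)
    idx = np.sort(rng.choice(len(monomers), size=n, replace=False))
    return [monomers[i] for i in idx]


@dataclass
class DistanceMatrix:
    labels: list[str]
    matrix: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (len(self.labels), len(self.labels)):
            raise ValueError("matrix shape does not match labels")
        if not np.allclose(m, m.T, atol=1e-9):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(m), 0.0):
            raise ValueError("distance matrix must have a zero diagonal")
        self.matrix = m


def _msa_k2p_matrix(rows: np.ndarray) -> np.ndarray:
    """Pairwise K2P over the rows of a coded MSA (n, m); gaps/N excluded."""
    valid = rows < 4
    purine = np.isin(rows, (0, 2))
    pv = valid[:, None, :] & valid[None, :, :]
    diff = (rows[:, None, :] != rows[None, :, :]) & pv
    same_class = purine[:, None, :] == purine[None, :, :]
    ts = (diff & same_class).sum(axis=2)
    tv = (diff & ~same_class).sum(axis=2)
    sites = pv.sum(axis=2)
    with np.errstate(divide="ignore", invalid="ignore"):
        P = np.where(sites > 0, ts / np.maximum(sites, 1), np.nan)
        Q = np.where(sites > 0, tv / np.maximum(sites, 1), np.nan)
        w1 = 1.0 - 2.0 * P - Q
        w2 = 1.0 - 2.0 * Q
        d = np.where(
            (w1 > 0) & (w2 > 0),
            -0.5 * np.log(np.maximum(w1, 1e-300) * np.sqrt(np.maximum(w2, 1e-300))),
            np.inf,
        )
    np.fill_diagonal(d, 0.0)
    return d


def distance_matrix(monomers: list[tuple[str, str]], aligned: bool = False) -> DistanceMatrix:
    """Pairwise K2P distances between monomers.

    Unaligned monomers are globally aligned pair by pair with the package
    scoring; ``aligned=True`` treats the inputs as MSA rows. Monomers causing
    saturated (infinite) pairs are dropped, most-offending first, with a log.
    """
    if len(monomers) < 3:
        raise ValueError("distance matrix requires at least 3 monomers")
    labels = [m[0] for m in monomers]
    n = len(labels)
    if aligned:
        mat = _msa_k2p_matrix(np.stack([encode(m[1]) for m in monomers]))
    else:
        mat = np.zeros((n, n))
        for i, j in itertools.combinations(range(n), 2):
            ga, gb = global_align(monomers[i][1], monomers[j][1])
            try:
                d = k2p_distance(ga, gb).d
            except ValueError:
                d = np.inf
            mat[i, j] = mat[j, i] = d
    keep = list(range(n))
    while True:
        sub = mat[np.ix_(keep, keep)]
        bad = ~np.isfinite(sub)
        if not bad.any():
            break
        if len(keep) <= 3:
            raise ValueError("too many saturated pairs: no usable distance matrix")
        worst = keep[int(bad.sum(axis=1).argmax())]
        logger.info("distance_matrix: dropping %s (saturated pairs)", labels[worst])
        keep.remove(worst)
    return DistanceMatrix([labels[i] for i in keep], mat[np.ix_(keep, keep)])


# ---------------------------------------------------------------------------
# neighbor joining
# ---------------------------------------------------------------------------

def nj_tree(dm: DistanceMatrix) -> dendropy.Tree:
    """Classic neighbor joining; returns an (arbitrarily rooted) dendropy tree.

    Ties in the Q criterion break to the lexicographically first index pair,
    so the topology is deterministic. Branch lengths may be negative on
    non-additive inputs; on additive inputs the tree inverts the matrix
    exactly.
    """
    n = len(dm.labels)
    tns = dendropy.TaxonNamespace(dm.labels)
    nodes = []
    for label in dm.labels:
        node = dendropy.Node()
        node.taxon = tns.get_taxon(label)
        nodes.append(node)
    d = dm.matrix.astype(float).copy()
    active = list(range(n))

    def join(i: int, j: int, li: float, lj: float) -> int:
        parent = dendropy.Node()
        ci, cj = nodes[i], nodes[j]
        parent.add_child(ci)
        parent.add_child(cj)
        ci.edge.length = li
        cj.edge.length = lj
        nodes.append(parent)
        return len(nodes) - 1

    while len(active) > 3:
        m = len(active)
        sub = d[np.ix_(active, active)]
        r = sub.sum(axis=1)
        q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        ai, aj = np.unravel_index(np.argmin(q), q.shape)
        if ai > aj:
            ai, aj = aj, ai
        i, j = active[ai], active[aj]
        dij = sub[ai, aj]
        li = 0.5 * dij + (r[ai] - r[aj]) / (2 * (m - 2))
        lj = dij - li
        k = join(i, j, li, lj)
        d = np.pad(d, ((0, 1), (0, 1)))
        for ax, x in enumerate(active):
            if x in (i, j):
                continue
            d[k, x] = d[x, k] = 0.5 * (sub[ai, ax] + sub[aj, ax] - dij)
        active = [x for x in active if x not in (i, j)] + [k]

    root = dendropy.Node()
    if len(active) == 3:
        a, b, c = active
        la = 0.5 * (d[a, b] + d[a, c] - d[b, c])
        lb = 0.5 * (d[a, b] + d[b, c] - d[a, c])
        lc = 0.5 * (d[a, c] + d[b, c] - d[a, b])
        for x, lx in ((a, la), (b, lb), (c, lc)):
            root.add_child(nodes[x])
            nodes[x].edge.length = lx
    elif len(active) == 2:
        a, b = active
        for x in (a, b):
            root.add_child(nodes[x])
            nodes[x].edge.length = d[a, b] / 2
    else:
        root = nodes[active[0]]
    tree = dendropy.Tree(taxon_namespace=tns, seed_node=root)
    tree.is_rooted = False
    return tree


def tree_path_distances(tree: dendropy.Tree) -> DistanceMatrix:
    """Leaf-to-leaf path lengths of a tree (for inversion checks)."""
    pdm = tree.phylogenetic_distance_matrix()
    labels = sorted(t.label for t in tree.taxon_namespace)
    n = len(labels)
    mat = np.zeros((n, n))
    taxa = {t.label: t for t in tree.taxon_namespace}
    for i, j in itertools.combinations(range(n), 2):
        mat[i, j] = mat[j, i] = pdm.distance(taxa[labels[i]], taxa[labels[j]])
    return DistanceMatrix(labels, mat)


def bipartitions(tree: dendropy.Tree) -> set[frozenset]:
    """Non-trivial bipartitions as canonical frozensets of leaf labels.

    Each internal edge splits the leaves in two; the side not containing the
    lexicographically first label is kept, making the encoding rooting-free.
    """
    labels = sorted(l.taxon.label for l in tree.leaf_node_iter())
    all_set = frozenset(labels)
    anchor = labels[0]
    splits = set()
    for node in tree.preorder_node_iter():
        if node.parent_node is None or node.is_leaf():
            continue
        below = frozenset(l.taxon.label for l in node.leaf_iter())
        side = all_set - below if anchor in below else below
        if 2 <= len(side) <= len(labels) - 2:
            splits.add(side)
    return splits


def bootstrap_support(
    alignment: list[tuple[str, str]],
    n_replicates: int = 100,
    rng_seed: int | np.random.Generator = 0,
) -> tuple[dendropy.Tree, dict[frozenset, float]]:
    """Column-resampling bootstrap supports for the NJ tree of an MSA.

    Returns the tree built from the full alignment and, for each of its
    non-trivial bipartitions, the fraction of replicates containing it.
    """
    if len(alignment) < 4:
        raise ValueError("bootstrap requires at least 4 aligned sequences")
    lengths = {len(s) for _l, s in alignment}
    if len(lengths) != 1:
        raise ValueError("bootstrap input must be an alignment (equal-length rows)")
    (m,) = lengths
    rng = rng_seed if isinstance(rng_seed, np.random.Generator) else np.random.default_rng(rng_seed)
    labels = [l for l, _s in alignment]
    rows = np.stack([encode(s) for _l, s in alignment])

    def tree_from_columns(cols: np.ndarray) -> dendropy.Tree:
        mat = _msa_k2p_matrix(rows[:, cols])
        mat[~np.isfinite(mat)] = np.nanmax(np.where(np.isfinite(mat), mat, np.nan)) * 2 + 1.0
        return nj_tree(DistanceMatrix(labels, mat))

    original = tree_from_columns(np.arange(m))
    original_splits = bipartitions(original)
    hits = {s: 0 for s in original_splits}
    for _ in range(n_replicates):
        cols = rng.integers(0, m, size=m)
        rep_splits = bipartitions(tree_from_columns(cols))
        for s in original_splits:
            if s in rep_splits:
                hits[s] += 1
    support = {s: hits[s] / n_replicates for s in original_splits}
    return original, support
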