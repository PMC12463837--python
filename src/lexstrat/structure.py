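"""Population-structure recovery from a distance matrix.

Three complementary views of the same labeled distance matrix:

* classical (Torgerson) multidimensional scaling into 2 or 3 dimensions,
* hierarchical agglomerative clustering (Ward or average linkage) as a
  rooted dendrogram,
* a Saitou-Nei neighbor-joining tree (unrooted, additive branch lengths),

plus Newick serialization and dendrogram cutting. Lexical distance
matrices are generally non-Euclidean, so MDS reports its full eigenvalue
spectrum: negative eigenvalues are excluded from coordinates but kept so
the user can judge distortion.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
from scipy.cluster import hierarchy

from .wordlist_io import DistanceMatrix, ValidationError

__all__ = [
    "Embedding",
    "TreeNode",
    "Tree",
    "classical_mds",
    "agglomerative",
    "cut_tree",
    "neighbor_joining",
    "to_newick",
    "cophenetic_matrix",
    "tree_distance_matrix",
]


@dataclass
class Embedding:
    """Low-dimensional MDS coordinates.

    ``eigenvalues`` are the k eigenvalues backing the coordinate axes
    (descending; zero where an axis was padded); ``all_eigenvalues`` is the
    full spectrum of the double-centered matrix, negatives included.
    ``stress`` is the residual sum of squared discrepancies between
    embedded and input distances. ``degenerate`` flags fewer than k
    positive eigenvalues.
    """

    labels: list[str]
    coords: np.ndarray
    eigenvalues: np.ndarray
    all_eigenvalues: np.ndarray
    stress: float
    degenerate: bool = False

    def distances(self) -> np.ndarray:
        diff = self.coords[:, None, :] - self.coords[None, :, :]
        return np.sqrt((diff**2).sum(axis=-1))


@dataclass
class TreeNode:
    name: str | None = None
    length: float = 0.0  # branch length to parent
    children: list["TreeNode"] = field(default_factory=list)
    clamped: bool = False  # NJ branch length was negative, clamped to 0
    height: float = 0.0  # dendrogram merge height (0 at leaves)

    def leaves(self) -> list["TreeNode"]:
        if not self.children:
            return [self]
        out: list[TreeNode] = []
        for c in self.children:
            out.extend(c.leaves())
        return out


@dataclass
class Tree:
    """A rooted dendrogram or an unrooted NJ tree (trifurcating root node).

    Dendrograms additionally carry the scipy linkage matrix that produced
    them (``merges``) so cutting and cophenetics use the standard
    machinery.
    """

    root: TreeNode
    rooted: bool
    labels: list[str]
    merges: np.ndarray | None = None  # scipy linkage matrix, dendrograms only

    def leaf_names(self) -> list[str]:
        return [leaf.name for leaf in self.root.leaves()]

    def has_clamped_branches(self) -> bool:
        def walk(node: TreeNode) -> bool:
            return node.clamped or any(walk(c) for c in node.children)

        return walk(self.root)


# ---------------------------------------------------------------------------
# classical MDS


def classical_mds(d: DistanceMatrix, k: int = 2) -> Embedding:
    """Torgerson double-centering MDS.

    Squared distances are double-centered, eigendecomposed, and the top-k
    nonnegative eigenpairs scaled by the square root of their eigenvalue
    give the coordinates. Axis orientation is made deterministic by
    flipping each axis so the lexicographically smallest label has a
    nonpositive coordinate there.
    """
    if k not in (2, 3):
        raise ValueError("k must be 2 or 3")
    n = len(d)
    if n < k + 1:
        raise ValidationError(f"need at least {k + 1} points for k={k}")
    D2 = d.values**2
    J = np.eye(n) - np.full((n, n), 1.0 / n)
    B = -0.5 * J @ D2 @ J
    B = (B + B.T) / 2
    evals, evecs = np.linalg.eigh(B)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]

    tol = max(1e-12, 1e-12 * abs(evals[0])) if n else 0.0
    positive = np.flatnonzero(evals > tol)
    use = positive[:k]
    coords = np.zeros((n, k))
    used_evals = np.zeros(k)
    coords[:, : len(use)] = evecs[:, use] * np.sqrt(evals[use])
    used_evals[: len(use)] = evals[use]
    degenerate = len(use) < k

    anchor = int(np.argmin(np.array(d.labels, dtype=object)))
    for axis in range(k):
        if coords[anchor, axis] > 0:
            coords[:, axis] = -coords[:, axis]
    coords -= coords.mean(axis=0, keepdims=True)

    diff = coords[:, None, :] - coords[None, :, :]
    emb = np.sqrt((diff**2).sum(axis=-1))
    iu = np.triu_indices(n, k=1)
    stress = float(((emb[iu] - d.values[iu]) ** 2).sum())
    return Embedding(
        labels=list(d.labels),
        coords=coords,
        eigenvalues=used_evals,
        all_eigenvalues=evals,
        stress=stress,
        degenerate=degenerate,
    )


# ---------------------------------------------------------------------------
# agglomerative clustering


def agglomerative(d: DistanceMatrix, linkage: str = "average") -> Tree:
    """Hierarchical agglomerative clustering of a distance matrix.

    ``linkage`` is ``average`` (UPGMA-style Lance-Williams) or ``ward``.
    Ward operates on the supplied distances with merge heights reported in
    distance units (the ward.D2 convention). Returns the full merge tree;
    Newick branch lengths are merge-height differences, leaves at height 0.
    """
    if linkage not in ("average", "ward"):
        raise ValueError("linkage must be 'average' or 'ward'")
    if len(d) < 2:
        raise ValidationError("need at least 2 varieties to cluster")
    Z = hierarchy.linkage(d.condensed(), method=linkage)
    nodes: dict[int, TreeNode] = {
        i: TreeNode(name=label) for i, label in enumerate(d.labels)
    }
    n = len(d)
    for step, (a, b, height, _size) in enumerate(Z):
        left, right = nodes.pop(int(a)), nodes.pop(int(b))
        for child in (left, right):
            child.length = float(height) - child.height
        parent = TreeNode(children=[left, right], height=float(height))
        nodes[n + step] = parent
    (root,) = nodes.values()
    return Tree(root=root, rooted=True, labels=list(d.labels), merges=Z)


def cut_tree(t: Tree, k: int) -> dict[str, int]:
    """Partition the dendrogram leaves into k groups by removing the k-1
    highest merges. Returns a mapping label -> group index (0-based)."""
    if not t.rooted or t.merges is None:
        raise ValidationError("cut_tree requires a rooted dendrogram")
    n = len(t.labels)
    if not 1 <= k <= n:
        raise ValueError(f"k={k} out of range [1, {n}]")
    assignment = hierarchy.cut_tree(t.merges, n_clusters=k).ravel()
    return {label: int(g) for label, g in zip(t.labels, assignment)}


def cophenetic_matrix(t: Tree) -> DistanceMatrix:
    """Cophenetic distances (merge height at which two leaves first join)."""
    if t.merges is None:
        raise ValidationError("cophenetics require a dendrogram")
    from scipy.spatial.distance import squareform

    coph = hierarchy.cophenet(t.merges)
    return DistanceMatrix(list(t.labels), squareform(coph), kind="other")


# ---------------------------------------------------------------------------
# neighbor joining


def neighbor_joining(d: DistanceMatrix) -> Tree:
    """Saitou-Nei neighbor joining with the standard Q-criterion.

    Exact on additive matrices. The unrooted tree is returned with a
    trifurcating root; negative branch lengths (possible on non-additive
    input) are clamped to 0 with the ``clamped`` flag kept on the node.
    Ties in the Q minimization break on the lowest (row, column) index pair
    in the current node ordering, making the result bit-reproducible.
    """
    n = len(d)
    if n < 3:
        raise ValidationError("neighbor joining needs at least 3 taxa")
    D = d.values.astype(float).copy()
    nodes = [TreeNode(name=label) for label in d.labels]

    def settle(node: TreeNode, length: float) -> None:
        if length < 0:
            node.length = 0.0
            node.clamped = True
        else:
            node.length = float(length)

    while len(nodes) > 3:
        m = len(nodes)
        r = D.sum(axis=1)
        Q = (m - 2) * D - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        # lowest (i, j) among the minima, i < j
        qmin = Q.min()
        ii, jj = np.nonzero(np.isclose(Q, qmin, rtol=0, atol=1e-12))
        pairs = sorted((a, b) for a, b in zip(ii, jj) if a < b)
        i, j = pairs[0]
        li = 0.5 * D[i, j] + (r[i] - r[j]) / (2 * (m - 2))
        lj = D[i, j] - li
        settle(nodes[i], li)
        settle(nodes[j], lj)
        parent = TreeNode(children=[nodes[i], nodes[j]])
        du = 0.5 * (D[i, :] + D[j, :] - D[i, j])
        keep = [x for x in range(m) if x not in (i, j)]
        newD = np.zeros((m - 1, m - 1))
        newD[:-1, :-1] = D[np.ix_(keep, keep)]
        newD[-1, :-1] = newD[:-1, -1] = du[keep]
        D = newD
        nodes = [nodes[x] for x in keep] + [parent]

    # resolve the final three nodes around a trifurcating root
    (d01, d02, d12) = (D[0, 1], D[0, 2], D[1, 2])
    lengths = [
        0.5 * (d01 + d02 - d12),
        0.5 * (d01 + d12 - d02),
        0.5 * (d02 + d12 - d01),
    ]
    for node, length in zip(nodes, lengths):
        settle(node, length)
    root = TreeNode(children=list(nodes))
    return Tree(root=root, rooted=False, labels=list(d.labels))


# ---------------------------------------------------------------------------
# Newick serialization and tree metrics

_NEEDS_QUOTE = re.compile(r"[\s,;:()\[\]']")


def _quote(label: str) -> str:
    if _NEEDS_QUOTE.search(label):
        return "'" + label.replace("'", "''") + "'"
    return label


def to_newick(t: Tree) -> str:
    """Standard Newick with branch lengths at full precision."""

    def walk(node: TreeNode, is_root: bool = False) -> str:
        if node.children:
            inner = ",".join(walk(c) for c in node.children)
            body = f"({inner})"
        else:
            body = _quote(node.name or "")
        if is_root:
            return body
        return f"{body}:{node.length:.12g}"

    return walk(t.root, is_root=True) + ";"


def tree_distance_matrix(t: Tree) -> DistanceMatrix:
    """Leaf-to-leaf path lengths (sum of branch lengths along the path)."""
    leaves = t.root.leaves()
    names = [leaf.name for leaf in leaves]
    index = {id(leaf): i for i, leaf in enumerate(leaves)}
    n = len(leaves)
    values = np.zeros((n, n))

    def walk(node: TreeNode) -> dict[int, float]:
        """Map leaf index -> distance from `node`, filling pairs en route."""
        if not node.children:
            return {index[id(node)]: 0.0}
        below: dict[int, float] = {}
        for child in node.children:
            sub = {k: v + child.length for k, v in walk(child).items()}
            for a, da in below.items():
                for b, db in sub.items():
                    values[a, b] = values[b, a] = da + db
            below.update(sub)
        return below

    walk(t.root)
    return DistanceMatrix(names, values, kind="other")
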