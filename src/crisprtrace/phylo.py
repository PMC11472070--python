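"""Rooted phylogenies, array-aware distances, and UPGMA/NJ tree building.

The tree container is a flat, index-based structure (parent pointers and
branch-length arrays) so that reconstruction and likelihood code can run
tight numpy loops over it.  Conversion to and from newick goes through
dendropy.

When no tree is supplied by the user, one can be estimated directly from
the spacer arrays with UPGMA or neighbor joining on an event-count
distance: private leader-end runs are counted as one insertion per spacer
(insertions happen one at a time at the leader), while each private
internal or trailer-end run is counted as a single block-deletion event.
Branch lengths of such trees are in event units, not substitutions per
site, so rate estimates on them are not comparable to substitution-scaled
rates.
"""

from __future__ import annotations

import logging
from typing import Sequence

import dendropy
import numpy as np


class TreeError(ValueError):
    pass


class Phylogeny:
    """Rooted tree with named nodes and non-negative branch lengths.

    Nodes are indexed 0..n_nodes-1 in preorder (root = 0).  ``parent[i]``
    is the index of node i's parent (-1 for the root) and ``length[i]`` is
    the length of the branch above node i (0.0 for the root).
    """

    def __init__(
        self,
        parent: Sequence[int],
        length: Sequence[float],
        names: Sequence[str],
    ) -> None:
        self.parent = np.asarray(parent, dtype=np.int64)
        self.length = np.asarray(length, dtype=np.float64)
        self.names = list(names)
        n = len(self.names)
        if not (len(self.parent) == len(self.length) == n):
            raise TreeError("parent/length/names size mismatch")
        if n == 0 or self.parent[0] != -1 or np.any(self.parent[1:] >= np.arange(1, n)):
            raise TreeError("nodes must be in preorder with root first")
        if np.any(~np.isfinite(self.length)) or np.any(self.length < 0):
            raise TreeError("branch lengths must be finite and >= 0")
        if len(set(self.names)) != n:
            raise TreeError("node names must be unique")
        self.children: list[list[int]] = [[] for _ in range(n)]
        for i in range(1, n):
            self.children[int(self.parent[i])].append(i)
        self._name_to_index = {nm: i for i, nm in enumerate(self.names)}

    # ------------------------------------------------------------------
    @property
    def n_nodes(self) -> int:
        return len(self.names)

    @property
    def root(self) -> int:
        return 0

    def is_leaf(self, i: int) -> bool:
        return not self.children[i]

    @property
    def leaves(self) -> list[int]:
        return [i for i in range(self.n_nodes) if self.is_leaf(i)]

    @property
    def leaf_names(self) -> list[str]:
        return [self.names[i] for i in self.leaves]

    def index_of(self, name: str) -> int:
        return self._name_to_index[name]

    def preorder(self) -> range:
        return range(self.n_nodes)

    def postorder(self) -> list[int]:
        return list(range(self.n_nodes - 1, -1, -1))

    def depths(self) -> np.ndarray:
        """Root-to-node path lengths."""
        d = np.zeros(self.n_nodes)
        for i in range(1, self.n_nodes):
            d[i] = d[self.parent[i]] + self.length[i]
        return d

    def ancestors(self, i: int) -> list[int]:
        """Strict ancestors of node i, child-to-root order."""
        out = []
        j = int(self.parent[i])
        while j != -1:
            out.append(j)
            j = int(self.parent[j])
        return out

    def total_length(self) -> float:
        return float(self.length[1:].sum())

    # ------------------------------------------------------------------
    @classmethod
    def from_dendropy(cls, tree: dendropy.Tree) -> "Phylogeny":
        root = tree.seed_node
        if len(root.child_nodes()) > 2:
            raise TreeError(
                "tree root has more than two children (ambiguous rooting); "
                "root the tree explicitly, e.g. by midpoint rooting"
            )
        parent: list[int] = []
        length: list[float] = []
        names: list[str] = []
        seen: set[str] = set()
        counter = 0

        def name_of(node: dendropy.Node) -> str:
            nonlocal counter
            if node.taxon is not None and node.taxon.label:
                return str(node.taxon.label)
            if node.label:
                return str(node.label)
            nm = f"N{counter}"
            counter += 1
            return nm

        index: dict[int, int] = {}
        for node in tree.preorder_node_iter():
            nm = name_of(node)
            if nm in seen:
                raise TreeError(f"duplicate node name {nm!r} in tree")
            seen.add(nm)
            idx = len(names)
            index[id(node)] = idx
            names.append(nm)
            if node.parent_node is None:
                parent.append(-1)
                length.append(0.0)
            else:
                parent.append(index[id(node.parent_node)])
                if node.edge.length is None:
                    raise TreeError(
                        f"branch above node {nm!r} has no length; "
                        "all branch lengths are required"
                    )
                length.append(float(node.edge.length))
        return cls(parent, length, names)

    def to_dendropy(self) -> dendropy.Tree:
        taxa = dendropy.TaxonNamespace()
        tree = dendropy.Tree(taxon_namespace=taxa)
        nodes: list[dendropy.Node] = [tree.seed_node]
        tree.seed_node.label = self.names[0]
        for i in range(1, self.n_nodes):
            nd = nodes[int(self.parent[i])].new_child()
            nd.edge.length = float(self.length[i])
            nd.label = self.names[i]
            nodes.append(nd)
        for i, nd in enumerate(nodes):
            if not nd.child_nodes():
                nd.taxon = taxa.new_taxon(self.names[i])
                nd.label = None
        return tree

    @classmethod
    def from_newick(cls, text: str) -> "Phylogeny":
        try:
            tree = dendropy.Tree.get(
                data=text, schema="newick", suppress_internal_node_taxa=True
            )
        except Exception as exc:  # dendropy's reader errors are varied
            raise TreeError(f"could not parse newick: {exc}") from exc
        return cls.from_dendropy(tree)

    def to_newick(self) -> str:
        tree = self.to_dendropy()
        out = tree.as_string(
            schema="newick",
            suppress_rooting=True,
            suppress_internal_node_labels=False,
            real_value_format_specifier=".12g",
        ).strip()
        return out + "\n"


# ----------------------------------------------------------------------
# Array distance
# ----------------------------------------------------------------------

def array_distance(a: Sequence[str], b: Sequence[str]) -> float:
    """Event-count distance between two spacer arrays.

    Counts the most parsimonious explanation under ordered insertion and
    block deletion: a maximal run of spacers private to one array that
    touches the leader end is explained by that many single-spacer
    insertions, while every other maximal private run is one block
    deletion on the sister lineage.  Symmetric, zero iff the arrays are
    identical; the triangle inequality is not guaranteed.
    """

    def one_side(x: Sequence[str], other: set[str]) -> int:
        cost = 0
        run = 0
        for pos, lab in enumerate(x):
            if lab not in other:
                run += 1
            else:
                if run:
                    # run ended at `pos`; leader run iff it started at 0
                    cost += run if run == pos else 1
                run = 0
        if run:
            cost += run if run == len(x) else 1
        return cost

    ta, tb = tuple(a), tuple(b)
    if ta == tb:
        return 0.0
    sa, sb = set(ta), set(tb)
    if not (sa & sb):
        logging.getLogger(__name__).warning(
            "arrays share no spacers; distance is low-confidence"
        )
    d = float(one_side(ta, sb) + one_side(tb, sa))
    # identical sets but different order still differ by >= 1 event
    return max(d, 1.0)


def distance_matrix(arrays: Sequence[Sequence[str]]) -> np.ndarray:
    n = len(arrays)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = array_distance(arrays[i], arrays[j])
    return d


# ----------------------------------------------------------------------
# UPGMA and neighbor joining
# ----------------------------------------------------------------------

def _check_matrix(dist: np.ndarray, labels: Sequence[str]) -> np.ndarray:
    dist = np.asarray(dist, dtype=float)
    n = dist.shape[0]
    if n < 2:
        raise TreeError("need at least two taxa to build a tree")
    if dist.shape != (n, n) or len(labels) != n:
        raise TreeError("distance matrix / label size mismatch")
    if not np.allclose(dist, dist.T) or np.any(np.diag(dist) != 0):
        raise TreeError("distance matrix must be symmetric with zero diagonal")
    return dist


def _assemble(edges: dict[str, tuple[str | None, float]], root_name: str) -> Phylogeny:
    """Build a Phylogeny from child->(parent, length) links."""
    kids: dict[str, list[str]] = {}
    for c, (p, _) in edges.items():
        if p is not None:
            kids.setdefault(p, []).append(c)
    parent: list[int] = []
    length: list[float] = []
    names: list[str] = []
    idx: dict[str, int] = {}

    def visit(name: str, parent_idx: int) -> None:
        idx[name] = len(names)
        names.append(name)
        parent.append(parent_idx)
        length.append(edges[name][1])
        for c in sorted(kids.get(name, [])):
            visit(c, idx[name])

    visit(root_name, -1)
    return Phylogeny(parent, length, names)


def upgma_tree(dist: np.ndarray, labels: Sequence[str]) -> Phylogeny:
    """UPGMA clustering; output is ultrametric.

    Ties are broken by merging the lexicographically smallest cluster
    pair, making the result deterministic.
    """
    dist = _check_matrix(dist, labels)
    active: dict[str, tuple[float, int]] = {lab: (0.0, 1) for lab in labels}
    d = {
        frozenset((a, b)): dist[i, j]
        for i, a in enumerate(labels)
        for j, b in enumerate(labels)
        if i < j
    }
    edges: dict[str, tuple[str | None, float]] = {lab: (None, 0.0) for lab in labels}
    k = 0
    while len(active) > 1:
        pair = min(
            d.items(), key=lambda kv: (kv[1], tuple(sorted(kv[0])))
        )[0]
        a, b = sorted(pair)
        height = d[pair] / 2.0
        new = f"U{k}"
        k += 1
        ha, na = active.pop(a)
        hb, nb = active.pop(b)
        edges[a] = (new, height - ha)
        edges[b] = (new, height - hb)
        edges[new] = (None, 0.0)
        newd = {}
        for c in active:
            newd[frozenset((new, c))] = (
                na * d[frozenset((a, c))] + nb * d[frozenset((b, c))]
            ) / (na + nb)
        d = {key: v for key, v in d.items() if a not in key and b not in key}
        d.update(newd)
        active[new] = (height, na + nb)
    return _assemble(edges, next(iter(active)))


def nj_tree(dist: np.ndarray, labels: Sequence[str]) -> Phylogeny:
    """Neighbor joining (Saitou & Nei) with deterministic tie-breaking.

    Negative branch-length estimates are clamped to zero.  The unrooted
    NJ result is returned rooted at the final join.
    """
    dist = _check_matrix(dist, labels)
    n = dist.shape[0]
    if n == 2:
        root = "NJ0"
        h = dist[0, 1] / 2.0
        edges = {
            labels[0]: (root, h),
            labels[1]: (root, h),
            root: (None, 0.0),
        }
        return _assemble(edges, root)
    names = list(labels)
    d = {frozenset((a, b)): dist[i, j] for i, a in enumerate(names)
         for j, b in enumerate(names) if i < j}
    edges: dict[str, tuple[str | None, float]] = {lab: (None, 0.0) for lab in names}
    active = list(names)
    k = 0
    while len(active) > 2:
        m = len(active)
        r = {a: sum(d[frozenset((a, c))] for c in active if c != a) for a in active}
        best = None
        for i, a in enumerate(active):
            for b in active[i + 1:]:
                q = (m - 2) * d[frozenset((a, b))] - r[a] - r[b]
                key = (q, tuple(sorted((a, b))))
                if best is None or key < best[0]:
                    best = (key, a, b)
        _, a, b = best
        dab = d[frozenset((a, b))]
        la = 0.5 * dab + (r[a] - r[b]) / (2 * (m - 2))
        lb = dab - la
        la, lb = max(la, 0.0), max(lb, 0.0)
        new = f"NJ{k}"
        k += 1
        edges[a] = (new, la)
        edges[b] = (new, lb)
        edges[new] = (None, 0.0)
        for c in active:
            if c in (a, b):
                continue
            d[frozenset((new, c))] = max(
                0.5 * (d[frozenset((a, c))] + d[frozenset((b, c))] - dab), 0.0
            )
        active = [c for c in active if c not in (a, b)] + [new]
    a, b = sorted(active[:2])
    root = f"NJ{k}"
    h = max(d[frozenset((a, b))], 0.0) / 2.0
    edges[a] = (root, h)
    edges[b] = (root, max(d[frozenset((a, b))] - h, 0.0))
    edges[root] = (None, 0.0)
    return _assemble(edges, root)
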