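"""Rooted phylogenies with branch lengths.

The :class:`Phylogeny` container stores the topology as flat parent/length
arrays (tips first), which keeps every downstream Brownian-motion computation
(tree covariance, ancestral states, simulation) a plain numpy exercise.
Newick parsing and writing go through :mod:`dendropy`.
"""

from __future__ import annotations

from typing import Sequence

import dendropy
import numpy as np

__all__ = ["Phylogeny"]


class Phylogeny:
    """A rooted tree with branch lengths and uniquely labelled tips.

    Nodes are integer indices: tips are ``0 .. n_tips-1`` (in the order the
    Newick string lists them), internal nodes follow, and the root is always
    present.  Branch lengths are the length of the edge *above* each node
    (0 for the root).
    """

    def __init__(self, parent: Sequence[int], length: Sequence[float],
                 labels: Sequence[str | None]):
        self.parent = np.asarray(parent, dtype=int)
        self.length = np.asarray(length, dtype=float)
        self.labels = list(labels)
        m = self.parent.size
        if self.length.size != m or len(self.labels) != m:
            raise ValueError("parent, length and labels must have equal size")
        roots = np.flatnonzero(self.parent < 0)
        if roots.size != 1:
            raise ValueError(f"tree must have exactly one root, found {roots.size}")
        self.root = int(roots[0])
        if np.any(self.length[np.arange(m) != self.root] < 0):
            bad = np.flatnonzero(self.length < 0)
            raise ValueError(f"negative branch length on node(s) {bad.tolist()}")
        self.length[self.root] = 0.0
        # children lists and tip bookkeeping
        self._children: list[list[int]] = [[] for _ in range(m)]
        for i in range(m):
            if i != self.root:
                self._children[self.parent[i]].append(i)
        self._tips = [i for i in range(m) if not self._children[i]]
        tip_labels = [self.labels[i] for i in self._tips]
        if any(lab is None or lab == "" for lab in tip_labels):
            raise ValueError("every tip must be labelled")
        if len(set(tip_labels)) != len(tip_labels):
            dupes = sorted({x for x in tip_labels if tip_labels.count(x) > 1})
            raise ValueError(f"duplicate tip label(s): {dupes}")

    # ------------------------------------------------------------------ I/O
    @classmethod
    def from_newick(cls, newick: str) -> "Phylogeny":
        try:
            tree = dendropy.Tree.get(data=newick, schema="newick",
                                     preserve_underscores=True)
        except dendropy.dataio.newickreader.NewickReader.NewickReaderDuplicateTaxonError as e:
            raise ValueError(f"duplicate tip label in Newick: {e}") from e
        nodes = list(tree.preorder_node_iter())
        leaves = [nd for nd in nodes if nd.is_leaf()]
        internals = [nd for nd in nodes if not nd.is_leaf()]
        index = {}
        for i, nd in enumerate(leaves):
            index[nd] = i
        for j, nd in enumerate(internals):
            index[nd] = len(leaves) + j
        m = len(nodes)
        parent = np.full(m, -1, dtype=int)
        length = np.zeros(m)
        labels: list[str | None] = [None] * m
        for nd in nodes:
            i = index[nd]
            if nd.parent_node is not None:
                parent[i] = index[nd.parent_node]
                el = nd.edge.length
                if el is None:
                    raise ValueError("branch lengths are required on every edge")
                length[i] = float(el)
            if nd.is_leaf():
                labels[i] = nd.taxon.label if nd.taxon is not None else None
            elif nd.taxon is not None:
                labels[i] = nd.taxon.label
        return cls(parent, length, labels)

    @classmethod
    def read(cls, path) -> "Phylogeny":
        with open(path) as fh:
            return cls.from_newick(fh.read())

    def to_newick(self) -> str:
        def rec(i: int) -> str:
            if not self._children[i]:
                return f"{self.labels[i]}:{self.length[i]:.12g}"
            inner = ",".join(rec(c) for c in self._children[i])
            if i == self.root:
                return f"({inner})"
            return f"({inner}):{self.length[i]:.12g}"
        return rec(self.root) + ";"

    def write(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_newick() + "\n")

    # ------------------------------------------------------------ structure
    @property
    def n_nodes(self) -> int:
        return self.parent.size

    @property
    def n_tips(self) -> int:
        return len(self._tips)

    @property
    def tip_indices(self) -> list[int]:
        return list(self._tips)

    @property
    def tip_labels(self) -> list[str]:
        return [self.labels[i] for i in self._tips]

    def children(self, i: int) -> list[int]:
        return list(self._children[i])

    def is_tip(self, i: int) -> bool:
        return not self._children[i]

    def preorder(self) -> list[int]:
        order: list[int] = []
        stack = [self.root]
        while stack:
            i = stack.pop()
            order.append(i)
            stack.extend(reversed(self._children[i]))
        return order

    def postorder(self) -> list[int]:
        order: list[int] = []
        stack = [self.root]
        while stack:
            i = stack.pop()
            order.append(i)
            stack.extend(self._children[i])
        order.reverse()
        return order

    def edges(self) -> list[tuple[int, int, float]]:
        """(parent, child, length) for every edge."""
        return [(int(self.parent[i]), i, float(self.length[i]))
                for i in range(self.n_nodes) if i != self.root]

    def depths(self) -> np.ndarray:
        """Root-to-node path length for every node."""
        d = np.zeros(self.n_nodes)
        stack = [self.root]
        while stack:
            i = stack.pop()
            for c in self._children[i]:
                d[c] = d[i] + self.length[c]
                stack.append(c)
        return d

    def max_depth(self) -> float:
        return float(self.depths()[self._tips].max())

    def is_ultrametric(self, rtol: float = 1e-6) -> bool:
        td = self.depths()[self._tips]
        span = td.max()
        if span <= 0:
            return False
        return bool((td.max() - td.min()) <= rtol * span)

    def ancestor_path(self, i: int) -> list[int]:
        """Nodes from the root down to ``i`` (inclusive)."""
        path = [i]
        while self.parent[path[-1]] >= 0:
            path.append(int(self.parent[path[-1]]))
        path.reverse()
        return path

    def mrca(self, i: int, j: int) -> int:
        pi, pj = self.ancestor_path(i), self.ancestor_path(j)
        anc = self.root
        for a, b in zip(pi, pj):
            if a == b:
                anc = a
            else:
                break
        return anc

    def mrca_of(self, labels: Sequence[str]) -> int:
        idx = [self.index_of(lab) for lab in labels]
        node = idx[0]
        for j in idx[1:]:
            node = self.mrca(node, j)
        return node

    def index_of(self, label: str) -> int:
        for i in self._tips:
            if self.labels[i] == label:
                return i
        raise KeyError(f"tip {label!r} not in tree")

    def descendant_tips(self, i: int) -> list[int]:
        out, stack = [], [i]
        while stack:
            j = stack.pop()
            if not self._children[j]:
                out.append(j)
            else:
                stack.extend(self._children[j])
        return sorted(out)

    # --------------------------------------------------------- derivations
    def vcv(self) -> np.ndarray:
        """Brownian-motion tip covariance: C[i,j] = depth of MRCA(i,j).

        Rows/columns follow ``tip_labels`` order.
        """
        d = self.depths()
        if self.max_depth() <= 0:
            raise ValueError("tree has zero depth")
        n = self.n_tips
        C = np.zeros((n, n))
        paths = [self.ancestor_path(t) for t in self._tips]
        for a in range(n):
            C[a, a] = d[self._tips[a]]
            for b in range(a + 1, n):
                anc = self.root
                for x, y in zip(paths[a], paths[b]):
                    if x == y:
                        anc = x
                    else:
                        break
                C[a, b] = C[b, a] = d[anc]
        return C

    def node_vcv(self) -> np.ndarray:
        """MRCA-depth matrix over *all* nodes (tips and internals)."""
        d = self.depths()
        m = self.n_nodes
        paths = [self.ancestor_path(i) for i in range(m)]
        C = np.zeros((m, m))
        for a in range(m):
            C[a, a] = d[a]
            for b in range(a + 1, m):
                anc = self.root
                for x, y in zip(paths[a], paths[b]):
                    if x == y:
                        anc = x
                    else:
                        break
                C[a, b] = C[b, a] = d[anc]
        return C

    def prune(self, keep: Sequence[str]) -> "Phylogeny":
        """Return a new tree restricted to the tips in ``keep``.

        Internal nodes left with a single child are suppressed and their
        branch lengths merged.
        """
        keep_set = set(keep)
        missing = keep_set - set(self.tip_labels)
        if missing:
            raise KeyError(f"tips not in tree: {sorted(missing)}")
        if len(keep_set) < 2:
            raise ValueError("cannot prune to fewer than 2 tips")

        # mark nodes that survive (on a path root -> kept tip)
        alive = np.zeros(self.n_nodes, dtype=bool)
        for t in self._tips:
            if self.labels[t] in keep_set:
                for a in self.ancestor_path(t):
                    alive[a] = True

        # rebuild child lists over surviving nodes, then collapse unaries
        new_children = {i: [c for c in self._children[i] if alive[c]]
                        for i in range(self.n_nodes) if alive[i]}
        length = {i: float(self.length[i]) for i in new_children}

        def collapse(i: int) -> tuple[int, float]:
            """Follow unary chains; return (surviving node, accumulated length)."""
            acc = length[i]
            while len(new_children[i]) == 1 and self._children[i]:
                i = new_children[i][0]
                acc += length[i]
            return i, acc

        # find new root: descend while root has a single child
        root = self.root
        while len(new_children[root]) == 1:
            root = new_children[root][0]

        parent_map: dict[int, tuple[int, float]] = {}
        stack = [root]
        order = [root]
        while stack:
            i = stack.pop()
            for c in new_children[i]:
                cc, acc = collapse(c)
                parent_map[cc] = (i, acc)
                stack.append(cc)
                order.append(cc)

        remap = {old: new for new, old in enumerate(order)}
        m = len(order)
        parent = np.full(m, -1, dtype=int)
        lengths = np.zeros(m)
        labels: list[str | None] = [None] * m
        for old, new in remap.items():
            labels[new] = self.labels[old]
            if old in parent_map:
                p, acc = parent_map[old]
                parent[new] = remap[p]
                lengths[new] = acc
        return Phylogeny(parent, lengths, labels)

    # -------------------------------------------------------------- dunder
    def __repr__(self) -> str:
        return f"Phylogeny(n_tips={self.n_tips}, n_nodes={self.n_nodes})"

    def __eq__(self, other) -> bool:
        if not isinstance(other, Phylogeny):
            return NotImplemented
        return self.to_newick() == other.to_newick()
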