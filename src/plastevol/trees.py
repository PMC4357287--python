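"""Phylogeny ingestion and manipulation.

Trees enter the pipeline from outside (Newick or NEXUS, single tree or a
posterior sample) with branch lengths in expected substitutions per site
("operational time").  This module provides a light array-based tree
representation shared by the likelihood, simulation and mapping code:
nodes are integers, tips come first, and every non-root node owns the edge
to its parent.  That layout makes post-order peeling, branch painting and
history bookkeeping cheap and deterministic.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field

import dendropy
import numpy as np


class TreeParseError(ValueError):
    """Raised when tree text cannot be parsed or fails validation."""


@dataclass
class Phylogeny:
    """A rooted tree with branch lengths, stored as parent-pointer arrays.

    Nodes are numbered ``0 .. n_nodes-1`` with tips first (``0 .. n_tips-1``,
    matching ``tip_labels``) and the root last.  ``edge_length[i]`` is the
    length of the edge above node ``i`` (0 for the root).  Edges are
    identified by their child node index throughout the package.
    """

    parent: np.ndarray          # (n_nodes,) int, -1 at the root
    edge_length: np.ndarray     # (n_nodes,) float, 0.0 at the root
    children: list[list[int]]
    tip_labels: list[str]

    def __post_init__(self) -> None:
        self.parent = np.asarray(self.parent, dtype=int)
        self.edge_length = np.asarray(self.edge_length, dtype=float)
        if np.any(self.edge_length < 0):
            raise TreeParseError("negative branch length")
        if len(set(self.tip_labels)) != len(self.tip_labels):
            dup = sorted({t for t in self.tip_labels if self.tip_labels.count(t) > 1})
            raise TreeParseError(f"duplicate tip labels: {dup}")
        roots = np.flatnonzero(self.parent < 0)
        if len(roots) != 1:
            raise TreeParseError("tree must have exactly one root")
        self._root = int(roots[0])
        self._postorder = self._compute_postorder()

    # -- basic structure -------------------------------------------------

    @property
    def n_tips(self) -> int:
        return len(self.tip_labels)

    @property
    def n_nodes(self) -> int:
        return len(self.parent)

    @property
    def root(self) -> int:
        return self._root

    @property
    def postorder(self) -> np.ndarray:
        """Node indices in post-order (children before parents, root last)."""
        return self._postorder

    def _compute_postorder(self) -> np.ndarray:
        order: list[int] = []
        stack = [self._root]
        while stack:
            node = stack.pop()
            order.append(node)
            stack.extend(self.children[node])
        return np.asarray(order[::-1], dtype=int)

    def tip_index(self, label: str) -> int:
        try:
            return self.tip_labels.index(label)
        except ValueError:
            raise KeyError(f"tip label not in tree: {label!r}") from None

    # -- derived quantities ----------------------------------------------

    def total_length(self) -> float:
        return float(self.edge_length.sum())

    def node_depths(self) -> np.ndarray:
        """Distance from the root to every node."""
        depth = np.zeros(self.n_nodes)
        for node in self._postorder[::-1]:
            if self.parent[node] >= 0:
                depth[node] = depth[self.parent[node]] + self.edge_length[node]
        return depth

    def rescaled(self, target: float) -> "Phylogeny":
        """Return a copy whose branch lengths sum to ``target``.

        All branch-length proportions are preserved.  Used before applying
        priors on the overall character-change rate, so that the rate is
        expressed per total tree length.
        """
        if target <= 0:
            raise ValueError("target total length must be positive")
        total = self.total_length()
        if total <= 0:
            raise ValueError("cannot rescale a zero-length tree")
        return Phylogeny(
            parent=self.parent.copy(),
            edge_length=self.edge_length * (target / total),
            children=[list(c) for c in self.children],
            tip_labels=list(self.tip_labels),
        )

    def mrca_matrix(self) -> np.ndarray:
        """(n_tips, n_tips) array of MRCA node indices (diagonal = tip itself)."""
        M = np.zeros((self.n_tips, self.n_tips), dtype=int)
        np.fill_diagonal(M, np.arange(self.n_tips))
        tipsets: dict[int, list[int]] = {}
        for node in self._postorder:
            if not self.children[node]:
                tipsets[node] = [node]
            else:
                kids = self.children[node]
                for a_i in range(len(kids)):
                    for b_i in range(a_i + 1, len(kids)):
                        for i in tipsets[kids[a_i]]:
                            for j in tipsets[kids[b_i]]:
                                M[i, j] = M[j, i] = node
                merged: list[int] = []
                for k in kids:
                    merged.extend(tipsets.pop(k))
                tipsets[node] = merged
        return M

    def vcv(self) -> np.ndarray:
        """Brownian-motion covariance structure C.

        ``C[i, j]`` is the root-to-MRCA path length shared by tips i and j
        (tip order = ``tip_labels``); the diagonal holds root-to-tip
        distances.  Under single-rate BM with rate sigma^2 the tip values
        are jointly normal with covariance ``sigma^2 * C``.
        """
        depth = self.node_depths()
        return depth[self.mrca_matrix()]

    # -- serialization ---------------------------------------------------

    @staticmethod
    def _quote(label: str) -> str:
        if any(ch in label for ch in " ()[]{}:;,'\""):
            return "'" + label.replace("'", "''") + "'"
        return label

    def to_newick(self) -> str:
        def render(node: int) -> str:
            if not self.children[node]:
                s = self._quote(self.tip_labels[node])
            else:
                s = "(" + ",".join(render(c) for c in self.children[node]) + ")"
            if self.parent[node] >= 0:
                s += f":{self.edge_length[node]:.17g}"
            return s

        return render(self._root) + ";"

    @classmethod
    def from_dendropy(cls, tree: dendropy.Tree) -> "Phylogeny":
        nodes = list(tree.postorder_node_iter())
        tips = [nd for nd in nodes if nd.is_leaf()]
        internals = [nd for nd in nodes if not nd.is_leaf()]
        index: dict[int, int] = {}
        labels: list[str] = []
        for i, nd in enumerate(tips):
            index[id(nd)] = i
            label = nd.taxon.label if nd.taxon is not None else (nd.label or f"tip{i}")
            labels.append(label)
        for j, nd in enumerate(internals):
            index[id(nd)] = len(tips) + j
        n = len(nodes)
        parent = np.full(n, -1, dtype=int)
        lengths = np.zeros(n)
        children: list[list[int]] = [[] for _ in range(n)]
        missing = 0
        for nd in nodes:
            i = index[id(nd)]
            if nd.parent_node is not None:
                parent[i] = index[id(nd.parent_node)]
                children[parent[i]].append(i)
                if nd.edge.length is None:
                    missing += 1
                else:
                    lengths[i] = nd.edge.length
        if missing:
            warnings.warn(
                f"{missing} branch lengths absent; defaulting to 0", stacklevel=2
            )
        return cls(parent=parent, edge_length=lengths, children=children,
                   tip_labels=labels)

    @classmethod
    def from_newick(cls, text: str) -> "Phylogeny":
        return parse_trees(text)[0]


@dataclass
class TreeSet:
    """An ordered collection of trees over one tip-label universe.

    Typically a sample from a Bayesian posterior; optional per-tree weights.
    """

    trees: list[Phylogeny]
    weights: np.ndarray | None = None

    def __post_init__(self) -> None:
        if not self.trees:
            raise ValueError("TreeSet must contain at least one tree")
        ref = set(self.trees[0].tip_labels)
        for k, t in enumerate(self.trees[1:], start=2):
            if set(t.tip_labels) != ref:
                raise TreeParseError(
                    f"tree {k} has a different tip-label set from tree 1"
                )

    def __len__(self) -> int:
        return len(self.trees)

    def __getitem__(self, i: int) -> Phylogeny:
        return self.trees[i]

    def __iter__(self):
        return iter(self.trees)


def parse_trees(text: str) -> TreeSet:
    """Parse Newick or NEXUS tree text into a :class:`TreeSet`.

    Square-bracket comments are stripped, quoted labels are supported, and
    a missing branch length defaults to 0 with a warning.
    """
    stripped = text.lstrip()
    schema = "nexus" if stripped.upper().startswith("#NEXUS") else "newick"
    try:
        tl = dendropy.TreeList.get(
            data=text, schema=schema, suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:  # dendropy raises assorted error types
        raise TreeParseError(f"could not parse {schema} tree text: {exc}") from exc
    if not tl:
        raise TreeParseError("no trees found in input")
    return TreeSet(trees=[Phylogeny.from_dendropy(t) for t in tl])


def read_trees(path) -> TreeSet:
    with open(path) as fh:
        return parse_trees(fh.read())


def rescale_total_length(tree: Phylogeny, target: float) -> Phylogeny:
    """Rescale all branch lengths so the tree's total length equals ``target``."""
    return tree.rescaled(target)


def vcv_matrix(tree: Phylogeny) -> np.ndarray:
    """Species-by-species shared path-length matrix (see :meth:`Phylogeny.vcv`)."""
    return tree.vcv()


def sample_trees(ts: TreeSet, n: int, seed: int) -> TreeSet:
    """Draw ``n`` trees uniformly with replacement (reproducible via ``seed``)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, len(ts), size=n)
    return TreeSet(trees=[ts.trees[i] for i in idx])
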