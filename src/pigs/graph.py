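"""Core data types for probabilistic identity-by-descent (IBD) graphs.

At a genomic locus, IBD between haplotypes behaves like an equivalence
relation: if haplotypes *a* and *b* inherited the locus from a common
ancestor, and *b* and *c* did as well, then *a* and *c* share an ancestor
too.  A biologically valid IBD graph at a locus is therefore a disjoint
union of cliques — equivalently, a set partition of the haplotypes.

This module provides the in-memory objects the rest of the package builds
on:

* :class:`HaplotypeId` — a node label: sample identifier plus haplotype
  index (1 or 2 for a diploid).
* :class:`ProbabilisticIBDGraph` — a complete weighted graph ``G_P`` whose
  edge weights are marginal IBD probabilities ``p_ij``; pairs never called
  by an upstream pairwise method carry a small prior ``epsilon`` rather
  than zero, so every proposed configuration keeps positive probability.
* :class:`IBDConfiguration` — one concrete binary edge assignment ``g``,
  with the transitivity predicate and the clique closure that repairs an
  intransitive assignment.
* :func:`graph_probability` — ``P(g | G_P)``, the product of induced edge
  probabilities, evaluated in log space.
"""

from __future__ import annotations

import math
from typing import Hashable, Iterable, Iterator, Mapping, NamedTuple, Sequence

import numpy as np

__all__ = [
    "DEFAULT_EPSILON",
    "HaplotypeId",
    "ProbabilisticIBDGraph",
    "IBDConfiguration",
    "edge_key",
    "graph_probability",
    "log_graph_probability",
    "is_transitive",
    "connected_components",
    "clique_close",
]

#: Genome-average probability that a random haplotype pair is IBD at a
#: random locus; also the probability assigned to uncalled edges.
DEFAULT_EPSILON = 0.0046

Node = Hashable


class HaplotypeId(NamedTuple):
    """One phased chromosome copy of a diploid sample.

    Equality and (lexicographic) ordering come from the tuple fields
    ``(sample, hap_index)``, which makes ``HaplotypeId`` usable directly as
    a canonical edge-key component.
    """

    sample: str
    hap_index: int = 1

    def __str__(self) -> str:
        return f"{self.sample}.{self.hap_index}"

    @classmethod
    def parse(cls, text: str) -> "HaplotypeId":
        """Parse ``sample.index`` notation; a bare name gets index 1."""
        sample, _, idx = text.rpartition(".")
        if sample and idx.isdigit():
            return cls(sample, int(idx))
        return cls(text, 1)


def _lt(a: Node, b: Node) -> bool:
    try:
        return a < b  # type: ignore[operator]
    except TypeError:
        return str(a) < str(b)


def _sorted_nodes(nodes: Iterable[Node]) -> list:
    try:
        return sorted(nodes)  # type: ignore[type-var]
    except TypeError:
        return sorted(nodes, key=str)


def edge_key(a: Node, b: Node) -> tuple:
    """Canonical unordered pair: the ordered ``(min, max)`` tuple.

    Every edge-indexed mapping in the package stores one entry per
    unordered pair under this key, which rules out silent asymmetry bugs.
    """
    if a == b:
        raise ValueError(f"self-edges are undefined (node {a!r})")
    return (a, b) if _lt(a, b) else (b, a)


class ProbabilisticIBDGraph:
    """Complete graph with marginal IBD probabilities on every pair.

    Parameters
    ----------
    nodes
        Node labels (typically :class:`HaplotypeId`); order is preserved
        and defines the internal index.
    edge_probabilities
        Mapping ``(a, b) -> p`` for called pairs, in any key order.  Pairs
        absent from the mapping receive ``epsilon``.
    matrix
        Alternative constructor input: a full symmetric ``(n, n)`` array of
        probabilities (diagonal ignored).
    region
        Optional ``(chromosome, start_bp, end_bp)`` provenance tag.
    epsilon
        Probability assigned to uncalled pairs; must lie in ``(0, 1)``.
    """

    def __init__(
        self,
        nodes: Iterable[Node],
        edge_probabilities: Mapping[tuple, float] | None = None,
        *,
        matrix: np.ndarray | None = None,
        region: tuple | None = None,
        epsilon: float = DEFAULT_EPSILON,
    ) -> None:
        nodes = tuple(nodes)
        if len(set(nodes)) != len(nodes):
            raise ValueError("duplicate node labels")
        self._nodes = nodes
        self._index = {v: k for k, v in enumerate(nodes)}
        self.region = region
        self.epsilon = float(epsilon)
        if not 0.0 < self.epsilon < 1.0:
            raise ValueError("epsilon must lie strictly inside (0, 1)")
        n = len(nodes)
        if matrix is not None:
            if edge_probabilities is not None:
                raise ValueError("pass either edge_probabilities or matrix, not both")
            M = np.asarray(matrix, dtype=float).copy()
            if M.shape != (n, n):
                raise ValueError(f"matrix shape {M.shape} does not match {n} nodes")
            if not np.allclose(M, M.T, atol=1e-12):
                raise ValueError("probability matrix must be symmetric")
            M = (M + M.T) / 2.0
        else:
            M = np.full((n, n), self.epsilon, dtype=float)
            for (a, b), p in (edge_probabilities or {}).items():
                try:
                    i, j = self._index[a], self._index[b]
                except KeyError as exc:
                    raise ValueError(f"unknown node {exc.args[0]!r} in edge ({a!r}, {b!r})") from None
                if i == j:
                    raise ValueError(f"self-edge on node {a!r}")
                M[i, j] = M[j, i] = float(p)
        np.fill_diagonal(M, 0.0)
        off = ~np.eye(n, dtype=bool)
        if n and (np.any(M[off] < 0.0) or np.any(M[off] > 1.0)):
            raise ValueError("edge probabilities must lie in [0, 1]")
        M.flags.writeable = False
        self._matrix = M

    # -- basic accessors -------------------------------------------------

    @property
    def nodes(self) -> tuple:
        return self._nodes

    @property
    def n_nodes(self) -> int:
        return len(self._nodes)

    @property
    def matrix(self) -> np.ndarray:
        """Read-only symmetric ``(n, n)`` probability matrix."""
        return self._matrix

    def index(self, node: Node) -> int:
        return self._index[node]

    def probability(self, a: Node, b: Node) -> float:
        i, j = self._index[a], self._index[b]
        if i == j:
            raise ValueError("p_ii is undefined (no self-edges)")
        return float(self._matrix[i, j])

    def pairs(self) -> Iterator[tuple]:
        """Canonical keys of all unordered node pairs."""
        n = self.n_nodes
        for i in range(n):
            for j in range(i + 1, n):
                yield edge_key(self._nodes[i], self._nodes[j])

    def edge_items(self) -> Iterator[tuple[tuple, float]]:
        n = self.n_nodes
        for i in range(n):
            for j in range(i + 1, n):
                yield edge_key(self._nodes[i], self._nodes[j]), float(self._matrix[i, j])

    def subgraph(self, nodes: Sequence[Node]) -> "ProbabilisticIBDGraph":
        idx = [self._index[v] for v in nodes]
        return ProbabilisticIBDGraph(
            nodes,
            matrix=self._matrix[np.ix_(idx, idx)],
            region=self.region,
            epsilon=self.epsilon,
        )

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"<ProbabilisticIBDGraph n={self.n_nodes} region={self.region}>"


class IBDConfiguration:
    """One proposed IBD scenario: a symmetric binary edge assignment.

    A configuration is *transitive* iff every connected component of its
    present edges is a complete clique; only transitive configurations can
    represent true IBD at a locus.
    """

    def __init__(
        self,
        nodes: Iterable[Node],
        edges: Iterable[tuple] = (),
        *,
        adjacency: np.ndarray | None = None,
    ) -> None:
        nodes = tuple(nodes)
        if len(set(nodes)) != len(nodes):
            raise ValueError("duplicate node labels")
        self._nodes = nodes
        self._index = {v: k for k, v in enumerate(nodes)}
        n = len(nodes)
        if adjacency is not None:
            A = np.asarray(adjacency, dtype=bool).copy()
            if A.shape != (n, n):
                raise ValueError("adjacency shape mismatch")
            if not np.array_equal(A, A.T):
                raise ValueError("adjacency must be symmetric")
        else:
            A = np.zeros((n, n), dtype=bool)
            for a, b in edges:
                try:
                    i, j = self._index[a], self._index[b]
                except KeyError as exc:
                    raise ValueError(f"unknown node {exc.args[0]!r} in edge ({a!r}, {b!r})") from None
                if i == j:
                    raise ValueError(f"self-edge on node {a!r}")
                A[i, j] = A[j, i] = True
        np.fill_diagonal(A, False)
        A.flags.writeable = False
        self._adj = A

    # -- constructors ----------------------------------------------------

    @classmethod
    def from_partition(cls, nodes: Iterable[Node], blocks: Iterable[Iterable[Node]]) -> "IBDConfiguration":
        """Build the (transitive) configuration whose cliques are *blocks*."""
        nodes = tuple(nodes)
        index = {v: k for k, v in enumerate(nodes)}
        labels = np.full(len(nodes), -1, dtype=np.int64)
        for lab, block in enumerate(blocks):
            for v in block:
                if labels[index[v]] != -1:
                    raise ValueError(f"node {v!r} appears in more than one block")
                labels[index[v]] = lab
        if np.any(labels < 0):
            raise ValueError("blocks do not cover all nodes")
        return cls.from_labels(nodes, labels)

    @classmethod
    def from_labels(cls, nodes: Iterable[Node], labels: np.ndarray) -> "IBDConfiguration":
        labels = np.asarray(labels)
        adj = labels[:, None] == labels[None, :]
        np.fill_diagonal(adj, False)
        return cls(nodes, adjacency=adj)

    # -- accessors -------------------------------------------------------

    @property
    def nodes(self) -> tuple:
        return self._nodes

    @property
    def n_nodes(self) -> int:
        return len(self._nodes)

    @property
    def adjacency(self) -> np.ndarray:
        return self._adj

    def index(self, node: Node) -> int:
        return self._index[node]

    def has_edge(self, a: Node, b: Node) -> bool:
        return bool(self._adj[self._index[a], self._index[b]])

    def edges(self) -> frozenset:
        """Present edges as canonical unordered pairs."""
        ii, jj = np.nonzero(np.triu(self._adj, 1))
        return frozenset(edge_key(self._nodes[i], self._nodes[j]) for i, j in zip(ii, jj))

    @property
    def n_edges(self) -> int:
        return int(np.count_nonzero(np.triu(self._adj, 1)))

    # -- structure -------------------------------------------------------

    def _component_labels(self) -> np.ndarray:
        n = self.n_nodes
        labels = np.full(n, -1, dtype=np.int64)
        nxt = 0
        for start in range(n):
            if labels[start] != -1:
                continue
            stack = [start]
            labels[start] = nxt
            while stack:
                u = stack.pop()
                for v in np.flatnonzero(self._adj[u]):
                    if labels[v] == -1:
                        labels[v] = nxt
                        stack.append(int(v))
            nxt += 1
        return labels

    def connected_components(self) -> list[tuple]:
        """Maximal connected node sets, deterministically ordered.

        Members are sorted within each component and components are sorted
        by their smallest member.
        """
        labels = self._component_labels()
        comps: dict[int, list] = {}
        for v, lab in zip(self._nodes, labels):
            comps.setdefault(int(lab), []).append(v)
        out = [tuple(_sorted_nodes(c)) for c in comps.values()]
        try:
            out.sort(key=lambda c: c[0])
        except TypeError:
            out.sort(key=lambda c: str(c[0]))
        return out

    def is_transitive(self) -> bool:
        """True iff every connected component is a complete clique."""
        labels = self._component_labels()
        same = labels[:, None] == labels[None, :]
        np.fill_diagonal(same, False)
        return bool(np.array_equal(same, self._adj))

    def clique_close(self) -> "IBDConfiguration":
        """Minimal transitive configuration containing this one's edges.

        Within each connected component every pairwise edge is set; the
        operation is idempotent and never adds cross-component edges.
        """
        return IBDConfiguration.from_labels(self._nodes, self._component_labels())

    # -- dunder ----------------------------------------------------------

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, IBDConfiguration):
            return NotImplemented
        return self._nodes == other._nodes and np.array_equal(self._adj, other._adj)

    def __hash__(self) -> int:
        return hash((self._nodes, self._adj.tobytes()))

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"<IBDConfiguration n={self.n_nodes} edges={self.n_edges}>"


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------


def log_graph_probability(g: IBDConfiguration, G: ProbabilisticIBDGraph) -> float:
    """``log P(g | G_P)`` under independent edges.

    Probabilities of exactly 0 or 1 are tolerated only when the
    configuration agrees with them (a sure edge must be present, an
    impossible edge absent); any conflict raises ``ValueError``.
    """
    if set(g.nodes) != set(G.nodes):
        raise ValueError("configuration and graph must share the same node set")
    perm = [G.index(v) for v in g.nodes]
    P = G.matrix[np.ix_(perm, perm)]
    iu = np.triu_indices(g.n_nodes, 1)
    p = P[iu]
    e = g.adjacency[iu]
    if np.any((p == 1.0) & ~e):
        raise ValueError("edge with p_ij = 1 absent from configuration")
    if np.any((p == 0.0) & e):
        raise ValueError("edge with p_ij = 0 present in configuration")
    terms = np.where(e, p, 1.0 - p)
    return float(np.log(terms).sum())


def graph_probability(g: IBDConfiguration, G: ProbabilisticIBDGraph) -> float:
    """``P(g | G_P) = prod_{i<j} p_ij^{e_ij} (1 - p_ij)^{1 - e_ij}``.

    Accumulated in log space (components can reach dozens of nodes, i.e.
    hundreds of factors) and exponentiated at the end.
    """
    return math.exp(log_graph_probability(g, G))


def is_transitive(g: IBDConfiguration) -> bool:
    """True iff every connected component of ``g`` is a clique."""
    return g.is_transitive()


def connected_components(g: IBDConfiguration) -> list[tuple]:
    """Partition of the node set into maximal connected sets."""
    return g.connected_components()


def clique_close(g: IBDConfiguration) -> IBDConfiguration:
    """Add all within-component edges, restoring transitivity."""
    return g.clique_close()
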