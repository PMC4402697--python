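"""Exact conditional IBD probabilities by enumerating clique partitions.

Transitive IBD configurations on *n* labeled nodes are in bijection with
set partitions of the nodes (each clique is a block), so there are exactly
Bell(n) of them.  Enumerating partitions directly — via restricted-growth
strings — avoids filtering all 2^(n(n-1)/2) binary graphs for transitivity
and yields the identical result set.

The conditional probability of an edge given the whole probabilistic graph
is the mass of transitive configurations containing the edge over the mass
of all transitive configurations:

    p_dot_ij = sum_{g transitive, e_ij in g} P(g | G_P)
               / sum_{g transitive} P(g | G_P)

This module is the correctness oracle for the Monte-Carlo sampler.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Iterator

import numpy as np

from .graph import IBDConfiguration, ProbabilisticIBDGraph, edge_key

__all__ = [
    "BELL_NUMBERS",
    "DEFAULT_MAX_EXACT_NODES",
    "ConditionalEstimate",
    "iter_partition_labels",
    "enumerate_transitive",
    "exact_conditionals",
    "exact_conditional_matrix",
]

#: Bell numbers B(0)..B(12): the number of transitive configurations on n nodes.
BELL_NUMBERS = (1, 1, 2, 5, 15, 52, 203, 877, 4140, 21147, 115975, 678570, 4213597)

#: Default refusal cap for exact enumeration; B(12) ~ 4.2M partitions keeps
#: the worst case in the seconds-to-minutes range.
DEFAULT_MAX_EXACT_NODES = 12


@dataclass(frozen=True)
class ConditionalEstimate:
    """Exact conditional probability for one unordered node pair."""

    edge: tuple
    p_dot: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_dot <= 1.0:
            raise ValueError("p_dot must lie in [0, 1]")


def iter_partition_labels(n: int) -> Iterator[np.ndarray]:
    """Yield every set partition of ``range(n)`` as a block-label array.

    Partitions are generated as restricted-growth strings: ``a[0] = 0`` and
    ``a[i] <= 1 + max(a[:i])``.  Each array is a fresh copy.
    """
    if n < 1:
        raise ValueError("need at least one node")
    a = [0] * n
    while True:
        yield np.array(a, dtype=np.int64)
        i = n - 1
        while i > 0 and a[i] > max(a[:i]):
            i -= 1
        if i == 0:
            return
        a[i] += 1
        for k in range(i + 1, n):
            a[k] = 0


def _check_cap(n: int, max_nodes: int) -> None:
    if n > max_nodes:
        raise ValueError(
            f"exact enumeration refused for {n} nodes: the number of transitive "
            f"configurations grows as the Bell numbers "
            f"(B({max_nodes}) = {BELL_NUMBERS[max_nodes] if max_nodes < len(BELL_NUMBERS) else '...'}); "
            f"raise max_nodes explicitly or use the sampler"
        )


def enumerate_transitive(
    nodes: int | Iterable,
    max_nodes: int = DEFAULT_MAX_EXACT_NODES,
) -> Iterator[IBDConfiguration]:
    """Yield every transitive configuration on the given nodes exactly once.

    ``nodes`` may be an integer *n* (nodes become ``1..n``) or an explicit
    node sequence.  The number of configurations equals Bell(n).
    """
    if isinstance(nodes, int):
        nodes = tuple(range(1, nodes + 1))
    else:
        nodes = tuple(nodes)
    _check_cap(len(nodes), max_nodes)
    for labels in iter_partition_labels(len(nodes)):
        yield IBDConfiguration.from_labels(nodes, labels)


def _exact_condensed(P: np.ndarray) -> np.ndarray:
    """Conditional probabilities for the condensed upper triangle of ``P``.

    Log-domain accumulation with a fixed offset (the log-probability of the
    most probable *unconstrained* edge assignment) so that every weight is
    <= 1: no overflow, and underflow only affects negligible terms.
    """
    n = P.shape[0]
    ii, jj = np.triu_indices(n, 1)
    p = P[ii, jj]
    if np.any((p <= 0.0) | (p >= 1.0)):
        raise ValueError(
            "exact conditioning requires all edge probabilities strictly inside "
            "(0, 1); clamp or pin edges before calling"
        )
    logp = np.log(p)
    log1mp = np.log1p(-p)
    offset = float(np.maximum(logp, log1mp).sum())
    num = np.zeros(p.size)
    den = 0.0
    for labels in iter_partition_labels(n):
        same = labels[ii] == labels[jj]
        logw = float(np.where(same, logp, log1mp).sum())
        w = math.exp(logw - offset)
        den += w
        num[same] += w
    return num / den


def exact_conditionals(
    G: ProbabilisticIBDGraph,
    max_nodes: int = DEFAULT_MAX_EXACT_NODES,
) -> dict[tuple, ConditionalEstimate]:
    """Exact conditional probability for every unordered pair of ``G``.

    Enumerates all Bell(n) transitive configurations, so ``G`` must have at
    most ``max_nodes`` nodes, and every ``p_ij`` must be strictly inside
    ``(0, 1)``.
    """
    n = G.n_nodes
    _check_cap(n, max_nodes)
    if n < 2:
        return {}
    pdot = _exact_condensed(G.matrix)
    ii, jj = np.triu_indices(n, 1)
    out: dict[tuple, ConditionalEstimate] = {}
    for k, (i, j) in enumerate(zip(ii, jj)):
        edge = edge_key(G.nodes[i], G.nodes[j])
        out[edge] = ConditionalEstimate(edge, float(pdot[k]))
    return out


def exact_conditional_matrix(
    G: ProbabilisticIBDGraph,
    max_nodes: int = DEFAULT_MAX_EXACT_NODES,
) -> np.ndarray:
    """Like :func:`exact_conditionals` but as a symmetric ``(n, n)`` array."""
    n = G.n_nodes
    _check_cap(n, max_nodes)
    M = np.zeros((n, n))
    if n < 2:
        return M
    ii, jj = np.triu_indices(n, 1)
    pdot = _exact_condensed(G.matrix)
    M[ii, jj] = pdot
    M[jj, ii] = pdot
    return M
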