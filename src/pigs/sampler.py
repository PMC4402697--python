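"""Monte-Carlo sampling of transitive IBD configurations.

Exact conditioning requires enumerating all Bell(n) clique partitions,
which is infeasible beyond a dozen haplotypes.  The sampler instead
*discovers* transitive configurations and accumulates probability mass —
a randomized partial enumeration:

* ``N_g`` — sum of ``P(g | G_P)`` over every distinct configuration
  sampled so far (each configuration's mass is counted once; its exact
  probability is known, so revisits add no information);
* ``N_ij`` — the same sum restricted to configurations containing edge
  ``(i, j)``;
* ``p_hat_ij = N_ij / N_g`` — the running conditional-probability
  estimate, which equals the exact conditional probability once every
  configuration with non-negligible mass has been sampled.

Configurations are proposed by two complementary mechanisms, one of each
per iteration:

1. *Weighted local move.*  One non-pinned edge is selected with
   probability proportional to a bell-shaped weight centred at p = 0.5
   (edges near 0 or 1 say little about which configuration to visit
   next).  The configuration with that edge's state flipped — repaired
   for transitivity — is sampled, and becomes the new current state with
   probability ``p_ij`` (flip to present) or ``1 - p_ij`` (flip to
   absent).  This mass-seeking walk finds the high-probability
   configurations quickly.
2. *Uniform partition proposal.*  An independent set partition drawn
   uniformly at random (Stam's algorithm) over the pinned super-nodes.
   In the limit this samples every valid configuration with equal
   probability — the condition under which the accumulation estimator
   converges to the exact conditional — and it covers the long tail of
   configurations the local walk reaches slowly.

Edges with ``p_ij`` at or above a pinning threshold (default 0.99) are
fixed present and never sampled; nodes linked by pinned edges act as a
single super-node throughout.

Transitivity repair after adding an edge is clique closure of the merged
component.  After removing edge ``(i, j)``, the affected block is split
in two: all non-pinned edges of the block are cleared, the surviving
pinned sub-cliques and loose nodes are assigned to the side (``S_i`` or
``S_j``) they are more strongly connected to on average, ties are broken
by a fair coin, and both sides are made cliques.

Internally a transitive configuration is represented as a block-label
array (one label per node), which makes every accumulated configuration
transitive by construction.
"""

from __future__ import annotations

import math
import time
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy.special import ndtr

from .graph import (
    IBDConfiguration,
    ProbabilisticIBDGraph,
    edge_key,
)

__all__ = [
    "WeightParams",
    "SamplerConfig",
    "SamplerState",
    "edge_weight",
    "initialize_configuration",
    "repair_after_add",
    "repair_after_remove",
    "run_sampler",
]


@dataclass(frozen=True)
class WeightParams:
    """Edge-selection weighting curve: a normal CDF folded about p = 0.5.

    ``sigma`` controls how sharply mid-range edges are preferred: near 0
    the extremes are never selected and mixing stalls; very large values
    select edges uniformly.  The default 0.234 balances the two.
    """

    mu: float = 0.5
    sigma: float = 0.234

    def __post_init__(self) -> None:
        if not self.sigma > 0:
            raise ValueError("sigma must be positive")


@dataclass(frozen=True)
class SamplerConfig:
    """Termination and pinning controls for one sampling run.

    Parameters
    ----------
    fixed_edge_threshold
        Edges with ``p_ij`` at or above this are fixed present (reported
        as 1) and excluded from sampling.
    convergence_tol, convergence_window
        Declare convergence when every per-edge estimate changes by less
        than ``convergence_tol`` for ``convergence_window`` consecutive
        iterations.
    max_seconds
        Wall-clock cap per run (checked once per iteration); ``None``
        disables it.
    max_iterations
        Optional hard iteration cap.
    seed
        Seed for the run's random generator.
    """

    fixed_edge_threshold: float = 0.99
    convergence_tol: float = 1e-11
    convergence_window: int = 5000
    max_seconds: float | None = 120.0
    max_iterations: int | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        if not 0.0 < self.fixed_edge_threshold <= 1.0:
            raise ValueError("fixed_edge_threshold must lie in (0, 1]")
        if not self.convergence_tol > 0:
            raise ValueError("convergence_tol must be positive")
        if self.convergence_window < 1:
            raise ValueError("convergence_window must be >= 1")


@dataclass
class SamplerState:
    """Accumulators and diagnostics of a finished (or interrupted) run.

    ``n_g`` and ``n_ij`` are stored relative to a common scale
    ``exp(log_scale)`` (the initial configuration's probability) so that
    very large components cannot underflow; the ratio ``n_ij / n_g`` is
    unaffected by the scaling.
    """

    n_g: float = 0.0
    n_ij: dict = field(default_factory=dict)
    p_hat: dict = field(default_factory=dict)
    iteration: int = 0
    stable_count: int = 0
    converged: bool = False
    timed_out: bool = False
    log_scale: float = 0.0
    checkpoints: dict = field(default_factory=dict)


def edge_weight(p, params: WeightParams | None = None):
    """Selection weight for an edge with IBD probability ``p``.

    ``Phi((p - mu)/sigma)`` for ``p <= 0.5`` and its mirror image above,
    so the curve peaks at 0.5 and is strictly positive on (0, 1).
    Accepts scalars or arrays.
    """
    params = params or WeightParams()
    arr = np.asarray(p, dtype=float)
    phi = ndtr((arr - params.mu) / params.sigma)
    w = np.where(arr <= 0.5, phi, 1.0 - phi)
    if np.ndim(p) == 0:
        return float(w)
    return w


# ---------------------------------------------------------------------------
# transitivity repair on block-label arrays
# ---------------------------------------------------------------------------


def _pinned_component_labels(pinned: np.ndarray, members: np.ndarray) -> dict[int, list[int]]:
    """Connected components of the pinned-edge subgraph on ``members``."""
    comp_of: dict[int, int] = {}
    comps: dict[int, list[int]] = {}
    nxt = 0
    member_set = set(int(v) for v in members)
    for v in members:
        v = int(v)
        if v in comp_of:
            continue
        stack = [v]
        comp_of[v] = nxt
        comps[nxt] = [v]
        while stack:
            u = stack.pop()
            for w in np.flatnonzero(pinned[u]):
                w = int(w)
                if w in member_set and w not in comp_of:
                    comp_of[w] = nxt
                    comps[nxt].append(w)
                    stack.append(w)
        nxt += 1
    return {c: sorted(ms) for c, ms in comps.items()}


def _split_block(
    labels: np.ndarray,
    P: np.ndarray,
    pinned: np.ndarray,
    i: int,
    j: int,
    rng: np.random.Generator,
) -> None:
    """Split the block containing ``i`` and ``j`` after removing edge (i, j).

    In-place on ``labels``.  Non-pinned edges of the block are cleared;
    pinned sub-cliques survive intact and are assigned as whole blocks.
    If ``i`` and ``j`` remain linked by pinned edges the block cannot be
    split without cutting a pinned edge and is left unchanged (the removed
    edge is restored by closure).
    """
    members = np.flatnonzero(labels == labels[i])
    comps = _pinned_component_labels(pinned, members)
    comp_of = {v: c for c, ms in comps.items() for v in ms}
    ci, cj = comp_of[int(i)], comp_of[int(j)]
    if ci == cj:
        return
    side_i = list(comps[ci])
    side_j = list(comps[cj])
    others = [ms for c, ms in comps.items() if c not in (ci, cj)]
    multi = sorted((ms for ms in others if len(ms) > 1), key=min)
    singles = sorted(ms[0] for ms in others if len(ms) == 1)
    for X in multi:
        p_i = float(P[i, X].mean())
        p_j = float(P[j, X].mean())
        if p_i > p_j:
            side_i.extend(X)
        elif p_j > p_i:
            side_j.extend(X)
        elif rng.random() < 0.5:
            side_i.extend(X)
        else:
            side_j.extend(X)
    if singles:
        for k in rng.permutation(np.asarray(singles, dtype=np.int64)):
            k = int(k)
            p_i = float(P[k, side_i].mean())
            p_j = float(P[k, side_j].mean())
            if p_i > p_j:
                side_i.append(k)
            elif p_j > p_i:
                side_j.append(k)
            elif rng.random() < 0.5:
                side_i.append(k)
            else:
                side_j.append(k)
    new_label = int(labels.max()) + 1
    labels[np.asarray(side_j, dtype=np.int64)] = new_label


def _canonical_key(labels: np.ndarray) -> bytes:
    """Relabel blocks by first occurrence: a partition-unique hash key."""
    mapping: dict[int, int] = {}
    out = bytearray()
    for x in labels:
        x = int(x)
        v = mapping.setdefault(x, len(mapping))
        out += v.to_bytes(2, "little")
    return bytes(out)


def _urn_weights(k: int) -> np.ndarray:
    """Stam's urn-count distribution for uniform random set partitions.

    To draw a uniform partition of k elements: draw the number of urns u
    with P(u) proportional to u**k / u!, then drop each element into a
    uniform urn; occupied urns form the blocks.
    """
    u = np.arange(1, 4 * k + 20, dtype=float)
    lw = k * np.log(u) - np.array([math.lgamma(x + 1) for x in u])
    w = np.exp(lw - lw.max())
    return w / w.sum()


# ---------------------------------------------------------------------------
# public repair / initialization operations
# ---------------------------------------------------------------------------


def initialize_configuration(
    G: ProbabilisticIBDGraph,
    config: SamplerConfig | None = None,
) -> IBDConfiguration:
    """Starting configuration: pinned edges present, then clique-closed.

    Every edge with ``p_ij`` at or above the pinning threshold is set
    present; clique closure then forces any remaining within-component
    edges (including low-probability ones) so the result is transitive.
    """
    config = config or SamplerConfig()
    adj = G.matrix >= config.fixed_edge_threshold
    np.fill_diagonal(adj, False)
    return IBDConfiguration(G.nodes, adjacency=adj).clique_close()


def repair_after_add(g: IBDConfiguration, edge: tuple) -> IBDConfiguration:
    """Clique closure after setting ``edge`` present in ``g``."""
    a, b = edge
    i, j = g.index(a), g.index(b)
    adj = g.adjacency.copy()
    adj[i, j] = adj[j, i] = True
    return IBDConfiguration(g.nodes, adjacency=adj).clique_close()


def repair_after_remove(
    g: IBDConfiguration,
    G: ProbabilisticIBDGraph,
    edge: tuple,
    config: SamplerConfig | None = None,
    rng: np.random.Generator | int | None = None,
) -> IBDConfiguration:
    """Transitivity repair after setting ``edge`` absent.

    ``g`` is the (transitive) configuration *before* removal and must
    contain the edge; the returned configuration has the affected block
    split into the two cliques ``S_i`` and ``S_j`` described in the module
    docstring, with all other blocks untouched.
    """
    config = config or SamplerConfig()
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    if set(g.nodes) != set(G.nodes):
        raise ValueError("configuration and graph must share the same node set")
    if not g.is_transitive():
        raise ValueError("repair_after_remove expects a transitive configuration")
    a, b = edge
    i, j = g.index(a), g.index(b)
    if not g.adjacency[i, j]:
        raise ValueError(f"edge {edge!r} is not present in the configuration")
    perm = np.array([G.index(v) for v in g.nodes])
    P = G.matrix[np.ix_(perm, perm)]
    pinned = P >= config.fixed_edge_threshold
    np.fill_diagonal(pinned, False)
    labels = g._component_labels()
    _split_block(labels, P, pinned, i, j, rng)
    return IBDConfiguration.from_labels(g.nodes, labels)


# ---------------------------------------------------------------------------
# the main accumulation loop
# ---------------------------------------------------------------------------


def run_sampler(
    G: ProbabilisticIBDGraph,
    config: SamplerConfig | None = None,
    weight_params: WeightParams | None = None,
    *,
    checkpoints: tuple[int, ...] = (),
    rng: np.random.Generator | None = None,
    callback: Callable[[int, np.ndarray, np.ndarray], None] | None = None,
) -> tuple[dict[tuple, float], SamplerState]:
    """Estimate conditional edge probabilities for the whole graph.

    Runs the accumulation loop described in the module docstring until
    convergence, ``max_iterations``, or the wall-clock cap.  Returns a
    mapping of every unordered pair to its estimate (pinned edges report
    exactly 1) together with the :class:`SamplerState`.

    ``checkpoints`` requests snapshots of the estimates after the given
    iteration counts (the initial accumulation is iteration 0); they are
    stored in ``state.checkpoints``.  When checkpoints are requested and
    both caps are disabled, the run stops at the last checkpoint.
    ``callback(iteration, labels, p_hat)`` is invoked after every
    iteration — intended for tracing and invariant checks in tests.
    Identical seed and configuration give a bit-identical trajectory.
    """
    config = config or SamplerConfig()
    wparams = weight_params or WeightParams()
    if rng is None:
        rng = np.random.default_rng(config.seed)

    nodes = G.nodes
    n = len(nodes)
    state = SamplerState()
    if n < 2:
        state.converged = True
        return {}, state

    P = G.matrix
    pinned = P >= config.fixed_edge_threshold
    np.fill_diagonal(pinned, False)
    ii, jj = np.triu_indices(n, 1)
    pin_flat = pinned[ii, jj]
    free = ~pin_flat
    fi = ii[free]
    fj = jj[free]
    fp = P[fi, fj]
    if np.any((fp <= 0.0) | (fp >= 1.0)):
        raise ValueError(
            "non-pinned edge probabilities must lie strictly inside (0, 1); "
            "assign uncalled pairs the epsilon prior first"
        )

    # initial configuration: pinned components become cliques
    labels = np.arange(n, dtype=np.int64)
    for a, b in zip(*np.nonzero(np.triu(pinned, 1))):
        la, lb = labels[a], labels[b]
        if la != lb:
            labels[labels == lb] = la

    cps = sorted(set(int(c) for c in checkpoints))

    if fi.size == 0:
        # everything pinned: the initial configuration is the answer
        state.n_g = 1.0
        state.converged = True
        result = {edge_key(nodes[a], nodes[b]): 1.0 for a, b in zip(ii, jj)}
        state.p_hat = dict(result)
        state.n_ij = {e: 1.0 for e in result}
        state.checkpoints = {c: dict(result) for c in cps}
        return result, state

    # super-nodes for uniform partition proposals: one representative row
    # per pinned component (members always share a block)
    reps: list[int] = []
    rep_of = np.zeros(n, dtype=np.int64)
    for k2, lab in enumerate(np.unique(labels)):
        members = np.flatnonzero(labels == lab)
        reps.append(int(members[0]))
        rep_of[members] = k2
    n_super = len(reps)
    urn_w = _urn_weights(n_super)
    urn_cum = np.cumsum(urn_w)

    lp = np.log(fp)
    l1p = np.log1p(-fp)
    diff = lp - l1p
    base = float(l1p.sum())

    weights = edge_weight(fp, wparams)
    cumw = np.cumsum(weights)
    total_w = float(cumw[-1])

    same = labels[fi] == labels[fj]
    log0 = base + float(np.dot(diff, same))
    n_g = 1.0  # exp(log0 - log0)
    n_ij = same.astype(float)
    seen = {_canonical_key(labels)}

    p_hat = n_ij / n_g
    stable = 0
    iteration = 0
    converged = False
    timed_out = False
    snapshots: dict[int, np.ndarray] = {}
    if 0 in cps:
        snapshots[0] = p_hat.copy()

    def accumulate(lab: np.ndarray) -> None:
        nonlocal n_g, n_ij
        key = _canonical_key(lab)
        if key in seen:
            return
        seen.add(key)
        s = lab[fi] == lab[fj]
        w = math.exp(base + float(np.dot(diff, s)) - log0)
        n_g += w
        n_ij = n_ij + w * s

    max_iter = config.max_iterations
    start = time.monotonic()
    while not converged:
        if max_iter is not None and iteration >= max_iter:
            break
        if cps and iteration >= cps[-1] and max_iter is None and config.max_seconds is None:
            break
        if config.max_seconds is not None and time.monotonic() - start > config.max_seconds:
            timed_out = True
            break
        iteration += 1

        # (1) weighted local move: sample the flipped configuration
        k = int(np.searchsorted(cumw, rng.random() * total_w, side="right"))
        if k >= fi.size:  # guard against cumulative-sum rounding
            k = fi.size - 1
        i = int(fi[k])
        j = int(fj[k])
        if labels[i] == labels[j]:
            flipped = labels.copy()
            _split_block(flipped, P, pinned, i, j, rng)
            accumulate(flipped)
            if rng.random() >= fp[k]:  # e_ij drawn absent: move to the split
                labels = flipped
        else:
            flipped = labels.copy()
            flipped[flipped == flipped[j]] = flipped[i]
            accumulate(flipped)
            if rng.random() < fp[k]:  # e_ij drawn present: move to the merge
                labels = flipped

        # (2) uniform partition proposal over super-nodes
        u = int(np.searchsorted(urn_cum, rng.random() * urn_cum[-1], side="right")) + 1
        proposal = rng.integers(0, u, size=n_super)
        accumulate(proposal[rep_of])

        new_p = n_ij / n_g
        if float(np.max(np.abs(new_p - p_hat))) < config.convergence_tol:
            stable += 1
            if stable >= config.convergence_window:
                converged = True
        else:
            stable = 0
        p_hat = new_p
        if callback is not None:
            callback(iteration, labels.copy(), p_hat)
        if cps and iteration in cps:
            snapshots[iteration] = p_hat.copy()

    def _as_dict(values: np.ndarray) -> dict[tuple, float]:
        out: dict[tuple, float] = {}
        for a, b in zip(ii[pin_flat], jj[pin_flat]):
            out[edge_key(nodes[a], nodes[b])] = 1.0
        for k2, (a, b) in enumerate(zip(fi, fj)):
            out[edge_key(nodes[a], nodes[b])] = float(values[k2])
        return out

    result = _as_dict(p_hat)
    state.n_g = float(n_g)
    state.n_ij = {}
    for a, b in zip(ii[pin_flat], jj[pin_flat]):
        state.n_ij[edge_key(nodes[a], nodes[b])] = float(n_g)
    for k2, (a, b) in enumerate(zip(fi, fj)):
        state.n_ij[edge_key(nodes[a], nodes[b])] = float(n_ij[k2])
    state.p_hat = dict(result)
    state.iteration = iteration
    state.stable_count = stable
    state.converged = converged
    state.timed_out = timed_out
    state.log_scale = log0
    state.checkpoints = {c: _as_dict(v) for c, v in snapshots.items()}
    return result, state
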