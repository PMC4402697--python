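"""Model/Results interface for conditioning a probabilistic IBD graph.

Follows the fit-and-results idiom of statistical modelling packages::

    model = IBDGraphModel(graph)
    res = model.fit()            # exact for small graphs, sampling above
    print(res.summary())
    res.conditional(hap_a, hap_b)

The "model" is the probabilistic IBD graph itself — independent marginal
edge probabilities constrained to transitive configurations — and
fitting computes the conditional probability of every edge given all
others simultaneously.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .exact import DEFAULT_MAX_EXACT_NODES, enumerate_transitive, exact_conditionals
from .graph import (
    DEFAULT_EPSILON,
    IBDConfiguration,
    ProbabilisticIBDGraph,
    edge_key,
    log_graph_probability,
)
from .sampler import SamplerConfig, SamplerState, WeightParams, run_sampler

__all__ = ["IBDGraphModel", "IBDGraphResults"]

#: node count at or below which fit(method="auto") enumerates exactly
AUTO_EXACT_NODES = 8


def _edge_series(mapping: Mapping[tuple, float]) -> pd.Series:
    keys = sorted(mapping, key=lambda e: (str(e[0]), str(e[1])))
    index = pd.MultiIndex.from_tuples(keys, names=["hap_a", "hap_b"])
    return pd.Series([float(mapping[k]) for k in keys], index=index, name="probability")


class IBDGraphModel:
    """Transitive-IBD conditioning model over one probabilistic graph."""

    def __init__(self, graph: ProbabilisticIBDGraph) -> None:
        self.graph = graph

    # -- constructors ----------------------------------------------------

    @classmethod
    def from_edges(
        cls,
        edge_probabilities: Mapping[tuple, float],
        nodes: Sequence | None = None,
        epsilon: float = DEFAULT_EPSILON,
    ) -> "IBDGraphModel":
        if nodes is None:
            seen: list = []
            for a, b in edge_probabilities:
                for v in (a, b):
                    if v not in seen:
                        seen.append(v)
            try:
                nodes = sorted(seen)
            except TypeError:
                nodes = sorted(seen, key=str)
        return cls(ProbabilisticIBDGraph(nodes, edge_probabilities, epsilon=epsilon))

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        hap_a: str = "hap_a",
        hap_b: str = "hap_b",
        prob: str = "prob",
        epsilon: float = DEFAULT_EPSILON,
    ) -> "IBDGraphModel":
        """Build from a long-format edge table (one row per called pair)."""
        probs = {
            edge_key(row[hap_a], row[hap_b]): float(row[prob])
            for _, row in df.iterrows()
        }
        return cls.from_edges(probs, epsilon=epsilon)

    # -- fitting ---------------------------------------------------------

    def fit(
        self,
        method: str = "auto",
        config: SamplerConfig | None = None,
        weight_params: WeightParams | None = None,
        checkpoints: tuple[int, ...] = (),
        max_exact_nodes: int = DEFAULT_MAX_EXACT_NODES,
    ) -> "IBDGraphResults":
        """Condition every edge on the whole graph.

        ``method`` is ``"exact"`` (enumerate all clique partitions;
        refuses above ``max_exact_nodes``), ``"sampling"`` (Monte-Carlo
        accumulation), or ``"auto"`` (exact up to 8 nodes, sampling
        beyond).
        """
        n = self.graph.n_nodes
        if method == "auto":
            method = "exact" if n <= AUTO_EXACT_NODES else "sampling"
        if method not in ("exact", "sampling"):
            raise ValueError("method must be 'auto', 'exact' or 'sampling'")
        prior = dict(self.graph.edge_items())
        if method == "exact":
            graph = self.graph
            if any(p <= 0.0 or p >= 1.0 for p in prior.values()):
                # enumeration needs p strictly inside (0, 1); hard 0/1
                # edges are nudged inside by a negligible amount
                graph = _clamped(graph)
            estimates = {
                e: float(c.p_dot)
                for e, c in exact_conditionals(graph, max_nodes=max_exact_nodes).items()
            }
            state = None
        else:
            estimates, state = run_sampler(
                self.graph, config, weight_params, checkpoints=checkpoints
            )
        return IBDGraphResults(
            model=self,
            method=method,
            edge_probabilities=_edge_series(estimates),
            prior_probabilities=_edge_series(prior),
            state=state,
        )

    # -- simulation ------------------------------------------------------

    def simulate(
        self, n_draws: int, seed=None, max_exact_nodes: int = DEFAULT_MAX_EXACT_NODES
    ) -> list[IBDConfiguration]:
        """Draw transitive configurations from ``P(g | G_P)`` restricted
        to transitive graphs (small graphs only: uses enumeration)."""
        configs = list(enumerate_transitive(self.graph.nodes, max_nodes=max_exact_nodes))
        logw = np.array([log_graph_probability(g, self.graph) for g in configs])
        w = np.exp(logw - logw.max())
        w /= w.sum()
        rng = np.random.default_rng(seed)
        idx = rng.choice(len(configs), size=n_draws, p=w)
        return [configs[int(i)] for i in idx]


@dataclass
class IBDGraphResults:
    """Conditional edge probabilities plus fit diagnostics.

    ``edge_probabilities`` holds the conditional estimate for every
    unordered pair; ``prior_probabilities`` the marginal inputs.  For a
    sampling fit, ``state`` carries the accumulator diagnostics
    (iterations, convergence, timeout, checkpoint snapshots).
    """

    model: IBDGraphModel
    method: str
    edge_probabilities: pd.Series
    prior_probabilities: pd.Series
    state: SamplerState | None = None

    @property
    def converged(self) -> bool:
        return True if self.state is None else self.state.converged

    @property
    def iterations(self) -> int:
        return 0 if self.state is None else self.state.iteration

    @property
    def timed_out(self) -> bool:
        return False if self.state is None else self.state.timed_out

    def conditional(self, a, b) -> float:
        return float(self.edge_probabilities[edge_key(a, b)])

    def to_frame(self) -> pd.DataFrame:
        thr = SamplerConfig().fixed_edge_threshold
        df = pd.DataFrame(
            {
                "prior": self.prior_probabilities,
                "conditional": self.edge_probabilities,
            }
        )
        df["pinned"] = df["prior"] >= thr
        return df

    def summary(self) -> str:
        df = self.to_frame()
        n = self.model.graph.n_nodes
        lines = [
            "Probabilistic IBD graph conditioning",
            "=" * 52,
            f"nodes: {n}    edges: {len(df)}    method: {self.method}",
        ]
        if self.state is not None:
            lines.append(
                f"iterations: {self.iterations}    converged: {self.converged}"
                f"    timed out: {self.timed_out}"
            )
        lines.append("-" * 52)
        lines.append(f"{'edge':<28}{'prior':>10}{'cond.':>10}")
        for (a, b), row in df.iterrows():
            tag = " *" if row["pinned"] else ""
            lines.append(f"{str(a) + ' - ' + str(b):<28}{row['prior']:>10.4f}{row['conditional']:>10.4f}{tag}")
        lines.append("-" * 52)
        lines.append("* edge at or above the pinning threshold (reported as 1)")
        return "\n".join(lines)


def _clamped(graph: ProbabilisticIBDGraph, margin: float = 1e-9) -> ProbabilisticIBDGraph:
    M = np.clip(graph.matrix, margin, 1.0 - margin)
    np.fill_diagonal(M, 0.0)
    return ProbabilisticIBDGraph(
        graph.nodes, matrix=M, region=graph.region, epsilon=graph.epsilon
    )
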