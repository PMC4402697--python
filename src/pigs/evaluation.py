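"""Assessment metrics: sampler convergence, segment recovery, clique recovery.

Three families of metrics:

* **Convergence delta** — the mean relative percent difference between
  sampled and exact conditional edge probabilities, the diagnostic used
  to validate the sampler against the enumeration oracle on random
  graphs (:func:`run_convergence_experiment` reproduces the standard
  protocol: Uniform(0, 0.99) edge probabilities, 25 seeded runs,
  snapshots at fixed iteration counts).

* **Segment metrics** — truth-indexed power (average covered proportion
  of true segments) and prediction-indexed error measures (fraction of
  predicted segments intersecting no truth, average uncovered
  proportion, and the rate of predictions with at least 50% overlap),
  tabulated by centimorgan size bins.  "Intersect" means at least one
  shared base pair on the same haplotype pair.

* **Clique metrics** — per true clique, the proportion of its edges
  recovered by a predicted graph (edge power); per predicted connected
  component, the proportion of edges joining nodes that no true clique
  puts together (edge false-positive rate), tabulated by clique size.

Power-style rates use truth-indexed denominators and error-style rates
prediction-indexed ones; the two are never mixed.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .exact import ConditionalEstimate, exact_conditionals
from .graph import IBDConfiguration, edge_key
from .sampler import SamplerConfig, WeightParams, run_sampler
from .segments import GeneticMap, IBDSegment, segment_length_cm
from .synthetic import random_probabilistic_graph

__all__ = [
    "convergence_delta",
    "ConvergenceResult",
    "run_convergence_experiment",
    "SegmentMetrics",
    "segment_metrics",
    "CliqueMetrics",
    "clique_metrics",
]


# ---------------------------------------------------------------------------
# convergence
# ---------------------------------------------------------------------------


def convergence_delta(
    exact: Mapping[tuple, float | ConditionalEstimate],
    estimate: Mapping[tuple, float],
    exclude: Iterable[tuple] = (),
) -> float:
    """Mean relative percent difference between estimates and exact values.

    ``mean_edges(|p_dot - p_hat| / p_dot) * 100`` over the shared edge
    set, optionally excluding edges (e.g. pinned ones, which are not
    estimated).  Exact values must be strictly positive.
    """
    skip = set(exclude)
    exact_vals = {
        e: (v.p_dot if isinstance(v, ConditionalEstimate) else float(v))
        for e, v in exact.items()
        if e not in skip
    }
    est_keys = set(estimate) - skip
    if set(exact_vals) != est_keys:
        raise ValueError("exact and estimated edge sets differ")
    if not exact_vals:
        raise ValueError("no edges to compare")
    rel = []
    for e, pd_ in exact_vals.items():
        if pd_ <= 0.0:
            raise ValueError(f"exact conditional for edge {e!r} is not positive")
        rel.append(abs(pd_ - float(estimate[e])) / pd_)
    return float(np.mean(rel) * 100.0)


@dataclass(frozen=True)
class ConvergenceResult:
    """Run-averaged convergence deltas for one random graph."""

    n_nodes: int
    n_runs: int
    delta_bar: dict  # iteration -> mean delta over runs (percent)
    per_run: dict  # iteration -> array of per-run deltas
    graph_seed: object = None


def run_convergence_experiment(
    n_nodes: int,
    n_runs: int = 25,
    checkpoint_iters: Sequence[int] = (5000,),
    seed=0,
    graph=None,
    config: SamplerConfig | None = None,
    weight_params: WeightParams | None = None,
) -> ConvergenceResult:
    """Sampler-vs-oracle accuracy on one random probabilistic graph.

    Draws a graph with Uniform(0, 0.99) edge probabilities (unless one is
    supplied), computes exact conditionals by enumeration, then runs the
    sampler ``n_runs`` times with distinct seeds and evaluates
    :func:`convergence_delta` at each checkpoint iteration, averaging
    over runs.
    """
    ss = np.random.SeedSequence(seed)
    graph_seed, *run_seeds = ss.spawn(n_runs + 1)
    if graph is None:
        graph = random_probabilistic_graph(n_nodes, seed=graph_seed)
    exact = exact_conditionals(graph)
    cps = tuple(sorted(int(c) for c in checkpoint_iters))
    base_cfg = config or SamplerConfig(max_seconds=None)
    per_run: dict[int, list[float]] = {c: [] for c in cps}
    for rs in run_seeds:
        cfg = replace(
            base_cfg,
            max_iterations=cps[-1],
            convergence_window=max(base_cfg.convergence_window, cps[-1] + 1),
        )
        _, state = run_sampler(
            graph, cfg, weight_params,
            rng=np.random.default_rng(rs), checkpoints=cps,
        )
        for c in cps:
            per_run[c].append(convergence_delta(exact, state.checkpoints[c]))
    return ConvergenceResult(
        n_nodes=graph.n_nodes,
        n_runs=n_runs,
        delta_bar={c: float(np.mean(v)) for c, v in per_run.items()},
        per_run={c: np.asarray(v) for c, v in per_run.items()},
        graph_seed=seed,
    )


# ---------------------------------------------------------------------------
# segment metrics
# ---------------------------------------------------------------------------


def _overlap_bp(a: IBDSegment, b: IBDSegment) -> int:
    if a.chrom != b.chrom or a.pair != b.pair:
        return 0
    return max(0, min(a.end_bp, b.end_bp) - max(a.start_bp, b.start_bp) + 1)


def _covered_bp(seg: IBDSegment, others: Sequence[IBDSegment]) -> int:
    """Base pairs of ``seg`` covered by the union of ``others`` (same pair)."""
    ivs = sorted(
        (max(seg.start_bp, o.start_bp), min(seg.end_bp, o.end_bp))
        for o in others
        if _overlap_bp(seg, o) > 0
    )
    covered = 0
    cur_s = cur_e = None
    for s, e in ivs:
        if cur_e is None or s > cur_e + 1:
            if cur_e is not None:
                covered += cur_e - cur_s + 1
            cur_s, cur_e = s, e
        else:
            cur_e = max(cur_e, e)
    if cur_e is not None:
        covered += cur_e - cur_s + 1
    return covered


@dataclass(frozen=True)
class SegmentMetrics:
    """Size-binned segment-recovery tables.

    ``predicted`` is indexed by predicted-segment size bin and reports
    counts, the error rate (fraction intersecting no true segment), both
    false-discovery variants and the 50%-overlap true-positive rate;
    ``truth`` is indexed by true-segment size bin and reports power (the
    average covered proportion of true segments).
    """

    predicted: pd.DataFrame
    truth: pd.DataFrame


def _bin_label(length_cm: float, edges: np.ndarray) -> float | None:
    if length_cm < edges[0]:
        return None
    idx = int(np.searchsorted(edges, length_cm, side="right")) - 1
    idx = min(idx, len(edges) - 2) if len(edges) >= 2 else 0
    return float(edges[min(idx, len(edges) - 1)])


def segment_metrics(
    predicted: Sequence[IBDSegment],
    truth: Sequence[IBDSegment],
    gmap: GeneticMap | None = None,
    size_bins_cm: Sequence[float] | None = None,
    min_truth_cm: float = 0.1,
) -> SegmentMetrics:
    """Power/error tables for predicted against true segments.

    Truth segments shorter than ``min_truth_cm`` are dropped before
    comparison (the conventional truth-length floor).  Bins are
    left-closed and labelled by their lower edge; the final bin is
    open-ended.
    """
    if size_bins_cm is None:
        size_bins_cm = np.round(np.arange(0.5, 3.01, 0.1), 10)
    edges = np.asarray(sorted(size_bins_cm), dtype=float)
    truth = [t for t in truth if segment_length_cm(t, gmap) >= min_truth_cm]
    truth_by_pair: dict[tuple, list[IBDSegment]] = {}
    for t in truth:
        truth_by_pair.setdefault((t.chrom, t.pair), []).append(t)
    pred_by_pair: dict[tuple, list[IBDSegment]] = {}
    for p in predicted:
        pred_by_pair.setdefault((p.chrom, p.pair), []).append(p)

    pred_rows = []
    for p in predicted:
        partners = truth_by_pair.get((p.chrom, p.pair), [])
        cov = _covered_bp(p, partners)
        frac = cov / p.length_bp
        pred_rows.append(
            dict(
                bin=_bin_label(segment_length_cm(p, gmap), edges),
                intersects=cov > 0,
                covered_frac=frac,
                tp50=frac >= 0.5,
            )
        )
    truth_rows = []
    for t in truth:
        partners = pred_by_pair.get((t.chrom, t.pair), [])
        cov = _covered_bp(t, partners)
        truth_rows.append(
            dict(
                bin=_bin_label(segment_length_cm(t, gmap), edges),
                covered_frac=cov / t.length_bp,
            )
        )

    pred_df = pd.DataFrame(pred_rows, columns=["bin", "intersects", "covered_frac", "tp50"])
    pred_df = pred_df[pred_df["bin"].notna()]
    if len(pred_df):
        grouped = pred_df.groupby("bin")
        predicted_table = pd.DataFrame(
            {
                "n_predicted": grouped.size(),
                "n_intersecting": grouped["intersects"].sum(),
                "error_rate": 1.0 - grouped["intersects"].mean(),
                "fdr_uncovered": 1.0 - grouped["covered_frac"].mean(),
                "fdr_no_overlap": 1.0 - grouped["intersects"].mean(),
                "tp50_rate": grouped["tp50"].mean(),
            }
        )
    else:
        predicted_table = pd.DataFrame(
            columns=[
                "n_predicted", "n_intersecting", "error_rate",
                "fdr_uncovered", "fdr_no_overlap", "tp50_rate",
            ]
        )
    truth_df = pd.DataFrame(truth_rows, columns=["bin", "covered_frac"])
    truth_df = truth_df[truth_df["bin"].notna()]
    if len(truth_df):
        grouped = truth_df.groupby("bin")
        truth_table = pd.DataFrame(
            {"n_truth": grouped.size(), "power": grouped["covered_frac"].mean()}
        )
    else:
        truth_table = pd.DataFrame(columns=["n_truth", "power"])
    return SegmentMetrics(predicted=predicted_table, truth=truth_table)


# ---------------------------------------------------------------------------
# clique metrics
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CliqueMetrics:
    """Size-binned clique-recovery tables (truth- and prediction-indexed)."""

    truth: pd.DataFrame
    predicted: pd.DataFrame


DEFAULT_CLIQUE_BINS = (0, 30, 60, 90, 120, 150)


def clique_metrics(
    predicted_graph: IBDConfiguration,
    truth_partition: Sequence[Iterable],
    size_bins: Sequence[int] = DEFAULT_CLIQUE_BINS,
) -> CliqueMetrics:
    """Edge power and edge false-positive rate at one locus.

    ``truth_partition`` lists the true cliques (iterables of nodes; only
    cliques of size >= 2 matter).  Edge power for a true clique is the
    fraction of its k(k-1)/2 edges present in the predicted graph,
    averaged per clique-size bin.  The false-positive rate of a predicted
    connected component is the fraction of its present edges joining two
    nodes that no true clique contains together, averaged per
    component-size bin.
    """
    edges_lo = np.asarray(sorted(size_bins), dtype=float)
    pred_edges = predicted_graph.edges()
    together: set = set()
    truth_rows = []
    for clique in truth_partition:
        members = sorted(clique, key=str)
        k = len(members)
        if k < 2:
            continue
        hit = 0
        total = 0
        for a in range(k):
            for b in range(a + 1, k):
                e = edge_key(members[a], members[b])
                together.add(e)
                total += 1
                if e in pred_edges:
                    hit += 1
        truth_rows.append(dict(bin=_bin_label(k, edges_lo), power=hit / total, size=k))
    pred_rows = []
    for comp in predicted_graph.connected_components():
        if len(comp) < 2:
            continue
        comp_set = set(comp)
        comp_edges = [e for e in pred_edges if e[0] in comp_set and e[1] in comp_set]
        if not comp_edges:
            continue
        false = sum(1 for e in comp_edges if e not in together)
        pred_rows.append(
            dict(bin=_bin_label(len(comp), edges_lo), fp_rate=false / len(comp_edges), size=len(comp))
        )
    truth_df = pd.DataFrame(truth_rows, columns=["bin", "power", "size"])
    truth_df = truth_df[truth_df["bin"].notna()]
    if len(truth_df):
        g = truth_df.groupby("bin")
        truth_table = pd.DataFrame({"n_cliques": g.size(), "edge_power": g["power"].mean()})
    else:
        truth_table = pd.DataFrame(columns=["n_cliques", "edge_power"])
    pred_df = pd.DataFrame(pred_rows, columns=["bin", "fp_rate", "size"])
    pred_df = pred_df[pred_df["bin"].notna()]
    if len(pred_df):
        g = pred_df.groupby("bin")
        pred_table = pd.DataFrame({"n_components": g.size(), "edge_fp_rate": g["fp_rate"].mean()})
    else:
        pred_table = pd.DataFrame(columns=["n_components", "edge_fp_rate"])
    return CliqueMetrics(truth=truth_table, predicted=pred_table)
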