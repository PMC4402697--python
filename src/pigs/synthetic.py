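"""Synthetic IBD data with known ground truth.

Two generators:

* :func:`random_probabilistic_graph` — complete graphs with i.i.d.
  Uniform(0, 0.99) edge probabilities, the input distribution used for
  sampler-convergence experiments.
* :func:`simulate_truth` / :func:`emit_noisy_calls` — a segment-level
  stand-in for a coalescent-simulation + pairwise-calling pipeline.  True
  IBD arises as clique events scattered along a chromosome (Poisson in
  position): a clique of k haplotypes sharing one interval contributes all
  k(k-1)/2 pairwise true segments, so the truth graph at any locus is a
  union of cliques by construction.  The noisy emitter then reproduces the
  statistical structure of a real pairwise caller's output: detection
  probability decays for short segments, endpoints are jittered, LOD
  scores increase with segment length for true calls and stay low for the
  Poisson background of false calls.

The emitter's incomplete detection of cliques (a detected clique with one
or two edges missing) is precisely the situation graph conditioning is
designed to repair, which makes these datasets the end-to-end test bed.

What this generator does **not** emulate: linkage disequilibrium,
population demography, phasing errors correlated along the genome, or
genotyping-array ascertainment.  Conclusions from these datasets are about
the graph-inference machinery, not about any particular cohort.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .graph import HaplotypeId, ProbabilisticIBDGraph, edge_key
from .segments import IBDSegment

__all__ = [
    "CliqueEvent",
    "TruthSet",
    "random_probabilistic_graph",
    "simulate_truth",
    "emit_noisy_calls",
    "default_detection",
    "default_true_lod",
    "default_false_lod",
]

#: default chromosome length, matching a typical simulated region
DEFAULT_CHROM_LENGTH_BP = 30_000_000
#: constant genetic-map scale used when converting lengths
CM_PER_BP = 1e-6


def random_probabilistic_graph(
    n: int,
    seed=None,
    *,
    low: float = 0.0,
    high: float = 0.99,
    nodes: Sequence | None = None,
) -> ProbabilisticIBDGraph:
    """Complete graph with i.i.d. Uniform(low, high) edge probabilities.

    Draws on the open interval (zeros are redrawn so every probability is
    strictly positive); reproducible under ``seed``.
    """
    if n < 2:
        raise ValueError("need at least two nodes")
    rng = np.random.default_rng(seed)
    iu = np.triu_indices(n, 1)
    vals = rng.uniform(low, high, size=len(iu[0]))
    while np.any(vals <= low):  # open interval
        redo = vals <= low
        vals[redo] = rng.uniform(low, high, size=int(redo.sum()))
    P = np.zeros((n, n))
    P[iu] = vals
    P += P.T
    if nodes is None:
        nodes = tuple(range(1, n + 1))
    return ProbabilisticIBDGraph(nodes, matrix=P)


@dataclass(frozen=True)
class CliqueEvent:
    """One true IBD-sharing event: ``members`` share ``[start_bp, end_bp]``."""

    chrom: str
    start_bp: int
    end_bp: int
    members: tuple


@dataclass(frozen=True)
class TruthSet:
    """Ground-truth cliques and the pairwise segments they imply."""

    events: tuple
    haplotypes: tuple
    chrom_length_bp: int
    seed: object = None
    params: dict = field(default_factory=dict)

    @property
    def true_segments(self) -> list[IBDSegment]:
        segs = []
        for ev in self.events:
            members = sorted(ev.members)
            for i in range(len(members)):
                for j in range(i + 1, len(members)):
                    segs.append(
                        IBDSegment(
                            hap_a=members[i],
                            hap_b=members[j],
                            chrom=ev.chrom,
                            start_bp=ev.start_bp,
                            end_bp=ev.end_bp,
                        )
                    )
        return segs

    def truth_partition_at(self, chrom: str, pos: int) -> list[set]:
        """Blocks of the true IBD graph at one position (cliques merged
        transitively when events overlap), singletons omitted."""
        active = [ev for ev in self.events if ev.chrom == chrom and ev.start_bp <= pos <= ev.end_bp]
        blocks: list[set] = []
        for ev in active:
            ms = set(ev.members)
            merged = [b for b in blocks if b & ms]
            for b in merged:
                blocks.remove(b)
                ms |= b
            blocks.append(ms)
        return blocks

    def truth_edges_at(self, chrom: str, pos: int) -> set:
        edges = set()
        for block in self.truth_partition_at(chrom, pos):
            members = sorted(block)
            for i in range(len(members)):
                for j in range(i + 1, len(members)):
                    edges.add(edge_key(members[i], members[j]))
        return edges


def simulate_truth(
    chrom_length_bp: int = DEFAULT_CHROM_LENGTH_BP,
    n_haplotypes: int = 200,
    clique_rate_per_mb: float = 2.0,
    clique_sizes: tuple[int, int] = (2, 8),
    mean_length_cm: float = 0.8,
    min_length_cm: float = 0.1,
    seed=None,
    chrom: str = "1",
) -> TruthSet:
    """Scatter clique events along one chromosome.

    Event count is Poisson with mean ``clique_rate_per_mb`` per megabase;
    positions are uniform, clique sizes uniform on ``clique_sizes``
    (inclusive), and segment lengths exponential with mean
    ``mean_length_cm`` centimorgans, redrawn below ``min_length_cm`` so
    every true segment passes the conventional truth-length floor.
    A constant 1 cM/Mb map converts lengths to base pairs.
    """
    if n_haplotypes < clique_sizes[1]:
        raise ValueError("n_haplotypes must be at least the largest clique size")
    rng = np.random.default_rng(seed)
    haps = tuple(
        HaplotypeId(f"S{k // 2 + 1:04d}", k % 2 + 1) for k in range(n_haplotypes)
    )
    n_events = int(rng.poisson(clique_rate_per_mb * chrom_length_bp / 1e6)) if clique_rate_per_mb > 0 else 0
    events = []
    for _ in range(n_events):
        size = int(rng.integers(clique_sizes[0], clique_sizes[1] + 1))
        length_cm = float(rng.exponential(mean_length_cm))
        while length_cm < min_length_cm:
            length_cm = float(rng.exponential(mean_length_cm))
        length_bp = max(1, int(round(length_cm / CM_PER_BP)))
        start = int(rng.integers(1, max(2, chrom_length_bp - length_bp)))
        end = min(chrom_length_bp, start + length_bp - 1)
        # the truth graph at every locus must be a union of cliques, so
        # events overlapping in position may not share haplotypes (a
        # shared member would transitively merge the two cliques)
        busy = set()
        for ev in events:
            if ev.start_bp <= end and ev.end_bp >= start:
                busy.update(ev.members)
        free = [h for h in haps if h not in busy]
        if len(free) < size:
            continue  # locus too crowded: drop the event
        members = rng.choice(len(free), size=size, replace=False)
        events.append(
            CliqueEvent(chrom, start, end, tuple(free[int(m)] for m in members))
        )
    events.sort(key=lambda ev: (ev.start_bp, ev.end_bp))
    return TruthSet(
        events=tuple(events),
        haplotypes=haps,
        chrom_length_bp=chrom_length_bp,
        seed=seed,
        params=dict(
            clique_rate_per_mb=clique_rate_per_mb,
            clique_sizes=clique_sizes,
            mean_length_cm=mean_length_cm,
            min_length_cm=min_length_cm,
        ),
    )


def default_detection(length_cm) -> np.ndarray:
    """Detection probability of a true segment: logistic in cM length.

    Roughly 0.5 at 0.3 cM and >0.99 above 0.8 cM — short segments are the
    hard case for pairwise callers.
    """
    arr = np.asarray(length_cm, dtype=float)
    return 1.0 / (1.0 + np.exp(-(arr - 0.3) / 0.1))


def default_true_lod(length_cm, rng: np.random.Generator) -> float:
    """LOD for a detected true segment: increases with length, noisy."""
    base = 3.0 * float(length_cm)
    return max(0.1, float(rng.normal(base, 0.5)))


def default_false_lod(rng: np.random.Generator) -> float:
    """LOD for a spurious segment: small, exponentially distributed."""
    return 0.1 + float(rng.exponential(0.2))


def emit_noisy_calls(
    truth: TruthSet,
    detect_fn: Callable = default_detection,
    lod_true: Callable = default_true_lod,
    lod_false: Callable = default_false_lod,
    false_rate_per_mb: float = 0.5,
    endpoint_jitter_cm: float = 0.02,
    false_mean_length_cm: float = 0.3,
    seed=None,
) -> list[IBDSegment]:
    """Pairwise calls a noisy caller would emit for ``truth``.

    Each true pairwise segment is emitted with probability
    ``detect_fn(length_cm)``, endpoints jittered by a centred normal of
    scale ``endpoint_jitter_cm``, and a LOD from ``lod_true``.  False
    segments arrive as a Poisson background (``false_rate_per_mb`` per
    megabase) on random haplotype pairs with short exponential lengths
    and ``lod_false`` scores.  The result is valid input for
    :func:`pigs.segments.read_segments` round-trips.
    """
    rng = np.random.default_rng(seed)
    calls: list[IBDSegment] = []
    jitter_bp = endpoint_jitter_cm / CM_PER_BP
    for seg in truth.true_segments:
        length_cm = (seg.end_bp - seg.start_bp + 1) * CM_PER_BP
        if rng.random() >= float(detect_fn(length_cm)):
            continue
        start = seg.start_bp + int(round(rng.normal(0.0, jitter_bp)))
        end = seg.end_bp + int(round(rng.normal(0.0, jitter_bp)))
        start = max(1, min(start, truth.chrom_length_bp - 1))
        end = max(start + 1, min(end, truth.chrom_length_bp))
        calls.append(
            IBDSegment(
                hap_a=seg.hap_a,
                hap_b=seg.hap_b,
                chrom=seg.chrom,
                start_bp=start,
                end_bp=end,
                lod=lod_true(length_cm, rng),
            )
        )
    if false_rate_per_mb > 0:
        n_false = int(rng.poisson(false_rate_per_mb * truth.chrom_length_bp / 1e6))
        haps = truth.haplotypes
        for _ in range(n_false):
            i, j = rng.choice(len(haps), size=2, replace=False)
            length_bp = max(1, int(round(rng.exponential(false_mean_length_cm) / CM_PER_BP)))
            start = int(rng.integers(1, max(2, truth.chrom_length_bp - length_bp)))
            end = min(truth.chrom_length_bp, start + length_bp - 1)
            calls.append(
                IBDSegment(
                    hap_a=haps[int(i)],
                    hap_b=haps[int(j)],
                    chrom=truth.events[0].chrom if truth.events else "1",
                    start_bp=start,
                    end_bp=end,
                    lod=lod_false(rng),
                )
            )
    calls.sort(key=lambda s: (s.chrom, s.start_bp, s.end_bp, str(s.hap_a), str(s.hap_b)))
    return calls
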