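# Methods

## Model

At a genomic locus, the IBD status of all haplotype pairs is modelled as
a random graph with independent edges: pair (i, j) is IBD with marginal
probability p_ij, so a binary configuration g has probability
P(g | G_P) = ∏ p_ij^{e_ij} (1 − p_ij)^{1 − e_ij}. Biology constrains the
support: descent from a common ancestor is transitive, so the true graph
must be a disjoint union of cliques — a set partition of the haplotypes.
The quantity of interest is the conditional probability of each edge
given that constraint,

    ṗ_ij = Σ_{g ∈ V, e_ij ∈ g} P(g|G_P) / Σ_{g ∈ V} P(g|G_P),

where V is the set of transitive configurations (|V| = Bell(n)).

Two assumptions are worth making explicit. First, the marginal p_ij are
taken at face value from the upstream caller's calibration; conditioning
redistributes belief among configurations but cannot repair a
miscalibrated input. Second, independence of edges in the prior is a
modelling convenience — in truth the caller's errors are correlated
along haplotypes — so conditional probabilities inherit that
approximation.

## Exact conditioning

Transitive configurations are in bijection with set partitions, so exact
conditioning enumerates partitions directly via restricted-growth
strings rather than filtering all 2^(n(n−1)/2) binary graphs: identical
result set, Bell(n) instead of exponential-in-edges work. Probabilities
are accumulated in the log domain against a fixed offset (the
log-probability of the most probable unconstrained edge assignment), so
every term is ≤ 1: no overflow, and underflow touches only negligible
terms. The enumeration refuses beyond a configurable cap (default 12
nodes, B(12) ≈ 4.2 M partitions); the automatic model interface switches
to sampling above 8 nodes, where enumeration stops being interactive.

Exact enumeration requires every p_ij strictly inside (0, 1). Uncalled
pairs carry the prior ε rather than 0 for exactly this reason; inputs of
exactly 0 or 1 are rejected (or, through the model interface, nudged
inside by 1e−9).

## Sampling

Beyond the enumeration cap the conditional is estimated by a randomized
partial enumeration. The estimator keeps running sums over every
*distinct* transitive configuration sampled so far — N_g of P(g|G_P),
and N_ij of the same restricted to configurations containing (i, j) —
and reports p̂_ij = N_ij / N_g. Because each configuration's exact
probability is known, a configuration contributes exactly once; the only
error is the mass of configurations not yet discovered, and p̂ equals ṗ
exactly once everything with non-negligible mass has been visited. A
direct consequence: if every valid configuration is sampled with
positive probability, p̂ → ṗ, and the approach to the limit is governed
by coverage of probability mass, not by averaging noise.

Each iteration proposes two configurations:

1. **Weighted local move.** One non-pinned edge is selected with
   probability proportional to w(p) = Φ((p − 0.5)/0.234) folded about
   0.5 — a bell curve that prefers mid-range edges, since near-certain
   and near-impossible edges distinguish little between configurations.
   The current configuration with that edge's state flipped (repaired
   for transitivity, below) is accumulated, and becomes the new state
   with probability p_ij (flip to present) or 1 − p_ij (flip to absent).
   This walk concentrates on the high-mass region and finds the
   configurations that dominate both sums early.
2. **Uniform partition proposal.** An independent set partition drawn
   uniformly at random by Stam's method (draw the urn count u with
   P(u) ∝ u^n/u!, drop each super-node into a uniform urn), accumulated
   if new. This guarantees every valid configuration is sampled with
   equal probability in the limit and covers the long tail the local
   walk reaches slowly. Proposals are drawn over pinned super-nodes
   (below), so they never separate near-certain edges.

The two mechanisms are deliberately complementary: the local walk alone
leaves the tail uncovered (measured: mean relative errors of several
percent on 6–7-node graphs after 5000 iterations), while uniform
proposals alone miss high-mass configurations at random with heavy-tailed
consequences. Together, measured on the standard protocol (below), the
worst mean relative error over 3–7-node graphs at 5000 iterations is
~0.03%, and 8-node graphs sit at ~1–4% at 5000 and under 2% at 7500.

**Pinning.** Edges with p_ij ≥ 0.99 (configurable) are fixed present and
reported as 1; nodes linked by pinned edges behave as one super-node.
Pinned edges contribute a constant factor to every configuration, which
cancels in N_ij / N_g, so they are treated as probability exactly 1.

**Transitivity repair.** The state is stored as a block-label array (one
clique label per node), so every accumulated configuration is transitive
by construction. Flipping an edge to present merges the two blocks
(clique closure). Flipping (i, j) to absent splits their block: all
non-pinned edges of the block are notionally cleared; the pinned
sub-cliques containing i and j seed the two sides S_i and S_j; every
other surviving sub-clique joins the side to whose anchor it has the
higher mean probability (whole blocks at a time), then remaining single
nodes, visited in seeded random order, join the side whose current
members they match better on average; exact ties are settled by a fair
coin from the run's generator. If i and j are themselves linked by
pinned edges the block cannot be split and is left intact.

**Termination.** Convergence is declared when every per-edge estimate
changes by less than 1e−11 for 5000 consecutive iterations — with
deduplicated accumulation the estimate moves only when a new
configuration is found, so this reads "no new probability mass for 5000
iterations". Runs are additionally bounded by a wall-clock cap (default
120 s per component, checked every iteration) and an optional iteration
cap. Identical seed and configuration give bit-identical trajectories;
numerical accumulation is in linear space relative to the initial
configuration's probability, so the common scale cancels and large
components cannot underflow.

**Accuracy protocol.** The standard validation draws random graphs with
i.i.d. Uniform(0, 0.99) edge probabilities, computes exact conditionals
by enumeration, runs the sampler 25 times with distinct seeds, and
reports δ = mean over edges of |ṗ − p̂|/ṗ × 100 at fixed iteration
counts, averaged over runs (pinned edges excluded — they are not
estimated). This is what `scripts/acceptance.py` and the acceptance
tests recompute. Note one property of δ worth remembering when reading
results: it is a *relative* error, so edges with tiny ṗ dominate it long
before they matter for calling decisions.

## LOD calibration

The upstream caller's LOD score is the base-10 log likelihood ratio of
one shared haplotype versus none. With prior odds O = ε/(1 − ε) and
posterior odds o = O·10^lod, the theoretical conversion is p = o/(1+o)
(`mode="odds"`). The default `mode="curve"` instead uses a rational
curve of the same form fitted to the observed LOD-versus-true-positive
relationship on array-scale simulated data:

    p = (2o + a·f)/(o + f),   f = ε·10³/0.997 − ε·10³,
    a = (1 − lod)³/7 for lod ≤ 1, else −0.15.

The prior ε = 0.0046 is the genome-average proportion shared IBD between
random pairs in that reference simulation; it is also the probability
assigned to pairs with no call at all, which keeps every configuration's
probability positive and every edge sampleable. The raw curve exceeds 1
above roughly lod 0.5 (its printed asymptote is 2); outputs are clamped
to [ε, 0.999]. The upper clamp preserves the sampler's pin-at-0.99 rule
while keeping probabilities strictly inside (0, 1). The clamped curve is
monotone on the working LOD range (verified on a grid — the a-term makes
a small downward step at lod = 1, but both sides are already clamped
there).

Because the fitted constants reflect one simulated demography, a third
mode rebuilds the conversion empirically from labelled calls: calls are
grouped into equal-count LOD bins, per-bin true-positive fractions are
made non-decreasing by isotonic regression (pool-adjacent-violators,
weighted by bin counts), and the result is interpolated piecewise
linearly and clamped like the fitted curve.

## Regions, merging, inferred segments

Input segments use the tab-delimited pairwise dialect (sample, haplotype
index 1/2, chromosome, 1-based inclusive bp interval, LOD). Internally
intervals are half-open after adding 1 to ends; outputs convert back.
Centimorgan lengths come from linear interpolation on a genetic map
(PLINK `.map` or chromosome/bp/cM columns); without a map a constant
1 cM/Mb is assumed, matching the uniform 1e−8 per-bp recombination rate
of typical simulated data.

The genome is cut at breakpoints — the unique starts and (end+1)s of all
segments — because the IBD graph is constant between consecutive
breakpoints and any finer analysis would be redundant. Within an
interval, called pairs get calibrated probabilities (a pair covered by
several calls keeps the maximum), connected components of called edges
are found, and uncalled pairs *within* a component get ε. Components are
independent problems: conditioning factorises across them exactly, so
cross-component pairs are never instantiated. Components with at most 8
nodes are conditioned exactly; larger ones by sampling under the time
cap; a lone pair is left unchanged (conditioning on itself is the
identity). Components larger than 200 nodes are processed but logged
prominently — the time cap, not a size cutoff, is the guard.

Per-region results are merged back per haplotype pair: adjacent or
overlapping pieces whose probabilities pass the threshold (default 0.99)
fuse into one segment carrying the maximum probability; pieces below the
threshold are emitted as-is, one per region, carrying their updated
probabilities. For an uncalled pair whose conditional passes the
threshold, a new segment is emitted spanning the intersection of its
component's member-segment intervals — the graph carries no sequence
evidence, so IBD can only be localised to where every supporting call
overlaps — and flagged `inferred`. Every member segment covers the
analysis interval, so the intersection is never empty. The final report
filter keeps calls of at least 0.5 cM by default; all thresholds are
configurable.

Component seeds are spawned deterministically from the run seed in
region/component order, so the whole pipeline is byte-reproducible.

## Synthetic data

The generator emulates, at segment level, the statistical structure of a
pairwise caller's output over a cohort, for testing the graph machinery:

* **Truth**: clique events Poisson in position (default 2 events/Mb on a
  30 Mb chromosome, 200 haplotypes), clique sizes uniform on 2–8,
  segment lengths exponential with mean 0.8 cM redrawn below the 0.1 cM
  truth floor, 1 cM/Mb throughout. All pairs of a clique share the event
  interval, and positionally overlapping events never share haplotypes,
  so the implied truth graph is a union of cliques at every locus.
* **Calls**: each true pairwise segment is emitted with a probability
  that rises logistically with length (≈0.5 at 0.3 cM, >0.99 above
  0.8 cM), endpoints jittered (normal, 0.02 cM), LOD increasing in
  length with noise (3·cM ± 0.5, floored at 0.1); false calls arrive as
  a Poisson background (0.5/Mb) on random pairs with short exponential
  lengths and low LODs.

What passing tests on these data do **not** show: robustness to linkage
disequilibrium, demography-dependent haplotype frequencies, correlated
phasing errors, or a miscalibrated LOD curve — none of which the
generator models. They do show that incomplete cliques are completed,
non-IBD pairs are left alone, inferred segments stay inside their
evidential interval, and the pipeline is deterministic.

## Evaluation metrics

Segment metrics separate truth-indexed from prediction-indexed
denominators: power is the mean covered proportion of true segments
(≥0.1 cM), tabulated by true-segment size; the error rate is the
fraction of predicted segments intersecting no truth ("intersect" = ≥1
shared bp on the same haplotype pair — the weakest faithful reading);
the false-discovery rate is reported in both circulating variants (mean
uncovered proportion, and the binary no-overlap fraction), clearly
separated; the TP50 rate is the fraction of predictions with ≥50% of
their length covered. Size bins are left-closed, labelled by lower edge,
0.1 cM steps from 0.5 cM by default. Clique metrics report, per
true-clique size bin, the mean fraction of within-clique edges recovered
and, per predicted-component size bin, the mean fraction of predicted
edges joining nodes no true clique puts together.

## Design notes and limitations

* The sampler's proposal schedule (local walk + uniform proposals) is a
  design choice validated against the enumeration oracle; the estimator
  itself (deduplicated mass accumulation) is what carries the
  convergence guarantee. Accumulating duplicate visits instead would
  bias the estimate toward the walk's stationary distribution — on the
  3-node worked example that limit is 0.476 rather than 0.324 — which is
  why revisits are discarded.
* Memory grows with the number of distinct configurations visited (one
  hash key each); the iteration and time caps bound it in practice.
* A single miscalibrated near-certain call is enough to pin two cliques
  together, and every cross pair then inherits probability 1. This is
  the method's intended behaviour under its inputs, but it makes the
  0.99 pinning threshold and the calibration's upper clamp (0.999) a
  coupled pair: the clamp must stay above the threshold for pinning to
  engage at all, and both defaults follow the production settings.
* The 3-node family p12 = p13 = a, p23 = b shows the conditional of the
  weak edge is U-shaped in a, not monotone: weak shared edges first
  "explain away" the pair before strong shared edges pull it together.
  Tests assert the rising branch (a ≥ 0.5).
* Problem sizes in the test-suite experiments (4 Mb chromosomes, 40–60
  haplotypes, 25-run convergence protocols on 3–8-node graphs) were
  chosen to exercise every code path at desk scale while keeping the
  suite around a minute; the defaults baked into the generators are the
  larger study-scale values quoted above.
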