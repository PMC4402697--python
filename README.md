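# pigs — probabilistic IBD graph sampling

Clique-aware conditioning of pairwise identity-by-descent (IBD)
probabilities.

## The problem

Pairwise IBD callers (Refined IBD, Germline and relatives) estimate, for
each pair of haplotypes independently, the probability that the pair
shares a segment inherited from a common ancestor. But IBD at a locus is
(almost) an equivalence relation: if haplotypes *a*~*b* and *b*~*c* share
a common ancestor there, then *a*~*c* do too. A valid IBD graph is
therefore a disjoint union of cliques — and pairwise callers throw that
structure away. The cost is power, especially for short segments: a pair
called with low confidence may in fact be embedded in a clique of
confidently called pairs, which makes its IBD status near-certain.

`pigs` takes the pairwise output and updates every edge by conditioning
on all edges simultaneously under the cliques-only constraint. It is
aimed at people building IBD-based analyses — IBD mapping, clique
calling, relatedness screens — on top of a pairwise caller's output.

## The model

At one locus, build the probabilistic IBD graph *G_P* = (N, P): one node
per haplotype, each unordered pair carrying the marginal probability
*p_ij* that the pair is IBD (calibrated from the caller's LOD score;
never-called pairs get the genome-wide prior ε = 0.0046). Edges are
treated as independent, so a proposed IBD graph *g* with edge indicators
*e_ij* has probability

    P(g | G_P) = ∏_{i<j} p_ij^{e_ij} (1 − p_ij)^{1 − e_ij}.

Let *V* be the set of *transitive* configurations (every connected
component a clique — equivalently, set partitions of the nodes; there
are Bell(n) of them). The updated probability of an edge is its
conditional probability given that the true graph lies in *V*:

    ṗ_ij = Σ_{g ∈ V, e_ij ∈ g} P(g | G_P) / Σ_{g ∈ V} P(g | G_P).

For up to 12 nodes this is computed exactly by enumerating set
partitions. Beyond that, a seeded Monte-Carlo procedure discovers
transitive configurations — by a weighted local walk with transitivity
repair plus uniform random partition proposals — and accumulates each
distinct configuration's probability once into running sums *N_g* and
*N_ij*, estimating ṗ_ij = N_ij / N_g.

Around the core sits the full pipeline: LOD→probability calibration,
breakpoint regions (intervals over which the IBD graph is constant),
per-component conditioning, merging of per-region results (maximum
probability, threshold 0.99), and emission of newly *inferred* segments
for pairs the caller never reported, localised to the intersection of
their component's segment intervals.

## Worked example

```python
from pigs import IBDGraphModel, ProbabilisticIBDGraph

G = ProbabilisticIBDGraph([1, 2, 3], {(1, 2): 0.9, (1, 3): 0.9, (2, 3): 0.1})
res = IBDGraphModel(G).fit()
print(res.summary())
```

```
Probabilistic IBD graph conditioning
====================================================
nodes: 3    edges: 3    method: exact
----------------------------------------------------
edge                             prior     cond.
1 - 2                           0.9000    0.6403
1 - 3                           0.9000    0.6403
2 - 3                           0.1000    0.3241
----------------------------------------------------
* edge at or above the pinning threshold (reported as 1)
```

Two strong edges and one weak edge cannot all be right at once: the weak
pair 2–3 is pulled up from 0.10 to ṗ = 0.324 (transitivity makes its
presence much more plausible), while the strong edges drop from 0.90 to
0.640 (the weak edge casts doubt on the triangle). The five transitive
3-node graphs carry total mass 0.253, of which 0.082 contains edge 2–3:
0.082 / 0.253 = 0.324.

The same machinery from the shell, end to end:

```sh
pigs simulate --out demo --seed 7 --n-hap 60 --length-mb 5
pigs run --ibd demo.calls.ibd --out demo.updated.ibd --seed 1
pigs evaluate --pred demo.updated.ibd --truth demo.truth.ibd --out report.tsv
```

`pigs run` writes the updated segments (plus a probability column and an
inferred flag), a per-component convergence log and a JSON provenance
record with the seed and configuration.

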