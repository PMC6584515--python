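# Methods

This note documents the models implemented in `pdprank`, the numerical
choices behind them, what the synthetic generator does and does not
emulate, and the design decisions taken where the design was genuinely
open. It states no empirical number that the test suite or
`scripts/acceptance.py` does not itself compute.

## The smoothing model

The substrate is an undirected weighted graph G = (V, E, w) whose nodes
are genes and whose edge weights w_uv ∈ (0, 1] are posterior
probabilities of a tissue-specific functional interaction. Given curated
positives C (f ≡ 1) and negatives C̄ (f ≡ 0), the scores of the unlabeled
nodes U = V ∖ (C ∪ C̄) minimize the quadratic smoothness energy

    ½ Σ_{(u,v)∈E} w_uv (f(u) − f(v))²

with the labeled values fixed. The minimizer is harmonic: each unlabeled
score equals the weighted average of its neighbors' scores. Collecting
the unlabeled nodes into a vector, the fixed point satisfies f = M f + c
with

    M_uv = w_uv / (λ + d_u)  for u, v ∈ U,
    c_u  = (Σ_{v ∈ N_u ∩ C} w_uv) / (λ + d_u),

where d_u = Σ_{v∈N_u} w_uv is the weighted degree and λ ≥ 0 is the weight
of a virtual edge from every node to an always-negative sink. The three
method variants are assembled from this one system:

* **SinkSource** — λ = 0, negatives used.
* **SinkSource+** — λ > 0, negative labels discarded (their nodes are
  scored as unlabeled); all negative influence comes from the sink.
* **Pseudo-SinkSource+** — λ ≥ 0 and negatives used; λ = 0 recovers
  SinkSource exactly.

The numerator of c is implemented as the *weighted* sum of edges to
positives, which is the fixed point of the harmonic update; the
count-of-positive-neighbors reading (which coincides with it on
unit-weight graphs) is available as `eq8_count=True`.

### Solvers

Two backends are provided and must agree.

* **Iterative** (default, the field-standard procedure): Jacobi iteration
  f_t = M f_{t−1} + c from f₀ = 0.5, stopping when the L1 change
  Σ_u |f_t(u) − f_{t−1}(u)| over the unlabeled nodes drops to ε (default
  0.001) or after `max_iter` (default 500) iterations. Labeled nodes are
  constant, so this residual equals the sum over all of V. The update is
  a sub-convex combination of values in [0, 1] plus nonnegative source
  mass, so every iterate stays in [0, 1]; the iteration contracts
  whenever every unlabeled node either feels the sink (λ > 0) or lies in
  a component containing a label.
* **Direct**: sparse LU solve of (I − M) f = c. This is the exact fixed
  point and serves as the oracle for the iterative solver in the tests;
  both are exposed because the direct solve is preferable for repeated
  small systems and the iterative one for large sparse networks.

All accumulation is double precision; M is CSR.

### Degenerate inputs

At λ = 0, an unlabeled node in a connected component containing no
labeled node (isolated nodes included) can never receive label mass; its
harmonic value is undetermined and (I − M) is singular on its block.
These nodes are detected at system-build time by connected components,
**frozen at their 0.5 initialization**, excluded from the linear system,
and reported in `ScoreVector.frozen`. This matches what the iteration
would do (0.5 is its fixed point there), keeps the direct solve
nonsingular, and makes the two backends agree on every input. With λ > 0
no node is frozen: an isolated unlabeled node then scores 0 (pure sink).

### Parameters that matter

| parameter | meaning | default | notes |
|---|---|---|---|
| λ | sink edge weight (dimensionless, same units as w) | method-specific; 1.0 in PDP runs | divides scores by (λ + d_u); large λ ranks by raw positive-adjacent weight |
| ε | L1 convergence threshold | 0.001 | per the standard procedure; tests tighten it to 1e−9+ when comparing with the oracle |
| max_iter | iteration cap | 500 | the threshold is reached well before this on all shipped fixtures |
| ω | supernode spoke weight (multilayer) | 1.0 | uniform ω makes f(v₀) the plain mean of the copies |
| l | layer count | 2 | must satisfy 2 ≤ l ≤ min(|C|, |C̄|) |

## Multi-layer construction

`build_multilayer_graph` makes l exact copies of G, partitions the
positives and negatives independently, uniformly at random (seeded), into
l near-equal parts — each label lives in exactly one layer and the node's
other copies are unlabeled — and adds one supernode v₀ per base node,
connected to its copies v₁..v_l with weight ω. Pseudo-SinkSource+ runs on
the expanded graph and each base node's final score is f(v₀).

Two choices here were genuinely open:

* **Partition rule.** Stratified-by-class seeded random splitting; the
  source material does not specify a rule, and stratification guarantees
  every layer carries both classes (enforced by the l ≤ |C|, l ≤ |C̄|
  precondition).
* **Sink placement.** The sink attaches to the copy nodes only. Attaching
  it to supernodes as well would turn f(v₀) into the copy average damped
  by ωl/(λ + ωl), breaking the defining property that a gene's final
  score *is* the (ω-weighted) average of its copies; the uniform
  treatment is available via `sink_on_supernodes=True` for comparison.

On the shipped fixture the layer mechanism *reduces* the low-degree bias
even at λ = 0 — a decoy's supernode averages its labeled-layer copy
(score 1) with a strictly smaller unlabeled-layer copy — so the
literature's report of a *worse* λ = 0 bias for the multilayer method is
fixture-dependent and is not asserted by the tests; likewise the
aggregate "layers correct more than the sink alone at λ = 1" is a
near-tie at this fixture's scale. What the tests assert is the forced
per-node mechanism: every decoy scores below 1 under the multilayer
method at λ = 0, and below its Pseudo-SinkSource+ score at λ = 1.

## PDP scoring

With disease sets (C_D, C̄_D) and process positives C_P, two runs share
the disease negatives:

    f_D = learn(G, λ, C_D, C̄_D),  f_P = learn(G, λ, C_P, C̄_D),

and candidates are ranked by g(v) = f_D(v)·f_P(v). At λ = 0 this gives
g = 1 on C_D ∩ C_P, g = f_P on nodes labeled only in D, and g = f_D on
nodes labeled only in P. f_D and f_P are optionally normalized by their
maximum over a reference set (default: all nodes, a no-op when positives
are fixed at 1; narrower references may push other scores above 1 — no
clipping is applied, the reference is the caller's statement of what
"full score" means). g itself is never normalized. Ranking uses full
precision with a deterministic tie-break (g desc, f_D desc, f_P desc,
gene id asc). The union baseline f_{D∪P} pools the positives into one
run; every pooled positive is fixed at 1, so the union ranking cannot
distinguish dual-relevance among labeled genes — the contrast that
motivates the product score.

## Evaluation harness

* **CV**: stratified k-fold (default k = 5) hiding one fold of each class,
  repeated (default 10 times, 50 AUCs) with fold seeds derived from one
  master seed via a seeded integer stream. The smoother only ever sees
  the train assignment (asserted structurally in the tests).
* **AUC**: Mann–Whitney convention (ties half-credited), computed by
  scikit-learn; ties are common at λ = 0 where many scores are exactly 1.
* **Welch's t-test**: scipy's unequal-variance t-test, two-sided or
  one-tailed; raw p-values, no multiple-testing correction.
* **Degree-rank profile**: nodes sorted by score (deterministic
  tie-break), per-rank unweighted degree, centered moving average
  (default window 15, shrunk at the boundaries), and the mean degree of
  the first m unlabeled nodes (default m = 100) as the headline bias
  statistic.
* **Control negatives**: uniform random draws, and degree-matched draws
  that preserve the template's unweighted-degree histogram in log2 bins
  ({1}, {2,3}, {4..7}, …) — exact degree matching is usually infeasible,
  and log-binning is the standard relaxation for heavy-tailed degree
  distributions. Sampling is without replacement within bins; an
  undersized bin is an error naming the bin.

## Synthetic worlds

The generator emulates only the structural assumptions the methods
exploit; a green test on it establishes solver and harness correctness,
not performance on real tissue networks (no heavy-tailed degrees, no
edge-weight calibration, ~500 nodes vs tens of thousands).

* **Default world** (`FixtureSpec()`): 500 nodes, one planted community
  of 100 with within-density p_in = 0.15 over a background density
  p_out = 0.01, edge weights uniform on (0.15, 1.0] (mirroring a
  posterior cutoff at 0.15), 40 positives inside the community, 80
  negatives in the background, and 20 unit-weight degree-1 decoys wired
  to random positives. Positives cluster, negatives are dispersed and
  "clean", decoys exercise the low-degree bias. Sized so repeated CV
  runs in seconds.
* **Disease-like world** (`FixtureSpec.disease_like()`): adds a second
  100-node community holding the negatives, coupled to the positive
  community with p_cross = 0.10. This is the structural reading of
  "curated negatives carry signal": hard negatives sit near the
  positives, so discarding them (SinkSource+) or blurring multi-hop
  structure (large λ) costs measurable AUC. These densities were fixed
  a priori as the stated condition, not tuned to test outcomes.

All randomness flows from one master seed through
`numpy.random.SeedSequence(seed).spawn(4)`: stream 0 seeds the block-model
topology, stream 1 the edge weights, stream 2 the label draws, stream 3
the decoy wiring. Fixtures are bit-reproducible.

## Known limitations

* Scores of labeled nodes are fixed; an unlabeled gene can never outrank
  a positive within one run (GeneMANIA-style relabeling is out of scope).
* λ is a free parameter; the package offers no automatic selection rule.
* The multilayer partition is one random draw; averaging over partitions
  is left to the caller (run with several seeds).
* File formats are deliberately minimal: whitespace-separated edge lists
  and one-gene-per-line sets, with `#` comments. Building the networks
  themselves (e.g. tissue-specific posterior estimation) is out of scope.
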