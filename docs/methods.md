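# Methods

## Scope and model

`lcpnet` scores the *existing* edges of a simple undirected, unweighted
graph (link reliability). The scorers also accept absent pairs (the
decomposition records the mode), but no candidate-pair enumeration is
provided: large-scale link prediction, directed/weighted/bipartite graphs,
and the computation of GO semantic similarity from ontology files are out
of scope — similarity matrices are consumed precomputed (e.g. Wang
similarity from GOSemSim).

## Neighbourhood decomposition

For a pair (x, y), common neighbours are CN = N(x) ∩ N(y); per common
neighbour i, iLCL(i) = |N(i) ∩ CN|, eLCL(i) = |N(i)| − iLCL(i) − 2 (the 2
are i's links to the seeds — exact because a common neighbour is adjacent
to both), and nLCL(x) = |N(x)| − |CN| − [edge present]. The evaluated link
itself is counted in neither nLCL term: using the link under test as
evidence about itself would be circular, and the identity
|N(x)| = nLCL(x) + |CN| holds in prediction mode where the link is absent.
The arithmetic shortcut for eLCL is verified against a raw set-membership
scan in the tests. Multiple disjoint communities attached to the same
seeds need no special handling — all counts are taken over the union of
common neighbours; a single common neighbour is a degenerate one-node
community with iLCL = 0.

## Index conventions

- **AA** uses the natural logarithm; the base is configurable
  (`aa_log_base`) since the index is sometimes quoted in other bases.
  **CAA** uses log base 2, exactly as that index is defined.
- **JC/CJC** denominators are the literal union |N(x) ∪ N(y)|; on an
  existing edge this union contains x and y themselves. Documented so
  prediction-mode users are not surprised.
- **C1\*/C2\*** with nLCL(x) + nLCL(y) = 0: the denominator is taken as 1
  (score = numerator). Zero non-community links is maximal isolation —
  the most favourable configuration — and the penalty term simply
  vanishes; dividing by zero is undefined. The exponent (default 2, the
  value at which the binomial cross-term 2·nLCL(x)·nLCL(y) best penalises
  doubly-outward-pointing seed pairs) is exposed as a parameter to support
  exponent sweeps from 1 to 7.
- **FSW** follows its original formulation: the product of two directed
  ratios over neighbour sets that include the node itself, with pseudo-
  count λ_v = max(0, n̄ − (|S_v∖S_other| + 2|S_x∩S_y|)) where n̄ is the
  network's mean degree; **ACD** uses λ_v = max(0, n̄ − |N(v)|) and reduces
  exactly to SCD when every seed degree is at least n̄. Both are validated
  by internal properties (range, symmetry, the SCD reduction) and by the
  brute-force oracle, since no hand-derived constants exist for them.
- **IG1** (1 + the number of neighbourhood nodes whose only interaction is
  with a seed) is a generality count: *low* is reliable. The score table
  stores the raw value and ranks IG1 ascending; every other method ranks
  descending. Ties always break by lexicographic (min-node, max-node)
  edge identifier, making every ranking bit-reproducible.

## LCP-correlation

Pearson correlation (Spearman available) over edges between the
common-neighbour count and the count of links among the common
neighbours. When either vector is constant (triangles-only or
triangle-free degenerate networks) the result is an explicit "undefined"
profile rather than a NaN. Classification: ≥ 0.7 LCP, ≤ 0.3 non-LCP,
otherwise "intermediate" (empirically rare).

## Evaluation framework

Truth labels come from similarity channels in [0, 1]. The conservative
combined channel is the element-wise **minimum** of BP and CC — an
interaction must share biological process *and* cellular component — and
a label is true when similarity is **strictly** above the threshold
(default 0.5; exactly 0.5 is unreliable). MF channels are accepted but
excluded from the combined label by default, because shared molecular
function is weak evidence of physical interaction; per-channel evaluation
remains available by passing a single channel.

- **Precision curve**: precision of the top `step`, 2·`step`, … ranked
  interactions (default step 10; step 1 for fine curves); a final partial
  window is included. **AUP** is the arithmetic mean of the points —
  equivalently the rank-normalised area — chosen because it is robust to
  the step size; whether the area should instead integrate over absolute
  rank is genuinely open, and the normalised convention is used
  throughout.
- **Recall curve**: recall TP(k)/P at ranks k = 1…P (P = positives),
  x-axis normalised by P, trapezoidal area from the origin. This is the
  one convention under which the best possible ranking scores exactly
  AUR = 0.5 at any prevalence, hence sAUR = 2·AUR ∈ [0, 1].
- **AUPR**: average precision (mean of precision@k over positive ranks),
  the standard non-interpolated estimator; trapezoidal interpolation over
  (recall, precision) was rejected as ambiguous at ties. Note the exact
  expectation under a random ranking is
  (P−1)/(N−1) + H_N(N−P)/(N(N−1)) — prevalence plus a positive
  O(log N/N) finite-list bias; the test suite checks against this closed
  form.

## Input curation

Interactome files arrive as two-column TSV edge lists or binary adjacency
matrices (dense CSV or MatrixMarket, optional label sidecar). Parsing
drops self-loops and collapses duplicate/reversed edges with warnings,
ignores weight columns (all indices are binary-topology functions), and
OR-symmetrizes asymmetric matrices. `curate()` removes small isolated
components, on which neighbourhood indices are uninformative; published
curation practice states no universal cutoff, so the default keeps only
the largest connected component and `min_component_size` makes the choice
explicit.

## Synthetic benchmark generator

`planted_benchmark()` emulates the premise that true interactions
concentrate in dense, topologically isolated protein complexes. Defaults:
10 complexes of 8 nodes, intra-complex edge probability 0.9, 5 genuine
inter-complex bridges, 30 random inter-complex false-positive edges, and
BP/CC similarities drawn uniform(0.55, 1) for genuine edges and
uniform(0, 0.45) for contaminants — the 0.05 margin around the strict 0.5
threshold avoids boundary flakiness — with 10% of edges having both
channels flipped across the boundary (annotation noise). The bridge count
is a small fraction (~2%) of edges, reflecting that genuine inter-complex
contacts exist but are rare. One integer seed drives all randomness.

What the generator does *not* emulate: scale-free degree distributions,
overlapping complexes, correlated noise between BP and CC, and the size
(10³–10⁴ nodes) of real interactomes. Tests passing on these benchmarks
show the machinery is correct and that community-aware indices beat
community-blind ones under the planted-complex premise; they do not
certify performance on any real interactome.

## Numerical and size choices

All scorers are exact rational/log arithmetic in double precision;
equivalence with a brute-force set-enumeration oracle is asserted to
1e-9 across random graphs (G(n, p), n ≤ 60 — sizes at which the oracle is
exhaustive yet the whole suite runs in seconds). Stochastic tests fix
their seeds. Fuzz suites use 200 G(50, 0.1) graphs for the
degree-conservation identities, 100 random graphs for oracle
equivalence, 50 perturbation trials for the monotonicity of the
local-ring automata, and 20 generator seeds for the benchmark-ordering
and LCP-correlation claims.

## Known limitations

- Scoring is O(Σ_edges (deg_x + deg_y + Σ_{i∈CN} deg_i)) per method in
  pure Python; adequate for interactome-scale networks but not optimised
  for multi-million-edge graphs.
- The evaluation assumes truth labels exist for every scored edge;
  partially annotated networks must be subset first.
- IG2, IRAP and global/embedding-based reliability methods are not
  implemented.
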