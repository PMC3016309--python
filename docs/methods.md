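# Methods

## Model and assumptions

`cbpln` scores directed links between gene sets ("processes") on a weighted
undirected interaction network, in the context of one expression contrast.
The working assumptions are:

* The network `H = (V, E)` is simple (no self-loops, no parallel edges) and
  its weights `w(u,v) > 0` are interaction confidences; after the default
  rescaling (dividing STRING-style integer confidences by 1000) they lie in
  (0, 1] so that a single edge can contribute at most `s(u)·s(v)` to a score.
* Per-gene expression p-values are exchangeable evidence of perturbation;
  the score `s(g) = |log_b p_g|` uses base `b = 10` by default. The base is
  a display choice: empirical link p-values are invariant to it (it rescales
  observed and null scores identically), only reported magnitudes change.
  Genes with no measured p-value score 0 — absence of evidence contributes
  nothing. Zero p-values are floored at `1e-300` before the logarithm.
* Analyses are confined to the annotated universe `U` (genes in at least one
  set): the network is restricted to `U` and isolated nodes dropped before
  scoring, and `U` is the sampling frame for the randomizations and for the
  hypergeometric baseline.

For an ordered pair `(A, B)`, `N(A)` is the set of genes adjacent to
`G_A`-annotated genes but not themselves annotated with `A`, and
`N(A,B) = N(A) ∩ G_B`. The contextual linkage score is

    S(A,B) = Σ_{v ∈ N(A,B)} s(v)·f_A(v),
    f_A(v) = max over neighbors u of v with u ∈ G_A of w(u,v)·s(u),

with `f_A(v) = 0` when `v` has no scored source neighbor. `S` is homogeneous
of degree 2 in the scores and degree 1 in the weights, monotone in every
score and weight, and reduces exactly to `|N(A,B)|` at unit scores and
weights.

**Normalization.** `S_bg(A,B)` recomputes `S` after giving *every* gene the
mean score over measured genes in `U`; `S_norm = S − S_bg` (possibly
negative) removes what topology alone would produce. The averaging set is
measured-genes-in-`U`: unmeasured genes carry no evidence, and including
them at score 0 would deflate the background arbitrarily. Whenever
normalization is on, the same subtraction is applied to every null
replicate, with `S_bg` recomputed on that replicate's randomized
annotations or network — observed and null statistics are the same
functional.

## Significance

Two empirical null models, each run `R` times:

* **Gene-set randomization** applies one uniform permutation of gene labels
  on the gene–process bipartite graph per replicate. Every process keeps its
  size and any group of processes keeps its exact co-annotation counts. For
  a pair `(A, B)` the randomized collection replaces the *target* set `B`
  (the source set and network stay fixed); a configuration switch
  (`randomize_set="source"`) randomizes `A` instead, and results should
  always be reported together with this mode.
* **Network randomization** rewires the graph with degree-preserving edge
  swaps: `Q·|E|` attempts, each picking two edge slots, proposing one of the
  two endpoint rewirings with equal probability, and applying it only if
  neither candidate edge exists already or is a self-loop. Degrees, the node
  set and the weight multiset are preserved exactly; each surviving edge
  slot keeps its weight, so weights travel deterministically with the
  endpoint listed first. `Q = 100` attempts per edge is standard practice
  for this randomization family and is exposed in the configuration.

The empirical link p-value is the fraction of null scores **strictly
larger** than the observed score. The strict rule can return exactly 0
(e.g. when the observed score tops every replicate, or when a network
admits no valid swap and the null is degenerate at the observed value); a
`(count+1)/(R+1)` pseudo-count estimator is available behind
`pseudo_count=True` for users who need strictly positive p-values.
Benjamini–Hochberg adjustment (step-up, forced monotone in the raw-p
ordering, capped at 1) is applied per test across the family of ordered
pairs that passed the `K`-interactor filter; the filter runs *before*
testing so unstable small-count pairs do not consume the FDR budget. The
reported network keeps links whose adjusted p-value passes `fdr_alpha`
under **every** configured test.

**Seeding.** All randomness flows from one master seed. Per-pair null
streams derive from `(seed, test, source, target, replicate)`, so results
do not depend on evaluation order. The pipeline default is
*shared-replicate* mode: one randomized annotation set (or network) per
replicate is scored against all pairs at once — distributionally identical
per pair and orders of magnitude cheaper than per-pair randomization, at
the price of correlation between pair p-values within a replicate set
(`shared_replicates=False` restores fully independent per-pair streams).
Identical inputs and seed give byte-identical link tables.

## The context-free baseline

`cbpln.bpln` implements the neighborhood-count predecessor: the link
p-value of `(A, B)` is the hypergeometric tail probability of drawing
`|N(A,B)|` or more `B`-annotated genes when `|N(A)|` genes are drawn from
the universe. Because `N(A)` by construction excludes `A`-annotated genes,
the default sampling frame is `U \ G_A` with successes `G_B \ G_A`
(`population="exclude_source"`); `population="universe"` is available, and
the choice is deliberately explicit rather than silent. Note that the
empirical gene-set randomization draws the replacement target set from all
of `U`, so its exact analytic law on single-annotation data is the
hypergeometric with population `|U|`, successes `|N(A)|`, draws `|G_B|` —
and the strict "larger than" rule estimates the strict tail `P(X > obs)`;
the convergence checks in the test suite use precisely that law.

## Configuration defaults

| parameter | default | meaning |
|---|---|---|
| `permutations` (R) | 10000 | null replicates per test |
| `swap_multiplier` (Q) | 100 | swap attempts per edge |
| `fdr_alpha` | 0.01 | BH cutoff per test |
| `min_interactors` (K) | 10 | minimum `N(A,B)` to test a pair |
| `log_base` | 10 | base of the perturbation score |
| `pvalue_floor` | 1e-300 | replaces p = 0 before the log |
| `weight_min` / `weight_scale` | 500 / 1000 | raw-confidence threshold and divisor at read time |
| `normalize` | true | subtract the average-expression background |
| `tests` | geneset, network | both null models; links must pass all configured tests |
| `randomize_set` | target | which set the annotation permutation replaces |
| `shared_replicates` | true | one randomization per replicate scored against all pairs |
| `pseudo_count` | false | `(count+1)/(R+1)` empirical p-values |

## Synthetic benchmark

The generator (`cbpln.simulate`) emulates the three inputs with a known
ground truth. Defaults: a 500-gene pool; 9 processes of 25–40 genes with
~10% of each set drawn from already-annotated genes (pairwise overlaps stay
below 20%); background edges drawn independently at probability 0.02 with
STRING-style integer weights uniform in {500..1000} (stored /1000); 5
planted process pairs, each realized as cross-edges at probability 0.3
between the two sets' genes, with high weights in {900..1000}; genes
incident to planted edges receive expression p-values uniform on
(0, 0.001), all other genes uniform on (0, 1). Planted pairs are re-drawn
(bounded retries) until both directions have at least `K = 10` linking
genes. The background edge probability (0.02) is set so that typical
non-planted ordered pairs also clear the 10-interactor filter and the
benchmark actually exercises the multiple-testing machinery (>= 50
non-planted candidate pairs).

Three design points matter for interpreting recovery results:

* **The truth is bidirectional.** Planted cross-edges are undirected and
  perturb both endpoint sets, so each planted pair is genuine signal in
  both directions; the truth records both ordered links (10 for the default
  5 pairs). One-directional fixtures are constructed separately (below).
* **Planted edges connect private genes.** Cross-edges only touch genes
  annotated with no third process. A dual-annotated gene would carry
  planted wiring and perturbation into its other processes and make the
  directed truth inseparable — early versions of the benchmark showed
  exactly that as irreducible "false" positives that were in fact real
  induced crosstalk.
* **No process joins more than two planted pairs.** A hub process
  concentrating many planted pairs owns so many heavy perturbed edges that
  degree-preserving rewiring builds fat null tails for each of its pairs,
  costing power for true links.

The **directional fixture** (`generate_directional_fixture`) plants a
one-way link: five hub genes of the source set wire densely (edge
probability 0.8, weights {900..1000}) into a 30-gene perturbed target set
over a very sparse background (edge probability 0.002). Read forward,
~30 target genes link to the source; read backward, only the hubs link
back, which stays below the 10-interactor filter — so only the forward
link can be called. This realizes one of the two mechanisms that make the
method's links directed (neighborhood-size asymmetry); the other is the
score asymmetry itself.

What the generator does **not** emulate: STRING's evidence channels and
transitivity structure, MSigDB's hierarchical redundancy between sets,
probe-level microarray noise, and correlation between expression p-values
of interacting genes. Passing benchmarks therefore demonstrates the
statistical machinery (calibration, FDR behavior, recovery of planted
wiring-plus-perturbation signal), not performance on any particular
organism's data.

## Numerical choices

* Scores and weights are float64 throughout; the score engine and the
  readable per-pair implementation agree to ~1e-12 relative and are
  cross-checked in the tests.
* Empirical p-values compare null and observed statistics with a strict
  `>`; exact ties count as "not larger" (they arise only in degenerate
  networks where swaps are impossible, or with constant scores).
* The edge-swap inner loop is JIT-compiled (numba) and uses a boolean
  adjacency matrix (n² memory: fine for the ~10⁴-node networks this
  package targets). Attempts drawing the same edge slot twice are no-ops.
* Degenerate inputs fail loudly: empty gene sets, networks that are empty
  after thresholding or after restriction to `U`, p-values outside [0, 1],
  and count inconsistencies in the hypergeometric all raise validation
  errors naming the offender.
* Deterministic output ordering (source, then target) and full-precision
  float repr make the link TSV byte-reproducible and round-trippable.

## Problem sizes used by the test and acceptance runs

The automated checks scale the study down so the whole suite runs on one
core in minutes: exact reductions and oracle comparisons use 90–250-gene
fixtures; analytic-convergence checks use R = 10000 (cheap in the
annotation-permutation algebra); type-I calibration uses a 12-process null
fixture at R = 1000 (~130 candidate pairs); planted-link recovery runs the
full default fixture over 10 seeds at R = 2000 — granular enough that
working raw p-values sit well below the 0.01 FDR band. These sizes are the
package's own benchmark choices; production runs on real networks should
keep the R = 10000 default.

## Known limitations

* Under gene-set randomization alone, any pair whose *target* set is
  heavily perturbed can look significant regardless of wiring (the null
  replaces the target with mostly-unperturbed random sets). The network
  test conditions on the annotations and perturbation and is insensitive
  to that axis; requiring both tests (the default) is what gives the
  method its specificity, and single-test runs should be interpreted
  accordingly.
* Shared-replicate mode makes pair p-values within one run positively
  correlated through the shared randomizations (and, regardless of mode,
  through the shared observed data); BH still controls FDR in the standard
  sense but the number of discoveries fluctuates more than independence
  would suggest.
* The strict empirical rule emits p = 0 at resolution 1/R; reported zeros
  mean "beyond the resolution of R replicates", not literal impossibility.
  Use the pseudo-count option when downstream tools cannot handle zeros.
* Scores ignore the sign of regulation; up- and down-regulated genes
  contribute identically. Alternative aggregations (e.g. sums instead of
  the max in `f_A`) are out of scope.
* Gene identifiers are matched verbatim across the three inputs; identifier
  mapping is upstream of this package.
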