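# Methods

## Model

The package ranks candidate lncRNAs for a disease by a random walk with
restart (RWR) on an lncRNA similarity network. Its working assumption is
guilt by association at the network level: lncRNAs with similar
functions tend to be associated with similar diseases. Two ingredients
depart from a classical association-seeded RWR:

1. the network is the **integrated similarity** of a Gaussian
   interaction-profile kernel and an (optional) precomputed functional
   similarity matrix, and
2. the **seed vector is similarity-derived**: lncRNAs without a known
   association to the query disease still receive seed mass from
   expression similarity to the disease's known lncRNAs and from the
   semantic similarity of the query disease to their own known diseases.
   This is what lets the walk score a disease with zero known lncRNAs.

### Disease semantic similarity

Each disease *A* carries a DAG `D(A)` — itself plus all ancestor terms
in a MeSH-like hierarchy (supplied as a `child<TAB>parent` edge file).
A term's contribution is its negative log DAG-frequency over the loaded
disease set: terms shared by every disease contribute 0, terms unique
to one disease contribute `log(n_diseases)`. The similarity is the
shared contribution relative to the total, which lies in [0,1], is
symmetric, and is invariant to the logarithm base (a ratio of log
sums); natural log is used for intermediates. The printed form of the
contribution carries a per-disease subscript, but its formula has no
disease dependence, so it is computed once per term and shared. When
both diseases carry zero total contribution (all their terms are
universal) the 0/0 ratio is defined by its limit: 1 for identical node
sets, else 0. "Number of diseases" means diseases present in the loaded
association data, not a global nomenclature.

### Expression similarity

Spearman rank correlation (average ranks on ties) between tissue
expression profiles, defined only when both transcripts are flagged
lincRNAs — expression compendia cover lincRNAs, not all lncRNAs — and 0
otherwise. A constant profile has undefined rank correlation; it is
treated as "no evidence" (similarity 0, with a warning), consistent
with the non-lincRNA rule. Negative correlations are preserved in the
ES matrix; they are only floored when they reach the seed vector,
because seeds are probabilities.

### Interaction-profile kernel and integration

`KL(i,j) = exp(−γ‖IP(i)−IP(j)‖²)` on the binary association rows, with
`γ = γ′ / mean‖IP‖²`. The normalization makes the bandwidth follow the
density of the association data; `γ′` defaults to 1.0, the convention
of the kernel literature this construction comes from. An all-zero
association matrix leaves the bandwidth undefined and is rejected.
Integration averages FS and KL on the set IF of lncRNAs covered by the
FS matrix (inferred from its row labels) and uses the kernel elsewhere;
without an FS file the pipeline runs in pure-kernel mode.

### Walk

`p_{t+1} = (1−r) W p_t + r p0` with `W` the column-normalized LS.
Defaults: restart `r = 0.9` (the value used across the random-walk
prioritization lineage this model extends), L1 cutoff `1e-10`,
`max_iter = 10000`. For column-stochastic `W` the iteration is an L1
contraction with factor `1−r`, so convergence at `r = 0.9` takes ~10
iterations; the stationary vector equals the direct linear solve
`r(I−(1−r)W)⁻¹p0`, which the tests use as an independent oracle.
All-zero columns of `W` (a lncRNA with no similarity support) are left
zero rather than filled uniformly — uniform filling would invent edges
the data does not support; the mass-conservation identity is asserted
only for fully stochastic `W`. Candidates (lncRNAs not already known
for the disease) are ranked by `p∞` with average ranks on ties; known
lncRNAs are reported separately, since a ranking that includes them
would only restate the input.

## Evaluation protocol

LOOCV holds out each known association in turn. The held-out pair is
removed **before** the kernel, the integrated similarity and the seeds
are computed (kernel refit per fold is the default; a switch disables
it for speed at the cost of leakage), and the held-out lncRNA is ranked
among the candidates — the lncRNAs with no remaining known association
to the disease, which now include itself. If masking leaves the seed
vector all zero, the walk would return the zero vector, so the fold is
assigned the expected random rank `(N+1)/2` over its `N` candidates and
flagged; pooled over many such folds this produces the characteristic
ROC step near FPR = 0.5 (exactly at 0.5 up to a `1/(2N)`
discretization).

ROC pooling across diseases with unequal candidate sets uses
rank-fraction thresholds `k ∈ [0,1]`: a fold is detected when
`rank/(N+1) ≤ k`, and its false-positive fraction is the share of its
own candidates at or above the same cut. Absolute-rank thresholds are
incomparable across diseases, and no single pooling is canonical, so
the closed-form rank-AUC `mean((N+1−rank)/N)` — the per-fold
probability that the held-out lncRNA outranks a random candidate — is
reported alongside; on equal candidate sets the two agree to the
trapezoid discretization.

## Synthetic benchmark

The generator makes the model's assumption true by construction:
lncRNAs and diseases are split into matching blocks; associations are
Bernoulli at density 0.6 inside a block over a 0.02 background; the
disease ontology is a rooted tree in which each block shares a recent
ancestor (the root, common to all, contributes zero, so between-block
semantic similarity is 0); expression profiles mix a per-block latent
tissue profile with noise at weight ρ = 0.8, giving within-block
correlation ≈ ρ. Defaults are 80 lncRNAs × 20 diseases × 22 tissues in
4 blocks with 80% of lncRNAs flagged lincRNA — a desk-scale analogue of
a curated association study (hundreds of associations, tissue-panel
expression). A single integer seed (split into independent streams per
generator) fixes every draw; identical configurations produce
byte-identical files.

What the benchmark does **not** emulate: real ontology depth statistics
(MeSH DAGs are deeper and multi-parented), scale-free association
degree distributions, correlated evidence between the association list
and the expression compendium, and any functional-similarity input.
Passing tests therefore show that the pipeline recovers planted
block-structured signal and is correctly calibrated at chance on
structureless data — not that it attains any particular accuracy on
real curated databases, which additionally depend on inputs (a
functional-similarity matrix among them) that are external to this
package.

## Numerical choices and degenerate inputs

- Empty max conventions: *score1*/*score2* over an empty set are 0 — a
  lncRNA with no evidence gets no seed mass.
- Seeds are clamped to [0,1]; known-association entries are exactly 1
  regardless of scores.
- Matrix text files carry 12 significant digits, bounding round-trip
  relative error at 5e-12.
- Identifier matching is case-sensitive with whitespace trimming;
  silent case-folding of curated disease names causes irreproducible
  merges.
- Tie ranks are average ranks everywhere (deterministic, and consistent
  with the `(N+1)/2` expected-rank convention for uninformative
  scores).
- A fold whose masked matrix has no associations at all skips the
  kernel entirely (its bandwidth would be undefined) and takes the
  fallback path; this is the 1-association corner case.

## Problem sizes

The default test and acceptance runs use the 80×20 planted benchmark
(~260 LOOCV folds, each refitting an 80×80 kernel and converging in
~10 walk iterations) and a 100×20 structureless control (~270 folds);
both complete in seconds on one CPU, chosen as the smallest sizes at
which the statistical checks (chance-level band, planted-signal
margin, permutation baselines) have comfortable resolution.

## Known limitations

- The functional-similarity matrix is an input; no miRNA-mediated
  similarity is computed here.
- Walks are seeded and run on the lncRNA side only; heterogeneous
  lncRNA–disease network walks are out of scope.
- Cyclic ontologies are rejected rather than repaired.
- The ROC pooling choice (rank fractions) is one of several defensible
  conventions; the rank-AUC is the pooling-free summary.
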