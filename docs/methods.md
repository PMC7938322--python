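# Methods

## Taxonomic similarity

Depths count nodes, with the root at depth 1. This convention makes the
Wu–Palmer formula well defined at the root (a pair of top-level concepts
whose lowest common subsumer is the root scores 2·1/(N₁+N₂) rather than
0/…) and gives sim(x, x) = 1 exactly. On a balanced tree with leaves at
depth D+1, two leaves whose lowest common subsumer sits at depth k+1
score (k+1)/(D+1) — a closed form the test suite checks for every k.

Ontologies with multiple inheritance (WordNet-style hypernym DAGs) are
accepted in edge-list form and reduced to a tree at load time: each node
keeps the parent lying on a maximal-depth root path, ties broken by
lexicographically smallest parent name, and every reduction is logged.
This *deepest-path* convention is a package choice — it preserves the
most specific available ancestry — not a property of any particular
ontology export. Newick input must label internal nodes, because
superordinate groups are named by internal concepts; branch lengths are
ignored.

The leaf set (the categories under analysis) is an explicit ordered
argument everywhere. It must be non-ancestral — no category may subsume
another — which guarantees off-diagonal similarities strictly below 1,
and its order is inherited by every matrix the pipeline produces, so a
silent permutation between the taxonomic and representational sides is
structurally impossible (alignment is still verified by name on every
comparison).

## Category representations

Stimulus responses are averaged per category (arithmetic mean, no
reweighting of unbalanced categories) and category pairs are correlated
across units. Pearson correlation is the default; a Spearman switch
ranks each pattern across units first. Activations are taken as loaded —
no rectification, centering or standardization — so the matrix reflects
the representation as given. A category whose mean pattern is constant
across units has no defined correlation; this raises an error naming the
category rather than propagating NaN into downstream statistics.

All correspondence statistics use strictly-lower-triangle entries only.
The diagonal (self-similarity, fixed at 1) would otherwise inflate every
correlation with a cluster of guaranteed-equal points.

## Correspondence at three granularities

- **Global**: correlation of the two lower triangles over all category
  pairs.
- **Coarse**: category similarities are averaged into superordinate-pair
  means (within-group means fill the diagonal but are excluded from the
  correlation, since the taxonomic diagonal is degenerate at 1), and the
  two superordinate-level matrices are correlated.
- **Fine**: within each superordinate group, the sub-triangles are
  correlated; groups with fewer than three categories or a constant
  taxonomic sub-triangle are skipped and logged; the mean over retained
  groups is unweighted.

No multiple-testing correction is applied across branches or
superordinates; the per-statistic pair counts are reported so users can
adjust externally. Significance is only computed for the structure test
below — the sampling distribution of a correspondence correlation under
a meaningful null would require a matrix-permutation scheme whose choice
we do not impose.

## Permutation structure test

The observed statistic is the variance of the lower-triangle RSM
entries. The null randomizes *category structure*: stimulus-to-category
label assignments are permuted as a block (category sizes preserved) and
the RSM is rebuilt per permutation, destroying any category-level
organization while leaving the activation distribution untouched. The
upper-tail p-value uses the add-one rule p = (1 + #{null ≥ obs})/(1+B),
so finite permutation counts never report p = 0 and the minimal
attainable p is 1/(B+1). If a permutation produces a degenerate
(zero-variance) pattern it is resampled once, then the test errors:
repeated degeneracy means the data cannot support the test. Fixing the
seed fixes the entire null distribution bit for bit.

Calibration: under exchangeable labels the p-values are super-uniform up
to the add-one discreteness; the acceptance suite verifies a rejection
rate within [0.03, 0.08] at nominal 5% over 500 independent noise
datasets (199 permutations each).

## Trajectories and plateaus

Stages are opaque ordered labels — no equal spacing is assumed. A series
plateaus at the first stage whose value is within epsilon of the final
stage's value; epsilon defaults to 0.05 (absolute, on the correlation
scale) and is configurable and reported. The rule is monotone in
epsilon (larger tolerance never yields a later stage), which the
property tests check.

## The synthetic generator

Each taxonomy node below the root at level l draws an independent
Gaussian feature vector across units with standard deviation
`level_sd[l]` (default 1 for all levels). A category prototype is the
sum of draws along its root path, excluding the root so there is no
global offset shared by all categories; stimuli add independent Gaussian
noise (`noise_sd`, default 0.5 — half the ancestral scale, i.e. a
signal-dominated regime appropriate for category-mean analyses with ~10
stimuli per category). Two categories sharing k of D ancestral levels
then have prototype correlation (Σ_{l≤k} sd_l²)/(Σ_{l≤D} sd_l²) = k/D
for equal sds — an increasing function of Wu–Palmer similarity on a
balanced tree, which is exactly the structure the analysis is designed
to detect. The default problem size (depth 4, branching 3, 200 units,
81 categories, 10 stimuli each) keeps every simulation in the test suite
and acceptance script in the seconds-to-a-minute range on one CPU while
leaving per-pair correlation noise (~1/√200) well below the signal
spread.

**Dynamics.** Stage t scales the level-l contribution by
α_l(t) = A_l·(1 − exp(−t/τ_l)). All stages share one set of underlying
draws — only the scalings change — so a trajectory reflects the smooth
evolution of one system rather than independent re-simulations. Choosing
τ non-decreasing with depth produces the coarse-before-fine emergence
pattern: between-group structure, carried by shallow levels, saturates
first. The default experiment uses τ = (0.5, 1, 4, 4) over stages
0.25…32.

**Task granularity.** A_l = 1 for levels l ≤ g (the deepest level the
simulated objective discriminates) and A_l = λ (default 0.2) beyond.
One structural fact matters for experiment design: level-D (leaf-level)
contributions are never shared between two distinct categories, so
attenuating them removes no pairwise information — it only shrinks the
denominator of every correlation and can slightly *raise* fine
correspondence. The task-granularity experiment therefore runs on a
depth-5 binary taxonomy with superordinates at level 2 and probes
g ∈ {4, 3, 2}, where each decrement attenuates a level that carries
within-superordinate structure (levels 4 and 3), with the untruncated
g = D run as the coarse-stability reference. It uses a noisier regime
(noise_sd = 2, four stimuli per category) so that λ-attenuated levels
fall below the measurement noise rather than remaining comfortably
detectable.

**Co-occurrence.** Paired categories receive a shared standard-normal
background vector scaled by `strength` (and a `background_sd`), drawn
once per unordered pair so the knob is symmetric in the pair order;
strength 0 is an exact identity.

**What the generator does not emulate.** Real network activations are
non-Gaussian, units are correlated and heavy-tailed, category manifolds
are not spherical, and learning dynamics are neither exponential nor
level-separable. Passing tests therefore establish that the *pipeline*
is correct and that the statistics behave as designed when their
assumptions hold — not that any particular network represents categories
hierarchically. Real activation tables enter through the same file
interfaces for that question.

## Pipeline and determinism

A run is configured by one YAML document and one seed. The seed is split
per stage by hashing `"{seed}:{stage_name}"` (BLAKE2, reduced below
2³¹), so adding or removing a stage never shifts another stage's
randomness. Reports are JSON with sorted keys, no timestamps and
full-precision floats, and are byte-identical across repeated runs of
the same config; inputs are fingerprinted by SHA-256 (files) or by their
parameter block and derived seed (simulations). Delimited outputs store
floats at %.17g and readers parse with correctly-rounded round-trip
precision, so write-then-read is exact. On any stage error the partial
outputs are removed and the error is re-raised with the stage name.

## Known limitations

- Only tree-reduced ontologies are analyzed; alternative DAG conventions
  (e.g. shortest-path or all-paths subsumers) are not offered.
- Only Wu–Palmer similarity is implemented; path, Lin or Resnik measures
  would slot into the same matrix interface but are out of scope.
- The structure test's null randomizes labels; it does not test the
  *correspondence* correlations themselves against a null.
- Superordinate schemes must be mutually non-ancestral; overlapping
  groupings are rejected rather than resolved.
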