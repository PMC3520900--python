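# Methods

This note documents the models, algorithms, parameter choices and
known limitations behind `cladebin`. It is the place to look when a
number in a report needs an explanation.

## The decision problem

A genus circumscribed by morphology turns out, on a molecular
phylogeny, to consist of several well-supported clades. Candidate
re-classifications partition the sequenced species into named,
monophyletic groups at different granularities (here: 2, 4 or 5
genera). Most described species, however, have no sequence data; any
classification must also place them. The package scores each candidate
classification by (i) how confidently morphology places the
unsequenced species into its groups and (ii) how morphologically
coherent the resulting groups are.

## Character scoring engines

**Parsimony.** Unordered (including binary) characters are scored
with the Fitch set dynamic program; ordered multistate characters
with the Sankoff DP under linear costs `|i − j|` on the (consecutive,
order-preserving) state codes. Missing observations use the
all-states-possible convention: a missing leaf contributes zero cost
to every state, so the taxon set is identical across characters. Both
DPs are validated against exhaustive minimisation over all internal
state assignments on trees up to 7 leaves.

**Likelihood.** The Mk model: a k-state continuous-time Markov chain
with equal exchange rates, uniform stationary frequencies, and the
root at stationarity. Transition probabilities use the k-state
closed form `P(same) = 1/k + (k−1)/k · e^(−kt/(k−1))`. The pruning
recursion rescales partials per node, and is validated to 1e−10
against direct summation over internal-state combinations. There is
no rate heterogeneity and no ascertainment correction; likelihoods
are root-position invariant (tested), which is why the randomized
trees of the weighting null can be generated as rooted trees.

## Character weighting

**ML scheme.** `w_c` is the fraction of `n_random` (default 100)
randomized trees on which character *c* has strictly lower Mk
log-likelihood than on the reference tree. The randomization draws
topologies uniformly from labelled rooted binary topologies (random
sequential attachment) and permutes the reference tree's own branch
lengths onto the edges — the null preserves the observed length
distribution while destroying structure. One tree set, fixed by the
seed, is shared by all characters. Log-likelihood ties within 1e−9
count as "not worse", so characters whose likelihood is genuinely
tree-independent (at most one observed taxon) get weight 0.

A subtlety worth knowing: the likelihood of a *constant* character is
not tree-independent (the probability of an all-same pattern depends
on where the long and short edges sit), so constant characters
receive coin-flip ML weights near 0.5 rather than 0. This is a
property of the scheme itself — likelihood weighting is known to
inflate weights of characters with little signal — and one reason the
MP scheme is offered alongside.

**MP scheme.** The retention index on the reference tree:
`w_c = (g_c − s_c)/(g_c − m_c)`, with `s_c` the character's steps on
the reference tree, `m_c` its minimum possible steps (observed states
minus one; observed range for ordered characters) and `g_c` its
maximum possible steps on any tree (`n_obs` minus the largest state
frequency; for ordered characters the star-tree length
`min_m Σ_i |x_i − m|`, attained at a median state). Invariant
characters (`g_c = m_c`) are defined to have weight 1. This is the
standard score-to-weight conversion that gives a clean synapomorphy
weight 1 and a maximally homoplastic character weight 0.

## Placement (binning)

A query with character states `x` is scored on every edge *e* of the
reference tree as `score(e) = Σ_c w_c · s_c(T + x@e)` — the weighted
parsimony score of the tree with the query attached at *e*. Both
weighting schemes use parsimony attachment; only the weights differ.
Scores are computed with an inside/outside Sankoff decomposition
(`Down` and `Out` tables per character), giving every edge × state
attachment cost in one O(n·k²) pass per character; the tables are
exactly equal to physically attaching and re-scoring (tested), and
make bootstrap replicates a table lookup.

Ties within 1e−9 prefer an edge inside a named group over the
backbone, then the smallest edge index in the fixed preorder
enumeration (logged at debug level). A best edge on the backbone —
below no single group's crown — is an OUTSIDE placement, a
first-class outcome.

Support: characters are resampled with replacement `n_boot` (default
100) times, weights travelling with them; a group's support is the
fraction of replicates assigning it. The reported group is the modal
one (ties: OUTSIDE last, then lexicographic). A replicate that draws
only zero-weight characters carries no signal and falls back to the
point placement. Queries whose ML and MP groups differ are reported
as *conflicting* — the same caution flag practitioners use before
making formal combinations.

## MRPP

Distances between taxon state vectors: Euclidean with
pairwise-deletion rescaling, `d = sqrt(Σ_shared (x−y)² · C/C_obs)`,
or correlation distance `d = 1 − r` over shared characters
(zero-variance profiles get `r = 0`, logged). The statistic is
`δ = Σ_i (n_i/N)·ξ_i` with `ξ_i` the mean within-group pairwise
distance; group-size weights `n_i/N` are the conventional default,
with `(n_i−1)`-weighting available. Significance comes from shuffling
group labels with sizes fixed; `p = (1 + #{δ_perm ≤ δ_obs})/(1 +
n_perm)` (add-one: unbiased and never zero). The chance-corrected
agreement is `A = 1 − δ_obs/E[δ_perm]` from the permutation sample.

Two companions to the Monte-Carlo p:

* `mrpp_exact` enumerates every label assignment with the given group
  sizes (bounded at 1e5 assignments) and is the oracle the
  Monte-Carlo test is validated against.
* `p_approx`, a Pearson type III left-tail probability fitted to the
  mean, variance and skewness of the permutation sample — the
  approximation classic MRPP software reports. It matters because the
  Monte-Carlo p is floored at `1/(n_perm+1)`: with strong group
  structure *every* candidate classification can sit below the floor,
  and only the moment approximation resolves *how far* below, which
  is what makes two classifications comparable in that regime.

## Kruskal–Wallis discrimination

Per character and per candidate grouping, the tie-corrected H with
its chi-square p (df = groups − 1), via scipy; all-identical values
are defined as H = 0, p = 1, and an exact permutation p is available
for n ≤ 12. Characters are analysed on their numeric codes — the test
is rank-based, so coding scale is immaterial for ordered characters.
Summary counts use raw thresholds (significant p < 0.05, marginal
0.05 ≤ p < 0.10) with no multiple-testing correction, because the
counts themselves are the statistic of interest when comparing
solutions on the same matrix; Benjamini–Hochberg adjusted p-values
are emitted alongside for transparency.

## The evaluation pipeline and verdict

`evaluate` runs weighting → binning → MRPP → Kruskal–Wallis for every
solution × scheme. Group membership of query taxa in the MRPP/KW
stages comes from their **binned** assignment (OUTSIDE queries are
excluded); that is the framework's own logic — binning proposes, the
permutation tests dispose. A `use_true_groups` option substitutes
known groups for recovery experiments, and `pool` selects whether
reference taxa, query taxa or both enter the tests (default: both).

The ranked verdict sorts by lowest Monte-Carlo MRPP p (minimum over
the two metrics), then more significantly discriminating characters,
then fewer conflicting placements. The hierarchy is a formalisation
of an informal argument and is reported as advisory, never as the
only output: all per-stage tables are always written.

## Synthetic scenarios

The generator emulates the motivating study design: `n_ref = 21`
sequenced reference species, `n_query = 65` morphology-only queries,
`n_chars = 24` characters (75% binary, the rest ordered with 3–4
states), and nested 2/4/5-clade candidate solutions with group sizes
proportional to the published placements (queries 8/8/24/5/20 across
Ia/Ib/IIa/IIb/IIc; references allocated by largest remainder with a
floor of two per group, giving 3/2/8/2/6).

* **Tree.** Pure-birth subtrees per fine group joined on the fixed
  backbone ((Ia,Ib),(IIa,(IIb,IIc))), so every candidate group is
  monophyletic by construction. Branch lengths are exponential with
  mean `branch_scale = 0.2` — the substitutions-per-site scale of a
  real congeneric molecular tree. The scale matters: with unit-mean
  lengths the Mk engine operates at saturation and even a perfect
  clade marker no longer beats every randomized tree, which would
  misrepresent the likelihood weighting scheme's intended regime.
* **Diagnostic characters.** With probability `clade_signal` a
  character is a clean synapomorphy of one 4-clade-level group: the
  marked group carries derived state k−1, everyone else state 0.
  Ground truth is therefore exact. States are assigned at the 4-clade
  level deliberately: the Ia/Ib subdivision is phylogenetically real
  but carries no diagnostic morphology, so the 4-clade solution is
  the ground-truth optimum and the 5-clade split can only win through
  noise — mirroring the study system.
* **Neutral characters** evolve on the tree under Mk at `mk_rate = 5`
  (5 × 0.2 = one expected change per mean edge — substantial
  homoplasy, as real morphological data show).
* **Queries** are sister lineages: each query draws a random donor
  among its group's reference members and its own exp(branch_scale)
  pendant branch; neutral characters evolve onward from the donor
  state, diagnostic characters take the group state. Every state is
  then flipped to a random different state with probability
  `noise_rate`, and cells are masked with probability `missing_rate`
  (defaults 0.1 and 0).
* **Coupling.** All randomness is split into substreams keyed by
  (seed, character index), so raising `clade_signal` at a fixed seed
  converts characters from neutral to diagnostic while leaving every
  other character byte-identical. Signal-response curves are
  therefore paired comparisons (common random numbers), which is what
  makes strict monotonicity of recovery across a signal grid a
  testable property at this sample size.

What passing tests on these scenarios do **not** show: real
morphological matrices have correlated characters, coding ambiguity,
and taxon-specific missingness patterns; diagnostic states in nature
are rarely perfectly clean within a clade; and the generator never
attempts to imitate the actual (unpublished) character matrix of any
study. Results on synthetic data validate the machinery and its
statistical behaviour, not any particular taxonomic conclusion.

## Numerical choices and degenerate inputs

* Newick: polytomies are resolved to binary with zero-length edges,
  deterministically by smallest descendant leaf label (score-neutral
  for both engines); missing branch lengths default to 1.0; both are
  logged. Round-trips preserve lengths to 10 significant digits.
* State codes are remapped per character to consecutive integers
  preserving numeric order; the generator emits already-consecutive
  codes so files round-trip bit-exactly.
* Placement and bootstrap tie tolerance: 1e−9 on weighted scores.
  Log-likelihood tie tolerance in ML weighting: 1e−9.
* Correlation distances snap |1 − r| < 1e−12 to exactly 0 so
  identical profiles have distance zero despite float residue.
* All Monte-Carlo machinery takes explicit seeds; reports are
  byte-identical across reruns with the same config (tested).

## Problem sizes used in validation

The test suite and the acceptance script validate at sizes chosen to
make exhaustive oracles feasible while exercising the real code
paths: parsimony/likelihood oracles on trees of 3–7 leaves (hundreds
of random characters), MRPP exactness on ≤10 taxa (where full
enumeration is ≤252 assignments), type-I calibration over
500–1000 null simulations at 199 permutations, and
recovery/contrast checks on the full 21 + 65 × 24 study design with
100 random trees, 100 bootstrap replicates and 999 permutations.
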