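# Methods

## Model

A discrete character with k states evolves on a rooted tree with branch
lengths under a continuous-time Markov chain: rate matrix Q with
off-diagonal q_ij ≥ 0 (expected changes from i to j per unit branch
length; per million years at the motivating study's scale) and rows
summing to zero.  Transition probabilities over a branch of length t are
P(t) = exp(Qt), computed by eigendecomposition (vectorised over all
branches) with a scaling-and-squaring `expm` fallback whenever the
eigenvector matrix fails a reconstruction check (defective Q); t = 0 is
forced to the exact identity so zero-length branches pin states exactly.

Three nested parameterisations are supported: ER (1 rate), SYM
(k(k−1)/2), ARD (k(k−1)).  For binary characters SYM is identical to ER
and is collapsed before fitting so a candidate is never counted twice.

The likelihood of the tip data is computed by the pruning algorithm in a
vectorised post-order (nodes grouped by height), with per-node rescaling
and accumulated log scalers to prevent underflow.  Missing tip states
contribute an all-ones partial vector.  The root prior is uniform by
default — mirroring the default of the standard R implementation this
workflow is modelled on, whose results are conventionally reported
without root-prior discussion — with a stationary-distribution option.

## Fitting and model choice

Rates are optimised on the log scale, bounded to [1e−8, 1e3] per rate,
with L-BFGS-B.  Because the likelihood saturates as rates grow (all
states equilibrate within a branch), a gradient path started far below
the optimum can overshoot onto the flat plateau and stall at the upper
bound; the optimiser therefore first scans a 22-point log grid of the
shared-rate scale and then polishes from deterministic multiples
(×1, ×10, ×0.1) of the grid optimum — three restarts by default, best
log-likelihood kept, honest `converged` flag.  Tolerances: ftol 1e−10,
gtol 1e−7, ≤100 iterations per restart.

Model choice per tree: minimum AIC, except that a more complex model
whose AIC advantage over a simpler candidate is ≤ `tie_margin` loses to
the simpler one.  `tie_margin` defaults to 0 (simpler wins exact ties):
the qualitative rule "prefer the simpler model unless rejected" is not
a quantified test, so the margin is exposed as a knob for sensitivity
analysis rather than guessed.  A likelihood-ratio test is deliberately
not provided.

## Ancestral states

*Marginal reconstruction* combines upward partial likelihoods with
downward outside messages (equivalent to re-rooting at every node),
normalised per node so rescaling factors cancel.

*Stochastic mapping* fixes Q at its per-tree MLE (empirical Bayes — the
default of the reference tool; a full hierarchical treatment resampling
Q is out of scope).  Each draw samples the root state from
prior × partial likelihood, then each child conditionally on its parent
and its own subtree data; branch substitution paths are then sampled
conditioned on both endpoints by uniformization with dominating rate
Λ = max_i |Q_ii|: the number of candidate jumps is drawn from the
endpoint-reweighted Poisson mixture (series truncated when the
cumulative conditional mass exceeds 1 − 1e−10), jump times are uniform
order statistics, jump states are backward-conditioned through powers of
the jump matrix, and self-jumps are collapsed.  For Λt < 1e−8 the path
is a single segment (differing endpoints are then an error, as their
probability is zero).  Node-state sampling is vectorised across draws;
pipelines that only need per-node state frequencies skip path sampling.

Per-tree "most likely state" at a node defaults to the argmax of the
stochastic-map node frequencies (100 draws/tree by default, a
precision/runtime compromise; the marginal-ML argmax is available by
switch).  Ties break toward the lowest state code and are logged.

## Cross-tree aggregation

For each tree: tips without data for the trait are pruned (path lengths
summed through suppressed unifurcations, so patristic distances are
preserved), models fitted and chosen, states reconstructed, and each
named clade's crown (MRCA of present members) and stem (crown's parent)
read off.  Non-monophyletic clades are included via the MRCA with a
per-clade non-monophyly count reported (exclusion available by policy
switch); a crown that is the tree's root contributes nothing to the stem
row — the denominator shrinks, nothing is imputed.

Summaries: per (trait, clade, crown/stem, state) the proportion of
trees whose most likely state is that state; a state is confident iff
its proportion is strictly greater than the threshold (default 0.90);
a strong-change call requires both nodes confident in differing states.
Rendered tables round half away from zero to 2 decimals and flag
proportions > 0.90 bold; confidence is always computed on full-precision
values.  Rate tables aggregate per chosen model (never pooled across
models) in the fixed directional order 0→1, 0→2, 1→0, 1→2, 2→0, 2→1.

## Synthetic data generator

The generator emulates the study conditions end to end: a Yule base
tree rescaled to crown age 56 time units with 110 tips; a 300-tree
posterior-like sample where each tree receives 2 random NNI moves and
mean-preserving lognormal branch-length noise (CV 0.1) before rescaling
back to the crown age; six focal characters; and a trait matrix of 149
accessions over the species (within-species concordant discrete values,
lognormal continuous traits, half of them state-shifted) with 10%
missing data injected completely at random.

The six packaged characters mirror the empirical mix: a binary marker
trait forced to the derived state on the focal clade with no background
change (its real counterpart is a clean synapomorphy confined to one
subclade); slowly evolving binary/ternary characters (ER 0.004); a
ternary character with symmetric but unequal rates (0.050/0.004/0.008,
so transitions between the two extreme states pass through the
intermediate); a fast binary character (ER 0.117) whose deep nodes stay
equivocal; and an asymmetric binary character (ARD 0.005/0.02, the loss
rate four times the gain rate, low enough that both states persist among
the tips).  The
focal clade is the mid-sized clade with the longest stem branch on the
base tree: a forced change on a very short stem is intrinsically
unidentifiable (one change on a short stem competes with two changes on
long crown-child branches), so using it would test tree geometry, not
the pipeline.

What the generator does *not* emulate: real posterior correlation
structure between topology and branch lengths (NNI + noise is a cheap
stand-in), rate heterogeneity across lineages, character correlation,
or non-random missingness.  Passing tests therefore demonstrate
correctness of the machinery and recoverability under the stated
conditions, not robustness to violations of the Mk model.

## Problem sizes used by tests and the acceptance script

Oracle and closed-form checks run at full specified size (200 random
trees ≤ 6 tips; 1,000 random (Q, t); 10,000 mapping draws on a 20-tip
tree; 50 replicates of 200-tip rate recovery and model selection).  The
end-to-end forced-clade check runs on a reduced study (40 tips, 12-tree
sample, 20 draws/tree, seeds 1–5) in the test suite and a mid-size study
(60 tips, 60 trees, 50 draws) in the acceptance script; the assertion
thresholds (crown proportion > 0.90, exactly one strong-change call)
are the same as at full scale.  Generator defaults remain the full study
conditions (110 tips, 300 trees, 100 draws).

## Known limitations

* No hidden-rate, covarion, threshold or correlated-character models.
* Branch lengths are taken as given; no re-estimation or dating.
* The AIC tie rule is a strict-minimum convention, not a calibrated
  hypothesis test.
* Empirical-Bayes mapping understates uncertainty in Q; cross-tree
  aggregation recovers topology uncertainty but not rate uncertainty
  within a tree.
* Reproduction of the motivating study's published tables requires its
  deposited trees and trait matrix, which cannot ship with this
  repository; the corresponding tests fail with an explanatory message
  until those files are supplied under `data/`.
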