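# Methods

## The trait model

A binary character on a fixed rooted phylogeny evolves as a two-state
continuous-time Markov chain with gain rate `q01` (0 → 1 per unit branch
length) and loss rate `q10` (1 → 0).  With `s = q01 + q10`, the transition
probabilities have the closed form `P01(t) = (q01/s)(1 − e^{−st})`,
`P10(t) = (q10/s)(1 − e^{−st})`, diagonals by complement; `s = 0` or
`t = 0` give the identity.  Branch lengths are taken exactly as supplied
(typically substitutions per site for phylogenomic trees); rates are in
events per unit branch length.  Zero-length branches are legal and behave
as identities.

Tip states may be 0, 1 or missing; missing tips enter the likelihood as
the all-ones partial vector — the standard treatment, needed for taxa whose
life stages cannot be scored as either state.  The likelihood is computed
by Felsenstein pruning with per-node rescaling.  Three root-state
policies are available: `flat` (½, ½ — the default, matching common
stochastic-mapping practice), `stationary` (q10/s, q01/s) and `fixed`.
The choice matters mostly for strongly asymmetric rates; all analyses here
default to flat because no principled prior on the root state exists for
the traits this package targets.

Rates are estimated by L-BFGS-B on log rates (bounds 1e−9 … 1e3) from five
log-spaced starts (1e−3 … 10), either with `q01 = q10` (ER, 1 parameter)
or free (ARD, 2 parameters).  The ER/ARD comparison reports both a
likelihood-ratio test (χ², 1 df, α = 0.05) and AIC, with the LRT as the
pipeline default; the two can disagree near the boundary and both are
always shown.  Marginal ancestral states come from an exact up-down
(outside) pass, so tips with observed states get posterior 1 and the root
marginal equals the normalized product of root distribution and root
partials.

## Stochastic mapping

A mapped history assigns a state to every node and an ordered list of
(state, duration) segments to every branch.  Conditional histories are
drawn in two steps:

1. node states jointly from the exact conditional distribution — root
   state from the normalized root partials, then each child given its
   parent using `P(t)[parent, j] · L_child[j]` in a root-to-tip pass;
2. each branch path conditional on its endpoint states by
   **uniformization**: the chain is embedded in a Poisson process with
   dominating rate `Λ = 1.05 · max(q01, q10)` and jump matrix
   `R = I + Q/Λ`; the number of (possibly virtual) jumps is drawn from the
   exact endpoint-conditioned distribution with the series truncated once
   the cumulative Poisson mass reaches 1 − 1e−10; jump times are uniform
   order statistics and the jump chain is a standard discrete bridge.
   If the truncated series degenerates numerically the sampler falls back
   to rejection (forward simulation, capped at 1e6 attempts per branch).

Unconditional ("prior") histories are simulated forward with Gillespie
draws from a root state drawn from the root policy.

For Bayes-factor work only the number of 0 → 1 events matters, so batch
counters sample node states for thousands of histories at once and count
within-branch gains through the same uniformization bridge, vectorized
across histories.  Forward-simulated endpoints plus bridge-conditioned
interiors are distributionally identical to full forward paths, so the
fast prior counter is exact; the test suite cross-checks both counters
against fully materialized histories.

Maps are drawn on a single fixed topology.  Averaging summaries over a
posterior tree sample is possible by calling the samplers per tree and
pooling histories; no special machinery is provided because the package's
inputs are point estimates of topology.  The default number of maps is
1,000, CLI-overridable; every Monte-Carlo output carries a binomial
standard error.

## Origins Bayes factor

H0: the trait arose exactly once; HA: two or more times.  An *origin* is a
0 → 1 event anywhere on the tree; a root reconstructed in state 1 counts
as one origin by default (otherwise "arose once" is undefined for traits
present at the root), with `count_root=False` / `--root-origin=ignore` to
change the convention.  Histories in which the trait never arises are
excluded before forming odds — both hypotheses presuppose the trait
evolved — and the excluded fraction is always reported.

`BF = [post P(H0)/post P(HA)] / [prior P(H0)/prior P(HA)]`, prior odds
from `n_sim` forward simulations, posterior odds from `n_maps` conditional
maps, both at the same fixed (gain, loss) rates.  No smoothing is applied
in the regular case; when one side has a zero count it is replaced by a
half count and the result flagged as a *bound* (`is_bound`, e.g.
`"> 42.3"`) rather than reported as a silent 0 or ∞.  Model posterior
probabilities assume equal prior model odds: `ppH0 = BF/(1+BF)`.
Standard errors for log BF use the delta method on the two conditional
proportions.  Rates are fixed point values by design (the "rates
estimated from observed data" reading); redrawing rates per simulation
from a hyperprior was considered and rejected as out of scope for the
sensitivity analysis the grid already provides.

The sensitivity grid runs the empirical setting (ER fit: gain = loss)
plus each requested ratio, by default 10:1 and 1:10 taken literally as
rates (10, 1) and (1, 10) times an optional scale.

## Synthetic study conditions

The generator's defaults define the conditions under which the method
claims are tested:

- **Trees**: Yule (pure birth, death 0 — the simplest adequate test
  model), birth rate 1, 60 tips for origins analyses, 500 for rate
  recovery.  Optional `tree_depth` rescales the tree to a target
  root-to-tip depth.  The origins analyses use depth 0.15: on such trees
  the ER rates fitted to single-origin traits have median ≈ 0.45–0.5,
  matching the empirical gain/loss magnitudes (0.2–0.7) that motivate the
  10:1 / 1:10 grid; on an unrescaled 60-tip Yule tree (total length ≈ 59)
  a rate of 10 implies hundreds of events and the grid is meaningless.
- **Traits**: `mk` (forward simulation at the configured rates, generating
  history returned as ground truth), `single_origin` (a random clade
  containing 10–50% of the tips painted state 1; exactly one gain, placed
  mid-branch), `scattered` (iid Bernoulli(0.5) tips; no generating
  history exists, so the history slot is None).
- **Orthogroups**: per orthogroup, taxa drop out independently (p = 0.2;
  focal-clade taxa at 0.55, making the focal clade sparse); the gene tree
  is the species tree pruned to survivors; in-paralogs duplicate a tip in
  place (p = 0.08); an out-paralog is grafted onto a random branch with
  p = 0.05; each focal-clade sequence is a contaminant with probability
  `0.8 · expit(2 − m)` where `m` is the number of focal members present —
  a logistic decrease reproducing the empirical pattern that sparse
  partitions concentrate contamination, without claiming a mechanistic
  model of it.  The default focal clade is the tree clade closest to 5
  taxa.
- **Hit tables**: clean sequences draw best-ingroup e-values log-uniform
  in [1e−180, 1e−30] and outgroup in [1e−20, 1]; contaminants the
  reverse; 2% of sequences swap sides to emulate borderline cases.  This
  fixes the ceiling of the alien-index filter's operating characteristics
  at ~98% by construction.

What the generator does **not** emulate: residue-level sequence evolution
(partition alignments are uniform-random placeholders), rate variation
across branches or characters, correlated characters, gene-tree/species-
tree discordance beyond paralogy and dropout, and biased taxon sampling.
Passing tests therefore demonstrate correctness of the algorithms and the
qualitative behaviour of the statistics under clean model conditions, not
robustness to the full mess of real transcriptome data.

## Numerical choices and problem sizes

- Uniformization truncation at cumulative Poisson mass 1 − 1e−10;
  dominating rate 5% above the larger rate.
- Optimizer: ftol 1e−10 on the objective; ER nesting is enforced in the
  LRT by clamping the statistic at 0 against optimizer jitter.
- Paralog-pruning tie-breaks: more distinct taxa, then more underlying
  sequences, then lexicographically smallest sorted tip-label list; the
  representative of a merged same-taxon group is the longest-named
  sequence id.  Support-collapse threshold defaults to 0 (no collapse).
- Occupancy filtering is strict (> threshold), so 31/62 is dropped at 0.5.
- Enrichment: two-sided Fisher exact tests with Benjamini–Hochberg
  correction, calls at q < 0.05.
- Test problem sizes: enumeration oracles on ≤ 6-tip trees (likelihood,
  marginals) and ≤ 10-tip orthogroups (pruning); 10,000 maps per mapping
  check; 20 replicates × (1,000 prior simulations + 1,000 maps) per
  Bayes-factor condition; 2,000 orthogroups for contamination profiling.
  These sizes put Monte-Carlo error well below the asserted tolerances
  while keeping the whole suite under a few minutes.

## Known limitations

- Exactly two states; no hidden-rate or correlated-character models.
- One topology at a time; uncertainty in the tree is not propagated.
- The origins BF is the prior/posterior origin-odds construction — not a
  marginal-likelihood (stepping-stone) estimate — and inherits Monte-Carlo
  noise near BF = 1: with 1,000 + 1,000 histories, conclusions within
  ~2 standard errors of log BF = 0 are genuinely unstable, and the
  rate-sensitivity grid at strongly asymmetric exaggerated rates can
  flip sign for traits whose conditional maps regain the trait inside the
  painted clade.
- The alien index uses best e-values only; composition- or
  coverage-based contamination signals are out of scope.
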