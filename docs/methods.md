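# Methods

This note records the models paleorange implements, the defaults and why
they were chosen, the numerical machinery behind them, and the limits of
what the synthetic-data tests demonstrate.

## Conventions

Time is measured in Ma before present; the present is age 0 and ages
increase into the past. All rates are per Myr (dispersal and biome-shift
events per lineage, speciation/extinction per lineage, substitutions per
site for molecular clocks). Trees are rooted and, in this version,
strictly ultrametric: only extant, contemporaneous tips are supported,
and any edge of non-positive duration is rejected at validation. Tip
labels are the join key across all data sources; whitespace is
normalized to underscores on read.

Discrete observations are ambiguity sets: a wide-ranging taxon is coded
ambiguous among the states it occupies, and `?` (missing) is the full
state space, which contributes a factor of one to every likelihood and
is therefore exactly equivalent to pruning the tip.

## Epoch-stratified dispersal

Paleogeographic structure enters as an `EpochGraphStack`: strictly
decreasing epoch boundary ages ending at 0, and per epoch one binary
adjacency matrix per feature channel. Ages older than the oldest
boundary are assigned to the oldest epoch, so a sampled root age may
exceed the stack's span without special-casing; epoch `e` covers the
half-open interval `(b[e+1], b[e]]`.

For the area model the channels are the three dispersal modes. The rate
from area i to j in epoch e is `d · m_ij(e)` where `m` is 1 for
short-mode adjacency, the medium multiplier for pairs reachable only by
medium-distance dispersal, the long multiplier for long-only pairs, and
0 otherwise. The multipliers are constrained `0 < long ≤ medium ≤ 1`, a
hard ordering that encodes increasingly wide water barriers rather than
relying on the data to order them. Tip ranges are single-area states;
species occupying several areas are ambiguity sets over those areas.
This is the minimal reading of presence/absence range data in an
anagenetic CTMC; cladogenetic range splitting is deliberately out of
scope (both daughters inherit the parent state at nodes).

For the biome-region model, states are compound (biome, region) pairs
and only single-component moves have positive rate. The per-epoch rate
graph is the weighted combination `w_U·A_U + w_G·A_G + w_B·A_B` of an
uninformative (complete) channel, a land-adjacency channel, and a
biome-continuity channel, scaled by a base rate and by a biome-shift vs
region-shift relative rate. The weights live on a 3-simplex: the
published two-weight parameterization leaves `1 − w_G − w_B` of the mass
unaccounted, and the uninformative channel is the natural carrier for
it, so the package always estimates the full triple with a flat
Dirichlet(1,1,1) prior. Biome availability per (epoch, biome, region) is
carried explicitly in the stack (and used by the mismatch statistic);
when absent it is derived from the biome channel's incoming edges.

## Likelihood engine

Branches are segmented at epoch boundaries; the transition matrix over a
branch is the chronologically ordered product of per-segment
exponentials `exp(Q_e Δt)`, oldest segment first. Symmetric generators
(undirected graphs make every dispersal and biome-region generator
symmetric) are diagonalized once per likelihood evaluation with `eigh`,
and all segment matrices for a tree are produced in one batched einsum
per epoch; non-symmetric generators fall back to scaling-and-squaring
`expm`. Products are clipped to [0,1] and row-renormalized to absorb
eigen-roundoff at the 1e-15 level. Agreement of this propagation with
direct integration of the forward Kolmogorov equation is part of the
test suite (max-abs 1e-6 on random 3-epoch branches).

Felsenstein pruning rescales partials per node and accumulates log
scalers, so likelihoods of hundreds of tips in 25-state spaces stay in
range. Root state frequencies default to uniform for biogeographic
characters — no range prior beyond the CTMC itself — and to the
stationary/empirical frequencies for nucleotides.

Marginal ancestral states combine the postorder conditionals with a
preorder outside pass. Stochastic maps draw node states exactly from
their joint conditional (root first, then each child given its parent),
then fill in each branch segment by endpoint-conditioned uniformization:
the number of uniformized jumps is drawn from its exact conditional
distribution (powers of `R = I + Q/μ` are cached per epoch), the jump
chain is filtered forward given the endpoint, jump times are uniform
order statistics, and virtual self-jumps are discarded. A rejection
retry (capped at 10,000) guards the rare numerical-underflow branch;
exceeding the cap is an explicit error rather than a silent
approximation.

## Molecular model

Each partition gets an independent GTR+Γ model: exchangeabilities and
base frequencies on simplices, a gamma shape α with 4 equal-probability
discrete categories using category means (the field-standard
discretization), and a per-partition rate multiplier. Branch lengths in
expected substitutions are `duration × clock × multiplier × category
rate`; the clock is strict in this version, but the branch-length
computation accepts per-branch multipliers so a relaxed clock can be
layered without touching the pruning code. Site patterns are compressed
before pruning. The generator is normalized to unit mean rate, so clock
and duration are jointly identified exactly as in standard dating
software (doubling one is halving the other; this identity is tested).

## Episodic birth–death

The EBD likelihood uses the piecewise-constant survival function
`y(t) = 1 − E(t)`, which obeys the logistic ODE `y' = (λ−μ)y − λy²`
within an interval and therefore has a closed-form update per interval;
per-branch contributions are products of closed-form flow factors, so no
numerical integration enters. The likelihood conditions on the root age
and on both root lineages surviving to be sampled, with uniform
sampling probability ρ at the present. Degenerate `λ = μ` intervals use
the analytic limit rather than the generic formula.

Twenty equal-length intervals between the root and the present are the
analysis default, with the autocorrelated prior
`log λ_i(older) ~ Normal(log λ_i(younger), σ)` applied backward in time
(and likewise for extinction); first-interval and σ hyperpriors are
caller-supplied so the reversal-symmetry of the increment chain is
preserved by default.

Clade-specific sampling fractions are implemented per branch: a branch
uses the fraction of the innermost configured clade containing its
entire subtree, which fixes the `y` function integrated from the
present for that branch (tips contribute their clade's ρ; root
conditioning uses each root child's own `y`). For a single global ρ
this is exact; with multiple clades it is the standard practical
treatment — a hypothetical unsampled lineage is assumed to belong to
the clade of the branch it would attach to — not an exact marginal over
assignment of missing taxa.

## Biome HiSSE

Six combined states (3 observed biomes × 2 hidden states) each carry
their own λ and μ. Biome transitions are temperature-ordered by default
(tropical ↔ warm-temperate ↔ cold-temperate, separate warming/cooling
rates), matching a niche axis with an ordering; a free 3×3 matrix and a
symmetric option are available. Hidden-state switches occur at a single
rate independent of biome, and simultaneous biome+hidden jumps are
excluded. The biome-independent null ties λ and μ across biomes within
each hidden state, leaving the same number of hidden-rate parameters,
and is nested in the full model.

Extinction probabilities `E(t)` are integrated once over the tree span
(RK45, rtol 1e-8, atol 1e-10) with a solver check that E stays in
[0, 1]; E is monotone non-decreasing into the past only under complete
sampling — with ρ < 1 the initial condition `E(0) = 1 − ρ` can exceed
the short-horizon extinction probability, so monotonicity is not
enforced as an invariant. Branch D vectors are integrated against the
dense E interpolant and renormalized with log-scaler accumulation. The
root combines `Σ_i π_i D_i / (λ_i (1 − E_i)²)` — the standard
survival-conditioning convention. Tip coding follows the analysis
conventions: the coldest occupied biome (order cold > warm > tropical)
in the headline analysis, ambiguity among occupied biomes as the
sensitivity variant, and full 3-biome ambiguity for unknowns. Derived
summaries are net diversification `λ − μ` and turnover `μ/λ`, computed
per posterior draw.

## Inference

The sampler is random-scan Metropolis–Hastings over a dict-valued state.
Moves: multiplicative scale (scalars and vector elements, Jacobian
`log m`), uniform slide, Dirichlet-centered simplex proposals with the
exact Hastings ratio, node-age slides uniform in (oldest child age,
parent age) (symmetric, since the window depends only on unchanged
neighbors), root-age scaling, and NNI for topology. NNI preserves node
ages and rejects age-incompatible swaps; SPR is not implemented in this
version — at desk scale NNI plus age moves keep the dated-tree space
connected (a property one of the tests exercises directly), and the
topology machinery exists to support constraints and MAP summaries
rather than large-tree topology search. Monophyly constraints wrap any
move set and reject violating proposals before the likelihood is
evaluated. Chains are reproducible under a seed; acceptance rates are
tracked per move; burn-in defaults to 25%.

Summaries follow the reporting conventions used throughout: posterior
mean, 95% and 80% shortest (HPD) intervals, an autocorrelation-based
effective sample size, and a MAP tree (most frequent sampled topology,
ties broken by mean log-posterior, node ages averaged per clade across
that topology's samples). Marginal likelihoods use stepping-stone
integration over 32 powers placed at Beta(0.3, 1) quantiles — the
standard ladder concentrating rungs near the prior — with per-rung ESS
reported and a hard error on non-finite contributions.

## Synthetic data

Every simulator is exact (Gillespie event simulation; no tau-leaping)
and deterministic under a seed, and each generated dataset carries a
metadata echo of its recipe sufficient to regenerate it. Trees are
simulated forward conditioned on reaching the target number of extant
lineages, with the present placed uniformly inside the waiting time to
the next event (this guarantees strictly positive terminal branches);
extinct and unsampled lineages are pruned and unary nodes suppressed.
Character histories switch generators at epoch boundaries, which is
exact because the process is piecewise-homogeneous and exponential
waiting times are memoryless. Sequence simulation draws root states
from the stationary frequencies and one gamma category per site. The
SSE simulator evolves tree and 6-state character jointly and discards
the hidden component in its output.

The default desk-scale recipe — 200 tips, birth 0.1 and death 0.03 per
Myr (a root age around 60–120 Ma at that size), 3 biomes × 4 regions, 4
epochs, dispersal base 0.03/Myr, biome-shift base 0.05/Myr with
biome-dominant weights (0.05, 0.05, 0.90), 2 loci × 600 bp under GTR+Γ
with a 0.005 subst/site/Myr clock, 15% ambiguous and 5% missing tips —
was chosen once to mirror the statistical structure of a
museum-scale damselfly dataset (hundreds of taxa, a few loci, coarse
range coding with real ambiguity and missingness) while letting the full
pipeline run in minutes on one core. What passing tests on these data
show is that the estimators recover the generating process at realistic
sizes and signal strengths; what they cannot show is robustness to the
features real data add — phylogenetic error, non-random museum
sampling, range coding built from administrative units, model
misspecification in the paleogeographic graphs — so conclusions about
any empirical system still require the sensitivity analyses (weak-prior
dating, alternative tip codings) the interfaces expose.

## Event analytics

Event series pair every event with its nearest root-ward predecessor on
the lineage path, crossing speciation nodes, so an ancestral event can
open one series in each daughter path while every event closes at most
one series; a pair is binned by the age of its second (closing) event.
This convention is well-defined on trees and reduces to the intuitive
chain on an unbranched lineage; counting strictly within branches is
the main alternative and would undercount series that straddle
speciation events. Same-feature pairs are reversals when the overall
start and end states coincide and flights otherwise; mixed pairs are
named for the earlier event (biome-first / region-first). Time bins
default to the paleobiome epoch boundaries. Lineage-state proportions
and the biome-availability mismatch statistic count branches spanning
each grid age on the fixed summary tree, with events at exactly the
grid age treated as having occurred.

## Known limitations

- Extant-tips-only trees; no fossil or serially sampled tips.
- Anagenetic character change only; no cladogenetic range inheritance
  (DEC-style splitting) in the dating model.
- Strict clock default; relaxed clocks enter only via per-branch
  multipliers supplied by the caller.
- The HiSSE model is time-constant and ignores paleoclimatic movement
  of the biomes themselves.
- NNI-only topology proposals; large-tree topology inference is not the
  package's aim.
- Per-clade sampling fractions use the branch-clade approximation
  described above.
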