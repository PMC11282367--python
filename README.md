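# paleorange

Epoch-stratified historical biogeography and diversification analyses for
dated phylogenies, built around the kind of question posed by the
latitudinal diversity gradient (LDG): did a clade accumulate its tropical
diversity through higher tropical speciation, lower tropical extinction,
an early tropical start, or dispersal and biome-shift dynamics?

The package implements, as a single tested Python stack:

- **Biogeographic dating.** A time-heterogeneous CTMC over discrete areas
  whose dispersal rates follow empirical paleogeography: each epoch
  carries adjacency graphs for short-, medium-, and long-distance
  dispersal modes (nested, `short ⊆ medium ⊆ long`), so
  `q_ij(e) = d · m(i,j,e)` with `m` the best available mode multiplier.
  Because transition probabilities depend on absolute time, the process
  informs node ages; the root age takes a TruncatedNormal(120, 20,
  [40, 240]) Ma prior (with Uniform weak/no-geography variants).
- **Biome-shift and within-biome dispersal.** Compound (biome, region)
  states with single-component moves; per-epoch rate graphs are a
  weighted sum `w_U·A_U + w_G·A_G + w_B·A_B` of an uninformative, a
  land-adjacency, and a biome-continuity channel, with the simplex
  weights estimated from the data. Stochastic character mapping yields
  lineage-state proportions through time, event series (biome/region
  reversals and flights, biome-first/region-first pairs), and the
  proportion of lineages whose biome is regionally unavailable.
- **Diversification.** An episodic birth–death (EBD) likelihood with
  piecewise-constant rates on equal-length intervals, Brownian log-rate
  prior backward in time, and clade sampling fractions; and a HiSSE
  likelihood (3 biomes × 2 hidden states) with its biome-independent
  null, net diversification `λ − μ` and turnover `μ/λ` per state.
- **Inference.** Metropolis–Hastings MCMC over scalars, simplices, node
  ages, and topologies (with monophyly constraints), PM/HPD/MAP
  summaries, and stepping-stone marginal likelihoods.
- **Synthetic data.** Exact forward simulators for every input: dated
  birth–death trees, epoch graph stacks, Gillespie character histories,
  GTR+Γ partitioned alignments, and joint tree+trait SSE simulation.

## Worked example

```python
import numpy as np
from paleorange import (BiomeShiftParams, DirichletPrior, EpochCTMC,
                        ExponentialPrior, prune_loglik, run_mcmc,
                        simulate_history, simulate_tree)
from paleorange.simulate import make_biome_region_stack, tip_states_to_data
from paleorange.inference import ScaleMove, SimplexMove

tree = simulate_tree(birth=0.1, death=0.03, n_tips=200, seed=1)
stack = make_biome_region_stack([max(tree.root_age * 1.25, 120), 60, 25, 0],
                                seed=2)
truth = BiomeShiftParams(base=0.05, weights=(0.05, 0.05, 0.90))
_, tips = simulate_history(tree, EpochCTMC.from_biome_shift(stack, truth), 3)
data = tip_states_to_data(tips, stack.space, 4, frac_ambiguous=0.1,
                          frac_missing=0.05)

wprior, bprior = DirichletPrior([1, 1, 1]), ExponentialPrior(10.0)
loglik = lambda s: prune_loglik(
    tree, data, EpochCTMC.from_biome_shift(
        stack, BiomeShiftParams(base=s["base"], weights=tuple(s["w"]))))
logprior = lambda s: wprior.logpdf(s["w"]) + bprior.logpdf(s["base"])
trace = run_mcmc(loglik, logprior, {"w": np.full(3, 1/3), "base": 0.02},
                 [SimplexMove("w", 100.0, weight=2), ScaleMove("base", 0.4)],
                 n_iter=2000, seed=5)
print(trace.summary(["w[0]", "w[1]", "w[2]"]).to_string(index=False))
```

prints (posterior mean and HPD intervals for the three feature weights):

```
param       pm  hpd95_low  hpd95_high  hpd80_low  hpd80_high       ess
 w[0] 0.074800   0.003327    0.159947   0.017298    0.125464 25.303269
 w[1] 0.053199   0.000251    0.154719   0.000251    0.085247 29.733934
 w[2] 0.872001   0.766191    0.958189   0.826747    0.958189 23.374814
```

The chain recovers the biome-dominant weighting it was simulated under
(truth `w = (0.05, 0.05, 0.90)`): the posterior mean of the biome weight
`w_B ≈ 0.87` dominates, and the geography weight is near zero — the same
qualitative signature (biome continuity, not mere land adjacency,
shaping dispersal) that motivates the model.

A full desk-scale pipeline — simulate → date → EBD → HiSSE → biome shift
→ event analytics — is one call (`paleorange.pipeline.run_desk_pipeline`)
or, from the shell, `paleorange smoke --seed 1`. `paleorange simulate`
writes a complete synthetic dataset; `paleorange graphs validate` checks
an epoch graph-stack file.

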