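# Methods

## Model

### Search environment

Landscapes follow the standard NK construction. For each dimension `i` a
contribution table with `2^(K+1)` i.i.d. Uniform(0,1) entries is drawn,
indexed by the state of bit `i` (high position) and the bits of `K` linked
dimensions (in interaction-map order). The raw payoff of a solution is the
arithmetic mean of the `N` contributions. Two normalizations are applied in
this order: division by the maximal raw payoff (found by exhaustive
enumeration of all `2^N` solutions), then the monotone transform `x ↦ x^8`.
The order matters for intermediate values but not for the maximum; the
transform preserves payoff rankings exactly, so the set of local optima is
unchanged by it. The power-8 transform concentrates mass near zero: most
solutions are mediocre and only a few are very good, which is what makes
the search problem interesting.

Interaction partners are drawn uniformly at random without replacement
(excluding self), per dimension. An `adjacent` topology (the `K` cyclically
following dimensions) is available as an option; all shipped analyses use
the random topology. Exhaustive enumeration is guarded at `N ≤ 20`
(≈ 10^6 solutions); larger `N` is refused rather than silently subsampled.

Ties between distinct payoffs have probability zero under continuous
draws. On hand-built integer-valued tables they can occur; the acceptance
rule below treats equal payoff as "not better".

### Individual search

Agents are memoryless: one round = one uniformly drawn dimension from the
agent's DoF set, flipped; strict improvement is always accepted; otherwise
the agent keeps the worse solution with probability `r` and reverts with
probability `1 − r`. The revert is free — it happens within the same round
— mirroring an experimental protocol in which participants could undo a
move before the next round started. The uniform draw deciding keep/revert
is consumed for every non-improving sample regardless of `r`, so runs at
different `r` values share one underlying random stream. `r` is applied
uniformly to every non-improving sample; it is not conditioned on the
payoff gap or the agent's position in a chain.

### Group architectures

Both architectures are evaluated from the same start solution. The chain
passes positions sequentially; the independent group searches in parallel
and takes the max. Per-member random streams are spawned from the master
seed with `numpy` `SeedSequence.spawn`; child `i` does not depend on the
group size, so truncating a stored result to `k` members is *exactly* a
fresh `k`-member run (verified bit-for-bit in the test suite). Step-resolved
performance interleaves independent members round-robin; the interleaving
convention affects only the shape of the step-resolved curve, never the
final collective payoff.

## Parameter defaults

| Parameter | Default | Meaning |
|---|---|---|
| `N` | 10 | binary dimensions (1024 solutions) |
| `K` | swept (0–9) | interdependencies per dimension; ruggedness |
| `DoF` | swept (1–10) | manipulable dimensions per agent |
| `r` | 0 (simulation), 0.11 (behaviourally fitted) | risky-decision ratio |
| group size | 8 | members per group |
| steps | 16 per member (sweeps); `2 × DoF` (sessions) | rounds of search |
| repetitions | 2500 (CLI sweep default) | Monte-Carlo repetitions |
| display multiplier | 1000 | payoff scale shown to participants |

The synthetic experiment design crosses `K ∈ {1, 8}`, `DoF ∈ {3, 6}` and
the two architectures (8 conditions, randomized order), with 16 fresh
landscapes per condition — 128 levels — groups of 8, and `2 × DoF` rounds
per member.

## Synthetic sessions vs. real data

`simulate_session` emulates the *design* of a laboratory study (conditions,
level counts, round limits, display scale) with model agents at a chosen
`r`. It does not emulate human learning across levels, fatigue, individual
differences in `r`, or payoff-gap-sensitive risk taking. Consequently,
passing parameter-recovery tests shows the estimator is consistent for the
model's data-generating process — not that `r` summarizes human behaviour;
with real logs the estimator is the same computation, but its
interpretation inherits the model's assumptions (uniform, context-free
`r`).

DoF subsets are redrawn independently per member per level. Under this
scheme the group-diversity metric concentrates: for 3-subsets of 10
dimensions across 28 pairs the mean is ≈ 4.1 with SD ≈ 0.26. The
diversity–performance effect for independent solvers is therefore real but
small in these units (OLS slope ≈ +0.02 payoff per diversity unit at
`K = 8, DoF = 3`), and resolving it at 2 SE needs on the order of 10^4
simulated groups; the shipped analyses use 20 000. Real groups with stable,
heterogeneous skill sets would show much wider diversity variation.

## Numerical and design choices

- **Paired sweeps.** Within a repetition, both architectures face the same
  landscape, start and member profiles (common random numbers), and
  difference maps use the paired standard error. This lowers the variance
  of method differences without changing their expectation.
- **Estimator edge cases.** `estimate_r` raises on logs with no strict
  payoff decrease rather than returning 0; exact-equality samples are
  excluded from the denominator.
- **Degenerate fits.** `diversity_effect` refuses zero-variance diversity;
  a constant response yields slope 0 and an undefined (NaN) adjusted R².
- **Serialization.** Landscapes round-trip through JSON bit-exactly
  (shortest-repr floats); solutions serialize as left-to-right bit strings
  with 0-based dimensions.
- **Problem sizes.** Shipped analyses use 500 paired repetitions per
  (K, DoF) cell for performance maps (Monte-Carlo SE ≈ 0.01 per cell),
  1000 runs for volatility and hill-climbing success rates, ≥ 5000
  worsening decisions per r-recovery estimate, and 20 000 groups for the
  diversity regression. These sizes put every reported aggregate's
  Monte-Carlo error well inside the effects of interest.

## Known limitations

- Only binary dimensions and single-bit moves; no continuous spaces or
  multi-bit leaps.
- The chain has no memory: a good intermediate solution lost to a risky
  decision is gone. Architectures that archive past solutions are out of
  scope.
- Group members are homogeneous in `r`; heterogeneous-risk groups are not
  modelled.
- Inferential statistics on human data (t-tests, Bayes factors) are out of
  scope; the analysis layer reports means, variances, Monte-Carlo standard
  errors, and OLS summaries.
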