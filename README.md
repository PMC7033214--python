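# nkcollective

Simulation toolkit for studying how the *structure* of a group shapes its
ability to solve multi-dimensional problems. Two classic architectures are
compared on tunably rugged NK fitness landscapes:

- **Transmission chains** — members search sequentially, each starting from
  the predecessor's final solution; the collective solution is the last
  member's final position.
- **Independent solvers** — members search in parallel from a shared start
  without interacting; the collective solution is the best final individual
  solution.

The package is aimed at researchers in collective behaviour, cultural
evolution and organizational problem solving who want a reproducible,
seeded implementation of this model family, including the experiment-design
generator, a group-diversity metric, group-size truncation analyses, and an
estimator that recovers the behavioural risk parameter from decision logs.

## The model

**Search environment.** An NK landscape assigns a payoff to each of the
`2^N` binary solutions. Dimension `i` contributes `c_i(s_i, s_{i_1}, …,
s_{i_K})`, a Uniform(0,1) table value indexed by its own bit and the bits of
`K` other dimensions; the raw payoff is the mean contribution. Payoffs are
divided by the landscape maximum and raised to the eighth power, so the
optimum scores exactly 1 and most solutions are mediocre. `K` tunes
ruggedness: `K = 0` is single-peaked, large `K` yields many local optima.

**Individual search.** Agents are memoryless hill climbers with restricted
*degrees of freedom* (DoF): each round an agent flips one uniformly chosen
dimension from its manipulable subset and keeps the new solution iff the
payoff strictly improves. The *risky-decision ratio* `r ∈ [0, 1]` extends
this rule: after sampling a worse solution the agent keeps it with
probability `r` instead of reverting (the revert is free — one flip attempt
is one round). `r = 0` is pure hill climbing; `r = 1` ignores payoff.

**Estimating r.** Given a decision log, `r̂` is the fraction of
payoff-decreasing decisions that were *not* immediately reverted.

**Diversity.** A group's diversity is the mean, over all member pairs, of
the number of dimensions manipulable by exactly one member of the pair
(pairwise symmetric-difference size).

## Worked example

```python
import nkcollective as nk

landscape = nk.generate_landscape(N=10, K=8, rng=42)
print("solutions:", landscape.solution_count)
optimum, n_local = landscape.enumerate_optima()
print("local optima:", n_local)

profiles = [nk.AgentProfile(dof_dims=dims, r=0.11)
            for dims in nk.assign_dof(N=10, DoF=3, group_size=8, rng=1)]
config = nk.GroupRunConfig(method="chain", group_size=8,
                           steps_per_individual=16, seed=7)
result = nk.run_transmission_chain(landscape, profiles, config)
print(f"chain collective payoff: {result.collective_payoff:.3f}")

summaries = nk.sweep([1, 8], [3, 6], repetitions=200, seed=3)
print(nk.difference_map(summaries).to_string(index=False))
```

prints

```
solutions: 1024
local optima: 79
chain collective payoff: 0.065
 K  DoF  difference  standard_error  repetitions
 1    3   -0.329417        0.020944          200
 1    6   -0.117697        0.017713          200
 8    3    0.051815        0.016145          200
 8    6    0.148408        0.019151          200
```

The rugged `K = 8` landscape has 79 local optima, and the low-DoF chain
lands on a poor one (payoff 0.065, i.e. 65 points on the ×1000 display
scale used in experiments). The difference map shows `independent − chain`
collective performance: chains win decisively on smooth landscapes with
unskilled (low-DoF) members (−0.33 at `K=1, DoF=3`), while independent
solvers win on rugged landscapes with skilled members (+0.15 at `K=8,
DoF=6`). Each cell is a paired Monte-Carlo comparison, so the standard
errors refer to the difference directly.

## Command line

```bash
nkcollective landscape --n 10 --k 8 --seed 1 --payoffs --out landscape.json
nkcollective sweep --k-values 1,8 --dof-values 3,6 --reps 500 --seed 1 --out sweep.csv
nkcollective experiment --r 0.11 --seed 1 --out session.csv   # 128-level synthetic session + r̂
nkcollective groupsize --k 8 --dof 3 --groups 500 --seed 1 --out curve.csv
nkcollective diversity --k 8 --dof 3 --groups 300 --seed 1 --out diversity.json
nkcollective trace --k 8 --dof 6 --r 0.11 --seed 1 --out trace.csv
```

Every subcommand is fully determined by its flags plus `--seed`.

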