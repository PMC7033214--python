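"""Memoryless hill-climbing search with restricted degrees of freedom.

Each round an agent flips one uniformly chosen dimension from its manipulable
set (its degrees of freedom, DoF).  If the sampled solution pays strictly more
it is adopted.  Otherwise the agent keeps the worse solution with probability
``r`` — the risky-decision ratio — and reverts to its previous solution with
probability ``1 - r``; the revert is free and the whole exchange counts as one
round.  ``r = 0`` is pure hill climbing; ``r = 1`` ignores payoff entirely.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .errors import InvalidInputError, InvalidParameterError
from .landscape import NKLandscape, Solution, as_rng

OUTCOME_ACCEPTED = "accepted_better"
OUTCOME_KEPT_WORSE = "kept_worse"
OUTCOME_REVERTED = "reverted"
OUTCOMES = (OUTCOME_ACCEPTED, OUTCOME_KEPT_WORSE, OUTCOME_REVERTED)


@dataclass(frozen=True)
class AgentProfile:
    """One searcher: the dimensions it may flip and its risky-decision ratio."""

    dof_dims: tuple[int, ...]
    r: float = 0.0

    def __post_init__(self) -> None:
        dims = tuple(sorted(int(d) for d in self.dof_dims))
        if len(dims) == 0:
            raise InvalidParameterError("dof_dims must be non-empty")
        if len(set(dims)) != len(dims) or any(d < 0 for d in dims):
            raise InvalidParameterError(f"dof_dims must be distinct non-negative, got {self.dof_dims}")
        if not 0.0 <= self.r <= 1.0:
            raise InvalidParameterError(f"r must lie in [0, 1], got {self.r}")
        object.__setattr__(self, "dof_dims", dims)

    @property
    def dof(self) -> int:
        return len(self.dof_dims)


@dataclass(frozen=True, slots=True)
class DecisionRecord:
    """One round of search: the sampled flip and how it was resolved."""

    round_index: int
    from_solution: Solution
    flipped_dim: int
    sampled_solution: Solution
    payoff_before: float
    payoff_after: float
    outcome: str

    @property
    def resolved_solution(self) -> Solution:
        """The position after this round (sampled unless reverted)."""
        return self.from_solution if self.outcome == OUTCOME_REVERTED else self.sampled_solution

    @property
    def resolved_payoff(self) -> float:
        return self.payoff_before if self.outcome == OUTCOME_REVERTED else self.payoff_after


@dataclass(frozen=True)
class SearchTrace:
    """An agent's full search: start, per-round records, final position."""

    agent: AgentProfile
    start: Solution
    records: tuple[DecisionRecord, ...]
    final: Solution

    def resolved_payoffs(self, landscape: NKLandscape) -> list[float]:
        """Payoff of the resolved position after round 0, 1, ..., len(records)."""
        return [landscape.payoff(self.start)] + [r.resolved_payoff for r in self.records]

    @property
    def final_payoff(self) -> float:
        if self.records:
            return self.records[-1].resolved_payoff
        raise InvalidInputError("empty trace has no recorded final payoff; evaluate start instead")


def _validate_profile(agent: AgentProfile, landscape: NKLandscape) -> None:
    if max(agent.dof_dims) >= landscape.N:
        raise InvalidParameterError(
            f"dof_dims {agent.dof_dims} exceed landscape dimensions (N={landscape.N})"
        )


def search_step(
    current: Sequence[int],
    agent: AgentProfile,
    landscape: NKLandscape,
    rng: int | np.random.Generator | None = None,
    round_index: int = 1,
) -> tuple[Solution, DecisionRecord]:
    """Run one round of search from ``current`` and return (next, record).

    Exactly one dimension, uniform over ``agent.dof_dims``, is flipped.  A
    strict payoff improvement is always adopted; a non-improving sample is
    kept with probability ``agent.r`` and reverted otherwise.
    """
    gen = as_rng(rng)
    _validate_profile(agent, landscape)
    cur = landscape.validate_solution(current)
    d = agent.dof_dims[int(gen.integers(len(agent.dof_dims)))]
    sampled = cur[:d] + (1 - cur[d],) + cur[d + 1:]
    p_before = landscape.payoff(cur)
    p_after = landscape.payoff(sampled)
    if p_after > p_before:
        outcome = OUTCOME_ACCEPTED
        nxt = sampled
    else:
        # the uniform draw happens for every non-improving sample, so traces
        # at different r values share one underlying random stream
        if gen.random() < agent.r:
            outcome = OUTCOME_KEPT_WORSE
            nxt = sampled
        else:
            outcome = OUTCOME_REVERTED
            nxt = cur
    rec = DecisionRecord(
        round_index=round_index,
        from_solution=cur,
        flipped_dim=d,
        sampled_solution=sampled,
        payoff_before=p_before,
        payoff_after=p_after,
        outcome=outcome,
    )
    return nxt, rec


def run_agent(
    start: Sequence[int],
    steps: int,
    agent: AgentProfile,
    landscape: NKLandscape,
    rng: int | np.random.Generator | None = None,
) -> SearchTrace:
    """Run ``steps`` consecutive rounds and return the full trace."""
    if steps < 0:
        raise InvalidParameterError(f"steps must be >= 0, got {steps}")
    gen = as_rng(rng)
    _validate_profile(agent, landscape)
    cur = landscape.validate_solution(start)
    records: list[DecisionRecord] = []
    for t in range(1, steps + 1):
        cur, rec = search_step(cur, agent, landscape, gen, round_index=t)
        records.append(rec)
    return SearchTrace(agent=agent, start=landscape.validate_solution(start),
                       records=tuple(records), final=cur)
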