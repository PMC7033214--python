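"""The two collective search architectures.

Transmission chain: members search sequentially, each starting from the
predecessor's final solution; the collective solution is the last member's
final position.  Independent solvers: members search in parallel from a shared
start without interacting; the collective solution is the best final solution
in the group.

Randomness is organized so that member ``i`` consumes the same substream
regardless of group size: a master seed spawns one child stream per member
(plus one for the start draw when no start is given).  Truncating a stored
result to ``k`` members therefore reproduces a fresh ``k``-member run exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from .agents import AgentProfile, SearchTrace, run_agent
from .errors import InvalidParameterError
from .landscape import NKLandscape, Solution

METHOD_CHAIN = "chain"
METHOD_INDEPENDENT = "independent"
METHODS = (METHOD_CHAIN, METHOD_INDEPENDENT)


@dataclass(frozen=True)
class GroupRunConfig:
    """Parameters of one collective run.

    ``start=None`` means: draw a shared uniform-random start solution from the
    seed's dedicated substream.  Both architectures use the same start so they
    are compared from identical initial conditions.
    """

    method: str
    group_size: int
    steps_per_individual: int
    seed: int
    start: Solution | None = None

    def __post_init__(self) -> None:
        if self.method not in METHODS:
            raise InvalidParameterError(f"method must be one of {METHODS}, got {self.method!r}")
        if self.group_size < 1:
            raise InvalidParameterError(f"group_size must be >= 1, got {self.group_size}")
        if self.steps_per_individual < 0:
            raise InvalidParameterError(
                f"steps_per_individual must be >= 0, got {self.steps_per_individual}"
            )


@dataclass(frozen=True)
class GroupResult:
    """Traces of all members plus the collective payoff of the architecture."""

    method: str
    config: GroupRunConfig
    start: Solution
    traces: tuple[SearchTrace, ...]
    per_member_final_payoffs: tuple[float, ...]
    collective_payoff: float

    @property
    def group_size(self) -> int:
        return len(self.traces)


def _member_streams(config: GroupRunConfig) -> tuple[np.random.Generator, list[np.random.Generator]]:
    """(start stream, one stream per member), all spawned from the master seed."""
    root = np.random.SeedSequence(config.seed)
    children = root.spawn(config.group_size + 1)
    return np.random.default_rng(children[0]), [np.random.default_rng(c) for c in children[1:]]


def _resolve_start(config: GroupRunConfig, landscape: NKLandscape,
                   start_rng: np.random.Generator) -> Solution:
    if config.start is not None:
        return landscape.validate_solution(config.start)
    return landscape.random_solution(start_rng)


def _check_profiles(profiles: Sequence[AgentProfile], config: GroupRunConfig) -> None:
    if len(profiles) != config.group_size:
        raise InvalidParameterError(
            f"got {len(profiles)} profiles for group_size {config.group_size}"
        )


def run_transmission_chain(
    landscape: NKLandscape,
    profiles: Sequence[AgentProfile],
    config: GroupRunConfig,
) -> GroupResult:
    """Run a transmission chain; the collective payoff is the last member's final payoff."""
    if config.method != METHOD_CHAIN:
        raise InvalidParameterError(f"config.method must be 'chain', got {config.method!r}")
    _check_profiles(profiles, config)
    start_rng, streams = _member_streams(config)
    start = _resolve_start(config, landscape, start_rng)
    traces: list[SearchTrace] = []
    cur = start
    for profile, stream in zip(profiles, streams):
        trace = run_agent(cur, config.steps_per_individual, profile, landscape, stream)
        traces.append(trace)
        cur = trace.final
    finals = tuple(landscape.payoff(t.final) for t in traces)
    return GroupResult(
        method=METHOD_CHAIN, config=config, start=start, traces=tuple(traces),
        per_member_final_payoffs=finals, collective_payoff=finals[-1],
    )


def run_independent_group(
    landscape: NKLandscape,
    profiles: Sequence[AgentProfile],
    config: GroupRunConfig,
) -> GroupResult:
    """Run independent solvers; the collective payoff is the best member's final payoff."""
    if config.method != METHOD_INDEPENDENT:
        raise InvalidParameterError(
            f"config.method must be 'independent', got {config.method!r}"
        )
    _check_profiles(profiles, config)
    start_rng, streams = _member_streams(config)
    start = _resolve_start(config, landscape, start_rng)
    traces = tuple(
        run_agent(start, config.steps_per_individual, profile, landscape, stream)
        for profile, stream in zip(profiles, streams)
    )
    finals = tuple(landscape.payoff(t.final) for t in traces)
    return GroupResult(
        method=METHOD_INDEPENDENT, config=config, start=start, traces=traces,
        per_member_final_payoffs=finals, collective_payoff=max(finals),
    )


def run_group(landscape: NKLandscape, profiles: Sequence[AgentProfile],
              config: GroupRunConfig) -> GroupResult:
    """Dispatch on ``config.method``."""
    if config.method == METHOD_CHAIN:
        return run_transmission_chain(landscape, profiles, config)
    return run_independent_group(landscape, profiles, config)


def truncate_group(result: GroupResult, k: int) -> GroupResult:
    """Recompute the collective payoff keeping only the first ``k`` members.

    No re-simulation: stored traces are reused, later members are dropped.
    """
    if not 1 <= k <= result.group_size:
        raise InvalidParameterError(
            f"k must lie in [1, {result.group_size}], got {k}"
        )
    traces = result.traces[:k]
    finals = result.per_member_final_payoffs[:k]
    collective = finals[-1] if result.method == METHOD_CHAIN else max(finals)
    return GroupResult(
        method=result.method,
        config=replace(result.config, group_size=k),
        start=result.start,
        traces=traces,
        per_member_final_payoffs=finals,
        collective_payoff=collective,
    )


def performance_over_steps(result: GroupResult, landscape: NKLandscape) -> list[tuple[int, float]]:
    """Group performance after each total search step.

    Total steps sum over all members.  For a chain the performance at step
    ``t`` is the resolved payoff of the member active at ``t`` (members occupy
    consecutive segments).  For independent solvers members advance
    round-robin and the performance is the best current resolved payoff in
    the group.  Step 0 is the shared start payoff.
    """
    steps = result.config.steps_per_individual
    g = result.group_size
    # per-member resolved payoff after 0..steps of their own rounds
    per_member = [t.resolved_payoffs(landscape) for t in result.traces]
    out = [(0, landscape.payoff(result.start))]
    if result.method == METHOD_CHAIN:
        for t in range(1, g * steps + 1):
            member = (t - 1) // steps
            within = t - member * steps
            out.append((t, per_member[member][within]))
    else:
        for t in range(1, g * steps + 1):
            full, rem = divmod(t, g)
            current = max(
                per_member[i][full + (1 if i < rem else 0)] for i in range(g)
            )
            out.append((t, current))
    return out
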