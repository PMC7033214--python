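"""Synthetic experimental sessions, DoF assignment, diversity, and r estimation.

The design generator reproduces the structure of the behavioural study the
model was built for: 8 conditions crossing landscape ruggedness (K = 1 or 8),
degrees of freedom (DoF = 3 or 6) and architecture (chain or independent),
each played on 16 fresh N = 10 landscapes by groups of 8, with search limited
to 2 x DoF rounds and payoffs displayed on a x1000 scale.  Sessions are
simulated with model agents at a chosen risky-decision ratio ``r``, and
``estimate_r`` recovers ``r`` from the resulting decision log the same way it
would be fit to human data: among payoff-decreasing decisions, the fraction
not immediately reverted.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .agents import OUTCOME_KEPT_WORSE, AgentProfile
from .errors import EstimatorUndefinedError, InvalidInputError, InvalidParameterError
from .groups import METHOD_CHAIN, METHOD_INDEPENDENT, GroupRunConfig, run_group
from .landscape import as_rng, generate_landscape, solution_to_string

#: Column order of the decision-log CSV.
LOG_COLUMNS = [
    "session", "condition_K", "condition_DoF", "method", "landscape_id",
    "member", "round", "from_solution", "flipped_dim", "sampled_solution",
    "payoff_before", "payoff_after",
    "payoff_before_display", "payoff_after_display", "outcome",
]

DEFAULT_K_LEVELS = (1, 8)
DEFAULT_DOF_LEVELS = (3, 6)
DISPLAY_MULTIPLIER = 1000


@dataclass(frozen=True)
class Condition:
    """One experimental condition with its per-level landscape seeds."""

    K: int
    DoF: int
    method: str
    rounds: int
    landscape_seeds: tuple[int, ...]


@dataclass(frozen=True)
class ExperimentDesign:
    """The full session plan: 8 conditions x 16 landscapes, groups of 8."""

    conditions: tuple[Condition, ...]
    N: int = 10
    group_size: int = 8
    landscapes_per_condition: int = 16
    display_multiplier: int = DISPLAY_MULTIPLIER

    @property
    def total_levels(self) -> int:
        return sum(len(c.landscape_seeds) for c in self.conditions)

    def to_dict(self) -> dict:
        return {
            "N": self.N,
            "group_size": self.group_size,
            "landscapes_per_condition": self.landscapes_per_condition,
            "display_multiplier": self.display_multiplier,
            "conditions": [
                {
                    "K": c.K, "DoF": c.DoF, "method": c.method,
                    "rounds": c.rounds,
                    "landscape_seeds": list(c.landscape_seeds),
                }
                for c in self.conditions
            ],
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict()))

    @classmethod
    def from_dict(cls, d: dict) -> "ExperimentDesign":
        return cls(
            conditions=tuple(
                Condition(
                    K=int(c["K"]), DoF=int(c["DoF"]), method=c["method"],
                    rounds=int(c["rounds"]),
                    landscape_seeds=tuple(int(s) for s in c["landscape_seeds"]),
                )
                for c in d["conditions"]
            ),
            N=int(d.get("N", 10)),
            group_size=int(d.get("group_size", 8)),
            landscapes_per_condition=int(d.get("landscapes_per_condition", 16)),
            display_multiplier=int(d.get("display_multiplier", DISPLAY_MULTIPLIER)),
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "ExperimentDesign":
        return cls.from_dict(json.loads(Path(path).read_text()))


def generate_design(
    rng: int | np.random.Generator | None = None,
    *,
    N: int = 10,
    K_levels: Sequence[int] = DEFAULT_K_LEVELS,
    DoF_levels: Sequence[int] = DEFAULT_DOF_LEVELS,
    landscapes_per_condition: int = 16,
    group_size: int = 8,
) -> ExperimentDesign:
    """Generate the experimental design in randomized condition order.

    Rounds per level are 2 x DoF; each condition gets fresh landscape seeds.
    """
    gen = as_rng(rng)
    cells = list(itertools.product(K_levels, DoF_levels, (METHOD_CHAIN, METHOD_INDEPENDENT)))
    order = gen.permutation(len(cells))
    conditions = []
    for idx in order:
        k, dof, method = cells[int(idx)]
        seeds = tuple(int(s) for s in gen.integers(0, 2**31, size=landscapes_per_condition))
        conditions.append(Condition(K=k, DoF=dof, method=method, rounds=2 * dof,
                                    landscape_seeds=seeds))
    return ExperimentDesign(
        conditions=tuple(conditions), N=N, group_size=group_size,
        landscapes_per_condition=landscapes_per_condition,
    )


def assign_dof(
    N: int,
    DoF: int,
    group_size: int,
    rng: int | np.random.Generator | None = None,
) -> list[tuple[int, ...]]:
    """Draw one uniform-random DoF-subset of {0..N-1} per member (sets may overlap)."""
    if not 1 <= DoF <= N:
        raise InvalidParameterError(f"DoF must satisfy 1 <= DoF <= N, got DoF={DoF}, N={N}")
    gen = as_rng(rng)
    return [
        tuple(sorted(int(d) for d in gen.choice(N, size=DoF, replace=False)))
        for _ in range(group_size)
    ]


def diversity(dof_sets: Sequence[Iterable[int]]) -> float:
    """Mean pairwise symmetric-difference size of the members' manipulable sets.

    Zero when everyone can manipulate the same dimensions; bounded above by
    twice the set size for equal-size sets.
    """
    sets = [frozenset(s) for s in dof_sets]
    if len(sets) < 2:
        raise InvalidInputError("diversity needs at least 2 DoF sets")
    pairs = list(itertools.combinations(sets, 2))
    return float(np.mean([len(a ^ b) for a, b in pairs]))


def simulate_session(
    design: ExperimentDesign,
    r: float = 0.0,
    rng: int | np.random.Generator | None = None,
    session: str = "synthetic-1",
) -> pd.DataFrame:
    """Play every level of the design with model agents and log every decision.

    Returns a flat table, one row per decision, in the :data:`LOG_COLUMNS`
    schema.  Payoffs are reported both normalized and on the x1000 display
    scale; solutions are serialized as bit strings.
    """
    gen = as_rng(rng)
    rows: list[dict] = []
    level_id = 0
    for cond in design.conditions:
        for ls_seed in cond.landscape_seeds:
            landscape = generate_landscape(design.N, cond.K, ls_seed)
            dof_sets = assign_dof(design.N, cond.DoF, design.group_size, gen)
            profiles = [AgentProfile(dof_dims=s, r=r) for s in dof_sets]
            config = GroupRunConfig(
                method=cond.method, group_size=design.group_size,
                steps_per_individual=cond.rounds,
                seed=int(gen.integers(0, 2**31)),
            )
            result = run_group(landscape, profiles, config)
            mult = design.display_multiplier
            for member, trace in enumerate(result.traces):
                for rec in trace.records:
                    rows.append({
                        "session": session,
                        "condition_K": cond.K,
                        "condition_DoF": cond.DoF,
                        "method": cond.method,
                        "landscape_id": level_id,
                        "member": member,
                        "round": rec.round_index,
                        "from_solution": solution_to_string(rec.from_solution),
                        "flipped_dim": rec.flipped_dim,
                        "sampled_solution": solution_to_string(rec.sampled_solution),
                        "payoff_before": rec.payoff_before,
                        "payoff_after": rec.payoff_after,
                        "payoff_before_display": rec.payoff_before * mult,
                        "payoff_after_display": rec.payoff_after * mult,
                        "outcome": rec.outcome,
                    })
            level_id += 1
    return pd.DataFrame(rows, columns=LOG_COLUMNS)


def estimate_r(log: pd.DataFrame) -> float:
    """Estimate the risky-decision ratio from a decision log.

    Only payoff-decreasing decisions (strict) enter the denominator; the
    estimate is the fraction of those that were not immediately reverted.
    """
    for col in ("payoff_before", "payoff_after", "outcome"):
        if col not in log.columns:
            raise InvalidInputError(f"decision log lacks required column {col!r}")
    worse = log[log["payoff_after"] < log["payoff_before"]]
    if len(worse) == 0:
        raise EstimatorUndefinedError(
            "no payoff-decreasing decisions in the log; r is undefined"
        )
    return float((worse["outcome"] == OUTCOME_KEPT_WORSE).mean())


def write_log(log: pd.DataFrame, path: str | Path) -> None:
    """Write a decision log as CSV with the documented header."""
    log.to_csv(path, index=False)


def read_log(path: str | Path) -> pd.DataFrame:
    """Read a decision-log CSV, keeping solution bit strings as strings."""
    return pd.read_csv(path, dtype={"from_solution": str, "sampled_solution": str})
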