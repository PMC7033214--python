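"""Monte-Carlo sweeps and aggregate analyses of collective performance.

The sweep is paired: within one repetition the chain and the independent
group face the same landscape, the same start solution and the same member
profiles, and differ only in architecture.  Pairing uses common random
draws for the shared ingredients, which lowers the variance of method
differences without changing their expectation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .agents import AgentProfile
from .errors import (
    DegenerateFitError,
    InvalidParameterError,
    MissingConditionError,
)
from .experiment import assign_dof, diversity
from .groups import (
    METHOD_CHAIN,
    METHOD_INDEPENDENT,
    METHODS,
    GroupResult,
    GroupRunConfig,
    run_group,
    truncate_group,
)
from .landscape import generate_landscape


@dataclass(frozen=True)
class ConditionSummary:
    """Collective-performance aggregates of one (K, DoF, method) cell."""

    K: int
    DoF: int
    method: str
    group_size: int
    steps: int
    r: float
    payoffs: tuple[float, ...]

    @property
    def repetitions(self) -> int:
        return len(self.payoffs)

    @property
    def mean(self) -> float:
        return float(np.mean(self.payoffs))

    @property
    def variance(self) -> float:
        return float(np.var(self.payoffs, ddof=1)) if len(self.payoffs) > 1 else 0.0

    @property
    def standard_error(self) -> float:
        return float(np.sqrt(self.variance / self.repetitions))


def sweep(
    K_values: Sequence[int],
    DoF_values: Sequence[int],
    methods: Sequence[str] = METHODS,
    group_size: int = 8,
    steps: int = 16,
    repetitions: int = 2500,
    r: float = 0.0,
    seed: int = 0,
    N: int = 10,
) -> list[ConditionSummary]:
    """Collective performance over a (K, DoF) grid for each architecture.

    Every repetition draws a fresh landscape, start solution and DoF
    assignment; all requested methods reuse that draw (paired design) but
    search with their own random streams.
    """
    if not (len(K_values) and len(DoF_values) and len(methods)):
        raise InvalidParameterError("K_values, DoF_values and methods must be non-empty")
    for m in methods:
        if m not in METHODS:
            raise InvalidParameterError(f"unknown method {m!r}")
    root = np.random.SeedSequence(seed)
    cells = [(k, dof) for k in K_values for dof in DoF_values]
    cell_seeds = root.spawn(len(cells))
    summaries: list[ConditionSummary] = []
    for (k, dof), cell_ss in zip(cells, cell_seeds):
        payoffs: dict[str, list[float]] = {m: [] for m in methods}
        for rep_ss in cell_ss.spawn(repetitions):
            ls_ss, draw_ss, chain_ss, indep_ss = rep_ss.spawn(4)
            landscape = generate_landscape(N, k, np.random.default_rng(ls_ss))
            draw_rng = np.random.default_rng(draw_ss)
            start = landscape.random_solution(draw_rng)
            profiles = [
                AgentProfile(dof_dims=s, r=r)
                for s in assign_dof(N, dof, group_size, draw_rng)
            ]
            run_seeds = {
                METHOD_CHAIN: int(chain_ss.generate_state(1)[0] % 2**31),
                METHOD_INDEPENDENT: int(indep_ss.generate_state(1)[0] % 2**31),
            }
            for method in methods:
                config = GroupRunConfig(
                    method=method, group_size=group_size,
                    steps_per_individual=steps, start=start,
                    seed=run_seeds[method],
                )
                payoffs[method].append(run_group(landscape, profiles, config).collective_payoff)
        for method in methods:
            summaries.append(ConditionSummary(
                K=k, DoF=dof, method=method, group_size=group_size,
                steps=steps, r=r, payoffs=tuple(payoffs[method]),
            ))
    return summaries


def summaries_to_frame(summaries: Iterable[ConditionSummary]) -> pd.DataFrame:
    """Tidy one-row-per-cell view of sweep output."""
    return pd.DataFrame([
        {
            "K": s.K, "DoF": s.DoF, "method": s.method,
            "group_size": s.group_size, "steps": s.steps, "r": s.r,
            "repetitions": s.repetitions, "mean_collective_payoff": s.mean,
            "variance": s.variance, "standard_error": s.standard_error,
        }
        for s in summaries
    ])


def difference_map(summaries: Iterable[ConditionSummary]) -> pd.DataFrame:
    """Per-(K, DoF) mean difference: independent minus chain.

    Positive values mean independent solvers outperform transmission chains.
    When the two summaries of a cell come from a paired sweep (equal
    repetition counts), the Monte-Carlo standard error is the paired one.
    """
    by_cell: dict[tuple[int, int], dict[str, ConditionSummary]] = {}
    for s in summaries:
        by_cell.setdefault((s.K, s.DoF), {})[s.method] = s
    rows = []
    for (k, dof), pair in sorted(by_cell.items()):
        if METHOD_CHAIN not in pair or METHOD_INDEPENDENT not in pair:
            raise MissingConditionError(
                f"cell (K={k}, DoF={dof}) lacks one of the two methods"
            )
        ind, cha = pair[METHOD_INDEPENDENT], pair[METHOD_CHAIN]
        if ind.repetitions == cha.repetitions:
            diffs = np.asarray(ind.payoffs) - np.asarray(cha.payoffs)
            se = float(diffs.std(ddof=1) / np.sqrt(len(diffs)))
            mean_diff = float(diffs.mean())
        else:
            mean_diff = ind.mean - cha.mean
            se = float(np.sqrt(ind.variance / ind.repetitions + cha.variance / cha.repetitions))
        rows.append({
            "K": k, "DoF": dof,
            "difference": mean_diff, "standard_error": se,
            "repetitions": min(ind.repetitions, cha.repetitions),
        })
    return pd.DataFrame(rows)


def group_size_curve(results: Sequence[GroupResult], sizes: Sequence[int]) -> pd.DataFrame:
    """Mean and variance of collective performance truncated to each size.

    Later members of each stored result are dropped (no re-simulation), so
    the curve shows what the same groups would have achieved at smaller size.
    """
    max_size = min(r.group_size for r in results)
    for k in sizes:
        if not 1 <= k <= max_size:
            raise InvalidParameterError(
                f"size {k} exceeds the smallest stored group ({max_size})"
            )
    rows = []
    by_method: dict[str, list[GroupResult]] = {}
    for res in results:
        by_method.setdefault(res.method, []).append(res)
    for method, group in sorted(by_method.items()):
        for k in sizes:
            vals = [truncate_group(res, k).collective_payoff for res in group]
            rows.append({
                "method": method, "group_size": k,
                "mean_collective_payoff": float(np.mean(vals)),
                "variance": float(np.var(vals, ddof=1)) if len(vals) > 1 else 0.0,
                "n": len(vals),
            })
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class DiversityFit:
    """OLS fit of collective payoff on group diversity."""

    slope: float
    slope_se: float
    intercept: float
    pvalue: float
    adj_r2: float
    n: int

    @property
    def tvalue(self) -> float:
        return self.slope / self.slope_se


def diversity_effect(records: Sequence[tuple[float, float]]) -> DiversityFit:
    """Regress collective payoff on diversity across groups.

    ``records`` holds one ``(diversity, collective_payoff)`` pair per group.
    """
    arr = np.asarray(list(records), dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 3:
        raise InvalidParameterError(
            "records must be >= 3 (diversity, payoff) pairs"
        )
    x, y = arr[:, 0], arr[:, 1]
    if np.ptp(x) == 0:
        raise DegenerateFitError("diversity has zero variance; slope is undefined")
    model = sm.OLS(y, sm.add_constant(x)).fit()
    with np.errstate(invalid="ignore"):  # adj R2 is NaN when y is constant
        adj_r2 = float(model.rsquared_adj)
    return DiversityFit(
        slope=float(model.params[1]),
        slope_se=float(model.bse[1]),
        intercept=float(model.params[0]),
        pvalue=float(model.pvalues[1]),
        adj_r2=adj_r2,
        n=int(model.nobs),
    )


def simulate_diversity_records(
    n_groups: int,
    K: int = 8,
    DoF: int = 3,
    method: str = METHOD_INDEPENDENT,
    group_size: int = 8,
    steps: int | None = None,
    r: float = 0.0,
    seed: int = 0,
    N: int = 10,
) -> list[tuple[float, float]]:
    """Simulate groups and return their (diversity, collective payoff) pairs.

    Steps default to the 2 x DoF rule of the experimental protocol.
    """
    if steps is None:
        steps = 2 * DoF
    root = np.random.SeedSequence(seed)
    records = []
    for grp_ss in root.spawn(n_groups):
        ls_ss, draw_ss, run_ss = grp_ss.spawn(3)
        landscape = generate_landscape(N, K, np.random.default_rng(ls_ss))
        draw_rng = np.random.default_rng(draw_ss)
        start = landscape.random_solution(draw_rng)
        dof_sets = assign_dof(N, DoF, group_size, draw_rng)
        profiles = [AgentProfile(dof_dims=s, r=r) for s in dof_sets]
        config = GroupRunConfig(
            method=method, group_size=group_size, steps_per_individual=steps,
            start=start, seed=int(run_ss.generate_state(1)[0] % 2**31),
        )
        result = run_group(landscape, profiles, config)
        records.append((diversity(dof_sets), result.collective_payoff))
    return records
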