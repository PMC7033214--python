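"""Transmission chains vs independent solvers: collective payoff, truncation, traces."""

import numpy as np
import pytest

from nkcollective import (
    AgentProfile,
    GroupRunConfig,
    generate_landscape,
    performance_over_steps,
    run_agent,
    run_independent_group,
    run_transmission_chain,
    truncate_group,
)
from nkcollective.errors import InvalidParameterError
from nkcollective.groups import _member_streams


def make_profiles(n_members, dof_dims, r=0.0):
    return [AgentProfile(dof_dims=dof_dims, r=r) for _ in range(n_members)]


class TestChain:
    def test_single_member_equals_run_agent(self, rugged_landscape):
        config = GroupRunConfig(method="chain", group_size=1,
                                steps_per_individual=16, seed=21)
        profile = AgentProfile(dof_dims=(0, 1, 2), r=0.0)
        result = run_transmission_chain(rugged_landscape, [profile], config)
        start_rng, streams = _member_streams(config)
        start = rugged_landscape.random_solution(start_rng)
        solo = run_agent(start, 16, profile, rugged_landscape, streams[0])
        assert result.traces[0] == solo
        assert result.collective_payoff == rugged_landscape.payoff(solo.final)

    def test_collective_is_last_members_final(self, rugged_landscape):
        config = GroupRunConfig(method="chain", group_size=8,
                                steps_per_individual=16, seed=4)
        result = run_transmission_chain(
            rugged_landscape, make_profiles(8, (0, 1, 2), r=0.5), config)
        assert result.collective_payoff == rugged_landscape.payoff(result.traces[-1].final)
        # with r>0 an intermediate member may have done better; collective ignores it
        assert result.collective_payoff == result.per_member_final_payoffs[-1]

    def test_members_chain_positions(self, smooth_landscape):
        config = GroupRunConfig(method="chain", group_size=4,
                                steps_per_individual=10, seed=9)
        result = run_transmission_chain(
            smooth_landscape, make_profiles(4, (0, 3, 5), r=0.2), config)
        for prev, nxt in zip(result.traces, result.traces[1:]):
            assert nxt.start == prev.final

    def test_complementary_dof_composes_additive_optimum(self):
        """Sequential optimization of disjoint sub-cubes solves a K=0 landscape."""
        solved = 0
        n = 1000
        for seed in range(n):
            ls = generate_landscape(4, 0, 10_000 + seed)
            profiles = [AgentProfile(dof_dims=(0, 1)), AgentProfile(dof_dims=(2, 3))]
            config = GroupRunConfig(method="chain", group_size=2,
                                    steps_per_individual=50, seed=seed)
            result = run_transmission_chain(ls, profiles, config)
            if result.collective_payoff == pytest.approx(1.0, abs=1e-12):
                solved += 1
        assert solved >= 0.99 * n

    def test_method_mismatch_rejected(self, smooth_landscape):
        config = GroupRunConfig(method="independent", group_size=2,
                                steps_per_individual=5, seed=0)
        with pytest.raises(InvalidParameterError):
            run_transmission_chain(smooth_landscape, make_profiles(2, (0, 1)), config)

    def test_profile_count_mismatch_rejected(self, smooth_landscape):
        config = GroupRunConfig(method="chain", group_size=3,
                                steps_per_individual=5, seed=0)
        with pytest.raises(InvalidParameterError):
            run_transmission_chain(smooth_landscape, make_profiles(2, (0, 1)), config)


class TestIndependent:
    def test_collective_is_best_member(self, rugged_landscape):
        config = GroupRunConfig(method="independent", group_size=8,
                                steps_per_individual=16, seed=13)
        result = run_independent_group(
            rugged_landscape, make_profiles(8, (0, 1, 2, 3), r=0.11), config)
        assert result.collective_payoff == max(result.per_member_final_payoffs)
        for p in result.per_member_final_payoffs:
            assert result.collective_payoff >= p

    def test_all_members_share_start(self, rugged_landscape):
        config = GroupRunConfig(method="independent", group_size=5,
                                steps_per_individual=8, seed=2)
        result = run_independent_group(
            rugged_landscape, make_profiles(5, (1, 2, 6)), config)
        assert all(t.start == result.start for t in result.traces)

    def test_reproducible_under_seed(self, rugged_landscape):
        config = GroupRunConfig(method="independent", group_size=4,
                                steps_per_individual=12, seed=77)
        profiles = make_profiles(4, (0, 4, 9), r=0.3)
        a = run_independent_group(rugged_landscape, profiles, config)
        b = run_independent_group(rugged_landscape, profiles, config)
        assert a == b


class TestTruncation:
    @pytest.fixture()
    def pair(self, rugged_landscape):
        results = {}
        for method in ("chain", "independent"):
            config = GroupRunConfig(method=method, group_size=8,
                                    steps_per_individual=16, seed=31)
            profiles = make_profiles(8, (0, 2, 5), r=0.11)
            runner = run_transmission_chain if method == "chain" else run_independent_group
            results[method] = (runner(rugged_landscape, profiles, config), profiles)
        return results

    def test_full_size_is_identity(self, pair):
        for result, _ in pair.values():
            assert truncate_group(result, 8).collective_payoff == result.collective_payoff

    def test_truncation_equals_fresh_smaller_run(self, pair, rugged_landscape):
        """Member substreams do not depend on group size, so dropping later
        members reproduces a fresh smaller run exactly."""
        for method, (result, profiles) in pair.items():
            for k in (1, 3, 5):
                truncated = truncate_group(result, k)
                config = GroupRunConfig(method=method, group_size=k,
                                        steps_per_individual=16, seed=31)
                runner = run_transmission_chain if method == "chain" else run_independent_group
                fresh = runner(rugged_landscape, profiles[:k], config)
                assert truncated.collective_payoff == fresh.collective_payoff
                assert truncated.traces == fresh.traces

    def test_chain_truncation_reads_member_k(self, pair, rugged_landscape):
        result, _ = pair["chain"]
        assert truncate_group(result, 3).collective_payoff == pytest.approx(
            rugged_landscape.payoff(result.traces[2].final))

    def test_independent_monotone_in_size(self, pair):
        result, _ = pair["independent"]
        vals = [truncate_group(result, k).collective_payoff for k in range(1, 9)]
        assert all(a <= b for a, b in zip(vals, vals[1:]))

    def test_out_of_range_rejected(self, pair):
        result, _ = pair["chain"]
        for k in (0, 9):
            with pytest.raises(InvalidParameterError):
                truncate_group(result, k)


class TestPerformanceOverSteps:
    @pytest.mark.parametrize("method", ["chain", "independent"])
    def test_step_zero_is_start_payoff(self, method, rugged_landscape):
        config = GroupRunConfig(method=method, group_size=4,
                                steps_per_individual=6, seed=3)
        profiles = make_profiles(4, (0, 1, 2))
        runner = run_transmission_chain if method == "chain" else run_independent_group
        result = runner(rugged_landscape, profiles, config)
        series = performance_over_steps(result, rugged_landscape)
        assert series[0] == (0, rugged_landscape.payoff(result.start))
        assert len(series) == 4 * 6 + 1
        assert series[-1][1] == pytest.approx(result.collective_payoff)

    @pytest.mark.parametrize("method", ["chain", "independent"])
    def test_hill_climbers_never_lose_ground(self, method, rugged_landscape):
        config = GroupRunConfig(method=method, group_size=8,
                                steps_per_individual=16, seed=41)
        profiles = make_profiles(8, (0, 1, 2), r=0.0)
        runner = run_transmission_chain if method == "chain" else run_independent_group
        result = runner(rugged_landscape, profiles, config)
        perf = [p for _, p in performance_over_steps(result, rugged_landscape)]
        assert all(a <= b + 1e-15 for a, b in zip(perf, perf[1:]))

    def test_risky_chains_are_volatile(self, rugged_landscape):
        """r>0 chains show within-trace payoff drops; r=0 chains never do."""
        drops = {0.0: 0, 0.11: 0}
        for r, key in ((0.0, 0.0), (0.11, 0.11)):
            for seed in range(200):
                config = GroupRunConfig(method="chain", group_size=8,
                                        steps_per_individual=16, seed=seed)
                profiles = make_profiles(8, (0, 1, 2), r=r)
                result = run_transmission_chain(rugged_landscape, profiles, config)
                perf = [p for _, p in performance_over_steps(result, rugged_landscape)]
                if any(b < a for a, b in zip(perf, perf[1:])):
                    drops[key] += 1
        assert drops[0.0] == 0
        assert drops[0.11] > 0
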