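"""Emission trajectories and per-gram benefit computations."""

import numpy as np
import pandas as pd
import pytest

from dioxin_bpt import (
    BASELINE,
    POLICY,
    EmissionTrajectory,
    Period,
    TrajectorySegment,
    ValidationError,
    bpt_group,
    bpt_national,
    bpt_region,
    build_trajectory,
    compute_monetized_mortality,
    cumulative_net_bpt,
    net_bpt,
    net_bpt_table,
    share_of_total,
)
from conftest import brute_force_mdc

PERIODS = [Period("2020", 2020, 2020)] + [
    Period(f"{y}-{y + 4}", y, y + 4) for y in range(2021, 2070, 5)
]


class TestBuildTrajectory:
    def test_linear_halving_over_six_periods(self):
        seg = TrajectorySegment(0, 6, 1.0, 0.5)
        tail = TrajectorySegment(6, 10, 0.5, 0.1)
        traj = build_trajectory({"nation": 57.8}, [seg, tail], PERIODS)
        assert traj.level(POLICY, "nation", "2021-2025") == pytest.approx(52.9833, abs=5e-4)
        assert traj.level(POLICY, "nation", "2046-2050") == pytest.approx(28.9, abs=1e-9)
        # second, steeper leg down to 10% of base
        assert traj.level(POLICY, "nation", "2051-2055") == pytest.approx(23.1200, abs=5e-4)
        assert traj.level(POLICY, "nation", "2066-2070") == pytest.approx(5.78, abs=1e-9)
        # baseline holds the base level throughout
        assert set(traj.emissions[BASELINE]) == {57.8}

    def test_flat_segment_reproduces_base_everywhere(self):
        seg = TrajectorySegment(0, 10, 1.0, 1.0)
        traj = build_trajectory({"a": 3.0, "b": 7.0}, [seg], PERIODS)
        assert set(traj.emissions.loc["a", POLICY]) == {3.0}
        assert (traj.emissions[POLICY] == traj.emissions[BASELINE]).all()

    def test_regions_scale_proportionally(self):
        seg = TrajectorySegment(0, 10, 1.0, 0.5)
        traj = build_trajectory({"a": 10.0, "b": 40.0}, [seg], PERIODS)
        ratios = traj.emissions.loc["b", POLICY] / traj.emissions.loc["a", POLICY]
        assert np.allclose(ratios, 4.0, rtol=1e-12)

    def test_gap_between_segments_rejected(self):
        with pytest.raises(ValidationError, match="tile"):
            build_trajectory(
                {"a": 1.0},
                [TrajectorySegment(0, 4, 1.0, 0.5), TrajectorySegment(5, 10, 0.5, 0.2)],
                PERIODS,
            )

    def test_increasing_segment_rejected(self):
        with pytest.raises(ValidationError):
            TrajectorySegment(0, 5, 0.5, 0.8)

    def test_policy_above_baseline_rejected(self):
        df = pd.DataFrame(
            {POLICY: [2.0], BASELINE: [1.0]},
            index=pd.MultiIndex.from_tuples([("a", "2020")]),
        )
        with pytest.raises(ValidationError):
            EmissionTrajectory(emissions=df)


class TestPerGramBenefits:
    def test_group_level_division(self, taiwan_mdc, taiwan_trajectory):
        value = bpt_group(taiwan_mdc, taiwan_trajectory, BASELINE, "children", "taiwan",
                          "2021-2025")
        assert value == pytest.approx(7_748.2, rel=1e-4)
        value = bpt_group(taiwan_mdc, taiwan_trajectory, POLICY, "children", "taiwan",
                          "2021-2025")
        assert value == pytest.approx(8_452.6, rel=1e-4)

    def test_region_level_sums_age_groups(self, taiwan_mdc, taiwan_trajectory):
        assert bpt_region(taiwan_mdc, taiwan_trajectory, POLICY, "northern", "2020") == (
            pytest.approx(693_882, abs=2)
        )
        assert bpt_region(taiwan_mdc, taiwan_trajectory, POLICY, "southern", "2020") == (
            pytest.approx(1_186_675, abs=2)
        )

    def test_national_headline(self, taiwan_mdc, taiwan_trajectory):
        assert bpt_national(taiwan_mdc, taiwan_trajectory, POLICY, "taiwan", "2020") == (
            pytest.approx(837_915, abs=2)
        )
        assert bpt_national(taiwan_mdc, taiwan_trajectory, BASELINE, "taiwan",
                            "2021-2025") == pytest.approx(861_095, abs=2)

    def test_zero_emissions_guarded(self, taiwan_mdc):
        df = pd.DataFrame(
            {POLICY: [0.0], BASELINE: [1.0]},
            index=pd.MultiIndex.from_tuples([("taiwan", "2020")]),
        )
        with pytest.raises(ValidationError):
            EmissionTrajectory(emissions=df)


class TestNetBPT:
    def test_group_net(self, taiwan_mdc, taiwan_trajectory):
        value = net_bpt(taiwan_mdc, taiwan_trajectory, "taiwan", "2021-2025",
                        age_group="children")
        assert value == pytest.approx(704, abs=2)

    def test_coinciding_paths_give_zero(self, taiwan_mdc, taiwan_trajectory):
        for region in ("northern", "central", "southern", "eastern", "taiwan"):
            assert net_bpt(taiwan_mdc, taiwan_trajectory, region, "2020") == 0.0

    def test_region_net_sums_groups(self, taiwan_mdc, taiwan_trajectory):
        total = net_bpt(taiwan_mdc, taiwan_trajectory, "taiwan", "2021-2025")
        assert total == pytest.approx(78_282, abs=2)
        parts = [
            net_bpt(taiwan_mdc, taiwan_trajectory, "taiwan", "2021-2025", age_group=g)
            for g in ("children", "working_age", "older")
        ]
        assert total == pytest.approx(sum(parts), rel=1e-12)

    def test_all_national_cells_match_published_values(self, taiwan_mdc, taiwan_trajectory):
        """The national net-benefit rows across all ten projection periods."""
        published = {
            "children": [704, 1451, 2261, 3389, 4720, 6270, 8780, 12759, 20692, 44723],
            "working_age": [42761, 88351, 138170, 192278, 252014, 320885, 446480,
                            641320, 1009752, 2119758],
            "older": [34817, 91947, 174239, 282928, 430241, 630022, 936866, 1427554,
                      2379924, 5038875],
            None: [78282, 181748, 314671, 478595, 686975, 957177, 1392126, 2081633,
                   3410368, 7203356],
        }
        period_ids = [p.id for p in PERIODS[1:]]
        for group, expected in published.items():
            actual = [
                net_bpt(taiwan_mdc, taiwan_trajectory, "taiwan", pid, age_group=group)
                for pid in period_ids
            ]
            np.testing.assert_allclose(actual, expected, rtol=1e-4, atol=2,
                                       err_msg=f"group={group}")

    def test_monotone_in_policy_reduction(self, taiwan_mdc, taiwan_trajectory):
        """With the burden fixed, cutting policy emissions deeper raises the
        net benefit strictly."""
        df = taiwan_trajectory.emissions.copy()
        base = net_bpt(taiwan_mdc, taiwan_trajectory, "taiwan", "2021-2025")
        df.loc[("taiwan", "2021-2025"), POLICY] *= 0.9
        deeper = net_bpt(taiwan_mdc, EmissionTrajectory(emissions=df), "taiwan",
                         "2021-2025")
        assert deeper > base > 0

    def test_homogeneity_in_emissions(self, taiwan_mdc, taiwan_trajectory):
        """Scaling all emissions by c scales every per-gram value by 1/c."""
        scaled = EmissionTrajectory(emissions=taiwan_trajectory.emissions * 4.0)
        for region in ("taiwan", "southern"):
            a = net_bpt(taiwan_mdc, taiwan_trajectory, region, "2031-2035")
            b = net_bpt(taiwan_mdc, scaled, region, "2031-2035")
            assert b == pytest.approx(a / 4.0, rel=1e-12)
            a = bpt_region(taiwan_mdc, taiwan_trajectory, POLICY, region, "2031-2035")
            b = bpt_region(taiwan_mdc, scaled, POLICY, region, "2031-2035")
            assert b == pytest.approx(a / 4.0, rel=1e-12)


class TestCumulativeAndShares:
    def test_cumulative_sums(self, taiwan_mdc, taiwan_trajectory):
        result = net_bpt_table(taiwan_mdc, taiwan_trajectory)
        first = [p.id for p in PERIODS[1:7]]
        second = [p.id for p in PERIODS[7:]]
        assert cumulative_net_bpt(result, first, "taiwan") == pytest.approx(
            2_697_448, rel=1e-4, abs=12
        )
        assert cumulative_net_bpt(result, second, "central") == pytest.approx(
            4_225_620, rel=1e-4, abs=8
        )

    def test_empty_period_list_sums_to_zero(self, taiwan_mdc, taiwan_trajectory):
        result = net_bpt_table(taiwan_mdc, taiwan_trajectory)
        assert cumulative_net_bpt(result, [], "taiwan") == 0.0

    def test_unknown_period_rejected(self, taiwan_mdc, taiwan_trajectory):
        result = net_bpt_table(taiwan_mdc, taiwan_trajectory)
        with pytest.raises(ValidationError, match="2999"):
            cumulative_net_bpt(result, ["2999"], "taiwan")

    def test_share_of_total(self):
        assert share_of_total(14_087_483, [2_697_448, 14_087_483]) == pytest.approx(
            0.8393, abs=5e-5
        )
        assert share_of_total(2_697_448, [2_697_448, 14_087_483]) == pytest.approx(
            0.1607, abs=5e-5
        )
        assert share_of_total(3.0, [3.0]) == 1.0

    def test_zero_denominator_rejected(self):
        with pytest.raises(ValidationError):
            share_of_total(1.0, [0.0])


def test_brute_force_oracle_equivalence(small_scenario):
    """Every per-gram value on a random scenario equals a scalar-loop
    recomputation to near machine precision."""
    sc = small_scenario
    mdc = compute_monetized_mortality(sc)
    oracle_mdc = brute_force_mdc(sc)
    aligned = oracle_mdc.reindex(mdc.mdc.index)
    np.testing.assert_allclose(mdc.mdc.to_numpy(), aligned.to_numpy(), rtol=1e-12)

    result = net_bpt_table(mdc, sc.trajectory)
    for region in [r.id for r in sc.regions]:
        for period in sc.periods:
            e_pol = sc.trajectory.level(POLICY, region, period.id)
            e_base = sc.trajectory.level(BASELINE, region, period.id)
            for group in [g.value for g in sc.age_groups]:
                cell = oracle_mdc.loc[(group, region, period.id)]
                expected = cell / e_pol
                actual = bpt_group(mdc, sc.trajectory, POLICY, group, region, period.id)
                assert actual == pytest.approx(expected, rel=1e-12)
            total = sum(
                oracle_mdc.loc[(g.value, region, period.id)] for g in sc.age_groups
            )
            assert bpt_region(mdc, sc.trajectory, POLICY, region, period.id) == (
                pytest.approx(total / e_pol, rel=1e-12)
            )
            assert net_bpt(mdc, sc.trajectory, region, period.id) == pytest.approx(
                total * (1 / e_pol - 1 / e_base), rel=1e-12, abs=1e-9
            )
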