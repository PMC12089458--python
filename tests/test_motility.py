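"""Cone-section direction classification and the line x class association test."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from alskit import motility
from alskit.motility import MotilityClass, MotilityParams, classify_direction

AXIS_X = (1.0, 0.0)


class TestClassifyDirection:
    @pytest.mark.parametrize(
        "step,expected",
        [
            ((1.0, 0.0), "anterograde"),
            ((-2.0, 0.0), "retrograde"),
            ((0.0, 3.0), "orthogonal"),
        ],
    )
    def test_examples(self, step, expected):
        assert classify_direction(step, AXIS_X) == expected

    def test_boundary_cosine_is_inclusive_to_motile_classes(self):
        # a step like (1, sqrt(8)) has cosine 1/3 against +x; classify with
        # the exactly-computed cosine so the boundary case is hit in floats
        step = np.array([1.0, math.sqrt(8.0)])
        c = step[0] / np.linalg.norm(step)
        assert classify_direction(step, AXIS_X, cos_half_angle=c) == "anterograde"
        assert classify_direction(-step, AXIS_X, cos_half_angle=c) == "retrograde"

    def test_zero_step_is_sentinel(self):
        assert classify_direction((0.0, 0.0), AXIS_X) is None

    @given(
        hnp.arrays(np.float64, 3, elements=st.floats(-10, 10, allow_nan=False)),
        st.floats(0.01, 100.0),
    )
    @settings(deadline=None)
    def test_scale_invariance(self, step, scale):
        axis = (0.0, 0.0, 1.0)
        assert classify_direction(step, axis) == classify_direction(step * scale, axis)

    @given(hnp.arrays(np.float64, 3, elements=st.floats(-10, 10, allow_nan=False)))
    @settings(deadline=None)
    def test_axis_flip_swaps_polar_classes(self, step):
        axis = np.array([0.0, 0.6, 0.8])
        a = classify_direction(step, axis)
        b = classify_direction(step, -axis)
        swap = {"anterograde": "retrograde", "retrograde": "anterograde"}
        assert b == swap.get(a, a)

    def test_sphere_trisection_monte_carlo(self, rng):
        """The cos(1/3) cone trisects the sphere: each class gets 1/3 of
        isotropic 3D directions, within 3 Monte-Carlo standard errors."""
        n = 100_000
        v = rng.normal(size=(n, 3))
        v /= np.linalg.norm(v, axis=1, keepdims=True)
        c = v @ np.array([0.0, 0.0, 1.0])
        fracs = [
            np.mean(c >= 1 / 3),
            np.mean(c <= -1 / 3),
            np.mean((c > -1 / 3) & (c < 1 / 3)),
        ]
        se = math.sqrt((1 / 3) * (2 / 3) / n)
        for f in fracs:
            assert abs(f - 1 / 3) < 3 * se

    def test_internal_cone_angle_is_141_degrees(self):
        assert round(2 * math.degrees(math.acos(motility.CONE_COS_HALF_ANGLE))) == 141


class TestClassifyBranch:
    def test_steady_run_is_anterograde(self, branch_factory):
        # 20 steps of 0.15 um at 2 s: max speed 0.075 um/s, path 3 um
        b = branch_factory([(0.15 * i, 0.0) for i in range(21)])
        assert motility.classify_branch(b, MotilityParams()) == MotilityClass.ANTEROGRADE

    def test_slow_jitter_is_stationary_by_speed(self, branch_factory, rng):
        pos = np.cumsum(rng.uniform(-0.01, 0.01, size=(180, 2)), axis=0)
        b = branch_factory(pos)
        assert b.max_step_speed < 0.05
        assert motility.classify_branch(b, MotilityParams()) == MotilityClass.STATIONARY

    def test_short_oscillation_is_stationary_by_distance(self, branch_factory):
        # 10 steps of 0.19 um alternating +-x: path 1.9 um, max speed 0.095 um/s
        xs = [0.0]
        for i in range(10):
            xs.append(xs[-1] + (0.19 if i % 2 == 0 else -0.19))
        b = branch_factory([(x, 0.0) for x in xs])
        assert b.path_length == pytest.approx(1.9)
        assert motility.classify_branch(b, MotilityParams()) == MotilityClass.STATIONARY

    def test_fast_perpendicular_run_is_excluded(self, branch_factory):
        b = branch_factory([(0.0, 0.3 * i) for i in range(21)])
        assert (
            motility.classify_branch(b, MotilityParams())
            == MotilityClass.ORTHOGONAL_EXCLUDED
        )

    def test_zero_net_displacement_degenerates_to_stationary(self, branch_factory):
        # out 3 um and exactly back: fast, long path, zero net displacement
        pos = [(0.3 * i, 0.0) for i in range(11)] + [(3.0 - 0.3 * i, 0.0) for i in range(1, 11)]
        b = branch_factory(pos)
        assert np.allclose(b.net_displacement, 0)
        assert motility.classify_branch(b, MotilityParams()) == MotilityClass.STATIONARY

    def test_raising_speed_threshold_never_unmakes_stationary(self, branch_factory, rng):
        branches = [
            branch_factory(np.cumsum(rng.uniform(-s, s, size=(30, 2)), axis=0))
            for s in np.linspace(0.005, 0.3, 20)
        ]
        counts = []
        for thr in (0.01, 0.05, 0.2, 1.0):
            p = MotilityParams(speed_threshold=thr)
            counts.append(
                sum(
                    motility.classify_branch(b, p) == MotilityClass.STATIONARY
                    for b in branches
                )
            )
        assert counts == sorted(counts)


class TestSummarize:
    def test_orthogonal_excluded_from_proportions(self, branch_factory):
        branches = (
            [branch_factory([(0.001 * i, 0.0) for i in range(10)]) for _ in range(6)]
            + [branch_factory([(0.3 * i, 0.0) for i in range(11)]) for _ in range(2)]
            + [branch_factory([(-0.3 * i, 0.0) for i in range(11)]) for _ in range(2)]
            + [branch_factory([(0.0, 0.3 * i) for i in range(11)]) for _ in range(5)]
        )
        s = motility.summarize_recording(branches, MotilityParams(), "r", "l")
        assert s.counts[MotilityClass.ORTHOGONAL_EXCLUDED] == 5
        assert s.proportions[MotilityClass.STATIONARY] == pytest.approx(0.6)
        assert s.proportions[MotilityClass.ANTEROGRADE] == pytest.approx(0.2)
        assert sum(s.proportions.values()) == pytest.approx(1.0)

    def test_single_anterograde_branch(self, branch_factory):
        s = motility.summarize_recording(
            [branch_factory([(0.3 * i, 0.0) for i in range(11)])], MotilityParams()
        )
        assert s.proportions[MotilityClass.ANTEROGRADE] == 1.0
        assert s.ternary_xy == pytest.approx((1.0, 0.0))

    def test_all_excluded_flags_undefined(self, branch_factory):
        s = motility.summarize_recording(
            [branch_factory([(0.0, 0.3 * i) for i in range(11)])], MotilityParams()
        )
        assert s.proportions is None and s.ternary_xy is None


def _brute_chi2(table):
    table = np.asarray(table, dtype=float)
    total = table.sum()
    chi2 = 0.0
    for i in range(table.shape[0]):
        for j in range(table.shape[1]):
            e = table[i].sum() * table[:, j].sum() / total
            chi2 += (table[i, j] - e) ** 2 / e
    return chi2


class TestAssociation:
    def test_identical_rows_are_independent(self):
        res = motility.association_test([[5, 10, 15], [5, 10, 15]])
        assert res.chi2 == pytest.approx(0.0, abs=1e-12)
        assert np.allclose(res.pearson_residuals.to_numpy(), 0.0)

    def test_hand_computed_2x2(self):
        res = motility.association_test([[20, 10], [10, 20]])
        assert res.chi2 == pytest.approx(100 / 15)
        assert res.df == 1

    def test_df_for_7x3_table(self, rng):
        table = rng.integers(1, 50, size=(7, 3))
        assert motility.association_test(table).df == 12

    def test_matches_brute_force_on_random_tables(self, rng):
        for _ in range(100):
            shape = (int(rng.integers(2, 6)), int(rng.integers(2, 6)))
            table = rng.integers(1, 40, size=shape)
            res = motility.association_test(table)
            assert abs(res.chi2 - _brute_chi2(table)) < 1e-10
            assert res.contributions.to_numpy().sum() == pytest.approx(1.0)
            # residual signs mark attraction/repulsion; margins of O-E vanish
            diff = res.observed.to_numpy() - res.expected.to_numpy()
            assert np.allclose(diff.sum(axis=0), 0, atol=1e-9)
            assert np.allclose(diff.sum(axis=1), 0, atol=1e-9)

    def test_zero_margin_errors(self):
        with pytest.raises(ValueError, match="row"):
            motility.association_test(pd.DataFrame([[0, 0], [1, 2]], index=["a", "b"]))


def test_estimate_axis_recovers_line_orientation(rng):
    along = rng.uniform(0, 50, size=200)
    direction = np.array([0.8, 0.6])
    pos = np.outer(along, direction) + rng.normal(0, 0.1, size=(200, 2))
    axis = motility.estimate_axis(pos, sign=1)
    assert abs(abs(axis @ direction) - 1.0) < 1e-3
    assert np.allclose(motility.estimate_axis(pos, sign=-1), -axis)
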