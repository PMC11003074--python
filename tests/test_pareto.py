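"""Pareto grids, multilinear navigation, calibration commit and merging."""

import numpy as np
import pytest

import paretoplan as pp
from paretoplan.metrics import MetricSpec, cumulative_dvh, mean_dose
from paretoplan.pareto import (NavigationDimension, build_grid,
                               commit_calibration, interpolate,
                               merge_calibrations, navigate_metrics)


def dim(values, roi="rectum", goal_type="mean_dose", kind="weighting_factor"):
    return NavigationDimension(roi, goal_type, kind, tuple(values))


class TestBuildGrid:
    def test_cartesian_product_count(self):
        combos = build_grid([dim((1, 2, 3)), dim((10, 20, 30), roi="bladder")])
        assert len(combos) == 9
        assert combos[0] == (1, 10) and combos[-1] == (3, 30)

    def test_single_dimension_preserves_order(self):
        combos = build_grid([dim((1, 2, 3, 4, 5))])
        assert [c[0] for c in combos] == [1, 2, 3, 4, 5]

    def test_five_dimensions_warns_and_enumerates(self):
        dims = [dim((1, 2, 3, 4, 5), roi=f"r{i}") for i in range(5)]
        with pytest.warns(UserWarning, match="dimensions"):
            combos = build_grid(dims)
        assert len(combos) == 5**5

    def test_validation(self):
        with pytest.raises(ValueError):
            build_grid([])
        with pytest.raises(ValueError):
            dim((3, 2, 1))
        with pytest.raises(ValueError):
            dim((1,))


class TestDataset:
    def test_plan_count_matches_grid(self, tiny_dataset):
        n = np.prod([len(d.values) for d in tiny_dataset.dimensions])
        assert len(tiny_dataset.plans) == n == 9

    def test_rectum_dmean_non_increasing_in_wf(self, tiny_dataset, small_geo):
        rect = small_geo.mask("rectum")
        # corners along the rectum-WF dimension (fall-off fixed at its middle)
        means = [mean_dose(tiny_dataset.plans[(i, 1)].dose.values, rect)
                 for i in range(3)]
        assert means[0] >= means[1] >= means[2] - 0.05

    def test_unknown_dimension_goal_rejected(self, small_geo, proto_a,
                                             small_beams, fast_cfg):
        bad = dim((1, 2), roi="nonexistent")
        with pytest.raises(KeyError):
            pp.generate_dataset(small_geo, proto_a, [bad], small_beams, fast_cfg)


class TestInterpolate:
    def test_vertex_reproduces_corner_plan(self, tiny_dataset):
        key = (2, 0)
        pos = tiny_dataset.position_at_vertex(key)
        d = interpolate(tiny_dataset, pos)
        np.testing.assert_allclose(d.values, tiny_dataset.plans[key].dose.values,
                                   rtol=0, atol=1e-12)

    def test_midpoint_is_arithmetic_mean_on_one_dim(self, tiny_dataset):
        labels = tiny_dataset.labels
        d0, d1 = tiny_dataset.dimensions
        pos = {labels[0]: 0.5 * (d0.values[0] + d0.values[1]),
               labels[1]: d1.values[0]}
        mid = interpolate(tiny_dataset, pos).values
        expect = 0.5 * (tiny_dataset.plans[(0, 0)].dose.values
                        + tiny_dataset.plans[(1, 0)].dose.values)
        np.testing.assert_allclose(mid, expect, rtol=1e-12, atol=1e-12)

    def test_mean_dose_commutes_with_interpolation(self, tiny_dataset, small_geo,
                                                   rng):
        """Any linear functional of dose interpolates multilinearly."""
        rect = small_geo.mask("rectum")
        labels = tiny_dataset.labels
        d0, d1 = tiny_dataset.dimensions
        for _ in range(5):
            t0, t1 = rng.random(2)
            v0 = d0.values[0] + t0 * (d0.values[1] - d0.values[0])
            v1 = d1.values[1] + t1 * (d1.values[2] - d1.values[1])
            dose = interpolate(tiny_dataset, {labels[0]: v0, labels[1]: v1})
            corners = np.array([[mean_dose(tiny_dataset.plans[(i, 1 + j)].dose.values,
                                           rect) for j in (0, 1)] for i in (0, 1)])
            expect = ((1 - t0) * ((1 - t1) * corners[0, 0] + t1 * corners[0, 1])
                      + t0 * ((1 - t1) * corners[1, 0] + t1 * corners[1, 1]))
            assert mean_dose(dose.values, rect) == pytest.approx(expect, rel=1e-12)

    def test_out_of_range_position_rejected(self, tiny_dataset):
        pos = tiny_dataset.position_at_vertex((0, 0))
        pos[tiny_dataset.labels[0]] = 1e9
        with pytest.raises(ValueError, match="outside sampled range"):
            interpolate(tiny_dataset, pos)

    def test_coefficients_sum_to_one_nonnegative_dose(self, tiny_dataset):
        labels = tiny_dataset.labels
        d0, d1 = tiny_dataset.dimensions
        pos = {labels[0]: 0.3 * d0.values[0] + 0.7 * d0.values[1],
               labels[1]: d1.values[1]}
        d = interpolate(tiny_dataset, pos)
        assert d.values.min() >= 0.0
        # total integral interpolates too (coefficient partition of unity)
        tot = (0.3 * tiny_dataset.plans[(0, 1)].dose.values.sum()
               + 0.7 * tiny_dataset.plans[(1, 1)].dose.values.sum())
        assert d.values.sum() == pytest.approx(tot, rel=1e-12)


class TestNavigateMetrics:
    SPECS = [MetricSpec("Dmean", "rectum"), MetricSpec("HI", "PTV60")]

    def test_vertex_metrics_equal_plan_metrics(self, tiny_dataset, small_geo):
        key = (1, 1)
        pos = tiny_dataset.position_at_vertex(key)
        vals = navigate_metrics(tiny_dataset, pos, self.SPECS)
        plan = tiny_dataset.plans[key]
        assert vals["rectum Dmean"] == pytest.approx(
            mean_dose(plan.dose.values, small_geo.mask("rectum")), rel=1e-12)

    def test_interpolated_dvh_is_monotone(self, tiny_dataset, small_geo):
        labels = tiny_dataset.labels
        d0, d1 = tiny_dataset.dimensions
        pos = {labels[0]: 0.6 * d0.values[0] + 0.4 * d0.values[1],
               labels[1]: 0.5 * (d1.values[0] + d1.values[1])}
        dose = interpolate(tiny_dataset, pos)
        curve = cumulative_dvh(dose.values, small_geo.mask("rectum"),
                               small_geo.voxel_volume_cm3)
        assert np.all(np.diff(curve.volume_fraction) <= 1e-12)
        assert curve.volume_fraction[0] == 1.0

    def test_reference_snapshot_returned(self, tiny_dataset):
        pos = tiny_dataset.position_at_vertex((0, 0))
        ref = tiny_dataset.position_at_vertex((2, 2))
        vals, ref_vals = navigate_metrics(tiny_dataset, pos, self.SPECS,
                                          reference=ref)
        assert set(vals) == set(ref_vals) == {"rectum Dmean", "PTV60 HI"}

    def test_hundred_positions_are_fast(self, tiny_dataset, rng):
        """Real-time contract: navigation never reruns optimisation."""
        import time

        labels = tiny_dataset.labels
        d0, d1 = tiny_dataset.dimensions
        t0 = time.time()
        for _ in range(100):
            pos = {labels[0]: rng.uniform(d0.values[0], d0.values[-1]),
                   labels[1]: rng.uniform(d1.values[0], d1.values[-1])}
            navigate_metrics(tiny_dataset, pos, self.SPECS)
        assert time.time() - t0 < 2.0


class TestCommitAndMerge:
    def test_vertex_commit_matches_cloned_protocol(self, tiny_dataset, proto_a):
        pos = tiny_dataset.position_at_vertex((2, 0))
        out = commit_calibration(tiny_dataset, pos, proto_a)
        assert out.find_goal("rectum", "mean_dose").weighting_factor == \
            tiny_dataset.dimensions[0].values[2]
        assert out.find_goal("external", "dose_falloff_external").weighting_factor == \
            tiny_dataset.dimensions[1].values[0]

    def test_untouched_goals_unchanged(self, tiny_dataset, proto_a):
        pos = tiny_dataset.position_at_vertex((1, 1))
        out = commit_calibration(tiny_dataset, pos, proto_a)
        for g_in, g_out in zip(proto_a.goals, out.goals):
            if g_in.key() in [(d.roi, d.goal_type, d.dose_level)
                              for d in tiny_dataset.dimensions]:
                continue
            assert g_in == g_out

    def test_commit_then_replan_reproduces_corner(self, tiny_dataset, small_geo,
                                                  proto_a, small_beams,
                                                  small_influence):
        key = (0, 2)
        pos = tiny_dataset.position_at_vertex(key)
        proto = commit_calibration(tiny_dataset, pos, proto_a)
        cfg = pp.PBAIOConfig(inner_iterations=10, outer_loops=1)
        plan = pp.autoplan(small_geo, proto, small_beams, cfg,
                           influence=small_influence)
        np.testing.assert_array_equal(plan.dose.values,
                                      tiny_dataset.plans[key].dose.values)

    def test_merge_mean_and_permutation_invariance(self, proto_a):
        p2, p4 = proto_a.clone(), proto_a.clone()
        p2.find_goal("rectum", "mean_dose").weighting_factor = 2.0
        p4.find_goal("rectum", "mean_dose").weighting_factor = 4.0
        m1 = merge_calibrations([p2, p4])
        m2 = merge_calibrations([p4, p2])
        assert m1.find_goal("rectum", "mean_dose").weighting_factor == 3.0
        assert m1 == m2
        assert merge_calibrations([proto_a, proto_a]) == proto_a
        geo = merge_calibrations([p2, p4], method="geometric")
        assert geo.find_goal("rectum", "mean_dose").weighting_factor == \
            pytest.approx(np.sqrt(8.0))

    def test_merge_structural_mismatch_errors(self, proto_a, proto_b):
        with pytest.raises(ValueError):
            merge_calibrations([proto_a, proto_b])
        p = proto_a.clone()
        p.find_goal("rectum", "mean_dose").target = 6.0
        with pytest.raises(ValueError, match="targets disagree"):
            merge_calibrations([proto_a, p])
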