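"""Cumulated trees, V/D curves, medians, line fits and group statistics."""

import numpy as np
import pytest

import angioarch as aa
from angioarch.fingerprint import VDCurve, VDPoint
from conftest import make_stack
from oracles import ols_normal_equations, two_sample_t


def curve_from_arrays(sample_id, v, nhv):
    points = [
        VDPoint(level=i + 1, v_percent=float(vi), nhv=int(d), raw_cycles=int(d), offset_cycles=0)
        for i, (vi, d) in enumerate(zip(v, nhv))
    ]
    return VDCurve(sample_id=sample_id, points=points)


def classified_from_labels(labels):
    labels = np.asarray(labels)
    return aa.ClassifiedStack(aa.GridMeta(0.54, labels.shape), labels)


class TestCumulate:
    def test_single_class_gives_seven_identical_trees(self):
        labels = np.zeros((4, 4, 4), np.int64)
        labels[0, 0, :2] = 1
        trees = aa.cumulate_classes(classified_from_labels(labels))
        assert len(trees) == 7
        for t in trees:
            assert t.signal_count == 2
            assert np.array_equal(t.voxels, trees[0].voxels)

    def test_prefix_sum_voxel_counts(self):
        """Disjoint classes cumulate to prefix sums; OVER stays excluded."""
        rng = np.random.default_rng(0)
        labels = np.zeros((10, 10, 10), np.int64)
        flat = rng.permutation(1000)
        sizes = [3, 5, 7, 11, 13, 17, 19]
        pos = 0
        for k, s in enumerate(sizes, start=1):
            labels.flat[flat[pos:pos + s]] = k
            pos += s
        labels.flat[flat[pos:pos + 23]] = aa.OVER_LABEL
        trees = aa.cumulate_classes(classified_from_labels(labels))
        expected = np.cumsum(sizes)
        assert [t.signal_count for t in trees] == list(expected)

    def test_tree2_is_union_of_tree1_and_class2(self):
        labels = np.zeros((6, 6, 6), np.int64)
        labels[0] = 1
        labels[3] = 2
        trees = aa.cumulate_classes(classified_from_labels(labels))
        union = trees[0].voxels | (labels == 2)
        assert np.array_equal(trees[1].voxels, union)


class TestComputeVDCurve:
    def _trees(self, seed=0):
        rng = np.random.default_rng(seed)
        base = np.zeros((20, 20, 20), bool)
        trees = []
        for level in range(7):
            extra = rng.random((20, 20, 20)) < 0.002
            base = base | extra
            if not base.any():
                base[10, 10, 10] = True
            trees.append(make_stack(base.copy()))
        return trees

    def test_identical_trees_give_degenerate_curve(self):
        tree = self._trees()[0]
        curve = aa.compute_vd_curve([tree] * 7, sample_id="deg")
        assert len(curve.points) == 7
        assert len(set(p.nhv for p in curve.points)) == 1
        assert all(p.duplicate for p in curve.points[1:])
        assert len(curve.fit_points()) == 1

    def test_monotone_volume_and_cycles(self):
        curve = aa.compute_vd_curve(self._trees())
        v = curve.v_values
        raw = [p.raw_cycles for p in curve.points]
        assert (np.diff(v) >= 0).all()
        assert all(b <= a for a, b in zip(raw, raw[1:]))

    def test_transposed_trees_give_identical_curve(self):
        trees = self._trees(3)
        trees_t = [make_stack(np.transpose(t.voxels, (2, 0, 1))) for t in trees]
        c1 = aa.compute_vd_curve(trees)
        c2 = aa.compute_vd_curve(trees_t)
        assert [(p.v_percent, p.nhv) for p in c1.points] == [
            (p.v_percent, p.nhv) for p in c2.points
        ]

    def test_empty_first_tree_rejected(self):
        empty = make_stack(np.zeros((5, 5, 5), bool))
        with pytest.raises(aa.DomainError):
            aa.compute_vd_curve([empty] * 7)


class TestMedianCurve:
    def test_identical_curves_have_zero_iqr(self):
        c = curve_from_arrays("a", [1, 2, 3, 4, 5, 6, 7], [70, 60, 50, 40, 30, 20, 10])
        med = aa.median_curve([c] * 8)
        assert med.n_samples == 8
        assert np.allclose(med.v_median, c.v_values)
        assert np.allclose(med.v_iqr[:, 0], med.v_iqr[:, 1])
        assert np.allclose(med.nhv_iqr[:, 0], med.nhv_median)

    def test_odd_sample_median_is_middle_order_statistic(self):
        curves = [
            curve_from_arrays(str(i), np.arange(1, 8) * (i + 1), np.arange(7) + i)
            for i in range(5)
        ]
        med = aa.median_curve(curves)
        for lvl in range(7):
            vals = sorted(c.v_values[lvl] for c in curves)
            assert med.v_median[lvl] == vals[2]

    def test_two_sample_median_is_midpoint(self):
        c1 = curve_from_arrays("a", np.arange(1, 8), 2 * np.arange(1, 8))
        c2 = curve_from_arrays("b", np.arange(1, 8), 4 * np.arange(1, 8))
        med = aa.median_curve([c1, c2])
        assert np.allclose(med.nhv_median, 3 * np.arange(1, 8))

    def test_empty_input_rejected(self):
        with pytest.raises(aa.DomainError):
            aa.median_curve([])

    def test_iqr_brackets_median(self):
        rng = np.random.default_rng(5)
        curves = [
            curve_from_arrays(str(i), np.sort(rng.random(7)) * 3, rng.integers(5, 60, 7))
            for i in range(9)
        ]
        med = aa.median_curve(curves)
        assert (med.nhv_iqr[:, 0] <= med.nhv_median).all()
        assert (med.nhv_median <= med.nhv_iqr[:, 1]).all()


class TestFitLine:
    def test_exact_collinear_points(self):
        pts = [(v, -16.0 * v + 60.0) for v in (0.5, 1.0, 1.5, 2.0, 2.5)]
        fit = aa.fit_line(pts)
        assert fit.slope == pytest.approx(-16.0)
        assert fit.intercept == pytest.approx(60.0)
        assert fit.r_squared == pytest.approx(1.0)

    def test_matches_normal_equation_oracle(self):
        x = np.array([0.66, 1.1, 1.5, 1.8, 2.0, 2.2, 2.38])
        y = np.array([50.2, 44.0, 38.5, 31.0, 28.0, 24.5, 21.82])
        fit = aa.fit_line(list(zip(x, y)))
        slope, intercept, r2 = ols_normal_equations(x, y)
        assert fit.slope == pytest.approx(slope)
        assert fit.intercept == pytest.approx(intercept)
        assert fit.r_squared == pytest.approx(r2)
        assert fit.slope_ci95[0] < slope < fit.slope_ci95[1]

    def test_degenerate_abscissae_rejected(self):
        with pytest.raises(aa.DomainError):
            aa.fit_line([(1.0, 2.0), (1.0, 3.0)])

    def test_too_few_points_rejected(self):
        with pytest.raises(aa.DomainError):
            aa.fit_line([(1.0, 2.0)])


class TestExtractParameters:
    def test_endpoint_arithmetic(self):
        """Segment projections follow from the endpoint coordinates."""
        c = curve_from_arrays(
            "ctrl",
            np.linspace(0.66, 2.38, 7),
            np.round(np.linspace(50.20, 21.82, 7)).astype(int),
        )
        params = aa.extract_parameters(c)
        assert params.left_end[0] == pytest.approx(0.66)
        assert params.right_end[0] == pytest.approx(2.38)
        assert params.x_length == pytest.approx(2.38 - 0.66)
        assert params.y_length == pytest.approx(
            c.points[0].nhv - c.points[-1].nhv
        )
        assert params.slope < 0

    def test_group_lengths_are_medians_of_sample_lengths(self):
        c = curve_from_arrays("m", np.arange(1, 8), 70 - 5 * np.arange(7))
        params = aa.extract_parameters(
            c, per_sample_lengths=[(1.0, 8.0), (1.5, 9.0), (2.0, 10.0)]
        )
        assert params.x_length == 1.5
        assert params.y_length == 9.0

    def test_duplicate_levels_excluded_from_fit(self):
        points = [
            VDPoint(1, 1.0, 50, 50, 0),
            VDPoint(2, 1.0, 50, 50, 0, duplicate=True),
            VDPoint(3, 2.0, 40, 40, 0),
            VDPoint(4, 3.0, 30, 30, 0),
        ]
        curve = VDCurve("d", points)
        fit = aa.fit_line(curve.fit_points())
        assert fit.slope == pytest.approx(-10.0)
        assert fit.r_squared == pytest.approx(1.0)


def params_with(**kw):
    base = dict(
        slope=-20.0, intercept=60.0, r_squared=0.98, slope_ci95=(-25.0, -15.0),
        left_end=(0.7, 50.0), right_end=(2.0, 20.0), x_length=1.3, y_length=30.0,
    )
    base.update(kw)
    return aa.FingerprintParams(**base)


class TestCompareGroups:
    def test_identical_groups_not_significant(self):
        g = [params_with(slope=-20 + i) for i in range(4)]
        comparison = aa.compare_groups({"a": list(g), "b": list(g)})
        for pc in comparison.parameters.values():
            for pw in pc.pairwise.values():
                assert not pw["significant"]

    def test_t_statistic_matches_closed_form(self):
        a = np.array([-20.0, -22.0, -19.0, -21.0])
        b = np.array([-40.0, -44.0, -39.0, -41.0])
        ga = [params_with(slope=s) for s in a]
        gb = [params_with(slope=s) for s in b]
        comparison = aa.compare_groups({"a": ga, "b": gb})
        from scipy import stats

        t_oracle = two_sample_t(a, b)
        p_oracle = 2 * stats.t.sf(abs(t_oracle), len(a) + len(b) - 2)
        pw = comparison.parameters["slope"].pairwise[("a", "b")]
        assert pw["raw_p"] == pytest.approx(p_oracle)
        assert pw["significant"]
        assert pw["stars"] == "***"

    def test_three_groups_bonferroni(self):
        rng = np.random.default_rng(1)
        groups = {
            name: [params_with(slope=-20 + rng.normal()) for _ in range(4)]
            for name in ("a", "b", "c")
        }
        comparison = aa.compare_groups(groups)
        pc = comparison.parameters["slope"]
        assert pc.test == "anova+bonferroni"
        assert pc.anova_p is not None
        assert len(pc.pairwise) == 3
        for pw in pc.pairwise.values():
            assert pw["adjusted_p"] == pytest.approx(min(1.0, pw["raw_p"] * 3))

    def test_small_group_rejected(self):
        with pytest.raises(aa.DomainError):
            aa.compare_groups({"a": [params_with()], "b": [params_with()] * 3})

    def test_stars_convention(self):
        from angioarch.fingerprint import significance_stars

        assert significance_stars(0.04) == "*"
        assert significance_stars(0.009) == "**"
        assert significance_stars(0.0009) == "***"
        assert significance_stars(0.06) == ""


class TestBatchReference:
    def test_maximum_over_all_trees(self):
        small = make_stack(np.zeros((4, 4, 4), bool))
        small.voxels[0, 0, 0] = True
        big = make_stack(np.ones((4, 4, 4), bool))
        ref = aa.batch_reference_volume([[small], [small, big]])
        assert ref == 100.0
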