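import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from wingsym import (
    LandmarkConfiguration,
    SYM10_LABELS,
    WingCohort,
    ap_axis,
    cohort_symmetry_comparison,
    reflect_across_axis,
    symmetrize,
    symmetry_scores,
)
from wingsym.symmetry import AxisLine, DegenerateAxisError
from wingsym.synthetic import WingGenParams, generate_wing_cohort


def config_from_pairs(points, wing_id="w"):
    return LandmarkConfiguration(
        wing_id=wing_id, coords=np.asarray(points, float), labels=SYM10_LABELS
    )


class TestApAxis:
    def test_horizontal_axis_from_midpoints(self, scheme):
        coords = np.array(
            [[0, -1], [0, -1], [4, -1], [4, -1], [4, -1],
             [0, 1], [0, 1], [4, 1], [4, 1], [4, 1]], dtype=float
        )
        coords += np.arange(10)[:, None] * 1e-9  # break duplicate labels' coords apart
        config = config_from_pairs(coords)
        axis = ap_axis(config, scheme)
        assert abs(axis.direction[1]) < 1e-6
        assert abs(axis.origin[1]) < 1e-6

    def test_diagonal_axis_for_y_equals_x_symmetry(self, scheme, template):
        # reflect the template's posterior landmarks across y = x instead of y = 0
        coords = template.coords.copy()
        coords[5:] = coords[:5][:, ::-1]
        config = config_from_pairs(coords)
        axis = ap_axis(config, scheme)
        d = axis.direction * np.sign(axis.direction[0])
        np.testing.assert_allclose(d, [1, 1] / np.sqrt(2), atol=1e-12)

    def test_all_axis_points_coincident_errors(self, scheme):
        coords = np.zeros((10, 2))
        coords[[0, 2, 3, 5, 7, 8]] = [[1, 1], [2, 2], [3, 3], [4, 4], [5, 5], [6, 6]]
        config = config_from_pairs(coords)  # pairs 2 and 5 all at origin
        with pytest.raises(DegenerateAxisError):
            ap_axis(config, scheme)


class TestReflection:
    def test_reflect_across_x_axis(self):
        axis = AxisLine(origin=[0.0, 0.0], direction=[1.0, 0.0])
        np.testing.assert_allclose(reflect_across_axis([1.0, 2.0], axis), [1.0, -2.0])

    def test_point_on_axis_is_fixed(self):
        axis = AxisLine(origin=[2.0, 1.0], direction=[1.0, 1.0])
        np.testing.assert_allclose(reflect_across_axis([3.0, 2.0], axis), [3.0, 2.0], atol=1e-12)

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(
        ox=st.floats(-100, 100), oy=st.floats(-100, 100),
        dx=st.floats(-1, 1), dy=st.floats(-1, 1),
        px=st.floats(-1000, 1000), py=st.floats(-1000, 1000),
    )
    def test_involution_property(self, ox, oy, dx, dy, px, py):
        if np.hypot(dx, dy) < 1e-6:
            return
        axis = AxisLine(origin=[ox, oy], direction=[dx, dy])
        p = np.array([px, py])
        refl = reflect_across_axis(p, axis)
        np.testing.assert_allclose(reflect_across_axis(refl, axis), p, atol=1e-9)
        # distance to the line is preserved
        rel_p, rel_r = p - axis.origin, refl - axis.origin
        perp = lambda r: r - (r @ axis.direction) * axis.direction
        assert np.linalg.norm(perp(rel_p)) == pytest.approx(
            np.linalg.norm(perp(rel_r)), abs=1e-6
        )

    def test_involution_and_isometry(self, rng):
        axis = AxisLine(origin=rng.normal(size=2), direction=rng.normal(size=2))
        pts = rng.normal(size=(50, 2)) * 5
        refl = reflect_across_axis(pts, axis)
        np.testing.assert_allclose(reflect_across_axis(refl, axis), pts, atol=1e-12)
        # pairwise distances preserved
        d0 = np.linalg.norm(pts[:, None] - pts[None], axis=-1)
        d1 = np.linalg.norm(refl[:, None] - refl[None], axis=-1)
        np.testing.assert_allclose(d0, d1, atol=1e-9)


class TestSymmetrize:
    def test_symmetric_template_unchanged(self, template, scheme):
        ant = symmetrize(template, scheme, "anteriorized")
        np.testing.assert_allclose(ant.coords, template.coords, atol=1e-12)

    def test_displaced_posterior_landmark_removed(self, template, scheme):
        coords = template.coords.copy()
        coords[9] += [0.0, 0.4]  # 5P off its mirror position
        config = config_from_pairs(coords)
        ant = symmetrize(config, scheme, "anteriorized")
        axis = ap_axis(config, scheme)
        np.testing.assert_allclose(
            ant.coords[9], reflect_across_axis(config.coords[4], axis), atol=1e-12
        )

    @pytest.mark.parametrize("side", ["anteriorized", "posteriorized"])
    def test_idempotent(self, scheme, side, rng):
        cohort = generate_wing_cohort(WingGenParams(n=1, asym=0.15, noise_sd=0.01, seed=9))
        config = cohort.configurations[0]
        once = symmetrize(config, scheme, side)
        twice = symmetrize(once, scheme, side)
        np.testing.assert_allclose(twice.coords, once.coords, atol=1e-10)

    @pytest.mark.parametrize("side", ["anteriorized", "posteriorized"])
    def test_result_is_mirror_symmetric_about_original_axis(self, scheme, side):
        config = generate_wing_cohort(
            WingGenParams(n=1, asym=0.2, noise_sd=0.02, seed=11)
        ).configurations[0]
        axis = ap_axis(config, scheme)
        sym = symmetrize(config, scheme, side)
        for ant_lab, post_lab in scheme.pairs:
            mid = (sym.point(ant_lab) + sym.point(post_lab)) / 2.0
            # midpoint of each pair lies on the axis
            rel = mid - axis.origin
            perp = rel - (rel @ axis.direction) * axis.direction
            assert np.linalg.norm(perp) < 1e-9

    def test_labels_and_order_preserved(self, template, scheme):
        sym = symmetrize(template, scheme, "posteriorized")
        assert sym.labels == template.labels

    def test_unknown_side_rejected(self, template, scheme):
        with pytest.raises(ValueError, match="side"):
            symmetrize(template, scheme, "lateralized")


class TestSymmetryScores:
    def test_symmetric_template_scores_zero(self, template, scheme):
        d_ant, d_post = symmetry_scores(template, scheme)
        assert d_ant <= 1e-12 and d_post <= 1e-12

    def test_displaced_posterior_raises_anteriorized_score(self, template, scheme):
        coords = template.coords.copy()
        coords[9] += [0.0, 0.5]
        d_ant, _ = symmetry_scores(config_from_pairs(coords), scheme)
        assert d_ant > 1e-6

    def test_invariant_under_similarity_transform(self, scheme):
        config = generate_wing_cohort(
            WingGenParams(n=1, asym=0.2, noise_sd=0.02, seed=21)
        ).configurations[0]
        base = symmetry_scores(config, scheme)
        th = 1.1
        R = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        moved = config.with_coords(config.coords @ R.T * 3.3 + [100.0, -40.0])
        np.testing.assert_allclose(symmetry_scores(moved, scheme), base, atol=1e-10)

    def test_monotone_in_asymmetry_without_noise(self, scheme):
        scores = []
        for asym in (0.0, 0.05, 0.1, 0.2):
            config = generate_wing_cohort(
                WingGenParams(n=1, asym=asym, noise_sd=0.0, seed=0)
            ).configurations[0]
            scores.append(symmetry_scores(config, scheme)[0])
        assert all(b > a for a, b in zip(scores, scores[1:]))


class TestCohortComparison:
    def test_clone_cohorts_flagged_degenerate(self, template, scheme):
        clones = WingCohort([template.with_coords(template.coords) for _ in range(4)], "a")
        clones2 = WingCohort([template.with_coords(template.coords) for _ in range(4)], "b")
        comp = cohort_symmetry_comparison(clones, clones2, scheme)
        assert comp.anteriorized_test.degenerate
        assert comp.anteriorized_test.p_value is None

    def test_detects_halved_asymmetry_and_direction(self, scheme):
        controls = generate_wing_cohort(
            WingGenParams(n=50, asym=0.2, seed=101, cohort="control", name="ctl")
        )
        impaired = generate_wing_cohort(
            WingGenParams(n=50, asym=0.1, seed=202, cohort="impaired", name="imp")
        )
        comp = cohort_symmetry_comparison(controls, impaired, scheme)
        scores = comp.scores
        med_c = scores.loc[scores.cohort == "ctl", "d_anteriorized"].median()
        med_i = scores.loc[scores.cohort == "imp", "d_anteriorized"].median()
        assert med_i < med_c
        assert comp.anteriorized_test.p_value < 0.05

    def test_swapping_cohorts_keeps_p_value(self, scheme):
        a = generate_wing_cohort(WingGenParams(n=20, asym=0.2, seed=31, name="a"))
        b = generate_wing_cohort(WingGenParams(n=20, asym=0.1, seed=32, name="b"))
        fwd = cohort_symmetry_comparison(a, b, scheme)
        rev = cohort_symmetry_comparison(b, a, scheme)
        assert fwd.anteriorized_test.p_value == pytest.approx(
            rev.anteriorized_test.p_value, abs=1e-12
        )
        med = lambda comp, name: comp.scores.loc[
            comp.scores.cohort == name, "d_anteriorized"
        ].median()
        assert np.sign(med(fwd, "a") - med(fwd, "b")) == -np.sign(
            med(rev, "b") - med(rev, "a")
        ) or med(fwd, "a") == med(fwd, "b")
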