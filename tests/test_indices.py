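"""Posturographic index computations against independent oracles."""

import numpy as np
import pytest
from hypothesis import given, strategies as st
from hypothesis.extra import numpy as hnp
from scipy import stats
from scipy.spatial.transform import Rotation

from aclscreen.events import JumpSegment, SquatSegment
from aclscreen.indices import (
    SwayPath,
    ellipse_area,
    load_absorption,
    mobility,
    path_length,
    project_leg_axis,
    stability_indices_mcmj,
    stability_indices_sls,
)
from aclscreen.orientation import OrientationSeries
from aclscreen.signals import G


def _path(ap, ml):
    return SwayPath(AP=np.asarray(ap, float), ML=np.asarray(ml, float))


finite_paths = st.integers(2, 60).flatmap(
    lambda n: st.tuples(
        hnp.arrays(np.float64, n, elements=st.floats(-10, 10)),
        hnp.arrays(np.float64, n, elements=st.floats(-10, 10)),
    )
)


class TestPathLength:
    def test_three_four_five_triangle(self):
        pl, ap, ml = path_length(_path([0, 3], [0, 4]))
        assert (pl, ap, ml) == pytest.approx((5.0, 3.0, 4.0))

    def test_closed_unit_square(self):
        pl, _, _ = path_length(_path([0, 1, 1, 0, 0], [0, 0, 1, 1, 0]))
        assert pl == pytest.approx(4.0)

    def test_matches_bruteforce_on_random_path(self, rng):
        ap, ml = rng.normal(size=10_000), rng.normal(size=10_000)
        pl, pap, pml = path_length(_path(ap, ml))
        # independent single-loop re-summation
        acc = sum(
            ((ap[i + 1] - ap[i]) ** 2 + (ml[i + 1] - ml[i]) ** 2) ** 0.5
            for i in range(ap.size - 1)
        )
        assert pl == pytest.approx(acc, rel=1e-9)
        assert pap == pytest.approx(sum(abs(ap[i + 1] - ap[i]) for i in range(ap.size - 1)), rel=1e-9)

    @given(finite_paths)
    def test_triangle_inequality_chain(self, arrays):
        ap, ml = arrays
        pl, pap, pml = path_length(_path(ap, ml))
        assert max(pap, pml) <= pl + 1e-9
        assert pl <= pap + pml + 1e-9

    @given(finite_paths, st.floats(0.1, 10))
    def test_scaling_linear_for_pl_quadratic_for_ea(self, arrays, c):
        ap, ml = arrays
        p1, p2 = _path(ap, ml), _path(c * np.asarray(ap), c * np.asarray(ml))
        assert path_length(p2)[0] == pytest.approx(c * path_length(p1)[0], rel=1e-6)
        if p1.N >= 3 and np.std(ap) > 1e-3 and np.std(ml) > 1e-3:
            e1, e2 = ellipse_area(p1), ellipse_area(p2)
            if e1 > 1e-6:  # skip numerically singular covariances
                assert e2 == pytest.approx(c**2 * e1, rel=1e-6)


class TestEllipseArea:
    def test_degenerate_paths(self):
        with pytest.warns(UserWarning, match="degenerate"):
            assert ellipse_area(_path([1, 1, 1], [2, 2, 2])) == 0.0
        with pytest.raises(ValueError):
            ellipse_area(_path([0, 1], [0, 1]))

    def test_axis_swap_translation_invariance(self, rng):
        ap, ml = rng.normal(0, 2, 500), rng.normal(0, 1, 500)
        a = ellipse_area(_path(ap, ml))
        assert ellipse_area(_path(ml, ap)) == pytest.approx(a, rel=1e-12)
        assert ellipse_area(_path(ap + 5, ml - 3)) == pytest.approx(a, rel=1e-9)

    def test_gaussian_sample_matches_closed_form_and_coverage(self, rng):
        n = 20_000
        ap, ml = rng.standard_normal(n), rng.standard_normal(n)
        ea = ellipse_area(_path(ap, ml))
        cov = np.cov(ap, ml, ddof=1)
        expected = 2 * np.pi * stats.f.ppf(0.95, 2, n - 2) * np.sqrt(np.linalg.det(cov))
        assert ea == pytest.approx(expected, rel=1e-12)
        # the ellipse of that area centred on the mean covers ~95% of points
        xy = np.c_[ap - ap.mean(), ml - ml.mean()]
        d2 = np.einsum("ij,jk,ik->i", xy, np.linalg.inv(cov), xy)
        inside = d2 <= 2 * stats.f.ppf(0.95, 2, n - 2)
        assert np.mean(inside) == pytest.approx(0.95, abs=0.02)


class TestProjection:
    @staticmethod
    def _series(rots):
        q = rots.as_quat()
        return OrientationSeries(t=np.arange(len(q)) / 1000.0, q=np.c_[q[:, 3], q[:, :3]])

    def test_vertical_axis_projects_to_origin(self):
        rots = Rotation.identity(5)
        path = project_leg_axis(self._series(rots), (0.0, 0.004))
        assert np.allclose(path.AP, 0) and np.allclose(path.ML, 0)

    def test_45_degree_tilt_gives_unit_offset(self):
        rots = Rotation.from_rotvec(np.tile([0.0, np.deg2rad(45.0), 0.0], (5, 1)))
        path = project_leg_axis(self._series(rots), (0.0, 0.004), plane_offset_cm=1.0)
        assert np.allclose(np.abs(path.AP), 1.0, atol=1e-12)
        assert np.allclose(path.ML, 0.0, atol=1e-12)

    def test_conical_oscillation_radius_closed_form(self):
        half_angle = np.deg2rad(7.0)
        phase = np.linspace(0, 2 * np.pi, 1000)
        rotvec = half_angle * np.c_[np.cos(phase), np.sin(phase), np.zeros_like(phase)]
        rots = Rotation.from_rotvec(rotvec)
        path = project_leg_axis(self._series(rots), (0.0, 1.0), plane_offset_cm=1.0)
        r = np.hypot(path.AP, path.ML)
        assert np.allclose(r, np.tan(half_angle), atol=1e-6)

    def test_degenerate_horizontal_axis_rejected(self):
        rots = Rotation.from_rotvec(np.tile([0.0, np.pi / 2, 0.0], (5, 1)))
        with pytest.raises(ValueError, match="parallel"):
            project_leg_axis(self._series(rots), (0.0, 0.004))


class TestNormalization:
    def test_jump_indices_divide_by_ts(self):
        path = _path([0.0, 0.3, 0.5], [0.0, 0.2, 0.0])
        pl_raw, ap_raw, ml_raw = path_length(path)
        ea_raw = ellipse_area(path)
        seg = JumpSegment(FT_i=0.0, CT_i=0.4, dFT=0.4, dCT=0.6, Ts=0.25)
        out = stability_indices_mcmj(path, seg)
        assert out["PL"] == pytest.approx(pl_raw / 0.25)
        assert out["PL_AP"] == pytest.approx(ap_raw / 0.25)
        assert out["EA"] == pytest.approx(ea_raw / 0.25)
        # doubling the divisor halves every normalized index
        seg2 = JumpSegment(FT_i=0.0, CT_i=0.4, dFT=0.4, dCT=0.6, Ts=0.5)
        out2 = stability_indices_mcmj(path, seg2)
        for k in out:
            assert out2[k] == pytest.approx(out[k] / 2)

    def test_squat_indices_divide_by_tdp(self):
        path = _path([0.0, 0.3, 0.3], [0.0, 0.0, 0.4])
        seg = SquatSegment(DP_i=2.0, DP_e=3.4, theta_ymax=25.0, baseline_sd=0.1)
        out = stability_indices_sls(path, seg)
        assert out["PL"] == pytest.approx(0.7 / 1.4)
        assert mobility(seg) == 25.0

    def test_undefined_ts_excludes_rep(self):
        path = _path([0, 1], [0, 1])
        seg = JumpSegment(FT_i=0.0, CT_i=0.4, dFT=0.4, dCT=0.6, Ts=None)
        with pytest.raises(ValueError, match="excluded"):
            stability_indices_mcmj(path, seg)


class TestLoadAbsorption:
    def test_constant_vertical_acceleration_oracle(self):
        from aclscreen.signals import ImuTrial

        n = 2000
        t = np.arange(n) / 1000.0
        acc = np.tile([0.0, 0.0, G + 10.0], (n, 1))
        trial = ImuTrial(t=t, accel=acc, gyro=np.zeros((n, 3)), fs=1000.0, task="mcmj")
        q = np.tile([1.0, 0, 0, 0], (n, 1))
        orient = OrientationSeries(t=t, q=q)
        seg = JumpSegment(FT_i=0.0, CT_i=0.5, dFT=0.5, dCT=1.0, Ts=0.4)
        rms_z, rms_xy = load_absorption(trial, orient, seg, jump_duration=1.0)
        assert rms_z == pytest.approx(10.0, rel=1e-9)
        assert rms_xy == pytest.approx(0.0, abs=1e-12)

    def test_simulated_impact_matches_direct_recomputation(self, mcmj_trial, mcmj_oriented):
        _, trial, _, truth = mcmj_trial
        _, orient = mcmj_oriented
        seg = truth[0]
        rms_z, rms_xy = load_absorption(trial, orient, seg)
        sl = trial.slice_time(seg.CT_i, seg.CT_i + seg.Ts)
        aw = orient.as_rotation()[sl].apply(trial.accel[sl])
        az = aw[:, 2] - G
        axy = np.sqrt(aw[:, 0] ** 2 + aw[:, 1] ** 2)
        dur = seg.dFT + seg.dCT
        assert rms_z == pytest.approx(np.sqrt(np.mean(az**2)) / dur, rel=1e-9)
        assert rms_xy == pytest.approx(np.sqrt(np.mean(axy**2)) / dur, rel=1e-9)
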