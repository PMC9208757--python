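"""Velocity, stratification, depth and centrosome-offset contracts."""

import numpy as np
import pytest

from hcmotion import kinematics as kin
from hcmotion.imgio import PointTrack, TissueGeometry


def track_of(xy, frames=None, role="cell_centroid", tid="t"):
    xy = np.asarray(xy, dtype=float)
    frames = np.arange(len(xy)) if frames is None else frames
    return PointTrack(tid, frames, xy, role=role)


class TestVelocities:
    def test_three_four_five(self):
        samples = kin.velocities(track_of([[0, 0], [3, 4]]), interval_min=5.0)
        (v,) = samples
        assert v.speed_um_min == pytest.approx(1.0)
        assert v.direction.tolist() == [0.6, 0.8]
        assert v.valid

    def test_stationary_track_all_invalid(self):
        samples = kin.velocities(track_of([[1, 1]] * 5), interval_min=1.0)
        assert all(not s.valid for s in samples)

    def test_gap_splits_sequence(self):
        track = track_of([[0, 0], [1, 0], [5, 0], [6, 0]], frames=[0, 1, 4, 5])
        samples = kin.velocities(track, interval_min=1.0)
        assert [s.frame for s in samples] == [0, 4]  # nothing spans frames 1->4

    def test_speed_is_displacement_over_interval(self):
        rng = np.random.default_rng(3)
        xy = np.cumsum(rng.normal(0, 1, (20, 2)), axis=0)
        for dt in (1.0, 5.0):
            samples = kin.velocities(track_of(xy), interval_min=dt)
            for i, s in enumerate(samples):
                assert s.speed_um_min == pytest.approx(
                    np.linalg.norm(xy[i + 1] - xy[i]) / dt
                )


class TestSpeedThresholds:
    def _samples(self, speeds):
        return [
            kin.VelocitySample(i, np.array([1.0, 0.0]), s, valid=True)
            for i, s in enumerate(speeds)
        ]

    def test_percentiles_by_linear_interpolation(self):
        th, _ = kin.speed_thresholds(self._samples([1, 2, 3, 4, 5, 6, 7, 8]))
        assert th.p25_um_min == pytest.approx(2.75)
        assert th.p75_um_min == pytest.approx(6.25)

    def test_equal_speeds_all_mid(self):
        th, classes = kin.speed_thresholds(self._samples([2.0] * 6))
        assert th.p25_um_min == th.p75_um_min
        assert set(classes.values()) == {"mid"}

    def test_too_few_valid_samples_rejected(self):
        with pytest.raises(ValueError, match="4 valid"):
            kin.speed_thresholds(self._samples([1, 2, 3]))

    def test_low_fraction_close_to_quarter(self, kinematics_run):
        cfg, track, *_ = kinematics_run
        vels = kin.velocities(track, cfg.frame_interval_min)
        _, classes = kin.speed_thresholds(vels)
        frac_low = sum(c == "low" for c in classes.values()) / len(classes)
        assert frac_low == pytest.approx(0.25, abs=0.02)

    def test_invariant_under_reversal_and_rigid_motion(self):
        rng = np.random.default_rng(9)
        xy = np.cumsum(rng.normal(0, 1, (30, 2)), axis=0)
        th, _ = kin.speed_thresholds(kin.velocities(track_of(xy), 1.0))
        th_rev, _ = kin.speed_thresholds(kin.velocities(track_of(xy[::-1]), 1.0))
        phi = 0.7
        R = np.array([[np.cos(phi), -np.sin(phi)], [np.sin(phi), np.cos(phi)]])
        th_rot, _ = kin.speed_thresholds(kin.velocities(track_of(xy @ R.T + 5.0), 1.0))
        for other in (th_rev, th_rot):
            assert other.p25_um_min == pytest.approx(th.p25_um_min, abs=1e-9)
            assert other.p75_um_min == pytest.approx(th.p75_um_min, abs=1e-9)


class TestDepth:
    def _geometry(self, opl_y=40.0, n=10):
        return TissueGeometry(layers={"opl": {f: np.array(opl_y) for f in range(n)}})

    def test_sign_convention_positive_basal(self):
        track = track_of([[10, 50], [10, 50]])
        samples, _ = kin.depth_relative_to_layer(track, self._geometry(40.0))
        assert samples[0].depth_um == pytest.approx(10.0)

    def test_on_layer_is_zero(self):
        track = track_of([[10, 40], [10, 40]])
        samples, _ = kin.depth_relative_to_layer(track, self._geometry(40.0))
        assert samples[0].depth_um == 0.0

    def test_sign_flips_at_crossing(self):
        ys = np.linspace(30.1, 50.1, 9)
        track = track_of(np.column_stack([np.full(9, 5.0), ys]))
        samples, summary = kin.depth_relative_to_layer(track, self._geometry(40.0))
        depths = np.array([s.depth_um for s in samples])
        assert depths[0] < 0 < depths[-1]
        crossing = np.nonzero(np.diff(np.sign(depths)))[0]
        assert len(crossing) == 1 and ys[crossing[0]] < 40.0 <= ys[crossing[0] + 1]
        assert summary["max_basal_depth_um"] == pytest.approx(depths.max())

    def test_polyline_layer_distance(self):
        slanted = np.array([[0.0, 40.0], [100.0, 50.0]])
        geom = TissueGeometry(layers={"opl": {0: slanted, 1: slanted}})
        track = track_of([[50.0, 60.0], [50.0, 60.0]])
        samples, _ = kin.depth_relative_to_layer(track, geom)
        # perpendicular distance to the slanted line through (0,40)-(100,50)
        expected = abs(60.0 - 45.0) * np.cos(np.arctan(0.1))
        assert samples[0].depth_um == pytest.approx(expected, rel=1e-6)

    def test_translation_invariance_of_depth(self):
        track = track_of([[10, 50], [12, 55]])
        shift = np.array([7.0, -3.0])
        geom_a = self._geometry(40.0, n=2)
        geom_b = TissueGeometry(
            layers={"opl": {f: np.array(40.0 - 3.0) for f in range(2)}}
        )
        a, _ = kin.depth_relative_to_layer(track, geom_a)
        b, _ = kin.depth_relative_to_layer(track_of(track.xy_um + shift), geom_b)
        for sa, sb in zip(a, b):
            assert sb.depth_um == pytest.approx(sa.depth_um)

    def test_undefined_layer_frames_dropped(self):
        geom = TissueGeometry(layers={"opl": {0: np.array(40.0)}})
        track = track_of([[0, 50]] * 8)
        samples, _ = kin.depth_relative_to_layer(track, geom, max_gap=2)
        assert [s.frame for s in samples] == [0, 1, 2]


class TestCentrosome:
    def test_three_four_five_distance(self):
        cell = track_of([[0, 0], [1, 0]])
        cent = track_of([[3, 4], [4, 4]], role="centrosome")
        df = kin.centrosome_offset(cell, cent)
        assert df.distance_um.iloc[0] == pytest.approx(5.0)

    def test_coincident_tracks_undefined_label(self):
        cell = track_of([[0, 0], [1, 0], [2, 0]])
        cent = track_of([[0, 0], [1, 0], [2, 0]], role="centrosome")
        df = kin.centrosome_offset(cell, cent, interval_min=1.0)
        assert (df.distance_um == 0).all()
        assert (df.position == "undefined").all()

    def test_no_shared_frames_rejected(self):
        cell = track_of([[0, 0], [1, 0]], frames=[0, 1])
        cent = track_of([[0, 0], [1, 0]], frames=[5, 6], role="centrosome")
        with pytest.raises(ValueError, match="share"):
            kin.centrosome_offset(cell, cent)

    def test_alternating_fore_aft_labels_recovered(self, kinematics_run):
        cfg, track, _, _, _, centrosome = kinematics_run
        df = kin.centrosome_offset(track, centrosome, interval_min=cfg.frame_interval_min)
        labelled = df[df.position != "undefined"]
        expected = np.where(labelled.frame % 2 == 0, "front", "back")
        agreement = (labelled.position.to_numpy() == expected).mean()
        assert agreement >= 0.99


class TestPathProperties:
    def test_path_length_superadditive(self):
        rng = np.random.default_rng(12)
        for _ in range(10):
            xy = np.cumsum(rng.normal(0, 1, (15, 2)), axis=0)
            t = track_of(xy)
            assert kin.path_length(t) >= kin.net_displacement(t) - 1e-12

    def test_collinear_monotone_equality(self):
        xy = np.column_stack([np.linspace(0, 10, 6), np.zeros(6)])
        t = track_of(xy)
        assert kin.path_length(t) == pytest.approx(kin.net_displacement(t))
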