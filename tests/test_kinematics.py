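"""Segmentation, linking, speeds, and pioneer/trailing role analysis."""

import numpy as np
import pytest

from liqchan import kinematics as km
from liqchan.geometry_model import ChannelGeometry
from liqchan.kinematics import CellTrack, Detection
from liqchan.synthetic_scenes import SceneConfig, SyntheticCell, render_timelapse


def _timelapse(cast, n_frames=16, seed=3, slowdown=0.35, fov=200.0, interval=30.0):
    cfg = SceneConfig(
        geometry=ChannelGeometry(30.0), baseline_h=2.0, fov_y=fov, seed=seed
    )
    return (
        render_timelapse(
            cfg, cast, frame_interval_s=interval, n_frames=n_frames,
            slowdown_factor=slowdown,
        ),
        cfg,
    )


class TestSegmentCells:
    def test_three_disjoint_cells_found_near_truth(self):
        cast = [
            SyntheticCell(position=(-6.0, 30.0)),
            SyntheticCell(position=(6.0, 60.0)),
            SyntheticCell(position=(0.0, 100.0)),
        ]
        (movie, truth), cfg = _timelapse(cast, n_frames=2, slowdown=1.0)
        dets = km.segment_cells(movie[0], cfg.voxel_xy)
        assert len(dets) == 3
        gt = truth.tracks[truth.tracks.frame == 0]
        for _, row in gt.iterrows():
            best = min(
                np.hypot(d.centroid[0] - row.x_um, d.centroid[1] - row.y_um)
                for d in dets
            )
            assert best <= cfg.voxel_xy  # within one pixel of ground truth

    def test_blank_frame_empty(self):
        assert km.segment_cells(np.zeros((50, 50)), 0.5) == []

    def test_touching_cells_split_by_watershed(self):
        cast = [
            SyntheticCell(position=(0.0, 30.0), footprint=(3.0, 4.0)),
            SyntheticCell(position=(0.0, 38.2), footprint=(3.0, 4.0)),
        ]
        (movie, _), cfg = _timelapse(cast, n_frames=2, slowdown=1.0)
        dets = km.segment_cells(movie[0], cfg.voxel_xy)
        assert len(dets) == 2

    def test_area_gate_rejects_debris(self):
        frame = np.zeros((60, 60))
        frame[5:7, 5:7] = 1000.0  # 1 um^2 at 0.5 um pixels: below gate
        frame[20:40, 20:36] = 1000.0  # 80 um^2 object
        dets = km.segment_cells(frame, 0.5)
        assert len(dets) == 1


class TestLinkTracks:
    def test_non_crossing_tracks_fully_linked(self):
        cast = [
            SyntheticCell(position=(-6.0, 30.0), speed=15.0),
            SyntheticCell(position=(6.0, 60.0), speed=15.0),
        ]
        (movie, truth), cfg = _timelapse(cast, n_frames=10, slowdown=1.0)
        dets = [km.segment_cells(f, cfg.voxel_xy) for f in movie]
        tracks = km.link_tracks(dets, max_step=15.0)
        assert len(tracks) == 2
        assert all(len(t) == 10 for t in tracks)

    def test_single_detection_single_track(self):
        dets = [
            [Detection(centroid=(5.0, 10.0 + 3.0 * t), area=50.0, mask=None)]
            for t in range(6)
        ]
        tracks = km.link_tracks(dets, max_step=10.0)
        assert len(tracks) == 1 and len(tracks[0]) == 6

    def test_gap_closing_bridges_one_missing_frame(self):
        dets = [
            [Detection(centroid=(5.0, 10.0 + 3.0 * t), area=50.0, mask=None)]
            for t in range(6)
        ]
        dets[3] = []  # detection dropout
        tracks = km.link_tracks(dets, max_step=10.0)
        assert len(tracks) == 1
        assert tracks[0].frames == [0, 1, 2, 4, 5]

    def test_requires_two_frames(self):
        with pytest.raises(ValueError):
            km.link_tracks([[]], max_step=5.0)


class TestTrackSpeed:
    def test_arithmetic(self):
        tr = CellTrack(track_id=0)
        for t in range(4):
            tr.frames.append(t)
            tr.x_um.append(0.0)
            tr.y_um.append(10.0 * t)  # 10 um per 30 s step
            tr.area_um2.append(50.0)
            tr.roles.append("unassigned")
        assert km.track_speed(tr, 30.0) == pytest.approx(20.0)

    def test_stationary_zero(self):
        tr = CellTrack(track_id=0, frames=[0, 1, 2], x_um=[1, 1, 1], y_um=[2, 2, 2],
                       area_um2=[9, 9, 9], roles=["u"] * 3)
        assert km.track_speed(tr, 30.0) == 0.0

    def test_single_frame_undefined(self):
        tr = CellTrack(track_id=0, frames=[0], x_um=[1], y_um=[2], area_um2=[9],
                       roles=["u"])
        with pytest.raises(ValueError):
            km.track_speed(tr, 30.0)

    def test_recovered_within_five_percent_of_ground_truth(self):
        cast = [SyntheticCell(position=(0.0, 20.0), speed=18.0)]
        (movie, _), cfg = _timelapse(cast, n_frames=12, slowdown=1.0, fov=250.0)
        dets = [km.segment_cells(f, cfg.voxel_xy) for f in movie]
        tracks = km.link_tracks(dets, max_step=15.0)
        assert km.track_speed(tracks[0], 30.0) == pytest.approx(18.0, rel=0.05)


class TestRolesAndTransition:
    def _tracked_catchup(self, seed=3):
        cast = [
            SyntheticCell(position=(0.0, 60.0), speed=20.0),
            SyntheticCell(position=(0.0, 20.0), speed=20.0),
        ]
        (movie, truth), cfg = _timelapse(cast, n_frames=16, seed=seed)
        dets = [km.segment_cells(f, cfg.voxel_xy) for f in movie]
        tracks = km.link_tracks(dets, max_step=15.0)
        km.classify_roles(tracks, frame_interval_s=30.0)
        return tracks, truth

    def test_leading_cell_is_pioneer_every_frame(self):
        cast = [
            SyntheticCell(position=(0.0, 60.0), speed=10.0),
            SyntheticCell(position=(0.0, 20.0), speed=10.0),
        ]
        (movie, _), cfg = _timelapse(cast, n_frames=8, slowdown=1.0)
        dets = [km.segment_cells(f, cfg.voxel_xy) for f in movie]
        tracks = km.link_tracks(dets, max_step=15.0)
        km.classify_roles(tracks, frame_interval_s=30.0)
        lead = max(tracks, key=lambda t: t.y_um[0])
        trail = min(tracks, key=lambda t: t.y_um[0])
        assert all(r == "pioneer" for r in lead.roles)
        assert all(r == "trailing" for r in trail.roles)

    def test_at_most_one_pioneer_per_frame(self):
        tracks, _ = self._tracked_catchup()
        frames = sorted({f for t in tracks for f in t.frames})
        for f in frames:
            n_pioneer = sum(
                1 for t in tracks if f in t.frames and t.roles[t.frames.index(f)] == "pioneer"
            )
            assert n_pioneer <= 1

    def test_transition_detected_within_one_frame_of_truth(self):
        for seed in (0, 3, 9):
            tracks, truth = self._tracked_catchup(seed=seed)
            catcher = [t for t in tracks if t.roles[0] == "trailing" and "pioneer" in t.roles]
            assert len(catcher) == 1
            _, _, frame = km.transition_analysis(catcher[0], 30.0)
            assert abs(frame - truth.params["transition_frame"]) <= 1

    def test_speed_ratio_recovers_slowdown(self):
        tracks, _ = self._tracked_catchup()
        catcher = [t for t in tracks if t.roles[0] == "trailing" and "pioneer" in t.roles][0]
        before, after, _ = km.transition_analysis(catcher, 30.0)
        assert after / before == pytest.approx(0.35, abs=0.1)

    def test_catcher_roles_form_trailing_then_pioneer(self):
        """The overtaking cell's role sequence is trailing* -> pioneer*."""
        tracks, _ = self._tracked_catchup()
        catcher = [t for t in tracks if t.roles[0] == "trailing" and "pioneer" in t.roles][0]
        first_p = catcher.roles.index("pioneer")
        assert all(r == "trailing" for r in catcher.roles[:first_p])
        assert all(r == "pioneer" for r in catcher.roles[first_p:])

    def test_no_transition_rejected(self):
        tr = CellTrack(track_id=0, frames=[0, 1], x_um=[0, 0], y_um=[0, 5],
                       area_um2=[9, 9], roles=["trailing", "trailing"])
        with pytest.raises(ValueError):
            km.transition_analysis(tr, 30.0)
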