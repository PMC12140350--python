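"""Synthetic scene generators: determinism, ground-truth correctness, kinematics."""

import numpy as np
import pytest

from liqchan.geometry_model import ChannelGeometry
from liqchan.synthetic_scenes import (
    ProtrusionSpec,
    SceneConfig,
    SyntheticCell,
    arc_height_profile,
    mixture_concentration,
    render_channel_stack,
    render_protrusion_movie,
    render_timelapse,
    render_tissue_scene,
)


class TestChannelStack:
    def test_noiseless_interface_matches_analytic_arc(self, clean_stack_config):
        vol, truth = render_channel_stack(clean_stack_config, [])
        x = truth.params["x_um"]  # already centered on the channel axis
        expected = arc_height_profile(x, 30.0, clean_stack_config.baseline_h)
        assert np.allclose(truth.height_map[0], expected)
        # intensity steps exactly at the interface: media below, oil above
        nz = vol.shape[0]
        z = (np.arange(nz) + 0.5) * clean_stack_config.voxel_z
        j, i = 5, vol.shape[2] // 2
        col = vol[:, j, i]
        h = truth.height_map[j, i]
        assert np.all(col[z < h] == clean_stack_config.media_level)
        assert np.all(col[z > h] == clean_stack_config.oil_level)

    def test_cell_bump_apex_by_construction(self, clean_stack_config, bump_cell):
        _, truth = render_channel_stack(clean_stack_config, [bump_cell])
        apex = truth.params["apex_profile"]
        y = truth.params["y_um"]
        # grid samples at voxel centers, 0.25 um off the exact bump apex
        assert apex[np.argmin(np.abs(y - 30.0))] == pytest.approx(5.0, abs=0.01)
        assert apex[0] == pytest.approx(2.0, abs=1e-6)
        assert truth.height_map.max() == pytest.approx(5.0, abs=0.01)

    def test_seeded_determinism(self, stack_config, bump_cell):
        v1, _ = render_channel_stack(stack_config, [bump_cell])
        v2, _ = render_channel_stack(stack_config, [bump_cell])
        assert v1.tobytes() == v2.tobytes()

    def test_cell_outside_strip_rejected(self, stack_config):
        with pytest.raises(ValueError, match="outside"):
            render_channel_stack(
                stack_config, [SyntheticCell(position=(14.0, 30.0))]
            )

    def test_body_height_below_baseline_rejected(self, stack_config):
        with pytest.raises(ValueError, match="baseline"):
            render_channel_stack(
                stack_config, [SyntheticCell(position=(0.0, 30.0), body_height=1.0)]
            )


class TestTimelapse:
    def test_single_cell_displacement_per_frame(self, stack_config):
        cfg = SceneConfig(
            geometry=ChannelGeometry(30.0), baseline_h=2.0, fov_y=200.0, seed=0
        )
        cell = SyntheticCell(position=(0.0, 20.0), speed=20.0)
        _, truth = render_timelapse(
            cfg, [cell], frame_interval_s=30.0, n_frames=5, slowdown_factor=1.0
        )
        y = truth.tracks.sort_values("frame")["y_um"].to_numpy()
        assert np.allclose(np.diff(y), 10.0)  # 20 um/min x 0.5 min

    def test_pioneer_slowdown_is_exact(self):
        cfg = SceneConfig(
            geometry=ChannelGeometry(30.0), baseline_h=2.0, fov_y=300.0, seed=0
        )
        cast = [
            SyntheticCell(position=(0.0, 60.0), speed=20.0),
            SyntheticCell(position=(0.0, 20.0), speed=10.0),
        ]
        _, truth = render_timelapse(
            cfg, cast, frame_interval_s=30.0, n_frames=6, slowdown_factor=0.5
        )
        t = truth.tracks
        v_pioneer = t[(t.cell_id == 0) & (t.frame == 0)]["speed_um_min"].iloc[0]
        v_trail = t[(t.cell_id == 1) & (t.frame == 0)]["speed_um_min"].iloc[0]
        assert v_pioneer == pytest.approx(0.5 * 20.0)
        assert v_trail == pytest.approx(10.0)

    def test_catchup_transition_matches_closed_form(self):
        """A faster trailing cell takes the pioneer role at the catch-up time."""
        cfg = SceneConfig(
            geometry=ChannelGeometry(30.0), baseline_h=2.0, fov_y=200.0, seed=0
        )
        cast = [
            SyntheticCell(position=(0.0, 60.0), speed=20.0),
            SyntheticCell(position=(0.0, 20.0), speed=20.0),
        ]
        slowdown = 0.35
        _, truth = render_timelapse(
            cfg, cast, frame_interval_s=30.0, n_frames=16, slowdown_factor=slowdown
        )
        # closed form: gap 40 um closes at (20 - 0.35*20) um/min to the contact
        # distance (sum of y semi-axes, 8 um); one further full-speed frame
        # brings the new front to the interface
        gap0, contact = 40.0, 8.0
        closing = 20.0 * (1 - slowdown) / 2.0  # um per 30 s frame
        t_contact = int(np.ceil((gap0 - contact) / closing))
        expected = t_contact + 1
        assert truth.params["transition_cell"] == 1
        assert abs(truth.params["transition_frame"] - expected) <= 1
        roles = truth.tracks[truth.tracks.cell_id == 1].sort_values("frame")["role"]
        flip = np.argmax(roles.to_numpy() == "pioneer")
        assert flip == truth.params["transition_frame"]

    def test_queueing_prevents_overlap(self):
        cfg = SceneConfig(
            geometry=ChannelGeometry(30.0), baseline_h=2.0, fov_y=200.0, seed=0
        )
        cast = [
            SyntheticCell(position=(0.0, 50.0), speed=20.0, footprint=(3.0, 4.0)),
            SyntheticCell(position=(0.0, 38.0), speed=20.0, footprint=(3.0, 4.0)),
            SyntheticCell(position=(0.0, 26.0), speed=20.0, footprint=(3.0, 4.0)),
        ]
        _, truth = render_timelapse(
            cfg, cast, frame_interval_s=30.0, n_frames=10, slowdown_factor=0.35
        )
        t = truth.tracks
        for f in range(10):
            sub = t[(t.frame == f) & (t.role != "stalled")].sort_values("y_um")
            gaps = np.diff(sub["y_um"].to_numpy())
            assert np.all(gaps >= 8.0 - 1e-6)

    def test_determinism(self):
        cfg = SceneConfig(
            geometry=ChannelGeometry(30.0), baseline_h=2.0, fov_y=100.0, seed=9
        )
        cast = [SyntheticCell(position=(0.0, 20.0), speed=15.0)]
        m1, _ = render_timelapse(cfg, cast, n_frames=4)
        m2, _ = render_timelapse(cfg, cast, n_frames=4)
        assert m1.tobytes() == m2.tobytes()


class TestProtrusionMovie:
    def test_ground_truth_rate_and_speed_arithmetic(self):
        cfg = SceneConfig(
            geometry=ChannelGeometry(30.0), baseline_h=2.0, seed=1, voxel_xy=0.25
        )
        events = [
            ProtrusionSpec("bleb", onset_s=5.0 + 25.0 * k, duration_s=6.0, max_extent=3.0)
            for k in range(5)
        ]
        movie, truth = render_protrusion_movie(
            cfg, events, frame_interval_s=0.5, n_frames=300
        )
        span_min = 300 * 0.5 / 60.0
        n_blebs = sum(1 for e in truth.events if e["class"] == "bleb")
        assert n_blebs / span_min == pytest.approx(2.0)
        # 3 um reached in the rise time -> expansion speed in closed form
        ev = truth.events[0]
        assert ev["expansion_speed_um_s"] == pytest.approx(3.0 / ev["time_to_max_s"])
        assert ev["time_to_max_s"] <= 2.0 * 0.5 + 1e-9

    def test_bleb_in_slow_movie_rejected(self):
        cfg = SceneConfig(geometry=ChannelGeometry(30.0), baseline_h=2.0, seed=1)
        with pytest.raises(ValueError, match="frame_interval"):
            render_protrusion_movie(
                cfg, [ProtrusionSpec("bleb", 0.0, 6.0)], frame_interval_s=2.0
            )

    def test_too_short_event_rejected(self):
        cfg = SceneConfig(geometry=ChannelGeometry(30.0), baseline_h=2.0, seed=1)
        with pytest.raises(ValueError, match="duration"):
            render_protrusion_movie(
                cfg, [ProtrusionSpec("bleb", 0.0, duration_s=0.9)], frame_interval_s=1.0
            )

    def test_determinism(self):
        cfg = SceneConfig(
            geometry=ChannelGeometry(30.0), baseline_h=2.0, seed=1234, voxel_xy=0.25
        )
        events = [ProtrusionSpec("bleb", 2.0, 5.0)]
        m1, _ = render_protrusion_movie(cfg, events, frame_interval_s=1.0)
        m2, _ = render_protrusion_movie(cfg, events, frame_interval_s=1.0)
        assert m1.tobytes() == m2.tobytes()


class TestTissueScene:
    def _render(self, radius=4.0, tau=30.0, n=16):
        cfg = SceneConfig(
            geometry=ChannelGeometry(30.0), baseline_h=2.0, seed=5, voxel_xy=0.4
        )
        path = np.column_stack([np.full(n, 30.0), np.linspace(5.0, 55.0, n)])
        return render_tissue_scene(
            cfg, path, cell_packing=15.0, cell_radius=radius,
            recovery_tau_s=tau, frame_interval_s=10.0,
        )

    def test_max_displacement_equals_cell_radius(self):
        _, truth = self._render(radius=4.0)
        assert truth.params["max_displacement_um"] == pytest.approx(4.0, abs=1e-9)

    def test_zero_radius_no_displacement(self):
        _, truth = self._render(radius=1e-9)
        assert truth.displacement.max() == pytest.approx(0.0, abs=1e-9)

    def test_exponential_recovery_after_passage(self):
        """Displacement relaxes below 5% of peak within ~3 recovery times."""
        cfg = SceneConfig(
            geometry=ChannelGeometry(30.0), baseline_h=2.0, seed=5, voxel_xy=0.4
        )
        # cross the y = 15 um boundary early, then move far away; lane at
        # x = 22.5 runs between the vertical boundary lines
        n = 26
        path = np.column_stack([np.full(n, 22.5), np.linspace(5.0, 55.0, n)])
        tau = 20.0
        _, truth = render_tissue_scene(
            cfg, path, cell_packing=15.0, cell_radius=4.0,
            recovery_tau_s=tau, frame_interval_s=10.0,
        )
        disp = truth.displacement
        ref = truth.params["reference_boundary"]
        line = np.abs(ref[:, 1] - 15.0) < 1e-6  # the crossed horizontal boundary
        peak = disp[:, line].max()
        # the cell clears the line (> radius away) with >= 3 tau of movie left
        clear_t = int(np.argmax(path[:, 1] > 15.0 + 4.0))
        assert (n - 1 - clear_t) * 10.0 >= 3.0 * tau
        assert disp[-1, line].max() < 0.05 * peak + 1e-9

    def test_two_channels_rendered(self):
        movie, _ = self._render()
        assert movie.ndim == 4 and movie.shape[1] == 2


class TestMixtureConcentration:
    def test_collagen_dilution(self):
        assert mixture_concentration(10.0, (1, 1, 1), ndigits=2) == 3.33

    def test_cell_dilution(self):
        assert mixture_concentration(80_000, (1, 1, 1), ndigits=0) == 26_667

    def test_identity(self):
        assert mixture_concentration(7.7, (1,)) == pytest.approx(7.7)

    def test_exact_rational_before_rounding(self):
        # 1:2 of a 1 mg/mL stock is exactly 1/3, not a float artifact
        assert mixture_concentration(1, (1, 2), ndigits=10) == pytest.approx(
            1.0 / 3.0, abs=1e-10
        )

    def test_invalid_parts(self):
        with pytest.raises(ValueError):
            mixture_concentration(10.0, ())
        with pytest.raises(ValueError):
            mixture_concentration(10.0, (1, -1))
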