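"""Synthetic vasculature: generation, Poiseuille flow, rasterization."""

import numpy as np
import pytest

from vascuflow.graph import ARTERY, CAPILLARY, VEIN
from vascuflow.synthetic import (NetworkSpec, generate_network,
                                 rasterize_network, solve_network_flow)
from vascuflow.volumes import VoxelGrid


class TestGenerate:
    def test_tube_phantom_geometry(self):
        spec = NetworkSpec(kind="tube-phantom", domain_size=(400, 1200, 400),
                          tube_diameter=180.0, tube_angle_deg=8.0)
        g = generate_network(spec)
        assert len(g.nodes) == 2 and len(g.segments) == 1
        seg = next(iter(g.segments.values()))
        assert seg.mean_diameter == pytest.approx(180.0)
        d = seg.points[-1] - seg.points[0]
        angle = np.degrees(np.arcsin(abs(d[0]) / np.linalg.norm(d)))
        assert angle == pytest.approx(8.0, abs=1e-6)

    def test_minimal_cortical_chain(self):
        spec = NetworkSpec(n_arteries=1, n_veins=1, tree_levels=0,
                          n_capillary_paths=1, capillary_path_segments=(1, 1))
        g = generate_network(spec)
        # smallest connected unit: artery trunk -> capillary -> vein trunk
        labels = sorted(s.label for s in g.segments.values())
        assert CAPILLARY in labels
        assert len(g.connected_components()) == 1

    def test_determinism(self):
        spec = NetworkSpec(seed=11)
        g1, g2 = generate_network(spec), generate_network(spec)
        assert len(g1.nodes) == len(g2.nodes)
        assert len(g1.segments) == len(g2.segments)
        for nid in g1.nodes:
            assert np.array_equal(g1.nodes[nid].position, g2.nodes[nid].position)
        for sid in g1.segments:
            assert np.array_equal(g1.segments[sid].points, g2.segments[sid].points)
            assert np.array_equal(g1.segments[sid].radii, g2.segments[sid].radii)

    def test_unsatisfiable_spec_raises(self):
        spec = NetworkSpec(domain_size=(200, 120, 120), n_arteries=4, n_veins=4)
        with pytest.raises(ValueError, match="too dense"):
            generate_network(spec)

    def test_capillaries_lie_on_artery_vein_paths(self, default_network):
        _, g, _ = default_network
        # every capillary connects (through the graph) to both boundary sets
        assert len(g.connected_components()) == 1
        kinds = {n.kind for n in g.nodes.values()}
        assert {"inlet", "outlet"} <= kinds

    def test_pial_vessels_confined_to_surface_band(self, default_network):
        spec, g, _ = default_network
        for nid, n in g.nodes.items():
            if n.kind in ("inlet", "outlet"):
                assert n.position[0] <= spec.pial_depth


class TestFlow:
    def test_single_tube_matches_hagen_poiseuille(self):
        spec = NetworkSpec(kind="tube-phantom", domain_size=(400, 1200, 400),
                          tube_diameter=100.0, inlet_pressure=2000.0,
                          outlet_pressure=1000.0, viscosity=3.5e-3)
        g = generate_network(spec)
        flow = solve_network_flow(g, spec)
        seg = next(iter(g.segments.values()))
        r, L = seg.mean_radius, seg.length
        q_expected = np.pi * r**4 * 1000.0 / (8 * spec.viscosity * L)
        assert flow.flow[seg.id] == pytest.approx(q_expected, rel=1e-12)

    def test_junction_conservation(self):
        # Y junction: parent flow equals sum of daughter flows
        spec = NetworkSpec(n_arteries=1, n_veins=1, tree_levels=1,
                          n_capillary_paths=4, seed=3)
        g = generate_network(spec)
        flow = solve_network_flow(g, spec)
        net = {nid: 0.0 for nid in g.nodes}
        for sid, s in g.segments.items():
            net[s.start_node] -= flow.flow[sid]
            net[s.end_node] += flow.flow[sid]
        for nid, n in g.nodes.items():
            if n.kind == "interior":
                assert abs(net[nid]) < 1e-6 * max(abs(q) for q in flow.flow.values())

    def test_large_network_residual(self):
        spec = NetworkSpec(n_arteries=3, n_veins=3, n_capillary_paths=40, seed=7)
        g = generate_network(spec)
        assert len(g.segments) >= 200
        flow = solve_network_flow(g, spec)
        assert flow.conservation_residual(g) < 1e-9

    def test_default_velocities_physiological(self, default_network):
        _, g, flow = default_network
        caps = [abs(flow.velocity[sid]) for sid, s in g.segments.items()
                if s.label == CAPILLARY]
        arts = [abs(flow.velocity[sid]) for sid, s in g.segments.items()
                if s.label == ARTERY]
        assert 0.3 < np.median(caps) < 5.0
        assert max(caps) < 10.0
        assert max(arts) > np.median(caps)

    def test_isolated_component_raises(self):
        from tests.conftest import straight_segment_graph

        g = straight_segment_graph([0, 0, 0], [0, 100, 0], 5.0)
        spec = NetworkSpec()
        with pytest.raises(ValueError, match="no inlet or outlet"):
            solve_network_flow(g, spec)


class TestRasterize:
    def test_cylinder_cross_section_area(self):
        from tests.conftest import straight_segment_graph

        g = straight_segment_graph([16, 5, 16], [16, 55, 16], 4.0)
        grid = VoxelGrid((32, 60, 32), 1.0)
        mask, _ = rasterize_network(g, None, grid)
        # per-slice foreground area vs pi r^2, away from the capsule ends
        areas = mask.data[:, 15:45, :].sum(axis=(0, 2))
        assert np.allclose(areas, np.pi * 16, rtol=0.15)

    def test_plug_profile_uniform_speed(self):
        from tests.conftest import straight_segment_graph
        from vascuflow.graph import START_TO_END

        g = straight_segment_graph([16, 5, 16], [16, 55, 16], 4.0,
                                   v_tot=10.0, direction=START_TO_END)
        grid = VoxelGrid((32, 60, 32), 1.0)
        mask, vel = rasterize_network(g, None, grid)
        speed = np.sqrt((vel**2).sum(axis=0))
        assert np.allclose(speed[mask.data], 10.0)

    def test_parabolic_centerline_speed(self):
        from tests.conftest import straight_segment_graph
        from vascuflow.graph import START_TO_END

        g = straight_segment_graph([16, 5, 16], [16, 55, 16], 6.0,
                                   v_tot=10.0, direction=START_TO_END)
        grid = VoxelGrid((32, 60, 32), 1.0)
        mask, vel = rasterize_network(g, None, grid, profile="parabolic")
        speed = np.sqrt((vel**2).sum(axis=0))
        assert speed[16, 30, 16] == pytest.approx(20.0, rel=0.05)

    def test_thin_vessel_warns_and_stays_connected(self):
        from scipy import ndimage

        from tests.conftest import straight_segment_graph

        g = straight_segment_graph([16, 5, 16], [16, 55, 16], 0.8)
        grid = VoxelGrid((32, 60, 32), 2.0)
        with pytest.warns(UserWarning, match="grid too coarse"):
            mask, _ = rasterize_network(g, None, grid)
        _, n = ndimage.label(mask.data, structure=np.ones((3, 3, 3)))
        assert n == 1

    def test_raster_determinism(self, default_network):
        spec, g, flow = default_network
        grid = VoxelGrid((40, 60, 60), 8.0)
        with np.errstate(all="ignore"):
            import warnings

            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                m1, v1 = rasterize_network(g, flow, grid)
                m2, v2 = rasterize_network(g, flow, grid)
        assert np.array_equal(m1.data, m2.data)
        assert np.array_equal(v1, v2)
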