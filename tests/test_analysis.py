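"""Vessel typing, branching orders, path profiles, node-degree curves."""

import numpy as np
import pytest

from vascuflow.analysis import (arteriovenous_path_profiles,
                                compute_branching_orders, network_summaries,
                                node_degree_vs_axial_fov,
                                propagate_vessel_labels)
from vascuflow.graph import (ARTERY, CAPILLARY, MEASURED, START_TO_END, VEIN,
                             VesselGraph)


def chain_graph(diameters, labels=None, velocities=None):
    """Linear chain of segments with given mean diameters."""
    g = VesselGraph()
    nodes = [g.new_node([0.0, 50.0 * i, 0.0]) for i in range(len(diameters) + 1)]
    t = np.linspace(0, 1, 5)[:, None]
    for i, d in enumerate(diameters):
        pts = nodes[i].position * (1 - t) + nodes[i + 1].position * t
        kw = {}
        if velocities is not None and velocities[i] is not None:
            kw = dict(v_tot=float(velocities[i]), direction=START_TO_END,
                      velocity_source=MEASURED)
        seg = g.new_segment(nodes[i].id, nodes[i + 1].id, pts,
                            np.full(5, d / 2.0), **kw)
        if labels is not None:
            seg.label = labels[i]
    return g


class TestLabelPropagation:
    def test_diameter_stop_rule(self):
        g = chain_graph([20.0, 14.0, 10.0])
        propagate_vessel_labels(g, seeds={0: ARTERY})
        labs = [g.segments[i].label for i in range(3)]
        assert labs == [ARTERY, ARTERY, CAPILLARY]

    def test_no_seeds_all_capillary_with_warning(self):
        g = chain_graph([20.0, 14.0])
        with pytest.warns(UserWarning, match="no artery/vein seeds"):
            propagate_vessel_labels(g, seeds=None)
        assert all(s.label == CAPILLARY for s in g.segments.values())

    def test_conflicting_labels_stay_capillary(self):
        g = chain_graph([20.0, 20.0, 20.0])
        with pytest.warns(UserWarning, match="conflict"):
            propagate_vessel_labels(g, seeds={0: ARTERY, 2: VEIN})
        assert g.segments[1].label == CAPILLARY
        assert "label_conflict" in g.segments[1].flags

    def test_accuracy_on_synthetic_network(self, default_network):
        _, g0, _ = default_network
        g = g0.copy()
        truth = {sid: s.label for sid, s in g.segments.items()}
        # seed from the boundary (pial) segments, as the manual workflow would
        seeds = {}
        for sid, s in g.segments.items():
            for nid in (s.start_node, s.end_node):
                kind = g.nodes[nid].kind
                if kind == "inlet":
                    seeds[sid] = ARTERY
                elif kind == "outlet":
                    seeds[sid] = VEIN
        propagate_vessel_labels(g, seeds=seeds)
        non_cap = [sid for sid, lab in truth.items() if lab != CAPILLARY]
        acc = np.mean([g.segments[sid].label == truth[sid] for sid in non_cap])
        assert acc >= 0.95


class TestBranchingOrders:
    def test_hop_counting_on_chain(self):
        g = chain_graph([20.0, 8.0, 6.0, 6.0, 16.0],
                        labels=[ARTERY, CAPILLARY, CAPILLARY, CAPILLARY, VEIN])
        orders = compute_branching_orders(g)
        assert orders.loc[0, "arterial_order"] == 0
        assert orders.loc[1, "arterial_order"] == 1
        assert orders.loc[2, "arterial_order"] == 2
        assert orders.loc[2, "venous_order"] == 2
        assert orders.loc[4, "venous_order"] == 0

    def test_adjacent_orders_differ_by_at_most_one(self, default_network):
        _, g, _ = default_network
        orders = compute_branching_orders(g)
        adj = g.segment_adjacency()
        for sid, nbrs in adj.items():
            for other in nbrs:
                for col in ("arterial_order", "venous_order"):
                    a, b = orders.loc[sid, col], orders.loc[other, col]
                    if np.isfinite(a) and np.isfinite(b):
                        assert abs(a - b) <= 1

    def test_unreachable_class_is_nan(self):
        g = chain_graph([20.0, 6.0], labels=[ARTERY, CAPILLARY])
        orders = compute_branching_orders(g)
        assert np.isnan(orders.loc[0, "venous_order"])


class TestPathProfiles:
    def test_single_path_profile(self):
        g = chain_graph([20.0, 6.0, 6.0, 6.0, 16.0],
                        labels=[ARTERY, CAPILLARY, CAPILLARY, CAPILLARY, VEIN],
                        velocities=[10.0, 5.0, 2.0, 6.0, 8.0])
        prof = arteriovenous_path_profiles(g)
        assert prof.n_paths == 1
        # the single path's interpolated curve: endpoints near the
        # arterial / venous segment velocities
        assert prof.median[0] == pytest.approx(10.0, rel=0.01)
        assert prof.median[-1] == pytest.approx(8.0, rel=0.01)
        assert prof.mad.max() == 0.0

    def test_short_capillary_path_excluded(self):
        g = chain_graph([20.0, 6.0, 6.0, 16.0],
                        labels=[ARTERY, CAPILLARY, CAPILLARY, VEIN],
                        velocities=[10.0, 5.0, 4.0, 8.0])
        with pytest.warns(UserWarning, match="no qualifying"):
            prof = arteriovenous_path_profiles(g)
        assert prof.n_paths == 0

    def test_identical_paths_have_zero_mad(self, default_network):
        _, g0, _ = default_network
        g = g0.copy()
        for s in g.segments.values():
            s.v_tot = 3.0
        prof = arteriovenous_path_profiles(g)
        assert prof.n_paths > 10
        assert np.allclose(prof.mad, 0.0)

    def test_profile_invariant_to_enumeration_order(self, default_network):
        # same ids, reversed insertion order: medians must not change
        import copy

        _, g0, _ = default_network
        prof1 = arteriovenous_path_profiles(g0)
        g2 = VesselGraph()
        for nid in sorted(g0.nodes, reverse=True):
            g2.add_node(copy.deepcopy(g0.nodes[nid]))
        for sid in sorted(g0.segments, reverse=True):
            g2.add_segment(copy.deepcopy(g0.segments[sid]))
        prof2 = arteriovenous_path_profiles(g2)
        assert prof1.n_paths == prof2.n_paths
        assert np.allclose(prof1.median, prof2.median, equal_nan=True)


class TestNodeDegreeCurve:
    def test_full_window_y_graph(self):
        from tests.conftest import y_tree_graph

        g = y_tree_graph()
        df = node_degree_vs_axial_fov(g, [100.0])
        assert df["mean_degree"].iloc[0] == pytest.approx(1.5)  # {3,1,1,1}

    def test_window_above_junction_severs(self):
        from tests.conftest import y_tree_graph

        g = y_tree_graph()  # junction at z=30; arms descend to z=55
        df = node_degree_vs_axial_fov(g, [20.0])  # surface at z=5 -> cut at 25
        assert df["mean_degree"].iloc[0] == pytest.approx(1.0)

    def test_monotone_in_window_depth(self, default_network):
        _, g, _ = default_network
        depths = np.linspace(30, 320, 10)
        df = node_degree_vs_axial_fov(g, depths)
        vals = df["mean_degree"].to_numpy()
        assert np.all(np.diff(vals) >= -1e-9)

    def test_roundtrip_through_serialization(self, default_network, tmp_path):
        from vascuflow.io import load_graph_json, save_graph_json

        _, g, _ = default_network
        save_graph_json(g, tmp_path / "g.json")
        g2 = load_graph_json(tmp_path / "g.json")
        d1 = node_degree_vs_axial_fov(g, [100.0, 250.0])
        d2 = node_degree_vs_axial_fov(g2, [100.0, 250.0])
        assert np.allclose(d1["mean_degree"], d2["mean_degree"])


class TestSummaries:
    def test_equal_artery_vein_volume_split(self):
        g = chain_graph([10.0, 10.0], labels=[ARTERY, VEIN],
                        velocities=[5.0, 5.0])
        out = network_summaries(g)
        assert out["class_volumes"][ARTERY] == pytest.approx(0.5)
        assert out["class_volumes"][VEIN] == pytest.approx(0.5)

    def test_unset_fraction_zero_when_all_measured(self, default_network):
        _, g, _ = default_network
        out = network_summaries(g)
        assert out["unset_fraction"] == 0.0

    def test_class_volume_fractions_partition(self, default_network):
        _, g, _ = default_network
        out = network_summaries(g)
        assert sum(out["class_volumes"].values()) == pytest.approx(1.0, abs=1e-9)

    def test_velocity_volume_tables_normalized_per_class(self, default_network):
        _, g, _ = default_network
        out = network_summaries(g)
        for lab, table in out["velocity_volume"].items():
            assert table["relative_volume"].iloc[-1] == pytest.approx(1.0)
            assert (table["v_tot"].diff().dropna() >= 0).all()


class TestExternalGraphReader:
    def test_node_edge_tables_roundtrip(self, tmp_path):
        import pandas as pd

        from vascuflow.analysis import read_node_edge_tables

        nodes = pd.DataFrame({"id": [0, 1, 2, 3],
                              "z": [0.0, 30.0, 60.0, 60.0],
                              "x": [0.0, 0.0, -20.0, 20.0],
                              "y": [0.0, 0.0, 0.0, 0.0]})
        edges = pd.DataFrame({"node1": [0, 1, 1], "node2": [1, 2, 3],
                              "radius": [5.0, 3.0, 3.0]})
        nodes.to_csv(tmp_path / "n.csv", index=False)
        edges.to_csv(tmp_path / "e.csv", index=False)
        g = read_node_edge_tables(tmp_path / "n.csv", tmp_path / "e.csv")
        assert len(g.nodes) == 4 and len(g.segments) == 3
        df = node_degree_vs_axial_fov(g, [100.0])
        assert df["mean_degree"].iloc[0] == pytest.approx(1.5)
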