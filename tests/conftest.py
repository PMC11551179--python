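import numpy as np
import pytest

from vascuflow.graph import (MEASURED, START_TO_END, Node, Segment, VesselGraph)
from vascuflow.octsim import AcquisitionProtocol, SystemCalibration
from vascuflow.synthetic import NetworkSpec, generate_network, solve_network_flow
from vascuflow.volumes import VoxelGrid


@pytest.fixture(scope="session")
def protocol():
    return AcquisitionProtocol.doppler_default()


@pytest.fixture(scope="session")
def calibration():
    return SystemCalibration()


@pytest.fixture(scope="session")
def default_network():
    """Default cortical network with solved, annotated ground-truth flows."""
    spec = NetworkSpec(seed=0)
    g = generate_network(spec)
    flow = solve_network_flow(g, spec)
    flow.annotate(g)
    return spec, g, flow


def straight_segment_graph(p0, p1, radius, n_pts=9, **seg_kw):
    """Two-node graph with one straight segment (test helper)."""
    g = VesselGraph()
    a = g.new_node(np.asarray(p0, float))
    b = g.new_node(np.asarray(p1, float))
    t = np.linspace(0, 1, n_pts)[:, None]
    pts = a.position[None, :] * (1 - t) + b.position[None, :] * t
    g.new_segment(a.id, b.id, pts, np.full(n_pts, float(radius)), **seg_kw)
    return g


def y_tree_graph(radius=3.0):
    """Y-shaped tree: trunk + two arms, 4 nodes / 3 segments."""
    g = VesselGraph()
    n0 = g.new_node([5.0, 10.0, 32.0])
    n1 = g.new_node([30.0, 30.0, 32.0])
    n2 = g.new_node([55.0, 50.0, 12.0])
    n3 = g.new_node([55.0, 50.0, 52.0])
    t = np.linspace(0, 1, 9)[:, None]
    for a, b in [(n0, n1), (n1, n2), (n1, n3)]:
        pts = a.position[None, :] * (1 - t) + b.position[None, :] * t
        g.new_segment(a.id, b.id, pts, np.full(9, radius))
    return g


def star_graph(speeds_and_radii):
    """One central node with straight spokes; for conservation tests.

    ``speeds_and_radii``: list of (radius, v_tot or None, direction or None)
    where direction +1 means flow toward the center, -1 away, None unknown.
    """
    from vascuflow.graph import END_TO_START, UNKNOWN, UNSET

    g = VesselGraph()
    c = g.new_node([0.0, 0.0, 0.0])
    t = np.linspace(0, 1, 5)[:, None]
    for i, (r, v, d) in enumerate(speeds_and_radii):
        ang = 2 * np.pi * i / len(speeds_and_radii)
        outer = g.new_node([0.0, 100 * np.cos(ang), 100 * np.sin(ang)])
        pts = outer.position[None, :] * (1 - t) + c.position[None, :] * t
        kw = {}
        if v is not None and d is not None:
            kw = dict(v_tot=float(v),
                      direction=START_TO_END if d > 0 else END_TO_START,
                      velocity_source=MEASURED)
        g.new_segment(outer.id, c.id, pts, np.full(5, float(r)), **kw)
    return g
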