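"""Network-level analysis: vessel typing, branching orders, path profiles.

Artery/vein labels propagate from pial seed segments through the graph,
halting at pre-capillaries (median diameter below 12 um); the rest is
capillary bed.  Each segment receives arterial and venous branching orders
(minimum segment-hop distance to the respective labeled tree).  For every
capillary, the combined shortest path closest-artery -> capillary ->
closest-vein is normalized to unit length and resampled onto a common
grid; the median and MAD of total flow velocity per grid point summarize
how flow decays from diving arterioles into the capillary bed and picks up
again toward ascending venules.  A node-degree-versus-axial-window curve
quantifies how a limited depth of field severs network interconnections.
"""

from __future__ import annotations

import warnings
from collections import deque
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .graph import ARTERY, CAPILLARY, UNKNOWN, UNSET, VEIN, VesselGraph

__all__ = [
    "PathProfile",
    "propagate_vessel_labels",
    "compute_branching_orders",
    "arteriovenous_path_profiles",
    "node_degree_vs_axial_fov",
    "network_summaries",
    "read_node_edge_tables",
]

PRECAPILLARY_DIAMETER = 12.0  # um; propagation stop rule


@dataclass
class PathProfile:
    """Arteriovenous path velocity profile on a normalized [0, 1] grid.

    Position 0 is the arterial side, 1 the venous side.  ``median`` and
    ``mad`` are per-grid-point statistics of v_tot (mm/s) across paths;
    ``path_lengths`` holds each contributing path's segment count before
    normalization.
    """

    grid: np.ndarray
    median: np.ndarray
    mad: np.ndarray
    n_paths: int
    path_lengths: np.ndarray

    def length_histogram(self, bins=None):
        """Histogram counts of unnormalized path lengths (segment counts)."""
        if bins is None:
            m = int(self.path_lengths.max()) if len(self.path_lengths) else 1
            bins = np.arange(0.5, m + 1.5)
        counts, edges = np.histogram(self.path_lengths, bins=bins)
        return counts, edges


def propagate_vessel_labels(
    graph: VesselGraph,
    seeds: dict[int, str] | None = None,
    min_diameter: float = PRECAPILLARY_DIAMETER,
) -> VesselGraph:
    """Propagate artery/vein labels from pial seeds; the rest is capillary.

    ``seeds`` maps segment id -> label ('artery' or 'vein').  Propagation
    is breadth-first over segment adjacency and halts at segments whose
    median diameter falls below ``min_diameter`` (pre-capillaries).  A
    segment reachable from both classes in the same round stays capillary
    and the conflict is logged.  With no seeds everything becomes
    capillary (with a warning).
    """
    for s in graph.segments.values():
        s.label = CAPILLARY
    if not seeds:
        warnings.warn("no artery/vein seeds supplied: all segments labeled "
                      "capillary", stacklevel=2)
        return graph
    for sid, lab in seeds.items():
        if lab not in (ARTERY, VEIN):
            raise ValueError(f"seed label must be artery or vein, got {lab!r}")
        graph.segments[sid].label = lab

    adj = graph.segment_adjacency()
    frontier = deque(seeds)
    while frontier:
        nxt_claims: dict[int, set] = {}
        for _ in range(len(frontier)):
            sid = frontier.popleft()
            lab = graph.segments[sid].label
            for other in adj[sid]:
                o = graph.segments[other]
                if o.label != CAPILLARY or other in seeds:
                    continue
                if o.median_diameter < min_diameter:
                    continue  # pre-capillary: propagation halts here
                nxt_claims.setdefault(other, set()).add(lab)
        for other, labs in nxt_claims.items():
            if len(labs) > 1:
                graph.segments[other].flags.add("label_conflict")
                warnings.warn(f"artery/vein labels conflict at segment {other}; "
                              "left capillary", stacklevel=2)
                continue
            graph.segments[other].label = labs.pop()
            frontier.append(other)
    return graph


def compute_branching_orders(graph: VesselGraph) -> pd.DataFrame:
    """Arterial and venous branching order per segment (hop counts).

    Order 0 on segments of the class itself; elsewhere the minimum number
    of segments traversed to reach any segment of that class; NaN when the
    class is unreachable.
    """
    adj = graph.segment_adjacency()

    def orders_from(label):
        dist = {sid: np.inf for sid in graph.segments}
        q = deque()
        for sid, s in graph.segments.items():
            if s.label == label:
                dist[sid] = 0
                q.append(sid)
        while q:
            sid = q.popleft()
            for other in adj[sid]:
                if dist[other] > dist[sid] + 1:
                    dist[other] = dist[sid] + 1
                    q.append(other)
        return dist

    da = orders_from(ARTERY)
    dv = orders_from(VEIN)
    rows = [{"segment": sid,
             "label": graph.segments[sid].label,
             "arterial_order": da[sid] if np.isfinite(da[sid]) else np.nan,
             "venous_order": dv[sid] if np.isfinite(dv[sid]) else np.nan}
            for sid in sorted(graph.segments)]
    return pd.DataFrame(rows).set_index("segment")


def _shortest_path_to_class(graph, adj, start_sid, label):
    """BFS path (list of segment ids) from start to nearest ``label`` segment."""
    prev = {start_sid: None}
    q = deque([start_sid])
    while q:
        sid = q.popleft()
        if graph.segments[sid].label == label and sid != start_sid:
            path = [sid]
            while prev[sid] is not None:
                sid = prev[sid]
                path.append(sid)
            return path[::-1]
        for other in sorted(adj[sid]):
            if other not in prev:
                prev[other] = sid
                q.append(other)
    return None


def arteriovenous_path_profiles(
    graph: VesselGraph,
    n_grid: int = 21,
    min_capillary_segments: int = 3,
) -> PathProfile:
    """Median velocity profile over all normalized artery-to-vein paths.

    For each capillary segment the shortest paths to the closest artery
    and closest vein are joined through the segment; paths with fewer than
    ``min_capillary_segments`` capillary segments are discarded (they are
    usually falsely allocated direct artery-vein connections).  Each
    path's per-segment v_tot is placed at its normalized cumulative hop
    midpoint and linearly interpolated onto the common grid; the median
    and MAD across paths are taken per grid point.
    """
    adj = graph.segment_adjacency()
    grid = np.linspace(0.0, 1.0, n_grid)
    curves = []
    lengths = []
    seen_paths = set()
    for sid in sorted(graph.segments):
        if graph.segments[sid].label != CAPILLARY:
            continue
        pa = _shortest_path_to_class(graph, adj, sid, ARTERY)
        pv = _shortest_path_to_class(graph, adj, sid, VEIN)
        if pa is None or pv is None:
            continue
        # artery -> ... -> sid -> ... -> vein
        path = pa[::-1] + pv[1:]
        key = tuple(path)
        if key in seen_paths:  # several capillaries can share one path
            continue
        seen_paths.add(key)
        n_caps = sum(1 for p in path if graph.segments[p].label == CAPILLARY)
        if n_caps < min_capillary_segments:
            continue
        v = [graph.segments[p].v_tot for p in path]
        pos = (np.arange(len(path)) + 0.5) / len(path)
        good = np.array([x is not None for x in v])
        if good.sum() < 2:
            continue
        vv = np.array([x if x is not None else np.nan for x in v], float)
        curves.append(np.interp(grid, pos[good], vv[good]))
        lengths.append(len(path))
    if not curves:
        warnings.warn("no qualifying arteriovenous paths", stacklevel=2)
        return PathProfile(grid=grid, median=np.full(n_grid, np.nan),
                           mad=np.full(n_grid, np.nan), n_paths=0,
                           path_lengths=np.array([]))
    curves = np.array(curves)
    med = np.median(curves, axis=0)
    mad = np.median(np.abs(curves - med[None, :]), axis=0)
    return PathProfile(grid=grid, median=med, mad=mad, n_paths=len(curves),
                       path_lengths=np.array(lengths))


def node_degree_vs_axial_fov(
    graph: VesselGraph,
    window_depths,
    surface_z: float | None = None,
) -> pd.DataFrame:
    """Mean node degree as a function of the axial window depth.

    Windows are anchored at the cortical surface (minimum z by default)
    and grow downward.  Segments crossing the lower boundary are cut there
    and the cut points become degree-1 endpoints; nodes below the window
    are dropped.  A window beyond the graph extent returns the full-graph
    value.
    """
    if surface_z is None:
        surface_z = min(float(s.points[:, 0].min())
                        for s in graph.segments.values())
    rows = []
    for depth in np.atleast_1d(window_depths):
        z_max = surface_z + float(depth)
        degree: dict = {}
        n_cut = 0
        for s in graph.segments.values():
            z = s.points[:, 0]
            inside = z <= z_max
            if not inside.any():
                continue
            # count maximal inside runs; each run is one retained edge piece
            runs = np.flatnonzero(np.diff(np.concatenate(([0], inside.view(np.int8),
                                                          [0]))))
            for a, b in zip(runs[::2], runs[1::2]):
                ends = []
                for endpoint_idx, node in ((a, s.start_node), (b - 1, s.end_node)):
                    if endpoint_idx == 0 and node == s.start_node and inside[0]:
                        ends.append(("node", s.start_node))
                    elif endpoint_idx == len(z) - 1 and node == s.end_node \
                            and inside[-1]:
                        ends.append(("node", s.end_node))
                    else:
                        n_cut += 1
                        ends.append(("cut", n_cut))
                for kind, key in ends:
                    degree[(kind, key)] = degree.get((kind, key), 0) + 1
        mean_deg = float(np.mean(list(degree.values()))) if degree else np.nan
        rows.append({"window_depth": float(depth), "mean_degree": mean_deg,
                     "n_nodes": len(degree)})
    return pd.DataFrame(rows)


def network_summaries(graph: VesselGraph) -> dict:
    """Per-segment tables and per-class perfused-volume statistics.

    Returns a dict with a per-segment DataFrame ('segments'), per-class
    perfused volume fractions ('class_volumes'), velocity-vs-relative-
    volume tables per class ('velocity_volume'), and the fraction of
    segments without a velocity ('unset_fraction').
    """
    rows = []
    for sid in sorted(graph.segments):
        s = graph.segments[sid]
        rows.append({
            "segment": sid, "label": s.label, "length": s.length,
            "mean_diameter": s.mean_diameter, "tortuosity": s.tortuosity,
            "v_tot": np.nan if s.v_tot is None else s.v_tot,
            "direction": s.direction, "source": s.velocity_source,
            "volume": np.pi * s.mean_radius**2 * s.length,
        })
    df = pd.DataFrame(rows).set_index("segment")

    vol = df.groupby("label")["volume"].sum()
    class_volumes = (vol / vol.sum()).to_dict()

    velocity_volume = {}
    for lab, sub in df.dropna(subset=["v_tot"]).groupby("label"):
        sub = sub.sort_values("v_tot")
        velocity_volume[lab] = pd.DataFrame({
            "v_tot": sub["v_tot"].values,
            # relative volume is computed only within each vessel type
            "relative_volume": sub["volume"].cumsum().values / sub["volume"].sum(),
        })

    unset = float((df["source"] == UNSET).mean())
    return {
        "segments": df,
        "class_volumes": class_volumes,
        "velocity_volume": velocity_volume,
        "unset_fraction": unset,
    }


def read_node_edge_tables(node_csv, edge_csv) -> VesselGraph:
    """Read an ex vivo graph from node/edge tables.

    The node table needs columns (id, z, x, y) in um; the edge table
    (node1, node2) with optional ``radius``.  Nodes keep whatever degree
    structure the dataset defines (including high-curvature points);
    edges become straight two-point segments.
    """
    from .graph import Node, Segment

    nodes = pd.read_csv(node_csv)
    edges = pd.read_csv(edge_csv)
    g = VesselGraph()
    for _, r in nodes.iterrows():
        g.add_node(Node(int(r["id"]), np.array([r["z"], r["x"], r["y"]], float)))
    for i, (_, r) in enumerate(edges.iterrows()):
        n0, n1 = int(r["node1"]), int(r["node2"])
        radius = float(r["radius"]) if "radius" in edges.columns else 3.0
        pts = np.vstack([g.nodes[n0].position, g.nodes[n1].position])
        g.add_segment(Segment(i, n0, n1, pts, np.full(2, max(radius, 1e-3))))
    return g
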