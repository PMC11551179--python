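"""Vascular graph containers: nodes, segments and the network itself.

A :class:`VesselGraph` represents the vasculature as nodes placed at vessel
bifurcations and endpoints, connected by segments.  Each segment carries an
ordered centreline polyline (um), a per-point radius profile (um), a vessel
class label, a velocity record and a flow direction.  The choice of which
connected node is the "start" of a segment is arbitrary but persisted: flow
direction and the sign of axial velocity are expressed relative to it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional

import numpy as np

# Flow direction of a segment, relative to its (arbitrary) start node.
START_TO_END = "start_to_end"
END_TO_START = "end_to_start"
UNKNOWN = "unknown"
DIRECTIONS = (START_TO_END, END_TO_START, UNKNOWN)

# Vessel class labels.
ARTERY = "artery"
VEIN = "vein"
CAPILLARY = "capillary"
UNLABELED = "unlabeled"
LABELS = (ARTERY, VEIN, CAPILLARY, UNLABELED)

# Provenance of a segment's velocity record.
MEASURED = "measured"
RECOVERED = "recovered"
UNSET = "unset"


@dataclass
class Node:
    """Graph node at a bifurcation or endpoint.

    ``kind`` marks pressure boundary nodes of synthetic networks
    ('inlet'/'outlet'); imaged networks use 'interior' throughout.
    """

    id: int
    position: np.ndarray  # (3,) um, (z, x, y)
    kind: str = "interior"

    def __post_init__(self):
        self.position = np.asarray(self.position, dtype=float)
        if self.position.shape != (3,):
            raise ValueError("node position must be a 3-vector")


@dataclass
class Segment:
    """Vessel segment between two nodes."""

    id: int
    start_node: int
    end_node: int
    points: np.ndarray  # (n, 3) um polyline; endpoints coincide with nodes
    radii: np.ndarray  # (n,) um
    label: str = UNLABELED
    v_tot: Optional[float] = None  # mm/s, >= 0
    v_z: Optional[float] = None  # mm/s, signed along start->end convention
    direction: str = UNKNOWN
    velocity_source: str = UNSET
    flags: set = field(default_factory=set)
    # Per-skeleton-voxel velocity samples, filled by flow_mapping.
    v_tot_profile: Optional[np.ndarray] = None
    v_z_profile: Optional[np.ndarray] = None
    diameter_source: str = "radius_profile"

    def __post_init__(self):
        self.points = np.atleast_2d(np.asarray(self.points, dtype=float))
        self.radii = np.atleast_1d(np.asarray(self.radii, dtype=float))
        if self.points.ndim != 2 or self.points.shape[1] != 3:
            raise ValueError("polyline must be (n, 3)")
        if len(self.radii) != len(self.points):
            raise ValueError("radius profile length must match polyline")
        if np.any(self.radii <= 0):
            raise ValueError("radii must be positive")
        if self.direction not in DIRECTIONS:
            raise ValueError(f"bad direction {self.direction!r}")

    # -- derived geometry ---------------------------------------------------
    @property
    def length(self) -> float:
        """Arc length of the polyline (um)."""
        d = np.diff(self.points, axis=0)
        return float(np.sqrt((d**2).sum(axis=1)).sum())

    @property
    def chord_length(self) -> float:
        return float(np.linalg.norm(self.points[-1] - self.points[0]))

    @property
    def tortuosity(self) -> float:
        """Arc length over endpoint chord length (>= 1; loops guarded)."""
        chord = self.chord_length
        arc = self.length
        if chord <= 1e-9:
            return float("inf")
        return max(arc / chord, 1.0)

    @property
    def mean_radius(self) -> float:
        return float(np.mean(self.radii))

    @property
    def mean_diameter(self) -> float:
        return 2.0 * self.mean_radius

    @property
    def median_diameter(self) -> float:
        return 2.0 * float(np.median(self.radii))

    def tangents(self) -> np.ndarray:
        """Unit tangents at each polyline point (central differences)."""
        if len(self.points) == 1:
            return np.zeros((1, 3))
        t = np.gradient(self.points, axis=0)
        n = np.linalg.norm(t, axis=1, keepdims=True)
        n[n == 0] = 1.0
        return t / n

    @property
    def mean_tangent_z(self) -> float:
        """Mean z-component of the unit tangent along start->end."""
        return float(np.mean(self.tangents()[:, 0]))

    def other_node(self, node_id: int) -> int:
        if node_id == self.start_node:
            return self.end_node
        if node_id == self.end_node:
            return self.start_node
        raise KeyError(f"node {node_id} not on segment {self.id}")

    def signed_speed(self) -> Optional[float]:
        """v_tot signed positive along start->end, None when unset."""
        if self.v_tot is None or self.direction == UNKNOWN:
            return None
        return self.v_tot if self.direction == START_TO_END else -self.v_tot


class VesselGraph:
    """Node/segment representation of a vascular network."""

    def __init__(self, nodes: Iterable[Node] = (), segments: Iterable[Segment] = ()):
        self.nodes: dict[int, Node] = {}
        self.segments: dict[int, Segment] = {}
        for n in nodes:
            self.add_node(n)
        for s in segments:
            self.add_segment(s)

    # -- construction -------------------------------------------------------
    def add_node(self, node: Node) -> Node:
        if node.id in self.nodes:
            raise KeyError(f"duplicate node id {node.id}")
        self.nodes[node.id] = node
        return node

    def add_segment(self, seg: Segment) -> Segment:
        if seg.id in self.segments:
            raise KeyError(f"duplicate segment id {seg.id}")
        for nid in (seg.start_node, seg.end_node):
            if nid not in self.nodes:
                raise KeyError(f"segment {seg.id} references missing node {nid}")
        self.segments[seg.id] = seg
        return seg

    def new_node(self, position, kind: str = "interior") -> Node:
        nid = max(self.nodes, default=-1) + 1
        return self.add_node(Node(nid, np.asarray(position, float), kind))

    def new_segment(self, start: int, end: int, points, radii, **kw) -> Segment:
        sid = max(self.segments, default=-1) + 1
        return self.add_segment(Segment(sid, start, end, points, radii, **kw))

    # -- topology -----------------------------------------------------------
    def node_segments(self) -> dict[int, list[int]]:
        """Map node id -> incident segment ids."""
        adj: dict[int, list[int]] = {nid: [] for nid in self.nodes}
        for sid, s in self.segments.items():
            adj[s.start_node].append(sid)
            adj[s.end_node].append(sid)
        return adj

    def degree(self, node_id: int) -> int:
        return len(self.node_segments()[node_id])

    def segment_adjacency(self) -> dict[int, set[int]]:
        """Map segment id -> segment ids sharing a node (line graph)."""
        adj: dict[int, set[int]] = {sid: set() for sid in self.segments}
        for sids in self.node_segments().values():
            for a in sids:
                for b in sids:
                    if a != b:
                        adj[a].add(b)
        return adj

    def connected_components(self) -> list[set[int]]:
        """Connected components as sets of node ids."""
        adj = self.node_segments()
        seen: set[int] = set()
        comps = []
        for start in self.nodes:
            if start in seen:
                continue
            comp = {start}
            stack = [start]
            seen.add(start)
            while stack:
                nid = stack.pop()
                for sid in adj[nid]:
                    other = self.segments[sid].other_node(nid)
                    if other not in seen:
                        seen.add(other)
                        comp.add(other)
                        stack.append(other)
            comps.append(comp)
        return comps

    def validate(self, atol: float = 1e-6) -> None:
        """Check structural invariants; raise ValueError on violation."""
        for s in self.segments.values():
            p0 = self.nodes[s.start_node].position
            p1 = self.nodes[s.end_node].position
            if not np.allclose(s.points[0], p0, atol=atol):
                raise ValueError(f"segment {s.id}: polyline start != start node")
            if not np.allclose(s.points[-1], p1, atol=atol):
                raise ValueError(f"segment {s.id}: polyline end != end node")
            if s.length <= 0:
                raise ValueError(f"segment {s.id}: non-positive length")

    def copy(self) -> "VesselGraph":
        import copy as _copy

        return _copy.deepcopy(self)

    def __repr__(self):
        return f"VesselGraph(nodes={len(self.nodes)}, segments={len(self.segments)})"
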