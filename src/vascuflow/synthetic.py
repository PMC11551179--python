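"""Synthetic cortical vasculature with physically consistent flows.

The generator builds the hierarchy that cortical imaging resolves: pial
arteries and veins confined to a thin surface band, diving arterioles and
ascending venules connecting downward, and a capillary mesh joining the two
trees so every capillary lies on an artery-to-vein path.  Radii follow
Murray's law across bifurcations; flows are obtained from a steady
Hagen-Poiseuille network solve with fixed inlet/outlet pressures, which
enforces zero net flow at every interior node by construction.

A second network kind emulates the flow phantom: a single straight tube,
by default 180 um inner diameter placed at an 8-degree angle, as used to
validate the velocimetry against a syringe pump.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .graph import (
    ARTERY,
    CAPILLARY,
    END_TO_START,
    MEASURED,
    START_TO_END,
    VEIN,
    Node,
    Segment,
    VesselGraph,
)
from .volumes import SegmentationMask, VoxelGrid

__all__ = [
    "NetworkSpec",
    "FlowState",
    "generate_network",
    "solve_network_flow",
    "rasterize_network",
]


@dataclass(frozen=True)
class NetworkSpec:
    """Parameters of a synthetic vascular network.

    Defaults describe a desk-scale cortical block: a few pial arteries and
    veins whose trees dive/ascend through ~3 bifurcation generations, joined
    by capillary paths of 3-6 segments.  Radii (um): arterial tree roots 9,
    venous roots 10.5 (veins run wider and slower), capillaries 2-3.
    Pressures span 9 kPa -> 1 kPa across the block with blood viscosity
    3.5 mPa s, landing capillary velocities in the 0.5-3 mm/s band where the
    cortical velocity distribution peaks.  Because each arteriole feeds far
    fewer capillaries than in a real cortex, arterial velocities stay within
    a few mm/s of capillary ones at this scale.
    """

    domain_size: tuple[float, float, float] = (320.0, 480.0, 480.0)  # (z,x,y) um
    n_arteries: int = 2
    n_veins: int = 2
    tree_levels: int = 3
    n_capillary_paths: int = 40
    capillary_path_segments: tuple[int, int] = (3, 6)
    artery_root_radius: float = 9.0
    vein_root_radius: float = 10.5
    capillary_radius_range: tuple[float, float] = (2.0, 3.0)
    murray_exponent: float = 3.0
    pial_depth: float = 30.0  # um; pial vessels confined above this depth
    inlet_pressure: float = 9000.0  # Pa
    outlet_pressure: float = 1000.0  # Pa
    viscosity: float = 3.5e-3  # Pa s
    tree_step_fraction: float = 0.28  # lateral step per level, x min(dx,dy)
    tree_spread: float = 0.9  # radians; azimuthal half-angle between siblings
    min_clearance: float = 0.0  # um; >0 keeps non-adjacent vessels separated
    seed: int = 0
    kind: str = "cortical"  # or "tube-phantom"
    tube_diameter: float = 180.0  # um, phantom tubing inner diameter
    tube_angle_deg: float = 8.0  # phantom tube angle from horizontal

    def __post_init__(self):
        if any(s <= 0 for s in self.domain_size):
            raise ValueError("domain_size entries must be positive")
        if self.kind not in ("cortical", "tube-phantom"):
            raise ValueError(f"unknown network kind {self.kind!r}")
        for name in ("artery_root_radius", "vein_root_radius", "murray_exponent",
                     "pial_depth", "viscosity", "tube_diameter"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.kind == "cortical":
            if self.n_arteries < 1 or self.n_veins < 0:
                raise ValueError("need at least one artery")
            if self.n_capillary_paths > 0 and self.n_veins < 1:
                raise ValueError("capillary paths need at least one vein")
            if self.n_capillary_paths < 0:
                raise ValueError("n_capillary_paths must be >= 0")
            lo, hi = self.capillary_radius_range
            if not (0 < lo <= hi):
                raise ValueError("bad capillary radius range")
            lo, hi = self.capillary_path_segments
            if not (1 <= lo <= hi):
                raise ValueError("bad capillary_path_segments")
        if self.inlet_pressure <= self.outlet_pressure:
            raise ValueError("inlet pressure must exceed outlet pressure")


@dataclass
class FlowState:
    """Solved steady flow on a :class:`VesselGraph`.

    ``flow`` is the signed volumetric flow per segment (um^3/s, positive
    along start->end); ``pressure`` the per-node pressure (Pa);
    ``velocity`` the signed mean velocity Q / (pi r_bar^2) in mm/s.
    """

    flow: dict[int, float]
    pressure: dict[int, float]
    velocity: dict[int, float]

    def conservation_residual(self, graph: VesselGraph) -> float:
        """max interior-node |sum Q| normalised by mean |Q|."""
        net: dict[int, float] = {nid: 0.0 for nid in graph.nodes}
        for sid, s in graph.segments.items():
            q = self.flow[sid]
            net[s.start_node] -= q
            net[s.end_node] += q
        interior = [abs(net[nid]) for nid, n in graph.nodes.items()
                    if n.kind == "interior"]
        if not interior:
            return 0.0
        mean_q = np.mean([abs(q) for q in self.flow.values()]) or 1.0
        return float(max(interior) / mean_q)

    def annotate(self, graph: VesselGraph) -> VesselGraph:
        """Write ground-truth speeds and directions onto the graph segments.

        Sets v_tot (mm/s, unsigned), direction from the sign of Q, and v_z
        as the axial component implied by the mean start->end tangent.
        Marks segments as measured so downstream stages treat them as known.
        """
        for sid, s in graph.segments.items():
            v = self.velocity[sid]
            s.v_tot = abs(v)
            s.direction = START_TO_END if v >= 0 else END_TO_START
            s.v_z = v * s.mean_tangent_z
            s.velocity_source = MEASURED
        return graph


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------

def _spread_positions(rng, n, low, high, min_sep=40.0):
    """n jittered, evenly spread points in [low, high], pairwise >= min_sep."""
    if high - low < (n - 1) * min_sep:
        raise ValueError(
            f"cannot place {n} roots with separation {min_sep:.0f} um in "
            f"[{low:.0f}, {high:.0f}] um: spec too dense for the domain"
        )
    centers = np.linspace(low, high, n) if n > 1 else np.array([(low + high) / 2])
    slack = ((high - low) / max(n - 1, 1) - min_sep) / 2 if n > 1 else (high - low) / 2
    return centers + rng.uniform(-slack, slack, size=n)


def _grow_tree(graph, rng, root_pos, root_radius, levels, murray_exponent,
               depth_extent, domain_size, pial_depth, sign,
               step_fraction=0.28, spread0=0.9, clearance=None):
    """Grow one pial tree with a diving trunk and recursive bifurcations.

    Returns (root_node, terminal_nodes, terminal_radius).  ``sign`` only
    tags boundary kind: +1 artery (inlet), -1 vein (outlet).  All node
    positions are clamped inside the domain (small margin).
    """
    dz, dx, dy = domain_size
    lateral_extent = min(dx, dy)
    lo = np.array([0.6 * pial_depth, 0.03 * dx, 0.03 * dy])
    hi = np.array([0.92 * dz, 0.97 * dx, 0.97 * dy])

    kind = "inlet" if sign > 0 else "outlet"
    root = graph.new_node(np.clip(root_pos, lo, hi), kind=kind)
    child_factor = 2.0 ** (-1.0 / murray_exponent)
    center = np.array([0.0, dx / 2, dy / 2])

    def aim_inside(pos, horiz, dz_step, az):
        """Step from pos; re-aim toward the domain centre if it would exit."""
        for trial_az in (az, None):
            if trial_az is None:
                trial_az = np.arctan2(center[2] - pos[2], center[1] - pos[1]) \
                    + rng.normal(0, 0.25)
            cand = pos + np.array([dz_step, horiz * np.cos(trial_az),
                                   horiz * np.sin(trial_az)])
            if np.all(cand >= lo) and np.all(cand <= hi):
                return cand, trial_az
        return np.clip(cand, lo, hi), trial_az

    def branch_angle_ok(node, cand):
        d_new = cand - node.position
        d_new = d_new / max(np.linalg.norm(d_new), 1e-9)
        for sid in graph.node_segments().get(node.id, ()):
            s = graph.segments[sid]
            other = s.points[-2] if s.end_node == node.id else s.points[1]
            d_old = other - node.position
            d_old = d_old / max(np.linalg.norm(d_old), 1e-9)
            if float(d_new @ d_old) > np.cos(np.deg2rad(_MIN_BRANCH_ANGLE_DEG)):
                return False
        return True

    def place(node, horiz, dz_step, az, radius, r_end, n_tries=24):
        """Step from node, avoiding occupied space when clearance is on."""
        for t in range(n_tries):
            shrink = 1.0 if t < n_tries // 2 else (0.75 if t < 3 * n_tries // 4 else 0.55)
            cand, az_used = aim_inside(node.position, horiz * shrink,
                                       dz_step, az)
            if clearance is None or (
                    branch_angle_ok(node, cand)
                    and clearance.ok(node.position, cand,
                                     max(radius, r_end), {node.id})):
                child = graph.new_node(cand)
                seg = _straight_segment(graph, node, child, radius, r_end)
                if clearance is not None:
                    clearance.add(node.position, cand, max(radius, r_end),
                                  {node.id, child.id})
                return child, az_used
            az = az + rng.normal(0, 0.7)  # retry a different azimuth
        raise ValueError(
            "cannot grow vascular tree with the requested clearance: "
            "spec too dense for the domain"
        )

    # Pial segment: short horizontal run within the surface band.
    az = rng.uniform(0, 2 * np.pi)
    pial_len = 0.18 * lateral_extent
    dive_node, az = place(root, pial_len, 0.0, az, root_radius, root_radius)

    # Recursive diving bifurcations.
    terminals: list[Node] = []
    dz_level = depth_extent / (levels + 1)

    def grow(node, radius, level, az0, spread):
        if level >= levels:
            terminals.append(node)
            return
        r_child = radius * child_factor
        horiz = step_fraction * lateral_extent * 0.62**level
        for k, daz in enumerate((-spread, spread)):
            az = az0 + daz + rng.normal(0, 0.12)
            child, az = grow_step = place(node, horiz, dz_level, az, radius, r_child)
            grow(child, r_child, level + 1, az, spread * 0.75)

    grow(dive_node, root_radius * child_factor, 0, az, spread=spread0)
    term_radius = root_radius * child_factor ** (levels + 1)
    return root, terminals, term_radius


def _straight_segment(graph, n0, n1, r0, r1, n_pts=9, label=None):
    t = np.linspace(0.0, 1.0, n_pts)[:, None]
    pts = n0.position[None, :] * (1 - t) + n1.position[None, :] * t
    radii = np.linspace(r0, r1, n_pts)
    seg = graph.new_segment(n0.id, n1.id, pts, radii)
    if label:
        seg.label = label
    return seg


_MIN_BRANCH_ANGLE_DEG = 30.0  # below this, rasterized siblings merge


class _ClearanceIndex:
    """Point-sampled occupancy of placed vessels for clearance tests."""

    def __init__(self, clearance: float, step: float = 3.0):
        self.clearance = clearance
        self.step = step
        self.points: list[np.ndarray] = []
        self.radii: list[float] = []
        self.owners: list[set] = []

    def _sample(self, p0, p1):
        n = max(int(np.linalg.norm(p1 - p0) / self.step) + 1, 2)
        t = np.linspace(0, 1, n)[:, None]
        return p0[None, :] * (1 - t) + p1[None, :] * t

    def ok(self, p0, p1, radius, owners) -> bool:
        if not self.points:
            return True
        cand = self._sample(np.asarray(p0, float), np.asarray(p1, float))
        pts = np.concatenate([p for p in self.points])
        rad = np.concatenate([np.full(len(p), r)
                              for p, r in zip(self.points, self.radii)])
        skip = np.concatenate([np.full(len(p), bool(o & owners))
                               for p, o in zip(self.points, self.owners)])
        d = np.linalg.norm(pts[None, :, :] - cand[:, None, :], axis=2)
        gap = d - rad[None, :] - radius
        gap[:, skip] = np.inf
        return bool((gap >= self.clearance).all())

    def add(self, p0, p1, radius, owners):
        self.points.append(self._sample(np.asarray(p0, float), np.asarray(p1, float)))
        self.radii.append(float(radius))
        self.owners.append(set(owners))


def _try_capillary_path(graph, rng, spec, a, v, k, clearance,
                        cap_depth_hi, dx, dy, max_tries=25):
    """Place one a->v capillary path of k segments, respecting clearance.

    Returns True on success; the graph is only modified on success.
    """
    for _ in range(max_tries):
        positions = []
        ok = True
        for j in range(1, k):
            t = j / k
            base = a.position * (1 - t) + v.position * t
            dip = np.sin(np.pi * t) * rng.uniform(0.3, 1.0)
            z = base[0] + dip * (cap_depth_hi - base[0]) * 0.5
            jitter = rng.normal(0, 18.0, size=2)
            positions.append(np.array([
                min(z, cap_depth_hi),
                np.clip(base[1] + jitter[0], 2.0, dx - 2.0),
                np.clip(base[2] + jitter[1], 2.0, dy - 2.0)]))
        radii = [rng.uniform(*spec.capillary_radius_range) for _ in range(k)]
        if clearance is not None:
            pts = [a.position] + positions + [v.position]
            owners = {a.id, v.id}
            # require a clear branching angle at shared terminals, or the
            # rasterized siblings merge and the skeleton topology changes
            adj = graph.node_segments()
            for node, p_new in ((a, pts[1]), (v, pts[-2])):
                d_new = p_new - node.position
                nn = np.linalg.norm(d_new)
                if nn == 0:
                    ok = False
                    break
                d_new = d_new / nn
                for sid in adj[node.id]:
                    s = graph.segments[sid]
                    other = s.points[-2] if s.end_node == node.id else s.points[1]
                    d_old = other - node.position
                    d_old = d_old / max(np.linalg.norm(d_old), 1e-9)
                    if float(d_new @ d_old) > np.cos(np.deg2rad(_MIN_BRANCH_ANGLE_DEG)):
                        ok = False
                        break
                if not ok:
                    break
            for j in range(k):
                if not ok:
                    break
                if not clearance.ok(pts[j], pts[j + 1], radii[j], owners):
                    ok = False
        if not ok:
            if k == 1:
                return False  # straight connection is fully determined
            continue
        prev = a
        new_nodes = []
        for pos in positions:
            node = graph.new_node(pos)
            new_nodes.append(node)
        chain = [a] + new_nodes + [v]
        for j in range(k):
            seg = _straight_segment(graph, chain[j], chain[j + 1],
                                    radii[j], radii[j], label=CAPILLARY)
            if clearance is not None:
                clearance.add(seg.points[0], seg.points[-1], radii[j],
                              {seg.start_node, seg.end_node})
        return True
    return False


def generate_network(spec: NetworkSpec) -> VesselGraph:
    """Generate a ground-truth vascular graph from a spec.

    Deterministic given ``spec.seed``.  Raises ValueError when the requested
    density cannot be placed in the domain (never silently truncates).
    """
    rng = np.random.default_rng(spec.seed)
    if spec.kind == "tube-phantom":
        return _generate_tube(spec)

    dz, dx, dy = spec.domain_size
    graph = VesselGraph()
    lateral = min(dx, dy)
    margin = 0.12 * lateral
    n_roots = spec.n_arteries + spec.n_veins
    # Roots spread along x, arteries near one y edge and veins near the other.
    xs = _spread_positions(rng, n_roots, margin, dx - margin)
    rng.shuffle(xs)

    a_terms, v_terms = [], []
    clearance = _ClearanceIndex(spec.min_clearance) if spec.min_clearance > 0 else None
    depth_extent = dz - spec.pial_depth - 0.25 * dz  # leave room for cap bed
    for i in range(spec.n_arteries):
        pos = np.array([0.6 * spec.pial_depth, xs[i], margin + rng.uniform(0, 0.2 * dy)])
        _, terms, r_t = _grow_tree(graph, rng, pos, spec.artery_root_radius,
                                   spec.tree_levels, spec.murray_exponent,
                                   depth_extent, spec.domain_size,
                                   spec.pial_depth, sign=+1,
                                   step_fraction=spec.tree_step_fraction,
                                   spread0=spec.tree_spread, clearance=clearance)
        a_terms.extend(terms)
    for i in range(spec.n_veins):
        pos = np.array([0.6 * spec.pial_depth, xs[spec.n_arteries + i],
                        dy - margin - rng.uniform(0, 0.2 * dy)])
        _, terms, r_t = _grow_tree(graph, rng, pos, spec.vein_root_radius,
                                   spec.tree_levels, spec.murray_exponent,
                                   depth_extent, spec.domain_size,
                                   spec.pial_depth, sign=-1,
                                   step_fraction=spec.tree_step_fraction,
                                   spread0=spec.tree_spread, clearance=clearance)
        v_terms.extend(terms)

    # Ground-truth classes follow the pre-capillary convention used by the
    # analysis stage: tree segments of median diameter >= 12 um are
    # arteries/veins, narrower pre-capillary branches count as capillaries.
    comps = graph.connected_components()
    a_roots = {nid for nid, n in graph.nodes.items() if n.kind == "inlet"}
    for comp in comps:
        lab = ARTERY if comp & a_roots else VEIN
        for sid, s in graph.segments.items():
            if s.start_node in comp:
                s.label = lab if s.median_diameter >= 12.0 else CAPILLARY

    # Capillary mesh: paths of 3-6 segments from arterial to venous terminals.
    if spec.n_capillary_paths and (not a_terms or not v_terms):
        raise ValueError("trees produced no terminals; increase domain or levels")
    cap_depth_lo = spec.pial_depth + depth_extent * 0.6
    cap_depth_hi = dz * 0.95
    lo_n, hi_n = spec.capillary_path_segments
    for p in range(spec.n_capillary_paths):
        # round-robin so every terminal anchors at least one path
        a = a_terms[p % len(a_terms)]
        if clearance is not None:
            # nearest venous terminals first: short connections are far
            # less likely to collide with the rest of the network
            d = [np.linalg.norm(v.position - a.position) for v in v_terms]
            v_order = list(np.argsort(d))
        else:
            v_order = list(np.roll(np.arange(len(v_terms)), -(p // len(a_terms) + p)))
        placed = False
        for vi in v_order:
            v = v_terms[vi]
            k = int(rng.integers(lo_n, hi_n + 1))  # segments in the path
            if _try_capillary_path(graph, rng, spec, a, v, k, clearance,
                                   cap_depth_hi, dx, dy):
                placed = True
                break
        if not placed:
            raise ValueError(
                f"cannot place capillary path {p} with clearance "
                f"{spec.min_clearance:.1f} um: spec too dense for the domain"
            )

    if spec.n_capillary_paths:
        # every component must be perfusable: at least one inlet and one
        # outlet (capillary pairing may split the network into independent
        # artery-vein units, which is fine; a dangling unit is not)
        for comp in graph.connected_components():
            kinds = {graph.nodes[nid].kind for nid in comp}
            if not {"inlet", "outlet"} <= kinds:
                raise ValueError(
                    "generated graph has a component without both an inlet "
                    "and an outlet"
                )
    graph.validate()
    return graph


def _generate_tube(spec: NetworkSpec) -> VesselGraph:
    """Single straight cylinder at ``tube_angle_deg`` from horizontal."""
    dz, dx, dy = spec.domain_size
    ang = np.deg2rad(spec.tube_angle_deg)
    length = 0.8 * dx
    c = np.array([dz / 2, dx / 2, dy / 2])
    d = np.array([np.sin(ang), np.cos(ang), 0.0])  # dips in z along x
    p0, p1 = c - d * length / 2, c + d * length / 2
    if not (0 < p0[0] < dz and 0 < p1[0] < dz):
        raise ValueError("tube does not fit the domain at this angle")
    graph = VesselGraph()
    n0 = graph.new_node(p0, kind="inlet")
    n1 = graph.new_node(p1, kind="outlet")
    r = spec.tube_diameter / 2
    _straight_segment(graph, n0, n1, r, r, n_pts=33)
    return graph


# ---------------------------------------------------------------------------
# flow solve
# ---------------------------------------------------------------------------

def segment_conductance(seg: Segment, viscosity: float) -> float:
    """Hagen-Poiseuille conductance pi r^4 / (8 eta L) in um^3 / (Pa s)."""
    r = seg.mean_radius
    return np.pi * r**4 / (8.0 * viscosity * seg.length)


def solve_network_flow(graph: VesselGraph, spec: NetworkSpec) -> FlowState:
    """Solve the Poiseuille linear system with fixed boundary pressures.

    Inlet nodes (pial artery roots) are held at ``spec.inlet_pressure`` and
    outlets at ``spec.outlet_pressure``; interior pressures satisfy zero net
    flow at every interior node.
    """
    # every connected component must touch a boundary node
    for comp in graph.connected_components():
        if not any(graph.nodes[nid].kind in ("inlet", "outlet") for nid in comp):
            raise ValueError(
                f"singular flow system: component with nodes {sorted(comp)[:8]}... "
                "has no inlet or outlet"
            )

    node_ids = sorted(graph.nodes)
    idx = {nid: i for i, nid in enumerate(node_ids)}
    fixed = {}
    for nid, n in graph.nodes.items():
        if n.kind == "inlet":
            fixed[nid] = spec.inlet_pressure
        elif n.kind == "outlet":
            fixed[nid] = spec.outlet_pressure
    free = [nid for nid in node_ids if nid not in fixed]
    if not free:
        pressures = dict(fixed)
    else:
        fidx = {nid: i for i, nid in enumerate(free)}
        rows, cols, vals = [], [], []
        b = np.zeros(len(free))
        for sid, s in graph.segments.items():
            g = segment_conductance(s, spec.viscosity)
            u, v = s.start_node, s.end_node
            for a, bb in ((u, v), (v, u)):
                if a in fidx:
                    rows.append(fidx[a]); cols.append(fidx[a]); vals.append(g)
                    if bb in fidx:
                        rows.append(fidx[a]); cols.append(fidx[bb]); vals.append(-g)
                    else:
                        b[fidx[a]] += g * fixed[bb]
        A = sp.csr_matrix((vals, (rows, cols)), shape=(len(free), len(free)))
        p_free = spla.spsolve(A.tocsc(), b)
        pressures = dict(fixed)
        pressures.update({nid: float(p_free[fidx[nid]]) for nid in free})

    flow, velocity = {}, {}
    for sid, s in graph.segments.items():
        g = segment_conductance(s, spec.viscosity)
        q = g * (pressures[s.start_node] - pressures[s.end_node])  # um^3/s
        flow[sid] = float(q)
        v_um_s = q / (np.pi * s.mean_radius**2)
        velocity[sid] = float(v_um_s * 1e-3)  # mm/s
    return FlowState(flow=flow, pressure=pressures, velocity=velocity)


# ---------------------------------------------------------------------------
# rasterization
# ---------------------------------------------------------------------------

def rasterize_network(
    graph: VesselGraph,
    flow: FlowState | None,
    grid: VoxelGrid,
    profile: str = "plug",
):
    """Rasterize a vascular graph into a voxel mask and velocity field.

    A voxel is foreground iff it lies within the local radius of some
    segment polyline (capsule test per polyline edge).  The velocity at a
    foreground voxel is the segment's unit tangent times the local speed:
    the plug profile uses the mean speed v_bar everywhere; the parabolic
    profile uses 2 v_bar (1 - (rho/r)^2), the laminar profile expected in
    larger vessels.  Background voxels have zero velocity.

    Returns ``(SegmentationMask, velocity)`` with velocity shaped
    (3, nz, nx, ny) in mm/s, component order (v_z, v_x, v_y).

    Speeds come from ``flow`` when given, else from the segments' own
    velocity records (0 when unset).
    """
    if profile not in ("plug", "parabolic"):
        raise ValueError("profile must be 'plug' or 'parabolic'")
    h = grid.voxel_size
    min_r = min(s.radii.min() for s in graph.segments.values())
    if min_r < h / 2:
        warnings.warn(
            f"grid too coarse: smallest radius {min_r:.2f} um < half voxel "
            f"({h/2:.2f} um); thin vessels rasterized at >=1 voxel width",
            stacklevel=2,
        )
    nz, nx, ny = grid.shape
    mask = np.zeros(grid.shape, dtype=bool)
    vel = np.zeros((3,) + tuple(grid.shape), dtype=np.float32)
    # closest-centerline bookkeeping: overlapping capsules (edge end-caps,
    # junctions) must not overwrite a voxel owned by a closer centerline
    rho_best = np.full(grid.shape, np.inf, dtype=np.float32)

    origin = np.asarray(grid.origin, float)
    for sid, s in graph.segments.items():
        if flow is not None:
            v_bar = flow.velocity[sid]
        else:
            v_bar = s.signed_speed() or 0.0
        pts = (s.points - origin) / h  # voxel units
        radii_vox = s.radii / h
        for i in range(len(pts) - 1):
            p0, p1 = pts[i], pts[i + 1]
            r0, r1 = radii_vox[i], radii_vox[i + 1]
            rmax = max(r0, r1, 0.5)
            d = p1 - p0
            L2 = float(d @ d)
            tang = d / np.sqrt(L2) if L2 > 0 else np.zeros(3)
            lo = np.maximum(np.floor(np.minimum(p0, p1) - rmax - 1).astype(int), 0)
            hi = np.minimum(np.ceil(np.maximum(p0, p1) + rmax + 1).astype(int) + 1,
                            [nz, nx, ny])
            if np.any(lo >= hi):
                continue
            zz, xx, yy = np.meshgrid(*[np.arange(lo[k], hi[k]) for k in range(3)],
                                     indexing="ij")
            c = np.stack([zz, xx, yy], axis=-1).astype(float)
            rel = c - p0
            t = np.clip((rel @ d) / L2, 0.0, 1.0) if L2 > 0 else np.zeros(c.shape[:-1])
            proj = p0 + t[..., None] * d
            rho = np.linalg.norm(c - proj, axis=-1)
            r_loc = r0 + t * (r1 - r0)
            inside = rho <= np.maximum(r_loc, 0.5)  # >=1-voxel guarantee
            if not inside.any():
                continue
            if profile == "plug":
                speed = np.full(inside.shape, v_bar)
            else:
                frac = np.clip(rho / np.maximum(r_loc, 1e-6), 0.0, 1.0)
                speed = 2.0 * v_bar * (1.0 - frac**2)
            sl = (slice(lo[0], hi[0]), slice(lo[1], hi[1]), slice(lo[2], hi[2]))
            mask[sl] |= inside
            closer = inside & (rho < rho_best[sl])
            rb = rho_best[sl]
            rb[closer] = rho[closer]
            rho_best[sl] = rb
            for k in range(3):
                comp = vel[k][sl]
                comp[closer] = (speed * tang[k])[closer]
                vel[k][sl] = comp
    return SegmentationMask(mask, grid, provenance="internal-threshold"), vel
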