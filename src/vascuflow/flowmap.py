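"""Mapping voxel velocities onto the vessel graph and completing them.

Four stages: (1) an affine registration hook aligning the Doppler-derived
D_max volume to the angiogram (identity for co-simulated data); (2)
sphere-based aggregation of valid voxel velocities onto skeleton points
(mean of the top 30% within a sphere of the local diameter, smoothed along
the segment, median per segment); (3) flow-direction determination by
comparing the sign of the axial Doppler velocity with the axial component
of the local skeleton tangent (votes weighted by |v_z|·|tangent_z|); and
(4) recovery of missing velocities by enforcing zero net flow at nodes
whose other segments are fully described, iterated to a fixpoint.
"""

from __future__ import annotations

import warnings

import numpy as np

from .doppler import VelocityField
from .graph import (
    END_TO_START,
    MEASURED,
    RECOVERED,
    START_TO_END,
    UNKNOWN,
    UNSET,
    VesselGraph,
)
from .volumes import AngiogramVolume, VoxelGrid

__all__ = [
    "register_volumes",
    "apply_affine",
    "map_velocities_to_graph",
    "assign_flow_directions",
    "recover_missing_velocities",
]


# ---------------------------------------------------------------------------
# registration
# ---------------------------------------------------------------------------

def register_volumes(d_max: np.ndarray, angiogram, assume_identity: bool = False):
    """Affine transform aligning the D_max volume to the angiogram.

    Uses the Doppler spectral-maximum volume (which resembles an angiogram
    far more than the quantitative frequency maps do) as the moving image.
    Returns a 4x4 voxel-space affine matrix mapping angiogram indices to
    D_max indices.  ``assume_identity`` short-circuits for co-simulated
    volumes on a shared grid.  On optimizer failure the identity is
    returned with a warning.
    """
    angio = np.asarray(getattr(angiogram, "data", angiogram), dtype=np.float64)
    moving = np.nan_to_num(np.asarray(d_max, dtype=np.float64))
    if assume_identity:
        return np.eye(4)
    try:
        import SimpleITK as sitk

        fixed_img = sitk.GetImageFromArray(angio)
        moving_img = sitk.GetImageFromArray(moving)
        reg = sitk.ImageRegistrationMethod()
        reg.SetMetricAsCorrelation()
        reg.SetOptimizerAsRegularStepGradientDescent(
            learningRate=1.0, minStep=1e-4, numberOfIterations=200)
        reg.SetOptimizerScalesFromPhysicalShift()
        reg.SetInitialTransform(
            sitk.CenteredTransformInitializer(
                fixed_img, moving_img, sitk.AffineTransform(3),
                sitk.CenteredTransformInitializerFilter.GEOMETRY),
            inPlace=False)
        reg.SetInterpolator(sitk.sitkLinear)
        tf = reg.Execute(fixed_img, moving_img)
        if hasattr(tf, "Downcast"):
            tf = tf.Downcast()
        if tf.GetName() == "CompositeTransform":
            tf = tf.GetNthTransform(tf.GetNumberOfTransforms() - 1)
            if hasattr(tf, "Downcast"):
                tf = tf.Downcast()
        tf = sitk.AffineTransform(tf)
        mat = np.eye(4)
        # sitk orders coordinates (x, y, z) = our (y, x, z) reversed
        a = np.array(tf.GetMatrix()).reshape(3, 3)[::-1, ::-1]
        t = np.array(tf.GetTranslation())[::-1]
        c = np.array(tf.GetCenter())[::-1]
        mat[:3, :3] = a
        mat[:3, 3] = t + c - a @ c
        return mat
    except Exception as exc:  # pragma: no cover - depends on optimizer
        warnings.warn(f"affine registration failed ({exc}); using identity",
                      stacklevel=2)
        return np.eye(4)


def apply_affine(mat: np.ndarray, points: np.ndarray) -> np.ndarray:
    """Apply a 4x4 affine to (n, 3) points (voxel coordinates)."""
    pts = np.asarray(points, float)
    return pts @ mat[:3, :3].T + mat[:3, 3]


# ---------------------------------------------------------------------------
# sphere aggregation
# ---------------------------------------------------------------------------

def _top_fraction_mean(values: np.ndarray, fraction: float) -> float:
    """Mean of the highest ``fraction`` of values (at least one)."""
    v = np.sort(np.asarray(values, float))
    k = max(int(np.ceil(fraction * len(v))), 1)
    return float(v[-k:].mean())


def _moving_average(x: np.ndarray, window: int) -> np.ndarray:
    out = np.full(len(x), np.nan)
    hw = window // 2
    for i in range(len(x)):
        lo, hi = max(0, i - hw), min(len(x), i + hw + 1)
        vals = x[lo:hi]
        good = np.isfinite(vals)
        if good.any():
            out[i] = vals[good].mean()
    return out


def map_velocities_to_graph(
    graph: VesselGraph,
    field: VelocityField,
    grid: VoxelGrid,
    top_fraction: float = 0.3,
    smoothing_window: int = 5,
    affine: np.ndarray | None = None,
) -> VesselGraph:
    """Aggregate voxel velocities onto segment skeleton points.

    At each polyline point, valid v_tot and v_z voxels within a sphere of
    the locally fitted diameter contribute; the point value is the mean of
    the top ``top_fraction`` of them (bright-voxel average, robust to
    partial-volume dropout).  Profiles are smoothed with a moving average;
    the segment total velocity is the median over its skeleton points.
    Segments with no valid sample anywhere are left unset.
    """
    h = grid.voxel_size
    shape = field.v_tot.shape
    valid = field.valid & np.isfinite(field.v_tot)
    for seg in graph.segments.values():
        pts_vox = grid.um_to_index(seg.points)
        if affine is not None:
            pts_vox = apply_affine(affine, pts_vox)
        n = len(pts_vox)
        vtot_prof = np.full(n, np.nan)
        vz_prof = np.full(n, np.nan)
        for i in range(n):
            r_vox = max(seg.radii[i] / h, 1.0)
            c = pts_vox[i]
            lo = np.maximum(np.floor(c - r_vox).astype(int), 0)
            hi = np.minimum(np.ceil(c + r_vox).astype(int) + 1, shape)
            if np.any(lo >= hi):
                continue
            sl = tuple(slice(lo[k], hi[k]) for k in range(3))
            sub_valid = valid[sl]
            if not sub_valid.any():
                continue
            zz, xx, yy = np.meshgrid(*[np.arange(lo[k], hi[k]) for k in range(3)],
                                     indexing="ij")
            dist2 = (zz - c[0]) ** 2 + (xx - c[1]) ** 2 + (yy - c[2]) ** 2
            inside = sub_valid & (dist2 <= r_vox**2)
            if not inside.any():
                continue
            vt = field.v_tot[sl][inside]
            vz = field.v_z[sl][inside]
            vtot_prof[i] = _top_fraction_mean(vt, top_fraction)
            # keep the axial sign: take the v_z whose |v_z| is largest
            # among the top-|v_z| fraction
            order = np.argsort(np.abs(vz))
            k = max(int(np.ceil(top_fraction * len(vz))), 1)
            vz_prof[i] = float(vz[order][-k:].mean())
        seg.v_tot_profile = _moving_average(vtot_prof, smoothing_window)
        seg.v_z_profile = _moving_average(vz_prof, smoothing_window)
        good = np.isfinite(seg.v_tot_profile)
        if good.any():
            seg.v_tot = float(np.median(seg.v_tot_profile[good]))
            goodz = np.isfinite(seg.v_z_profile)
            seg.v_z = float(np.median(seg.v_z_profile[goodz])) if goodz.any() else None
            seg.velocity_source = MEASURED
        else:
            seg.v_tot = None
            seg.v_z = None
            seg.velocity_source = UNSET
    return graph


# ---------------------------------------------------------------------------
# flow direction
# ---------------------------------------------------------------------------

def assign_flow_directions(
    graph: VesselGraph,
    tangent_z_floor: float = 0.1,
) -> VesselGraph:
    """Set each measured segment's direction from axial Doppler votes.

    At every skeleton point with a valid axial velocity sample and a
    tangent whose |z component| exceeds the floor, the agreement between
    sign(v_z) and sign(tangent_z) casts a vote for start->end (agreement)
    or end->start, weighted by |v_z|*|tangent_z|.  The majority decides;
    segments with no votes stay unknown.  Points near the segment ends are
    excluded: their sampling spheres overlap the junctions, where a
    neighbouring vessel's (possibly opposite) axial flow contaminates the
    vote.
    """
    for seg in graph.segments.values():
        if seg.v_z_profile is None:
            continue
        tz = seg.tangents()[:, 0]
        n_pts = len(tz)
        trim = max(int(round(0.15 * n_pts)), 1) if n_pts >= 5 else 0
        score = 0.0
        n_votes = 0
        for i, (vz, t) in enumerate(zip(seg.v_z_profile, tz)):
            if trim and (i < trim or i >= n_pts - trim):
                continue
            if not np.isfinite(vz) or abs(t) < tangent_z_floor or vz == 0:
                continue
            w = abs(vz) * abs(t)
            score += w if np.sign(vz) == np.sign(t) else -w
            n_votes += 1
        if n_votes == 0:
            seg.direction = UNKNOWN
        else:
            seg.direction = START_TO_END if score >= 0 else END_TO_START
    return graph


# ---------------------------------------------------------------------------
# conservation-based recovery
# ---------------------------------------------------------------------------

def _known(seg) -> bool:
    return seg.v_tot is not None and seg.direction != UNKNOWN


def _node_flow_estimate(graph: VesselGraph, node_id: int, unknown_sid: int):
    """Flow estimate for ``unknown_sid`` from conservation at ``node_id``.

    Returns signed flow into the unknown segment (um^3/s-equivalent units
    of mm/s * um^2; positive = flowing away from the node into the
    segment), or None when the node does not determine it (an end node, or
    another incident segment is also unknown).
    """
    adj = graph.node_segments()
    sids = adj[node_id]
    if len(sids) < 2:
        return None  # end node
    total = 0.0
    for sid in sids:
        if sid == unknown_sid:
            continue
        s = graph.segments[sid]
        if not _known(s):
            return None
        area = np.pi * s.mean_radius**2
        q = s.v_tot * area
        # positive q_in means flow INTO the node
        flows_in = (s.direction == START_TO_END and s.end_node == node_id) or \
                   (s.direction == END_TO_START and s.start_node == node_id)
        total += q if flows_in else -q
    # conservation: the unknown segment must carry ``total`` away from node
    return total


def recover_missing_velocities(graph: VesselGraph, max_iter: int = 100) -> VesselGraph:
    """Fill unset segment velocities by zero-net-flow at their nodes.

    A segment with no Doppler-derived velocity gets, at each of its nodes
    where all other incident segments have velocity and direction, the
    flow that balances the node.  With both nodes determinable the two
    speed estimates are averaged; with conflicting implied directions the
    larger-|flow| node wins and the segment is flagged.  The sweep repeats
    until no segment changes.  Measured segments are never modified;
    rerunning on a completed graph is a no-op.
    """
    for _ in range(max_iter):
        unknowns = [sid for sid, s in graph.segments.items() if not _known(s)]
        if not unknowns:
            break
        # deterministic processing order: most known neighbours first
        adj = graph.segment_adjacency()
        order = sorted(
            unknowns,
            key=lambda sid: (-sum(_known(graph.segments[o]) for o in adj[sid]), sid),
        )
        changed = False
        for sid in order:
            s = graph.segments[sid]
            if _known(s):
                continue
            est = []
            for node_id, sign in ((s.start_node, +1.0), (s.end_node, -1.0)):
                q = _node_flow_estimate(graph, node_id, sid)
                if q is not None:
                    # q > 0: flow leaves the node into the segment; at the
                    # start node that means start->end (positive signed flow)
                    est.append(sign * q)
            if not est:
                continue
            area = np.pi * s.mean_radius**2
            if len(est) == 2 and np.sign(est[0]) != np.sign(est[1]) \
                    and est[0] != 0 and est[1] != 0:
                q_signed = est[0] if abs(est[0]) >= abs(est[1]) else est[1]
                s.flags.add("direction_conflict")
            else:
                q_signed = float(np.mean(est))
            s.v_tot = abs(q_signed) / area
            s.direction = START_TO_END if q_signed >= 0 else END_TO_START
            s.velocity_source = RECOVERED
            changed = True
        if not changed:
            break
    return graph
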