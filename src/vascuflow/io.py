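"""Serialization: graphs (JSON, GraphML), volumes (TIFF, NIfTI, HDF5).

Graph JSON schema (version 1):

    {
      "format": "vascuflow-graph", "version": 1,
      "nodes": [{"id", "position" [z,x,y] um, "kind"}, ...],
      "segments": [{"id", "start", "end",
                    "points" [[z,x,y], ...] um, "radii" [um, ...],
                    "label", "v_tot" mm/s | null, "v_z" mm/s | null,
                    "direction", "source", "flags"}, ...]
    }

Volumes carry voxel-size metadata: TIFF via ImageJ-style resolution tags,
NIfTI via the affine, HDF5 via attributes.
"""

from __future__ import annotations

import json

import h5py
import networkx as nx
import nibabel as nib
import numpy as np
import tifffile

from .graph import Node, Segment, VesselGraph
from .octsim import AcquisitionProtocol, MModeVolume, SystemCalibration
from .volumes import VoxelGrid

__all__ = [
    "graph_to_dict", "graph_from_dict", "save_graph_json", "load_graph_json",
    "save_graph_graphml", "load_graph_graphml",
    "save_volume_tiff", "load_volume_tiff",
    "save_volume_nifti", "load_volume_nifti",
    "save_mmode_h5", "load_mmode_h5",
]


# -- graphs -----------------------------------------------------------------

def graph_to_dict(graph: VesselGraph) -> dict:
    return {
        "format": "vascuflow-graph",
        "version": 1,
        "nodes": [
            {"id": n.id, "position": n.position.tolist(), "kind": n.kind}
            for n in graph.nodes.values()
        ],
        "segments": [
            {
                "id": s.id, "start": s.start_node, "end": s.end_node,
                "points": s.points.tolist(), "radii": s.radii.tolist(),
                "label": s.label, "v_tot": s.v_tot, "v_z": s.v_z,
                "direction": s.direction, "source": s.velocity_source,
                "flags": sorted(s.flags),
            }
            for s in graph.segments.values()
        ],
    }


def graph_from_dict(d: dict) -> VesselGraph:
    if d.get("format") != "vascuflow-graph":
        raise ValueError("not a vascuflow graph document")
    g = VesselGraph()
    for nd in d["nodes"]:
        g.add_node(Node(int(nd["id"]), np.asarray(nd["position"], float),
                        nd.get("kind", "interior")))
    for sd in d["segments"]:
        seg = Segment(
            int(sd["id"]), int(sd["start"]), int(sd["end"]),
            np.asarray(sd["points"], float), np.asarray(sd["radii"], float),
            label=sd.get("label", "unlabeled"),
            v_tot=sd.get("v_tot"), v_z=sd.get("v_z"),
            direction=sd.get("direction", "unknown"),
            velocity_source=sd.get("source", "unset"),
        )
        seg.flags = set(sd.get("flags", []))
        g.add_segment(seg)
    return g


def save_graph_json(graph: VesselGraph, path) -> None:
    with open(path, "w") as f:
        json.dump(graph_to_dict(graph), f)


def load_graph_json(path) -> VesselGraph:
    with open(path) as f:
        return graph_from_dict(json.load(f))


def save_graph_graphml(graph: VesselGraph, path) -> None:
    """GraphML export (multigraph; array attributes JSON-encoded)."""
    G = nx.MultiGraph()
    for n in graph.nodes.values():
        G.add_node(n.id, z=float(n.position[0]), x=float(n.position[1]),
                   y=float(n.position[2]), kind=n.kind)
    for s in graph.segments.values():
        G.add_edge(
            s.start_node, s.end_node, key=s.id,
            segment_id=s.id, points=json.dumps(s.points.tolist()),
            radii=json.dumps(s.radii.tolist()), label=s.label,
            v_tot=-1.0 if s.v_tot is None else float(s.v_tot),
            v_z=np.nan if s.v_z is None else float(s.v_z),
            direction=s.direction, source=s.velocity_source,
        )
    nx.write_graphml(G, path)


def load_graph_graphml(path) -> VesselGraph:
    G = nx.read_graphml(path, force_multigraph=True)
    g = VesselGraph()
    for nid, data in G.nodes(data=True):
        g.add_node(Node(int(nid), np.array([data["z"], data["x"], data["y"]]),
                        data.get("kind", "interior")))
    for u, v, _, data in G.edges(keys=True, data=True):
        v_tot = float(data.get("v_tot", -1.0))
        v_z = float(data.get("v_z", np.nan))
        g.add_segment(Segment(
            int(data["segment_id"]), int(u), int(v),
            np.asarray(json.loads(data["points"]), float),
            np.asarray(json.loads(data["radii"]), float),
            label=data.get("label", "unlabeled"),
            v_tot=None if v_tot < 0 else v_tot,
            v_z=None if np.isnan(v_z) else v_z,
            direction=data.get("direction", "unknown"),
            velocity_source=data.get("source", "unset"),
        ))
    return g


# -- volumes ----------------------------------------------------------------

def save_volume_tiff(data: np.ndarray, grid: VoxelGrid, path) -> None:
    """Multi-page TIFF with ImageJ voxel-size metadata (um)."""
    arr = np.asarray(data)
    if arr.dtype == bool:
        arr = arr.astype(np.uint8)
    h = grid.voxel_size
    tifffile.imwrite(
        path, arr, imagej=True,
        resolution=(1.0 / h, 1.0 / h),
        metadata={"spacing": h, "unit": "um", "axes": "ZYX"[: arr.ndim]},
    )


def load_volume_tiff(path):
    """Returns (array, voxel_size or None)."""
    with tifffile.TiffFile(path) as tf:
        arr = tf.asarray()
        h = None
        if tf.imagej_metadata and "spacing" in tf.imagej_metadata:
            h = float(tf.imagej_metadata["spacing"])
    return arr, h


def save_volume_nifti(data: np.ndarray, grid: VoxelGrid, path) -> None:
    arr = np.asarray(data)
    if arr.dtype == bool:
        arr = arr.astype(np.uint8)
    affine = np.diag([grid.voxel_size] * 3 + [1.0])
    nib.save(nib.Nifti1Image(arr, affine), path)


def load_volume_nifti(path):
    img = nib.load(path)
    h = float(img.affine[0, 0])
    return np.asarray(img.dataobj), h


def save_mmode_h5(mmode: MModeVolume, path) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=mmode.data, compression="gzip")
        if mmode.aliased is not None:
            f.create_dataset("aliased", data=mmode.aliased)
        p, c = mmode.protocol, mmode.calibration
        f.attrs.update({
            "ascan_rate": p.ascan_rate, "n_ascans": p.n_ascans,
            "bscan_repeats": p.bscan_repeats, "pixel_size": p.pixel_size,
            "n_volumes": p.n_volumes,
            "wavelength": c.wavelength, "refractive_index": c.refractive_index,
            "kappa": c.kappa, "highpass_cutoff": c.highpass_cutoff,
            "n_pad": c.n_pad,
        })


def load_mmode_h5(path) -> MModeVolume:
    with h5py.File(path, "r") as f:
        data = f["data"][()]
        aliased = f["aliased"][()] if "aliased" in f else None
        a = f.attrs
        protocol = AcquisitionProtocol(
            ascan_rate=float(a["ascan_rate"]), n_ascans=int(a["n_ascans"]),
            bscan_repeats=int(a["bscan_repeats"]),
            pixel_size=float(a["pixel_size"]), n_volumes=int(a["n_volumes"]))
        calibration = SystemCalibration(
            wavelength=float(a["wavelength"]),
            refractive_index=float(a["refractive_index"]),
            kappa=float(a["kappa"]), highpass_cutoff=float(a["highpass_cutoff"]),
            n_pad=int(a["n_pad"]))
    return MModeVolume(data=data, protocol=protocol, calibration=calibration,
                       aliased=aliased)
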