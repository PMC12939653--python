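"""Persistence of package artifacts in standard formats.

Images -> NIfTI (voxel size in the affine) or HDF5; k-space -> HDF5
(complex64, centered-DC convention recorded as an attribute); masks -> HDF5
boolean arrays with acceleration/center/seed attributes; graphs -> GraphML
with numeric edge attributes (polylines serialized as JSON strings);
persistence diagrams -> CSV (dim, birth, death, essential); sensor streams ->
CSV plus a JSON sidecar.
"""

from __future__ import annotations

import json

import h5py
import nibabel as nib
import numpy as np
import networkx as nx
import pandas as pd

from .core import ImageVolume, KSpaceMeasurement, SamplingMask
from .graphs import VascularGraph
from .sensors import SensorStream
from .topology import ESSENTIAL_DEATH, PersistenceDiagram

__all__ = [
    "save_image_nifti", "load_image_nifti",
    "save_kspace_h5", "load_kspace_h5",
    "save_mask_h5", "load_mask_h5",
    "save_graph_graphml", "load_graph_graphml",
    "save_diagrams_csv", "load_diagrams_csv",
    "save_stream_csv", "load_stream_csv",
]


def save_image_nifti(img: ImageVolume, path):
    vals = img.values
    if np.iscomplexobj(vals):
        vals = np.abs(vals)
    arr = vals if vals.ndim == 3 else vals[..., None]
    affine = np.diag([img.voxel_size_mm, img.voxel_size_mm,
                      img.voxel_size_mm, 1.0])
    nib.save(nib.Nifti1Image(np.asarray(arr, dtype=np.float32), affine),
             str(path))


def load_image_nifti(path) -> ImageVolume:
    ni = nib.load(str(path))
    arr = np.asarray(ni.get_fdata())
    if arr.ndim == 3 and arr.shape[2] == 1:
        arr = arr[..., 0]
    vx = float(abs(ni.affine[0, 0]))
    return ImageVolume(arr, vx)


def save_kspace_h5(ks: KSpaceMeasurement, path):
    with h5py.File(path, "w") as f:
        f.create_dataset("kspace", data=ks.values.astype(np.complex64))
        f.create_dataset("mask", data=ks.mask.mask)
        f.attrs["dc_convention"] = "centered"
        f.attrs["noise_sigma"] = ks.noise_sigma
        f.attrs["voxel_size_mm"] = ks.voxel_size_mm
        f.attrs["center_fraction"] = ks.mask.center_fraction


def load_kspace_h5(path) -> KSpaceMeasurement:
    with h5py.File(path, "r") as f:
        vals = np.asarray(f["kspace"], dtype=np.complex128)
        mask = SamplingMask(np.asarray(f["mask"], bool),
                            float(f.attrs["center_fraction"]))
        return KSpaceMeasurement(vals, mask, float(f.attrs["noise_sigma"]),
                                 float(f.attrs["voxel_size_mm"]))


def save_mask_h5(mask: SamplingMask, path, seed=None):
    with h5py.File(path, "w") as f:
        f.create_dataset("mask", data=mask.mask)
        f.attrs["acceleration"] = mask.acceleration
        f.attrs["center_fraction"] = mask.center_fraction
        if seed is not None:
            f.attrs["seed"] = seed


def load_mask_h5(path) -> SamplingMask:
    with h5py.File(path, "r") as f:
        return SamplingMask(np.asarray(f["mask"], bool),
                            float(f.attrs["center_fraction"]))


def save_graph_graphml(vg: VascularGraph, path):
    g = nx.MultiGraph()
    for n, d in vg.g.nodes(data=True):
        g.add_node(n, kind=d.get("kind", "junction"),
                   pos_mm=json.dumps(list(d["pos_mm"])))
    for u, v, k, d in vg.g.edges(keys=True, data=True):
        g.add_edge(u, v, key=k,
                   length_mm=float(d["length_mm"]),
                   diameter_mm=float(d["diameter_mm"]),
                   confidence=float(d["confidence"]),
                   conductance=float(d["conductance"] or 0.0)
                   if d.get("conductance") is not None else 0.0,
                   index=int(d["index"]),
                   polyline_mm=json.dumps(
                       np.asarray(d["polyline_mm"]).tolist()))
    nx.write_graphml(g, str(path))


def load_graph_graphml(path) -> VascularGraph:
    raw = nx.read_graphml(str(path), force_multigraph=True)
    vg = VascularGraph()
    for n, d in raw.nodes(data=True):
        vg.add_node(n, json.loads(d["pos_mm"]), d.get("kind", "junction"))
    edges = sorted(raw.edges(keys=True, data=True),
                   key=lambda e: int(e[3]["index"]))
    for u, v, k, d in edges:
        vg.add_edge(u, v, np.asarray(json.loads(d["polyline_mm"])),
                    float(d["diameter_mm"]), float(d["confidence"]),
                    float(d["conductance"]))
    return vg


def save_diagrams_csv(diagrams, path):
    rows = []
    for dg in diagrams:
        for b, d in zip(dg.births, dg.deaths):
            ess = not np.isfinite(d)
            rows.append({"dim": dg.dim, "birth": b,
                         "death": 0.0 if ess else d, "essential": ess})
    pd.DataFrame(rows, columns=["dim", "birth", "death", "essential"]
                 ).to_csv(path, index=False)


def load_diagrams_csv(path):
    df = pd.read_csv(path)
    out = []
    for dim in sorted(df["dim"].unique()):
        sub = df[df["dim"] == dim]
        deaths = np.where(sub["essential"].to_numpy(bool), ESSENTIAL_DEATH,
                          sub["death"].to_numpy(float))
        out.append(PersistenceDiagram(int(dim), sub["birth"].to_numpy(float),
                                      deaths))
    return tuple(out)


def save_stream_csv(stream: SensorStream, path):
    pd.DataFrame({"timestamp_s": stream.timestamps,
                  "value": stream.values}).to_csv(path, index=False)
    sidecar = {"channel": stream.channel, "rate_hz": stream.rate_hz,
               "noise_std": stream.noise_std}
    with open(str(path) + ".json", "w") as fh:
        json.dump(sidecar, fh)


def load_stream_csv(path) -> SensorStream:
    df = pd.read_csv(path)
    with open(str(path) + ".json") as fh:
        meta = json.load(fh)
    return SensorStream(meta["channel"], meta["rate_hz"],
                        df["timestamp_s"].to_numpy(),
                        df["value"].to_numpy(), meta["noise_std"])
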