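"""File formats: HDF5 RF containers, TIFF/MetaImage volumes, manifests.

RF container layout (HDF5), mirrored by a JSON sidecar of the root
attributes next to the file:

    /scan/rf         float64 [m, n]   RF samples
    /scan/positions  float64 [m, 2]   line positions, mm
    /reference/rf    float64 [1, n_ref]
    /truth/*         optional ground-truth arrays (synthetic data only)
    attrs: sampling_rate_hz, c_medium, c_cartilage

Volumes are stacked TIFF (one slice per page, uint8 0/1) with the voxel
size in the ImageJ-style resolution tags and a JSON sidecar, or
MetaImage MHD/RAW with ElementSpacing.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import tifffile

from cartiqus.morphometry import TrabecularVolume
from cartiqus.rf_processing import RFScan
from cartiqus.synthetic import GroundTruth


def write_rf_container(
    path, scan: RFScan, reference: RFScan, truth: GroundTruth | None = None
) -> Path:
    """Write one specimen-site scan plus its reference to HDF5 (+ JSON
    sidecar of the attributes)."""
    path = Path(path)
    attrs = {
        "sampling_rate_hz": float(scan.sampling_rate),
        "c_medium": float(scan.c_medium),
        "c_cartilage": float(scan.c_cartilage),
    }
    with h5py.File(path, "w") as f:
        g = f.create_group("scan")
        g.create_dataset("rf", data=scan.rf)
        g.create_dataset("positions", data=scan.positions)
        f.create_group("reference").create_dataset("rf", data=reference.rf)
        for k, v in attrs.items():
            f.attrs[k] = v
        f.attrs["metadata_json"] = json.dumps(scan.metadata, default=str)
        if truth is not None:
            tg = f.create_group("truth")
            tg.create_dataset("d_um", data=truth.d_um)
            tg.create_dataset("h_mm", data=truth.h_mm)
            tg.create_dataset("surface_amplitude_ratio", data=truth.surface_amplitude_ratio)
            tg.create_dataset("interface_amplitude_ratio", data=truth.interface_amplitude_ratio)
            tg.attrs["n_redraws"] = truth.n_redraws
    sidecar = dict(attrs, metadata=scan.metadata)
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2, default=str))
    return path


def read_rf_container(path) -> tuple[RFScan, RFScan, GroundTruth | None]:
    """Read a scan container; returns (scan, reference, truth-or-None)."""
    path = Path(path)
    with h5py.File(path, "r") as f:
        fs = float(f.attrs["sampling_rate_hz"])
        c_med = float(f.attrs["c_medium"])
        c_cart = float(f.attrs["c_cartilage"])
        meta = json.loads(f.attrs.get("metadata_json", "{}"))
        scan = RFScan(
            rf=f["scan/rf"][()],
            positions=f["scan/positions"][()],
            sampling_rate=fs,
            c_medium=c_med,
            c_cartilage=c_cart,
            metadata=meta,
        )
        ref_rf = f["reference/rf"][()]
        reference = RFScan(
            rf=ref_rf,
            positions=np.zeros((ref_rf.shape[0], 2)),
            sampling_rate=fs,
            c_medium=c_med,
            c_cartilage=c_cart,
            metadata={"kind": "reference"},
        )
        truth = None
        if "truth" in f:
            truth = GroundTruth(
                d_um=f["truth/d_um"][()],
                h_mm=f["truth/h_mm"][()],
                surface_amplitude_ratio=f["truth/surface_amplitude_ratio"][()],
                interface_amplitude_ratio=f["truth/interface_amplitude_ratio"][()],
                n_redraws=int(f["truth"].attrs.get("n_redraws", 0)),
            )
    return scan, reference, truth


def write_volume(path, volume: TrabecularVolume) -> Path:
    """Write a binary volume as stacked TIFF (.tif) or MetaImage (.mhd)."""
    path = Path(path)
    data = volume.voxels.astype(np.uint8)
    if path.suffix.lower() in {".tif", ".tiff"}:
        um = volume.voxel_size_um
        tifffile.imwrite(
            path,
            data,
            resolution=(1e4 / um, 1e4 / um),
            resolutionunit="CENTIMETER",
            metadata={"spacing": um, "unit": "um", "axes": "ZYX"},
        )
        path.with_suffix(".json").write_text(
            json.dumps({"voxel_size_um": um, "shape": list(data.shape)}, indent=2)
        )
    elif path.suffix.lower() == ".mhd":
        raw = path.with_suffix(".raw")
        sp = volume.voxel_size_um * 1e-3  # mm
        header = (
            "ObjectType = Image\nNDims = 3\nBinaryData = True\n"
            "BinaryDataByteOrderMSB = False\n"
            f"DimSize = {data.shape[2]} {data.shape[1]} {data.shape[0]}\n"
            f"ElementSpacing = {sp:g} {sp:g} {sp:g}\n"
            "ElementType = MET_UCHAR\n"
            f"ElementDataFile = {raw.name}\n"
        )
        path.write_text(header)
        raw.write_bytes(data.tobytes())
    else:
        raise ValueError(f"unsupported volume format: {path.suffix}")
    return path


def read_volume(path) -> TrabecularVolume:
    """Read a stacked TIFF or MetaImage volume written by write_volume."""
    path = Path(path)
    if path.suffix.lower() in {".tif", ".tiff"}:
        data = tifffile.imread(path)
        voxel_um = 12.0
        sidecar = path.with_suffix(".json")
        if sidecar.exists():
            voxel_um = float(json.loads(sidecar.read_text())["voxel_size_um"])
        else:
            with tifffile.TiffFile(path) as tf:
                ij = tf.imagej_metadata or {}
                if "spacing" in ij:
                    voxel_um = float(ij["spacing"])
        return TrabecularVolume(voxels=data > 0, voxel_size_um=voxel_um)
    if path.suffix.lower() == ".mhd":
        fields = {}
        for line in path.read_text().splitlines():
            if "=" in line:
                k, v = line.split("=", 1)
                fields[k.strip()] = v.strip()
        nx, ny, nz = (int(t) for t in fields["DimSize"].split())
        spacing_mm = float(fields["ElementSpacing"].split()[0])
        raw = path.parent / fields["ElementDataFile"]
        data = np.frombuffer(raw.read_bytes(), dtype=np.uint8).reshape(nz, ny, nx)
        return TrabecularVolume(voxels=data > 0, voxel_size_um=spacing_mm * 1e3)
    raise ValueError(f"unsupported volume format: {path.suffix}")


def read_manifest(path) -> pd.DataFrame:
    """Cohort manifest CSV: specimen_id, group, rf/volume paths."""
    df = pd.read_csv(path)
    required = {"specimen_id", "group"}
    if not required.issubset(df.columns):
        raise ValueError(f"manifest must have columns {sorted(required)}")
    return df
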