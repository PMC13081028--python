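"""File round-trips for the pipeline's plain-text exchange formats.

Meshes: STL (via trimesh) and a minimal ASCII VTK XML PolyData (.vtp)
writer with optional per-vertex arrays.  Centerlines: 3-column CSV
(x,y,z mm, ordered root -> distal) with a JSON landmark sidecar.
Waveforms, biaxial datasets and cohort tables: headered CSV.  WSS time
series: an NPZ bundle plus JSON manifest for runtime interchange.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import trimesh

from .geometry import Centerline
from .wall_metrics import WSSTimeSeries
from .windkessel import FlowWaveform

__all__ = [
    "write_stl",
    "write_vtp",
    "write_centerline_csv",
    "read_centerline_csv",
    "write_waveform_csv",
    "read_waveform_csv",
    "save_wss_series",
    "load_wss_series",
]


def write_stl(mesh: trimesh.Trimesh, path: str | Path) -> None:
    mesh.export(str(path), file_type="stl_ascii")


def write_vtp(
    mesh: trimesh.Trimesh, path: str | Path, point_data: dict | None = None
) -> None:
    """Write an ASCII VTK XML PolyData file with optional vertex arrays."""
    v = np.asarray(mesh.vertices, dtype=float)
    f = np.asarray(mesh.faces, dtype=int)

    def arr(a, fmt="{:.9g}"):
        return " ".join(fmt.format(x) for x in np.ravel(a))

    pd_blocks = []
    for name, data in (point_data or {}).items():
        data = np.asarray(data)
        ncomp = 1 if data.ndim == 1 else data.shape[1]
        pd_blocks.append(
            f'<DataArray type="Float64" Name="{name}" '
            f'NumberOfComponents="{ncomp}" format="ascii">{arr(data)}</DataArray>'
        )
    point_data_xml = f"<PointData>{''.join(pd_blocks)}</PointData>" if pd_blocks else ""

    xml = f"""<?xml version="1.0"?>
<VTKFile type="PolyData" version="0.1" byte_order="LittleEndian">
  <PolyData>
    <Piece NumberOfPoints="{len(v)}" NumberOfPolys="{len(f)}">
      <Points>
        <DataArray type="Float64" NumberOfComponents="3" format="ascii">{arr(v)}</DataArray>
      </Points>
      {point_data_xml}
      <Polys>
        <DataArray type="Int64" Name="connectivity" format="ascii">{arr(f, '{:d}')}</DataArray>
        <DataArray type="Int64" Name="offsets" format="ascii">{arr(3 * (np.arange(len(f)) + 1), '{:d}')}</DataArray>
      </Polys>
    </Piece>
  </PolyData>
</VTKFile>
"""
    Path(path).write_text(xml)


def write_centerline_csv(centerline: Centerline, path: str | Path) -> None:
    path = Path(path)
    pd.DataFrame(centerline.points, columns=["x_mm", "y_mm", "z_mm"]).to_csv(
        path, index=False
    )
    sidecar = path.with_suffix(".landmarks.json")
    sidecar.write_text(json.dumps({k: int(v) for k, v in centerline.landmarks.items()}))


def read_centerline_csv(path: str | Path) -> Centerline:
    path = Path(path)
    df = pd.read_csv(path)
    points = df[["x_mm", "y_mm", "z_mm"]].to_numpy(dtype=float)
    sidecar = path.with_suffix(".landmarks.json")
    landmarks = json.loads(sidecar.read_text()) if sidecar.exists() else {}
    return Centerline(points=points, landmarks=landmarks)


def write_waveform_csv(waveform: FlowWaveform, path: str | Path) -> None:
    df = pd.DataFrame({"time_s": waveform.times, "flow_ul_s": waveform.flows})
    with open(path, "w") as fh:
        fh.write(f"# period_s={waveform.period_T}\n")
        df.to_csv(fh, index=False)


def read_waveform_csv(path: str | Path) -> FlowWaveform:
    with open(path) as fh:
        first = fh.readline()
        if first.startswith("# period_s="):
            period = float(first.split("=", 1)[1])
            df = pd.read_csv(fh)
        else:
            fh.seek(0)
            df = pd.read_csv(fh)
            dt = np.median(np.diff(df["time_s"]))
            period = float(df["time_s"].iloc[-1] + dt)
    return FlowWaveform(
        times=df["time_s"].to_numpy(), flows=df["flow_ul_s"].to_numpy(), period_T=period
    )


def save_wss_series(series: WSSTimeSeries, path: str | Path) -> None:
    """NPZ bundle (times, vectors) with a JSON manifest alongside."""
    path = Path(path)
    np.savez(path, times=series.times, vectors=series.vectors)
    manifest = {
        "period_T": series.period_T,
        "n_frames": int(series.vectors.shape[0]),
        "n_vertices": int(series.vectors.shape[1]),
    }
    path.with_suffix(".json").write_text(json.dumps(manifest))


def load_wss_series(path: str | Path, mesh: trimesh.Trimesh | None = None) -> WSSTimeSeries:
    path = Path(path)
    data = np.load(path if path.suffix == ".npz" else path.with_suffix(".npz"))
    manifest = json.loads(path.with_suffix(".json").read_text())
    return WSSTimeSeries(
        times=data["times"],
        vectors=data["vectors"],
        period_T=float(manifest["period_T"]),
        mesh=mesh,
    )
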