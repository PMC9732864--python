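"""Readers/writers for the file formats the pipeline consumes and emits.

Lesion masks are NIfTI-1, surfaces are PLY triangle meshes, electrode
tables are TSV, and event logs / channel tables are CSV.  All on-disk
coordinates are world millimetres.
"""

from __future__ import annotations

from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import trimesh

from .geometry import CorticalSurface, ElectrodeArray, LesionVolume

ELECTRODE_COLUMNS = [
    "patient_id",
    "recording_id",
    "array_id",
    "row",
    "col",
    "x_mm",
    "y_mm",
    "z_mm",
    "visible",
]

CHANNEL_COLUMNS = [
    "patient_id",
    "recording_id",
    "channel_id",
    "mid_x",
    "mid_y",
    "mid_z",
    "d_edge_mm",
    "d_com_mm",
    "d_geo_mm",
]

EVENT_COLUMNS = [
    "patient_id",
    "recording_id",
    "channel_id",
    "event_type",
    "time_s",
    "epoch_length_s",
]

FLOAT_FMT = "%.10g"


def load_lesion(path: str | Path) -> LesionVolume:
    """Load a binary lesion mask from NIfTI; any nonzero voxel is foreground."""
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    return LesionVolume(mask=data != 0, affine=np.asarray(img.affine))


def save_lesion(lesion: LesionVolume, path: str | Path) -> None:
    img = nib.Nifti1Image(lesion.mask.astype(np.uint8), lesion.affine)
    nib.save(img, str(path))


def load_surface(path: str | Path) -> CorticalSurface:
    """Load a triangulated surface from PLY (vertex order preserved)."""
    mesh = trimesh.load(str(path), file_type="ply", process=False)
    if not isinstance(mesh, trimesh.Trimesh):
        raise ValueError(f"{path} does not contain a single triangle mesh")
    return CorticalSurface(
        vertices=np.asarray(mesh.vertices, float),
        faces=np.asarray(mesh.faces, np.int64),
    )


def save_surface(surface: CorticalSurface, path: str | Path) -> None:
    mesh = trimesh.Trimesh(
        vertices=surface.vertices, faces=surface.faces, process=False
    )
    mesh.export(str(path), file_type="ply")


def surface_from_trimesh(mesh: "trimesh.Trimesh") -> CorticalSurface:
    return CorticalSurface(
        vertices=np.asarray(mesh.vertices, float),
        faces=np.asarray(mesh.faces, np.int64),
    )


def save_electrodes(arrays: pd.DataFrame, path: str | Path) -> None:
    """Write the per-recording electrode table (TSV, blank = unknown)."""
    df = arrays[ELECTRODE_COLUMNS].copy()
    df.to_csv(str(path), sep="\t", index=False, float_format=FLOAT_FMT)


def load_electrodes(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(str(path), sep="\t")
    missing = set(ELECTRODE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"electrode table {path} lacks columns {sorted(missing)}")
    return df


def electrode_table_to_arrays(
    df: pd.DataFrame, nominal_spacing: float = 10.0
) -> dict[tuple, ElectrodeArray]:
    """Group an electrode TSV into ElectrodeArray objects.

    Keys are (patient_id, recording_id, array_id).  Grid shape is inferred
    from the maximal row/col index present; every electrode of the layout
    must have a row in the table (with blank coordinates if unknown).
    """
    out: dict[tuple, ElectrodeArray] = {}
    for key, g in df.groupby(["patient_id", "recording_id", "array_id"], sort=True):
        n_rows = int(g["row"].max()) + 1
        n_cols = int(g["col"].max()) + 1
        coords = np.full((n_rows * n_cols, 3), np.nan)
        visible = np.zeros(n_rows * n_cols, dtype=bool)
        for _, rec in g.iterrows():
            i = int(rec["row"]) * n_cols + int(rec["col"])
            coords[i] = [rec["x_mm"], rec["y_mm"], rec["z_mm"]]
            visible[i] = bool(rec["visible"])
        out[key] = ElectrodeArray(
            array_id=str(key[2]),
            n_rows=n_rows,
            n_cols=n_cols,
            coordinates=coords,
            visible=visible,
            nominal_spacing=nominal_spacing,
        )
    return out


def arrays_to_electrode_table(
    arrays: dict[tuple, ElectrodeArray]
) -> pd.DataFrame:
    rows = []
    for (pid, rid, aid), arr in arrays.items():
        for i in range(arr.n_electrodes):
            r, c = arr.rc(i)
            x, y, z = arr.coordinates[i]
            rows.append(
                {
                    "patient_id": pid,
                    "recording_id": rid,
                    "array_id": aid,
                    "row": r,
                    "col": c,
                    "x_mm": x,
                    "y_mm": y,
                    "z_mm": z,
                    "visible": int(arr.visible[i]),
                }
            )
    return pd.DataFrame(rows, columns=ELECTRODE_COLUMNS)


def save_channel_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(str(path), index=False, float_format=FLOAT_FMT)


def load_events(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(str(path))
    missing = set(EVENT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"event log {path} lacks columns {sorted(missing)}")
    return df


def load_artifacts(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(str(path))
    need = {"patient_id", "recording_id", "channel_id"}
    if not need <= set(df.columns):
        raise ValueError(f"artifact list {path} lacks columns {sorted(need)}")
    return df
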