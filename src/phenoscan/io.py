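"""Readers and writers for the on-disk formats.

* Point clouds as whitespace-delimited flat TXT (``x y z [intensity] [label]``,
  cm, label 0=stem 1=leaf 2=pot 3=other) — the platform's native exchange
  format — and as PLY (ASCII or binary little-endian) with an integer label
  vertex property plus a sidecar label-map JSON.
* Raw scan profiles as CSV with one row per valid return
  (``disc_angle_deg, beam_angle_deg, distance_cm, intensity``).
* Platform calibration as JSON.
* A tolerant loader for plant-scan folders laid out like the published
  database (one folder per plant and scan day containing the raw cloud, the
  labeled processed cloud and optional images/metadata).

Every writer emits a ``# phenoscan ... format=...`` header comment recording
the format version and units; readers skip any ``#`` comment lines.
"""

from __future__ import annotations

import datetime as _dt
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .geometry import PlatformCalibration, PointCloud, Profile

__all__ = [
    "LABEL_TO_INT",
    "INT_TO_LABEL",
    "ScanArchive",
    "RunConfig",
    "read_cloud_txt",
    "write_cloud_txt",
    "read_ply",
    "write_ply",
    "read_profiles_csv",
    "write_profiles_csv",
    "read_calibration_json",
    "write_calibration_json",
    "open_osf_scan",
]

FORMAT_VERSION = 1

LABEL_TO_INT = {"stem": 0, "leaf": 1, "pot": 2, "other": 3}
INT_TO_LABEL = {v: k for k, v in LABEL_TO_INT.items()}


def _labels_to_int(labels: np.ndarray) -> np.ndarray:
    return np.array([LABEL_TO_INT.get(str(lb), LABEL_TO_INT["other"]) for lb in labels],
                    dtype=np.int32)


def _int_to_labels(codes: np.ndarray) -> np.ndarray:
    return np.array([INT_TO_LABEL.get(int(c), "other") for c in codes])


# ---------------------------------------------------------------------------
# Flat TXT point clouds
# ---------------------------------------------------------------------------


def write_cloud_txt(path, cloud: PointCloud) -> None:
    """Write ``x y z [intensity] [label]`` with a format-version header."""
    path = Path(path)
    cols = ["x_cm", "y_cm", "z_cm"]
    data = [cloud.points]
    if cloud.intensity is not None:
        cols.append("intensity")
        data.append(np.asarray(cloud.intensity, dtype=float)[:, None])
    if cloud.labels is not None:
        cols.append("label")
        data.append(_labels_to_int(cloud.labels)[:, None].astype(float))
    arr = np.hstack(data) if data else np.zeros((0, 3))
    with path.open("w") as fh:
        fh.write(f"# phenoscan cloud format={FORMAT_VERSION} units=cm "
                 f"columns={','.join(cols)}\n")
        np.savetxt(fh, arr, fmt="%.6f")


def read_cloud_txt(path) -> PointCloud:
    """Read a flat TXT cloud; malformed rows raise with their line number."""
    path = Path(path)
    rows = []
    ncols = None
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped or stripped.startswith("#"):
                continue
            fields = stripped.split()
            if len(fields) < 3:
                raise ValueError(
                    f"{path}:{lineno}: expected at least 3 columns, got {len(fields)}"
                )
            try:
                row = [float(v) for v in fields]
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-numeric value: {exc}") from None
            if ncols is None:
                ncols = len(row)
            elif len(row) != ncols:
                raise ValueError(
                    f"{path}:{lineno}: inconsistent column count "
                    f"({len(row)} vs {ncols})"
                )
            rows.append(row)
    if not rows:
        return PointCloud(np.zeros((0, 3)))
    arr = np.asarray(rows, dtype=float)
    intensity = arr[:, 3] if arr.shape[1] >= 4 else None
    labels = _int_to_labels(arr[:, 4].astype(int)) if arr.shape[1] >= 5 else None
    return PointCloud(arr[:, :3], intensity, labels)


# ---------------------------------------------------------------------------
# PLY point clouds (minimal codec: no mesh faces, just vertices)
# ---------------------------------------------------------------------------


def write_ply(path, cloud: PointCloud, binary: bool = False,
              label_map_sidecar: bool = True) -> None:
    """Write x/y/z (float64) with optional intensity and integer label."""
    path = Path(path)
    props = [("x", "double"), ("y", "double"), ("z", "double")]
    columns = [cloud.points[:, 0], cloud.points[:, 1], cloud.points[:, 2]]
    if cloud.intensity is not None:
        props.append(("intensity", "double"))
        columns.append(np.asarray(cloud.intensity, dtype=float))
    if cloud.labels is not None:
        props.append(("label", "int"))
        columns.append(_labels_to_int(cloud.labels))
    fmt = "binary_little_endian" if binary else "ascii"
    header = ["ply", f"format {fmt} 1.0",
              f"comment phenoscan cloud format={FORMAT_VERSION} units=cm",
              f"element vertex {len(cloud)}"]
    header += [f"property {t} {n}" for n, t in props]
    header.append("end_header")
    with path.open("wb") as fh:
        fh.write(("\n".join(header) + "\n").encode())
        if binary:
            dtype = np.dtype(
                [(n, "<f8" if t == "double" else "<i4") for n, t in props]
            )
            rec = np.empty(len(cloud), dtype=dtype)
            for (n, _), col in zip(props, columns):
                rec[n] = col
            fh.write(rec.tobytes())
        else:
            arr = np.column_stack(columns)
            int_cols = {i for i, (_, t) in enumerate(props) if t == "int"}
            for row in arr:
                fh.write((" ".join(
                    str(int(v)) if i in int_cols else f"{v:.17g}"
                    for i, v in enumerate(row)
                ) + "\n").encode())
    if cloud.labels is not None and label_map_sidecar:
        path.with_suffix(path.suffix + ".labels.json").write_text(
            json.dumps(LABEL_TO_INT, indent=2)
        )


_PLY_DTYPES = {
    "float": "<f4", "float32": "<f4", "double": "<f8", "float64": "<f8",
    "int": "<i4", "int32": "<i4", "uint": "<u4", "uint32": "<u4",
    "short": "<i2", "ushort": "<u2", "char": "<i1", "uchar": "<u1",
    "int8": "<i1", "uint8": "<u1", "int16": "<i2", "uint16": "<u2",
}


def read_ply(path) -> PointCloud:
    """Read a vertex-only PLY written by this package (ASCII or binary LE)."""
    path = Path(path)
    with path.open("rb") as fh:
        if fh.readline().strip() != b"ply":
            raise ValueError(f"{path}: not a PLY file")
        fmt = None
        n_vertex = None
        props = []
        while True:
            line = fh.readline()
            if not line:
                raise ValueError(f"{path}: unterminated PLY header")
            tokens = line.decode("ascii", "replace").split()
            if not tokens or tokens[0] == "comment":
                continue
            if tokens[0] == "format":
                fmt = tokens[1]
            elif tokens[0] == "element":
                if tokens[1] != "vertex":
                    raise ValueError(f"{path}: unsupported element {tokens[1]!r}")
                n_vertex = int(tokens[2])
            elif tokens[0] == "property":
                if tokens[1] == "list":
                    raise ValueError(f"{path}: list properties unsupported")
                props.append((tokens[2], _PLY_DTYPES[tokens[1]]))
            elif tokens[0] == "end_header":
                break
        if fmt not in ("ascii", "binary_little_endian"):
            raise ValueError(f"{path}: unsupported PLY format {fmt!r}")
        names = [n for n, _ in props]
        for required in ("x", "y", "z"):
            if required not in names:
                raise ValueError(f"{path}: missing required property {required!r}")
        if fmt == "ascii":
            body = fh.read().decode("ascii", "replace").split()
            arr = np.array(body, dtype=float).reshape(n_vertex, len(props))
            data = {n: arr[:, i] for i, (n, _) in enumerate(props)}
        else:
            dtype = np.dtype(props)
            rec = np.frombuffer(fh.read(dtype.itemsize * n_vertex), dtype=dtype,
                                count=n_vertex)
            data = {n: np.asarray(rec[n], dtype=float) for n, _ in props}
    pts = np.column_stack([data["x"], data["y"], data["z"]])
    intensity = data.get("intensity")
    labels = _int_to_labels(data["label"].astype(int)) if "label" in data else None
    return PointCloud(pts, intensity, labels)


# ---------------------------------------------------------------------------
# Raw profiles CSV
# ---------------------------------------------------------------------------

_PROFILE_COLUMNS = ["disc_angle_deg", "beam_angle_deg", "distance_cm", "intensity"]


def write_profiles_csv(path, profiles: "list[Profile]") -> None:
    """One row per valid return; the mandatory header names the columns."""
    frames = []
    for p in profiles:
        frames.append(pd.DataFrame({
            "disc_angle_deg": np.full(len(p), p.disc_angle_phi),
            "beam_angle_deg": p.beam_angles_deg,
            "distance_cm": p.distances_cm,
            "intensity": p.intensity,
        }))
    df = (pd.concat(frames, ignore_index=True) if frames
          else pd.DataFrame(columns=_PROFILE_COLUMNS))
    with Path(path).open("w") as fh:
        fh.write(f"# phenoscan profiles format={FORMAT_VERSION} "
                 f"units=deg,cm repeat_count={profiles[0].repeat_count if profiles else 1}\n")
        df.to_csv(fh, index=False, float_format="%.6f")


def read_profiles_csv(path) -> "list[Profile]":
    path = Path(path)
    repeat_count = 1
    with path.open() as fh:
        first = fh.readline()
        if first.startswith("#"):
            for token in first.split():
                if token.startswith("repeat_count="):
                    repeat_count = int(token.split("=", 1)[1])
            df = pd.read_csv(fh)
        else:
            fh.seek(0)
            df = pd.read_csv(fh)
    missing = [c for c in _PROFILE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing profile columns {missing}")
    profiles = []
    for angle, group in df.groupby("disc_angle_deg", sort=True):
        group = group.sort_values("beam_angle_deg")
        profiles.append(Profile(
            beam_angles_deg=group["beam_angle_deg"].to_numpy(),
            distances_cm=group["distance_cm"].to_numpy(),
            intensity=group["intensity"].to_numpy(),
            disc_angle_phi=float(angle),
            repeat_count=repeat_count,
        ))
    return profiles


# ---------------------------------------------------------------------------
# Calibration JSON
# ---------------------------------------------------------------------------


def write_calibration_json(path, calib: PlatformCalibration) -> None:
    Path(path).write_text(json.dumps({
        "format": FORMAT_VERSION,
        "d_cm": calib.d,
        "h_cm": calib.h,
        "tilt_deg": calib.tilt_varphi,
        "target_fit_rms_cm": calib.target_fit_rms_cm,
        "created": _dt.datetime.now(_dt.timezone.utc).isoformat(),
    }, indent=2))


def read_calibration_json(path) -> PlatformCalibration:
    blob = json.loads(Path(path).read_text())
    return PlatformCalibration(
        d=blob["d_cm"], h=blob["h_cm"], tilt_varphi=blob.get("tilt_deg", 0.0),
        target_fit_rms_cm=blob.get("target_fit_rms_cm", 0.0),
    )


# ---------------------------------------------------------------------------
# Database-style scan folders
# ---------------------------------------------------------------------------


@dataclass
class ScanArchive:
    """One plant-scan folder: raw profiles, clouds, calibration, metadata."""

    folder: Path
    raw_cloud: PointCloud | None = None
    processed_cloud: PointCloud | None = None
    profiles: list | None = None
    calibration: PlatformCalibration | None = None
    metadata: dict = field(default_factory=dict)


def open_osf_scan(folder) -> ScanArchive:
    """Load a plant-scan folder laid out like the published database.

    Expects a folder per plant and day containing a raw point-cloud TXT, a
    processed (labeled) point-cloud TXT and, optionally, profile CSVs,
    calibration and metadata JSON, and images (ignored).  File roles are
    discovered by name (``raw``/``proc``) and, failing that, by column
    count: a 5-column TXT carries labels and is taken as processed.
    """
    folder = Path(folder)
    if not folder.is_dir():
        raise FileNotFoundError(f"{folder} is not a directory")
    txts = sorted(folder.glob("*.txt"))
    if not txts:
        raise ValueError(
            f"unrecognized scan layout in {folder}: expected at least one "
            "point-cloud .txt (raw and/or processed), optionally profiles "
            ".csv, calibration .json, metadata .json and images"
        )
    archive = ScanArchive(folder=folder)
    leftovers = []
    for txt in txts:
        name = txt.stem.lower()
        if "raw" in name:
            archive.raw_cloud = read_cloud_txt(txt)
        elif "proc" in name or "label" in name:
            archive.processed_cloud = read_cloud_txt(txt)
        else:
            leftovers.append(txt)
    for txt in leftovers:
        cloud = read_cloud_txt(txt)
        if cloud.labels is not None and archive.processed_cloud is None:
            archive.processed_cloud = cloud
        elif archive.raw_cloud is None:
            archive.raw_cloud = cloud
    profile_csvs = sorted(folder.glob("*profile*.csv"))
    if profile_csvs:
        archive.profiles = read_profiles_csv(profile_csvs[0])
    calib = sorted(folder.glob("*calib*.json"))
    if calib:
        archive.calibration = read_calibration_json(calib[0])
    meta = [p for p in sorted(folder.glob("*.json"))
            if "calib" not in p.stem.lower() and not p.name.endswith(".labels.json")]
    if meta:
        archive.metadata = json.loads(meta[0].read_text())
    if not archive.metadata:
        # fall back to the folder naming scheme <plant>_<day>
        parts = folder.name.split("_")
        if len(parts) == 2:
            archive.metadata = {"plant": parts[0], "day": parts[1]}
    return archive


# ---------------------------------------------------------------------------
# Run configuration
# ---------------------------------------------------------------------------


@dataclass
class RunConfig:
    """Bundle of per-module parameter blocks loaded from one JSON file."""

    scanner: dict = field(default_factory=dict)
    turntable: dict = field(default_factory=dict)
    calibration: dict = field(default_factory=dict)
    processing: dict = field(default_factory=dict)
    classification: dict = field(default_factory=dict)
    rng_seed: int = 0
    verbosity: str = "info"

    @staticmethod
    def from_json(path) -> "RunConfig":
        blob = json.loads(Path(path).read_text())
        known = {f for f in RunConfig.__dataclass_fields__}
        unknown = set(blob) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return RunConfig(**blob)
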