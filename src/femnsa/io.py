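"""Read and write region-labeled femoral point clouds and measurement results.

Supported cloud formats: PLY (ascii or binary little-endian, vertex
properties x, y, z plus an integer property ``label``), and 4-column
XYZ/CSV text (x y z label, whitespace- or comma-delimited, optional
header).  Labels encode the femoral region: 0 = head, 1 = neck,
2 = shaft.  Measurement results serialize to a JSON schema carrying the
angle, the two fitted axes, the projection plane (2D method only) and
every region centroid.
"""

from __future__ import annotations

import json
import struct
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .geometry import Axis, Plane

__all__ = [
    "LABEL_HEAD",
    "LABEL_NECK",
    "LABEL_SHAFT",
    "LABEL_NAMES",
    "LabeledPointCloud",
    "CloudFormatError",
    "read_cloud",
    "write_cloud",
    "write_result",
    "read_result",
]

LABEL_HEAD = 0
LABEL_NECK = 1
LABEL_SHAFT = 2
LABEL_NAMES = {LABEL_HEAD: "head", LABEL_NECK: "neck", LABEL_SHAFT: "shaft"}
_VALID_LABELS = frozenset(LABEL_NAMES)


class CloudFormatError(ValueError):
    """A point-cloud file does not conform to the expected layout."""


@dataclass
class LabeledPointCloud:
    """N points (mm) with one femoral-region label per point.

    Parameters
    ----------
    points : (N, 3) float array
        Cartesian coordinates in millimetres; the frame is arbitrary
        because the measurement is rotation-invariant.
    labels : (N,) int array
        Region codes, 0 = head, 1 = neck, 2 = shaft.
    id : str
        Free-text specimen identifier.
    """

    points: np.ndarray
    labels: np.ndarray
    id: str = ""

    def __post_init__(self):
        pts = np.asarray(self.points, dtype=float)
        lab = np.asarray(self.labels)
        if pts.ndim != 2 or pts.shape[1] != 3:
            raise ValueError("points must be an (N, 3) array")
        if pts.shape[0] < 4:
            raise ValueError("a labeled cloud needs at least 4 points")
        if not np.all(np.isfinite(pts)):
            raise ValueError("points contain non-finite coordinates")
        if lab.shape != (pts.shape[0],):
            raise ValueError("labels must be one integer per point")
        if not np.issubdtype(lab.dtype, np.integer):
            if not np.all(lab == np.floor(lab)):
                raise ValueError("labels must be integers")
            lab = lab.astype(np.int32)
        bad = set(np.unique(lab)) - _VALID_LABELS
        if bad:
            raise ValueError(f"unknown label value(s) {sorted(bad)}; expected 0/1/2")
        self.points = pts
        self.labels = lab.astype(np.int32)

    def __len__(self) -> int:
        return self.points.shape[0]

    def region(self, label: int) -> np.ndarray:
        """Points carrying the given region label ((M, 3), possibly empty)."""
        return self.points[self.labels == label]

    def transformed(self, rotation=None, translation=None, scale: float = 1.0) -> "LabeledPointCloud":
        """Rigidly transformed (and optionally uniformly scaled) copy."""
        pts = self.points * float(scale)
        if rotation is not None:
            pts = pts @ np.asarray(rotation, dtype=float).T
        if translation is not None:
            pts = pts + np.asarray(translation, dtype=float)
        return LabeledPointCloud(points=pts, labels=self.labels.copy(), id=self.id)


def _infer_format(path: Path, format: str | None) -> str:
    if format is not None:
        fmt = format.lower()
    else:
        fmt = path.suffix.lower().lstrip(".")
        if fmt == "txt":
            fmt = "xyz"
    if fmt not in ("ply", "xyz", "csv"):
        raise ValueError(f"unsupported point-cloud format {fmt!r}")
    return fmt


def read_cloud(path, format: str | None = None) -> LabeledPointCloud:
    """Read a labeled cloud; point order is preserved from the file."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = _infer_format(path, format)
    if fmt == "ply":
        points, labels = _read_ply(path)
    else:
        points, labels = _read_table(path)
    try:
        return LabeledPointCloud(points=points, labels=labels, id=path.stem)
    except ValueError as exc:
        raise CloudFormatError(f"{path}: {exc}") from exc


def write_cloud(cloud: LabeledPointCloud, path, format: str | None = None) -> Path:
    """Write a labeled cloud; round-trips exactly through ``read_cloud``."""
    path = Path(path)
    fmt = _infer_format(path, format)
    if fmt == "ply":
        _write_ply(cloud, path)
    elif fmt == "csv":
        _write_table(cloud, path, delim=",", header="x,y,z,label")
    else:
        _write_table(cloud, path, delim=" ", header=None)
    return path


# ---------------------------------------------------------------- PLY codec

_PLY_DTYPES = {
    "char": "i1", "int8": "i1", "uchar": "u1", "uint8": "u1",
    "short": "i2", "int16": "i2", "ushort": "u2", "uint16": "u2",
    "int": "i4", "int32": "i4", "uint": "u4", "uint32": "u4",
    "float": "f4", "float32": "f4", "double": "f8", "float64": "f8",
}


def _read_ply(path: Path) -> tuple[np.ndarray, np.ndarray]:
    with open(path, "rb") as fh:
        magic = fh.readline().strip()
        if magic != b"ply":
            raise CloudFormatError(f"{path}: not a PLY file")
        fmt = None
        n_vertex = None
        props: list[tuple[str, str]] = []
        in_vertex = False
        while True:
            line = fh.readline()
            if not line:
                raise CloudFormatError(f"{path}: truncated PLY header")
            tokens = line.decode("ascii", "replace").split()
            if not tokens or tokens[0] == "comment":
                continue
            if tokens[0] == "format":
                fmt = tokens[1]
            elif tokens[0] == "element":
                in_vertex = tokens[1] == "vertex"
                if in_vertex:
                    n_vertex = int(tokens[2])
            elif tokens[0] == "property" and in_vertex:
                if tokens[1] == "list":
                    raise CloudFormatError(f"{path}: list vertex properties unsupported")
                props.append((tokens[2], tokens[1]))
            elif tokens[0] == "end_header":
                break
        if fmt not in ("ascii", "binary_little_endian"):
            raise CloudFormatError(f"{path}: unsupported PLY format {fmt!r}")
        if n_vertex is None:
            raise CloudFormatError(f"{path}: no vertex element")
        names = [p[0] for p in props]
        for req in ("x", "y", "z"):
            if req not in names:
                raise CloudFormatError(f"{path}: missing vertex property {req!r}")
        if "label" not in names:
            raise CloudFormatError(f"{path}: missing integer vertex property 'label'")
        if _PLY_DTYPES[dict(props)["label"]][0] == "f":
            raise CloudFormatError(f"{path}: 'label' must be an integer property")
        dtype = np.dtype([(name, "<" + _PLY_DTYPES[typ]) for name, typ in props])
        if fmt == "ascii":
            data = np.empty(n_vertex, dtype=dtype)
            for i in range(n_vertex):
                line = fh.readline()
                if not line:
                    raise CloudFormatError(f"{path}: vertex {i}: unexpected end of file")
                tokens = line.split()
                if len(tokens) != len(props):
                    raise CloudFormatError(f"{path}: vertex {i}: wrong column count")
                try:
                    for (name, _), tok in zip(props, tokens):
                        data[name][i] = float(tok)
                except ValueError:
                    raise CloudFormatError(f"{path}: vertex {i}: non-numeric value") from None
        else:
            buf = fh.read(dtype.itemsize * n_vertex)
            if len(buf) < dtype.itemsize * n_vertex:
                raise CloudFormatError(f"{path}: truncated binary vertex data")
            data = np.frombuffer(buf, dtype=dtype, count=n_vertex)
    points = np.column_stack([data["x"], data["y"], data["z"]]).astype(float)
    if not np.all(np.isfinite(points)):
        bad = int(np.nonzero(~np.isfinite(points).all(axis=1))[0][0])
        raise CloudFormatError(f"{path}: non-finite coordinate at vertex {bad}")
    return points, data["label"].astype(np.int32)


def _write_ply(cloud: LabeledPointCloud, path: Path, binary: bool = True) -> None:
    n = len(cloud)
    header = (
        "ply\n"
        f"format {'binary_little_endian' if binary else 'ascii'} 1.0\n"
        f"element vertex {n}\n"
        "property double x\nproperty double y\nproperty double z\n"
        "property int label\n"
        "end_header\n"
    )
    with open(path, "wb") as fh:
        fh.write(header.encode("ascii"))
        if binary:
            rec = np.empty(n, dtype=np.dtype([("x", "<f8"), ("y", "<f8"), ("z", "<f8"), ("label", "<i4")]))
            rec["x"], rec["y"], rec["z"] = cloud.points.T
            rec["label"] = cloud.labels
            fh.write(rec.tobytes())
        else:
            for (x, y, z), lab in zip(cloud.points, cloud.labels):
                fh.write(f"{x:.17g} {y:.17g} {z:.17g} {int(lab)}\n".encode("ascii"))


# ------------------------------------------------------------- text tables

def _read_table(path: Path) -> tuple[np.ndarray, np.ndarray]:
    points: list[tuple[float, float, float]] = []
    labels: list[int] = []
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            tokens = [t for t in line.replace(",", " ").split() if t]
            if len(tokens) < 4:
                raise CloudFormatError(
                    f"{path}: line {lineno}: expected >= 4 columns (x y z label), got {len(tokens)}"
                )
            try:
                x, y, z = (float(t) for t in tokens[:3])
            except ValueError:
                if not points:  # optional header line
                    continue
                raise CloudFormatError(f"{path}: line {lineno}: non-numeric coordinate") from None
            if not all(np.isfinite(v) for v in (x, y, z)):
                raise CloudFormatError(f"{path}: line {lineno}: non-finite coordinate")
            try:
                lab = int(float(tokens[3]))
            except ValueError:
                raise CloudFormatError(f"{path}: line {lineno}: non-integer label") from None
            points.append((x, y, z))
            labels.append(lab)
    if not points:
        raise CloudFormatError(f"{path}: no data rows (is the label column present?)")
    return np.asarray(points, dtype=float), np.asarray(labels, dtype=np.int32)


def _write_table(cloud: LabeledPointCloud, path: Path, delim: str, header: str | None) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        if header:
            fh.write(header + "\n")
        for (x, y, z), lab in zip(cloud.points, cloud.labels):
            fh.write(f"{x:.17g}{delim}{y:.17g}{delim}{z:.17g}{delim}{int(lab)}\n")


# ------------------------------------------------------------ result JSON

def _axis_dict(axis: Axis) -> dict:
    return {"anchor": [float(v) for v in axis.anchor],
            "direction": [float(v) for v in axis.direction]}


def write_result(result, path) -> Path:
    """Serialize an NSA measurement result to JSON.

    Schema: ``{id, method, nsa_deg, neck_axis{anchor,direction},
    shaft_axis{anchor,direction}, plane{A,B,C,D}|null,
    centroids{...}, diagnostics{...}}``.  The plane entry is present only
    for the 2D (projection) method and is in unit-normal form.
    """
    path = Path(path)
    payload = {
        "id": result.id,
        "method": result.method,
        "nsa_deg": float(result.nsa_deg),
        "neck_axis": _axis_dict(result.neck_axis),
        "shaft_axis": _axis_dict(result.shaft_axis),
        "plane": None if result.plane is None else {
            "A": result.plane.A, "B": result.plane.B,
            "C": result.plane.C, "D": result.plane.D,
        },
        "centroids": {k: [float(v) for v in p] for k, p in result.centroids.items()},
        "diagnostics": {k: (float(v) if isinstance(v, (int, float, np.floating)) else v)
                        for k, v in result.diagnostics.items()},
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=2)
        fh.write("\n")
    return path


def read_result(path) -> dict:
    """Read back a result JSON written by :func:`write_result`."""
    with open(path, "r", encoding="utf-8") as fh:
        return json.load(fh)
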