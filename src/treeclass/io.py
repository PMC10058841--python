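"""Readers and writers for spatial-spectral point clouds.

Two on-disk dialects are supported:

* wide CSV with header ``x,y,z[,label],r550,r555,...,r1050`` — reflectance
  spectra — or ``v550...v1050`` for uncalibrated echo intensities;
* PLY with the same per-vertex scalar properties (``ascii`` and
  ``binary_little_endian`` accepted on read; binary written).  Labels are
  stored in PLY as a uchar code with a header comment naming the code
  mapping, since PLY has no portable string property.

``export_reconstruction`` writes the classified cloud as a standard colored
PLY (x, y, z + uint8 red/green/blue) readable by any point-cloud viewer.
"""

from __future__ import annotations

import re
import struct
from pathlib import Path

import numpy as np
import pandas as pd

from .cloud import LABEL_NAMES, ColorMap, ComponentLabel, SpectralPointCloud
from .grid import WavelengthGrid

__all__ = ["read_cloud", "write_cloud", "export_reconstruction", "FormatError"]


class FormatError(ValueError):
    """Raised when a file does not match the expected spectral-cloud schema."""


_SPECTRAL_RE = re.compile(r"^([rv])(\d+)$")


def _parse_spectral_columns(names: list[str]) -> tuple[str, list[float], WavelengthGrid]:
    """Infer spectra kind and wavelength grid from r/v-prefixed column names."""
    kinds = set()
    wavelengths = []
    for name in names:
        m = _SPECTRAL_RE.match(name)
        if not m:
            raise FormatError(f"unexpected column {name!r} (expected r<nm> or v<nm>)")
        kinds.add(m.group(1))
        wavelengths.append(float(m.group(2)))
    if not wavelengths:
        raise FormatError("no spectral columns found (r<nm> or v<nm>)")
    if len(kinds) > 1:
        raise FormatError("mixed r- and v-prefixed spectral columns")
    kind = "reflectance" if kinds.pop() == "r" else "intensity"

    wl = np.asarray(wavelengths)
    steps = np.diff(wl)
    if len(wl) < 2 or not np.all(steps == steps[0]) or steps[0] <= 0:
        raise FormatError("spectral columns must be in ascending uniform wavelength order")
    grid = WavelengthGrid(wl[0], wl[-1], steps[0])
    expected = grid.wavelengths
    if len(wl) != grid.n_channels or not np.array_equal(wl, expected):
        bad = names[int(np.argmin(wl == expected[: len(wl)]))]
        raise FormatError(f"spectral columns do not form a uniform grid near {bad!r}")
    return kind, wavelengths, grid


def _check_grid(grid: WavelengthGrid, names: list[str]) -> None:
    if grid.n_channels != 101 or grid.start_nm != 550 or grid.step_nm != 5:
        # the scanner grid is fixed; name the first column that breaks it
        expected = {550 + 5 * i for i in range(101)}
        got = {float(_SPECTRAL_RE.match(n).group(2)) for n in names}
        extra = sorted(got - expected)
        missing = sorted(expected - got)
        if extra:
            raise FormatError(f"unexpected spectral column at {extra[0]:g} nm")
        raise FormatError(f"missing spectral column at {missing[0]:g} nm")


def _spectral_names(cloud: SpectralPointCloud) -> list[str]:
    prefix = "r" if cloud.spectra_kind == "reflectance" else "v"
    return [f"{prefix}{int(w)}" for w in cloud.grid.wavelengths]


# ---------------------------------------------------------------- CSV


def _read_csv(path: Path) -> SpectralPointCloud:
    try:
        df = pd.read_csv(path)
    except ValueError as exc:
        raise FormatError(f"cannot parse {path}: {exc}") from exc
    cols = list(df.columns)
    for required in ("x", "y", "z"):
        if required not in cols:
            raise FormatError(f"missing coordinate column {required!r}")
    has_label = "label" in cols
    spectral = [c for c in cols if c not in ("x", "y", "z", "label")]
    kind, _, grid = _parse_spectral_columns(spectral)
    _check_grid(grid, spectral)

    numeric_cols = ["x", "y", "z"] + spectral
    block = df[numeric_cols].apply(pd.to_numeric, errors="coerce")
    bad = block.isna() & ~df[numeric_cols].isna()
    if bad.to_numpy().any():
        row = int(np.argwhere(bad.to_numpy().any(axis=1))[0, 0])
        raise FormatError(f"non-numeric cell in row {row} of {path}")
    if block.isna().to_numpy().any():
        row = int(np.argwhere(block.isna().to_numpy().any(axis=1))[0, 0])
        raise FormatError(f"empty cell in row {row} of {path}")

    labels = None
    if has_label:
        labels = np.array(
            [ComponentLabel.from_name(str(v)) for v in df["label"]], dtype=np.int64
        )
    return SpectralPointCloud(
        coords=block[["x", "y", "z"]].to_numpy(),
        spectra=block[spectral].to_numpy(),
        spectra_kind=kind,
        labels=labels,
        grid=grid,
    )


def _write_csv(cloud: SpectralPointCloud, path: Path) -> None:
    spectral = _spectral_names(cloud)
    data = {
        "x": cloud.coords[:, 0],
        "y": cloud.coords[:, 1],
        "z": cloud.coords[:, 2],
    }
    if cloud.labels is not None:
        data["label"] = [LABEL_NAMES[ComponentLabel(c)] for c in cloud.labels]
    for j, name in enumerate(spectral):
        data[name] = cloud.spectra[:, j]
    pd.DataFrame(data).to_csv(path, index=False)


# ---------------------------------------------------------------- PLY

_PLY_DTYPES = {
    "float": ("<f4", float), "float32": ("<f4", float),
    "double": ("<f8", float), "float64": ("<f8", float),
    "uchar": ("<u1", int), "uint8": ("<u1", int),
    "char": ("<i1", int), "int8": ("<i1", int),
    "ushort": ("<u2", int), "uint16": ("<u2", int),
    "short": ("<i2", int), "int16": ("<i2", int),
    "uint": ("<u4", int), "uint32": ("<u4", int),
    "int": ("<i4", int), "int32": ("<i4", int),
}


def _read_ply_vertices(path: Path) -> tuple[pd.DataFrame, list[str]]:
    """Parse the vertex element of an ascii or binary_little_endian PLY."""
    with open(path, "rb") as fh:
        magic = fh.readline().strip()
        if magic != b"ply":
            raise FormatError(f"{path} is not a PLY file")
        fmt = None
        elements: list[tuple[str, int, list[tuple[str, str]]]] = []
        comments: list[str] = []
        while True:
            line = fh.readline()
            if not line:
                raise FormatError("unexpected end of PLY header")
            tokens = line.decode("ascii", "replace").split()
            if not tokens:
                continue
            if tokens[0] == "format":
                fmt = tokens[1]
            elif tokens[0] == "comment":
                comments.append(" ".join(tokens[1:]))
            elif tokens[0] == "element":
                elements.append((tokens[1], int(tokens[2]), []))
            elif tokens[0] == "property":
                if tokens[1] == "list":
                    raise FormatError("list properties are not supported")
                elements[-1][2].append((tokens[1], tokens[2]))
            elif tokens[0] == "end_header":
                break
        if fmt not in ("ascii", "binary_little_endian"):
            raise FormatError(f"unsupported PLY format {fmt!r}")

        frames: dict[str, pd.DataFrame] = {}
        for name, count, props in elements:
            dtype = np.dtype([(p, _PLY_DTYPES[t][0]) for t, p in props])
            if fmt == "binary_little_endian":
                raw = fh.read(dtype.itemsize * count)
                if len(raw) != dtype.itemsize * count:
                    raise FormatError(f"truncated PLY data in element {name!r}")
                rec = np.frombuffer(raw, dtype=dtype, count=count)
            else:
                rows = []
                for i in range(count):
                    parts = fh.readline().split()
                    if len(parts) != len(props):
                        raise FormatError(f"bad vertex row {i} in {path}")
                    rows.append(tuple(float(v) for v in parts))
                rec = np.array(rows, dtype=dtype) if rows else np.empty(0, dtype=dtype)
            frames[name] = pd.DataFrame({p: rec[p] for _, p in props})
        if "vertex" not in frames:
            raise FormatError("PLY file has no vertex element")
        return frames["vertex"], comments


def _read_ply(path: Path) -> SpectralPointCloud:
    df, _ = _read_ply_vertices(path)
    cols = list(df.columns)
    for required in ("x", "y", "z"):
        if required not in cols:
            raise FormatError(f"missing vertex property {required!r}")
    has_label = "label" in cols
    spectral = [c for c in cols if c not in ("x", "y", "z", "label")]
    kind, _, grid = _parse_spectral_columns(spectral)
    _check_grid(grid, spectral)
    labels = df["label"].to_numpy(dtype=np.int64) if has_label else None
    return SpectralPointCloud(
        coords=df[["x", "y", "z"]].to_numpy(dtype=float),
        spectra=df[spectral].to_numpy(dtype=float),
        spectra_kind=kind,
        labels=labels,
        grid=grid,
    )


def _write_ply(cloud: SpectralPointCloud, path: Path) -> None:
    spectral = _spectral_names(cloud)
    fields: list[tuple[str, str, np.ndarray]] = [
        ("double", "x", cloud.coords[:, 0]),
        ("double", "y", cloud.coords[:, 1]),
        ("double", "z", cloud.coords[:, 2]),
    ]
    if cloud.labels is not None:
        fields.append(("uchar", "label", cloud.labels))
    for j, name in enumerate(spectral):
        fields.append(("double", name, cloud.spectra[:, j]))

    header = ["ply", "format binary_little_endian 1.0"]
    if cloud.labels is not None:
        codes = ", ".join(f"{int(l)}={LABEL_NAMES[l]}" for l in ComponentLabel)
        header.append(f"comment label codes: {codes}")
    header.append(f"element vertex {cloud.n_points}")
    header += [f"property {t} {n}" for t, n, _ in fields]
    header.append("end_header")

    dtype = np.dtype([(n, _PLY_DTYPES[t][0]) for t, n, _ in fields])
    rec = np.empty(cloud.n_points, dtype=dtype)
    for t, n, col in fields:
        rec[n] = col
    with open(path, "wb") as fh:
        fh.write(("\n".join(header) + "\n").encode("ascii"))
        fh.write(rec.tobytes())


# ---------------------------------------------------------------- API


def _infer_format(path: Path, format: str | None) -> str:
    if format is not None:
        if format not in ("csv", "ply"):
            raise ValueError(f"unknown format {format!r}")
        return format
    suffix = path.suffix.lower().lstrip(".")
    if suffix in ("csv", "ply"):
        return suffix
    raise ValueError(f"cannot infer format from {path.name!r}; pass format=")


def read_cloud(path: str | Path, format: str | None = None) -> SpectralPointCloud:
    """Read a spatial-spectral cloud from wide CSV or PLY.

    The wavelength grid and spectra kind (reflectance vs intensity) are
    inferred from the ``r<nm>`` / ``v<nm>`` column names; a ``label`` column
    of class names populates per-point labels.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = _infer_format(path, format)
    return _read_csv(path) if fmt == "csv" else _read_ply(path)


def write_cloud(
    cloud: SpectralPointCloud, path: str | Path, format: str | None = None
) -> None:
    """Write a cloud to CSV or PLY; readable back by :func:`read_cloud`."""
    path = Path(path)
    fmt = _infer_format(path, format)
    if fmt == "csv":
        _write_csv(cloud, path)
    else:
        _write_ply(cloud, path)


def export_reconstruction(
    cloud: SpectralPointCloud,
    labels: np.ndarray,
    colormap: ColorMap,
    path: str | Path,
) -> None:
    """Write a colored-PLY 3D reconstruction of the classification result.

    Each vertex carries x, y, z and the uint8 RGB color assigned to its
    component class, so the classified tree can be inspected in any
    standard point-cloud viewer.
    """
    labels = np.asarray(labels, dtype=np.int64)
    if labels.shape != (cloud.n_points,):
        raise ValueError("labels length must equal point count")
    for code in np.unique(labels):
        if ComponentLabel(code) not in colormap.mapping:
            raise KeyError(f"label {code} missing from colormap")
    rgb = colormap.as_array(labels) if len(labels) else np.empty((0, 3), np.uint8)

    header = [
        "ply",
        "format binary_little_endian 1.0",
        f"element vertex {cloud.n_points}",
        "property float x",
        "property float y",
        "property float z",
        "property uchar red",
        "property uchar green",
        "property uchar blue",
        "end_header",
    ]
    rec = np.empty(
        cloud.n_points,
        dtype=[("x", "<f4"), ("y", "<f4"), ("z", "<f4"),
               ("red", "u1"), ("green", "u1"), ("blue", "u1")],
    )
    rec["x"], rec["y"], rec["z"] = cloud.coords.T.astype(np.float32)
    rec["red"], rec["green"], rec["blue"] = rgb.T
    with open(path, "wb") as fh:
        fh.write(("\n".join(header) + "\n").encode("ascii"))
        fh.write(rec.tobytes())


def export_change_mask(
    cloud: SpectralPointCloud, changed: np.ndarray, path: str | Path
) -> None:
    """Two-color PLY of the reprogramming change mask (red kept, green changed)."""
    changed = np.asarray(changed, dtype=bool)
    rgb = np.where(changed[:, None], [0, 255, 0], [255, 0, 0]).astype(np.uint8)
    header = [
        "ply",
        "format binary_little_endian 1.0",
        f"element vertex {cloud.n_points}",
        "property float x", "property float y", "property float z",
        "property uchar red", "property uchar green", "property uchar blue",
        "end_header",
    ]
    rec = np.empty(
        cloud.n_points,
        dtype=[("x", "<f4"), ("y", "<f4"), ("z", "<f4"),
               ("red", "u1"), ("green", "u1"), ("blue", "u1")],
    )
    rec["x"], rec["y"], rec["z"] = cloud.coords.T.astype(np.float32)
    rec["red"], rec["green"], rec["blue"] = rgb.T
    with open(path, "wb") as fh:
        fh.write(("\n".join(header) + "\n").encode("ascii"))
        fh.write(rec.tobytes())
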