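"""Mesh I/O: VTK legacy ASCII polydata, PLY (ASCII) and OFF.

Per-vertex scalar fields round-trip in all three formats.  Labels are
stored as an integer field named ``"labels"``.  VTK legacy polydata is the
pipeline's native interchange format (POINTS / POLYGONS / POINT_DATA with
one SCALARS block per field); PLY stores fields as extra vertex properties;
OFF carries geometry only plus an optional sidecar-free scalar comment-less
extension is *not* attempted — fields are dropped with a warning on OFF
write.
"""

from __future__ import annotations

import os
import warnings

import numpy as np

from .mesh import TriangleMesh

__all__ = ["read_mesh", "write_mesh", "MeshParseError", "UnsupportedCellError"]

LABEL_FIELD = "labels"


class MeshParseError(ValueError):
    """Malformed mesh file; message names the offending record."""


class UnsupportedCellError(MeshParseError):
    """File contains non-triangle cells."""


def _detect_format(path: str, fmt: str | None) -> str:
    if fmt is not None:
        return fmt
    ext = os.path.splitext(path)[1].lower()
    return {".vtk": "vtk", ".ply": "ply", ".off": "off"}.get(ext, "vtk")


def read_mesh(path: str, fmt: str | None = None) -> TriangleMesh:
    """Read a triangle mesh; ``fmt`` in {"vtk", "ply", "off"} (inferred
    from the extension when omitted)."""
    fmt = _detect_format(path, fmt)
    if fmt == "vtk":
        mesh = _read_vtk(path)
    elif fmt == "ply":
        mesh = _read_ply(path)
    elif fmt == "off":
        mesh = _read_off(path)
    else:
        raise ValueError(f"unknown mesh format {fmt!r}")
    if LABEL_FIELD in mesh.scalar_fields:
        mesh.labels = mesh.scalar_fields.pop(LABEL_FIELD).astype(np.int64)
    return mesh


def write_mesh(mesh: TriangleMesh, path: str, fmt: str | None = None) -> None:
    fmt = _detect_format(path, fmt)
    fields = dict(mesh.scalar_fields)
    if mesh.labels is not None:
        fields[LABEL_FIELD] = mesh.labels
    if fmt == "vtk":
        _write_vtk(mesh, fields, path)
    elif fmt == "ply":
        _write_ply(mesh, fields, path)
    elif fmt == "off":
        if fields:
            warnings.warn("OFF format stores geometry only; fields dropped")
        _write_off(mesh, path)
    else:
        raise ValueError(f"unknown mesh format {fmt!r}")


# ---------------------------------------------------------------- VTK legacy


def _write_vtk(mesh: TriangleMesh, fields: dict, path: str) -> None:
    with open(path, "w") as f:
        f.write("# vtk DataFile Version 3.0\ncortiparc surface\nASCII\n")
        f.write("DATASET POLYDATA\n")
        f.write(f"POINTS {mesh.n_vertices} double\n")
        for p in mesh.vertices:
            f.write(f"{p[0]:.17g} {p[1]:.17g} {p[2]:.17g}\n")
        nf = mesh.n_triangles
        f.write(f"POLYGONS {nf} {4 * nf}\n")
        for t in mesh.triangles:
            f.write(f"3 {t[0]} {t[1]} {t[2]}\n")
        if fields:
            f.write(f"POINT_DATA {mesh.n_vertices}\n")
            for name, data in fields.items():
                data = np.asarray(data)
                if np.issubdtype(data.dtype, np.integer):
                    f.write(f"SCALARS {name} int 1\nLOOKUP_TABLE default\n")
                    f.write("\n".join(str(int(v)) for v in data) + "\n")
                else:
                    f.write(f"SCALARS {name} double 1\nLOOKUP_TABLE default\n")
                    f.write("\n".join(f"{float(v):.17g}" for v in data) + "\n")


def _read_vtk(path: str) -> TriangleMesh:
    with open(path) as f:
        tokens_lines = [ln.strip() for ln in f]
    # token stream with line bookkeeping for error messages
    toks: list[str] = []
    for ln in tokens_lines[2:]:  # skip the two header comment lines
        toks.extend(ln.split())
    pos = 0

    def take(n: int) -> list[str]:
        nonlocal pos
        if pos + n > len(toks):
            raise MeshParseError(f"{path}: truncated file near token {pos}")
        out = toks[pos : pos + n]
        pos += n
        return out

    def expect(word: str):
        got = take(1)[0]
        if got.upper() != word:
            raise MeshParseError(f"{path}: expected {word}, got {got!r}")

    expect("ASCII")
    expect("DATASET")
    kind = take(1)[0]
    if kind.upper() != "POLYDATA":
        raise MeshParseError(f"{path}: unsupported dataset {kind!r}")
    expect("POINTS")
    nv = int(take(1)[0])
    take(1)  # dtype
    vals = take(3 * nv)
    vertices = np.array(vals, dtype=float).reshape(nv, 3)
    expect("POLYGONS")
    nf = int(take(1)[0])
    size = int(take(1)[0])
    cell_toks = take(size)
    triangles = np.empty((nf, 3), dtype=np.int64)
    i = 0
    for c in range(nf):
        k = int(cell_toks[i])
        if k != 3:
            raise UnsupportedCellError(
                f"{path}: POLYGONS record {c} has {k} vertices; only "
                "triangles are supported"
            )
        triangles[c] = [int(x) for x in cell_toks[i + 1 : i + 4]]
        i += k + 1
    fields: dict[str, np.ndarray] = {}
    while pos < len(toks):
        word = take(1)[0].upper()
        if word == "POINT_DATA":
            n = int(take(1)[0])
            if n != nv:
                raise MeshParseError(
                    f"{path}: POINT_DATA count {n} != POINTS count {nv}"
                )
        elif word == "SCALARS":
            name = take(1)[0]
            dtype = take(1)[0]
            ncomp = take(1)[0]
            if int(ncomp) != 1:
                raise MeshParseError(f"{path}: SCALARS {name} has {ncomp} components")
            expect("LOOKUP_TABLE")
            take(1)
            data = np.array(take(nv), dtype=float)
            if dtype in ("int", "long", "short"):
                data = data.astype(np.int64)
            fields[name] = data
        else:
            raise MeshParseError(f"{path}: unsupported record {word!r}")
    mesh = TriangleMesh(vertices, triangles)
    for name, data in fields.items():
        mesh.scalar_fields[name] = np.asarray(data)
    return mesh


# ----------------------------------------------------------------------- PLY


def _write_ply(mesh: TriangleMesh, fields: dict, path: str) -> None:
    names = list(fields)
    with open(path, "w") as f:
        f.write("ply\nformat ascii 1.0\n")
        f.write(f"element vertex {mesh.n_vertices}\n")
        f.write("property double x\nproperty double y\nproperty double z\n")
        for name in names:
            kind = "int" if np.issubdtype(np.asarray(fields[name]).dtype, np.integer) else "double"
            f.write(f"property {kind} {name}\n")
        f.write(f"element face {mesh.n_triangles}\n")
        f.write("property list uchar int vertex_indices\nend_header\n")
        for i, p in enumerate(mesh.vertices):
            row = [f"{p[0]:.17g}", f"{p[1]:.17g}", f"{p[2]:.17g}"]
            for name in names:
                v = fields[name][i]
                row.append(str(int(v)) if isinstance(v, (int, np.integer)) else f"{float(v):.17g}")
            f.write(" ".join(row) + "\n")
        for t in mesh.triangles:
            f.write(f"3 {t[0]} {t[1]} {t[2]}\n")


def _read_ply(path: str) -> TriangleMesh:
    with open(path) as f:
        lines = [ln.strip() for ln in f if ln.strip()]
    if lines[0] != "ply":
        raise MeshParseError(f"{path}: missing 'ply' magic")
    i = 1
    nv = nf = 0
    vprops: list[tuple[str, str]] = []
    current = None
    while i < len(lines):
        ln = lines[i]
        i += 1
        if ln == "end_header":
            break
        parts = ln.split()
        if parts[0] == "format" and parts[1] != "ascii":
            raise MeshParseError(f"{path}: only ASCII PLY supported")
        if parts[0] == "element":
            current = parts[1]
            if current == "vertex":
                nv = int(parts[2])
            elif current == "face":
                nf = int(parts[2])
        elif parts[0] == "property" and current == "vertex":
            if parts[1] == "list":
                raise MeshParseError(f"{path}: list property on vertices")
            vprops.append((parts[2], parts[1]))
    else:
        raise MeshParseError(f"{path}: missing end_header")
    names = [n for n, _ in vprops]
    if names[:3] != ["x", "y", "z"]:
        raise MeshParseError(f"{path}: vertex properties must start with x y z")
    vdata = np.array(
        [ln.split() for ln in lines[i : i + nv]], dtype=float
    )
    if vdata.shape != (nv, len(vprops)):
        raise MeshParseError(f"{path}: bad vertex element block shape")
    i += nv
    triangles = np.empty((nf, 3), dtype=np.int64)
    for c in range(nf):
        parts = lines[i + c].split()
        if int(parts[0]) != 3:
            raise UnsupportedCellError(
                f"{path}: face record {c} has {parts[0]} vertices; only "
                "triangles are supported"
            )
        triangles[c] = [int(x) for x in parts[1:4]]
    mesh = TriangleMesh(vdata[:, :3], triangles)
    for k, (name, kind) in enumerate(vprops[3:], start=3):
        col = vdata[:, k]
        mesh.scalar_fields[name] = col.astype(np.int64) if kind in (
            "int", "uint", "short", "ushort", "uchar", "char"
        ) else col
    return mesh


# ----------------------------------------------------------------------- OFF


def _write_off(mesh: TriangleMesh, path: str) -> None:
    with open(path, "w") as f:
        f.write("OFF\n")
        f.write(f"{mesh.n_vertices} {mesh.n_triangles} 0\n")
        for p in mesh.vertices:
            f.write(f"{p[0]:.17g} {p[1]:.17g} {p[2]:.17g}\n")
        for t in mesh.triangles:
            f.write(f"3 {t[0]} {t[1]} {t[2]}\n")


def _read_off(path: str) -> TriangleMesh:
    with open(path) as f:
        lines = [ln.strip() for ln in f if ln.strip() and not ln.startswith("#")]
    if lines[0] != "OFF":
        raise MeshParseError(f"{path}: missing OFF magic")
    nv, nf, _ = (int(x) for x in lines[1].split())
    vertices = np.array([ln.split()[:3] for ln in lines[2 : 2 + nv]], dtype=float)
    triangles = np.empty((nf, 3), dtype=np.int64)
    for c in range(nf):
        parts = lines[2 + nv + c].split()
        if int(parts[0]) != 3:
            raise UnsupportedCellError(
                f"{path}: face record {c} has {parts[0]} vertices; only "
                "triangles are supported"
            )
        triangles[c] = [int(x) for x in parts[1:4]]
    return TriangleMesh(vertices, triangles)
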