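"""Mesh and image I/O.

Unstructured-grid files are written in ASCII (.vtu XML and legacy .vtk) with
tets as cell type 10 and the boundary triangles (cell type 5) appended after
them carrying an integer cell-data array ``cap_id`` (0 = wall, 1 = inlet,
2/3 = outlets; volume cells get -1).  Nodal fields travel as point-data
arrays ``pressure`` (scalar) and ``velocity`` (3-vector).  Images and masks
are NIfTI with the voxel spacing in the header.
"""

from __future__ import annotations

import xml.etree.ElementTree as ET
from pathlib import Path

import nibabel as nib
import numpy as np

from .mesh_core import CAP_IDS, CAP_NAMES, FieldSet, ImageVolume, VolumeMesh, extract_surface


def _boundary_cells(mesh: VolumeMesh):
    """Boundary triangles + per-triangle cap id (0 for unlabelled wall)."""
    surf = extract_surface(mesh)
    labels = np.zeros(surf.triangles.shape[0], dtype=np.int64)
    keyed = {tuple(t): i for i, t in enumerate(np.sort(surf.triangles, axis=1))}
    for cap, faces in mesh.cap_faces.items():
        for tri in np.sort(faces, axis=1):
            i = keyed.get(tuple(tri))
            if i is not None:
                labels[i] = CAP_IDS[cap]
    return surf.triangles, labels


def _fmt(arr, per_line=1):
    arr = np.asarray(arr)
    flat = arr.reshape(arr.shape[0], -1)
    return "\n".join(" ".join(repr(float(x)) for x in row) for row in flat)


def write_vtu(path, mesh: VolumeMesh, fields: FieldSet | None = None) -> None:
    tris, labels = _boundary_cells(mesh)
    ntet, ntri = mesh.tets.shape[0], tris.shape[0]
    conn = np.concatenate([mesh.tets.ravel(), tris.ravel()])
    offsets = np.concatenate(
        [4 * np.arange(1, ntet + 1), 4 * ntet + 3 * np.arange(1, ntri + 1)]
    )
    types = np.concatenate([np.full(ntet, 10), np.full(ntri, 5)])
    cap_id = np.concatenate([np.full(ntet, -1), labels])

    root = ET.Element(
        "VTKFile", type="UnstructuredGrid", version="0.1", byte_order="LittleEndian"
    )
    ug = ET.SubElement(root, "UnstructuredGrid")
    piece = ET.SubElement(
        ug,
        "Piece",
        NumberOfPoints=str(mesh.node_count),
        NumberOfCells=str(ntet + ntri),
    )
    pts = ET.SubElement(piece, "Points")
    da = ET.SubElement(
        pts, "DataArray", type="Float64", NumberOfComponents="3", format="ascii"
    )
    da.text = _fmt(mesh.nodes)
    cells = ET.SubElement(piece, "Cells")
    for name, data in [("connectivity", conn), ("offsets", offsets), ("types", types)]:
        da = ET.SubElement(cells, "DataArray", type="Int64", Name=name, format="ascii")
        da.text = " ".join(str(int(x)) for x in data)
    cd = ET.SubElement(piece, "CellData")
    da = ET.SubElement(cd, "DataArray", type="Int32", Name="cap_id", format="ascii")
    da.text = " ".join(str(int(x)) for x in cap_id)
    if fields is not None:
        pd = ET.SubElement(piece, "PointData")
        da = ET.SubElement(
            pd, "DataArray", type="Float64", Name="pressure", format="ascii"
        )
        da.text = _fmt(fields.pressure.reshape(-1, 1))
        da = ET.SubElement(
            pd,
            "DataArray",
            type="Float64",
            Name="velocity",
            NumberOfComponents="3",
            format="ascii",
        )
        da.text = _fmt(fields.velocity)
    ET.ElementTree(root).write(path, xml_declaration=True, encoding="unicode")


def _parse(text, dtype=np.float64):
    return np.array(text.split(), dtype=dtype)


def read_vtu(path):
    """Read a .vtu written by :func:`write_vtu` -> (VolumeMesh, FieldSet|None)."""
    root = ET.parse(path).getroot()
    piece = root.find(".//Piece")
    nodes = _parse(piece.find("Points/DataArray").text).reshape(-1, 3)
    arrays = {da.get("Name"): da for da in piece.findall("Cells/DataArray")}
    conn = _parse(arrays["connectivity"].text, np.int64)
    offsets = _parse(arrays["offsets"].text, np.int64)
    types = _parse(arrays["types"].text, np.int64)
    cap_da = piece.find("CellData/DataArray[@Name='cap_id']")
    cap_id = (
        _parse(cap_da.text, np.int64)
        if cap_da is not None
        else np.full(types.shape[0], -1)
    )
    starts = np.concatenate([[0], offsets[:-1]])
    tets, caps = [], {}
    for start, end, ctype, label in zip(starts, offsets, types, cap_id):
        cell = conn[start:end]
        if ctype == 10:
            tets.append(cell)
        elif ctype == 5 and label in CAP_NAMES:
            caps.setdefault(CAP_NAMES[label], []).append(cell)
    mesh = VolumeMesh(nodes, np.array(tets), {k: np.array(v) for k, v in caps.items()})
    fields = None
    pd = piece.find("PointData")
    if pd is not None:
        named = {da.get("Name"): da for da in pd.findall("DataArray")}
        if "pressure" in named and "velocity" in named:
            fields = FieldSet(
                _parse(named["pressure"].text),
                _parse(named["velocity"].text).reshape(-1, 3),
            )
    return mesh, fields


def write_vtk_legacy(path, mesh: VolumeMesh, fields: FieldSet | None = None) -> None:
    tris, labels = _boundary_cells(mesh)
    ntet, ntri = mesh.tets.shape[0], tris.shape[0]
    lines = [
        "# vtk DataFile Version 3.0",
        "volume mesh",
        "ASCII",
        "DATASET UNSTRUCTURED_GRID",
        f"POINTS {mesh.node_count} double",
    ]
    lines += [" ".join(repr(float(x)) for x in row) for row in mesh.nodes]
    ncell = ntet + ntri
    lines.append(f"CELLS {ncell} {5 * ntet + 4 * ntri}")
    lines += ["4 " + " ".join(str(int(v)) for v in t) for t in mesh.tets]
    lines += ["3 " + " ".join(str(int(v)) for v in t) for t in tris]
    lines.append(f"CELL_TYPES {ncell}")
    lines += ["10"] * ntet + ["5"] * ntri
    lines.append(f"CELL_DATA {ncell}")
    lines.append("SCALARS cap_id int 1")
    lines.append("LOOKUP_TABLE default")
    lines += ["-1"] * ntet + [str(int(x)) for x in labels]
    if fields is not None:
        lines.append(f"POINT_DATA {mesh.node_count}")
        lines.append("SCALARS pressure double 1")
        lines.append("LOOKUP_TABLE default")
        lines += [repr(float(x)) for x in fields.pressure]
        lines.append("VECTORS velocity double")
        lines += [" ".join(repr(float(x)) for x in row) for row in fields.velocity]
    Path(path).write_text("\n".join(lines) + "\n")


def read_vtk_legacy(path):
    tokens = Path(path).read_text().split("\n")
    it = iter(tokens)
    nodes = tets = None
    caps: dict[str, list] = {}
    tris = []
    fields_p = fields_v = None
    line = next(it)
    while True:
        try:
            if line.startswith("POINTS"):
                n = int(line.split()[1])
                nodes = np.array(
                    [[float(x) for x in next(it).split()] for _ in range(n)]
                )
            elif line.startswith("CELLS"):
                ncell = int(line.split()[1])
                cells = [[int(x) for x in next(it).split()] for _ in range(ncell)]
                tets = np.array([c[1:] for c in cells if c[0] == 4], dtype=np.int64)
                tris = [c[1:] for c in cells if c[0] == 3]
            elif line.startswith("SCALARS cap_id"):
                next(it)  # LOOKUP_TABLE
                labels = [int(next(it)) for _ in range(tets.shape[0] + len(tris))]
                for tri, lab in zip(tris, labels[tets.shape[0] :]):
                    if lab in CAP_NAMES:
                        caps.setdefault(CAP_NAMES[lab], []).append(tri)
            elif line.startswith("SCALARS pressure"):
                next(it)
                fields_p = np.array([float(next(it)) for _ in range(nodes.shape[0])])
            elif line.startswith("VECTORS velocity"):
                fields_v = np.array(
                    [[float(x) for x in next(it).split()] for _ in range(nodes.shape[0])]
                )
            line = next(it)
        except StopIteration:
            break
    mesh = VolumeMesh(nodes, tets, {k: np.array(v) for k, v in caps.items()})
    fields = (
        FieldSet(fields_p, fields_v)
        if fields_p is not None and fields_v is not None
        else None
    )
    return mesh, fields


def write_mesh(path, mesh: VolumeMesh, fields: FieldSet | None = None) -> None:
    path = Path(path)
    if path.suffix == ".vtu":
        write_vtu(path, mesh, fields)
    elif path.suffix == ".vtk":
        write_vtk_legacy(path, mesh, fields)
    else:
        raise ValueError(f"unsupported mesh format: {path.suffix}")


def read_mesh(path):
    path = Path(path)
    if path.suffix == ".vtu":
        return read_vtu(path)
    if path.suffix == ".vtk":
        return read_vtk_legacy(path)
    raise ValueError(f"unsupported mesh format: {path.suffix}")


# ---------------------------------------------------------------------------
# NIfTI images
# ---------------------------------------------------------------------------


def write_nifti(path, image: ImageVolume, dtype=None) -> None:
    data = image.voxels if dtype is None else image.voxels.astype(dtype)
    affine = np.diag([image.spacing] * 3 + [1.0])
    affine[:3, 3] = image.origin
    img = nib.Nifti1Image(np.asarray(data), affine)
    img.header.set_zooms((image.spacing,) * 3)
    nib.save(img, str(path))


def read_nifti(path) -> ImageVolume:
    img = nib.load(str(path))
    spacing = float(img.header.get_zooms()[0])
    origin = np.asarray(img.affine[:3, 3], dtype=np.float64)
    return ImageVolume(np.asarray(img.dataobj), spacing=spacing, origin=origin)
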