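"""Surface-mesh and table I/O.

All format dialect handling (STL binary/ASCII, PLY, CSV) lives here, backed
by :mod:`trimesh` for the mesh formats and :mod:`pandas` for tables.  The
rest of the package only ever sees :class:`SurfaceMesh` and DataFrames.

Units are assumed to be millimetres; STL carries no unit metadata, so a mesh
whose longest extent is below 1 (metres suspected) is rescaled by 1000 with
a warning on stderr.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import trimesh

from .errors import EmptyMeshError, MeshFormatError

log = logging.getLogger("femoromorph")

#: canonical column order for parameter tables (descriptive-table order).
PARAMETER_ORDER = [
    "FHD", "OSA", "OSV", "OSH", "ATA", "NSA",
    "GTH", "TFL", "NCDF", "NCDS", "NCVD", "NCHD",
]

TABLE_COLUMNS = ["specimen_id", "side"] + PARAMETER_ORDER


@dataclass(frozen=True)
class SurfaceMesh:
    """A triangulated bone surface in millimetres.

    Invariants (enforced by :func:`clean_mesh`): at least 4 vertices, valid
    face indices, no degenerate triangles, finite coordinates.
    """

    vertices: np.ndarray                    # (n, 3) float64, mm
    faces: np.ndarray                       # (m, 3) int
    source_path: str = "<memory>"
    side_hint: str = "unknown"              # {left, right, unknown}

    def __post_init__(self):
        object.__setattr__(self, "vertices", np.asarray(self.vertices, dtype=float))
        object.__setattr__(self, "faces", np.asarray(self.faces, dtype=np.int64))

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    @property
    def extents(self) -> np.ndarray:
        return self.vertices.max(axis=0) - self.vertices.min(axis=0)

    def to_trimesh(self) -> trimesh.Trimesh:
        return trimesh.Trimesh(vertices=self.vertices.copy(),
                               faces=self.faces.copy(), process=False)

    @classmethod
    def from_trimesh(cls, tm: trimesh.Trimesh, source_path: str = "<memory>",
                     side_hint: str = "unknown") -> "SurfaceMesh":
        return cls(vertices=np.asarray(tm.vertices, dtype=float),
                   faces=np.asarray(tm.faces, dtype=np.int64),
                   source_path=source_path, side_hint=side_hint)

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "SurfaceMesh":
        """Rigidly transformed copy (vertices @ R.T + t)."""
        return replace(self, vertices=self.vertices @ np.asarray(rotation).T
                       + np.asarray(translation, dtype=float))


@dataclass(frozen=True)
class ValidationReport:
    """Report-only mesh diagnostics; never raises."""

    watertight: bool
    n_vertices: int
    n_faces: int
    extents: np.ndarray                     # (3,) bounding-box extents, mm
    longest_extent: float
    scale_plausible: bool                   # femur-scale: longest in [300, 600] mm
    messages: tuple = field(default_factory=tuple)


def clean_mesh(mesh: SurfaceMesh) -> SurfaceMesh:
    """Merge duplicate vertices, drop degenerate faces and unreferenced
    vertices.  Idempotent.  Raises :class:`EmptyMeshError` if fewer than
    four vertices remain."""
    tm = trimesh.Trimesh(vertices=mesh.vertices, faces=mesh.faces, process=False)
    tm.merge_vertices()
    tm.update_faces(tm.nondegenerate_faces(height=1e-9))
    tm.remove_unreferenced_vertices()
    if len(tm.vertices) < 4 or len(tm.faces) < 1:
        raise EmptyMeshError(
            f"{mesh.source_path}: fewer than 4 vertices after cleaning")
    if not np.all(np.isfinite(tm.vertices)):
        raise MeshFormatError(f"{mesh.source_path}: non-finite coordinates")
    return SurfaceMesh.from_trimesh(tm, mesh.source_path, mesh.side_hint)


def read_mesh(path: str, expected_units: str = "mm",
              side_hint: str = "unknown") -> SurfaceMesh:
    """Read an STL (binary or ASCII) or PLY surface and clean it.

    Parameters
    ----------
    path : str
        Path to the mesh file; format inferred from the extension.
    expected_units : {"mm"}
        Only millimetres are supported; a mesh whose longest extent is < 1
        is assumed to be in metres and rescaled ×1000 (warning logged).
    side_hint : {"left", "right", "unknown"}
        Optional provenance annotation; never inferred here.
    """
    if expected_units != "mm":
        raise ValueError("only millimetre meshes are supported")
    if not os.path.exists(path):
        raise MeshFormatError(f"no such file: {path}")
    try:
        tm = trimesh.load(path, force="mesh", process=False)
    except Exception as exc:                              # noqa: BLE001
        raise MeshFormatError(f"unreadable mesh file {path}: {exc}") from exc
    if not isinstance(tm, trimesh.Trimesh) or len(tm.vertices) == 0:
        raise MeshFormatError(f"{path}: no triangulated surface found")
    mesh = SurfaceMesh.from_trimesh(tm, source_path=str(path), side_hint=side_hint)
    mesh = clean_mesh(mesh)
    if float(mesh.extents.max()) < 1.0:
        log.warning("%s: longest extent %.4f < 1; assuming metres, rescaling x1000",
                    path, float(mesh.extents.max()))
        mesh = replace(mesh, vertices=mesh.vertices * 1000.0)
    return mesh


def write_mesh(mesh: SurfaceMesh, path: str, *, ascii_stl: bool = False) -> str:
    """Write a mesh as STL (``.stl``) or ASCII PLY (``.ply``)."""
    tm = mesh.to_trimesh()
    ext = os.path.splitext(path)[1].lower()
    if ext == ".stl":
        data = trimesh.exchange.stl.export_stl_ascii(tm) if ascii_stl \
            else trimesh.exchange.stl.export_stl(tm)
    elif ext == ".ply":
        data = trimesh.exchange.ply.export_ply(tm, encoding="ascii")
    else:
        raise MeshFormatError(f"unsupported mesh extension: {ext}")
    mode = "w" if isinstance(data, str) else "wb"
    with open(path, mode) as fh:
        fh.write(data)
    return path


def validate_mesh(mesh: SurfaceMesh) -> ValidationReport:
    """Report watertightness, extents and femur-scale plausibility.

    Non-watertight meshes are accepted (CT segmentations often leak) but
    flagged; only operations needing enclosed volume should refuse them.
    """
    tm = mesh.to_trimesh()
    extents = mesh.extents
    longest = float(extents.max())
    plausible = 300.0 <= longest <= 600.0
    msgs = []
    if not tm.is_watertight:
        msgs.append("mesh is not watertight")
    if not plausible:
        msgs.append(f"longest extent {longest:.1f} mm outside femur range [300, 600]")
    return ValidationReport(
        watertight=bool(tm.is_watertight),
        n_vertices=mesh.n_vertices,
        n_faces=mesh.n_faces,
        extents=extents,
        longest_extent=longest,
        scale_plausible=plausible,
        messages=tuple(msgs),
    )


def write_table(rows: pd.DataFrame | Sequence[dict], path: str) -> str:
    """Write a parameter table as CSV in the canonical column order.

    Accepts a DataFrame or a sequence of row dicts; missing canonical
    columns are left out, extra columns are appended after the canonical
    ones.  Decimal separator is always a dot.
    """
    df = rows if isinstance(rows, pd.DataFrame) else pd.DataFrame(list(rows))
    if df.empty and not len(df.columns):
        df = pd.DataFrame(columns=TABLE_COLUMNS)
    ordered = [c for c in TABLE_COLUMNS if c in df.columns]
    ordered += [c for c in df.columns if c not in ordered]
    df[ordered].to_csv(path, index=False, float_format="%.9f")
    return path


def read_table(path: str) -> pd.DataFrame:
    """Read a parameter CSV written by :func:`write_table`."""
    return pd.read_csv(path)
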