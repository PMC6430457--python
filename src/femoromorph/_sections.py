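"""Planar cross-sections of a surface mesh.

:func:`trimesh.intersections.mesh_multiplane` supplies the raw 2-D line
segments per plane; the segments are chained into closed loops here and
each loop becomes a shapely polygon, so sections work without any spatial
index dependency.  Sections of a closed surface always chain into closed
loops; stray open chains (numerical slivers) are discarded.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional

import numpy as np
import trimesh
from shapely.geometry import Point, Polygon

from .mesh_io import SurfaceMesh


@dataclass(frozen=True)
class Section:
    """One planar cross-section polygon."""

    height: float               # offset along the slicing normal
    area: float                 # mm^2
    centroid: np.ndarray        # (3,) area centroid in mesh coordinates
    centroid_2d: np.ndarray     # (2,) in plane coordinates
    n_polygons: int


def _chain_loops(segments: np.ndarray, tol: float = 1e-6) -> List[np.ndarray]:
    """Chain (n, 2, 2) segments into closed 2-D loops.

    Endpoints are matched by rounding to ``tol``; chains that do not close
    are dropped.
    """
    if len(segments) == 0:
        return []
    key = lambda p: (round(p[0] / tol), round(p[1] / tol))   # noqa: E731
    adjacency: dict = {}
    for i, seg in enumerate(segments):
        for end in (0, 1):
            adjacency.setdefault(key(seg[end]), []).append((i, end))
    used = np.zeros(len(segments), dtype=bool)
    loops = []
    for start in range(len(segments)):
        if used[start]:
            continue
        used[start] = True
        loop = [segments[start][0], segments[start][1]]
        start_key = key(loop[0])
        closed = False
        for _ in range(len(segments)):
            tail = key(loop[-1])
            if tail == start_key and len(loop) > 2:
                closed = True
                break
            nxt = None
            for i, end in adjacency.get(tail, ()):
                if not used[i]:
                    nxt = (i, end)
                    break
            if nxt is None:
                break
            i, end = nxt
            used[i] = True
            loop.append(segments[i][1 - end])
        if closed and len(loop) >= 4:
            loops.append(np.asarray(loop[:-1]))
    return loops


def _polygons_of(lines_2d: np.ndarray) -> List[Polygon]:
    polys = []
    for loop in _chain_loops(np.asarray(lines_2d)):
        try:
            poly = Polygon(loop)
        except Exception:                                    # noqa: BLE001
            continue
        if poly.is_valid and poly.area > 1e-9:
            polys.append(poly)
    return polys


def cross_sections(mesh: SurfaceMesh, origin: np.ndarray, normal: np.ndarray,
                   heights: np.ndarray, *, station_2d: bool = False,
                   fallback_mm: float = 0.0) -> list:
    """Cut the mesh with the planes ``origin + h * normal``.

    Returns one :class:`Section` (or None) per height.  By default the
    largest closed polygon of each plane is used; with ``station_2d`` the
    smallest polygon containing the station point ``origin + h * normal``
    is preferred — that is what the neck-axis fit needs, where the largest
    polygon may be the shaft.  When no polygon contains the station and
    ``fallback_mm`` is positive, the polygon whose centroid lies within
    that distance of the station is accepted instead (closest first).
    """
    tm = mesh.to_trimesh()
    origin = np.asarray(origin, dtype=float)
    normal = np.asarray(normal, dtype=float)
    heights = np.asarray(heights, dtype=float)
    lines, transforms, _ = trimesh.intersections.mesh_multiplane(
        tm, origin, normal, heights)
    out = []
    for h, segs, T in zip(heights, lines, transforms):
        polys = _polygons_of(segs)
        if not polys:
            out.append(None)
            continue
        Tinv = np.linalg.inv(T)
        chosen = None
        if station_2d:
            st = Tinv @ np.append(origin + h * normal, 1.0)
            station = Point(st[0], st[1])
            containing = [p for p in polys if p.contains(station)]
            if containing:
                chosen = min(containing, key=lambda p: p.area)
            elif fallback_mm > 0:
                near = min(polys, key=lambda p: p.centroid.distance(station))
                if near.centroid.distance(station) <= fallback_mm:
                    chosen = near
            if chosen is None:
                out.append(None)
                continue
        if chosen is None:
            chosen = max(polys, key=lambda p: p.area)
        c2 = np.array([chosen.centroid.x, chosen.centroid.y])
        c3 = (T @ np.array([c2[0], c2[1], 0.0, 1.0]))[:3]
        out.append(Section(height=float(h), area=float(chosen.area),
                           centroid=c3, centroid_2d=c2, n_polygons=len(polys)))
    return out
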