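"""Femoral head sphere and neck axis.

The femoral head centre (FHC) and diameter (FHD) come from a robust
best-fit sphere to the proximal-medial surface: an algebraic least-squares
seed, RANSAC inlier search, and a final least-squares pass on the inliers.
The femoral neck axis (FNA) is the total-least-squares line through neck
cross-section centroids between the head surface and the trochanteric
junction.  The four head-centre eccentricity parameters (NCVD, NCHD signed;
NCDF, NCDS non-negative) measure how far the FHC sits off the FNA.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from typing import Optional, Union

import numpy as np

from . import _geom as g
from ._sections import cross_sections
from .anatomical_frame import AnatomicalFrame, Line3, shaft_radius_estimate
from .config import DEFAULT_CONFIG, MeasurementConfig
from .errors import (HeadFitError, InsufficientGeometryError,
                     LandmarkNotFoundError)
from .mesh_io import SurfaceMesh


@dataclass(frozen=True)
class Sphere:
    """Best-fit sphere; centre is the femoral head centre (FHC)."""

    center: np.ndarray
    radius: float
    inlier_fraction: float = 1.0

    def __post_init__(self):
        object.__setattr__(self, "center", np.asarray(self.center, dtype=float))
        if self.radius <= 0:
            raise ValueError("sphere radius must be positive")

    @property
    def diameter(self) -> float:
        return 2.0 * self.radius


@dataclass(frozen=True)
class NeckOffsets:
    """Head-centre eccentricity off the neck axis.

    ncds/ncdf are non-negative in-plane (sagittal/frontal) distances;
    ncvd is signed cranial(+)/caudal(-), nchd signed anterior(+)/posterior(-).
    """

    ncds: float
    ncdf: float
    ncvd: float
    nchd: float

    def __post_init__(self):
        if self.ncds < 0 or self.ncdf < 0:
            raise ValueError("projected neck distances must be non-negative")


def _mesh_seed(mesh: SurfaceMesh) -> int:
    h = hashlib.sha256(np.ascontiguousarray(mesh.vertices).tobytes()).digest()
    return int.from_bytes(h[:4], "little") % (2 ** 31)


def fit_sphere_points(points: np.ndarray, config: MeasurementConfig = DEFAULT_CONFIG,
                      seed: Optional[int] = None) -> Sphere:
    """Robust sphere fit to a point cloud.

    Algebraic least-squares seed, then RANSAC (4-point hypotheses,
    ``config.ransac_iters`` draws, inlier band ``config.inlier_band_mm``),
    then a final algebraic least-squares on the best inlier set, refined
    once by recomputing the inliers.
    """
    pts = np.asarray(points, dtype=float)
    if len(pts) < 4:
        raise LandmarkNotFoundError("femoral_head", "fewer than 4 candidate points")
    rng = np.random.default_rng(seed)

    def inliers_of(center, radius):
        err = np.abs(np.linalg.norm(pts - center, axis=1) - radius)
        return err < config.inlier_band_mm

    best_center, best_radius = g.fit_sphere_algebraic(pts)
    best_in = inliers_of(best_center, best_radius)
    for _ in range(config.ransac_iters):
        idx = rng.choice(len(pts), size=4, replace=False)
        try:
            c, r = g.fit_sphere_algebraic(pts[idx])
        except (ValueError, np.linalg.LinAlgError):
            continue
        if not (5.0 < r < 200.0):
            continue
        inl = inliers_of(c, r)
        if inl.sum() > best_in.sum():
            best_center, best_radius, best_in = c, r, inl
    # final least squares on inliers, one re-selection pass
    for _ in range(2):
        if best_in.sum() < 4:
            break
        best_center, best_radius = g.fit_sphere_algebraic(pts[best_in])
        best_in = inliers_of(best_center, best_radius)
    return Sphere(center=best_center, radius=float(best_radius),
                  inlier_fraction=float(best_in.mean()))


def fit_head_sphere(mesh: SurfaceMesh, frame: Union[AnatomicalFrame, Line3],
                    config: MeasurementConfig = DEFAULT_CONFIG,
                    seed: Optional[int] = None) -> Sphere:
    """Fit the femoral-head sphere (FHC, FHD = 2 radius).

    The candidate region is the proximal-medial vertex cloud: vertices in
    the superior ``config.head_region_fraction`` of the bone length and on
    the medial side of the shaft axis.  ``frame`` may be the anatomical
    frame or, during pipeline bootstrap, just the shaft axis — in the
    latter case the medial side is estimated from the proximal-slab
    centroid (head mass dominates).  Raises :class:`HeadFitError` if the
    inlier fraction ends up at or below ``config.min_inlier_fraction``.
    """
    verts = mesh.vertices
    if isinstance(frame, AnatomicalFrame):
        si = frame.axis_si
        medial = frame.axis_ml
        # recover a line through the diaphysis from the band centroid
        proj0 = verts @ si
        band = (proj0 > proj0.min() + 0.5 * np.ptp(proj0)) \
            & (proj0 < proj0.min() + 0.8 * np.ptp(proj0))
        centre = verts[band].mean(axis=0)
        shaft_line = Line3(centre, si)
    else:
        shaft_line = frame
        si = frame.direction
        proj0 = (verts - frame.point) @ si
        slab = proj0 > proj0.max() - config.head_region_fraction * np.ptp(proj0)
        off = verts[slab].mean(axis=0) - frame.point
        medial = off - (off @ si) * si
        if np.linalg.norm(medial) < 1e-6:
            raise LandmarkNotFoundError("femoral_head", "no medial asymmetry")
        medial = g.unit(medial)

    axis_point = shaft_line.point
    proj = (verts - axis_point) @ si
    lo, hi = proj.min(), proj.max()
    radial = g.point_line_distance(verts, shaft_line.point, shaft_line.direction)
    r_shaft = shaft_radius_estimate(mesh, shaft_line, config)
    region = ((proj > hi - config.head_region_fraction * (hi - lo))
              & ((verts - axis_point) @ medial > 0)
              & (radial > 1.1 * r_shaft))      # drop the medial shaft sliver
    if region.sum() < 4:
        raise LandmarkNotFoundError("femoral_head", "empty proximal-medial region")
    if seed is None:
        seed = _mesh_seed(mesh)
    sphere = fit_sphere_points(verts[region], config=config, seed=seed)
    if sphere.inlier_fraction <= config.min_inlier_fraction:
        raise HeadFitError(
            f"head not spherical: inlier fraction {sphere.inlier_fraction:.2f} "
            f"<= {config.min_inlier_fraction}")
    return sphere


def estimate_neck_axis(mesh: SurfaceMesh, frame: Optional[AnatomicalFrame],
                       head: Sphere, shaft: Line3,
                       config: MeasurementConfig = DEFAULT_CONFIG) -> Line3:
    """Fit the femoral neck axis (FNA), oriented from shaft toward head.

    Initial direction: the head-centre offset from the shaft axis, raised
    by a population-typical neck elevation of ~37 deg above the transversal
    plane (for a coaxial degenerate neck, the shaft direction itself); the
    iteration then converges to the bone's actual obliquity.  Cross-
    sections are taken perpendicular to the current direction from just
    outside the head sphere toward the trochanteric junction; the polygon
    containing the station point is used so the shaft body never leaks into
    the fit.  A total-least-squares line through the section centroids is
    refit ``config.neck_iterations`` times.

    ``frame`` is unused by the estimate itself (the axis is frame-free) and
    accepted for interface symmetry.
    """
    fhc = head.center
    p0 = shaft.project(fhc)
    offset = fhc - p0
    if np.linalg.norm(offset) < 1.0:
        # coaxial degenerate neck: head-ward along the shaft axis
        direction = shaft.direction
        if (fhc - mesh.vertices.mean(axis=0)) @ direction < 0:
            direction = -direction
    else:
        direction = g.unit(0.8 * g.unit(offset) + 0.6 * shaft.direction)

    t0 = config.neck_start_factor * head.radius
    t_max = max(np.linalg.norm(offset) + head.radius, t0 + 10.0)

    def collect(u, spacing):
        heights = np.arange(t0, t_max, spacing)
        secs = cross_sections(mesh, fhc, u, heights, station_2d=True,
                              fallback_mm=0.6 * head.radius)
        kept = []
        min_area = np.inf
        for s in secs:
            if s is None:
                continue
            if s.area > config.neck_area_flare * min_area:
                break                           # junction flare
            min_area = min(min_area, s.area)
            kept.append(s)
        return kept

    for _ in range(1 + config.neck_iterations):
        u = -direction                          # head -> shaft
        kept = []
        for divisor in (1.0, 2.0, 3.0):         # short necks: refine spacing
            kept = collect(u, config.neck_section_spacing_mm / divisor)
            if len(kept) >= config.min_neck_sections:
                break
        if len(kept) < config.min_neck_sections:
            raise InsufficientGeometryError(
                f"only {len(kept)} valid neck sections")
        centroids = np.array([s.centroid for s in kept])
        point, new_dir = g.fit_line_tls(centroids)
        # centroids of sections grazing the trochanteric junction sit off
        # the neck corridor; trim residual outliers and refit
        res = g.point_line_distance(centroids, point, new_dir)
        keep = res <= max(3.0 * float(np.median(res)), 0.15)
        if config.min_neck_sections <= keep.sum() < len(kept):
            point, new_dir = g.fit_line_tls(centroids[keep])
        if np.dot(new_dir, direction) < 0:
            new_dir = -new_dir
        direction = new_dir
    return Line3(point, direction)


def neck_center_offsets(fhc: np.ndarray, fna: Line3,
                        frame: AnatomicalFrame) -> NeckOffsets:
    """The four head-centre offsets relative to the neck axis.

    Let P be the projection of the FHC onto the FNA and d = FHC - P.
    ncvd = d . axis_si (cranial +), nchd = d . axis_ap (anterior +);
    ncdf/ncds are the 2-D point-to-line distances after projecting both the
    FHC and the FNA into the frontal / sagittal plane respectively.
    """
    fhc = np.asarray(fhc, dtype=float)
    d = fhc - fna.project(fhc)
    ncvd = float(d @ frame.axis_si)
    nchd = float(d @ frame.axis_ap)

    def plane_distance(ax_a, ax_b):
        p2 = np.array([fhc @ ax_a, fhc @ ax_b])
        o2 = np.array([fna.point @ ax_a, fna.point @ ax_b])
        d2 = np.array([fna.direction @ ax_a, fna.direction @ ax_b])
        return g.point_line_distance_2d(p2, o2, d2)

    ncdf = plane_distance(frame.axis_ml, frame.axis_si)   # frontal plane
    ncds = plane_distance(frame.axis_ap, frame.axis_si)   # sagittal plane
    return NeckOffsets(ncds=float(ncds), ncdf=float(ncdf), ncvd=ncvd, nchd=nchd)
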