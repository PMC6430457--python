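"""Anatomical coordinate frame, shaft axis and bony landmarks.

The frame follows the standard biomechanics convention for a femur measured
in its own coordinates: superior (+) along the diaphyseal axis, medial (+)
from the posterior-condylar line toward the head, anterior (+) completing
the triple so that the posterior condyles lie behind the shaft.  Left and
right femurs are both measured with these signs (no mirroring), which makes
every reported parameter side-independent; the side itself is recovered
from the handedness of the axis triple (right femur -> right-handed).

The shaft axis is the total-least-squares line through diaphyseal
cross-section area centroids in a band of the bone's length measured from
the distal end, iterated to a fixed point from a whole-bone principal-axis
seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from . import _geom as g
from ._sections import cross_sections
from .config import DEFAULT_CONFIG, MeasurementConfig
from .errors import (DegenerateFrameError, InsufficientGeometryError,
                     LandmarkNotFoundError)
from .mesh_io import SurfaceMesh


@dataclass(frozen=True)
class Line3:
    """An oriented 3-D line: anchor point + unit direction."""

    point: np.ndarray
    direction: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "point", np.asarray(self.point, dtype=float))
        object.__setattr__(self, "direction", g.unit(self.direction))

    def distance_to(self, p: np.ndarray) -> float:
        return g.point_line_distance(p, self.point, self.direction)

    def project(self, p: np.ndarray) -> np.ndarray:
        return g.project_point_on_line(p, self.point, self.direction)

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "Line3":
        R = np.asarray(rotation, dtype=float)
        return Line3(R @ self.point + np.asarray(translation, dtype=float),
                     R @ self.direction)


@dataclass(frozen=True)
class AnatomicalFrame:
    """Origin (most distal point) plus the three anatomical axes.

    frontal plane  = span(axis_si, axis_ml)
    sagittal plane = span(axis_si, axis_ap)
    transversal    = span(axis_ml, axis_ap)
    """

    origin: np.ndarray
    axis_si: np.ndarray     # superior +
    axis_ap: np.ndarray     # anterior +
    axis_ml: np.ndarray     # medial +
    side: str               # {left, right}

    def __post_init__(self):
        for name in ("origin", "axis_si", "axis_ap", "axis_ml"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float))
        for a, b in (("axis_si", "axis_ap"), ("axis_si", "axis_ml"),
                     ("axis_ap", "axis_ml")):
            if abs(np.dot(getattr(self, a), getattr(self, b))) > 1e-9:
                raise ValueError(f"frame axes {a}/{b} not orthogonal")
        for a in ("axis_si", "axis_ap", "axis_ml"):
            if abs(np.linalg.norm(getattr(self, a)) - 1.0) > 1e-9:
                raise ValueError(f"frame axis {a} not unit length")

    @property
    def handedness(self) -> float:
        """+1 for a right-handed (ml, ap, si) triple, -1 otherwise."""
        return float(np.sign(np.dot(np.cross(self.axis_ml, self.axis_ap), self.axis_si)))

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "AnatomicalFrame":
        R = np.asarray(rotation, dtype=float)
        t = np.asarray(translation, dtype=float)
        return AnatomicalFrame(R @ self.origin + t, R @ self.axis_si,
                               R @ self.axis_ap, R @ self.axis_ml, self.side)


@dataclass(frozen=True)
class Landmarks:
    """Bony landmark points used by the parameter definitions."""

    most_proximal: np.ndarray
    most_distal: np.ndarray
    gt_apex: np.ndarray          # apex of the greater trochanter
    lt_center: np.ndarray        # centre of the lesser trochanter
    condyle_medial: np.ndarray   # posterior extreme, medial distal quarter
    condyle_lateral: np.ndarray  # posterior extreme, lateral distal quarter


# ---------------------------------------------------------------------------
# shaft axis
# ---------------------------------------------------------------------------

def _extreme_index(values: np.ndarray, maximum: bool, tol: float = 1e-6) -> int:
    """Index of the extreme value; ties broken by lowest vertex index."""
    ext = values.max() if maximum else values.min()
    close = np.flatnonzero(np.abs(values - ext) <= tol)
    return int(close[0])


def _orient_superior(vertices: np.ndarray, point: np.ndarray,
                     direction: np.ndarray) -> np.ndarray:
    """Pick the superior sign of a shaft-axis direction.

    The proximal end of a femur carries the head, whose apex sits farther
    off the shaft axis (the femoral offset, >= ~28 mm) than any distal
    extreme (condyle undersides, ~23 mm).  When the cue is ambiguous
    (within 1 mm, e.g. a plain cylinder) the sign making the largest
    direction component positive is used, purely for determinism.
    """
    proj = (vertices - point) @ direction
    top = vertices[int(np.argmax(proj))]
    bot = vertices[int(np.argmin(proj))]
    r_top = g.point_line_distance(top, point, direction)
    r_bot = g.point_line_distance(bot, point, direction)
    if abs(r_top - r_bot) < 1.0:
        k = int(np.argmax(np.abs(direction)))
        return direction if direction[k] > 0 else -direction
    return direction if r_top > r_bot else -direction


def estimate_shaft_axis(mesh: SurfaceMesh,
                        fraction_range: Optional[tuple] = None,
                        config: MeasurementConfig = DEFAULT_CONFIG,
                        orientation_hint: Optional[np.ndarray] = None) -> Line3:
    """Fit the femoral shaft axis (FSA).

    Iterates: provisional axis (whole-mesh principal axis) -> provisional
    length -> diaphysis band selection (``fraction_range`` of the length
    from the distal end) -> cross-section area centroids at fixed spacing ->
    total-least-squares refit, until the direction changes by less than
    ``config.convergence_deg`` or ``config.max_axis_iterations`` is hit.

    The returned direction points superior; ``orientation_hint`` (any
    vector with positive dot product onto superior) overrides the built-in
    head-offset heuristic.
    """
    f0, f1 = fraction_range if fraction_range is not None else config.fraction_range
    if not (0.0 <= f0 < f1 <= 1.0):
        raise ValueError("fraction_range must satisfy 0 <= lo < hi <= 1")
    verts = mesh.vertices
    point, direction = g.fit_line_tls(verts)
    if orientation_hint is not None:
        if np.dot(direction, orientation_hint) < 0:
            direction = -direction
    else:
        direction = _orient_superior(verts, point, direction)

    for _ in range(config.max_axis_iterations):
        proj = (verts - point) @ direction
        lo, hi = proj.min(), proj.max()
        length = hi - lo
        band_lo = lo + f0 * length
        band_hi = lo + f1 * length
        origin = point + band_lo * direction
        heights = np.arange(0.0, band_hi - band_lo, config.section_spacing_mm)
        secs = [s for s in cross_sections(mesh, origin, direction, heights)
                if s is not None]
        if secs:
            # sections grazing the trochanters or condyles show an area
            # jump over the tubular diaphysis; trim them before the fit
            med_area = float(np.median([s.area for s in secs]))
            secs = [s for s in secs if 0.5 * med_area <= s.area <= 1.3 * med_area]
        if len(secs) < config.min_shaft_sections:
            raise InsufficientGeometryError(
                f"only {len(secs)} diaphyseal sections in band ({f0:.2f}, {f1:.2f})")
        centroids = np.array([s.centroid for s in secs])
        new_point, new_dir = g.fit_line_tls(centroids)
        if np.dot(new_dir, direction) < 0:
            new_dir = -new_dir
        change = g.angle_between_deg(new_dir, direction)
        point, direction = new_point, new_dir
        if change < config.convergence_deg:
            break
    return Line3(point, direction)


def shaft_radius_estimate(mesh: SurfaceMesh, shaft_axis: Line3,
                          config: MeasurementConfig = DEFAULT_CONFIG) -> float:
    """Median radial distance of diaphysis-band vertices from the axis."""
    f0, f1 = config.fraction_range
    proj = (mesh.vertices - shaft_axis.point) @ shaft_axis.direction
    lo, hi = proj.min(), proj.max()
    band = (proj >= lo + f0 * (hi - lo)) & (proj <= lo + f1 * (hi - lo))
    if not band.any():
        raise InsufficientGeometryError("empty diaphysis band")
    return float(np.median(g.point_line_distance(
        mesh.vertices[band], shaft_axis.point, shaft_axis.direction)))


# ---------------------------------------------------------------------------
# landmarks
# ---------------------------------------------------------------------------

def _provisional_directions(mesh: SurfaceMesh, shaft_axis: Line3,
                            head_center: np.ndarray):
    """Provisional medial/posterior unit vectors perpendicular to the shaft.

    The distal quarter of a femur is much wider medio-laterally (two
    condyles) than antero-posteriorly, so its in-plane principal axis gives
    the ML direction; the condylar mass bulges posterior of the shaft axis,
    giving the AP sign; the head-centre offset gives the medial sign.
    """
    d = shaft_axis.direction
    e1, e2 = g.orthonormal_basis_perp(d)
    rel = mesh.vertices - shaft_axis.point
    w = rel @ d
    uv = np.column_stack([rel @ e1, rel @ e2])
    distal = w < w.min() + 0.25 * (w.max() - w.min())
    if distal.sum() < 10:
        raise LandmarkNotFoundError("condyles", "distal quarter nearly empty")
    duv = uv[distal]
    c = duv.mean(axis=0)
    _, _, vt = np.linalg.svd(duv - c, full_matrices=False)
    ml2 = vt[0]
    head2 = np.array([(head_center - shaft_axis.point) @ e1,
                      (head_center - shaft_axis.point) @ e2])
    if head2 @ ml2 < 0:
        ml2 = -ml2
    post2 = c - ml2 * (c @ ml2)          # centroid offset orthogonal to ML
    n = np.linalg.norm(post2)
    if n < 1e-6:
        post2 = np.array([-ml2[1], ml2[0]])
    else:
        post2 = post2 / n
    to3 = lambda v2: v2[0] * e1 + v2[1] * e2      # noqa: E731
    return to3(ml2), to3(post2), e1, e2, uv, w


def detect_landmarks(mesh: SurfaceMesh, shaft_axis: Line3, head_sphere,
                     neck_axis: Optional[Line3] = None,
                     config: MeasurementConfig = DEFAULT_CONFIG) -> Landmarks:
    """Locate the six landmark points.

    ``head_sphere`` is a :class:`femoromorph.head_neck.Sphere`.  When the
    femoral neck axis is supplied, vertices close to it are excluded from
    the trochanter candidate regions; on varus necks the neck-base surface
    can otherwise out-rank the trochanter apex.
    """
    verts = mesh.vertices
    d = shaft_axis.direction
    proj = (verts - shaft_axis.point) @ d
    lo, hi = proj.min(), proj.max()
    length = hi - lo

    most_proximal = verts[_extreme_index(proj, maximum=True)]
    most_distal = verts[_extreme_index(proj, maximum=False)]

    fhc = np.asarray(head_sphere.center, dtype=float)
    r_head = float(head_sphere.radius)
    ml3, post3, e1, e2, uv, w = _provisional_directions(mesh, shaft_axis, fhc)
    ml_coord = (verts - shaft_axis.point) @ ml3
    post_coord = (verts - shaft_axis.point) @ post3
    dist_head = np.linalg.norm(verts - fhc, axis=1)
    radial = g.point_line_distance(verts, shaft_axis.point, shaft_axis.direction)
    if neck_axis is not None:
        dist_neck = g.point_line_distance(verts, neck_axis.point, neck_axis.direction)
    else:
        dist_neck = np.full(len(verts), np.inf)

    # --- condyles: posterior extremes of the medial / lateral distal quarters
    distal = proj < lo + 0.25 * length
    condyles = {}
    for name, sel in (("condyle_medial", distal & (ml_coord > 0)),
                      ("condyle_lateral", distal & (ml_coord < 0))):
        if not sel.any():
            raise LandmarkNotFoundError(name)
        s = post_coord[sel]
        cap = s > s.max() - config.condyle_cap_mm
        condyles[name] = verts[sel][cap].mean(axis=0)

    # --- greater trochanter apex: most superior lateral vertex clear of
    #     head and neck
    gt_sel = ((proj > hi - config.head_region_fraction * length)
              & (ml_coord < 0)
              & (dist_head > config.head_exclusion_factor * r_head)
              & (dist_neck > config.neck_exclusion_mm))
    if not gt_sel.any():
        raise LandmarkNotFoundError("gt_apex")
    gt_idx = np.flatnonzero(gt_sel)
    gt_apex = verts[gt_idx[_extreme_index(proj[gt_sel], maximum=True)]]

    # --- lesser trochanter centre: centroid of the posteromedial protrusion
    band = (proj > lo + config.lt_band[0] * length) & (proj < lo + config.lt_band[1] * length)
    if not band.any():
        raise LandmarkNotFoundError("lt_center", "empty diaphysis band")
    median_radial = float(np.median(radial[band]))
    lt_sel = (band & (ml_coord > 0)
              & (radial > median_radial + config.protrusion_threshold_mm)
              & (dist_head > config.head_exclusion_factor * r_head)
              & (dist_neck > config.neck_exclusion_mm))
    if not lt_sel.any():
        raise LandmarkNotFoundError("lt_center")
    lt_idx = np.flatnonzero(lt_sel)
    seed = verts[lt_idx[int(np.argmax(radial[lt_sel]))]]
    cluster = lt_idx[np.linalg.norm(verts[lt_idx] - seed, axis=1)
                     < config.lt_cluster_radius_mm]
    lt_center = verts[cluster].mean(axis=0)
    # the protrusion is a rounded boss; its best-fit sphere centre is a much
    # better "centre of the lesser trochanter" than the surface centroid
    if len(cluster) >= 10:
        try:
            c, r = g.fit_sphere_algebraic(verts[cluster])
            if r < 2.0 * config.lt_cluster_radius_mm \
                    and np.linalg.norm(c - lt_center) < 2.0 * r:
                lt_center = c
        except (ValueError, np.linalg.LinAlgError):
            pass

    lm = Landmarks(most_proximal=most_proximal, most_distal=most_distal,
                   gt_apex=gt_apex, lt_center=lt_center,
                   condyle_medial=condyles["condyle_medial"],
                   condyle_lateral=condyles["condyle_lateral"])
    if (lm.most_proximal - lm.most_distal) @ d <= 0:
        raise LandmarkNotFoundError("most_proximal",
                                    "proximal point not superior to distal point")
    return lm


# ---------------------------------------------------------------------------
# frame
# ---------------------------------------------------------------------------

def build_frame(mesh: SurfaceMesh, shaft_axis: Line3, landmarks: Landmarks,
                head_center: Optional[np.ndarray] = None,
                config: MeasurementConfig = DEFAULT_CONFIG) -> AnatomicalFrame:
    """Assemble the anatomical frame from shaft axis and landmarks.

    axis_si = shaft direction (superior+); axis_ml = condylar line
    orthogonalised against axis_si, medial+ (toward the head); axis_ap
    completes the triple, anterior+ (posterior condyles behind the axis).
    Side is the handedness of the resulting triple.
    """
    si = shaft_axis.direction
    cline = landmarks.condyle_lateral - landmarks.condyle_medial
    ang = g.angle_between_deg(cline, si)
    if min(ang, 180.0 - ang) < config.min_condyle_angle_deg:
        raise DegenerateFrameError(
            f"condylar line within {config.min_condyle_angle_deg} deg of shaft axis")
    ml = cline - (cline @ si) * si
    ml = g.unit(ml)
    if head_center is None:
        # fall back on the proximal-slab centroid as a head-mass proxy
        proj = (mesh.vertices - shaft_axis.point) @ si
        slab = proj > proj.max() - 0.25 * (proj.max() - proj.min())
        head_center = mesh.vertices[slab].mean(axis=0)
    head_off = head_center - shaft_axis.project(np.asarray(head_center, dtype=float))
    if head_off @ ml < 0:
        ml = -ml
    ap = np.cross(si, ml)
    cond_mid = 0.5 * (landmarks.condyle_medial + landmarks.condyle_lateral)
    cond_off = cond_mid - shaft_axis.project(cond_mid)
    if cond_off @ ap > 0:          # condyles must be posterior
        ap = -ap
    side = "right" if np.dot(np.cross(ml, ap), si) > 0 else "left"
    return AnatomicalFrame(origin=landmarks.most_distal, axis_si=si,
                           axis_ap=ap, axis_ml=ml, side=side)


def compute_tfl(mesh: SurfaceMesh, frame: AnatomicalFrame) -> float:
    """Total femur length: extent of the bone along the superior axis
    (distance between transversal planes through the most distal and most
    proximal points)."""
    proj = mesh.vertices @ frame.axis_si
    tfl = float(proj.max() - proj.min())
    if tfl <= 0:
        raise DegenerateFrameError("non-positive femur length")
    return tfl
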