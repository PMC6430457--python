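"""Synthetic femur cohorts and parametric femur meshes with exact ground truth.

Two generators live here:

* :func:`sample_cohort` draws parameter vectors from a multivariate model
  calibrated to a reference adult cohort (n = 169): per-parameter means and
  SDs, the full 12x12 inter-correlation matrix (repaired to the nearest
  positive-definite matrix), and folded-normal marginals for the two
  non-negative neck-distance parameters (NCDF, NCDS), whose cohort
  histograms are right-skewed rather than Gaussian.

* :func:`generate_femur_mesh` realises one parameter vector as a watertight
  triangulated surface by polygonising the signed-distance union of
  analytic primitives (shaft cylinder, neck frustum, head sphere, condylar
  block, trochanter bosses) with marching cubes, and returns the analytic
  :class:`GroundTruth` so recovery tests can compare against exactly known
  values.

A measured parameter vector is over-determined: a mesh cannot realise all
twelve values independently.  The generator treats OSA, OSV, NSA, ATA, FHD,
TFL, GTH, NCVD and NCHD as primary and derives OSH, NCDF and NCDS from the
realised geometry, replacing the sampled values (the substitution is
logged).  Recovery tests therefore always compare against the realised
ground truth.
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import dataclass, field, replace
from typing import Dict, Optional, Tuple

import numpy as np
import pandas as pd
from scipy import optimize, special
from skimage import measure as sk_measure

from . import _geom as g
from .anatomical_frame import AnatomicalFrame, Line3
from .cohort_stats import CohortTable
from .errors import CohortSpecError, FeasibilityError
from .mesh_io import PARAMETER_ORDER, SurfaceMesh, clean_mesh, write_mesh
from .morphometry import FemurParameters

log = logging.getLogger("femoromorph")

# ---------------------------------------------------------------------------
# reference-cohort calibration (adult healthy femurs, n = 169)
# ---------------------------------------------------------------------------

POPULATION_N = 169

POPULATION_MEANS = pd.Series({
    "FHD": 46.29, "OSA": 42.39, "OSV": 54.37, "OSH": 37.90,
    "ATA": 17.46, "NSA": 126.35, "GTH": 7.44, "TFL": 439.22,
    "NCDF": 1.51, "NCDS": 2.42, "NCVD": -0.09, "NCHD": 2.17,
})[PARAMETER_ORDER]

POPULATION_SDS = pd.Series({
    "FHD": 4.02, "OSA": 5.98, "OSV": 5.14, "OSH": 6.95,
    "ATA": 6.77, "NSA": 4.29, "GTH": 5.06, "TFL": 29.62,
    "NCDF": 1.22, "NCDS": 1.38, "NCVD": 1.43, "NCHD": 1.90,
})[PARAMETER_ORDER]

POPULATION_RANGES = pd.DataFrame({
    "min": {"FHD": 37.95, "OSA": 28.79, "OSV": 38.73, "OSH": 14.88,
            "ATA": 1.99, "NSA": 108.37, "GTH": -7.38, "TFL": 364.80,
            "NCDF": 0.01, "NCDS": 0.06, "NCVD": -4.03, "NCHD": -3.75},
    "max": {"FHD": 54.35, "OSA": 60.52, "OSV": 68.46, "OSH": 58.60,
            "ATA": 33.57, "NSA": 138.72, "GTH": 21.75, "TFL": 517.93,
            "NCDF": 6.45, "NCDS": 8.41, "NCVD": 3.18, "NCHD": 9.52},
}).loc[PARAMETER_ORDER]

_CORR_PAIRS = {
    ("FHD", "TFL"): 0.68, ("FHD", "NCVD"): -0.29, ("FHD", "GTH"): 0.08,
    ("FHD", "NCDF"): 0.20, ("FHD", "OSA"): 0.29, ("FHD", "NCDS"): 0.07,
    ("FHD", "OSH"): 0.27, ("FHD", "NSA"): 0.11, ("FHD", "ATA"): -0.09,
    ("FHD", "NCHD"): 0.08, ("FHD", "OSV"): 0.52,
    ("TFL", "NCVD"): -0.03, ("TFL", "GTH"): -0.09, ("TFL", "NCDF"): 0.03,
    ("TFL", "OSA"): 0.31, ("TFL", "NCDS"): 0.12, ("TFL", "OSH"): 0.30,
    ("TFL", "NSA"): -0.05, ("TFL", "ATA"): -0.23, ("TFL", "NCHD"): -0.03,
    ("TFL", "OSV"): 0.75,
    ("NCVD", "GTH"): -0.55, ("NCVD", "NCDF"): -0.43, ("NCVD", "OSA"): -0.62,
    ("NCVD", "NCDS"): 0.27, ("NCVD", "OSH"): -0.56, ("NCVD", "NSA"): 0.21,
    ("NCVD", "ATA"): 0.00, ("NCVD", "NCHD"): -0.05, ("NCVD", "OSV"): 0.25,
    ("GTH", "NCDF"): 0.38, ("GTH", "OSA"): 0.39, ("GTH", "NCDS"): -0.18,
    ("GTH", "OSH"): 0.41, ("GTH", "NSA"): -0.62, ("GTH", "ATA"): -0.02,
    ("GTH", "NCHD"): -0.04, ("GTH", "OSV"): -0.54,
    ("NCDF", "OSA"): 0.26, ("NCDF", "NCDS"): 0.03, ("NCDF", "OSH"): 0.25,
    ("NCDF", "NSA"): -0.07, ("NCDF", "ATA"): 0.06, ("NCDF", "NCHD"): 0.11,
    ("NCDF", "OSV"): -0.10,
    ("OSA", "NCDS"): -0.11, ("OSA", "OSH"): 0.92, ("OSA", "NSA"): -0.45,
    ("OSA", "ATA"): -0.01, ("OSA", "NCHD"): 0.11, ("OSA", "OSV"): 0.04,
    ("NCDS", "OSH"): 0.10, ("NCDS", "NSA"): 0.07, ("NCDS", "ATA"): -0.14,
    ("NCDS", "NCHD"): 0.77, ("NCDS", "OSV"): 0.19,
    ("OSH", "NSA"): -0.49, ("OSH", "ATA"): -0.25, ("OSH", "NCHD"): 0.27,
    ("OSH", "OSV"): 0.05,
    ("NSA", "ATA"): 0.26, ("NSA", "NCHD"): 0.10, ("NSA", "OSV"): 0.42,
    ("ATA", "NCHD"): 0.17, ("ATA", "OSV"): -0.13,
    ("NCHD", "OSV"): 0.02,
}


def _build_corr() -> pd.DataFrame:
    C = pd.DataFrame(np.eye(len(PARAMETER_ORDER)),
                     index=PARAMETER_ORDER, columns=PARAMETER_ORDER)
    for (a, b), r in _CORR_PAIRS.items():
        C.loc[a, b] = r
        C.loc[b, a] = r
    return C


POPULATION_CORR = _build_corr()


def nearest_positive_definite_corr(corr: pd.DataFrame,
                                   eig_floor: float = 1e-6) -> pd.DataFrame:
    """Repair a correlation matrix by eigenvalue clipping.

    Eigenvalues below ``eig_floor`` are raised to it, the matrix is
    reassembled and rescaled back to unit diagonal; iterated until positive
    definite.  Raises :class:`CohortSpecError` if repair fails.
    """
    A = corr.to_numpy(dtype=float).copy()
    if not np.allclose(A, A.T, atol=1e-12):
        raise CohortSpecError("correlation matrix must be symmetric")
    for _ in range(10):
        w, V = np.linalg.eigh(A)
        if w.min() >= eig_floor * 0.999:
            break
        w = np.clip(w, eig_floor, None)
        A = (V * w) @ V.T
        d = np.sqrt(np.diag(A))
        A = A / np.outer(d, d)
        A = 0.5 * (A + A.T)
    w = np.linalg.eigvalsh(A)
    if w.min() <= 0:
        raise CohortSpecError("correlation matrix not repairable to positive definite")
    np.fill_diagonal(A, 1.0)
    return pd.DataFrame(A, index=corr.index, columns=corr.columns)


def _folded_mean_ratio(t: float) -> float:
    """E|N(t, 1)| as a function of t = mu/sigma."""
    return float(np.sqrt(2.0 / np.pi) * np.exp(-0.5 * t * t)
                 + t * special.erf(t / np.sqrt(2.0)))


def folded_normal_latent(target_mean: float, target_sd: float) -> Tuple[float, float]:
    """Latent (mu, sigma) whose folded distribution |N(mu, sigma)| has the
    target mean; sigma is kept at the target SD and mu solved numerically.
    (Matching both moments exactly is impossible when mean/SD < ~1.32, the
    folded-normal minimum; the realised SD is reported by the caller.)"""
    if target_mean <= 0 or target_sd <= 0:
        raise CohortSpecError("folded parameters need positive mean and sd")
    sigma = target_sd
    ratio = target_mean / sigma
    f = lambda t: _folded_mean_ratio(t) - ratio          # noqa: E731
    if f(0.0) >= 0.0:
        mu = 0.0
    else:
        mu = sigma * optimize.brentq(f, 0.0, 20.0, xtol=1e-12)
    return mu, sigma


@dataclass(frozen=True)
class GeneratorSpec:
    """Sampling specification for synthetic cohorts."""

    means: pd.Series = field(default_factory=lambda: POPULATION_MEANS.copy())
    sds: pd.Series = field(default_factory=lambda: POPULATION_SDS.copy())
    corr: pd.DataFrame = field(default_factory=lambda: POPULATION_CORR.copy())
    distance_params: Tuple[str, ...] = ("NCDF", "NCDS")
    seed: int = 0
    n: int = POPULATION_N

    def __post_init__(self):
        if (self.sds <= 0).any():
            raise CohortSpecError("all SDs must be positive")
        if self.n < 1:
            raise CohortSpecError("cohort size must be >= 1")

    def repaired_corr(self) -> pd.DataFrame:
        return nearest_positive_definite_corr(self.corr)


def _row_ok(row: Dict[str, float]) -> bool:
    return (row["FHD"] > 0 and row["TFL"] > 0 and row["OSA"] > 0
            and row["OSV"] > 0 and row["OSH"] > 0
            and 90.0 < row["NSA"] < 180.0 and -90.0 < row["ATA"] < 90.0
            and row["NCDF"] >= 0 and row["NCDS"] >= 0)


def sample_cohort(spec: GeneratorSpec = GeneratorSpec(),
                  seed: Optional[int] = None) -> CohortTable:
    """Draw ``spec.n`` parameter vectors from the calibrated model.

    A latent standard multivariate normal with the repaired correlation
    matrix drives all twelve columns; normal parameters are scaled to their
    target moments, the non-negative distance parameters are folded
    (absolute value of their latent representation).  Rows that violate the
    hard parameter bounds are rejected and redrawn (with a logged warning),
    never silently clamped.
    """
    if seed is None:
        seed = spec.seed
    rng = np.random.default_rng(seed)
    L = np.linalg.cholesky(spec.repaired_corr().to_numpy())
    mu = spec.means[PARAMETER_ORDER].to_numpy()
    sd = spec.sds[PARAMETER_ORDER].to_numpy()
    folded = np.array([p in spec.distance_params for p in PARAMETER_ORDER])
    lat_mu = mu.copy()
    lat_sd = sd.copy()
    for j, p in enumerate(PARAMETER_ORDER):
        if folded[j]:
            lat_mu[j], lat_sd[j] = folded_normal_latent(mu[j], sd[j])

    records = []
    rejected = 0
    while len(records) < spec.n:
        z = L @ rng.standard_normal(len(PARAMETER_ORDER))
        x = lat_mu + lat_sd * z
        x[folded] = np.abs(x[folded])
        row = dict(zip(PARAMETER_ORDER, x))
        if not _row_ok(row):
            rejected += 1
            if rejected > 100 * spec.n:
                raise CohortSpecError("excessive rejection rate while sampling")
            continue
        i = len(records)
        records.append(FemurParameters(
            side="right" if rng.random() < 0.5 else "left",
            specimen_id=f"SYN-{i:04d}",
            **{k.lower(): float(v) for k, v in row.items()}))
    if rejected:
        log.warning("rejected %d out-of-bounds draws while sampling %d femurs",
                    rejected, spec.n)
    return CohortTable(tuple(records))


# ---------------------------------------------------------------------------
# signed-distance primitives
# ---------------------------------------------------------------------------

def sd_sphere(p: np.ndarray, center, radius: float) -> np.ndarray:
    return np.linalg.norm(p - np.asarray(center, dtype=float), axis=-1) - radius


def sd_capsule(p: np.ndarray, a, b, radius: float) -> np.ndarray:
    a = np.asarray(a, dtype=float)
    ab = np.asarray(b, dtype=float) - a
    t = np.clip((p - a) @ ab / (ab @ ab), 0.0, 1.0)
    return np.linalg.norm(p - a - t[..., None] * ab, axis=-1) - radius


def sd_capped_cylinder_z(p: np.ndarray, cx: float, cy: float,
                         z0: float, z1: float, radius: float) -> np.ndarray:
    dr = np.hypot(p[..., 0] - cx, p[..., 1] - cy) - radius
    dz = np.maximum(z0 - p[..., 2], p[..., 2] - z1)
    inside = np.minimum(np.maximum(dr, dz), 0.0)
    outside = np.hypot(np.maximum(dr, 0.0), np.maximum(dz, 0.0))
    return inside + outside


def sd_capped_cone(p: np.ndarray, a, b, ra: float, rb: float) -> np.ndarray:
    """Exact signed distance to a capped cone (frustum) from a to b."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    rba = rb - ra
    baba = float((b - a) @ (b - a))
    pa = p - a
    papa = np.einsum("...i,...i->...", pa, pa)
    paba = pa @ (b - a) / baba
    x = np.sqrt(np.maximum(papa - paba * paba * baba, 0.0))
    cax = np.maximum(0.0, x - np.where(paba < 0.5, ra, rb))
    cay = np.abs(paba - 0.5) - 0.5
    k = rba * rba + baba
    f = np.clip((rba * (x - ra) + paba * baba) / k, 0.0, 1.0)
    cbx = x - ra - f * rba
    cby = paba - f
    s = np.where((cbx < 0.0) & (cay < 0.0), -1.0, 1.0)
    return s * np.sqrt(np.minimum(cax * cax + cay * cay * baba,
                                  cbx * cbx + cby * cby * baba))


def mesh_from_sdf(sdf, bounds: np.ndarray, pitch: float,
                  source: str = "<sdf>") -> SurfaceMesh:
    """Polygonise the zero level-set of ``sdf`` on a regular grid.

    ``sdf`` maps an (..., 3) array of points to signed distances (negative
    inside).  Marching cubes on a regular grid always yields a closed
    (watertight) surface as long as the body stays inside ``bounds``.
    """
    bounds = np.asarray(bounds, dtype=float)
    lo = bounds[0] - 3.0 * pitch
    hi = bounds[1] + 3.0 * pitch
    axes = [np.arange(lo[i], hi[i] + pitch, pitch) for i in range(3)]
    X, Y, Z = np.meshgrid(*axes, indexing="ij")
    pts = np.stack([X, Y, Z], axis=-1)
    vol = sdf(pts.reshape(-1, 3)).reshape(X.shape).astype(np.float32)
    verts, faces, _, _ = sk_measure.marching_cubes(vol, level=0.0,
                                                   spacing=(pitch, pitch, pitch))
    verts = verts + lo
    return clean_mesh(SurfaceMesh(vertices=verts, faces=faces, source_path=source))


def _union(*sdfs):
    def f(p):
        out = sdfs[0](p)
        for s in sdfs[1:]:
            out = np.minimum(out, s(p))
        return out
    return f


# ---------------------------------------------------------------------------
# parametric femur
# ---------------------------------------------------------------------------

#: fixed structural constants of the primitive femur model (mm).  These are
#: anatomy-scale choices, not sampled quantities: the twelve parameters are
#: realised exactly regardless of them.
SHAFT_RADIUS = 13.5
CONDYLE_RADIUS = 22.0
CONDYLE_SPACING = 22.0          # half-distance between condyle centres
CONDYLE_POSTERIOR = 8.0         # posterior shift of the condylar block
BRIDGE_RADIUS = 16.0
GT_RADIUS = 13.0                # greater-trochanter boss
GT_LATERAL = 19.0               # lateral offset of the boss axis
LT_RADIUS = 9.0                 # lesser-trochanter boss
LT_OFFSET = 17.5                # radial offset of its centre, posteromedial
NECK_BASE_RADIUS = 13.5
DEFAULT_VOXEL_MM = 1.2


@dataclass(frozen=True)
class GroundTruth:
    """Analytic primitives and the realised parameter vector of one
    generated femur.  Measuring the primitives (no mesh involved)
    reproduces ``params`` to numerical precision."""

    params: FemurParameters
    frame: AnatomicalFrame
    fhc: np.ndarray
    gt_apex: np.ndarray
    lt_center: np.ndarray
    condyle_medial: np.ndarray
    condyle_lateral: np.ndarray
    fsa: Line3
    fna: Line3
    head_radius: float
    primitives: Dict[str, object] = field(default_factory=dict)

    def to_json_dict(self) -> Dict[str, object]:
        def arr(a):
            return np.asarray(a, dtype=float).tolist()
        return {
            "params": {k: (v if isinstance(v, str) else float(v))
                       for k, v in self.params.to_record().items()},
            "frame": {"origin": arr(self.frame.origin),
                      "axis_si": arr(self.frame.axis_si),
                      "axis_ap": arr(self.frame.axis_ap),
                      "axis_ml": arr(self.frame.axis_ml),
                      "side": self.frame.side},
            "primitives": {
                "fhc": arr(self.fhc), "head_radius": float(self.head_radius),
                "gt_apex": arr(self.gt_apex), "lt_center": arr(self.lt_center),
                "condyle_medial": arr(self.condyle_medial),
                "condyle_lateral": arr(self.condyle_lateral),
                "fsa": {"point": arr(self.fsa.point), "direction": arr(self.fsa.direction)},
                "fna": {"point": arr(self.fna.point), "direction": arr(self.fna.direction)},
                **{k: (arr(v) if isinstance(v, (list, tuple, np.ndarray)) else float(v))
                   for k, v in self.primitives.items()},
            },
        }


def mean_parameters(side: str = "right",
                    specimen_id: str = "mean") -> FemurParameters:
    """The cohort-mean parameter vector as a generator input."""
    m = POPULATION_MEANS
    return FemurParameters(side=side, specimen_id=specimen_id,
                           **{k.lower(): float(m[k]) for k in PARAMETER_ORDER})


def _check_feasible(p: FemurParameters) -> None:
    checks = [
        (p.fhd > 0, "fhd > 0"),
        (p.tfl > 100.0, "tfl > 100"),
        (95.0 < p.nsa < 165.0, "95 < nsa < 165"),
        (abs(p.ata) < 60.0, "|ata| < 60"),
        (p.osa > SHAFT_RADIUS + 6.0, f"osa > shaft radius + 6 ({SHAFT_RADIUS + 6.0})"),
        (p.osv > 0, "osv > 0"),
    ]
    bad = [name for ok, name in checks if not ok]
    if bad:
        raise FeasibilityError(f"infeasible parameter vector: {', '.join(bad)}")


def generate_femur_mesh(params: FemurParameters,
                        voxel_mm: float = DEFAULT_VOXEL_MM,
                        seed: Optional[int] = None,
                        noise_mm: float = 0.0,
                        bow_deg: float = 0.0) -> Tuple[SurfaceMesh, GroundTruth]:
    """Realise a parameter vector as a watertight femur mesh.

    The bone is assembled in its own anatomical frame (medial +x, anterior
    +y, superior +z, most distal point at z = 0) and mirrored in x for a
    left femur.  Head placement and the neck axis follow the primary
    parameters; OSH, NCDF and NCDS are derived from the realised geometry
    and replace the requested values in the returned ground truth.

    Parameters
    ----------
    voxel_mm : grid pitch of the marching-cubes polygonisation.
    seed : seeds the optional surface noise only; the geometry is
        deterministic in ``params``.
    noise_mm : Gaussian displacement of vertices along their normals,
        emulating segmentation roughness.
    bow_deg : anterior bow of the diaphysis (circular-arc centreline);
        0 gives the straight default shaft.
    """
    _check_feasible(params)
    r_head = params.fhd / 2.0
    theta = np.radians(180.0 - params.nsa)
    a = np.radians(params.ata)
    si = np.array([0.0, 0.0, 1.0])
    ap = np.array([0.0, 1.0, 0.0])
    ml = np.array([1.0, 0.0, 0.0])

    d = np.array([np.sin(theta) * np.cos(a), np.sin(theta) * np.sin(a),
                  np.cos(theta)])                       # shaft -> head
    fhc = np.array([params.osa * np.cos(a), params.osa * np.sin(a),
                    params.tfl - r_head])

    # neck axis offset so the head-centre eccentricity (ncvd, nchd) is
    # realised exactly: dvec is perpendicular to d with the requested
    # superior/anterior components
    e1, e2 = g.orthonormal_basis_perp(d)
    M = np.array([[e1 @ si, e2 @ si], [e1 @ ap, e2 @ ap]])
    det = np.linalg.det(M)
    if abs(det) < 0.05:
        raise FeasibilityError("neck direction too close to the ml axis for "
                               "the (ncvd, nchd) offsets to be realised")
    alpha, beta = np.linalg.solve(M, np.array([params.ncvd, params.nchd]))
    dvec = alpha * e1 + beta * e2
    if np.linalg.norm(dvec) > 0.45 * r_head:
        raise FeasibilityError(
            f"head-centre eccentricity |{np.linalg.norm(dvec):.1f}| mm too "
            f"large for head radius {r_head:.1f}")
    A = fhc - dvec                                      # FHC projects onto A
    fna = Line3(A, d)
    fsa = Line3(np.zeros(3), si)

    # neck frustum end points along the FNA
    d_xy2 = d[0] ** 2 + d[1] ** 2
    s_star = -(A[0] * d[0] + A[1] * d[1]) / d_xy2       # closest to shaft axis
    B = A + (s_star - 4.0) * d
    H = A + 0.55 * r_head * d
    r_neck_head = float(np.clip(0.55 * r_head, 8.0, 13.0))

    # trochanters
    apex_z = fhc[2] - params.gth
    gt_apex = np.array([-GT_LATERAL, 0.0, apex_z])
    gt_a = np.array([-GT_LATERAL, 0.0, apex_z - GT_RADIUS])
    # boss length scaled so its underside clears the diaphyseal fit band
    gt_len = float(np.clip(0.185 * params.tfl - r_head - params.gth - 4.0,
                           GT_RADIUS + 4.0, 40.0))
    gt_b = np.array([-GT_LATERAL, 0.0, apex_z - gt_len])
    z_lt = fhc[2] - params.osv
    lt_center = np.array([LT_OFFSET / np.sqrt(2.0), -LT_OFFSET / np.sqrt(2.0), z_lt])

    tfl_real = max(fhc[2] + r_head, apex_z)
    band_pos = z_lt / tfl_real
    if not (0.76 <= band_pos <= 0.89):
        raise FeasibilityError(
            f"lesser-trochanter plane at {band_pos:.3f} of bone length, "
            "outside the detectable band (0.76, 0.89)")

    z_top = max(B[2] + 2.0, 0.82 * params.tfl)
    z_bot = 30.0

    condyle_m = np.array([CONDYLE_SPACING, -CONDYLE_POSTERIOR, CONDYLE_RADIUS])
    condyle_l = np.array([-CONDYLE_SPACING, -CONDYLE_POSTERIOR, CONDYLE_RADIUS])
    # posterior tangent points of the condylar block (define the knee line)
    post_m = condyle_m + np.array([0.0, -CONDYLE_RADIUS, 0.0])
    post_l = condyle_l + np.array([0.0, -CONDYLE_RADIUS, 0.0])

    if bow_deg > 0:
        # circular-arc centreline bulging anterior, sampled as a capsule chain
        sag = np.tan(np.radians(bow_deg)) * (z_top - z_bot) / 4.0
        zs = np.linspace(z_bot, z_top, 24)
        ys = sag * (1.0 - ((zs - 0.5 * (z_bot + z_top)) / (0.5 * (z_top - z_bot))) ** 2)
        chain = [np.array([0.0, y, z]) for y, z in zip(ys, zs)]
        shaft_sdf = _union(*[
            (lambda aa, bb: lambda p: sd_capsule(p, aa, bb, SHAFT_RADIUS))(chain[i], chain[i + 1])
            for i in range(len(chain) - 1)])
    else:
        shaft_sdf = lambda p: sd_capped_cylinder_z(    # noqa: E731
            p, 0.0, 0.0, z_bot, z_top, SHAFT_RADIUS)

    sdf = _union(
        shaft_sdf,
        lambda p: sd_capped_cone(p, B, H, NECK_BASE_RADIUS, r_neck_head),
        lambda p: sd_sphere(p, fhc, r_head),
        lambda p: sd_capsule(p, gt_a, gt_b, GT_RADIUS),
        lambda p: sd_sphere(p, lt_center, LT_RADIUS),
        lambda p: sd_sphere(p, condyle_m, CONDYLE_RADIUS),
        lambda p: sd_sphere(p, condyle_l, CONDYLE_RADIUS),
        lambda p: sd_capsule(p, condyle_m, condyle_l, BRIDGE_RADIUS),
    )

    mirror = params.side == "left"
    if mirror:
        base_sdf = sdf
        sdf = lambda p: base_sdf(p * np.array([-1.0, 1.0, 1.0]))  # noqa: E731

    pts_of_interest = np.array([
        fhc + r_head, fhc - r_head, gt_a - GT_RADIUS, gt_b - GT_RADIUS,
        lt_center - LT_RADIUS, lt_center + LT_RADIUS,
        condyle_m - CONDYLE_RADIUS, condyle_l - CONDYLE_RADIUS,
        condyle_m + CONDYLE_RADIUS, condyle_l + CONDYLE_RADIUS,
        [SHAFT_RADIUS, SHAFT_RADIUS, z_top], [-SHAFT_RADIUS, -SHAFT_RADIUS, z_bot],
    ])
    bounds = np.array([pts_of_interest.min(axis=0), pts_of_interest.max(axis=0)])
    if mirror:
        bounds = np.array([[-bounds[1][0], bounds[0][1], bounds[0][2]],
                           [-bounds[0][0], bounds[1][1], bounds[1][2]]])

    mesh = mesh_from_sdf(sdf, bounds, voxel_mm,
                         source=f"<synthetic:{params.specimen_id or 'femur'}>")
    if noise_mm > 0:
        rng = np.random.default_rng(seed)
        tm = mesh.to_trimesh()
        disp = rng.normal(0.0, noise_mm, size=len(tm.vertices))
        mesh = replace(mesh, vertices=mesh.vertices
                       + disp[:, None] * np.asarray(tm.vertex_normals))

    # realised (derived) parameters — closed forms, independent of the
    # measurement code paths
    osh_real = params.osa * abs(np.cos(a))
    dxz = np.hypot(d[0], d[2])
    dyz = np.hypot(d[1], d[2])
    ncdf_real = abs(dvec[0] * d[2] - dvec[2] * d[0]) / dxz
    ncds_real = abs(dvec[1] * d[2] - dvec[2] * d[1]) / dyz
    if (abs(osh_real - params.osh) > 1e-9 or abs(ncdf_real - params.ncdf) > 1e-9
            or abs(ncds_real - params.ncds) > 1e-9):
        log.info("%s: derived osh=%.2f ncdf=%.2f ncds=%.2f replace sampled "
                 "osh=%.2f ncdf=%.2f ncds=%.2f",
                 params.specimen_id or "femur", osh_real, ncdf_real, ncds_real,
                 params.osh, params.ncdf, params.ncds)
    realised = replace(params, osh=float(osh_real), ncdf=float(ncdf_real),
                       ncds=float(ncds_real), tfl=float(tfl_real))
    realised.validate()

    def mir(v):
        v = np.asarray(v, dtype=float)
        return v * np.array([-1.0, 1.0, 1.0]) if mirror else v

    frame = AnatomicalFrame(origin=mir(condyle_m + [0, 0, -CONDYLE_RADIUS]),
                            axis_si=si, axis_ap=ap, axis_ml=mir(ml),
                            side="left" if mirror else "right")
    truth = GroundTruth(
        params=realised, frame=frame, fhc=mir(fhc), gt_apex=mir(gt_apex),
        lt_center=mir(lt_center), condyle_medial=mir(post_m),
        condyle_lateral=mir(post_l),
        fsa=Line3(mir(fsa.point) if mirror else fsa.point, si),
        fna=Line3(mir(A), mir(d)), head_radius=r_head,
        primitives={"neck_base": mir(B), "neck_head_end": mir(H),
                    "neck_base_radius": NECK_BASE_RADIUS,
                    "neck_head_radius": r_neck_head,
                    "shaft_radius": SHAFT_RADIUS,
                    "shaft_z": [z_bot, z_top], "voxel_mm": voxel_mm})
    return mesh, truth


# ---------------------------------------------------------------------------
# canonical test bodies
# ---------------------------------------------------------------------------

def make_cylinder_mesh(radius: float = 14.0, length: float = 440.0,
                       sections: int = 64) -> SurfaceMesh:
    """Exact right circular cylinder along z, centred on the origin."""
    import trimesh
    tm = trimesh.creation.cylinder(radius=radius, height=length,
                                   sections=sections)
    return clean_mesh(SurfaceMesh.from_trimesh(tm, source_path="<cylinder>"))


def make_sphere_mesh(radius: float, center=(0.0, 0.0, 0.0),
                     subdivisions: int = 4) -> SurfaceMesh:
    """Icosphere whose vertices lie exactly on the sphere."""
    import trimesh
    tm = trimesh.creation.icosphere(subdivisions=subdivisions, radius=radius)
    tm.apply_translation(np.asarray(center, dtype=float))
    return clean_mesh(SurfaceMesh.from_trimesh(tm, source_path="<sphere>"))


def make_coaxial_body(radius: float = 14.0, length: float = 300.0,
                      head_radius: float = 23.0,
                      voxel_mm: float = 1.5) -> SurfaceMesh:
    """Degenerate test body: a head sphere coaxial with the shaft
    (neck-shaft angle 180 deg)."""
    sdf = _union(
        lambda p: sd_capped_cylinder_z(p, 0.0, 0.0, 0.0, length, radius),
        lambda p: sd_sphere(p, [0.0, 0.0, length + 0.6 * head_radius], head_radius),
    )
    bounds = np.array([[-head_radius, -head_radius, 0.0],
                       [head_radius, head_radius, length + 1.6 * head_radius]])
    return mesh_from_sdf(sdf, bounds, voxel_mm, source="<coaxial>")


def make_bowed_shaft(radius: float = 14.0, length: float = 440.0,
                     bow_deg: float = 2.0, voxel_mm: float = 1.5):
    """Bowed cylindrical shaft (circular-arc centreline in the sagittal
    plane).  Returns (mesh, centreline_samples) for axis-fit oracles."""
    sag = np.tan(np.radians(bow_deg)) * length / 4.0
    zs = np.linspace(0.0, length, 48)
    ys = sag * (1.0 - ((zs - 0.5 * length) / (0.5 * length)) ** 2)
    chain = [np.array([0.0, y, z]) for y, z in zip(ys, zs)]
    sdf = _union(*[
        (lambda aa, bb: lambda p: sd_capsule(p, aa, bb, radius))(chain[i], chain[i + 1])
        for i in range(len(chain) - 1)])
    bounds = np.array([[-radius - sag, -radius - sag, -radius],
                       [radius + sag, radius + sag, length + radius]])
    mesh = mesh_from_sdf(sdf, bounds, voxel_mm, source="<bowed-shaft>")
    centreline = np.column_stack([np.zeros_like(zs), ys, zs])
    return mesh, centreline


def make_fixtures(out_dir: str, voxel_mm: float = DEFAULT_VOXEL_MM) -> list:
    """Write the canonical test bodies as STL with JSON ground-truth
    sidecars; deterministic, so repeated runs are byte-identical."""
    os.makedirs(out_dir, exist_ok=True)
    paths = []

    def dump(name, mesh, truth: Dict[str, object]):
        stl = os.path.join(out_dir, f"{name}.stl")
        write_mesh(mesh, stl)
        side = os.path.join(out_dir, f"{name}.json")
        with open(side, "w") as fh:
            json.dump(truth, fh, indent=1, sort_keys=True)
        paths.extend([stl, side])

    sphere = make_sphere_mesh(23.145)
    dump("sphere", sphere, {"kind": "sphere", "center": [0.0, 0.0, 0.0],
                            "radius": 23.145})
    cyl = make_cylinder_mesh()
    dump("cylinder", cyl, {"kind": "cylinder", "radius": 14.0, "length": 440.0,
                           "axis": [0.0, 0.0, 1.0]})
    bowed, centreline = make_bowed_shaft()
    dump("bowed_shaft", bowed, {"kind": "bowed_shaft", "radius": 14.0,
                                "bow_deg": 2.0,
                                "centreline": centreline.tolist()})
    for name, side in (("mean_femur", "right"), ("mirrored_femur", "left")):
        mesh, truth = generate_femur_mesh(mean_parameters(side=side,
                                                          specimen_id=name),
                                          voxel_mm=voxel_mm)
        dump(name, mesh, truth.to_json_dict())
    return paths
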