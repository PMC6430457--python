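"""The twelve proximal-femur parameters and the full measurement pipeline.

Parameter conventions (mm unless noted):

========  ==================================================================
FHD       diameter of the best-fit femoral-head sphere
TFL       total femur length along the superior axis
NSA (°)   neck-shaft angle, the obtuse 3-D angle between neck and shaft axes
ATA (°)   anteversion, signed transversal-plane angle of the neck axis
          against the posterior-condylar (knee medio-lateral) line;
          anterior tilt positive
OSA       absolute offset: 3-D distance head centre -> shaft axis
OSH       horizontal offset: the same distance after projection into the
          frontal plane
OSV       vertical offset: head-centre height above the lesser-trochanter
          transversal plane
GTH       signed head-centre height above the greater-trochanter apex plane
NCDF/NCDS head-centre to neck-axis distance projected into the frontal /
          sagittal plane (non-negative)
NCVD/NCHD signed cranial(+)/caudal(-) and anterior(+)/posterior(-)
          components of the head-centre eccentricity off the neck axis
========  ==================================================================
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, Optional

import numpy as np

from . import _geom as g
from .anatomical_frame import (AnatomicalFrame, Landmarks, Line3, build_frame,
                               compute_tfl, detect_landmarks,
                               estimate_shaft_axis)
from .config import DEFAULT_CONFIG, MeasurementConfig
from .errors import (MeasurementInconsistentError, ProjectionDegenerateError)
from .head_neck import (NeckOffsets, Sphere, estimate_neck_axis,
                        fit_head_sphere, neck_center_offsets)
from .mesh_io import PARAMETER_ORDER, SurfaceMesh

log = logging.getLogger("femoromorph")


@dataclass(frozen=True)
class FemurParameters:
    """The twelve named measurements for one femur."""

    fhd: float
    osa: float
    osv: float
    osh: float
    ata: float
    nsa: float
    gth: float
    tfl: float
    ncdf: float
    ncds: float
    ncvd: float
    nchd: float
    side: str = "unknown"
    specimen_id: str = ""

    def validate(self) -> None:
        checks = [
            (self.fhd > 0, "fhd > 0"),
            (self.tfl > 0, "tfl > 0"),
            (self.osa > 0, "osa > 0"),
            (self.osv > 0, "osv > 0"),
            (self.osh > 0, "osh > 0"),
            (self.osh <= self.osa + 1e-6, "osh <= osa"),
            (90.0 < self.nsa < 180.0, "90 < nsa < 180"),
            (-90.0 < self.ata < 90.0, "-90 < ata < 90"),
            (self.ncdf >= 0, "ncdf >= 0"),
            (self.ncds >= 0, "ncds >= 0"),
        ]
        bad = [name for ok, name in checks if not ok]
        if bad:
            raise MeasurementInconsistentError(
                f"parameter invariants violated: {', '.join(bad)}")

    def to_record(self) -> Dict[str, object]:
        rec = {"specimen_id": self.specimen_id, "side": self.side}
        rec.update({name: getattr(self, name.lower()) for name in PARAMETER_ORDER})
        return rec

    @classmethod
    def from_record(cls, rec: Dict[str, object]) -> "FemurParameters":
        kwargs = {name.lower(): float(rec[name]) for name in PARAMETER_ORDER}
        return cls(side=str(rec.get("side", "unknown")),
                   specimen_id=str(rec.get("specimen_id", "")), **kwargs)

    def values(self) -> np.ndarray:
        return np.array([getattr(self, name.lower()) for name in PARAMETER_ORDER])


# ---------------------------------------------------------------------------
# individual parameters
# ---------------------------------------------------------------------------

def compute_nsa(fsa: Line3, fna: Line3, fhc: Optional[np.ndarray] = None,
                mode: str = "three_d",
                frame: Optional[AnatomicalFrame] = None) -> float:
    """Neck-shaft angle in degrees, in (0, 180].

    The neck line is re-anchored through the head centre with the FNA's
    direction (the anchor does not change the angle).  The reported value
    is the obtuse anatomical angle: 180° minus the angle between the
    head-ward neck direction and the superior shaft direction.  With
    ``mode='frontal_projection'`` both directions are first projected into
    the frontal plane of ``frame``.
    """
    d_neck = fna.direction
    d_shaft = fsa.direction
    if mode == "frontal_projection":
        if frame is None:
            raise ValueError("frontal_projection mode needs the anatomical frame")
        ap = frame.axis_ap
        d_neck = d_neck - (d_neck @ ap) * ap
        d_shaft = d_shaft - (d_shaft @ ap) * ap
    elif mode != "three_d":
        raise ValueError(f"unknown nsa_mode: {mode}")
    return 180.0 - g.angle_between_deg(d_neck, d_shaft)


def compute_ata(fna: Line3, frame: AnatomicalFrame,
                config: MeasurementConfig = DEFAULT_CONFIG) -> float:
    """Anteversion angle in degrees, anterior tilt positive.

    The head-ward neck direction is projected into the transversal plane;
    ATA is the signed angle between that projection and the knee
    medio-lateral line (axis_ml), positive toward anterior.
    """
    ang = g.angle_between_deg(fna.direction, frame.axis_si)
    if min(ang, 180.0 - ang) < config.ata_degenerate_deg:
        raise ProjectionDegenerateError(
            f"neck axis within {config.ata_degenerate_deg} deg of the superior axis")
    m = float(fna.direction @ frame.axis_ml)
    a = float(fna.direction @ frame.axis_ap)
    return float(np.degrees(np.arctan2(a, m)))


def compute_offsets(fhc: np.ndarray, fsa: Line3, frame: AnatomicalFrame,
                    lt_center: np.ndarray) -> tuple:
    """(OSA, OSH, OSV): absolute, horizontal and vertical femoral offset."""
    fhc = np.asarray(fhc, dtype=float)
    osa = fsa.distance_to(fhc)
    p2 = np.array([fhc @ frame.axis_ml, fhc @ frame.axis_si])
    o2 = np.array([fsa.point @ frame.axis_ml, fsa.point @ frame.axis_si])
    d2 = np.array([fsa.direction @ frame.axis_ml, fsa.direction @ frame.axis_si])
    osh = g.point_line_distance_2d(p2, o2, d2)
    osv = float((fhc - np.asarray(lt_center, dtype=float)) @ frame.axis_si)
    return float(osa), float(osh), float(osv)


def compute_gth(fhc: np.ndarray, gt_apex: np.ndarray,
                frame: AnatomicalFrame) -> float:
    """Signed vertical distance of the head centre above the
    greater-trochanter apex plane (positive = FHC superior)."""
    return float((np.asarray(fhc, dtype=float)
                  - np.asarray(gt_apex, dtype=float)) @ frame.axis_si)


# ---------------------------------------------------------------------------
# full pipeline
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MeasurementDetail:
    """One femur's measurement with intermediate geometry and repeat spread."""

    params: FemurParameters
    repeat_sd: Dict[str, float]
    shaft_axis: Line3
    neck_axis: Line3
    head: Sphere
    frame: AnatomicalFrame
    landmarks: Landmarks
    offsets: NeckOffsets
    repeats: int = 1
    per_repeat: tuple = field(default_factory=tuple)


def _measure_once(mesh: SurfaceMesh, shaft: Line3, config: MeasurementConfig,
                  seed: Optional[int]) -> tuple:
    """One complete measurement pass given a fitted shaft axis."""
    head = fit_head_sphere(mesh, shaft, config=config, seed=seed)
    # confirm the superior orientation against the head position
    proj = (mesh.vertices - shaft.point) @ shaft.direction
    if (head.center - shaft.point) @ shaft.direction < 0.5 * (proj.min() + proj.max()):
        shaft = estimate_shaft_axis(mesh, config=config,
                                    orientation_hint=-shaft.direction)
        head = fit_head_sphere(mesh, shaft, config=config, seed=seed)
    neck = estimate_neck_axis(mesh, None, head, shaft, config=config)
    landmarks = detect_landmarks(mesh, shaft, head, neck_axis=neck, config=config)
    frame = build_frame(mesh, shaft, landmarks, head_center=head.center,
                        config=config)
    tfl = compute_tfl(mesh, frame)
    nsa = compute_nsa(shaft, neck, head.center, mode=config.nsa_mode, frame=frame)
    ata = compute_ata(neck, frame, config=config)
    osa, osh, osv = compute_offsets(head.center, shaft, frame, landmarks.lt_center)
    gth = compute_gth(head.center, landmarks.gt_apex, frame)
    off = neck_center_offsets(head.center, neck, frame)
    values = {"FHD": head.diameter, "OSA": osa, "OSV": osv, "OSH": osh,
              "ATA": ata, "NSA": nsa, "GTH": gth, "TFL": tfl,
              "NCDF": off.ncdf, "NCDS": off.ncds, "NCVD": off.ncvd,
              "NCHD": off.nchd}
    return values, shaft, neck, head, frame, landmarks, off


def measure_femur_detailed(mesh: SurfaceMesh, repeats: Optional[int] = None,
                           config: MeasurementConfig = DEFAULT_CONFIG,
                           seed: Optional[int] = None,
                           specimen_id: str = "") -> MeasurementDetail:
    """Measure all twelve parameters, averaging over repeat runs.

    Each repeat re-runs the stochastic stages (the RANSAC head fit and
    everything downstream of the head centre) with a distinct seed derived
    from ``seed``; the reported parameter is the mean over repeats and the
    per-parameter repeat standard deviation is kept for diagnostics.  The
    deterministic shaft-axis fit is shared by all repeats.
    """
    repeats = config.repeats if repeats is None else int(repeats)
    if repeats < 1:
        raise ValueError("repeats must be >= 1")
    shaft = estimate_shaft_axis(mesh, config=config)
    seeds = np.random.SeedSequence(seed).generate_state(repeats) % (2 ** 31)
    runs = []
    last = None
    for rep in range(repeats):
        values, *geom = _measure_once(mesh, shaft, config, int(seeds[rep]))
        runs.append(values)
        last = geom
    keys = list(runs[0])
    mean = {k: float(np.mean([r[k] for r in runs])) for k in keys}
    sd = {k: float(np.std([r[k] for r in runs], ddof=1)) if repeats > 1 else 0.0
          for k in keys}
    for k, v in sd.items():
        if v > 0.5:
            log.warning("repeat SD of %s is %.2f — unstable measurement", k, v)
    shaft_f, neck, head, frame, landmarks, off = last
    params = FemurParameters(
        fhd=mean["FHD"], osa=mean["OSA"], osv=mean["OSV"], osh=mean["OSH"],
        ata=mean["ATA"], nsa=mean["NSA"], gth=mean["GTH"], tfl=mean["TFL"],
        ncdf=mean["NCDF"], ncds=mean["NCDS"], ncvd=mean["NCVD"],
        nchd=mean["NCHD"], side=frame.side, specimen_id=specimen_id)
    params.validate()
    return MeasurementDetail(params=params, repeat_sd=sd, shaft_axis=shaft_f,
                             neck_axis=neck, head=head, frame=frame,
                             landmarks=landmarks, offsets=off, repeats=repeats,
                             per_repeat=tuple(runs))


def measure_femur(mesh: SurfaceMesh, repeats: Optional[int] = None,
                  config: MeasurementConfig = DEFAULT_CONFIG,
                  seed: Optional[int] = None,
                  specimen_id: str = "") -> FemurParameters:
    """Measure the twelve parameters of one femur (averaged over repeats)."""
    return measure_femur_detailed(mesh, repeats=repeats, config=config,
                                  seed=seed, specimen_id=specimen_id).params
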