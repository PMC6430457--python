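"""Tunable measurement parameters.

All knobs of the measurement pipeline live in one frozen dataclass so a run
is fully described by (mesh, config, seed).  Defaults are the values used
throughout the test-suite and the acceptance runs; units are millimetres and
degrees.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Tuple


@dataclass(frozen=True)
class MeasurementConfig:
    # --- shaft axis -------------------------------------------------------
    #: diaphysis band used for the shaft-axis fit, as fractions of total
    #: bone length measured from the distal end.
    fraction_range: Tuple[float, float] = (0.50, 0.80)
    #: spacing of diaphyseal cross-sections (mm).
    section_spacing_mm: float = 2.0
    #: iteration stops once the axis direction changes by less than this.
    convergence_deg: float = 0.1
    #: hard cap on shaft-axis refinement iterations.
    max_axis_iterations: int = 10
    #: minimum number of valid diaphyseal sections.
    min_shaft_sections: int = 5

    # --- femoral head -----------------------------------------------------
    #: proximal fraction of bone length searched for the head surface.
    head_region_fraction: float = 0.25
    #: RANSAC inlier band around the candidate sphere surface (mm).
    inlier_band_mm: float = 1.0
    #: number of RANSAC hypotheses.
    ransac_iters: int = 200
    #: minimum accepted inlier fraction for the head fit.
    min_inlier_fraction: float = 0.5

    # --- femoral neck -----------------------------------------------------
    #: spacing of neck cross-sections (mm).
    neck_section_spacing_mm: float = 1.5
    #: first neck station, as a multiple of the head radius from the centre.
    neck_start_factor: float = 1.05
    #: stop collecting neck sections once area exceeds this multiple of the
    #: smallest area seen so far (the anatomical neck is the minimal
    #: cross-section corridor; the trochanteric junction flares past it).
    neck_area_flare: float = 1.15
    #: number of neck-axis refinement passes after the initial direction.
    neck_iterations: int = 2
    #: minimum number of valid neck sections.
    min_neck_sections: int = 4

    # --- landmarks --------------------------------------------------------
    #: lesser-trochanter band, fractions of bone length from the distal end.
    lt_band: Tuple[float, float] = (0.75, 0.90)
    #: radial protrusion above the band median marking trochanter surface.
    protrusion_threshold_mm: float = 4.0
    #: cluster radius around the protrusion seed vertex (mm).
    lt_cluster_radius_mm: float = 12.0
    #: candidate vertices closer than this to the neck axis are excluded
    #: from trochanter landmark regions (mm).
    neck_exclusion_mm: float = 18.0
    #: head-sphere exclusion factor for trochanter regions.
    head_exclusion_factor: float = 1.15
    #: condyle landmark = centroid of vertices within this distance of the
    #: posterior extreme of each distal half (mm); averaging suppresses
    #: tessellation jitter of the extreme vertex.
    condyle_cap_mm: float = 2.0
    #: minimum angle between condylar line and shaft axis (deg).
    min_condyle_angle_deg: float = 5.0

    # --- parameter conventions -------------------------------------------
    #: 'three_d' measures the neck-shaft angle between the 3-D axes;
    #: 'frontal_projection' projects both axes into the frontal plane first.
    nsa_mode: str = "three_d"
    #: neck directions closer than this to the superior axis make the
    #: anteversion projection degenerate (deg).
    ata_degenerate_deg: float = 2.0

    # --- repeats ----------------------------------------------------------
    #: repeat measurements averaged per parameter.
    repeats: int = 6

    def with_updates(self, **kwargs) -> "MeasurementConfig":
        """Return a copy with the given fields replaced."""
        return replace(self, **kwargs)


DEFAULT_CONFIG = MeasurementConfig()
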