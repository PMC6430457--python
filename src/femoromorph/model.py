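"""Model / Results objects over the measurement and cohort pipelines.

``FemurModel`` wraps one surface mesh; ``fit()`` runs the full geometric
measurement and returns a :class:`FemurFitResults` carrying the twelve
parameter estimates, their repeat spread and the fitted geometry.
``CohortModel`` wraps a parameter table; ``fit()`` returns
:class:`CohortResults` with descriptives, the Pearson matrix and the
normality assessment.  Both results objects expose ``summary()``.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from typing import Optional, Union

import numpy as np
import pandas as pd

from .cohort_stats import (CohortLike, CohortTable, CorrelationResult,
                           DescriptiveSummary, _as_cohort, descriptives,
                           normality_report, pearson_matrix, plot_boxes,
                           plot_histograms, render_report)
from .config import DEFAULT_CONFIG, MeasurementConfig
from .mesh_io import PARAMETER_ORDER, SurfaceMesh, read_mesh, read_table
from .morphometry import MeasurementDetail, measure_femur_detailed

_UNITS = {"ATA": "deg", "NSA": "deg"}


@dataclass(frozen=True)
class FemurFitResults:
    """Result of fitting the morphometric model to one femur mesh."""

    detail: MeasurementDetail
    model: "FemurModel"

    @property
    def params(self):
        return self.detail.params

    @property
    def repeat_sd(self):
        return self.detail.repeat_sd

    @property
    def frame(self):
        return self.detail.frame

    @property
    def landmarks(self):
        return self.detail.landmarks

    def as_series(self) -> pd.Series:
        return pd.Series(self.params.to_record())

    def summary(self) -> str:
        p = self.params
        buf = io.StringIO()
        buf.write("Proximal femur morphometry\n")
        buf.write("=" * 46 + "\n")
        buf.write(f"specimen: {p.specimen_id or self.model.specimen_id or '<unnamed>'}"
                  f"    side: {p.side}    repeats: {self.detail.repeats}\n")
        buf.write(f"source:   {self.model.mesh.source_path}\n")
        buf.write("-" * 46 + "\n")
        buf.write(f"{'parameter':<10}{'estimate':>12}{'repeat SD':>12}  unit\n")
        rec = p.to_record()
        for name in PARAMETER_ORDER:
            buf.write(f"{name:<10}{rec[name]:>12.3f}"
                      f"{self.detail.repeat_sd.get(name, 0.0):>12.4f}"
                      f"  {_UNITS.get(name, 'mm')}\n")
        buf.write("-" * 46 + "\n")
        buf.write(f"head sphere inlier fraction: {self.detail.head.inlier_fraction:.2f}\n")
        return buf.getvalue()


class FemurModel:
    """Morphometric model for a single femur surface mesh.

    Parameters
    ----------
    mesh : SurfaceMesh or path
        The bone surface (STL/PLY path or an in-memory mesh), mm units.
    config : MeasurementConfig
        Pipeline tunables; defaults reproduce the standard protocol.
    specimen_id : str
        Carried through to the results table.
    """

    def __init__(self, mesh: Union[SurfaceMesh, str],
                 config: MeasurementConfig = DEFAULT_CONFIG,
                 specimen_id: str = ""):
        self.mesh = read_mesh(mesh) if isinstance(mesh, str) else mesh
        self.config = config
        self.specimen_id = specimen_id

    @classmethod
    def from_file(cls, path: str, config: MeasurementConfig = DEFAULT_CONFIG,
                  specimen_id: str = "") -> "FemurModel":
        return cls(read_mesh(path), config=config,
                   specimen_id=specimen_id or path)

    def fit(self, repeats: Optional[int] = None,
            seed: Optional[int] = None) -> FemurFitResults:
        detail = measure_femur_detailed(self.mesh, repeats=repeats,
                                        config=self.config, seed=seed,
                                        specimen_id=self.specimen_id)
        return FemurFitResults(detail=detail, model=self)


@dataclass(frozen=True)
class CohortResults:
    """Result of fitting the cohort statistics to a parameter table."""

    cohort: CohortTable
    descriptives: DescriptiveSummary
    correlation: CorrelationResult
    normality: pd.DataFrame

    def summary(self) -> str:
        buf = io.StringIO()
        buf.write(f"Cohort statistics (n = {self.cohort.n})\n")
        buf.write("=" * 62 + "\n")
        t = self.descriptives.table
        buf.write(f"{'parameter':<10}{'min':>9}{'max':>9}{'mean':>9}"
                  f"{'sd':>8}{'median':>9}  normal\n")
        for name in PARAMETER_ORDER:
            row = t.loc[name]
            normal = "yes" if bool(self.normality.loc[name, "normal"]) else "no"
            buf.write(f"{name:<10}{row['min']:>9.2f}{row['max']:>9.2f}"
                      f"{row['mean']:>9.2f}{row['sd']:>8.2f}"
                      f"{row['median']:>9.2f}  {normal}\n")
        buf.write("-" * 62 + "\n")
        r = self.correlation.r
        pairs = [("OSA", "OSH"), ("GTH", "NSA"), ("OSV", "TFL"), ("TFL", "FHD")]
        buf.write("headline correlations: " + ", ".join(
            f"r({a},{b})={r.loc[a, b]:+.2f}" for a, b in pairs) + "\n")
        iu = np.triu_indices(len(PARAMETER_ORDER), 1)
        n_sig = int(self.correlation.significant.to_numpy()[iu].sum())
        buf.write(f"significant pairs at alpha={self.correlation.alpha:g}: "
                  f"{n_sig} / 66\n")
        return buf.getvalue()

    def plot_box(self, path: Optional[str] = None):
        return plot_boxes(self.cohort, path)

    def plot_hist(self, path: Optional[str] = None):
        return plot_histograms(self.cohort, path)

    def save_report(self, out_dir: str) -> list:
        return render_report(self.cohort, out_dir, alpha=self.correlation.alpha)


class CohortModel:
    """Cohort statistics model over a table of femur parameters."""

    def __init__(self, data: CohortLike):
        self.cohort = _as_cohort(data)

    @classmethod
    def from_csv(cls, *paths: str) -> "CohortModel":
        frames = [read_table(p) for p in paths]
        return cls(pd.concat(frames, ignore_index=True))

    def fit(self, alpha: float = 0.05) -> CohortResults:
        return CohortResults(
            cohort=self.cohort,
            descriptives=descriptives(self.cohort),
            correlation=pearson_matrix(self.cohort, alpha=alpha),
            normality=normality_report(self.cohort, alpha=alpha),
        )
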