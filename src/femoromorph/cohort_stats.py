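"""Cohort-level statistics for the twelve femoral parameters.

Reproduces the analysis a morphometric study applies to a parameter table:
per-parameter descriptives (min/max/mean/SD/median), the 12x12 Pearson
inter-correlation matrix with t-test p-values at a stated significance
level, and a per-parameter normality assessment (Shapiro-Wilk) with
Freedman-Diaconis histogram binning.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy import stats

from .errors import CohortSpecError
from .mesh_io import PARAMETER_ORDER, write_table
from .morphometry import FemurParameters


@dataclass(frozen=True)
class CohortTable:
    """A cohort of measured (or sampled) femurs."""

    records: tuple

    def __post_init__(self):
        if len(self.records) < 1:
            raise CohortSpecError("a cohort needs at least one record")
        object.__setattr__(self, "records", tuple(self.records))

    @property
    def n(self) -> int:
        return len(self.records)

    @property
    def df(self) -> pd.DataFrame:
        return pd.DataFrame([r.to_record() for r in self.records])

    def matrix(self) -> np.ndarray:
        """(n, 12) array in canonical parameter order."""
        return np.array([r.values() for r in self.records])

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "CohortTable":
        return cls(tuple(FemurParameters.from_record(row)
                         for row in df.to_dict("records")))


CohortLike = Union[CohortTable, pd.DataFrame, Sequence[FemurParameters]]


def _as_cohort(data: CohortLike) -> CohortTable:
    if isinstance(data, CohortTable):
        return data
    if isinstance(data, pd.DataFrame):
        return CohortTable.from_dataframe(data)
    return CohortTable(tuple(data))


@dataclass(frozen=True)
class DescriptiveSummary:
    """Per-parameter min/max/mean/sd/median table."""

    table: pd.DataFrame          # index = parameter, columns = statistics
    n: int

    def __getitem__(self, param: str) -> pd.Series:
        return self.table.loc[param]


@dataclass(frozen=True)
class CorrelationResult:
    """Pearson r, two-sided t-test p-values and the significance mask."""

    r: pd.DataFrame
    p: pd.DataFrame
    n: int
    alpha: float
    significant: pd.DataFrame
    degenerate: tuple = field(default_factory=tuple)   # zero-variance columns


def descriptives(cohort: CohortLike) -> DescriptiveSummary:
    """Sample descriptives: min, max, mean, SD (n-1 denominator), median."""
    cohort = _as_cohort(cohort)
    if cohort.n < 2:
        raise CohortSpecError("sample SD undefined for n < 2")
    X = cohort.matrix()
    table = pd.DataFrame({
        "min": X.min(axis=0),
        "max": X.max(axis=0),
        "mean": X.mean(axis=0),
        "sd": X.std(axis=0, ddof=1),
        "median": np.median(X, axis=0),
    }, index=PARAMETER_ORDER)
    return DescriptiveSummary(table=table, n=cohort.n)


def pearson_matrix(cohort: CohortLike, alpha: float = 0.05) -> CorrelationResult:
    """Pairwise Pearson correlations with t-test p-values.

    For each pair, r is the product-moment coefficient and the p-value
    comes from ``t = r sqrt((n-2)/(1-r^2))`` against a t distribution with
    n-2 degrees of freedom (two-sided).  Zero-variance columns are flagged
    and yield NaN rather than aborting.
    """
    cohort = _as_cohort(cohort)
    n = cohort.n
    if n < 3:
        raise CohortSpecError("Pearson t-test needs n >= 3")
    X = cohort.matrix()
    sd = X.std(axis=0, ddof=1)
    degenerate = tuple(p for p, s in zip(PARAMETER_ORDER, sd) if s == 0)
    Xc = X - X.mean(axis=0)
    cov = Xc.T @ Xc
    denom = np.sqrt(np.outer(np.diag(cov), np.diag(cov)))
    with np.errstate(divide="ignore", invalid="ignore"):
        r = cov / denom
    r[~np.isfinite(r)] = np.nan
    np.fill_diagonal(r, np.where(sd > 0, 1.0, np.nan))
    rc = np.clip(r, -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = rc * np.sqrt((n - 2) / (1.0 - rc ** 2))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    p[np.isinf(t)] = 0.0
    np.fill_diagonal(p, np.where(sd > 0, 0.0, np.nan))
    idx = PARAMETER_ORDER
    rdf = pd.DataFrame(r, index=idx, columns=idx)
    pdf = pd.DataFrame(p, index=idx, columns=idx)
    return CorrelationResult(r=rdf, p=pdf, n=n, alpha=alpha,
                             significant=pdf < alpha, degenerate=degenerate)


def adjust_pvalues(result: CorrelationResult, method: str = "bonferroni") -> pd.DataFrame:
    """Optional multiple-testing correction of the 66 off-diagonal p-values
    (off by default in all reports; the primary analysis tests each pair at
    the plain alpha level)."""
    p = result.p.to_numpy().copy()
    iu = np.triu_indices_from(p, k=1)
    raw = p[iu]
    if method == "bonferroni":
        adj = np.minimum(raw * len(raw), 1.0)
    elif method == "fdr_bh":
        order = np.argsort(raw)
        ranked = raw[order] * len(raw) / (np.arange(len(raw)) + 1)
        ranked = np.minimum.accumulate(ranked[::-1])[::-1]
        adj = np.empty_like(raw)
        adj[order] = np.minimum(ranked, 1.0)
    else:
        raise ValueError(f"unknown adjustment method: {method}")
    p[iu] = adj
    p[(iu[1], iu[0])] = adj
    return pd.DataFrame(p, index=result.p.index, columns=result.p.columns)


def freedman_diaconis_edges(x: np.ndarray) -> np.ndarray:
    """Histogram bin edges by the Freedman-Diaconis rule (numpy 'fd')."""
    return np.histogram_bin_edges(np.asarray(x, dtype=float), bins="fd")


def normality_report(cohort: CohortLike, alpha: float = 0.05) -> pd.DataFrame:
    """Shapiro-Wilk normality assessment per parameter.

    Returns a DataFrame indexed by parameter with the W statistic, the
    p-value, the classification (``normal`` iff p >= alpha) and the
    Freedman-Diaconis bin edges for a histogram.  Constant columns are
    flagged degenerate and classified non-normal.
    """
    cohort = _as_cohort(cohort)
    if cohort.n < 8:
        raise CohortSpecError("normality assessment needs n >= 8")
    X = cohort.matrix()
    rows = []
    for j, name in enumerate(PARAMETER_ORDER):
        x = X[:, j]
        if np.ptp(x) == 0:
            rows.append({"parameter": name, "statistic": np.nan, "p": np.nan,
                         "normal": False, "degenerate": True,
                         "bin_edges": np.array([x[0] - 0.5, x[0] + 0.5])})
            continue
        w, p = stats.shapiro(x)
        rows.append({"parameter": name, "statistic": float(w), "p": float(p),
                     "normal": bool(p >= alpha), "degenerate": False,
                     "bin_edges": freedman_diaconis_edges(x)})
    return pd.DataFrame(rows).set_index("parameter")


# ---------------------------------------------------------------------------
# report rendering
# ---------------------------------------------------------------------------

def plot_boxes(cohort: CohortLike, path: Optional[str] = None):
    """Box plots of all twelve parameters (grouped by unit scale)."""
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    cohort = _as_cohort(cohort)
    X = cohort.matrix()
    groups = [
        (["FHD", "OSA", "OSV", "OSH", "GTH"], "mm"),
        (["NCDF", "NCDS", "NCVD", "NCHD"], "mm"),
        (["TFL"], "mm"),
        (["ATA", "NSA"], "deg"),
    ]
    fig, axes = plt.subplots(1, len(groups), figsize=(12, 4))
    for ax, (names, unit) in zip(axes, groups):
        cols = [X[:, PARAMETER_ORDER.index(nm)] for nm in names]
        ax.boxplot(cols, tick_labels=names)
        ax.set_ylabel(unit)
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=120, metadata={"Software": None})
        plt.close(fig)
    return fig


def plot_histograms(cohort: CohortLike, path: Optional[str] = None):
    """Histograms of all twelve parameters with Freedman-Diaconis bins."""
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    cohort = _as_cohort(cohort)
    X = cohort.matrix()
    fig, axes = plt.subplots(3, 4, figsize=(13, 8))
    for ax, name in zip(axes.ravel(), PARAMETER_ORDER):
        x = X[:, PARAMETER_ORDER.index(name)]
        ax.hist(x, bins=freedman_diaconis_edges(x), color="#4477aa")
        ax.set_title(name)
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=120, metadata={"Software": None})
        plt.close(fig)
    return fig


def render_report(cohort: CohortLike, out_dir: str,
                  alpha: float = 0.05) -> List[str]:
    """Write the full cohort report into ``out_dir``.

    Produces ``cohort.csv`` (raw table), ``table1.csv`` (descriptives),
    ``table2_r.csv`` / ``table2_p.csv`` (correlations and p-values),
    ``normality.csv``, ``boxplots.png`` and ``histograms.png``.
    """
    cohort = _as_cohort(cohort)
    os.makedirs(out_dir, exist_ok=True)
    paths = []

    def out(name):
        p = os.path.join(out_dir, name)
        paths.append(p)
        return p

    write_table(cohort.df, out("cohort.csv"))
    desc = descriptives(cohort)
    desc.table.to_csv(out("table1.csv"), float_format="%.9f")
    corr = pearson_matrix(cohort, alpha=alpha)
    corr.r.to_csv(out("table2_r.csv"), float_format="%.9f")
    corr.p.to_csv(out("table2_p.csv"), float_format="%.9g")
    norm = normality_report(cohort, alpha=alpha)
    norm.drop(columns=["bin_edges"]).to_csv(out("normality.csv"),
                                            float_format="%.9g")
    plot_boxes(cohort, out("boxplots.png"))
    plot_histograms(cohort, out("histograms.png"))
    return paths
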