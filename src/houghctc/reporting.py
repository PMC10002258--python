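"""Sample-level aggregation, intra-assay CV and validation statistics.

Counts follow the assay's vocabulary: a *free CTC* is a component with a
single Hough center, a *cluster* is a component with two or more centers,
*clustered CTCs* are the individual cells inside clusters, and
``total = free + clustered``.  Densities are normalized by the processed
blood volume (7 mL draws by default).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as dc_field, asdict

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import ConfigurationError, InsufficientDataError
from .hough import CellEvent, ClusterEvent


def _stats(values: list[float]) -> dict[str, float]:
    if not values:
        return {"mean": math.nan, "median": math.nan, "sd": math.nan}
    arr = np.asarray(values, dtype=float)
    sd = float(arr.std(ddof=1)) if arr.size > 1 else 0.0
    return {"mean": float(arr.mean()), "median": float(np.median(arr)), "sd": sd}


@dataclass
class SampleResult:
    """Counts, per-mL densities and size statistics for one sample."""

    sample_id: str
    blood_volume_ml: float
    total_ctcs: int
    free_ctcs: int
    clusters: int
    clustered_ctcs: int
    rejected_components: int
    free_diameter_um: dict = dc_field(default_factory=dict)
    clustered_diameter_um: dict = dc_field(default_factory=dict)
    cluster_area_um2: dict = dc_field(default_factory=dict)

    @property
    def total_ctcs_per_ml(self) -> float:
        return self.total_ctcs / self.blood_volume_ml

    @property
    def free_ctcs_per_ml(self) -> float:
        return self.free_ctcs / self.blood_volume_ml

    @property
    def clusters_per_ml(self) -> float:
        return self.clusters / self.blood_volume_ml

    @property
    def clustered_ctcs_per_ml(self) -> float:
        return self.clustered_ctcs / self.blood_volume_ml

    def to_dict(self) -> dict:
        d = asdict(self)
        d.update(
            total_ctcs_per_ml=self.total_ctcs_per_ml,
            free_ctcs_per_ml=self.free_ctcs_per_ml,
            clusters_per_ml=self.clusters_per_ml,
            clustered_ctcs_per_ml=self.clustered_ctcs_per_ml,
        )
        return d


def summarize_sample(
    cell_events: list[CellEvent],
    cluster_events: list[ClusterEvent],
    blood_volume_ml: float = 7.0,
    sample_id: str = "sample",
    rejected_components: int = 0,
) -> SampleResult:
    """Aggregate one sample's events into counts and size statistics."""
    if blood_volume_ml <= 0:
        raise ConfigurationError("blood volume must be positive (mL)")
    free = [e for e in cell_events if e.kind == "free"]
    clustered = [e for e in cell_events if e.kind == "clustered"]
    n_clustered = sum(c.n_cells for c in cluster_events)
    if n_clustered != len(clustered):
        raise ValueError(
            f"inconsistent events: {n_clustered} cluster members vs {len(clustered)} clustered cells"
        )
    return SampleResult(
        sample_id=sample_id,
        blood_volume_ml=float(blood_volume_ml),
        total_ctcs=len(free) + len(clustered),
        free_ctcs=len(free),
        clusters=len(cluster_events),
        clustered_ctcs=len(clustered),
        rejected_components=rejected_components,
        free_diameter_um=_stats([e.diameter_um for e in free]),
        clustered_diameter_um=_stats([e.diameter_um for e in clustered]),
        cluster_area_um2=_stats([c.area_um2 for c in cluster_events]),
    )


def intra_assay_cv(replicate_counts: list[float]) -> float:
    """Coefficient of variation (%) across replicate counts of one sample.

    Uses the sample (n-1) standard deviation.  Returns NaN (flagged
    undefined) when the mean is zero.
    """
    if len(replicate_counts) < 2:
        raise InsufficientDataError("intra-assay CV needs at least 2 replicates")
    arr = np.asarray(replicate_counts, dtype=float)
    mean = arr.mean()
    if mean == 0:
        return math.nan
    return float(100.0 * arr.std(ddof=1) / mean)


def intra_assay_cv_table(replicates: list[SampleResult]) -> dict[str, float]:
    """CV%% per count type over replicate runs of one sample."""
    return {
        "total_ctcs": intra_assay_cv([r.total_ctcs for r in replicates]),
        "free_ctcs": intra_assay_cv([r.free_ctcs for r in replicates]),
        "clusters": intra_assay_cv([r.clusters for r in replicates]),
        "clustered_ctcs": intra_assay_cv([r.clustered_ctcs for r in replicates]),
    }


@dataclass
class ValidationMetrics:
    """Recovery / sensitivity / accuracy against a known ground truth.

    recovery    = 100 * counted / true
    sensitivity = 100 * well-counted / true
    accuracy    = 100 * well-counted / counted

    where *well-counted* means a detection matched to a true tumor-cell
    center within the match radius.
    """

    n_true: int
    n_counted: int
    n_well_counted: int

    @property
    def recovery_pct(self) -> float:
        return math.nan if self.n_true == 0 else 100.0 * self.n_counted / self.n_true

    @property
    def sensitivity_pct(self) -> float:
        return math.nan if self.n_true == 0 else 100.0 * self.n_well_counted / self.n_true

    @property
    def accuracy_pct(self) -> float:
        return math.nan if self.n_counted == 0 else 100.0 * self.n_well_counted / self.n_counted

    def to_dict(self) -> dict:
        return {
            "n_true": self.n_true,
            "n_counted": self.n_counted,
            "n_well_counted": self.n_well_counted,
            "recovery_pct": self.recovery_pct,
            "sensitivity_pct": self.sensitivity_pct,
            "accuracy_pct": self.accuracy_pct,
        }


def evaluate_against_truth(
    detected_centers: list[tuple[float, float]],
    true_centers: list[tuple[float, float]],
    match_radius_px: float = 10.0,
) -> ValidationMetrics:
    """Greedy nearest-pair matching of detections to true tumor centers.

    Candidate pairs within ``match_radius_px`` are taken in order of
    increasing distance (ties broken by detection raster order); each true
    cell and each detection is used at most once.  Matched detections are
    the *well-counted* cells.
    """
    pairs = []
    for di, (dy, dx) in enumerate(detected_centers):
        for ti, (ty, tx) in enumerate(true_centers):
            dist = math.hypot(dy - ty, dx - tx)
            if dist <= match_radius_px:
                pairs.append((dist, dy, dx, di, ti))
    pairs.sort(key=lambda p: (p[0], p[1], p[2]))
    used_d: set[int] = set()
    used_t: set[int] = set()
    matched = 0
    for dist, _, _, di, ti in pairs:
        if di in used_d or ti in used_t:
            continue
        used_d.add(di)
        used_t.add(ti)
        matched += 1
    return ValidationMetrics(
        n_true=len(true_centers),
        n_counted=len(detected_centers),
        n_well_counted=matched,
    )


def correlation_report(x: list[float], y: list[float]) -> dict[str, float]:
    """Spearman R^2 plus the OLS slope/intercept with 95% CIs.

    Mirrors the validation statistics used for method comparison: rank
    correlation (squared) for agreement, and a linear fit whose slope CI
    should cover 1 for an unbiased counter.  Degenerate (constant) inputs
    are flagged with NaNs.
    """
    x_arr = np.asarray(x, dtype=float)
    y_arr = np.asarray(y, dtype=float)
    if x_arr.size != y_arr.size or x_arr.size < 3:
        raise InsufficientDataError("correlation needs >= 3 paired samples")
    out: dict[str, float] = {}
    if np.ptp(x_arr) == 0 or np.ptp(y_arr) == 0:
        return {
            "spearman_r2": math.nan,
            "pearson_r2": math.nan,
            "slope": math.nan,
            "intercept": math.nan,
            "slope_ci95": (math.nan, math.nan),
            "intercept_ci95": (math.nan, math.nan),
            "degenerate": True,
        }
    rho = sps.spearmanr(x_arr, y_arr).statistic
    fit = sps.linregress(x_arr, y_arr)
    dof = x_arr.size - 2
    tcrit = sps.t.ppf(0.975, dof)
    out = {
        "spearman_r2": float(rho**2),
        "pearson_r2": float(fit.rvalue**2),
        "slope": float(fit.slope),
        "intercept": float(fit.intercept),
        "slope_ci95": (
            float(fit.slope - tcrit * fit.stderr),
            float(fit.slope + tcrit * fit.stderr),
        ),
        "intercept_ci95": (
            float(fit.intercept - tcrit * fit.intercept_stderr),
            float(fit.intercept + tcrit * fit.intercept_stderr),
        ),
        "degenerate": False,
    }
    return out


def compare_counts(a: list[float], b: list[float]) -> dict[str, float]:
    """Convenience two-sample comparison (t-test and Mann-Whitney U).

    Standard statistics offered for completeness of validation tables;
    not part of the counting method itself.
    """
    t = sps.ttest_ind(a, b)
    try:
        u = sps.mannwhitneyu(a, b)
        u_p = float(u.pvalue)
    except ValueError:  # identical constant samples
        u_p = math.nan
    return {"t_pvalue": float(t.pvalue), "mannwhitney_pvalue": u_p}


def results_to_dataframe(results: list[SampleResult]) -> pd.DataFrame:
    rows = []
    for r in results:
        d = r.to_dict()
        for key in ("free_diameter_um", "clustered_diameter_um", "cluster_area_um2"):
            stats = d.pop(key)
            for s_name, s_val in stats.items():
                d[f"{key}_{s_name}"] = s_val
        rows.append(d)
    return pd.DataFrame(rows)
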