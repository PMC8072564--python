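"""Per-image metrics assembly, control normalization and dose-response fitting.

Raw morphological readouts are normalized in two steps, mirroring standard
high-content-screening practice: first to a per-cell basis (nuclei count, or
neuron count for mixed cultures where only a subpopulation carries the
neurite stain), then to the mean of the solvent-control images of the same
experiment, expressed as percent of control.  Dose-response relationships
are summarized by a variable-slope sigmoid (four-parameter logistic) with
the upper asymptote fixed at the solvent-control level, yielding the median
lesion concentration (LD50).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

#: Metric columns that are normalized to percent-of-control.
PER_CELL_METRICS = [
    "neurite_length_per_cell_um",
    "branches_per_cell",
    "soma_area_per_cell_um2",
    "mean_nucleus_area_um2",
    "nuclei_count",
    "neuron_count",
]


@dataclass
class ImageMetrics:
    """All per-frame morphological readouts."""

    frame_id: str
    compound: str = ""
    concentration_nM: float = 0.0
    is_control: bool = False
    experiment_id: str = ""
    nuclei_count: int = 0
    neuron_count: int = 0
    mean_nucleus_area_um2: float = float("nan")
    total_soma_area_um2: float = 0.0
    soma_area_per_cell_um2: float = float("nan")
    neurite_area_um2: float = 0.0
    total_neurite_length_um: float = 0.0
    neurite_length_per_cell_um: float = float("nan")
    branch_point_count: int = 0
    endpoint_count: int = 0
    branch_segment_count: int = 0
    branches_per_cell: float = float("nan")
    excluded: bool = False
    exclude_reason: str = ""

    def as_dict(self) -> dict:
        return dict(self.__dict__)


@dataclass
class DoseResponseFit:
    """Constrained variable-slope sigmoid parameters."""

    top: float
    bottom: float
    hill_slope: float
    ld50: float
    rss: float
    converged: bool
    n_points: int = 0


@dataclass
class RegressionResult:
    slope: float
    intercept: float
    r_squared: float


def compute_image_metrics(
    frame_id: str,
    condition,
    nuclei_summary: dict,
    neuron_count: int,
    total_soma_area_um2: float,
    neurite_area_um2: float,
    total_neurite_length_um: float,
    branch_stats: dict,
    denominator: str = "nuclei",
) -> ImageMetrics:
    """Assemble the per-frame metrics row from all stage outputs.

    ``denominator`` selects the per-cell normalizer: ``"nuclei"`` (pure
    neuronal cultures where every cell is a neuron) or ``"neurons"`` (mixed
    cultures normalized to stain-positive cells).  A zero denominator sets
    the exclusion flag instead of raising.
    """
    if denominator not in ("nuclei", "neurons"):
        raise ValueError("denominator must be 'nuclei' or 'neurons'")
    m = ImageMetrics(
        frame_id=frame_id,
        compound=condition.compound,
        concentration_nM=condition.concentration_nM,
        is_control=condition.is_control,
        experiment_id=condition.experiment_id,
        nuclei_count=int(nuclei_summary["count"]),
        neuron_count=int(neuron_count),
        mean_nucleus_area_um2=float(nuclei_summary["mean_area_um2"]),
        total_soma_area_um2=float(total_soma_area_um2),
        neurite_area_um2=float(neurite_area_um2),
        total_neurite_length_um=float(total_neurite_length_um),
        branch_point_count=int(branch_stats["branch_point_count"]),
        endpoint_count=int(branch_stats["endpoint_count"]),
        branch_segment_count=int(branch_stats["branch_segment_count"]),
    )
    denom = m.nuclei_count if denominator == "nuclei" else m.neuron_count
    if denom > 0:
        m.neurite_length_per_cell_um = m.total_neurite_length_um / denom
        m.branches_per_cell = m.branch_point_count / denom
        m.soma_area_per_cell_um2 = m.total_soma_area_um2 / denom
    else:
        m.excluded = True
        m.exclude_reason = f"zero {denominator} count"
    return m


def metrics_table(metrics: Sequence[ImageMetrics]) -> pd.DataFrame:
    return pd.DataFrame([m.as_dict() for m in metrics])


def normalize_to_control(
    table: pd.DataFrame,
    control_compound: str = "DMSO",
    metrics: Optional[Sequence[str]] = None,
) -> pd.DataFrame:
    """Express per-cell metrics as percent of the solvent-control mean.

    Within each experiment, every metric is divided by the mean of that
    metric over the experiment's non-excluded control images and multiplied
    by 100, so the control-group mean maps to 100%.  Excluded frames never
    contribute to control means.
    """
    if metrics is None:
        metrics = [m for m in PER_CELL_METRICS if m in table.columns]
    out = table.copy()
    is_ctrl = (out["compound"] == control_compound) | out.get(
        "is_control", pd.Series(False, index=out.index)
    )
    for exp_id, group in out.groupby("experiment_id"):
        if group["excluded"].all():
            for m in metrics:
                out.loc[group.index, f"{m}_pct_control"] = np.nan
            continue
        ctrl = group[is_ctrl.loc[group.index] & ~group["excluded"]]
        if ctrl.empty:
            raise ValueError(f"experiment {exp_id!r}: no usable control images")
        for m in metrics:
            ref = ctrl[m].mean()
            col = f"{m}_pct_control"
            if ref == 0 or np.isnan(ref):
                out.loc[group.index, col] = np.nan
            else:
                out.loc[group.index, col] = group[m] / ref * 100.0
    return out


def four_param_logistic(
    c: np.ndarray, bottom: float, top: float, ld50: float, hill_slope: float
) -> np.ndarray:
    """Variable-slope sigmoid: y = bottom + (top-bottom) / (1 + 10^((log10 LD50 - log10 c) h))."""
    c = np.asarray(c, dtype=float)
    return bottom + (top - bottom) / (1.0 + 10.0 ** ((np.log10(ld50) - np.log10(c)) * hill_slope))


def fit_four_param_logistic(
    concentrations_nM: Sequence[float],
    responses_pct: Sequence[float],
    top_value: float,
) -> DoseResponseFit:
    """Least-squares variable-slope dose-response fit with fixed top.

    The upper asymptote is constrained to the solvent-control value
    (``top_value``); bottom (>= 0) and hill slope are free.  Initialization
    is multi-start over log-spaced LD50 seeds spanning the concentration
    range; the reported fit is the best residual sum of squares.

    Controls (concentration 0) must not be included: they enter only through
    ``top_value``.
    """
    c = np.asarray(concentrations_nM, dtype=float)
    y = np.asarray(responses_pct, dtype=float)
    if c.shape != y.shape:
        raise ValueError("concentrations and responses must have equal length")
    if np.any(c <= 0):
        raise ValueError("concentrations must be positive (controls enter via top_value)")
    if len(np.unique(c)) < 4:
        raise ValueError("need at least 4 distinct concentrations")
    if np.allclose(y, y[0]):
        return DoseResponseFit(top_value, float("nan"), float("nan"), float("nan"),
                               float("nan"), converged=False, n_points=len(y))

    logc = np.log10(c)

    def residuals(theta):
        bottom, hill, log_ld50 = theta
        pred = bottom + (top_value - bottom) / (1.0 + 10.0 ** ((log_ld50 - logc) * hill))
        return pred - y

    # hill may be negative: a lesion readout falls with concentration, which
    # this parameterization expresses as a negative slope
    lo = [0.0, -20.0, logc.min() - 2.0]
    hi = [max(top_value, y.max()) + 1e-9, 20.0, logc.max() + 2.0]
    b0 = max(float(y.min()), 0.0)
    best = None
    for seed in np.linspace(logc.min() - 1.0, logc.max() + 1.0, 7):
        for h0 in (-2.0, -1.0, -0.5, 0.5, 1.0, 2.0):
            theta0 = [min(max(b0, lo[0]), hi[0]), h0, float(seed)]
            try:
                res = least_squares(residuals, theta0, bounds=(lo, hi))
            except ValueError:
                continue
            if best is None or res.cost < best.cost:
                best = res
    if best is None:
        return DoseResponseFit(top_value, float("nan"), float("nan"), float("nan"),
                               float("nan"), converged=False, n_points=len(y))
    bottom, hill, log_ld50 = best.x
    rss = float(2.0 * best.cost)
    return DoseResponseFit(
        top=float(top_value),
        bottom=float(bottom),
        hill_slope=float(hill),
        ld50=float(10.0 ** log_ld50),
        rss=rss,
        converged=bool(best.success),
        n_points=len(y),
    )


def ols_regression(x: Sequence[float], y: Sequence[float]) -> RegressionResult:
    """Closed-form ordinary least squares of y on x with R^2.

    Used for method comparison (automated readout regressed on manual).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("x and y must have equal length")
    if len(x) < 3:
        raise ValueError("need at least 3 paired points")
    if np.allclose(x, x[0]):
        raise ValueError("x is constant")
    xm, ym = x.mean(), y.mean()
    sxx = float(np.sum((x - xm) ** 2))
    sxy = float(np.sum((x - xm) * (y - ym)))
    slope = sxy / sxx
    intercept = ym - slope * xm
    sse = float(np.sum((y - (slope * x + intercept)) ** 2))
    sst = float(np.sum((y - ym) ** 2))
    r2 = 1.0 if sst == 0 else 1.0 - sse / sst
    return RegressionResult(slope=slope, intercept=intercept, r_squared=r2)
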