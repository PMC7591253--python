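"""Calcium-trace activity quantification for CSF-contacting neurons.

Per-cell activity is summarised as the time-normalised integral of the
fractional fluorescence change, written ∫ΔF/F min⁻¹: the baseline F0 is a
low percentile of the trace (robust to transients), ΔF/F = (F − F0)/F0,
and the trapezoidal integral over the recording (time in minutes) is
divided by the recording duration in minutes, so a constant ΔF/F of c
scores exactly c. Populations (genotypes or treatments) are compared by
median percent change and a two-sample Kolmogorov–Smirnov test on the
per-cell activity distributions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .de import ValidationError

__all__ = [
    "CellActivity",
    "PopulationComparison",
    "TraceSet",
    "compare_populations",
    "compute_dff",
    "integrate_dff",
    "ks_two_sample",
    "quantify_traceset",
]

ROI_CLASSES = ("ventral", "dorsolateral")


@dataclass
class TraceSet:
    """Uniformly sampled fluorescence traces with per-ROI metadata.

    ``traces`` is indexed by time in seconds with one column per ROI;
    ``roi_meta`` is indexed by ROI id with columns ``roi_class``
    (``ventral`` or ``dorsolateral``) and ``group``. ``ground_truth``
    optionally stores simulator-planted event times and noise-free
    integrals for recovery checks.
    """

    traces: pd.DataFrame
    roi_meta: pd.DataFrame
    ground_truth: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        time = self.traces.index.to_numpy(float)
        if len(time) < 2 or not (np.diff(time) > 0).all():
            raise ValidationError("trace time axis must be strictly increasing")
        if (self.traces.to_numpy(float) < 0).any():
            raise ValidationError("negative fluorescence in trace set")
        missing = {"roi_class", "group"} - set(self.roi_meta.columns)
        if missing:
            raise ValidationError(f"roi_meta missing columns: {sorted(missing)}")
        unknown = set(self.roi_meta["roi_class"]) - set(ROI_CLASSES)
        if unknown:
            raise ValidationError(f"unknown ROI class labels: {sorted(unknown)}")
        meta_only = set(self.roi_meta.index) - set(self.traces.columns)
        trace_only = set(self.traces.columns) - set(self.roi_meta.index)
        if meta_only or trace_only:
            raise ValidationError(
                f"trace/metadata ROI mismatch: only in meta {sorted(meta_only)}, "
                f"only in traces {sorted(trace_only)}"
            )

    @property
    def time(self) -> np.ndarray:
        return self.traces.index.to_numpy(float)


@dataclass
class CellActivity:
    roi: str
    group: str
    dff: np.ndarray
    integral_per_min: float


@dataclass
class PopulationComparison:
    """Median-based percent change plus KS test between two populations.

    ``percent_change`` is (median_ref − median_test) / median_ref × 100:
    positive for a decrease in the test group, negative for an increase.
    """

    label_ref: str
    label_test: str
    median_ref: float
    median_test: float
    percent_change: float
    ks_d: float
    ks_p: float
    n_ref: int
    n_test: int


def compute_dff(
    trace: np.ndarray,
    baseline_method: str = "percentile",
    p: float = 10.0,
    window: int | None = None,
) -> np.ndarray:
    """Fractional fluorescence change relative to a percentile baseline.

    F0 is the p-th percentile of the whole trace (default p = 10), or of a
    centered sliding window of ``window`` samples with
    ``baseline_method="sliding"``. Requires F0 > 0.
    """
    f = np.asarray(trace, dtype=float)
    if (f < 0).any():
        raise ValidationError("trace contains negative fluorescence")
    if baseline_method == "percentile":
        f0 = np.percentile(f, p)
    elif baseline_method == "sliding":
        if not window or window < 2:
            raise ValidationError("sliding baseline requires window >= 2 samples")
        half = window // 2
        f0 = np.array(
            [np.percentile(f[max(0, i - half) : i + half + 1], p) for i in range(len(f))]
        )
    else:
        raise ValidationError(f"unknown baseline method {baseline_method!r}")
    if np.any(np.asarray(f0) <= 0):
        raise ValidationError(f"baseline F0 <= 0 (percentile p={p}); cannot normalise")
    return (f - f0) / f0


def integrate_dff(dff: np.ndarray, time_s: np.ndarray, rectify: bool = False) -> float:
    """Trapezoidal ∫ΔF/F dt over the recording, per minute of recording.

    Time is converted to minutes and the integral divided by total
    duration, so the statistic is the time average of ΔF/F; a constant
    ΔF/F of c returns exactly c. Negative excursions subtract unless
    ``rectify`` floors the signal at zero.
    """
    d = np.asarray(dff, dtype=float)
    t = np.asarray(time_s, dtype=float)
    if len(d) != len(t) or len(d) < 2:
        raise ValidationError("need >= 2 samples with matching time axis")
    if not (np.diff(t) > 0).all():
        raise ValidationError("time axis must be strictly increasing")
    if rectify:
        d = np.maximum(d, 0.0)
    t_min = t / 60.0
    return float(np.trapezoid(d, t_min) / (t_min[-1] - t_min[0]))


def ks_two_sample(x, y, method: str = "asymptotic") -> tuple[float, float]:
    """Two-sample Kolmogorov–Smirnov statistic and p-value.

    D is the supremum over pooled values of |ECDF_x − ECDF_y|; the p-value
    uses the asymptotic two-sample distribution by default (the per-cell
    sample sizes this statistic is used with are large), or the exact
    distribution with ``method="exact"`` for small samples.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValidationError("KS test requires non-empty samples")
    mode = {"asymptotic": "asymp", "exact": "exact"}.get(method)
    if mode is None:
        raise ValidationError(f"unknown KS method {method!r}")
    res = stats.ks_2samp(x, y, method=mode)
    return float(res.statistic), float(min(res.pvalue, 1.0))


def compare_populations(
    activities_ref,
    activities_test,
    label_ref: str = "reference",
    label_test: str = "test",
    ks_method: str = "asymptotic",
) -> PopulationComparison:
    """Median percent change (test vs reference) with an attached KS test.

    Refuses groups smaller than 3 cells, where medians are unstable.
    """
    ref = np.asarray(activities_ref, dtype=float)
    test = np.asarray(activities_test, dtype=float)
    if len(ref) < 3 or len(test) < 3:
        raise ValidationError(
            f"need >= 3 cells per group (got {len(ref)} and {len(test)}): medians unstable"
        )
    med_ref = float(np.median(ref))
    med_test = float(np.median(test))
    if med_ref == 0:
        raise ValidationError("reference median is zero; percent change undefined")
    d, p = ks_two_sample(ref, test, method=ks_method)
    return PopulationComparison(
        label_ref=label_ref,
        label_test=label_test,
        median_ref=med_ref,
        median_test=med_test,
        percent_change=(med_ref - med_test) / med_ref * 100.0,
        ks_d=d,
        ks_p=p,
        n_ref=len(ref),
        n_test=len(test),
    )


def quantify_traceset(
    traceset: TraceSet,
    class_filter: str = "ventral",
    baseline_percentile: float = 10.0,
    rectify: bool = False,
) -> list[CellActivity]:
    """Per-ROI ΔF/F integral for one dorsoventral class of neurons.

    The ventral population is the default (the class showing spontaneous
    transients); dorsolateral cells are quantified separately.
    """
    if class_filter not in ROI_CLASSES:
        raise ValidationError(
            f"unknown ROI class {class_filter!r}; expected one of {ROI_CLASSES}"
        )
    rois = traceset.roi_meta.index[traceset.roi_meta["roi_class"] == class_filter]
    if len(rois) == 0:
        warnings.warn(f"no ROIs of class {class_filter!r} in trace set", stacklevel=2)
    time = traceset.time
    out: list[CellActivity] = []
    for roi in rois:
        dff = compute_dff(traceset.traces[roi].to_numpy(float), p=baseline_percentile)
        out.append(
            CellActivity(
                roi=str(roi),
                group=str(traceset.roi_meta.loc[roi, "group"]),
                dff=dff,
                integral_per_min=integrate_dff(dff, time, rectify=rectify),
            )
        )
    return out
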