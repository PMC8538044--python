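"""Stage-reporter fluorescence courses: normalization, peak calling, and
developmental toxicity calls.

Each reporter course is normalized to the total fluorescent signal over the
24 h time course per replicate, so the mean normalized value across the T
time points is exactly 1/T. A course has a developmental profile when the
across-replicate mean at any time point reaches ``threshold/T`` — the
normalized-scale equivalent of "threshold-fold greater than the mean of the
total signal". The per-reporter threshold is calibrated on control
developments as the highest grid value (1.1-1.6, step 0.1) at which a peak
is always observed in every control.

Treated-vs-control comparisons test per-replicate peak times and peak
values with two-sided Welch t-tests, yielding the six-way call vocabulary
normal/absent/delayed/advanced/attenuated/elevated.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ReporterCourse",
    "PeakCall",
    "DevToxCall",
    "ProportioningResult",
    "DeadCourseError",
    "CalibrationError",
    "ControlFailureError",
    "THRESHOLD_GRID",
    "normalize_course",
    "detect_profile",
    "calibrate_threshold",
    "compare_development",
    "proportioning_score",
    "agreement_tally",
]

#: Peak-threshold grid from the calibration rule, fold over the course mean.
THRESHOLD_GRID = (1.1, 1.2, 1.3, 1.4, 1.5, 1.6)


class DeadCourseError(ValueError):
    """All-zero fluorescence course: normalization undefined."""


class CalibrationError(ValueError):
    """No grid threshold detects a peak in every control development."""


class ControlFailureError(ValueError):
    """The control development lacks a profile; the assay run is invalid."""


@dataclass(frozen=True)
class ReporterCourse:
    """One stage-reporter's fluorescence time series, replicates x time.

    ``raw`` and ``normalized`` are (n_replicates, T) arrays sharing
    ``times``; each normalized row sums to 1.
    """

    reporter: str
    times: np.ndarray
    raw: np.ndarray
    normalized: np.ndarray
    replicate_ids: tuple[str, ...]

    @property
    def n_replicates(self) -> int:
        return self.raw.shape[0]

    def mean_course(self) -> np.ndarray:
        return self.normalized.mean(axis=0)


@dataclass(frozen=True)
class PeakCall:
    has_profile: bool
    threshold_used: float
    peak_time_h: float | None = None
    peak_value: float | None = None

    def __post_init__(self) -> None:
        if not 1.1 <= self.threshold_used <= 1.6:
            raise ValueError("threshold must lie in [1.1, 1.6]")
        if not self.has_profile and (
            self.peak_time_h is not None or self.peak_value is not None
        ):
            raise ValueError("no profile implies no peak time/value")


@dataclass(frozen=True)
class DevToxCall:
    reporter: str
    call: str  # normal | absent | delayed | advanced | attenuated | elevated
    timing_p: float | None = None
    strength_p: float | None = None


@dataclass(frozen=True)
class ProportioningResult:
    prespore_signal: float | None
    prestalk_signal: float | None
    ratio_vs_wildtype: float | None
    valid: bool
    p_value: float | None = None


def _course_from_long(df: pd.DataFrame, reporter: str | None = None) -> tuple:
    if reporter is None:
        reporters = df["reporter"].unique()
        if len(reporters) != 1:
            raise ValueError("long table contains multiple reporters; pass one")
        reporter = reporters[0]
    sub = df[df["reporter"] == reporter]
    wide = sub.pivot(index="replicate_id", columns="time_h", values="fluorescence")
    wide = wide.sort_index(axis=1)
    return reporter, wide.columns.to_numpy(dtype=float), wide.to_numpy(dtype=float), tuple(wide.index)


def normalize_course(raw, reporter: str = "", times=None, replicate_ids=None) -> ReporterCourse:
    """Normalize a raw course to the total signal per replicate.

    Accepts a long DataFrame (``reporter, replicate_id, time_h,
    fluorescence``) or a (n_replicates, T) array plus ``times``. Every
    replicate row is divided by its summed signal; an all-zero replicate is
    a dead course.
    """
    if isinstance(raw, pd.DataFrame):
        reporter, times, values, replicate_ids = _course_from_long(raw, reporter or None)
    else:
        values = np.atleast_2d(np.asarray(raw, dtype=float))
        if times is None:
            raise ValueError("times required for array input")
        times = np.asarray(times, dtype=float)
        if replicate_ids is None:
            replicate_ids = tuple(f"R{i + 1}" for i in range(values.shape[0]))
    if times.size < 2:
        raise ValueError("need >= 2 time points")
    if not np.all(np.diff(times) > 0):
        raise ValueError("times must be strictly increasing")
    if np.any(values < 0):
        raise ValueError("raw fluorescence must be >= 0")
    totals = values.sum(axis=1)
    if np.any(totals <= 0):
        raise DeadCourseError("replicate with zero total signal")
    normalized = values / totals[:, None]
    return ReporterCourse(reporter, times, values, normalized, tuple(replicate_ids))


def detect_profile(course: ReporterCourse, threshold: float) -> PeakCall:
    """Decide whether the course has a developmental profile.

    The course has a profile iff the across-replicate mean normalized value
    at any time point is >= ``threshold/T``; the peak is the argmax of the
    mean course among qualifying points.
    """
    if not 1.1 <= threshold <= 1.6:
        raise ValueError("threshold must lie in [1.1, 1.6]")
    mean = course.mean_course()
    t_count = course.times.size
    cutoff = threshold / t_count
    qualifying = mean >= cutoff
    if not qualifying.any():
        return PeakCall(False, threshold)
    idx = int(np.argmax(mean))
    return PeakCall(True, threshold, float(course.times[idx]), float(mean[idx]))


def calibrate_threshold(
    control_courses: Sequence[ReporterCourse],
    grid: Sequence[float] = THRESHOLD_GRID,
) -> float:
    """Per-reporter threshold: the highest grid value at which a peak is
    observed in every control development."""
    if len(control_courses) == 0:
        raise ValueError("empty control set")
    for threshold in sorted(grid, reverse=True):
        if all(detect_profile(c, threshold).has_profile for c in control_courses):
            return float(threshold)
    raise CalibrationError(
        "no grid threshold detects a peak in every control development"
    )


def _replicate_peaks(course: ReporterCourse) -> tuple[np.ndarray, np.ndarray]:
    idx = np.argmax(course.normalized, axis=1)
    return course.times[idx], course.normalized[np.arange(course.n_replicates), idx]


def _welch(a: np.ndarray, b: np.ndarray) -> float:
    """Two-sided Welch p-value, defined even when both groups are constant."""
    if np.ptp(a) == 0 and np.ptp(b) == 0:
        return 1.0 if a.mean() == b.mean() else 0.0
    with warnings.catch_warnings():
        # peak times snap to the 2 h grid, so near-identical groups are routine
        warnings.simplefilter("ignore", RuntimeWarning)
        return float(stats.ttest_ind(a, b, equal_var=False).pvalue)


def compare_development(
    control: ReporterCourse,
    treated: ReporterCourse,
    threshold: float,
    alpha: float = 0.05,
) -> DevToxCall:
    """Call the treated course against the control at the calibrated threshold.

    Absent when the control has a profile and the treated course does not.
    Otherwise per-replicate peak times and peak values are compared with
    two-sided Welch t-tests: a significant timing shift is delayed/advanced,
    a significant strength change attenuated/elevated (timing takes
    precedence when both are significant), else normal.
    """
    if control.n_replicates < 2 or treated.n_replicates < 2:
        raise ValueError("need >= 2 replicates per condition")
    control_call = detect_profile(control, threshold)
    if not control_call.has_profile:
        raise ControlFailureError(
            f"control {control.reporter} course has no profile at threshold {threshold}"
        )
    treated_call = detect_profile(treated, threshold)
    if not treated_call.has_profile:
        return DevToxCall(treated.reporter, "absent")

    ct, cv = _replicate_peaks(control)
    tt, tv = _replicate_peaks(treated)
    timing_p = _welch(tt, ct)
    strength_p = _welch(tv, cv)
    if timing_p < alpha:
        call = "delayed" if tt.mean() > ct.mean() else "advanced"
    elif strength_p < alpha:
        call = "attenuated" if tv.mean() < cv.mean() else "elevated"
    else:
        call = "normal"
    return DevToxCall(treated.reporter, call, timing_p, strength_p)


def proportioning_score(
    prespore: ReporterCourse,
    prestalk: ReporterCourse,
    wildtype_prespore: ReporterCourse,
    wildtype_prestalk: ReporterCourse,
    fruiting_body_call: DevToxCall,
    at_time_h: float = 24.0,
) -> ProportioningResult:
    """Prespore/prestalk proportioning at 24 h, relative to wild type.

    Only computed when the fruiting-body reporter call is normal, which
    guards against delay artifacts. The ratio is
    ``(prespore/prestalk)_treated / (prespore/prestalk)_wildtype`` at the
    24 h point; significance by a Welch t-test on per-replicate ratios.
    """
    if fruiting_body_call.call != "normal":
        return ProportioningResult(None, None, None, valid=False)

    def _at(course: ReporterCourse) -> np.ndarray:
        idx = int(np.argmin(np.abs(course.times - at_time_h)))
        return course.normalized[:, idx]

    sp, st = _at(prespore), _at(prestalk)
    wsp, wst = _at(wildtype_prespore), _at(wildtype_prestalk)
    if np.any(st == 0) or np.any(wst == 0):
        raise ValueError("zero prestalk signal at 24 h: ratio undefined")
    treated_ratio = sp / st
    wt_ratio = wsp / wst
    ratio = float(treated_ratio.mean() / wt_ratio.mean())
    p = _welch(treated_ratio, wt_ratio)
    return ProportioningResult(
        float(sp.mean()), float(st.mean()), ratio, valid=True, p_value=p
    )


#: Pooling rules for the qualitative-vs-quantitative agreement tally.
#: "timing_pooled" merges timing defects with lack of expression;
#: "timing_strength_pooled" additionally merges strength defects.
_POOLING = {
    "strict": {},
    "timing_pooled": {"delayed": "defect", "advanced": "defect", "absent": "defect"},
    "timing_strength_pooled": {
        "delayed": "defect",
        "advanced": "defect",
        "absent": "defect",
        "attenuated": "defect",
        "elevated": "defect",
    },
}


def agreement_tally(
    qualitative: Mapping, quantitative: Mapping
) -> dict[str, tuple[int, int]]:
    """Count identical observations between two call matrices.

    Both mappings are keyed by (compound, reporter) with call-string
    values and must share keys exactly. Returns ``(n_identical, n_total)``
    under three pooling rules: strict; timing defects pooled with absence;
    and timing plus strength defects pooled.
    """
    if set(qualitative) != set(quantitative):
        raise ValueError("call matrices must share (compound, reporter) keys")
    out: dict[str, tuple[int, int]] = {}
    for rule, mapping in _POOLING.items():
        n_same = sum(
            mapping.get(qualitative[k], qualitative[k])
            == mapping.get(quantitative[k], quantitative[k])
            for k in qualitative
        )
        out[rule] = (n_same, len(qualitative))
    return out
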