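"""Growth toxicity: doubling-time estimation and NOAEL/LOAEL calling.

Doubling times come from a log-linear least-squares fit of ln(count) vs
time over the best exponential sub-window inside the 8-48 h observation
span. Dose ranges are anchored by converting the rat LD50 (mg/kg) to a
molar concentration (1 kg of body weight taken as 1 l), and a compound's
growth NOAEL/LOAEL are called from per-dose replicate doubling times with
a Welch test against untreated control wells, adverse meaning slower
growth (a doubling-time increase).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "GrowthFit",
    "CompoundRecord",
    "DoseResponseResult",
    "InsufficientDataError",
    "fit_doubling_time",
    "anchor_dose_from_ld50",
    "build_dose_ladder",
    "call_noael_loael",
]

logger = logging.getLogger(__name__)

LN2 = math.log(2.0)


class InsufficientDataError(ValueError):
    """Too few usable count points to fit a growth rate."""


@dataclass(frozen=True)
class GrowthFit:
    """Result of a log-linear doubling-time fit on one well."""

    doubling_time_h: float | None
    fit_window: tuple[float, float]
    r_squared: float
    n_points: int
    well_id: str = ""
    no_growth: bool = False


@dataclass(frozen=True)
class CompoundRecord:
    """A test compound with physical chemistry and mammalian reference data."""

    name: str
    mw_g_per_mol: float
    solvent: str = "H2O"
    teratogen_truth: str | None = None  # "teratogen" | "nonteratogen"
    rat_ld50_mg_per_kg: float | None = None
    rat_noael_mg_per_kg: dict = field(default_factory=dict)
    rat_loael_mg_per_kg: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.mw_g_per_mol <= 0:
            raise ValueError("mw_g_per_mol must be > 0")
        if self.solvent not in ("H2O", "DMSO"):
            raise ValueError("solvent must be H2O or DMSO")
        if self.teratogen_truth not in (None, "teratogen", "nonteratogen"):
            raise ValueError("bad teratogen_truth label")


@dataclass(frozen=True)
class DoseResponseResult:
    """Per-compound, per-assay NOAEL/LOAEL in mol/l with censoring flags."""

    compound: str
    assay: str  # "growth" | "development"
    noael_molar: float | None
    loael_molar: float | None
    censored: str = "none"  # "none" | "noael_only_max_dose" | "precipitated"
    doses_tested: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        if self.noael_molar is not None and self.loael_molar is not None:
            if not self.noael_molar < self.loael_molar:
                raise ValueError("NOAEL must be < LOAEL when both are defined")
        if self.censored == "noael_only_max_dose" and self.loael_molar is not None:
            raise ValueError("noael_only_max_dose censoring implies no LOAEL")


def _as_time_count(counts) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(counts, pd.DataFrame):
        t = counts["time_h"].to_numpy(dtype=float)
        c = counts["count"].to_numpy(dtype=float)
    else:
        t, c = counts
        t = np.asarray(t, dtype=float)
        c = np.asarray(c, dtype=float)
    order = np.argsort(t, kind="stable")
    return t[order], c[order]


def fit_doubling_time(
    counts,
    window: tuple[float, float] = (8.0, 48.0),
    min_span_h: float = 8.0,
    min_points: int = 5,
    r2_tol: float = 0.02,
    well_id: str = "",
) -> GrowthFit:
    """Fit the exponential-phase doubling time of one well.

    ``counts`` is either a DataFrame with ``time_h``/``count`` columns or a
    ``(times, counts)`` pair. Within ``window`` every contiguous sub-window
    spanning at least ``min_span_h`` hours with at least ``min_points``
    points is fit by log-linear least squares. Among windows whose r² lies
    within ``r2_tol`` of the best, the longest is kept (then higher r²,
    then earlier start): a short window can beat a long one on raw r² by
    chance alone, so parsimony guards the selection while lag and
    saturation phases — which depress r² far more than ``r2_tol`` — are
    still excluded. A non-positive best slope yields a no-growth flag with
    an undefined doubling time.
    """
    t, c = _as_time_count(counts)
    mask = (t >= window[0]) & (t <= window[1]) & (c > 0)
    t, c = t[mask], c[mask]
    n = t.size
    if n < 4:
        raise InsufficientDataError(
            f"only {n} usable points in window {window}; need >= 4"
        )
    y = np.log(c)

    def _fit(i: int, j: int) -> tuple[float, float]:
        """Return (slope, r2) for points i..j inclusive."""
        tt, yy = t[i : j + 1], y[i : j + 1]
        vt = tt.var()
        vy = yy.var()
        cov = ((tt - tt.mean()) * (yy - yy.mean())).mean()
        if vy == 0.0 or vt == 0.0:
            return 0.0, 0.0
        slope = cov / vt
        return slope, (cov * cov) / (vt * vy)

    if n < min_points:
        slope, r2 = _fit(0, n - 1)
        best = (slope, r2, 0, n - 1)
    else:
        candidates = []
        for i in range(n - min_points + 1):
            for j in range(i + min_points - 1, n):
                if t[j] - t[i] < min_span_h:
                    continue
                slope, r2 = _fit(i, j)
                candidates.append((slope, r2, i, j))
        if not candidates:  # span never reaches min_span_h: fall back to all points
            slope, r2 = _fit(0, n - 1)
            best = (slope, r2, 0, n - 1)
        else:
            r2_max = max(c[1] for c in candidates)
            # a numerically perfect window is never traded for a longer
            # contaminated one (noise-free series with lag/saturation)
            cutoff = 1.0 - 1e-9 if r2_max >= 1.0 - 1e-9 else r2_max - r2_tol
            best = max(
                (c for c in candidates if c[1] >= cutoff),
                key=lambda c: (c[3] - c[2], round(c[1], 12), -t[c[2]]),
            )
    slope, r2, i, j = best
    fit_window = (float(t[i]), float(t[j]))
    n_used = j - i + 1
    if slope <= 0:
        return GrowthFit(None, fit_window, r2, n_used, well_id, no_growth=True)
    return GrowthFit(LN2 / slope, fit_window, r2, n_used, well_id)


def anchor_dose_from_ld50(ld50_mg_per_kg: float, mw_g_per_mol: float) -> float:
    """Convert a rat LD50 in mg/kg to a molar anchor dose (mol/l).

    Assumes 1 kg of body weight is equivalent to 1 l, so
    mg/kg ÷ (g/mol) = mmol/l, returned in mol/l.
    """
    if ld50_mg_per_kg <= 0 or mw_g_per_mol <= 0:
        raise ValueError("LD50 and molecular weight must be > 0")
    return ld50_mg_per_kg / mw_g_per_mol * 1e-3


#: Development-mode fold factors: three 5-fold steps below the anchor and
#: two above (anchor/125 ... anchor*25).
DEVELOPMENT_FOLDS = (1 / 125, 1 / 25, 1 / 5, 1.0, 5.0, 25.0)


def build_dose_ladder(
    anchor_molar: float,
    mode: str = "development",
    span_fold: float = 100.0,
    n_doses: int = 6,
) -> np.ndarray:
    """Build the ordered dose list around an anchor dose.

    ``development`` returns the fixed fold ladder
    {anchor/125, /25, /5, anchor, x5, x25}. ``growth_initial`` returns a
    geometric ladder of ``n_doses`` doses spanning ``span_fold`` total
    (default 100-fold, i.e. 2 log-units) centered on the anchor.
    """
    if anchor_molar <= 0:
        raise ValueError("anchor dose must be > 0")
    if mode == "development":
        return anchor_molar * np.array(DEVELOPMENT_FOLDS)
    if mode == "growth_initial":
        if span_fold <= 1 or n_doses < 2:
            raise ValueError("span_fold must exceed 1 and n_doses >= 2")
        half = math.sqrt(span_fold)
        return np.geomspace(anchor_molar / half, anchor_molar * half, n_doses)
    raise ValueError(f"unknown ladder mode {mode!r}")


def call_noael_loael(
    doses_molar: Sequence[float],
    endpoints_by_dose: Sequence[Sequence[float]],
    control: Sequence[float],
    alpha: float = 0.05,
    adverse: str = "increase",
    min_effect: float | None = None,
    compound: str = "",
    assay: str = "growth",
) -> DoseResponseResult:
    """Call NOAEL and LOAEL from per-dose replicate endpoints.

    A dose is adverse when a two-sided Welch test against the control
    replicates is significant at ``alpha`` *and* the effect lies in the
    adverse direction (endpoint increase by default: a longer doubling
    time). ``min_effect`` optionally additionally requires the dose/control
    mean ratio to reach the given fold (guards pure type-I calls in
    noise-free screening designs). LOAEL is the lowest adverse dose; NOAEL
    the highest non-adverse tested dose below it. With no adverse dose, the
    NOAEL is the maximum tested dose and the result is censored.
    """
    doses = np.asarray(doses_molar, dtype=float)
    if doses.size == 0:
        raise ValueError("no doses supplied")
    if not np.all(np.diff(doses) > 0):
        raise ValueError("doses must be sorted strictly ascending")
    if len(endpoints_by_dose) != doses.size:
        raise ValueError("endpoints_by_dose must align with doses")
    control = np.asarray(control, dtype=float)
    if control.size < 2:
        raise ValueError("need >= 2 control replicates")
    if adverse not in ("increase", "decrease"):
        raise ValueError("adverse must be 'increase' or 'decrease'")

    sign = 1.0 if adverse == "increase" else -1.0
    adverse_flags = []
    for ep in endpoints_by_dose:
        ep = np.asarray(ep, dtype=float)
        if ep.size < 2:
            raise ValueError("need >= 2 replicates per dose")
        delta = sign * (ep.mean() - control.mean())
        if delta <= 0:
            adverse_flags.append(False)
            continue
        _, p = stats.ttest_ind(ep, control, equal_var=False)
        flag = bool(p < alpha)
        if flag and min_effect is not None:
            ratio = (ep.mean() / control.mean()) ** sign
            flag = ratio >= min_effect
        adverse_flags.append(flag)

    adverse_flags = np.array(adverse_flags)
    if not adverse_flags.any():
        return DoseResponseResult(
            compound,
            assay,
            noael_molar=float(doses[-1]),
            loael_molar=None,
            censored="noael_only_max_dose",
            doses_tested=tuple(doses),
        )
    loael_idx = int(np.argmax(adverse_flags))
    if adverse_flags[loael_idx:].size > 1 and not adverse_flags[loael_idx:].all():
        logger.warning(
            "%s %s: non-monotone dose response (adverse at %g but not at a higher dose); "
            "LOAEL kept at the lowest adverse dose",
            compound,
            assay,
            doses[loael_idx],
        )
    noael = float(doses[loael_idx - 1]) if loael_idx > 0 else None
    return DoseResponseResult(
        compound,
        assay,
        noael_molar=noael,
        loael_molar=float(doses[loael_idx]),
        censored="none",
        doses_tested=tuple(doses),
    )
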