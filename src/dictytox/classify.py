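"""Teratogen classification and predictivity metrics.

A compound is classified teratogenic when the ratio of its growth LOAEL
(or, where no growth LOAEL could be defined, the growth NOAEL) to its
development NOAEL is >= 10 — the teratogenic-potential-ratio rule used
across alternative DART models. Predictivity against the mammalian truth
labels is summarized by sensitivity, specificity, positive and negative
predictive value, overall predictive value (mean of PPV and NPV), and
overall concordance, printed to the nearest integer and stored at full
precision.

Cross-model dose datasets (rat acute/subacute/subchronic/developmental,
and other alternative models) are converted from mg/kg to molarity
(1 kg body weight taken as 1 l) and compared by pairwise Pearson
correlation on log10 molar doses, with pairs of n <= 3 flagged untested.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .growth import DoseResponseResult

__all__ = [
    "TeratogenCall",
    "PredictivityMetrics",
    "RATIO_CUTOFF",
    "classify_compound",
    "confusion_counts",
    "predictivity_metrics",
    "compare_to_reported",
    "convert_dose_table",
    "correlation_matrix",
    "phenotype_dose_tests",
]

logger = logging.getLogger(__name__)

#: Teratogenic-potential-ratio cutoff (growth LOAEL / development NOAEL).
RATIO_CUTOFF = 10.0


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


@dataclass(frozen=True)
class TeratogenCall:
    compound: str
    ratio: float
    growth_value_used: str  # "LOAEL" | "NOAEL"
    call: str  # "teratogen" | "nonteratogen"


@dataclass(frozen=True)
class PredictivityMetrics:
    """Confusion counts plus derived percentages (None when undefined)."""

    tp: int
    fp: int
    tn: int
    fn: int
    sensitivity: float | None
    specificity: float | None
    ppv: float | None
    npv: float | None
    overall_predictive_value: float | None
    concordance: float | None

    def rounded(self) -> dict[str, int | None]:
        """Nearest-integer percentages, table style."""
        return {
            name: (None if v is None else _round_half_up(v))
            for name, v in (
                ("sensitivity", self.sensitivity),
                ("specificity", self.specificity),
                ("ppv", self.ppv),
                ("npv", self.npv),
                ("overall_predictive_value", self.overall_predictive_value),
                ("concordance", self.concordance),
            )
        }


def classify_compound(
    growth: DoseResponseResult,
    development: DoseResponseResult,
    ratio_cutoff: float = RATIO_CUTOFF,
) -> TeratogenCall:
    """Classify one compound by the growth/development dose ratio.

    Uses the growth LOAEL, falling back to the growth NOAEL when no LOAEL
    was defined (recorded in ``growth_value_used``). A missing development
    NOAEL makes the compound unclassifiable. A ratio exactly at the cutoff
    classifies teratogenic (the rule is inclusive).
    """
    if development.noael_molar is None:
        raise ValueError(f"{development.compound}: no development NOAEL; unclassifiable")
    if growth.loael_molar is not None:
        value, used = growth.loael_molar, "LOAEL"
    elif growth.noael_molar is not None:
        value, used = growth.noael_molar, "NOAEL"
    else:
        raise ValueError(f"{growth.compound}: no growth LOAEL or NOAEL; unclassifiable")
    ratio = value / development.noael_molar
    call = "teratogen" if ratio >= ratio_cutoff else "nonteratogen"
    return TeratogenCall(growth.compound, ratio, used, call)


def confusion_counts(
    calls: Sequence[TeratogenCall], truth: Mapping[str, str]
) -> tuple[int, int, int, int]:
    """(tp, fp, tn, fn) of calls against mammalian truth labels."""
    tp = fp = tn = fn = 0
    for c in calls:
        label = truth[c.compound]
        if label not in ("teratogen", "nonteratogen"):
            raise ValueError(f"bad truth label {label!r} for {c.compound}")
        if c.call == "teratogen":
            if label == "teratogen":
                tp += 1
            else:
                fp += 1
        else:
            if label == "nonteratogen":
                tn += 1
            else:
                fn += 1
    return tp, fp, tn, fn


def predictivity_metrics(
    tp: int, fp: int, tn: int, fn: int
) -> PredictivityMetrics:
    """Predictivity percentages from a confusion matrix.

    sensitivity = 100*tp/(tp+fn); specificity = 100*tn/(tn+fp);
    ppv = 100*tp/(tp+fp); npv = 100*tn/(tn+fn);
    overall predictive value = (ppv+npv)/2;
    concordance = 100*(tp+tn)/N. An empty denominator leaves the metric
    undefined (None), never 0.
    """

    def _pct(num: int, den: int) -> float | None:
        return None if den == 0 else 100.0 * num / den

    sens = _pct(tp, tp + fn)
    spec = _pct(tn, tn + fp)
    ppv = _pct(tp, tp + fp)
    npv = _pct(tn, tn + fn)
    opv = None if ppv is None or npv is None else (ppv + npv) / 2.0
    conc = _pct(tp + tn, tp + fp + tn + fn)
    return PredictivityMetrics(tp, fp, tn, fn, sens, spec, ppv, npv, opv, conc)


def compare_to_reported(
    metrics: PredictivityMetrics, reported: Mapping[str, float]
) -> dict[str, tuple[int, float]]:
    """Flag reported percentages inconsistent with the computed metrics.

    Returns ``{metric: (computed_rounded, reported)}`` for every reported
    value whose nearest-integer computed counterpart disagrees.
    """
    rounded = metrics.rounded()
    mismatches = {}
    for name, value in reported.items():
        if name not in rounded:
            raise KeyError(f"unknown metric {name!r}")
        got = rounded[name]
        if got is None or got != _round_half_up(float(value)):
            mismatches[name] = (got, float(value))
    return mismatches


def convert_dose_table(
    raw: pd.DataFrame, mw_g_per_mol: Mapping[str, float]
) -> pd.DataFrame:
    """Convert an mg/kg dose table to molarity, one row per compound.

    ``raw`` needs columns ``compound`` and ``dose_mg_per_kg``; duplicate
    rows per compound (conflicting sources) resolve to the lowest value.
    mol/l = (mg/kg) / (g/mol) / 1000. Compounds without a molecular weight
    are dropped with a warning.
    """
    required = {"compound", "dose_mg_per_kg"}
    if not required <= set(raw.columns):
        raise ValueError(f"dose table needs columns {sorted(required)}")
    lowest = raw.groupby("compound", sort=True)["dose_mg_per_kg"].min()
    if (lowest <= 0).any():
        raise ValueError("doses must be > 0")
    rows = []
    for compound, dose in lowest.items():
        mw = mw_g_per_mol.get(compound)
        if mw is None:
            logger.warning("%s: no molecular weight; dropped from dose table", compound)
            continue
        rows.append({"compound": compound, "dose_molar": dose / mw * 1e-3})
    return pd.DataFrame(rows, columns=["compound", "dose_molar"])


def correlation_matrix(
    datasets: pd.DataFrame, min_n: int = 3, log_scale: bool = True
) -> pd.DataFrame:
    """Pairwise Pearson correlations between toxicity endpoints.

    ``datasets`` is a compounds x endpoints table of molar doses (NaN for
    missing). Correlations use pairwise-complete compounds on log10 doses
    (doses span several orders of magnitude; a linear-scale variant sits
    behind ``log_scale=False``). Pairs with n <= ``min_n`` overlapping
    compounds are reported but flagged untested (r, p = NaN).

    Returns a long table ``endpoint_a, endpoint_b, n, r, r2, p, tested``.
    """
    values = datasets.astype(float)
    if log_scale:
        if (values <= 0).any().any():
            raise ValueError("doses must be > 0 for log-scale correlation")
        values = np.log10(values)
    cols = list(values.columns)
    rows = []
    for i, a in enumerate(cols):
        for b in cols[i:]:
            x, y = values[a], values[b]
            mask = x.notna() & y.notna()
            n = int(mask.sum())
            if n > min_n:
                r, p = stats.pearsonr(x[mask], y[mask])
                rows.append((a, b, n, float(r), float(r * r), float(p), True))
            else:
                rows.append((a, b, n, np.nan, np.nan, np.nan, False))
    return pd.DataFrame(
        rows, columns=["endpoint_a", "endpoint_b", "n", "r", "r2", "p", "tested"]
    )


def phenotype_dose_tests(
    groups: Mapping[str, Sequence[float]], log_scale: bool = True
) -> dict[str, float]:
    """Test whether development NOAEL doses differ between phenotype classes.

    One-way ANOVA on log10 NOAEL across >2 stage groups; a two-sided Welch
    t-test when exactly 2 groups are supplied (the proportioning
    comparison). Returns ``{"test": name, "statistic": ..., "p": ...}``.
    """
    arrays = []
    for label, vals in groups.items():
        v = np.asarray(vals, dtype=float)
        if v.size < 2:
            raise ValueError(f"group {label!r} needs >= 2 members")
        if log_scale:
            if np.any(v <= 0):
                raise ValueError("doses must be > 0 for log scale")
            v = np.log10(v)
        arrays.append(v)
    if len(arrays) < 2:
        raise ValueError("need >= 2 groups")
    if len(arrays) == 2:
        res = stats.ttest_ind(arrays[0], arrays[1], equal_var=False)
        return {"test": "welch_t", "statistic": float(res.statistic), "p": float(res.pvalue)}
    res = stats.f_oneway(*arrays)
    return {"test": "anova", "statistic": float(res.statistic), "p": float(res.pvalue)}
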