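"""End-to-end synthetic cohort: simulate -> growth -> devtox -> classify.

A planted cohort assigns each synthetic compound a growth-toxicity
threshold (the ladder position at which the doubling time doubles) and,
optionally, a developmental-block threshold (the dose from which the
fruiting-body reporter never activates). Running the real analysis stack
over the generated tables must recover the planted NOAEL/LOAEL positions
and hence the planted confusion matrix against the cohort's truth labels.

Two deliberate analysis choices keep the round trip deterministic at the
study noise levels (see docs/methods.md): growth adversity additionally
requires a 1.2-fold doubling-time increase on top of Welch significance,
and a development dose counts adverse when the fruiting-body profile is
absent at the calibrated threshold (the planted defect is a block).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import classify as _classify
from . import growth as _growth
from . import reporter as _reporter
from . import synthetic as _synthetic

__all__ = [
    "PlantedCompound",
    "CohortResult",
    "default_cohort",
    "simulate_cohort",
    "analyze_cohort",
    "growth_dose_response",
    "dev_dose_response",
    "run_cohort_pipeline",
]

#: Dose multiplier applied to the doubling time at adverse growth doses.
GROWTH_EFFECT = 2.0
#: Minimal doubling-time fold increase for a growth dose to count adverse.
MIN_GROWTH_EFFECT = 1.2


@dataclass(frozen=True)
class PlantedCompound:
    """Ground truth for one synthetic compound.

    ``growth_loael_index``/``dev_block_index`` are 1-based positions in the
    6-dose growth and development ladders from which the effect applies
    (None = no effect at any tested dose).
    """

    name: str
    anchor_molar: float
    truth: str  # teratogen | nonteratogen
    growth_loael_index: int | None
    dev_block_index: int | None
    mw_g_per_mol: float = 100.0
    solvent: str = "H2O"


@dataclass(frozen=True)
class CohortResult:
    calls: pd.DataFrame
    confusion: tuple[int, int, int, int]  # tp, fp, tn, fn
    metrics: _classify.PredictivityMetrics


def default_cohort() -> list[PlantedCompound]:
    """The 12-compound planted cohort used by the round-trip check.

    Seven compounds carry teratogen-range ratios (development blocked well
    below the growth LOAEL) and five nonteratogen-range ratios; truth
    labels are planted so the expected confusion matrix is
    tp=5, fp=2, tn=4, fn=1.
    """
    planted = [
        # name, anchor (mol/l), truth, growth LOAEL idx, dev block idx
        ("C01", 1.0e-3, "teratogen", 4, 2),
        ("C02", 3.0e-4, "teratogen", 3, 2),
        ("C03", 2.0e-3, "teratogen", 5, 3),
        ("C04", 5.0e-4, "teratogen", 4, 3),
        ("C05", 1.5e-3, "teratogen", 3, 3),
        ("C06", 8.0e-4, "nonteratogen", 4, 2),
        ("C07", 2.5e-3, "nonteratogen", 5, 2),
        ("C08", 1.2e-3, "nonteratogen", 4, 5),
        ("C09", 6.0e-4, "nonteratogen", 3, None),
        ("C10", 1.8e-3, "nonteratogen", 4, None),
        ("C11", 9.0e-4, "nonteratogen", 5, 5),
        ("C12", 1.4e-3, "teratogen", 4, 5),
    ]
    return [
        PlantedCompound(name, anchor, truth, g_idx, d_idx)
        for name, anchor, truth, g_idx, d_idx in planted
    ]


def _growth_doses(compound: PlantedCompound) -> np.ndarray:
    return _growth.build_dose_ladder(compound.anchor_molar, "growth_initial")


def _dev_doses(compound: PlantedCompound) -> np.ndarray:
    # The development ladder is anchored on the growth NOAEL, the dose one
    # step below the planted growth LOAEL (or the top dose when growth is
    # never affected).
    g = _growth_doses(compound)
    idx = compound.growth_loael_index
    noael = g[idx - 2] if idx is not None and idx >= 2 else g[-1]
    return _growth.build_dose_ladder(noael, "development")


def simulate_cohort(
    cohort: list[PlantedCompound] | None = None,
    seed: int = 0,
    count_noise_cv: float = 0.05,
    reporter_noise_cv: float = 0.05,
    n_wells: int = 3,
    n_reps: int = 3,
) -> dict[str, pd.DataFrame]:
    """Generate every input table for the cohort round trip.

    Returns a dict of long tables: ``growth_counts`` (compound, dose_molar,
    well_id, time_h, count; dose 0 = control), ``reporter_courses``
    (compound, dose_molar, reporter, replicate_id, time_h, fluorescence;
    dose 0 = control), and ``truth`` (compound, teratogen_truth,
    mw_g_per_mol, solvent).
    """
    if cohort is None:
        cohort = default_cohort()
    seq = np.random.SeedSequence(seed)
    sub = iter(seq.generate_state(16 * len(cohort)))  # 7 growth + 7 dev draws per compound

    growth_rows, reporter_rows, truth_rows = [], [], []
    for compound in cohort:
        gd = _growth_doses(compound)
        for dose_idx, dose in enumerate([0.0, *gd]):
            adverse = (
                compound.growth_loael_index is not None
                and dose_idx >= compound.growth_loael_index
            )
            cfg = _synthetic.SimConfig(
                seed=int(next(sub) % 2**31),
                n_wells=n_wells,
                count_noise_cv=count_noise_cv,
            )
            counts = _synthetic.gen_growth_counts(
                cfg, dose_effect=GROWTH_EFFECT if adverse else 1.0
            )
            counts.insert(0, "compound", compound.name)
            counts.insert(1, "dose_molar", dose)
            growth_rows.append(counts)

        dd = _dev_doses(compound)
        for dose_idx, dose in enumerate([0.0, *dd]):
            blocked = (
                compound.dev_block_index is not None
                and dose_idx >= compound.dev_block_index
            )
            course = _synthetic.gen_reporter_course(
                "fruiting_body",
                n_reps=n_reps,
                seed=int(next(sub) % 2**31),
                block_at="initiation" if blocked else None,
                noise_cv=reporter_noise_cv,
            )
            course.insert(0, "compound", compound.name)
            course.insert(1, "dose_molar", dose)
            reporter_rows.append(course)

        truth_rows.append(
            {
                "compound": compound.name,
                "teratogen_truth": compound.truth,
                "mw_g_per_mol": compound.mw_g_per_mol,
                "solvent": compound.solvent,
            }
        )
    return {
        "growth_counts": pd.concat(growth_rows, ignore_index=True),
        "reporter_courses": pd.concat(reporter_rows, ignore_index=True),
        "truth": pd.DataFrame(truth_rows),
    }


def growth_dose_response(
    counts: pd.DataFrame, compound: str, alpha: float, min_effect: float | None
) -> _growth.DoseResponseResult:
    sub = counts[counts["compound"] == compound]
    endpoints: dict[float, list[float]] = {}
    for (dose, _well), grp in sub.groupby(["dose_molar", "well_id"]):
        fit = _growth.fit_doubling_time(grp)
        if fit.doubling_time_h is None:
            continue
        endpoints.setdefault(float(dose), []).append(fit.doubling_time_h)
    control = endpoints.pop(0.0)
    doses = sorted(endpoints)
    return _growth.call_noael_loael(
        doses,
        [endpoints[d] for d in doses],
        control,
        alpha=alpha,
        adverse="increase",
        min_effect=min_effect,
        compound=compound,
        assay="growth",
    )


def dev_dose_response(
    courses: pd.DataFrame, compound: str
) -> _growth.DoseResponseResult:
    sub = courses[courses["compound"] == compound]
    by_dose = {}
    for dose, grp in sub.groupby("dose_molar"):
        by_dose[float(dose)] = _reporter.normalize_course(
            grp[["reporter", "replicate_id", "time_h", "fluorescence"]]
        )
    control = by_dose.pop(0.0)
    threshold = _reporter.calibrate_threshold([control])
    doses = sorted(by_dose)
    absent = [
        _reporter.compare_development(control, by_dose[d], threshold).call == "absent"
        for d in doses
    ]
    if not any(absent):
        return _growth.DoseResponseResult(
            compound,
            "development",
            noael_molar=doses[-1],
            loael_molar=None,
            censored="noael_only_max_dose",
            doses_tested=tuple(doses),
        )
    loael_idx = absent.index(True)
    return _growth.DoseResponseResult(
        compound,
        "development",
        noael_molar=doses[loael_idx - 1] if loael_idx > 0 else None,
        loael_molar=doses[loael_idx],
        censored="none",
        doses_tested=tuple(doses),
    )


def analyze_cohort(
    tables: dict[str, pd.DataFrame],
    alpha: float = 0.05,
    ratio_cutoff: float = _classify.RATIO_CUTOFF,
    min_growth_effect: float | None = MIN_GROWTH_EFFECT,
) -> CohortResult:
    """Run the growth -> devtox -> classify stack over simulated tables."""
    truth = tables["truth"].set_index("compound")["teratogen_truth"].to_dict()
    rows, calls = [], []
    for compound in tables["truth"]["compound"]:
        g = growth_dose_response(
            tables["growth_counts"], compound, alpha, min_growth_effect
        )
        d = dev_dose_response(tables["reporter_courses"], compound)
        call = _classify.classify_compound(g, d, ratio_cutoff=ratio_cutoff)
        calls.append(call)
        rows.append(
            {
                "compound": compound,
                "growth_noael_molar": g.noael_molar,
                "growth_loael_molar": g.loael_molar,
                "growth_censored": g.censored,
                "dev_noael_molar": d.noael_molar,
                "dev_loael_molar": d.loael_molar,
                "dev_censored": d.censored,
                "ratio": call.ratio,
                "growth_value_used": call.growth_value_used,
                "call": call.call,
                "truth": truth[compound],
            }
        )
    tp, fp, tn, fn = _classify.confusion_counts(calls, truth)
    metrics = _classify.predictivity_metrics(tp, fp, tn, fn)
    return CohortResult(pd.DataFrame(rows), (tp, fp, tn, fn), metrics)


def run_cohort_pipeline(seed: int = 0, **kwargs) -> CohortResult:
    """Simulate the default cohort and analyze it in one call."""
    tables = simulate_cohort(seed=seed)
    return analyze_cohort(tables, **kwargs)


def expected_confusion(cohort: list[PlantedCompound] | None = None) -> tuple[int, int, int, int]:
    """The confusion matrix implied by the planted thresholds alone.

    Computed analytically from the planted ladder positions (no
    simulation): growth LOAEL = ladder[idx-1], dev NOAEL = dev
    ladder[idx-2] (or the top dev dose when never blocked).
    """
    if cohort is None:
        cohort = default_cohort()
    tp = fp = tn = fn = 0
    for compound in cohort:
        g = _growth_doses(compound)
        if compound.growth_loael_index is not None:
            growth_value = g[compound.growth_loael_index - 1]
        else:
            growth_value = g[-1]  # NOAEL fallback
        dd = _dev_doses(compound)
        if compound.dev_block_index is not None:
            if compound.dev_block_index < 2:
                raise ValueError("planted dev block at the lowest dose leaves no NOAEL")
            dev_noael = dd[compound.dev_block_index - 2]
        else:
            dev_noael = dd[-1]
        call = "teratogen" if growth_value / dev_noael >= _classify.RATIO_CUTOFF else "nonteratogen"
        if call == "teratogen":
            if compound.truth == "teratogen":
                tp += 1
            else:
                fp += 1
        else:
            if compound.truth == "nonteratogen":
                tn += 1
            else:
                fn += 1
    return tp, fp, tn, fn
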