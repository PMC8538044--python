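"""Individual-mutant validation scores.

Competition fitness: a candidate mutant grows in 50:50 mixed culture with
a GFP-labeled wild type, with and without drug, for up to 6 rounds (or
until fixation). Trajectories are renormalized so the adjusted round-0
mutant fraction is exactly 0.5 (odds rescaling, preserving the [0,1]
range), and the fitness score is the mean log2 ratio of the normalized
drug to vehicle fractions at round 3 and the final round. Zero score means
the drug made no difference.

Fluid uptake: macropinocytosis measured as the median fluorescence of
ingested labeled dextran. Per strain the fold-change reduction after
treatment is MFI_untreated / MFI_treated; the uptake score is the log2
ratio of the test mutant's reduction to the control mutant's.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "FitnessScore",
    "UptakeScore",
    "normalize_competition",
    "competition_fitness",
    "fluid_uptake_score",
]


@dataclass(frozen=True)
class FitnessScore:
    mutant: str
    score: float  # log2 units
    rounds_used: tuple[int, ...]


@dataclass(frozen=True)
class UptakeScore:
    mutant: str
    drug: str
    fold_reduction_mutant: float
    fold_reduction_control: float
    score: float  # log2 units


def _as_rounds_series(series) -> pd.Series:
    if isinstance(series, pd.DataFrame):
        s = series.set_index("round")["fraction_mutant"]
    else:
        s = pd.Series(series)
        if not isinstance(series, pd.Series):
            s.index = range(len(s))
    return s.astype(float).sort_index()


def normalize_competition(series) -> pd.Series:
    """Renormalize a competition trajectory to an exact 50:50 start.

    ``series`` is a round-indexed Series of mutant fractions (or a
    DataFrame with ``round``/``fraction_mutant``). Every round's mutant
    odds are rescaled by the factor that maps the observed round-0 odds to
    1, so the adjusted round-0 fraction is exactly 0.5; output clipped to
    [0, 1].
    """
    s = _as_rounds_series(series)
    if 0 not in s.index:
        raise ValueError("round 0 must be present")
    f0 = s.loc[0]
    if not 0 < f0 < 1:
        raise ValueError("round-0 fraction must lie strictly in (0, 1)")
    if ((s < 0) | (s > 1)).any():
        raise ValueError("fractions must lie in [0, 1]")
    correction = (1.0 - f0) / f0  # maps round-0 odds to exactly 1
    with np.errstate(divide="ignore"):
        odds = s / (1.0 - s)
    adjusted = odds * correction
    out = adjusted / (1.0 + adjusted)
    out[s == 1.0] = 1.0  # fixation survives the odds transform
    return out.clip(0.0, 1.0)


def competition_fitness(
    drug_series,
    vehicle_series,
    mutant: str = "",
    mid_round: int = 3,
    epsilon: float = 5e-5,
) -> FitnessScore:
    """Competition fitness score from drug and vehicle trajectories.

    Both trajectories are normalized to the 50:50 start, then
    ``score = mean over {round 3, final round} of
    log2(norm_drug / norm_vehicle)``, the final round being round 6 or the
    round at which either strain fixed. Fractions are floored at
    ``epsilon`` (default 1/(2 x 10^4 cells measured)) so fixation keeps the
    score finite.
    """
    drug = normalize_competition(drug_series)
    vehicle = normalize_competition(vehicle_series)
    common = drug.index.intersection(vehicle.index)
    if mid_round not in common:
        raise ValueError(f"round {mid_round} missing from both series")
    final = int(common.max())
    rounds = (mid_round, final) if final != mid_round else (mid_round,)
    ratios = [
        np.log2(max(drug.loc[r], epsilon) / max(vehicle.loc[r], epsilon))
        for r in rounds
    ]
    return FitnessScore(mutant, float(np.mean(ratios)), rounds)


def fluid_uptake_score(
    mutant_mfi_untreated: float,
    mutant_mfi_treated: float,
    control_mfi_untreated: float,
    control_mfi_treated: float,
    mutant: str = "",
    drug: str = "",
) -> UptakeScore:
    """Fluid uptake score of a mutant relative to a control mutant.

    fold_reduction = MFI_untreated / MFI_treated per strain (values > 1
    mean treatment reduces uptake); score = log2(reduction_mutant /
    reduction_control). All MFIs must be positive.
    """
    mfis = (
        mutant_mfi_untreated,
        mutant_mfi_treated,
        control_mfi_untreated,
        control_mfi_treated,
    )
    if any(v <= 0 for v in mfis):
        raise ValueError("all median fluorescence intensities must be > 0")
    fr_mut = mutant_mfi_untreated / mutant_mfi_treated
    fr_ctl = control_mfi_untreated / control_mfi_treated
    return UptakeScore(mutant, drug, fr_mut, fr_ctl, float(np.log2(fr_mut / fr_ctl)))
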