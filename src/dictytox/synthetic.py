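"""Synthetic inputs for the toxicity pipeline.

Every table the downstream modules consume can be generated here with the
statistical structure the analyses assume: exponential well growth with lag
and overdispersed count noise, stage-reporter fluorescence courses over the
24 h developmental cycle, multi-round pooled selection screens with
per-mutant selection coefficients, and two-strain competition trajectories.

All generators are driven by a single integer seed; identical seeds yield
byte-identical tables. Replicate-level stochasticity uses independent
sub-streams spawned from the master seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "STAGES",
    "STAGE_ORDER",
    "SimConfig",
    "ScreenSimConfig",
    "gen_growth_counts",
    "gen_reporter_course",
    "gen_screen_counts",
    "gen_competition",
    "propagate_frequencies",
    "reporter_times",
]

#: Canonical ordering of the six developmental stages over the 24 h cycle.
STAGES = (
    "initiation",
    "streaming",
    "mound",
    "slug",
    "culminant",
    "fruiting_body",
)
STAGE_ORDER = {stage: i for i, stage in enumerate(STAGES)}

# Reporter course shape per stage: (peak center h, width h, peak amplitude,
# baseline). Centers follow the observed reporter timings: development
# initiation is maximal at the start and decays; streaming rises from ~6 h;
# the mound signal rises from ~12 h through mid/late development; the slug
# reporter spikes transiently between 12 and 16 h on an elevated baseline;
# the culminant reporter appears after ~20 h and the fruiting-body reporter
# only after 22-24 h.
_STAGE_SHAPES: dict[str, tuple[float, float, float, float]] = {
    "initiation": (2.0, 4.0, 6.0, 1.0),
    "streaming": (10.0, 4.0, 5.0, 1.0),
    "mound": (16.0, 4.0, 5.0, 1.0),
    "slug": (14.0, 2.0, 4.0, 1.5),
    "culminant": (22.0, 2.0, 5.0, 0.5),
    "fruiting_body": (24.0, 2.0, 6.0, 0.3),
}


def _lognorm_sigma(cv: float) -> float:
    """Sigma of a unit-mean lognormal with the given coefficient of variation."""
    return float(np.sqrt(np.log1p(cv * cv)))


def _noise_factors(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    """Unit-mean multiplicative lognormal noise with coefficient of variation cv."""
    if cv == 0:
        return np.ones(size)
    sigma = _lognorm_sigma(cv)
    return rng.lognormal(mean=-0.5 * sigma * sigma, sigma=sigma, size=size)


@dataclass(frozen=True)
class SimConfig:
    """Conditions for the time-lapse growth-count simulation.

    Defaults mirror the study design: 3 replicate wells filmed at a 1 h
    framerate over 48 h, with the wild-type doubling time of roughly 10 h
    in axenic medium.
    """

    seed: int = 0
    n_wells: int = 3
    true_doubling_h: float = 10.0
    lag_h: float = 0.0
    carrying_capacity: float = 1e5
    count_noise_cv: float = 0.05
    time_step_h: float = 1.0
    horizon_h: float = 48.0
    initial_count: float = 200.0

    def __post_init__(self) -> None:
        if self.true_doubling_h <= 0:
            raise ValueError("true_doubling_h must be > 0")
        if self.count_noise_cv < 0:
            raise ValueError("count_noise_cv must be >= 0")
        if self.n_wells < 1:
            raise ValueError("n_wells must be >= 1")
        if self.time_step_h <= 0 or self.horizon_h <= 0:
            raise ValueError("time grid must be positive")
        if self.initial_count <= 0 or self.carrying_capacity <= 0:
            raise ValueError("counts must be positive")


def gen_growth_counts(cfg: SimConfig, dose_effect: float = 1.0) -> pd.DataFrame:
    """Simulate per-well cell-count time series under a dose effect.

    ``dose_effect`` multiplies the doubling time (2.0 means growth is twice
    as slow). Counts follow a lag phase, then exponential growth capped at
    the carrying capacity. With ``count_noise_cv > 0`` counts are
    Poisson-lognormal (a Poisson draw around a lognormally jittered mean);
    with cv = 0 the deterministic mean curve is returned exactly.

    Returns a long table with columns ``well_id, time_h, count``.
    """
    if dose_effect <= 0:
        raise ValueError("dose_effect must be > 0 (it multiplies the doubling time)")
    times = np.arange(0.0, cfg.horizon_h + 0.5 * cfg.time_step_h, cfg.time_step_h)
    doubling = cfg.true_doubling_h * dose_effect
    t_eff = np.maximum(0.0, times - cfg.lag_h)
    mean = cfg.initial_count * np.exp2(t_eff / doubling)
    mean = np.minimum(mean, cfg.carrying_capacity)

    rng = np.random.default_rng(np.random.SeedSequence(cfg.seed))
    frames = []
    for w in range(cfg.n_wells):
        well_rng = np.random.default_rng(rng.integers(0, 2**31))
        if cfg.count_noise_cv == 0:
            counts = mean.copy()
        else:
            rate = mean * _noise_factors(well_rng, cfg.count_noise_cv, mean.shape)
            counts = well_rng.poisson(rate).astype(float)
        frames.append(
            pd.DataFrame(
                {"well_id": f"W{w + 1:02d}", "time_h": times, "count": counts}
            )
        )
    return pd.concat(frames, ignore_index=True)


def reporter_times() -> np.ndarray:
    """The plate-reader time grid: 0-24 h inclusive, read every 2 h (13 points)."""
    return np.arange(0.0, 24.1, 2.0)


def gen_reporter_course(
    stage: str,
    n_reps: int = 3,
    seed: int = 0,
    block_at: str | None = None,
    delay_h: float = 0.0,
    peak_scale: float = 1.0,
    baseline_scale: float = 1.0,
    noise_cv: float = 0.05,
) -> pd.DataFrame:
    """Simulate raw fluorescence for one stage reporter.

    Treatment effects compose: ``block_at`` zeroes the stage-specific peak of
    every reporter *downstream* of the named stage (its baseline remains);
    ``delay_h`` shifts the peak later; ``peak_scale`` scales the peak
    amplitude (<1 attenuates, >1 elevates); ``baseline_scale`` scales the
    constant baseline.

    Returns a long table with columns
    ``reporter, replicate_id, time_h, fluorescence``.
    """
    if stage not in _STAGE_SHAPES:
        raise ValueError(f"unknown stage {stage!r}; expected one of {STAGES}")
    if block_at is not None and block_at not in _STAGE_SHAPES:
        raise ValueError(f"unknown block stage {block_at!r}")
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    center, width, amplitude, baseline = _STAGE_SHAPES[stage]
    if block_at is not None and STAGE_ORDER[stage] > STAGE_ORDER[block_at]:
        amplitude = 0.0
    times = reporter_times()
    mean = baseline * baseline_scale + amplitude * peak_scale * np.exp(
        -0.5 * ((times - (center + delay_h)) / width) ** 2
    )

    rng = np.random.default_rng(np.random.SeedSequence(seed))
    frames = []
    for r in range(n_reps):
        rep_rng = np.random.default_rng(rng.integers(0, 2**31))
        values = mean * _noise_factors(rep_rng, noise_cv, mean.shape)
        frames.append(
            pd.DataFrame(
                {
                    "reporter": stage,
                    "replicate_id": f"R{r + 1}",
                    "time_h": times,
                    "fluorescence": values,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


@dataclass(frozen=True)
class ScreenSimConfig:
    """Conditions for the pooled-selection screen simulation.

    The defaults follow the screen design: ~3.5 generations of growth per
    round, 5 rounds, 2 biological replicate populations sequenced at rounds
    2 and 5. ``selection_coefficients`` apply to the drug screen only; the
    vehicle (DMSO) screen is neutral by construction.
    """

    seed: int = 0
    n_mutants: int = 2000
    n_rounds: int = 5
    generations_per_round: float = 3.5
    read_depth: int = 5_000_000
    n_replicates: int = 2
    selection_coefficients: np.ndarray | None = None
    abundance_dispersion: float = 1.0

    def __post_init__(self) -> None:
        if self.read_depth <= 0:
            raise ValueError("read_depth must be > 0")
        if self.n_mutants < 1 or self.n_rounds < 1 or self.n_replicates < 1:
            raise ValueError("counts must be >= 1")
        if self.abundance_dispersion < 0:
            raise ValueError("abundance_dispersion must be >= 0")
        s = self.s_array()
        if s.shape != (self.n_mutants,):
            raise ValueError("selection_coefficients must have length n_mutants")
        if np.any(s <= -1):
            raise ValueError("selection coefficients must be > -1")

    def s_array(self) -> np.ndarray:
        if self.selection_coefficients is None:
            return np.zeros(self.n_mutants)
        return np.asarray(self.selection_coefficients, dtype=float)


def propagate_frequencies(
    f0: np.ndarray, s: np.ndarray, generations: float
) -> np.ndarray:
    """Deterministic selection update: f_i proportional to f0_i*(1+s_i)^g.

    Returns normalized frequencies after ``generations`` generations of
    growth. The unnormalized per-mutant multiplier is ``(1+s)**generations``.
    """
    f = np.asarray(f0, dtype=float) * np.power(1.0 + np.asarray(s, dtype=float), generations)
    return f / f.sum()


def gen_screen_counts(
    cfg: ScreenSimConfig, sample_rounds: Sequence[int] = (2, 5)
) -> pd.DataFrame:
    """Simulate raw insertion read counts for the drug and vehicle screens.

    One starting mutant pool (lognormal abundances) seeds all screens.
    Frequencies update deterministically each round by
    ``f_i ∝ f_i (1+s_i)^g``; reads are drawn multinomially at the configured
    depth, independently per (screen, replicate, round).

    Returns a long table ``insertion_id, screen, replicate, round, count``
    with screens named ``drug`` and ``DMSO``.
    """
    rng = np.random.default_rng(np.random.SeedSequence(cfg.seed))
    sigma = cfg.abundance_dispersion
    f0 = rng.lognormal(mean=0.0, sigma=sigma, size=cfg.n_mutants) if sigma > 0 else np.ones(cfg.n_mutants)
    f0 = f0 / f0.sum()
    ids = np.array([f"M{i:05d}" for i in range(cfg.n_mutants)])

    screens = {"drug": cfg.s_array(), "DMSO": np.zeros(cfg.n_mutants)}
    rows = []
    for screen, s in screens.items():
        for rep in range(1, cfg.n_replicates + 1):
            rep_rng = np.random.default_rng(rng.integers(0, 2**31))
            for rnd in sample_rounds:
                if rnd > cfg.n_rounds:
                    raise ValueError(f"sample round {rnd} exceeds n_rounds={cfg.n_rounds}")
                freq = propagate_frequencies(f0, s, cfg.generations_per_round * rnd)
                counts = rep_rng.multinomial(cfg.read_depth, freq)
                rows.append(
                    pd.DataFrame(
                        {
                            "insertion_id": ids,
                            "screen": screen,
                            "replicate": rep,
                            "round": rnd,
                            "count": counts,
                        }
                    )
                )
    return pd.concat(rows, ignore_index=True)


def gen_competition(
    fitness_ratio: float,
    n_rounds: int = 6,
    start_frac: float = 0.5,
    seed: int = 0,
    noise_conc: float = 0.0,
) -> pd.DataFrame:
    """Simulate a two-strain competition trajectory.

    The mutant:reference odds multiply by ``fitness_ratio`` each round
    (growth to confluency, ~3.5 generations, folded into the per-round
    ratio). ``noise_conc`` is the concentration of beta-distributed
    measurement noise on the observed fraction (0 = noiseless).

    Returns a table ``round, fraction_mutant`` with rounds 0..n_rounds.
    """
    if fitness_ratio <= 0:
        raise ValueError("fitness_ratio must be > 0")
    if not 0 < start_frac < 1:
        raise ValueError("start_frac must be in (0, 1)")
    if n_rounds < 1:
        raise ValueError("n_rounds must be >= 1")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    odds = start_frac / (1.0 - start_frac)
    fracs = [start_frac]
    for _ in range(n_rounds):
        odds *= fitness_ratio
        fracs.append(odds / (1.0 + odds))
    fracs = np.array(fracs)
    if noise_conc > 0:
        a = np.clip(fracs * noise_conc, 1e-9, None)
        b = np.clip((1.0 - fracs) * noise_conc, 1e-9, None)
        observed = rng.beta(a, b)
        # the round-0 mix is set by the experimenter, not measured
        observed[0] = fracs[0]
    else:
        observed = fracs
    return pd.DataFrame({"round": np.arange(n_rounds + 1), "fraction_mutant": observed})
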