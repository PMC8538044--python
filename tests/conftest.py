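import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from dictytox import synthetic

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")


@pytest.fixture
def times13():
    """The 13-point plate-reader time grid, 0-24 h every 2 h."""
    return synthetic.reporter_times()


def make_screen_matrix(counts: dict) -> pd.DataFrame:
    """Build a normalized-count-style wide matrix from
    {(screen, replicate, round): {mutant: count}} without rescaling."""
    frames = {}
    for key, per_mutant in counts.items():
        frames[key] = pd.Series(per_mutant, dtype=float)
    wide = pd.DataFrame(frames)
    wide.columns = pd.MultiIndex.from_tuples(
        wide.columns, names=["screen", "replicate", "round"]
    )
    wide.index.name = "insertion_id"
    return wide.fillna(0.0)


@pytest.fixture
def peaked_course_builder(times13):
    """Build a ReporterCourse whose max mean normalized value is exactly k/T."""
    from dictytox import reporter

    def _build(k: float, n_reps: int = 2, peak_index: int = 6):
        # one point at a, the other T-1 points at 1: normalized peak a/(a+T-1)
        t_count = len(times13)
        a = (t_count - 1) * k / (t_count - k)
        raw = np.ones((n_reps, t_count))
        raw[:, peak_index] = a
        return reporter.normalize_course(raw, reporter="synthetic", times=times13)

    return _build
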