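import numpy as np
import pandas as pd
import pytest

from equisym import SimConfig, ThresholdConfig
from equisym.simulate import make_cohort, simulate_stride_table


@pytest.fixture
def small_config():
    return SimConfig(n_horses=6, n_visits=2, strides_per_trial=20, seed=7)


@pytest.fixture
def noise_free_config():
    return SimConfig(
        n_horses=3, n_visits=1, strides_per_trial=10,
        extremum_noise_sd=0.0, outlier_prob=0.0, seed=11,
    )


@pytest.fixture
def thresholds():
    return ThresholdConfig()


@pytest.fixture
def visit_records():
    """Small synthetic visit-record table joining summaries with answers."""
    cfg = SimConfig(n_horses=30, n_visits=3, seed=5)
    truth = make_cohort(cfg)
    strides = simulate_stride_table(truth, cfg)
    summ = (
        strides.groupby(["horse_id", "visit"], sort=True)
        .agg(
            hdmin=("hdmin", "mean"), hdmax=("hdmax", "mean"),
            pdmin=("pdmin", "mean"), pdmax=("pdmax", "mean"),
            pdmin_sd=("pdmin", "std"), pdmax_sd=("pdmax", "std"),
            stride_duration=("stride_duration", "mean"),
            surface=("surface", "first"),
        )
        .reset_index()
    )
    rng = np.random.default_rng(5)
    summ["q2a"] = rng.choice(["no", "left", "right"], len(summ))
    summ["q1"] = rng.choice(["no", "mild", "moderate", "severe"], len(summ))
    summ["q2b"] = rng.choice(["equally", "inner", "outer"], len(summ))
    for q in ("q3", "q4"):
        summ[q] = rng.choice(["none", "left", "right"], len(summ))
    summ["q5"] = rng.choice(["no", "left", "right"], len(summ))
    summ["tas"] = summ[["pdmin", "pdmax"]].abs().sum(axis=1) + 0.5 * summ[
        ["hdmin", "hdmax"]
    ].abs().sum(axis=1)
    return summ
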