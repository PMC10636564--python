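import logging

import numpy as np
import pandas as pd
import pytest

from abnmap import (CohortSimConfig, Parcellation, simulate_cohort,
                    synthetic_parcellation)
from abnmap.bands import BAND_NAMES
from abnmap.pipeline import analyze_cohort, compute_features

logging.getLogger("abnmap").setLevel(logging.ERROR)


@pytest.fixture
def rng():
    return np.random.default_rng(20230)


@pytest.fixture(scope="session")
def parcellation() -> Parcellation:
    return synthetic_parcellation(114)


@pytest.fixture(scope="session")
def small_cfg() -> CohortSimConfig:
    return CohortSimConfig(seed=11, n_controls=24, n_patients=12,
                           n_ieeg_norm_subjects=40, rois_per_norm_subject=12)


@pytest.fixture(scope="session")
def small_cohort(small_cfg):
    return simulate_cohort(small_cfg)


@pytest.fixture(scope="session")
def small_report(small_cohort):
    return analyze_cohort(small_cohort)


def make_abnormality_map(values, labels=None) -> pd.DataFrame:
    """An abnormality map with prescribed max |Z| per region."""
    values = np.asarray(values, dtype=float)
    if labels is None:
        labels = [f"roi{i:03d}" for i in range(values.size)]
    df = pd.DataFrame(0.0, index=pd.Index(labels, name="roi"),
                      columns=list(BAND_NAMES))
    df["delta"] = values
    df["max_abs_z"] = np.abs(values)
    return df


def reduced_recovery_cfg(seed, **overrides) -> CohortSimConfig:
    """Small fast cohort with clearly identifiable effect directions."""
    base = dict(seed=seed, n_patients=200, n_rois=40, n_controls=30,
                n_ieeg_norm_subjects=24, rois_per_norm_subject=10,
                contacts_per_roi=2, ez_size=4, n_implanted=8,
                targeting_tau=0.8, resection_quality_rho=0.6,
                targeting_concentration=1.0, outcome_noise_eps=0.05)
    base.update(overrides)
    return CohortSimConfig(**base)


def cohort_features(cfg) -> pd.DataFrame:
    """Feature table of a simulated cohort (no model fitting)."""
    return compute_features(simulate_cohort(cfg))["features"]
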