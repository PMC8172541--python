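"""Shared fixtures: small synthetic records and the strong-effects cohort.

The strong-effects cohort (8 participants x 5 days, large meal and
activity responses, low AR(1) noise, study-like CGM missingness) is the
workhorse for end-to-end effect-recovery checks; it is built once per
session. Model-fit configs used on it run a scaled-down selection forest
so the whole suite stays desk-sized.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from persglu.features import FeaturesConfig
from persglu.pipeline import PipelineConfig, build_feature_table
from persglu.synthetic import CohortConfig, generate_participant


def strong_effects_config(seed: int = 11) -> CohortConfig:
    """The effect-recovery study conditions: strong planted meal/activity
    effects, low noise, study-like CGM gaps."""
    return CohortConfig(
        n_participants=8, days_min=5, days_max=5, seed=seed,
        meal_rise_per_g_sugar=1.2, meal_rise_per_g_carb=0.4,
        activity_dip_mg_dl=20.0, noise_sd=1.0, wear_gap_fraction=0.42,
    )


@pytest.fixture(scope="session")
def tiny_record():
    """One participant, 3 gap-free days, default physiology."""
    cfg = CohortConfig(n_participants=2, days_min=3, days_max=3,
                       wear_gap_fraction=0.0, seed=5)
    return generate_participant(cfg, 1), cfg


@pytest.fixture(scope="session")
def strong_table():
    """Labeled 69-feature table of the strong-effects cohort."""
    cfg = PipelineConfig()
    cfg.cohort = strong_effects_config()
    table = build_feature_table(cfg)
    return table


def random_feature_table(rng: np.random.Generator, n_participants: int = 3,
                         rows_per_participant: int = 60, n_features: int = 6,
                         target=None) -> tuple[pd.DataFrame, list]:
    """A small feature-table-shaped frame with generic feature names."""
    names = [f"f{i}" for i in range(n_features)]
    frames = []
    for pid in range(1, n_participants + 1):
        X = rng.normal(size=(rows_per_participant, n_features))
        df = pd.DataFrame(X, columns=names)
        df.insert(0, "participant_id", pid)
        df.insert(1, "epoch_start", 300.0 * np.arange(rows_per_participant))
        df["glucose_target"] = (target(X, rng) if target is not None
                                else rng.uniform(80, 180, size=rows_per_participant))
        frames.append(df)
    return pd.concat(frames, ignore_index=True), names
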