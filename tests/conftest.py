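"""Shared fixtures: small synthetic studies reused across the suite."""

import pytest

from glycotwin.features import build_feature_table
from glycotwin.model import ModelConfig, make_folds, train
from glycotwin.registry import load_registry
from glycotwin.synthetic import (GroundTruthPatient, SimConfig,
                                 generate_cohort, simulate_study)


@pytest.fixture(scope="session")
def registry():
    return load_registry()


@pytest.fixture(scope="session")
def small_config():
    return SimConfig(n_patients=12, days=21, seed=7, noise_sd=12.0)


@pytest.fixture(scope="session")
def small_cohort(small_config):
    return generate_cohort(small_config)


@pytest.fixture(scope="session")
def small_dataset(small_config, small_cohort):
    return simulate_study(small_cohort, small_config)


@pytest.fixture(scope="session")
def small_features(small_dataset, registry):
    features, _ = build_feature_table(small_dataset, registry)
    return features


@pytest.fixture(scope="session")
def small_model(small_features):
    folds = make_folds(small_features["meal_timestamp"], k=5, gap_days=14)
    return train(small_features, config=ModelConfig(seed=7), folds=folds)


def linear_patient(i: int, carb_sensitivity: float = 2.0,
                   noise_sd: float = 0.0) -> GroundTruthPatient:
    """A patient whose response is exactly rise = cs * carbs * GI/100."""
    return GroundTruthPatient(
        patient_id=f"L{i:03d}", basal_glucose=110.0, circadian_amplitude=0.0,
        circadian_phase_hour=6.0, carb_sensitivity=carb_sensitivity,
        fiber_damping=0.0, protein_fat_damping=0.0, activity_damping=0.0,
        sleep_penalty=0.0, med_effect=0.0, noise_sd=noise_sd,
        age=50, sex="F", bmi=28.0, hba1c=7.0, homa=3.0, waist_cm=95.0,
        medications=[])


@pytest.fixture(scope="session")
def recovery_study():
    """Noiseless cohort with truth inside the model class (600 meals)."""
    cfg = SimConfig(n_patients=20, days=10, seed=3, noise_sd=0.0,
                    enrollment_span_days=60)
    cohort = [linear_patient(i) for i in range(cfg.n_patients)]
    dataset = simulate_study(cohort, cfg)
    features, _ = build_feature_table(dataset)
    return dataset, features


@pytest.fixture(scope="session")
def recovery_model(recovery_study):
    _, features = recovery_study
    folds = make_folds(features["meal_timestamp"], k=5, gap_days=14)
    return train(features, config=ModelConfig(seed=3), folds=folds)


@pytest.fixture(scope="session")
def noiseless_dataset():
    cfg = SimConfig(n_patients=4, days=7, seed=21, noise_sd=0.0)
    return simulate_study(generate_cohort(cfg), cfg), cfg
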