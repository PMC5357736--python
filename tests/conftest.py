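import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import metabodiet as md

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def small_library(n_up=4, n_down=2, n_nuisance=10):
    """Coarse-grid library: wide peaks resolvable on a few hundred points,
    with strong planted effects so the cohort separates cleanly."""
    return md.signature_library(
        n_up, n_down, n_nuisance,
        effect_ratio_range=(4.0, 6.0),
        cv_between_subject=0.15,
        cv_within=0.1,
        nuisance_cv_between=0.1,
        nuisance_cv_within=0.05,
        peak_width=0.02,
        min_peak_separation=0.25,
        disc_peak_range=(1, 1),
        nuisance_peak_range=(1, 2),
    )


@pytest.fixture(scope="session")
def small_cohort():
    """8 subjects x 4 diets x 1 day, 600 points, 6 discriminants, 8 nuisance."""
    design = md.CohortDesign(
        n_subjects=8, days=1, n_points=600, seed=7,
        baseline_noise_sd=0.01, dilution_log_sd=0.2,
    )
    sigs = small_library()
    matrix, annotations, truth = md.generate_cohort(design, sigs)
    return dict(design=design, signatures=sigs, matrix=matrix,
                annotations=annotations, truth=truth)


@pytest.fixture(scope="session")
def small_normalised(small_cohort):
    normalised, record = md.normalise_cohort(small_cohort["matrix"])
    return {**small_cohort, "matrix": normalised, "record": record}


@pytest.fixture(scope="session")
def small_ensemble(small_normalised):
    config = md.MCCVConfig(n_models=30, seed=11)
    ensemble, summaries = md.run_mccv(small_normalised["matrix"], config)
    return {**small_normalised, "ensemble": ensemble, "summaries": summaries}


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
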