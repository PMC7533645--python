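"""Shared fixtures: synthetic cohorts and pipeline runs (session-scoped)."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pytest

from cortiparcel.data_model_io import LabeledSurface, PipelineConfig
from cortiparcel.pipeline import parcellate_and_post, run_stages_1_to_4
from cortiparcel.synthetic_cohort import Cohort, make_cohort, make_labeled_sphere

DEFAULT_SEED = 1
SWEEP_SEED = 5
OVERLAP_SEED = 11


@dataclass
class PipelineRun:
    cohort: Cohort
    cfg: PipelineConfig
    filtered: list
    counts: dict
    result: object
    post_labels: np.ndarray


def _run(cohort: Cohort, cfg: PipelineConfig) -> PipelineRun:
    filtered, counts = run_stages_1_to_4(
        cohort.tractograms, cohort.surface, cohort.atlas, cfg)
    result, post = parcellate_and_post(filtered, cohort.surface, cohort.atlas, cfg)
    return PipelineRun(cohort=cohort, cfg=cfg, filtered=filtered, counts=counts,
                       result=result, post_labels=post)


@pytest.fixture(scope="session")
def default_cohort() -> Cohort:
    """10 subjects, 8 regions, disjoint footprints, sigma 0.5, 20% distractors."""
    return make_cohort(DEFAULT_SEED, n_subjects=10)


@pytest.fixture(scope="session")
def default_run(default_cohort) -> PipelineRun:
    return _run(default_cohort, PipelineConfig())


@pytest.fixture(scope="session")
def sweep_cohort() -> Cohort:
    """Cohort with graded footprint overlaps for threshold sweeps."""
    return make_cohort(SWEEP_SEED, n_subjects=10,
                       overlap_spec=[(0, 0.2), (1, 0.4), (2, 0.6), (3, 0.85)])


@pytest.fixture(scope="session")
def sweep_filtered(sweep_cohort):
    filtered, _ = run_stages_1_to_4(
        sweep_cohort.tractograms, sweep_cohort.surface, sweep_cohort.atlas,
        PipelineConfig())
    return filtered


@pytest.fixture(scope="session")
def overlap_cohort() -> Cohort:
    """Cohort whose region 0 holds two footprints sharing >=80% of their area."""
    return make_cohort(OVERLAP_SEED, n_subjects=10, overlap_spec=[(0, 0.85)])


@pytest.fixture(scope="session")
def small_sphere() -> LabeledSurface:
    return make_labeled_sphere(2, 6, seed=3)


@pytest.fixture(scope="session")
def sphere642() -> LabeledSurface:
    return make_labeled_sphere(3, 8, seed=3)


@pytest.fixture()
def cfg() -> PipelineConfig:
    return PipelineConfig()
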