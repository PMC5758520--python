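"""Shared fixtures: one mini pipeline run and one full-scale run per session."""

from __future__ import annotations

import warnings

import pytest

from panlineage import pipeline, synthetic_cohort


@pytest.fixture(scope="session")
def mini_run(tmp_path_factory):
    """Full pipeline on the 30-strain reduced fixture (seed 1)."""
    cfg = pipeline.PipelineConfig(
        out_dir=tmp_path_factory.mktemp("mini_run"), profile="mini", seed=1
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        result = pipeline.run_all(cfg)
    return result


@pytest.fixture(scope="session")
def mini_metrics(mini_run):
    return pipeline.evaluate_against_truth(mini_run)


@pytest.fixture(scope="session")
def paper_run(tmp_path_factory):
    """Full pipeline on the 113-strain fixture (seed 1)."""
    cfg = pipeline.PipelineConfig(
        out_dir=tmp_path_factory.mktemp("paper_run"), profile="paper", seed=1
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        result = pipeline.run_all(cfg)
    return result


@pytest.fixture(scope="session")
def paper_metrics(paper_run):
    return pipeline.evaluate_against_truth(paper_run)


@pytest.fixture(scope="session")
def mini_cohort():
    """Raw mini cohort records + truth ledger (no pipeline)."""
    cfg = synthetic_cohort.mini_profile(seed=3)
    records, ledger = synthetic_cohort.simulate_cohort(cfg)
    return cfg, records, ledger
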