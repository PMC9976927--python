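import numpy as np
import pytest

from pausescape.modeling import ModelSpec
from pausescape.pipeline import PipelineSettings, inputs_from_bundle, run_pipeline
from pausescape.synthetic import GeneratorConfig, generate_bundle

E2E_SEEDS = (1, 2, 3)


def fast_model_spec(seed: int) -> ModelSpec:
    """Reduced hyperparameter grid used throughout the suite to keep runs
    fast; the search space (learning rate / depth / early stopping) is the
    same shape as the full default grid."""
    return ModelSpec(
        learning_rates=(0.1,),
        max_depths=(4, 6),
        n_rounds=300,
        early_stopping_rounds=25,
        seed=seed,
    )


@pytest.fixture(scope="session")
def small_bundle():
    """A cheap bundle for unit-level tests (a few seconds to build)."""
    cfg = GeneratorConfig(
        n_genes=200,
        n_ncrnas=30,
        n_factors=12,
        n_causal=4,
        n_interactions=2,
        seed=5,
    )
    return generate_bundle(cfg)


@pytest.fixture(scope="session")
def small_report(small_bundle):
    settings = PipelineSettings(model=fast_model_spec(5))
    return run_pipeline(inputs_from_bundle(small_bundle), settings)


@pytest.fixture(scope="session")
def e2e_runs():
    """Full-scale default bundles and pipeline runs for the recovery tests.

    One entry per seed: (bundle, report). Default generator conditions
    (3000 genes, 60 factors, 10 causal factors, noise calibrated to an
    oracle R^2 of 0.7).
    """
    runs = {}
    for seed in E2E_SEEDS:
        bundle = generate_bundle(GeneratorConfig(seed=seed))
        settings = PipelineSettings(model=fast_model_spec(seed))
        report = run_pipeline(inputs_from_bundle(bundle), settings)
        runs[seed] = (bundle, report)
    return runs


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
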