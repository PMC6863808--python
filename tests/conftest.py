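"""Shared fixtures: small toy models and the reduced Monte Carlo runs."""

import numpy as np
import pytest

from mixirt.estimate import (
    FitConfig,
    compute_standard_errors,
    fit_em,
    posterior_classification,
)
from mixirt.model import ModelSpec, ParameterSet
from mixirt.simulate import generate_dataset, load_fixture, replication_seed


@pytest.fixture(scope="session")
def fixture():
    return load_fixture()


@pytest.fixture(scope="session")
def rmgpcm_truth(fixture):
    return fixture.parameters["rmGPCM"]


@pytest.fixture()
def small_params():
    """2 classes, 2 items, 4 categories — cheap but fully featured."""
    rng = np.random.default_rng(42)
    return ParameterSet(
        delta_beta=rng.uniform(-1.5, 1.5, size=(2, 2, 3)),
        item_discrimination=np.array([1.0, 1.3]),
        trait_scale=np.array([0.5, 0.8]),
        class_logit=np.array([0.0, 0.4]),
    )


@pytest.fixture()
def small_spec():
    return ModelSpec(n_items=2, n_categories=4, n_classes=2)


def _challenging_run(truth, n, n_reps, base_seed=1):
    """Warm-started EM fits with observed-information SEs and posteriors.

    Seeds follow the same stream as scripts/acceptance.py, so the reduced
    runs here are leading subsets of the full 50-replication runs.
    """
    spec = ModelSpec(5, 11, 3)
    cfg = FitConfig()
    fits = []
    for r in range(n_reps):
        seed = replication_seed(base_seed, f"acceptance_N{n}", r)
        data = generate_dataset(truth, n, seed=seed)
        fit = fit_em(data.responses, spec, truth, cfg)
        fit = compute_standard_errors(fit, data.responses, cfg)
        fit = posterior_classification(fit, data.responses, cfg)
        fits.append(fit)
    return fits


@pytest.fixture(scope="session")
def mc_n500(rmgpcm_truth):
    """Reduced challenging-condition run at N=500 (12 replications)."""
    return _challenging_run(rmgpcm_truth, 500, 12)


@pytest.fixture(scope="session")
def mc_n2500(rmgpcm_truth):
    """Reduced challenging-condition run at N=2500 (10 replications)."""
    return _challenging_run(rmgpcm_truth, 2500, 10)
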