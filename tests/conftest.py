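import numpy as np
import pandas as pd
import pytest

from satsem.model_spec import (LatentVariable, ModelDefinition,
                               StructuralPath, default_initial_model)
from satsem.synthetic import GeneratorConfig, default_grm_params, simulate_survey


@pytest.fixture(scope="session")
def draft_model():
    return default_initial_model()


@pytest.fixture(scope="session")
def survey_small(draft_model):
    """Default-condition survey at construction-sample scale."""
    return simulate_survey(GeneratorConfig(n_respondents=600, seed=3),
                           draft_model)


@pytest.fixture(scope="session")
def survey_sharp(draft_model):
    """High-discrimination survey (near-noiseless ordinal measurement),
    used for structural recovery checks."""
    cfg = GeneratorConfig(
        n_respondents=2000, seed=1,
        grm_params=default_grm_params(draft_model, a=8.0))
    d = simulate_survey(cfg, draft_model)
    d.responses.attrs["generating"] = cfg.structural_coefficients
    return d


def two_construct_model(n_items=(1, 1), sign=+1):
    """Tiny A -> B model for oracle comparisons."""
    a_items = tuple(f"a{i}" for i in range(n_items[0]))
    b_items = tuple(f"b{i}" for i in range(n_items[1]))
    return ModelDefinition(
        latents=[LatentVariable("A", "exogenous", a_items),
                 LatentVariable("B", "endogenous", b_items)],
        paths=[StructuralPath("A", "B", sign)])


def simulate_two_construct(beta, n, seed, n_items=(1, 1), loading=0.95):
    """Continuous-indicator data from A -> B with known beta."""
    rng = np.random.default_rng(seed)
    A = rng.standard_normal(n)
    B = beta * A + np.sqrt(1 - beta**2) * rng.standard_normal(n)
    cols = {}
    for i in range(n_items[0]):
        cols[f"a{i}"] = loading * A + np.sqrt(1 - loading**2) * rng.standard_normal(n)
    for i in range(n_items[1]):
        cols[f"b{i}"] = loading * B + np.sqrt(1 - loading**2) * rng.standard_normal(n)
    return pd.DataFrame(cols)
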