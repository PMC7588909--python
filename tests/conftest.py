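import numpy as np
import pytest

import aphasim as ap
from aphasim.engine import Factor, GenerativeModel, Modality, floor_distribution


@pytest.fixture(scope="session")
def task_model():
    """The default calibrated bilingual task model (built once)."""
    return ap.build_task_model()


def make_toy_model(seed: int = 0, controllable_actions: int = 2) -> GenerativeModel:
    """A small random 3-factor, 2-modality model for oracle cross-checks."""
    rng = np.random.default_rng(seed)
    factors = (
        Factor("a", ("a0", "a1")),
        Factor("b", ("b0", "b1", "b2")),
        Factor("c", ("c0", "c1")),
    )
    modalities = (Modality("x", ("x0", "x1", "x2")), Modality("y", ("y0", "y1", "y2", "y3")))
    shape = tuple(f.n for f in factors)
    likelihoods = {
        m.name: floor_distribution(rng.random((m.n, *shape)), axis=0) for m in modalities
    }
    transitions = {}
    for f in factors:
        n_act = controllable_actions if f.name == "a" else 1
        transitions[f.name] = floor_distribution(rng.random((f.n, f.n, n_act)), axis=0)
    priors = {f.name: floor_distribution(rng.random(f.n)) for f in factors}
    prefs = {m.name: np.zeros(m.n) for m in modalities}
    policies = tuple({"a": i} for i in range(controllable_actions))
    return GenerativeModel(
        factors=factors,
        modalities=modalities,
        likelihoods=likelihoods,
        transitions=transitions,
        initial_priors=priors,
        preferences=prefs,
        policies=policies,
        horizon=2,
    )


@pytest.fixture
def toy_model():
    return make_toy_model(0)
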