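import pytest

from priorddm import synthetic_data as sd


@pytest.fixture(scope="session")
def small_experiment():
    """Four synthetic subjects under the default (start-bias) truth."""
    cfg = sd.GeneratorConfig(n_subjects=4, seed=5)
    ratings, trials = sd.generate_experiment(cfg)
    return cfg, ratings, trials


@pytest.fixture(scope="session")
def fixation_experiment():
    """Two subjects with accumulator-coupled fixations (attentional truth)."""
    cfg = sd.GeneratorConfig(
        n_subjects=2, seed=9, model="asddm", theta=0.7, fixations=True
    )
    ratings, trials = sd.generate_experiment(cfg)
    return cfg, ratings, trials
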