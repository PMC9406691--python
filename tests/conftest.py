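import pytest

from cwqsar import GeneratorConfig, generate, make_splits, optimize

#: study conditions of the synthetic recovery experiment
STUDY = dict(T=1, n_epoch=15)


@pytest.fixture(scope="session")
def congeneric_series():
    """Synthetic congeneric series with planted effects (default config)."""
    records, truth = generate(GeneratorConfig())
    return records, truth


@pytest.fixture(scope="session")
def study_split(congeneric_series):
    records, _ = congeneric_series
    return make_splits(records, n_splits=1, fraction=0.75, seed=0)[0]


@pytest.fixture(scope="session")
def trained_model(study_split):
    """One Monte Carlo run at the study conditions (T=1, 15 epochs)."""
    return optimize(study_split, seed=0, **STUDY)


@pytest.fixture(scope="session")
def run_models(study_split):
    """Three independent optimization runs with different seeds."""
    return [
        optimize(study_split, seed=seed, n_epoch=8, T=1)
        for seed in (11, 22, 33)
    ]
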