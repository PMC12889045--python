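import pytest

from scdispense import classify_experiment, make_dual_fluorophore_fixture


@pytest.fixture(scope="session")
def dual_fixture():
    """The deterministic six-plate dual-fluorophore experiment."""
    readings, truth, meta = make_dual_fluorophore_fixture(seed=0)
    return readings, truth, meta


@pytest.fixture(scope="session")
def dual_fixture_classified(dual_fixture):
    readings, _, _ = dual_fixture
    classified, thresholds, counts = classify_experiment(readings)
    return classified, thresholds, counts


@pytest.fixture(scope="session")
def fixture_counts(dual_fixture_classified):
    return dual_fixture_classified[2]
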