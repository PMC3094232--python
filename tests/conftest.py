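import pytest

from armdyn import synthetic


@pytest.fixture(scope="session")
def fixture_dataset(tmp_path_factory):
    """The small standard synthetic dataset (TSV + YAML config) used suite-wide."""
    out = tmp_path_factory.mktemp("fixture_data")
    cfg = synthetic.write_fixture_dataset(out, seed=0)
    return {"dir": out, "config": cfg}


@pytest.fixture()
def two_inversion_scenario():
    """Two disjoint inversions per arm; null planted intensities."""
    return synthetic.SharingScenario(
        n_homologs=200, seed=42,
        inversions1=[("A1", 5.0, 20.0), ("A2", 25.0, 40.0)],
        inversions2=[("B1", 10.0, 28.0), ("B2", 35.0, 50.0)],
    )
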