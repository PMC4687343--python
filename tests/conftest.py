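import pytest

from fxsmap import synthetic


@pytest.fixture(scope="session")
def mouse_sim():
    """Default 42-sample mouse dataset (fixed seed)."""
    cfg = synthetic.MouseSimConfig(seed=0)
    return synthetic.simulate_mouse_dataset(cfg)


@pytest.fixture(scope="session")
def human_sim():
    """Default human developmental series (fixed seed)."""
    cfg = synthetic.HumanSimConfig(seed=2)
    return synthetic.simulate_human_devseries(cfg)


@pytest.fixture(scope="session")
def bundle_dir(tmp_path_factory):
    """A complete on-disk fixture bundle with default configs."""
    path = tmp_path_factory.mktemp("bundle")
    synthetic.write_fixture_bundle(
        path,
        synthetic.MouseSimConfig(seed=0),
        synthetic.HumanSimConfig(seed=1),
    )
    return path
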