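import sys
from pathlib import Path

import pytest
from hypothesis import settings

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles module

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from crelink import simulate  # noqa: E402


@pytest.fixture(scope="session")
def default_world():
    return simulate.gen_world(simulate.FixtureConfig(seed=0))


@pytest.fixture(scope="session")
def default_pairdata(default_world):
    return simulate.gen_pair_data(default_world, simulate.FixtureConfig(seed=0))


@pytest.fixture(scope="session")
def noisefree_pairdata():
    """Noise-free labels: the planted-logistic conditions for recovery."""
    cfg = simulate.FixtureConfig(seed=3, label_noise=0.0)
    world = simulate.gen_world(cfg)
    return cfg, simulate.gen_pair_data(world, cfg)


@pytest.fixture(scope="session")
def network_scale_run(tmp_path_factory):
    """Network-scale fixture run once through the full pipeline."""
    from crelink import pipeline

    base = tmp_path_factory.mktemp("netscale")
    cfg = simulate.FixtureConfig.network_scale(seed=3, planted_fe=2.0,
                                               motif_planted_or=8.0)
    truth = pipeline.simulate_fixture(cfg, base / "in")
    rc = pipeline.RunConfig(input_dir=str(base / "in"), output_dir=str(base / "out"),
                            seed=3, n_boot=200, n_perm=100)
    artifacts = pipeline.run_pipeline(rc)
    return cfg, truth, artifacts, base
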