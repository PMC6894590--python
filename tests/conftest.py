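import numpy as np
import pytest

from satpose.synth import FigureModel, SynthConfig, generate_dataset, synthesize_subject


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_subject():
    """One short in-memory synthetic sequence (images, coords, trajectory, model)."""
    cfg = SynthConfig(n_frames=60, seed=7, subject_id="synth-A")
    model = FigureModel.default(64)
    images, coords, traj = synthesize_subject(cfg, model)
    return cfg, model, images, coords, traj


@pytest.fixture(scope="session")
def dataset_dir(tmp_path_factory):
    """A small synthetic dataset written to disk."""
    out = tmp_path_factory.mktemp("synthdata") / "seq"
    cfg = SynthConfig(n_frames=24, seed=11, subject_id="synth-B")
    manifest = generate_dataset(cfg, FigureModel.default(64), out)
    return out, cfg, manifest
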