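import numpy as np
import pytest

from stablate.orchestrator import build_paired_bundle, desk_model_config
from stablate.synthetic import SceneConfig, generate_scene


@pytest.fixture(scope="session")
def tiny_config():
    """A small, fast scene: 4 niches, 8 genes, ~100 patches at 16 px."""
    return SceneConfig(
        width_px=160,
        height_px=160,
        n_cell_types=4,
        n_genes=8,
        cells_per_type=150,
        niche_sd=45.0,
        seed=7,
    )


@pytest.fixture(scope="session")
def tiny_scene(tiny_config):
    return generate_scene(tiny_config)


@pytest.fixture(scope="session")
def tiny_bundle(tiny_config):
    """Paired modalities + replicate for the tiny scene (built once)."""
    return build_paired_bundle(tiny_config, patch_size=16.0, seed=3)


@pytest.fixture(scope="session")
def fast_model_config():
    """A deliberately small model for speed-sensitive unit tests."""
    import dataclasses

    return dataclasses.replace(desk_model_config(epochs=10), batch_size=32)
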