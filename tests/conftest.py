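import numpy as np
import pytest

from whisker_connectome import (
    GeneratorConfig,
    PipelineConfig,
    generate,
    load_panel,
    run_bundle,
)


@pytest.fixture(scope="session")
def panel():
    return load_panel()


@pytest.fixture(scope="session")
def bundle7():
    """Default separable synthetic bundle, seed 7."""
    return generate(GeneratorConfig(seed=7))


@pytest.fixture(scope="session")
def result7(bundle7):
    """Pipeline result on the seed-7 bundle (trimmed permutation sizes)."""
    return run_bundle(bundle7, PipelineConfig(n_perm=500, n_null=10, seed=7))


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


def small_generator_config(seed: int, **overrides) -> GeneratorConfig:
    """Compact study conditions for repeated-draw tests."""
    params = dict(
        n_structures=20,
        grid_shape=(8, 8, 8),
        n_injection_voxels=100,
        lines_per_category={"excitatory": 1, "inhibitory": 1, "uncategorized": 1},
        seed=seed,
    )
    params.update(overrides)
    return GeneratorConfig(**params)
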