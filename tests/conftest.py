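import numpy as np
import pytest

import psmdim as p


@pytest.fixture(scope="session")
def glyph_data() -> p.GrayDataset:
    """800 synthetic glyphs (80 per class) at default generator settings."""
    return p.generate_dataset(p.GlyphParams(n_per_class=80, seed=7))


@pytest.fixture(scope="session")
def untrained_network() -> p.TrainedNetwork:
    """A built (randomly initialized) network for activation-plumbing tests."""
    return p.TrainedNetwork(p.default_network_spec(), seed=11)


@pytest.fixture(scope="session")
def small_colored(glyph_data) -> p.ColorDataset:
    """A small RC-colored set (32 images) shared by activation tests."""
    subset = glyph_data.subset(np.arange(32))
    return p.build_dataset(subset, p.ColorAssignment("RC"), seed=5)


@pytest.fixture(scope="session")
def tiny_report() -> p.ExperimentReport:
    """A fast, deliberately small end-to-end run for report-shape tests."""
    config = p.ExperimentConfig.scaled_down(
        seed=3, n_train=300, n_test=120, epochs=2, pca_max_components=60
    )
    return p.run_experiment(config)
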