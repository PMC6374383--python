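import numpy as np
import pytest

from iftomo.phantom import PhantomConfig, generate_phantom


@pytest.fixture(scope="session")
def small_phantom():
    """Noise-free, perfectly placed phantom: 12 non-touching nuclei, 10 sections."""
    cfg = PhantomConfig(
        tissue_extent=(48.0, 48.0, 20.0),
        n_cells=12,
        nucleus_radius_range=(2.5, 3.5),
        divisions_max=8,
        seed=21,
    )
    sections, truth = generate_phantom(cfg)
    return cfg, sections, truth


@pytest.fixture(scope="session")
def misaligned_phantom():
    """Phantom with per-section misplacement and mild noise, for registration."""
    cfg = PhantomConfig(
        tissue_extent=(56.0, 56.0, 20.0),
        n_cells=30,
        nucleus_radius_range=(3.0, 4.5),
        misalignment_range=(8.0, 8.0, 3.0),
        noise_sd=8.0,
        enforce_separation=True,
        field_margin=8.0,
        z_overhang=4.0,
        stratify_z=True,
        seed=17,
    )
    sections, truth = generate_phantom(cfg)
    return cfg, sections, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
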