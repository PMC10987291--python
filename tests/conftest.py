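import numpy as np
import pytest

from tmaquant import CoreImageConfig, StainMatrix, generate_core_image


@pytest.fixture(scope="session")
def reference_stains() -> StainMatrix:
    return StainMatrix.reference()


@pytest.fixture
def clean_core():
    """A noise-free rendered core with ground truth (moderate size)."""
    cfg = CoreImageConfig(
        image_size_px=(384, 384), n_cells=25, cell_radius_um=6.0,
        fraction_positive=0.3, noise_sd=0.0, seed=7,
    )
    image, truth = generate_core_image(cfg)
    return cfg, image, truth


def truth_stain_matrix(cfg: CoreImageConfig) -> StainMatrix:
    sv = np.asarray(cfg.stain_vectors)
    return StainMatrix(sv[0], sv[1])
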