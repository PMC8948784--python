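import numpy as np
import pytest

import voccast as vc


@pytest.fixture(scope="session")
def tiny_design():
    """Small, fast cohort design with a strong planted effect."""
    return vc.default_design(
        seed=7,
        matrix_shape=(60, 48),
        n_per_group=(12, 12),
        n_shared=12,
        n_effect=3,
        effect_multiplier=3.0,
    )


@pytest.fixture(scope="session")
def tiny_cohort(tiny_design):
    spectra, labels, truth = vc.simulate_cohort(tiny_design)
    return spectra, labels, truth


@pytest.fixture(scope="session")
def tiny_features(tiny_design, tiny_cohort):
    spectra, labels, _ = tiny_cohort
    fm = vc.build_feature_matrix(
        spectra,
        vc.default_crop_window(tiny_design),
        vc.default_background_regions(tiny_design),
    )
    return fm, labels


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


@pytest.fixture()
def small_spectrum(rng):
    return vc.GCIMSSpectrum(
        sample_id="S1",
        intensities=rng.uniform(0, 10, size=(10, 8)),
        retention_axis=np.arange(10, dtype=float),
        drift_axis=np.arange(8, dtype=float) * 0.5 + 1.0,
        meta={"instrument": "synthetic"},
    )
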