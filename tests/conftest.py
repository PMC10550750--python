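import numpy as np
import pytest

from pcead.anomaly_model import (calibrate_threshold, fit_nerd, mahalanobis_map,
                                 reconstruction_error)
from pcead.synthetic_fixtures import OracleReconstructor, make_cohort
from pcead.wsi_tiling import compute_tissue_mask, extract_patches


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20230922)


@pytest.fixture(scope="session")
def small_cohort():
    """9 in-memory pseudo-slides: 4 training normals, 2 inference normals,
    3 tumor slides."""
    return make_cohort(n_slides=9, n_tumor=3, n_normal_inference=2, seed=5,
                       slide_size=512)


@pytest.fixture(scope="session")
def oracle():
    return OracleReconstructor()


def _phase_errors(manifest, phase, oracle, patch_size=128, downsample=16):
    for entry in manifest["slides"]:
        if entry["phase"] != phase:
            continue
        slide, _ = manifest["rendered"][entry["slide"]]
        mask = compute_tissue_mask(slide, downsample)
        for patch in extract_patches(slide, mask, patch_size, 0.5):
            yield reconstruction_error(patch, oracle.reconstruct(patch))


@pytest.fixture(scope="session")
def fitted_nerd(small_cohort, oracle):
    return fit_nerd(_phase_errors(small_cohort, "phase2", oracle))


@pytest.fixture(scope="session")
def calibrated_threshold(small_cohort, oracle, fitted_nerd):
    distances = (mahalanobis_map(err, fitted_nerd).ravel()
                 for err in _phase_errors(small_cohort, "phase3", oracle))
    return calibrate_threshold(distances, q=0.05)
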