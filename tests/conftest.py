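import numpy as np
import pytest

from beadpcr import segmentation as seg
from beadpcr import synthetic as syn
from beadpcr.quantify import StudyDesign


@pytest.fixture(scope="session")
def design() -> StudyDesign:
    return StudyDesign()


@pytest.fixture(scope="session")
def seg_params() -> seg.SegmentationParams:
    """Bounds matched to ~6 px beads (94.8 um at 8 um/px)."""
    return seg.SegmentationParams(min_radius_px=3.0, max_radius_px=10.0)


@pytest.fixture(scope="session")
def noiseless_well():
    """50 monodisperse beads, no noise: ground-truth render fixture."""
    pop = syn.BeadPopulationSpec(n_beads=50, mean_diameter_um=96.0, diameter_cv=0.0)
    spec = syn.ImageSpec(width=400, height=400, pixel_size_um=8.0, noise_sd=0.0)
    marker, detect, truth = syn.render_well_image(pop, spec, lam=0.7, seed=1)
    return marker, detect, truth


@pytest.fixture(scope="session")
def bimodal_intensities() -> np.ndarray:
    """Two well-separated Gaussian intensity modes, 1500 draws each."""
    rng = np.random.default_rng(42)
    return np.concatenate([rng.normal(100, 10, 1500), rng.normal(1000, 50, 1500)])
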