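"""Shared fixtures: small phantoms with known geometry."""

import numpy as np
import pytest

from octquant import IntensityGrid, PhantomParams

# layered step phantom with exactly known boundaries
STEP_ILM, STEP_RNFL, STEP_RPE_IN, STEP_RPE_OUT = 150, 170, 300, 320


def make_step_phantom(n_rows: int = 340, n_cols: int = 64) -> np.ndarray:
    """Noiseless piecewise-constant b-scan: vitreous 20, ILM-RNFL band 180,
    inner retina 80, RPE band 220, below 40."""
    img = np.empty((n_rows, n_cols))
    img[:STEP_ILM] = 20.0
    img[STEP_ILM:STEP_RNFL] = 180.0
    img[STEP_RNFL:STEP_RPE_IN] = 80.0
    img[STEP_RPE_IN:STEP_RPE_OUT] = 220.0
    img[STEP_RPE_OUT:] = 40.0
    return img


def speckled(img: np.ndarray, sigma: float, seed: int) -> np.ndarray:
    """Unit-mean multiplicative lognormal speckle."""
    rng = np.random.default_rng(seed)
    return img * rng.lognormal(-sigma**2 / 2, sigma, img.shape)


@pytest.fixture
def step_grid() -> IntensityGrid:
    return IntensityGrid(make_step_phantom(), pixel_area=9.0)


@pytest.fixture
def small_phantom() -> PhantomParams:
    """Scaled phantom used for session-level tests (fast to segment)."""
    return PhantomParams(
        n_rows=248, n_cols=512,
        ilm_row=100, rnfl_outer_row=115,
        rpe_inner_row=190, rpe_outer_row=205,
    )
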