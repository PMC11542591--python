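"""Shared fixtures: small synthetic detectors, noiseless edge images, and one
module-scoped end-to-end characterization reused by the slower tests."""

from __future__ import annotations

import numpy as np
import pytest

from dqekit import (
    DetectorModel,
    EdgeImage,
    ExposureSpec,
    characterize_detector,
    gaussian_kernel,
)


def make_step_edge(
    n_rows: int = 256,
    n_cols: int = 256,
    angle_deg: float = 3.0,
    offset: float = 0.0,
    level: float = 1000.0,
    orientation: str = "vertical",
) -> EdgeImage:
    """Noiseless box-sampled step edge: pixel value = bright fraction * level."""
    t = np.tan(np.radians(angle_deg))
    rows, cols = np.meshgrid(
        np.arange(n_rows) + 0.5, np.arange(n_cols) + 0.5, indexing="ij"
    )
    if orientation == "vertical":
        d = cols - (n_cols / 2 + offset + t * (rows - n_rows / 2))
    else:
        d = rows - (n_rows / 2 + offset + t * (cols - n_cols / 2))
    frac = np.clip(d + 0.5, 0.0, 1.0)
    data = np.rint(frac * level * 64).astype(np.int64)
    return EdgeImage(data, orientation, true_angle=angle_deg)


@pytest.fixture(scope="session")
def ideal_detector() -> DetectorModel:
    return DetectorModel()


@pytest.fixture(scope="session")
def gauss_detector() -> DetectorModel:
    return DetectorModel(event_psf=gaussian_kernel(0.5))


@pytest.fixture(scope="session")
def short_exposure() -> ExposureSpec:
    return ExposureSpec(dose_rate=7.5, exposure_time=16 / 75, frame_time=1 / 75, pixel_size=1.0)


@pytest.fixture(scope="session")
def ideal_characterization():
    """End-to-end MTF/NNPS/DQE measurement of the ideal counting detector."""
    return characterize_detector(
        DetectorModel(),
        seed=7,
        edge_exposure_time=30.0,
        n_flat_frames=64,
    )
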