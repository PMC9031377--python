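import numpy as np
import pytest

from resosharp import SyntheticModel, synth_return_loss
from resosharp.sharpen import SharpenParams

GHZ = 1e9


@pytest.fixture(scope="session")
def paper_model() -> SyntheticModel:
    """The synthetic single-resonance model with its canonical constants."""
    return SyntheticModel(
        f_true=2.25 * GHZ,
        amplitude=18.0,
        offset=2.0,
        sigma_left=0.07 * GHZ,
        sigma_right=0.10 * GHZ,
        band=(2.0 * GHZ, 3.0 * GHZ),
    )


@pytest.fixture(scope="session")
def example_trace(paper_model):
    """The 101-point example curve."""
    return synth_return_loss(paper_model, 101)


@pytest.fixture
def example_params():
    """The example sharpening settings (alpha=0.1, beta=0.05, 512/512)."""
    return SharpenParams(alpha=0.1, beta=0.05, nt=512, n_hat_f=512)


@pytest.fixture(scope="session")
def symmetric_model() -> SyntheticModel:
    """Equal widths left and right: the phase-slope oracle's input."""
    return SyntheticModel(
        f_true=2.5 * GHZ,
        sigma_left=0.08 * GHZ,
        sigma_right=0.08 * GHZ,
    )


def fwhm(x: np.ndarray, y: np.ndarray) -> float:
    """Full width at half maximum via linear interpolation of the crossings."""
    y = np.asarray(y, dtype=float)
    half = y.max() / 2.0
    peak = int(np.argmax(y))
    above = y >= half

    def cross(i, j, step):
        # linear interpolation between samples j (below) and i (above)
        return x[i] + (x[j] - x[i]) * (y[i] - half) / (y[i] - y[j])

    left = x[0]
    for i in range(peak, 0, -1):
        if not above[i - 1]:
            left = cross(i, i - 1, -1)
            break
    right = x[-1]
    for i in range(peak, len(y) - 1):
        if not above[i + 1]:
            right = cross(i, i + 1, +1)
            break
    return float(right - left)
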