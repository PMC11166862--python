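import numpy as np
import pytest

from effcnr import PhantomSpec, make_disk_phantom


@pytest.fixture(scope="session")
def sharp_disk():
    """Noiseless unblurred disk: contrast 100 HU, radius 12, 128x128."""
    spec = PhantomSpec(insert_contrast_hu=100.0)
    return make_disk_phantom(spec), spec


@pytest.fixture(scope="session")
def blurred_disk():
    """Noiseless disk with 2 px Gaussian edge blur."""
    spec = PhantomSpec(insert_contrast_hu=100.0, edge_blur_sigma=2.0)
    return make_disk_phantom(spec), spec


def stable_central_difference(t: np.ndarray, params, h: float = 2e-5) -> np.ndarray:
    """Central finite difference of Phi(g(t)) that avoids cancellation.

    Where Phi(g) ~ 1 (plateau, g > 0) the difference is formed from the
    survival function 1 - Phi = Phi(-g), which is algebraically identical
    but keeps both operands small; the edge/tail side uses Phi directly.
    """
    from scipy.special import ndtr

    from effcnr import g_of_t

    gp, gm, g0 = g_of_t(t + h, params), g_of_t(t - h, params), g_of_t(t, params)
    direct = (ndtr(gp) - ndtr(gm)) / (2 * h)
    survival = (ndtr(-gm) - ndtr(-gp)) / (2 * h)
    return np.where(g0 > 0, survival, direct)


def brute_force_moving_average_sd(roi: np.ndarray, r: int) -> float:
    """Independent double-loop oracle: SD of all r x r window means, stride 1."""
    side = roi.shape[0]
    means = []
    for i in range(side - r + 1):
        for j in range(side - r + 1):
            means.append(roi[i : i + r, j : j + r].mean())
    return float(np.std(means, ddof=1))
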