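import numpy as np
import pytest

from topocell.synthetic import (CellState, FrameGeometry, NoiseParams,
                                render_frame, sample_orientations)


@pytest.fixture
def geometry():
    return FrameGeometry(256, 256, 1.0)


@pytest.fixture
def quiet_noise():
    """Low-noise imaging: visible cells at SNR well above 5."""
    return NoiseParams(background_level=100.0, photon_noise_scale=1.0,
                       psf_sigma_px=1.0)


def place_cells(n, frame_um, spacing_um, rng, semi_major=40.0, semi_minor=10.0,
                mu_deg=90.0, kappa=8.0, margin=None):
    """Rejection-place n non-overlapping ellipses with axial orientations."""
    margin = spacing_um * 0.6 if margin is None else margin
    xs, ys = [], []
    attempts = 0
    while len(xs) < n:
        attempts += 1
        if attempts > 20000:
            raise RuntimeError("placement failed")
        x, y = rng.uniform(margin, frame_um - margin, 2)
        if all((x - a) ** 2 + (y - b) ** 2 >= spacing_um ** 2
               for a, b in zip(xs, ys)):
            xs.append(x)
            ys.append(y)
    thetas = sample_orientations(n, mu_deg, kappa, rng)
    return [CellState((x, y), semi_major, semi_minor, float(t))
            for x, y, t in zip(xs, ys, thetas)]


@pytest.fixture
def aligned_field(quiet_noise):
    """50 elongated cells (4:1) oriented near 90 deg in a 1024 px frame."""
    rng = np.random.default_rng(42)
    cells = place_cells(50, 1024.0, 85.0, rng)
    frame, labels = render_frame(cells, FrameGeometry(1024, 1024, 1.0),
                                 quiet_noise, rng_seed=7, condition="aligned")
    return frame, labels, cells
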