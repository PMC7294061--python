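"""Shared fixtures: small montages, trial lists and simulated epochs.

Expensive simulated objects are session-scoped; tests must not mutate them.
"""

import numpy as np
import pytest

from bindnet import design, simulate
from bindnet.containers import Montage, make_equidistant_montage


@pytest.fixture(scope="session")
def montage8():
    return make_equidistant_montage(8)


@pytest.fixture(scope="session")
def montage30():
    return make_equidistant_montage(30)


@pytest.fixture(scope="session")
def sphere_montage():
    """Full-sphere Fibonacci montage (for surface-Laplacian properties that
    need closed quadrature over the sphere)."""
    n = 64
    i = np.arange(n)
    cos_th = 1.0 - 2.0 * (i + 0.5) / n
    theta = np.degrees(np.arccos(cos_th))
    phi = np.mod(i * 137.50776405003785, 360.0)
    return Montage(tuple(f"S{j:02d}" for j in range(n)), theta, phi)


@pytest.fixture(scope="session")
def trials128():
    """One factorial pass with behavior filled in."""
    return design.generate_behavior(design.generate_design(1, 0), seed=1)


@pytest.fixture(scope="session")
def epochs_clean(montage8, trials128):
    """80 trials of S+C+R plus moderate 1/f noise, no oscillatory coupling:
    the RIDE test bed."""
    params = simulate.EegSimParams(coupling_strength_uv=0.0, noise_rms_uv=2.0)
    return simulate.generate_eeg(trials128[:80], montage8, params, seed=3)


@pytest.fixture(scope="session")
def epochs_full(montage30):
    """A full simulated session (384 trials, coupling on) at 30 channels."""
    trials = design.generate_behavior(design.generate_design(3, 11), seed=12)
    return simulate.generate_eeg(trials, montage30, simulate.EegSimParams(),
                                 seed=13)
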