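"""Shared fixtures: small phantoms and simulated stacks.

Session-scoped fixtures cache the expensive simulations so several tests
can share one run without re-simulating.
"""

from __future__ import annotations

import numpy as np
import pytest

from gmmrefine import GaussianMixture, Pose
from gmmrefine.simulate import SimSpec, simulate_particles, random_phantom, two_domain_phantom
from gmmrefine.io import phase_flip_stack


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def small_gmm():
    """20 random Gaussians comfortably inside a 64 A box."""
    r = np.random.default_rng(0)
    return GaussianMixture(r.normal(0, 8, (20, 3)), r.uniform(0.5, 1.5, 20),
                           r.uniform(1.6, 2.5, 20))


@pytest.fixture(scope="session")
def phantom48():
    """Two-domain phantom sized for a 48-pixel box."""
    gmm, labels = two_domain_phantom(300, seed=3)
    return gmm, labels


@pytest.fixture(scope="session")
def clean_stack48(phantom48):
    """100 noise-free, CTF-free particles at 48 px from the phantom."""
    gmm, _ = phantom48
    spec = SimSpec(phantom=gmm, n_particles=100, n=48, apix=1.0,
                   snr=np.inf, apply_ctf=False, seed=5)
    ps, te, ts = simulate_particles(spec)
    return ps, te, ts


@pytest.fixture(scope="session")
def noisy_stack48(phantom48):
    """600 CTF + SNR 0.3 particles at 48 px, phase flipped."""
    gmm, _ = phantom48
    spec = SimSpec(phantom=gmm, n_particles=600, n=48, apix=1.0, snr=0.3, seed=5)
    ps, te, ts = simulate_particles(spec)
    return phase_flip_stack(ps), te, ts
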