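"""Shared fixtures: expensive model runs are session-scoped so the
sensitivity, MCMC and PDE checks reuse one set of simulations."""

from __future__ import annotations

import numpy as np
import pytest

from gpcuq import bundled_space, fit_surrogates, gprotein
from gpcuq.surrogate import SampleSet


@pytest.fixture(scope="session")
def gp2_space():
    return bundled_space("gprotein2")


@pytest.fixture(scope="session")
def gp2_sampleset(gp2_space):
    """1000 uniform samples of the G-protein response vector over the
    two-parameter space (the production fitting configuration)."""
    count, seed = 1000, 101
    Y = gp2_space.sample_uniform(count, seed)
    Z = np.empty((count, len(gprotein.OBSERVATION_GRID)))
    for i, y in enumerate(Y):
        p = gprotein.BASELINE.with_values(
            **gp2_space.natural_dict(gp2_space.from_cube(y))
        )
        Z[i] = gprotein.response_vector(p)
    labels = [f"L{L:g}_T{T:g}" for L, T in gprotein.OBSERVATION_GRID]
    return SampleSet(Y=Y, Z=Z, seed=seed, labels=labels)


@pytest.fixture(scope="session")
def gp2_surrogates(gp2_space, gp2_sampleset):
    """Degree-10 least-squares surrogates, one per observation point."""
    return fit_surrogates(gp2_sampleset, degree=10, space=gp2_space)


@pytest.fixture(scope="session")
def pde_steady_baseline():
    """Full-resolution steady-state run of the polarization model at the
    baseline parameter set (N = 400, dt = 0.05, t_end = 1000 s)."""
    from gpcuq import polarization

    return polarization.simulate_to_steady(
        polarization.BASELINE, polarization.Geometry(), t_end=1000.0, dt=0.05
    )


@pytest.fixture(scope="session")
def pde15_sampleset(tmp_path_factory):
    """200 cutoff-response samples over the screened 15-parameter space at
    reduced PDE resolution (N = 64, dt = 0.25, t_end = 150 s); the
    surrogate-fitting properties under test are resolution-independent."""
    from gpcuq import polarization, synth

    space = bundled_space("polarization15")
    return synth.make_pde_sampleset(
        space,
        count=200,
        seed=7,
        geometry=polarization.Geometry(N=64),
        t_end=150.0,
        dt=0.25,
    )
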