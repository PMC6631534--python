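"""Shared fixtures: the packaged parameter set and a few reference simulations.

Expensive trajectories are session-scoped so the suite simulates each
scenario once.
"""

import numpy as np
import pytest

import nfkb_btrcp as nb
from nfkb_btrcp.model import NFKB_POOLS, SPECIES, _NUCLEAR


@pytest.fixture(scope="session")
def params() -> nb.ParameterSet:
    return nb.load_parameter_fixture()


@pytest.fixture(scope="session")
def unstim_ss(params) -> nb.StateVector:
    return nb.unstimulated_steady_state(params, btrcp_nM=1.0)


@pytest.fixture(scope="session")
def traj_b1(params) -> nb.Trajectory:
    """TNF step response at 1 nM β-TrCP (the base-model special case)."""
    return nb.stimulated_response(params, nb.Stimulus(tnf=1, btrcp_nM=1.0))


@pytest.fixture(scope="session")
def traj_b001(params) -> nb.Trajectory:
    """TNF step response at 0.01 nM β-TrCP (near the duration maximum)."""
    return nb.stimulated_response(params, nb.Stimulus(tnf=1, btrcp_nM=1.0e-2))


def random_conserved_state(params, rng) -> nb.StateVector:
    """A random non-negative 15-species state satisfying NF-κB conservation.

    NF-κB pool fractions are Dirichlet-distributed over the five pools
    (nuclear pool concentrations carry the kv factor); the remaining
    species are log-uniform over a physiological range.
    """
    total_nM = params.nf_total * 1.0e3
    frac = rng.dirichlet(np.ones(len(NFKB_POOLS)))
    values = 10.0 ** rng.uniform(-3, 2, len(SPECIES))
    for f, sp in zip(frac, NFKB_POOLS):
        w = params.kv if sp in _NUCLEAR else 1.0
        values[SPECIES.index(sp)] = f * total_nM * w
    return nb.StateVector(values)
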