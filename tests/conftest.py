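import itertools

import numpy as np
import pytest

from moietydeconv import ParameterSet, default_space

# Published 48 h subunit fractions (free parameters; the fully-labeled
# glucose/ribose/acetyl and triply-labeled uracil states follow by closure:
# g6=0.84, r5=0.93, a2=0.30, u3=0.14).
PRINTED_48H_FREE = {
    "g0": 0.16,
    "r0": 0.07,
    "a0": 0.70,
    "u0": 0.22,
    "u1": 0.18,
    "u2": 0.46,
}

EXPERIMENTAL_TIMEPOINTS = (0.0, 3.0, 6.0, 11.0, 24.0, 34.0, 48.0)


@pytest.fixture(scope="session")
def space():
    return default_space()


@pytest.fixture(scope="session")
def printed_48h_params(space):
    return ParameterSet.from_free(space, PRINTED_48H_FREE)


def brute_force_profile(space, params):
    """Independent oracle: explicit sum over all joint label states."""
    out = np.zeros(space.max_mass_shift + 1)
    per_subunit = [list(zip(s.allowed_labels, s.parameter_names)) for s in space.subunits]
    for combo in itertools.product(*per_subunit):
        shift = sum(l for l, _ in combo)
        prob = 1.0
        for _, name in combo:
            prob *= params[name]
        out[shift] += prob
    return out


def random_params(space, rng):
    """Uniform draw on each subunit's simplex."""
    fractions = {}
    for s in space.subunits:
        block = rng.dirichlet(np.ones(len(s.allowed_labels)))
        fractions.update(dict(zip(s.parameter_names, block)))
    return ParameterSet(fractions).validate(space)
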