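import numpy as np
import pytest
from hypothesis import settings

import upwellsurv as u

settings.register_profile("ci", derandomize=True, max_examples=25, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def field_calendar():
    return u.fielddata.study_calendar()


@pytest.fixture(scope="session")
def sim300(field_calendar):
    """Synthetic C. granosus/Talcaruca-style dataset: N=300, monthly
    survival 0.9, detection 0.4 on searched occasions, seed 1."""
    truth = u.TruthConfig(
        n_individuals=300, phi=0.9, p=0.4,
        site="talcaruca", species="chiton_granosus",
        calendar=field_calendar, seed=1,
    )
    return u.simulate_histories(truth)


@pytest.fixture(scope="session")
def study_protocol_fit(sim300):
    """Constant-survival fit at the study's MCMC protocol
    (3 chains x 10,000 iterations, burn-in 1,000)."""
    model = u.CJSModel(sim300, structure="phi_dot")
    return model.fit(n_chains=3, n_iter=10_000, n_burn=1_000, seed=1)


def enumerate_history_prob(y, f, phi_vec, p_vec):
    """Independent brute-force CJS history probability: sum over the
    occasion d after which the animal is dead (d = T means it survived the
    study), of survival/death factors times detection outcomes while alive.
    """
    y = np.asarray(y, dtype=int)
    T = y.shape[0]
    last = int(np.flatnonzero(y)[-1]) + 1
    total = 0.0
    for d in range(f, T + 1):  # last occasion alive
        if last > d:
            continue
        pr = 1.0
        for t in range(f, d):  # survive intervals f..d-1
            pr *= phi_vec[t - 1]
        if d < T:
            pr *= 1.0 - phi_vec[d - 1]
        for t in range(f + 1, d + 1):  # detection outcomes while alive
            pt = p_vec[t - 2]
            pr *= pt if y[t - 1] else (1.0 - pt)
        total += pr
    return total


def all_post_release_histories(T, f):
    """Every 0/1 history of length T with first detection exactly at f."""
    out = []
    for bits in range(2 ** (T - f)):
        y = np.zeros(T, dtype=int)
        y[f - 1] = 1
        for k in range(T - f):
            y[f + k] = (bits >> k) & 1
        out.append(y)
    return out
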