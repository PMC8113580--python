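"""Shared fixtures and independent oracle implementations.

The oracles here are deliberately naive (exhaustive enumeration, recursion,
closed forms) and independent of the package's production code paths; tests
compare the two routes.
"""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from atdfret import (
    EmissionParams,
    KineticParams,
    PhotophysicsParams,
    simulate_experiment,
)

NO_BLEACH = PhotophysicsParams(donor_bleach_mean=1e9, acceptor_bleach_mean=1e9)


@pytest.fixture(scope="session")
def kp_default() -> KineticParams:
    return KineticParams(kon=1.0, koff=0.46, conc=0.3)


@pytest.fixture(scope="session")
def em_default() -> EmissionParams:
    return EmissionParams()


@pytest.fixture(scope="session")
def small_traceset(kp_default, em_default):
    """A small simulated experiment at 300 nM with realistic photophysics."""
    return simulate_experiment(kp_default, em_default, PhotophysicsParams(),
                               n_movies=2, traces_per_movie=30, duration=60.0, seed=1234)


def brute_force_viterbi(x, means, sds, log_a, log_pi):
    """Best labeling by exhaustive enumeration of all K^T paths (oracle)."""
    k, t = len(means), len(x)
    emit = (-0.5 * ((x[:, None] - means[None, :]) / sds[None, :]) ** 2
            - np.log(sds[None, :]) - 0.5 * np.log(2 * np.pi))
    paths = np.array(list(itertools.product(range(k), repeat=t)), dtype=int)
    scores = log_pi[paths[:, 0]] + emit[np.arange(t), paths].sum(axis=1)
    scores += log_a[paths[:, :-1], paths[:, 1:]].sum(axis=1)
    best = int(np.argmax(scores))
    return paths[best], float(scores[best])


def recursive_merge_oracle(runs, dead_time):
    """Dead-time merging by literal recursion on the stated rule (oracle)."""
    runs = [(s, d) for s, d in runs]
    # coalesce adjacent same-state runs
    out = []
    for s, d in runs:
        if out and out[-1][0] == s:
            out[-1] = (s, out[-1][1] + d)
        else:
            out.append((s, d))
    runs = out
    for i, (s, d) in enumerate(runs):
        if d < dead_time - 1e-12 and len(runs) > 1:
            if i == 0:
                rest = [(runs[1][0], runs[1][1] + d)] + runs[2:]
            else:
                rest = runs[:i - 1] + [(runs[i - 1][0], runs[i - 1][1] + d)] + runs[i + 1:]
            return recursive_merge_oracle(rest, dead_time)
    return runs


def gillespie_dwell_table(q, n_dwells, seed, start=None):
    """Complete (non-censored) dwells of a long stationary realization."""
    from atdfret import simulate_state_path

    rng = np.random.default_rng(seed)
    states, durs = [], []
    # long path; chop into chunks until enough complete dwells
    while len(durs) < n_dwells:
        lam = -np.diag(q)
        mean_rate = lam[lam > 0].mean()
        span = (n_dwells - len(durs) + 10) / mean_rate * 1.5
        p = simulate_state_path(q, span, start_state=start, seed=rng)
        if len(p.states) < 3:
            continue
        d = np.diff(p.bounds)
        states.extend(p.states[1:-1])       # drop censored first/last dwells
        durs.extend(d[1:-1])
    return np.asarray(states[:n_dwells]), np.asarray(durs[:n_dwells])
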