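"""Shared fixtures: small synthetic fits, survey records, and oracles."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from gutsgof.guts_core import ExposureProfile, GutsParamsSD
from gutsgof.synthetic_fits import generate_fit_library
from gutsgof import synthetic_survey as ss

settings.register_profile("ci", derandomize=True, deadline=None, max_examples=25)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def fit_library():
    return generate_fit_library(n_fits=40, seed=3)


@pytest.fixture(scope="session")
def truth_model():
    return ss.TrueScoreModel()


@pytest.fixture(scope="session")
def survey_records(fit_library, truth_model):
    design = ss.generate_survey_design(64, fit_library, seed=5)
    rec = ss.sample_scores(design, truth_model, seed=6)
    return ss.sample_rejection_reasons(rec, truth_model, seed=7)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_profile(rng, interpolation=None):
    """Random piecewise exposure profile with concentrations well away from 0
    so relative damage comparisons are meaningful."""
    n = int(rng.integers(2, 6))
    times = np.sort(rng.uniform(0.0, 6.0, size=n))
    times[0] = 0.0
    while np.any(np.diff(times) <= 1e-3):
        times = np.sort(rng.uniform(0.0, 6.0, size=n))
        times[0] = 0.0
    concs = rng.uniform(0.5, 3.0, size=n)
    interp = interpolation or ("linear" if rng.uniform() < 0.5 else "constant")
    return ExposureProfile(times, concs, interpolation=interp)


def ode_damage(profile, kd, times):
    """Adaptive numerical ODE oracle for the damage dynamic, integrated
    segment by segment so discontinuities never cross a solver step."""
    from scipy.integrate import solve_ivp

    times = np.asarray(times, dtype=float)
    knots = np.unique(np.concatenate([[0.0], profile.times, times]))
    knots = knots[(knots >= 0.0) & (knots <= times[-1])]
    if knots[-1] < times[-1]:
        knots = np.append(knots, times[-1])
    D = 0.0
    out = {0.0: 0.0}
    for a, b in zip(knots[:-1], knots[1:]):
        if b <= a:
            continue
        sol = solve_ivp(
            lambda t, y: kd * (profile.concentration_at(np.array([t]))[0] - y[0]),
            (a, b),
            [D],
            rtol=1e-11,
            atol=1e-13,
            dense_output=True,
            max_step=(b - a) / 4,
        )
        D = float(sol.y[0, -1])
        out[float(b)] = D
    interp_knots = sorted(out)
    return np.array(
        [out[min(interp_knots, key=lambda k: abs(k - t))] for t in times]
    )
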