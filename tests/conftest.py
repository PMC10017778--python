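import numpy as np
import pytest
from hypothesis import settings, HealthCheck

import senopbk as sp

settings.register_profile(
    "ci", derandomize=True, max_examples=25,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture(scope="session")
def params():
    return sp.PBKParameters()


@pytest.fixture(scope="session")
def lin_params(params):
    return sp.linearized(params)


@pytest.fixture(scope="session")
def sim_sen_55(params):
    """Default 24-h simulation of 55 μmol/kg oral SEN (shared, read-only)."""
    return sp.simulate(params, sp.DoseSpec(sp.SEN, 55.0))


@pytest.fixture(scope="session")
def sim_seno_55(params):
    return sp.simulate(params, sp.DoseSpec(sp.SENO, 55.0))


@pytest.fixture(scope="session")
def rep_pair_55(params):
    """Paired-arm REP at the in-vivo study dose with 63% residual kcat."""
    return sp.run_rep_pair(params, sp.REPInputs(dose_per_bw=55.0,
                                                residual_kcat_frac=0.63))


def rk4_integrate(rhs, y0, t_end, dt):
    """Fixed-step classic Runge-Kutta reference integrator."""
    y = np.array(y0, dtype=float)
    t = 0.0
    n = int(round(t_end / dt))
    for _ in range(n):
        k1 = np.asarray(rhs(t, y))
        k2 = np.asarray(rhs(t + dt / 2, y + dt / 2 * k1))
        k3 = np.asarray(rhs(t + dt / 2, y + dt / 2 * k2))
        k4 = np.asarray(rhs(t + dt, y + dt * k3))
        y = y + dt / 6 * (k1 + 2 * k2 + 2 * k3 + k4)
        t += dt
    return y
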