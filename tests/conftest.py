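import numpy as np
import pytest

from cardiopop import model
from cardiopop.pharmacology import load_drug_library, load_iso_effects
from cardiopop.protocols import PacingProtocol


@pytest.fixture(scope="session")
def base():
    return model.ModelParameters()


@pytest.fixture(scope="session")
def yss():
    """Shipped 1 Hz control steady state (fast warm start)."""
    return model.steady_state()


@pytest.fixture(scope="session")
def library():
    return load_drug_library()


@pytest.fixture(scope="session")
def cq(library):
    return library["CQ"]


@pytest.fixture(scope="session")
def azm(library):
    return library["AZM"]


@pytest.fixture(scope="session")
def iso():
    return load_iso_effects()


@pytest.fixture(scope="session")
def lsoda_reference_apd(base, yss):
    """APD90 of one beat from the steady state, integrated by scipy's stiff
    LSODA on the same right-hand side as the production kernel (stimulus
    window integrated separately so the solver sees the discontinuity)."""
    from scipy.integrate import solve_ivp

    from cardiopop import _ord, biomarkers

    P = base.to_vector()

    def rhs(t, y):
        istim = base.stim_amplitude if t < base.stim_duration else 0.0
        return _ord.rhs(t, y, P, istim)

    s1 = solve_ivp(rhs, (0.0, base.stim_duration), yss.copy(), method="LSODA",
                   rtol=1e-8, atol=1e-10, max_step=0.05,
                   t_eval=np.arange(0.0, base.stim_duration, 0.02))
    s2 = solve_ivp(rhs, (base.stim_duration, 1000.0), s1.y[:, -1], method="LSODA",
                   rtol=1e-8, atol=1e-10, max_step=1.0,
                   t_eval=np.arange(base.stim_duration, 1000.0, 0.25))
    t = np.concatenate([s1.t, s2.t])
    v = np.concatenate([s1.y[0], s2.y[0]])
    return biomarkers.apd(t, v, v_diastolic=yss[0])


@pytest.fixture()
def quick_proto():
    """A few beats from the warm start: enough for plumbing checks."""
    return PacingProtocol(frequency_hz=1.0, n_prepace=3, n_record=2, min_prepace=1)
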