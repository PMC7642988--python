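"""O'Hara-Rudy (2011) human ventricular epicardial myocyte: public interface.

The model is the widely used human ventricular cardiomyocyte ODE system
(41 state variables; epicardial parameterization). This module exposes the
state layout, a parameter container with the hooks the analysis needs
(per-current conductance multipliers, extracellular ion concentrations,
I_CaL steady-state gating shifts, stimulus), derivative evaluation with a
current snapshot, and the I_CaL window-current diagnostic.

Units: time ms, voltage mV, concentrations mM, currents uA/uF.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from importlib import resources

import numpy as np

from . import _ord

__all__ = [
    "STATE_NAMES",
    "CURRENT_NAMES",
    "SCALABLE_CURRENTS",
    "VARIED_CURRENTS",
    "ModelParameters",
    "SolverSettings",
    "initial_state",
    "steady_state",
    "derivatives",
    "steady_state_ical_window",
]

STATE_NAMES = (
    "v", "nai", "nass", "ki", "kss", "cai", "cass", "cansr", "cajsr",
    "m", "hf", "hs", "j", "hsp", "jp", "mL", "hL", "hLp",
    "a", "iF", "iS", "ap", "iFp", "iSp",
    "d", "ff", "fs", "fcaf", "fcas", "jca", "nca", "ffp", "fcafp",
    "xrf", "xrs", "xs1", "xs2", "xk1",
    "Jrelnp", "Jrelp", "CaMKt",
)

CURRENT_NAMES = (
    "INa", "INaL", "Ito", "ICaL", "ICaNa", "ICaK", "IKr", "IKs", "IK1",
    "INaCa_i", "INaCa_ss", "INaK", "INab", "IKb", "IpCa", "ICab",
)

#: currents with a conductance multiplier hook, mapped to parameter-vector slots
SCALABLE_CURRENTS = {
    "INa": _ord.P_INA,
    "INaL": _ord.P_INAL,
    "ICaL": _ord.P_ICAL,
    "IKr": _ord.P_IKR,
    "IKs": _ord.P_IKS,
    "IK1": _ord.P_IK1,
    "Ito": _ord.P_ITO,
    "INaCa": _ord.P_INACA,
    "INaK": _ord.P_INAK,
    "IKb": _ord.P_IKB,
    "INab": _ord.P_INAB,
    "ICab": _ord.P_ICAB,
    "IpCa": _ord.P_IPCA,
}

#: the nine currents varied in the population of models
VARIED_CURRENTS = ("INa", "INaL", "ICaL", "IKr", "IKs", "IK1", "Ito", "INaCa", "INaK")

# gating variables are the dimensionless states in [0, 1]
GATING_SLICE = slice(_ord.IM, _ord.ICAMKT)
_CONC_IDX = tuple(range(_ord.INAI, _ord.IM))


@dataclass
class ModelParameters:
    """Baseline epicardial model with runtime perturbation hooks.

    Parameters
    ----------
    scale
        Current-name -> dimensionless conductance/permeability multiplier
        (default 1.0). Keys must be in :data:`SCALABLE_CURRENTS`.
    ko_mM, nao_mM, cao_mM
        Extracellular K+, Na+, Ca2+ concentrations (defaults 5.4, 140, 1.8).
    dv_act_mV, dv_inact_mV
        Signed voltage shifts applied to the I_CaL steady-state activation
        and inactivation curves only (time constants untouched). Activation
        is evaluated at V - dv_act, so a negative dv_act shifts the curve
        leftward (channels open at more negative potentials); a positive
        dv_inact shifts inactivation rightward. Together they enlarge the
        window current.
    stim_amplitude, stim_duration
        Square stimulus pulse (uA/uF, ms) delivered at each beat onset.
        The default 1 ms pulse keeps capture reliable even from the
        hyperpolarized resting potentials of severe hypokalemia.
    """

    scale: dict[str, float] = field(default_factory=dict)
    ko_mM: float = 5.4
    nao_mM: float = 140.0
    cao_mM: float = 1.8
    dv_act_mV: float = 0.0
    dv_inact_mV: float = 0.0
    stim_amplitude: float = -80.0
    stim_duration: float = 1.0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        for name, mult in self.scale.items():
            if name not in SCALABLE_CURRENTS:
                raise ValueError(f"unknown current {name!r}; known: {sorted(SCALABLE_CURRENTS)}")
            if not mult >= 0.0:
                raise ValueError(f"scale[{name!r}] must be >= 0, got {mult}")
        if not self.ko_mM > 0:
            raise ValueError("ko_mM must be positive")
        if not (self.nao_mM > 0 and self.cao_mM > 0):
            raise ValueError("extracellular concentrations must be positive")
        if not self.stim_duration > 0:
            raise ValueError("stim_duration must be positive")

    def copy(self) -> "ModelParameters":
        return replace(self, scale=dict(self.scale))

    def to_vector(self) -> np.ndarray:
        """Pack into the kernel parameter vector."""
        self.validate()
        P = np.ones(_ord.NP)
        for name, mult in self.scale.items():
            P[SCALABLE_CURRENTS[name]] = mult
        P[_ord.P_KO] = self.ko_mM
        P[_ord.P_NAO] = self.nao_mM
        P[_ord.P_CAO] = self.cao_mM
        P[_ord.P_DVACT] = self.dv_act_mV
        P[_ord.P_DVINACT] = self.dv_inact_mV
        P[_ord.P_STIMAMP] = self.stim_amplitude
        P[_ord.P_STIMDUR] = self.stim_duration
        return P


@dataclass
class SolverSettings:
    """Adaptive Rush-Larsen / forward-Euler integrator controls.

    ``dv_target_mV`` bounds the voltage change per step; phase-dependent
    caps keep steps small during the upstroke/notch (``dt_max_ap_ms``) and
    allow long steps in diastole (``dt_max_dia_ms``). Defaults were chosen
    so that action potentials agree with a stiff reference integration of
    the same equations (scipy LSODA, rtol 1e-6) to well under 1 ms in APD90.
    """

    dv_target_mV: float = 0.05
    dt_min_ms: float = 0.001
    dt_max_ap_ms: float = 0.1
    dt_max_dia_ms: float = 1.0
    dt_output_ms: float = 0.25


def _load_state(name: str) -> np.ndarray:
    with resources.files("cardiopop").joinpath("data", name).open() as fh:
        data = json.load(fh)
    vals = data["state"]
    return np.array([vals[k] for k in STATE_NAMES], dtype=float)


def initial_state() -> np.ndarray:
    """Published resting initial conditions (epicardial), as shipped in the
    versioned parameter file. Returns a fresh copy on each call."""
    return _load_state("ord_epi_initial_state.json")


def steady_state() -> np.ndarray:
    """Model state after 1,000 beats of 1 Hz prepacing of the unperturbed
    epicardial model (precomputed once with this package and shipped as
    data). A convenient warm start for paced protocols."""
    return _load_state("ord_epi_steady_1hz.json")


def validate_state(y: np.ndarray) -> None:
    y = np.asarray(y, dtype=float)
    if y.shape != (len(STATE_NAMES),):
        raise ValueError(f"state vector must have length {len(STATE_NAMES)}")
    if not np.all(np.isfinite(y)):
        raise ValueError("state vector contains non-finite entries")
    gates = y[GATING_SLICE]
    # nca and the Jrel fluxes live outside [0,1]; check the true gates
    for idx in range(_ord.IM, _ord.INCA):
        if not -1e-9 <= y[idx] <= 1.0 + 1e-9:
            raise ValueError(f"gating variable {STATE_NAMES[idx]} outside [0,1]: {y[idx]}")
    del gates
    for idx in _CONC_IDX:
        if not y[idx] > 0:
            raise ValueError(f"concentration {STATE_NAMES[idx]} must be positive")


def derivatives(t: float, y: np.ndarray, p: ModelParameters, i_stim: float = 0.0):
    """Evaluate the full right-hand side.

    Returns ``(dy, currents)`` where ``dy`` is the 41-vector of time
    derivatives and ``currents`` maps each name in :data:`CURRENT_NAMES` to
    its instantaneous value (uA/uF). Each current is scaled by its
    multiplier before summation into dV/dt.
    """
    y = np.ascontiguousarray(y, dtype=float)
    if not np.all(np.isfinite(y)):
        raise FloatingPointError("non-finite state passed to derivatives()")
    P = p.to_vector()
    dy = np.empty(_ord.NY)
    inf = np.empty(_ord.NY)
    tau = np.empty(_ord.NY)
    cur = np.empty(_ord.NCUR)
    _ord.rates(y, P, i_stim, dy, inf, tau, cur)
    return dy, dict(zip(CURRENT_NAMES, cur))


def ical_steady_states(p: ModelParameters, v: np.ndarray):
    """I_CaL steady-state activation/inactivation on a voltage grid, with the
    parameterized shifts applied."""
    v = np.asarray(v, dtype=float)
    act = 1.0 / (1.0 + np.exp(-((v - p.dv_act_mV) + 3.940) / 4.230))
    inact = 1.0 / (1.0 + np.exp(((v - p.dv_inact_mV) + 19.58) / 3.696))
    return act, inact


def steady_state_ical_window(p: ModelParameters, v_grid: np.ndarray):
    """Window-current measure: activation and inactivation curves on
    ``v_grid`` plus the integral of their product (mV-weighted overlap).

    A leftward activation shift (negative ``dv_act_mV``) combined with a
    rightward inactivation shift (positive ``dv_inact_mV``) strictly
    enlarges the window, favouring I_CaL reactivation during the plateau.
    """
    v_grid = np.asarray(v_grid, dtype=float)
    if v_grid.min() > -80.0 or v_grid.max() < 20.0:
        raise ValueError("v_grid must span at least [-80, +20] mV")
    act, inact = ical_steady_states(p, v_grid)
    window = float(np.trapezoid(act * inact, v_grid))
    return act, inact, window
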