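"""The reference in-silico study: canonical condition grid and protocols.

This module wires the packaged drug-block table, ISO effect set and
calibration windows into the two standard workflows:

* :func:`single_model_effects` — the default epicardial model paced to
  steady state (1,000 conditioning beats) across the drug x rate x ISO x
  [K+]o x window grid;
* :func:`population_effects` — the same grid over a calibrated population
  of conductance variants, at desk scale (each run warm-starts from the
  shipped 1 Hz steady state and prepaces up to 300 beats with an early stop
  once APD90 drifts < 0.05 ms/beat for 10 beats).

Both are deterministic given their seeds and inputs.
"""

from __future__ import annotations


from .model import ModelParameters, steady_state
from .pharmacology import load_drug_library, load_iso_effects
from .population import (PopulationSpec, load_calibration_ranges,
                         run_population, sample_population)
from .protocols import Condition, PacingProtocol, run_condition

__all__ = [
    "reference_protocol",
    "population_protocol",
    "single_model_conditions",
    "population_conditions",
    "single_model_effects",
    "population_effects",
]

#: a 3 mV window-enlarging shift of the I_CaL steady-state gates
WINDOW_SHIFT = {"dv_act_mV": -3.0, "dv_inact_mV": 3.0}
SEVERE_HYPOKALEMIA_KO = 2.0


def reference_protocol() -> PacingProtocol:
    """Full-fidelity steady-state pacing: 1,000 conditioning beats."""
    return PacingProtocol(frequency_hz=1.0, n_prepace=1000, n_record=2)


def population_protocol() -> PacingProtocol:
    """Desk-scale pacing for population runs: warm-started, up to 300
    conditioning beats with an APD90-convergence early stop."""
    return PacingProtocol(frequency_hz=1.0, n_prepace=300, n_record=2,
                          steady_state_tol_ms=0.05, min_prepace=100)


def default_setup():
    base = ModelParameters()
    library = load_drug_library()
    iso = load_iso_effects()
    return base, library, iso


def single_model_conditions(library) -> dict[str, Condition]:
    """The labelled single-model grid: four drug groups at 1 Hz, 2 Hz and
    2 Hz + maximal ISO, plus severe hypokalemia and the phosphorylation-
    disabled ISO variant handled separately."""
    cq, azm = library["CQ"], library["AZM"]
    groups = {"ctl": (), "cq": (cq,), "azm": (azm,), "comb": (cq, azm)}
    conds = {}
    for gname, drugs in groups.items():
        conds[f"{gname}_1hz"] = Condition(drugs=drugs, frequency_hz=1.0)
        conds[f"{gname}_2hz"] = Condition(drugs=drugs, frequency_hz=2.0)
        conds[f"{gname}_2hz_iso"] = Condition(drugs=drugs, frequency_hz=2.0, iso_fraction=1.0)
    conds["ctl_1hz_hypo"] = Condition(ko_mM=SEVERE_HYPOKALEMIA_KO, frequency_hz=1.0)
    conds["comb_1hz_hypo"] = Condition(drugs=groups["comb"], ko_mM=SEVERE_HYPOKALEMIA_KO,
                                       frequency_hz=1.0)
    conds["comb_2hz_iso_win"] = Condition(drugs=groups["comb"], frequency_hz=2.0,
                                          iso_fraction=1.0, **WINDOW_SHIFT)
    return conds


def single_model_effects(keys=None, protocol=None):
    """Run the labelled grid on the default model.

    Returns ``{key: BiomarkerSet}``. ``keys`` restricts the grid (all keys
    when None). All runs warm-start from the shipped 1 Hz steady state.
    """
    base, library, iso = default_setup()
    proto = protocol or reference_protocol()
    conds = single_model_conditions(library)
    if keys is not None:
        conds = {k: conds[k] for k in keys}
    y0 = steady_state()
    out = {}
    for key, cond in conds.items():
        _, bm = run_condition(base, cond, proto, iso_set=iso, y0=y0)
        out[key] = bm
    return out


def population_conditions(library) -> list[Condition]:
    """The population condition grid: single and combined drugs at 1 Hz,
    the combination at 2 Hz with maximal ISO (with and without the 3 mV
    window shift), and the combination under severe hypokalemia."""
    cq, azm = library["CQ"], library["AZM"]
    return [
        Condition(drugs=(cq,), frequency_hz=1.0, label="CQ 1Hz"),
        Condition(drugs=(azm,), frequency_hz=1.0, label="AZM 1Hz"),
        Condition(drugs=(cq, azm), frequency_hz=1.0, label="CQ+AZM 1Hz"),
        Condition(drugs=(cq, azm), frequency_hz=2.0, iso_fraction=1.0,
                  label="CQ+AZM 2Hz ISO"),
        Condition(drugs=(cq, azm), frequency_hz=2.0, iso_fraction=1.0,
                  label="CQ+AZM 2Hz ISO win", **WINDOW_SHIFT),
        Condition(drugs=(cq, azm), frequency_hz=1.0, ko_mM=SEVERE_HYPOKALEMIA_KO,
                  label="CQ+AZM 1Hz hypoK"),
    ]


def population_effects(n_models=100, seed=0, conditions=None, n_jobs=1):
    """Sample, calibrate and run the population grid.

    Returns ``(PopulationSummary, per-variant table, baseline table)``.
    """
    base, library, iso = default_setup()
    conds = conditions if conditions is not None else population_conditions(library)
    spec = PopulationSpec(n_models=n_models, seed=seed)
    variants = sample_population(spec)
    ranges = load_calibration_ranges()
    return run_population(base, variants, conds, population_protocol(),
                          iso_set=iso, ranges=ranges, seed=seed, n_jobs=n_jobs)
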