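"""Pacing protocols and the experiment grid (drug x rate x ISO x [K+]o x
I_CaL window shift).

All simulations follow the same scheme: prepace to approximate steady state
(state carried over between beats, optional early stop on beat-to-beat APD90
convergence), then record a handful of beats on a uniform output grid for
biomarker extraction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _ord, biomarkers
from .model import ModelParameters, SolverSettings, initial_state
from .pharmacology import DrugSpec, IsoEffectSet, apply_drugs, apply_iso

__all__ = ["PacingProtocol", "PacedTrace", "Condition", "run_paced", "run_condition", "rate_sweep"]

FREQ_RANGE_HZ = (0.25, 4.0)


class SolverError(RuntimeError):
    """Integration failure, carrying the condition label and beat index."""

    def __init__(self, label: str, beat: int):
        super().__init__(f"solver failure in condition {label!r} at beat {beat}")
        self.label = label
        self.beat = beat


@dataclass(frozen=True)
class PacingProtocol:
    """Steady-state pacing: ``n_prepace`` conditioning beats (optionally
    stopped early once |dAPD90| < ``steady_state_tol_ms`` for 10 beats),
    then ``n_record`` recorded beats."""

    frequency_hz: float = 1.0
    n_prepace: int = 1000
    n_record: int = 2
    steady_state_tol_ms: float | None = None
    min_prepace: int = 50
    record_currents: bool = False
    solver: SolverSettings = field(default_factory=SolverSettings)

    def __post_init__(self):
        if not FREQ_RANGE_HZ[0] <= self.frequency_hz <= FREQ_RANGE_HZ[1]:
            raise ValueError(f"frequency must be within {FREQ_RANGE_HZ} Hz")
        if self.n_prepace < 1:
            raise ValueError("n_prepace must be >= 1")
        if self.n_record < 2:
            raise ValueError("n_record must be >= 2 (alternans needs beat pairs)")

    @property
    def cycle_length_ms(self) -> float:
        return 1000.0 / self.frequency_hz

    def at_frequency(self, f_hz: float) -> "PacingProtocol":
        from dataclasses import replace

        return replace(self, frequency_hz=f_hz)


@dataclass
class PacedTrace:
    """Recorded beats of a paced run.

    ``time_ms`` is the beat-local uniform grid; ``v_mV`` and ``cai_mM`` have
    shape (n_record, n_samples). Per-beat APD90/RMP statistics cover every
    simulated beat (prepace included) for convergence diagnostics.
    """

    time_ms: np.ndarray
    v_mV: np.ndarray
    cai_mM: np.ndarray
    currents: dict[str, np.ndarray] | None
    apd_per_beat: np.ndarray
    rmp_per_beat: np.ndarray
    vpeak_per_beat: np.ndarray
    cat_min_per_beat: np.ndarray
    cat_max_per_beat: np.ndarray
    prepace_beats: int
    cycle_length_ms: float
    label: str = ""
    final_state: np.ndarray | None = None

    @property
    def n_beats(self) -> int:
        return self.v_mV.shape[0]

    def beat(self, i: int):
        return self.time_ms, self.v_mV[i], self.cai_mM[i]

    def recorded_apds(self) -> np.ndarray:
        return self.apd_per_beat[self.prepace_beats:]


@dataclass(frozen=True)
class Condition:
    """One cell of the experiment grid; fully determines a simulation given
    base parameters, the ISO effect set and the protocol."""

    drugs: tuple[DrugSpec, ...] = ()
    iso_fraction: float = 0.0
    ko_mM: float = 5.4
    dv_act_mV: float = 0.0
    dv_inact_mV: float = 0.0
    frequency_hz: float = 1.0
    label: str = ""

    def describe(self) -> str:
        if self.label:
            return self.label
        parts = ["+".join(d.name for d in self.drugs) or "control", f"{self.frequency_hz:g}Hz"]
        if self.iso_fraction > 0:
            parts.append(f"ISO{self.iso_fraction:g}")
        if self.ko_mM != 5.4:
            parts.append(f"Ko{self.ko_mM:g}")
        if self.dv_act_mV or self.dv_inact_mV:
            parts.append(f"win({self.dv_act_mV:g},{self.dv_inact_mV:g})")
        return " ".join(parts)

    def drug_free(self) -> "Condition":
        """The matched control: same rate/ISO/[K+]o/window shift, no drugs."""
        from dataclasses import replace

        return replace(self, drugs=(), label="")

    def parameters(self, base: ModelParameters, iso_set: IsoEffectSet | None) -> ModelParameters:
        p = base.copy()
        p.ko_mM = self.ko_mM
        p.dv_act_mV += self.dv_act_mV
        p.dv_inact_mV += self.dv_inact_mV
        p = apply_drugs(p, self.drugs)
        if self.iso_fraction > 0:
            if iso_set is None:
                raise ValueError("condition requests ISO but no effect set was given")
            p = apply_iso(p, iso_set.with_fraction(self.iso_fraction))
        return p


def run_paced(
    p: ModelParameters,
    proto: PacingProtocol,
    y0: np.ndarray | None = None,
    label: str = "",
) -> PacedTrace:
    """Integrate the paced protocol and return the recorded trace.

    The state is carried over between beats; ``y0`` defaults to the shipped
    resting initial conditions. Deterministic: identical inputs give
    bit-identical outputs (fixed step-selection rule, no randomness).
    """
    y = (initial_state() if y0 is None else np.array(y0, dtype=float)).copy()
    P = p.to_vector()
    s = proto.solver
    cl = proto.cycle_length_ms
    ss_tol = proto.steady_state_tol_ms if proto.steady_state_tol_ms is not None else 0.0
    (apd_b, rmp_b, vpeak_b, cat_min, cat_max, _dvdt, rec_v, rec_cai, rec_cur,
     n_run, n_prepace, status) = _ord.pace(
        y, P, cl, proto.n_prepace, proto.n_record, proto.min_prepace, ss_tol,
        s.dt_output_ms, s.dv_target_mV, s.dt_min_ms, s.dt_max_ap_ms,
        s.dt_max_dia_ms, 90.0, proto.record_currents,
    )
    if status != 0:
        raise SolverError(label, int(n_run))
    time_ms = np.arange(rec_v.shape[1]) * s.dt_output_ms
    currents = None
    if proto.record_currents:
        from .model import CURRENT_NAMES

        currents = {name: rec_cur[:, :, k] for k, name in enumerate(CURRENT_NAMES)}
    return PacedTrace(
        time_ms=time_ms,
        v_mV=rec_v,
        cai_mM=rec_cai,
        currents=currents,
        apd_per_beat=apd_b[:n_run],
        rmp_per_beat=rmp_b[:n_run],
        vpeak_per_beat=vpeak_b[:n_run],
        cat_min_per_beat=cat_min[:n_run],
        cat_max_per_beat=cat_max[:n_run],
        prepace_beats=int(n_prepace),
        cycle_length_ms=cl,
        label=label,
        final_state=y,
    )


def run_condition(
    base: ModelParameters,
    cond: Condition,
    proto: PacingProtocol,
    iso_set: IsoEffectSet | None = None,
    y0: np.ndarray | None = None,
    config: biomarkers.BiomarkerConfig = biomarkers.BiomarkerConfig(),
) -> tuple[PacedTrace, biomarkers.BiomarkerSet]:
    """Compose drugs/ISO/[K+]o/window settings onto ``base``, pace at the
    condition's frequency, and extract biomarkers from the last recorded
    beat (flags are set if any recorded beat shows an event)."""
    p = cond.parameters(base, iso_set)
    proto = proto.at_frequency(cond.frequency_hz)
    trace = run_paced(p, proto, y0=y0, label=cond.describe())
    bm = trace_biomarkers(trace, config)
    return trace, bm


def trace_biomarkers(trace: PacedTrace, config=biomarkers.BiomarkerConfig()) -> biomarkers.BiomarkerSet:
    last = trace.n_beats - 1
    t, v, cai = trace.beat(last)
    bm = biomarkers.from_beat(
        t, v, cai, trace.cycle_length_ms,
        apd_history=list(trace.recorded_apds()), config=config,
    )
    # an event on any recorded beat flags the condition
    for i in range(trace.n_beats - 1):
        t, v, cai = trace.beat(i)
        if not bm.ead:
            ead, et, ea = biomarkers.detect_ead(t, v, config=config)
            if ead:
                bm.ead, bm.ead_time_ms, bm.ead_amplitude_mV = True, et, ea
        if not bm.rf and biomarkers.detect_rf(t, v, config=config):
            bm.rf = True
    return bm


def rate_sweep(
    base: ModelParameters,
    cond: Condition,
    frequencies,
    proto: PacingProtocol,
    iso_set: IsoEffectSet | None = None,
    y0: np.ndarray | None = None,
):
    """Biomarkers per pacing frequency (one row each), flagging incomplete
    repolarization (RF) at fast rates. Returns a list of (frequency_hz,
    BiomarkerSet) ordered as given."""
    from dataclasses import replace

    rows = []
    for f in frequencies:
        c = replace(cond, frequency_hz=f)
        _, bm = run_condition(base, c, proto, iso_set=iso_set, y0=y0)
        rows.append((f, bm))
    return rows
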