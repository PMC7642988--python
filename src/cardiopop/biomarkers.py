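"""Action-potential and Ca2+-transient biomarkers and proarrhythmia event
detection (EADs, repolarization failure, alternans) on paced traces.

Detector thresholds are operational choices exposed in
:class:`BiomarkerConfig`: a secondary depolarization must rise >= 2 mV above
a local minimum to count as an EAD; repolarization failure means the
membrane never returns below -60 mV between 50 ms post-upstroke and the
next stimulus; alternans means consecutive APD differences > 5 ms with
alternating sign.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "BiomarkerConfig",
    "BiomarkerSet",
    "apd",
    "rmp",
    "detect_ead",
    "detect_rf",
    "detect_alternans",
    "percent_change",
    "from_beat",
]


@dataclass(frozen=True)
class BiomarkerConfig:
    ead_rise_mV: float = 2.0
    ead_search_start_ms: float = 100.0
    rf_threshold_mV: float = -60.0
    rf_blanking_ms: float = 50.0
    alternans_tol_ms: float = 5.0
    upstroke_dvdt: float = 10.0  # mV/ms
    apd_level: float = 90.0


@dataclass
class BiomarkerSet:
    """Per-condition biomarkers of the last recorded beat plus event flags.

    When repolarization fails (``rf``), APD90 is undefined; it is reported
    as the cycle length and ``apd_defined`` is False.
    """

    apd90_ms: float
    rmp_mV: float
    v_peak_mV: float
    cat_amplitude_mM: float
    cat_diastolic_mM: float
    ead: bool
    rf: bool
    alternans: bool
    apd_defined: bool = True
    apd_per_beat: list = field(default_factory=list)
    ead_time_ms: float = float("nan")
    ead_amplitude_mV: float = float("nan")

    def as_dict(self) -> dict:
        return {
            "apd90_ms": self.apd90_ms,
            "rmp_mV": self.rmp_mV,
            "v_peak_mV": self.v_peak_mV,
            "cat_amplitude_mM": self.cat_amplitude_mM,
            "cat_diastolic_mM": self.cat_diastolic_mM,
            "ead": self.ead,
            "rf": self.rf,
            "alternans": self.alternans,
            "apd_defined": self.apd_defined,
        }


def _upstroke(t, v, dvdt_threshold):
    dv = np.diff(v) / np.diff(t)
    if not np.any(dv > dvdt_threshold):
        raise ValueError("no upstroke: dV/dt never exceeds threshold")
    return int(np.argmax(dv))


def apd(t, v, level: float = 90.0, v_diastolic: float | None = None,
        dvdt_threshold: float = 10.0) -> float:
    """Action-potential duration at ``level``% repolarization.

    Measured from the maximum-dV/dt instant to the first downward crossing
    of ``V_peak - level/100 * (V_peak - V_diastolic)``, with linear
    interpolation between samples. ``v_diastolic`` defaults to the first
    sample (pre-stimulus potential). Returns NaN when the level is never
    crossed before the trace ends (consumed by :func:`detect_rf`).
    """
    t = np.asarray(t, dtype=float)
    v = np.asarray(v, dtype=float)
    if not 0 < level < 100:
        raise ValueError("level must be in (0, 100)")
    iu = _upstroke(t, v, dvdt_threshold)
    t_up = t[iu + 1]
    vdia = float(v[0]) if v_diastolic is None else float(v_diastolic)
    ipk = int(np.argmax(v))
    vpk = float(v[ipk])
    v_level = vpk - level / 100.0 * (vpk - vdia)
    seg = np.where((t > t[ipk]) & (v < v_level))[0]
    seg = seg[seg > ipk]
    if seg.size == 0:
        return float("nan")
    i1 = seg[0]
    i0 = i1 - 1
    frac = (v[i0] - v_level) / (v[i0] - v[i1])
    return float(t[i0] + frac * (t[i1] - t[i0]) - t_up)


def rmp(t, v) -> float:
    """Resting membrane potential: the last pre-stimulus sample. On a
    beat-aligned trace (stimulus at t=0) this is the first sample."""
    v = np.asarray(v, dtype=float)
    return float(v[0])


def detect_ead(t, v, config: BiomarkerConfig = BiomarkerConfig()):
    """Early afterdepolarization: after the AP peak and before repolarization
    to the APD level, a local minimum followed by a rise >= ``ead_rise_mV``.

    The search starts ``ead_search_start_ms`` into the beat so that the
    normal phase-1 notch / dome morphology of epicardial cells (a legitimate
    early rise) is not mistaken for an afterdepolarization.

    Returns ``(flag, event_time_ms, amplitude_mV)``; time/amplitude are NaN
    when no event is found.
    """
    t = np.asarray(t, dtype=float)
    v = np.asarray(v, dtype=float)
    # the reference peak is the initial spike: a large EAD may overshoot it,
    # so the search window must not anchor on the global maximum
    spike = v[t <= t[0] + 50.0]
    ipk = int(np.argmax(spike)) if spike.size else int(np.argmax(v))
    vpk = v[ipk]
    vdia = v[0]
    v_level = vpk - config.apd_level / 100.0 * (vpk - vdia)
    run_min = np.inf
    t_min = np.nan
    best_rise = 0.0
    best_t = np.nan
    start = max(ipk + 1, int(np.searchsorted(t, t[0] + config.ead_search_start_ms)))
    for i in range(start, len(v)):
        if v[i] < v_level:
            break
        if v[i] < run_min:
            run_min = v[i]
            t_min = t[i]
        rise = v[i] - run_min
        if rise > best_rise:
            best_rise = rise
            best_t = t[i]
    if best_rise >= config.ead_rise_mV:
        return True, float(best_t), float(best_rise)
    return False, float("nan"), float("nan")


def detect_rf(t, v, v_threshold: float | None = None,
              config: BiomarkerConfig = BiomarkerConfig(),
              dvdt_threshold: float | None = None) -> bool:
    """Repolarization failure: membrane potential never falls below the
    threshold between ``rf_blanking_ms`` after the upstroke and the next
    stimulus (trace end)."""
    t = np.asarray(t, dtype=float)
    v = np.asarray(v, dtype=float)
    thr = config.rf_threshold_mV if v_threshold is None else v_threshold
    dvdt_thr = config.upstroke_dvdt if dvdt_threshold is None else dvdt_threshold
    try:
        iu = _upstroke(t, v, dvdt_thr)
        t_up = t[iu + 1]
    except ValueError:
        t_up = t[0]
    tail = v[t >= t_up + config.rf_blanking_ms]
    if tail.size == 0:
        return False
    return bool(np.min(tail) > thr)


def detect_alternans(apds, tol_ms: float = 5.0) -> bool:
    """Beat-to-beat APD alternans: successive differences all exceed
    ``tol_ms`` in magnitude with strictly alternating sign. Needs >= 4 beats."""
    apds = np.asarray(list(apds), dtype=float)
    if apds.size < 4:
        raise ValueError("alternans detection needs >= 4 recorded beats")
    d = np.diff(apds)
    if np.any(np.abs(d) <= tol_ms):
        return False
    signs = np.sign(d)
    return bool(np.all(signs[1:] * signs[:-1] == -1))


def percent_change(value: float, reference: float) -> float:
    """100 * (value - reference) / reference."""
    if not reference > 0:
        raise ValueError("reference must be positive")
    return 100.0 * (value - reference) / reference


def from_beat(t, v, cai, cycle_length_ms: float, apd_history=None,
              config: BiomarkerConfig = BiomarkerConfig()) -> BiomarkerSet:
    """Extract the full biomarker set from one beat-aligned trace.

    ``apd_history`` (APD90 of the recorded beats, last beat included) feeds
    alternans detection when it holds >= 4 defined values.
    """
    t = np.asarray(t, dtype=float)
    v = np.asarray(v, dtype=float)
    cai = np.asarray(cai, dtype=float)
    rf = detect_rf(t, v, config=config)
    try:
        apd90 = apd(t, v, level=config.apd_level, dvdt_threshold=config.upstroke_dvdt)
    except ValueError:
        apd90 = float("nan")
    defined = np.isfinite(apd90)
    if rf or not defined:
        apd90 = float(cycle_length_ms)
        defined = False
    ead, ead_t, ead_amp = detect_ead(t, v, config=config)
    alternans = False
    hist = [a for a in (apd_history or []) if np.isfinite(a)]
    if len(hist) >= 4:
        alternans = detect_alternans(hist, tol_ms=config.alternans_tol_ms)
    return BiomarkerSet(
        apd90_ms=float(apd90),
        rmp_mV=rmp(t, v),
        v_peak_mV=float(np.max(v)),
        cat_amplitude_mM=float(np.max(cai) - np.min(cai)),
        cat_diastolic_mM=float(np.min(cai)),
        ead=bool(ead),
        rf=bool(rf),
        alternans=bool(alternans),
        apd_defined=bool(defined),
        apd_per_beat=list(apd_history or []),
        ead_time_ms=ead_t,
        ead_amplitude_mV=ead_amp,
    )
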