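"""Synthetic data generators with known ground truth.

These produce inputs carrying the statistical structure the analysis
assumes — noisy concentration-inhibition curves, parametric AP-like traces
with injectable EADs / repolarization failure / alternans, and precomputed
population biomarker tables — so that Hill fitting, the event detectors and
the population summaries are testable without any ODE integration. The
waveforms are piecewise linear/exponential caricatures, not physiological
simulations; labels are exact by construction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .pharmacology import HillParams, hill_inhibition

__all__ = ["SyntheticAPSpec", "gen_hill_dataset", "gen_ap_trace", "gen_population_fixture"]


def gen_hill_dataset(hp: HillParams, concentrations, noise_sd: float = 0.0, seed: int = 0):
    """Noisy concentration-inhibition points from a known Hill curve.

    Returns ``(points, truth)`` where ``points`` is an (n, 2) array of
    (concentration uM, inhibition fraction clipped to [0, 1]) and ``truth``
    is the generating :class:`HillParams`.
    """
    c = np.asarray(concentrations, dtype=float)
    if np.any(c < 0):
        raise ValueError("concentrations must be non-negative")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    b = hill_inhibition(c, hp)
    b = np.clip(b + rng.normal(0.0, noise_sd, size=c.shape), 0.0, 1.0)
    return np.column_stack([c, b]), hp


@dataclass(frozen=True)
class SyntheticAPSpec:
    """Parametric AP-like waveform: resting potential, a square upstroke to
    ``peak_mV``, a plateau decaying linearly into a repolarization ramp,
    then rest until the cycle ends. Optional injected features carry their
    ground-truth labels."""

    rest_mV: float = -85.0
    peak_mV: float = 40.0
    plateau_ms: float = 200.0
    ramp_ms: float = 100.0
    cycle_length_ms: float = 1000.0
    n_beats: int = 4
    ead_bump: tuple[float, float, float] | None = None  # (time ms, amplitude mV, width ms)
    rf: bool = False
    alternans_d_apd_ms: float = 0.0
    noise_sd_mV: float = 0.0
    dt_ms: float = 0.5
    seed: int = 0

    def __post_init__(self):
        if self.plateau_ms + self.ramp_ms >= self.cycle_length_ms:
            raise ValueError("AP longer than the cycle length")
        if self.ead_bump is not None:
            t_b = self.ead_bump[0]
            if not 0 < t_b < self.plateau_ms + self.ramp_ms:
                raise ValueError("EAD bump must fall before the AP ends")


def _one_beat(t, spec: SyntheticAPSpec, plateau_ms: float):
    """Voltage at beat-local times for one beat (vectorized)."""
    rest, peak = spec.rest_mV, spec.peak_mV
    ramp_end = plateau_ms + spec.ramp_ms
    v = np.full_like(t, rest)
    up = 1.0  # upstroke duration
    rising = t < up
    v[rising] = rest + (peak - rest) * (t[rising] / up)
    # plateau: gentle linear sag of 15% of the AP amplitude
    plate = (t >= up) & (t < plateau_ms)
    v[plate] = peak - 0.15 * (peak - rest) * (t[plate] - up) / max(plateau_ms - up, 1.0)
    v_plateau_end = peak - 0.15 * (peak - rest)
    if spec.rf:
        # repolarization failure: sustained depolarized potential to cycle end
        v[t >= plateau_ms] = v_plateau_end - 5.0
    else:
        ramp = (t >= plateau_ms) & (t < ramp_end)
        v[ramp] = v_plateau_end + (rest - v_plateau_end) * (t[ramp] - plateau_ms) / spec.ramp_ms
    if spec.ead_bump is not None:
        t0, amp, width = spec.ead_bump
        v += amp * np.exp(-0.5 * ((t - t0) / (width / 2.355)) ** 2)  # FWHM = width
    return v


def gen_ap_trace(spec: SyntheticAPSpec):
    """Generate ``n_beats`` beat-aligned waveforms plus ground-truth labels.

    Returns ``(time_ms, v (n_beats, n), cai (n_beats, n), labels)`` with
    ``labels`` a dict of ead/rf/alternans booleans (exact by construction).
    """
    t = np.arange(0.0, spec.cycle_length_ms, spec.dt_ms)
    rng = np.random.default_rng(spec.seed)
    beats = []
    cais = []
    for b in range(spec.n_beats):
        plateau = spec.plateau_ms + (spec.alternans_d_apd_ms if b % 2 else 0.0)
        v = _one_beat(t, spec, plateau)
        if spec.noise_sd_mV > 0:
            v = v + rng.normal(0.0, spec.noise_sd_mV, size=t.shape)
        beats.append(v)
        # schematic Ca transient: fast rise, exponential decay
        cai = 1e-4 + 4e-4 * (1 - np.exp(-t / 5.0)) * np.exp(-t / 150.0)
        cais.append(cai)
    labels = {
        "ead": spec.ead_bump is not None,
        "rf": bool(spec.rf),
        "alternans": abs(spec.alternans_d_apd_ms) > 0 and spec.n_beats >= 4,
    }
    return t, np.vstack(beats), np.vstack(cais), labels


def gen_population_fixture(n: int, seed: int = 0,
                           apd_mean: float = 230.0, apd_sd: float = 30.0,
                           rmp_mean: float = -88.0, rmp_sd: float = 1.5,
                           ead_rate: float = 0.0, rf_rate: float = 0.0) -> pd.DataFrame:
    """Per-variant biomarker table drawn from normal (APD90, RMP) and
    Bernoulli (event flag) distributions — a drop-in for calibration and
    summary statistics without simulation."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    return pd.DataFrame(
        {
            "variant": np.arange(n),
            "apd90_ms": rng.normal(apd_mean, apd_sd, n),
            "rmp_mV": rng.normal(rmp_mean, rmp_sd, n),
            "ead": rng.random(n) < ead_rate,
            "rf": rng.random(n) < rf_rate,
        }
    )
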