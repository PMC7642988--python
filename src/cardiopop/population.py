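"""Population-of-models: seeded conductance sampling, physiological
calibration, batched condition runs, and summary statistics.

Inter-individual variability is represented by scaling the maximal
conductances of nine major currents (INa, INaL, ICaL, IKr, IKs, IK1, Ito,
INaCa, INaK) with independent Normal(1.0, 0.2) factors. Variants whose
drug-free 1 Hz baseline APD90 or RMP falls outside the physiological
calibration window are excluded. Drug effects are always reported per
variant against that variant's own drug-free control at the same pacing
rate / ISO / [K+]o setting.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

from . import biomarkers
from .model import ModelParameters, VARIED_CURRENTS, steady_state
from .pharmacology import IsoEffectSet
from .protocols import Condition, PacingProtocol, SolverError, run_condition

__all__ = [
    "PopulationSpec",
    "CalibrationRanges",
    "PopulationSummary",
    "sample_population",
    "calibrate",
    "run_population",
    "load_calibration_ranges",
]


@dataclass(frozen=True)
class PopulationSpec:
    n_models: int = 1000
    sigma: float = 0.2
    mean: float = 1.0
    varied_currents: tuple[str, ...] = VARIED_CURRENTS
    seed: int = 0

    def __post_init__(self):
        if self.n_models < 1:
            raise ValueError("n_models must be >= 1")
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")


@dataclass(frozen=True)
class CalibrationRanges:
    """Physiological acceptance windows (mean +/- 3 SD of experimental
    reference data) for the drug-free 1 Hz baseline."""

    apd90_ms: tuple[float, float]
    rmp_mV: tuple[float, float]

    def __post_init__(self):
        if not self.apd90_ms[0] < self.apd90_ms[1]:
            raise ValueError("apd90 window must have lower < upper")
        if not self.rmp_mV[0] < self.rmp_mV[1]:
            raise ValueError("rmp window must have lower < upper")

    def contains(self, apd90: float, rmp: float) -> bool:
        return (
            self.apd90_ms[0] <= apd90 <= self.apd90_ms[1]
            and self.rmp_mV[0] <= rmp <= self.rmp_mV[1]
        )


def load_calibration_ranges(path=None) -> CalibrationRanges:
    """Human epicardial calibration windows (packaged default or user JSON)."""
    if path is None:
        with resources.files("cardiopop").joinpath("data", "calibration_ranges.json").open() as fh:
            cfg = json.load(fh)
    else:
        with open(path) as fh:
            cfg = json.load(fh)
    return CalibrationRanges(
        apd90_ms=tuple(cfg["apd90_ms"]), rmp_mV=tuple(cfg["rmp_mV"])
    )


def sample_population(spec: PopulationSpec) -> np.ndarray:
    """Draw ``n_models`` vectors of conductance multipliers, one per varied
    current, from Normal(mean, sigma). Negative draws are resampled (not
    truncated to zero) to preserve the distribution shape. Reproducible from
    ``spec.seed``."""
    rng = np.random.default_rng(spec.seed)
    k = len(spec.varied_currents)
    out = rng.normal(spec.mean, spec.sigma, size=(spec.n_models, k))
    bad = out < 0
    while np.any(bad):
        out[bad] = rng.normal(spec.mean, spec.sigma, size=int(bad.sum()))
        bad = out < 0
    return out


def variant_parameters(base: ModelParameters, multipliers, varied=VARIED_CURRENTS) -> ModelParameters:
    p = base.copy()
    for name, m in zip(varied, multipliers):
        p.scale[name] = p.scale.get(name, 1.0) * float(m)
    return p


def calibrate(variants: np.ndarray, baseline: pd.DataFrame, ranges: CalibrationRanges):
    """Partition variant indices into (included, excluded) according to the
    drug-free 1 Hz baseline APD90/RMP windows.

    ``baseline`` must carry one row per variant with columns ``apd90_ms``
    and ``rmp_mV`` (order matching ``variants``).
    """
    if len(baseline) != len(variants):
        raise ValueError("baseline table and variants must align")
    ok = np.array(
        [
            ranges.contains(a, r) and np.isfinite(a)
            for a, r in zip(baseline["apd90_ms"], baseline["rmp_mV"])
        ]
    )
    idx = np.arange(len(variants))
    return idx[ok], idx[~ok]


@dataclass
class PopulationSummary:
    """Per-condition medians/IQRs of APD90 change vs same-variant control and
    EAD/RF incidence (% of included variants)."""

    n_models: int
    n_included: int
    n_excluded: int
    n_failed: int
    seed: int
    conditions: dict[str, dict] = field(default_factory=dict)

    def as_dict(self) -> dict:
        return {
            "n_models": self.n_models,
            "n_included": self.n_included,
            "n_excluded": self.n_excluded,
            "n_failed": self.n_failed,
            "seed": self.seed,
            "conditions": self.conditions,
        }


def _variant_rows(
    vid: int,
    mult: np.ndarray,
    base: ModelParameters,
    conditions,
    proto: PacingProtocol,
    iso_set,
    y_start: np.ndarray,
    config: biomarkers.BiomarkerConfig,
):
    """Run every condition (plus the matched drug-free controls) for one
    variant, warm-starting from the shared 1 Hz steady state."""
    p_var = variant_parameters(base, mult)
    rows = []
    control_states: dict[str, np.ndarray] = {}
    control_bm: dict[str, biomarkers.BiomarkerSet] = {}

    def run_control(ctrl: Condition):
        key = ctrl.describe()
        if key not in control_bm:
            trace, bm = run_condition(base=p_var, cond=ctrl, proto=proto,
                                      iso_set=iso_set, y0=y_start, config=config)
            control_states[key] = trace.final_state
            control_bm[key] = bm
        return control_bm[key], control_states[key]

    for cond in conditions:
        ctrl = cond.drug_free()
        try:
            bm_ctrl, y_ctrl = run_control(ctrl)
            if cond.drugs:
                _, bm = run_condition(base=p_var, cond=cond, proto=proto,
                                      iso_set=iso_set, y0=y_ctrl, config=config)
            else:
                bm = bm_ctrl
        except SolverError:
            rows.append({"variant": vid, "condition": cond.describe(), "failed": True})
            continue
        row = {
            "variant": vid,
            "condition": cond.describe(),
            "failed": False,
            "d_apd90_ms": bm.apd90_ms - bm_ctrl.apd90_ms,
            "control_apd90_ms": bm_ctrl.apd90_ms,
            **bm.as_dict(),
        }
        for name, m in zip(VARIED_CURRENTS, mult):
            row[f"mult_{name}"] = float(m)
        rows.append(row)
    return rows


def run_population(
    base: ModelParameters,
    variants: np.ndarray,
    conditions,
    proto: PacingProtocol,
    iso_set: IsoEffectSet | None = None,
    ranges: CalibrationRanges | None = None,
    seed: int = 0,
    n_jobs: int = 1,
    config: biomarkers.BiomarkerConfig = biomarkers.BiomarkerConfig(),
    baseline_proto: PacingProtocol | None = None,
):
    """Run the condition grid over a (to-be-calibrated) population.

    For every variant the drug-free 1 Hz baseline is simulated first (from
    the shipped unperturbed steady state); variants outside the calibration
    windows are excluded. Each remaining condition is warm-started from the
    variant's own matched control at the same rate/ISO/[K+]o setting, and
    the APD90 change is taken against that control. Results are independent
    of ``n_jobs`` (each variant is a self-contained task).

    Returns ``(PopulationSummary, per-variant DataFrame, baseline DataFrame)``.
    """
    variants = np.asarray(variants, dtype=float)
    if variants.ndim == 1:
        variants = variants[None, :]
    n = len(variants)
    if ranges is None:
        ranges = load_calibration_ranges()
    bproto = baseline_proto or proto
    y_ss = steady_state()

    baseline_cond = Condition(frequency_hz=1.0, label="baseline 1Hz control")

    def baseline_one(vid):
        p_var = variant_parameters(base, variants[vid])
        try:
            trace, bm = run_condition(base=p_var, cond=baseline_cond, proto=bproto,
                                      iso_set=iso_set, y0=y_ss, config=config)
        except SolverError:
            return {"variant": vid, "apd90_ms": np.nan, "rmp_mV": np.nan}, None
        return {"variant": vid, **bm.as_dict()}, trace.final_state

    def variant_one(vid, y_start):
        return _variant_rows(vid, variants[vid], base, conditions, proto,
                             iso_set, y_start, config)

    if n_jobs != 1:
        from joblib import Parallel, delayed

        base_out = Parallel(n_jobs=n_jobs)(delayed(baseline_one)(i) for i in range(n))
    else:
        base_out = [baseline_one(i) for i in range(n)]
    baseline = pd.DataFrame([r for r, _ in base_out])
    states = {i: s for i, (_, s) in enumerate(base_out) if s is not None}

    included, excluded = calibrate(variants, baseline, ranges)
    included = [i for i in included if i in states]

    if n_jobs != 1:
        from joblib import Parallel, delayed

        all_rows = Parallel(n_jobs=n_jobs)(
            delayed(variant_one)(i, states[i]) for i in included
        )
    else:
        all_rows = [variant_one(i, states[i]) for i in included]
    rows = [r for chunk in all_rows for r in chunk]
    table = pd.DataFrame(rows)

    summary = PopulationSummary(
        n_models=n,
        n_included=len(included),
        n_excluded=n - len(included),
        n_failed=0,
        seed=seed,
    )
    if len(table):
        failed = table.get("failed")
        summary.n_failed = int(failed.sum()) if failed is not None else 0
        ok = table[~table["failed"]] if "failed" in table else table
        for cond in conditions:
            key = cond.describe()
            sub = ok[ok["condition"] == key]
            if not len(sub):
                continue
            d = sub["d_apd90_ms"].to_numpy()
            a = sub["apd90_ms"].to_numpy()
            ev = (sub["ead"] | sub["rf"]).to_numpy()
            summary.conditions[key] = {
                "n": int(len(sub)),
                "median_d_apd90_ms": float(np.median(d)),
                "iqr_d_apd90_ms": [float(np.percentile(d, 25)), float(np.percentile(d, 75))],
                "median_apd90_ms": float(np.median(a)),
                "max_apd90_ms": float(np.max(a)),
                "ead_rf_incidence_pct": float(100.0 * np.mean(ev)),
                "ead_incidence_pct": float(100.0 * np.mean(sub["ead"].to_numpy())),
                "rf_incidence_pct": float(100.0 * np.mean(sub["rf"].to_numpy())),
            }
    return summary, table, baseline
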