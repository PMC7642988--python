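"""Concentration-dependent multichannel drug block and beta-adrenergic
(isoproterenol) parameter transformations.

Drug effects are simple pore block: each targeted current keeps a fraction
``1 - b`` of its conductance, where ``b`` follows a Hill concentration-
inhibition curve. Multiple drugs combine under the independent-binding-site
assumption (unblocked fractions multiply). Beta-adrenergic stimulation is
phenomenological: a set of per-current conductance multipliers and I_CaL
gating shifts representing the maximal (1 uM ISO) effect, linearly
interpolated by ``iso_fraction``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from importlib import resources

import numpy as np
from scipy.optimize import curve_fit

from .model import ModelParameters

__all__ = [
    "DRUG_TARGET_CURRENTS",
    "HillParams",
    "DrugSpec",
    "IsoEffectSet",
    "IsoTarget",
    "hill_inhibition",
    "fit_hill",
    "combined_block",
    "apply_drugs",
    "apply_iso",
    "disable_iso_phosphorylation",
    "load_drug_library",
    "load_iso_effects",
]

#: the seven currents with measured concentration-inhibition data
DRUG_TARGET_CURRENTS = ("INa", "INaL", "ICaL", "Ito", "IKr", "IKs", "IK1")


@dataclass(frozen=True)
class HillParams:
    """Hill concentration-inhibition curve: b(c) = c^h / (IC50^h + c^h)."""

    ic50_uM: float
    hill: float = 1.0

    def __post_init__(self):
        if not self.ic50_uM > 0:
            raise ValueError("ic50_uM must be positive")
        if not self.hill > 0:
            raise ValueError("hill coefficient must be positive")


def hill_inhibition(c, hp: HillParams):
    """Fractional inhibition at concentration ``c`` (uM); in [0, 1)."""
    c = np.asarray(c, dtype=float)
    if np.any(c < 0):
        raise ValueError("concentration must be non-negative")
    with np.errstate(divide="ignore"):
        b = 1.0 / (1.0 + (hp.ic50_uM / np.where(c > 0, c, np.nan)) ** hp.hill)
    b = np.where(c > 0, b, 0.0)
    return float(b) if b.ndim == 0 else b


def fit_hill(points) -> tuple[HillParams, float]:
    """Least-squares Hill fit to (concentration uM, inhibition fraction) pairs.

    Returns the fitted parameters and the residual sum of squares. Requires
    at least 3 points with at least 2 distinct non-zero concentrations and
    some non-zero inhibition (an all-zero response is unidentifiable).
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 3:
        raise ValueError("need >= 3 (concentration, inhibition) points")
    c, b = pts[:, 0], pts[:, 1]
    if np.any(c < 0):
        raise ValueError("concentrations must be non-negative")
    if len(np.unique(c[c > 0])) < 2:
        raise ValueError("need >= 2 distinct non-zero concentrations")
    if np.all(b <= 0):
        raise ValueError("all-zero inhibition: Hill parameters unidentifiable")

    def f(cc, log_ic50, log_h):
        ic50, h = np.exp(log_ic50), np.exp(log_h)
        with np.errstate(divide="ignore", over="ignore"):
            return np.where(cc > 0, 1.0 / (1.0 + (ic50 / np.maximum(cc, 1e-300)) ** h), 0.0)

    # initial guess: IC50 near the half-response concentration
    order = np.argsort(c)
    c0 = np.interp(0.5, np.clip(b[order], 0, 1), c[order]) if b.max() > 0.5 else np.median(c[c > 0])
    c0 = max(c0, 1e-6)
    popt, _ = curve_fit(f, c, b, p0=[np.log(c0), 0.0], maxfev=20000)
    hp = HillParams(ic50_uM=float(np.exp(popt[0])), hill=float(np.exp(popt[1])))
    rss = float(np.sum((f(c, *popt) - b) ** 2))
    return hp, rss


@dataclass(frozen=True)
class DrugSpec:
    """A drug at a fixed concentration with per-current Hill parameters."""

    name: str
    concentration_uM: float
    channels: dict[str, HillParams] = field(default_factory=dict)

    def __post_init__(self):
        if self.concentration_uM < 0:
            raise ValueError("concentration must be >= 0")
        for ch in self.channels:
            if ch not in DRUG_TARGET_CURRENTS:
                raise ValueError(
                    f"{ch!r} is not a drug target; allowed: {DRUG_TARGET_CURRENTS}"
                )

    def block_table(self) -> dict[str, float]:
        """Evaluated per-current block fractions at this spec's concentration."""
        return {
            ch: float(hill_inhibition(self.concentration_uM, hp))
            for ch, hp in self.channels.items()
        }

    def at(self, concentration_uM: float) -> "DrugSpec":
        return replace(self, concentration_uM=concentration_uM)


def combined_block(blocks) -> float:
    """Total block of independent binding sites: 1 - prod(1 - b_i)."""
    blocks = np.asarray(list(blocks), dtype=float)
    if blocks.size and (np.any(blocks < 0) or np.any(blocks > 1)):
        raise ValueError("block fractions must lie in [0, 1]")
    return float(1.0 - np.prod(1.0 - blocks))


def apply_drugs(p: ModelParameters, drugs) -> ModelParameters:
    """Return a copy of ``p`` with each targeted current's multiplier reduced
    by the combined block of all drugs (independent binding sites).

    Untargeted currents are untouched; the input is never modified.
    """
    out = p.copy()
    per_current: dict[str, list[float]] = {}
    for drug in drugs:
        for ch, b in drug.block_table().items():
            per_current.setdefault(ch, []).append(b)
    for ch, bs in per_current.items():
        out.scale[ch] = out.scale.get(ch, 1.0) * (1.0 - combined_block(bs))
    return out


@dataclass(frozen=True)
class IsoTarget:
    """Maximal (1 uM ISO) transformation of one current: a conductance
    multiplier and optional I_CaL steady-state gating shifts (mV)."""

    g_mult: float = 1.0
    dv_act_shift_mV: float = 0.0
    dv_inact_shift_mV: float = 0.0

    def __post_init__(self):
        if self.g_mult < 0:
            raise ValueError("g_mult must be >= 0")


@dataclass(frozen=True)
class IsoEffectSet:
    """Phenomenological beta-adrenergic effect set.

    ``iso_fraction`` interpolates linearly between no effect (0) and the
    maximal 1 uM ISO effect (1): multipliers as 1 + f*(m - 1), shifts as
    f*shift. The interpolation is a phenomenological convenience, not a
    mechanistic receptor-occupancy model.
    """

    targets: dict[str, IsoTarget] = field(default_factory=dict)
    iso_fraction: float = 1.0

    def __post_init__(self):
        if not 0.0 <= self.iso_fraction <= 1.0:
            raise ValueError("iso_fraction must be in [0, 1]")

    def with_fraction(self, f: float) -> "IsoEffectSet":
        return replace(self, iso_fraction=f)


def apply_iso(p: ModelParameters, iso: IsoEffectSet) -> ModelParameters:
    """Return a copy of ``p`` with the (fraction-interpolated) beta-adrenergic
    transformation applied. Pure multipliers commute with drug block."""
    out = p.copy()
    f = iso.iso_fraction
    for ch, t in iso.targets.items():
        mult = 1.0 + f * (t.g_mult - 1.0)
        if mult != 1.0 or ch in out.scale:
            out.scale[ch] = out.scale.get(ch, 1.0) * mult
        if ch == "ICaL":
            out.dv_act_mV += f * t.dv_act_shift_mV
            out.dv_inact_mV += f * t.dv_inact_shift_mV
    return out


def disable_iso_phosphorylation(iso: IsoEffectSet, targets) -> IsoEffectSet:
    """Replace the named targets' transformations with the identity,
    emulating absent PKA phosphorylation of those currents."""
    targets = set(targets)
    unknown = targets - set(iso.targets)
    if unknown:
        raise ValueError(f"not in effect set: {sorted(unknown)}")
    new = {ch: (IsoTarget() if ch in targets else t) for ch, t in iso.targets.items()}
    return replace(iso, targets=new)


# --- packaged configuration -----------------------------------------------------

def _parse_drug(name: str, entry: dict) -> DrugSpec:
    channels = {
        ch: HillParams(ic50_uM=v["ic50_uM"], hill=v.get("hill", 1.0))
        for ch, v in entry["channels"].items()
    }
    return DrugSpec(name=name, concentration_uM=entry["concentration_uM"], channels=channels)


def load_drug_library(path=None) -> dict[str, DrugSpec]:
    """Load the drug-block table (packaged default, or a user JSON file with
    the same schema). Keys are drug names; each spec carries its reference
    clinical concentration."""
    if path is None:
        with resources.files("cardiopop").joinpath("data", "drug_blocks.json").open() as fh:
            cfg = json.load(fh)
    else:
        with open(path) as fh:
            cfg = json.load(fh)
    return {name: _parse_drug(name, entry) for name, entry in cfg["drugs"].items()}


def load_iso_effects(path=None) -> IsoEffectSet:
    """Load the maximal (1 uM) ISO effect set (packaged default or user JSON)."""
    if path is None:
        with resources.files("cardiopop").joinpath("data", "iso_effects.json").open() as fh:
            cfg = json.load(fh)
    else:
        with open(path) as fh:
            cfg = json.load(fh)
    targets = {
        ch: IsoTarget(
            g_mult=v.get("g_mult", 1.0),
            dv_act_shift_mV=v.get("dv_act_shift_mV", 0.0),
            dv_inact_shift_mV=v.get("dv_inact_shift_mV", 0.0),
        )
        for ch, v in cfg["targets"].items()
    }
    return IsoEffectSet(targets=targets, iso_fraction=1.0)
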