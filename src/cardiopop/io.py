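"""Configuration-driven experiment runner and result serialization.

An experiment is fully described by a JSON/YAML config: base-model tweaks,
drug/ISO tables, a condition grid, the pacing protocol, and an optional
population section. Results land in an output directory as CSV (biomarkers,
population tables), JSON (summary + run manifest with config hash, seeds and
solver settings) and optional per-condition trace CSVs, so that a run can be
reproduced and audited from its manifest alone.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__, population as pop
from .model import ModelParameters, steady_state
from .pharmacology import load_drug_library, load_iso_effects
from .protocols import Condition, PacingProtocol, run_condition

__all__ = ["ExperimentConfig", "ConfigError", "run_experiment", "summarize_results"]

SCHEMA = "cardiopop/experiment-v1"


class ConfigError(ValueError):
    """Raised on schema violations before any simulation starts."""


@dataclass
class ExperimentConfig:
    seed: int = 0
    model: dict = field(default_factory=dict)
    protocol: dict = field(default_factory=dict)
    conditions: list = field(default_factory=list)
    population: dict | None = None
    drug_table: str | None = None
    iso_table: str | None = None
    calibration_ranges: str | None = None
    save_traces: bool = False

    @classmethod
    def from_file(cls, path) -> "ExperimentConfig":
        path = Path(path)
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if not isinstance(raw, dict):
            raise ConfigError(f"{path}: config must be a mapping")
        if raw.get("schema") != SCHEMA:
            raise ConfigError(f"{path}: schema must be {SCHEMA!r}")
        known = {f for f in cls.__dataclass_fields__} | {"schema"}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"{path}: unknown keys {sorted(unknown)}")
        cfg = cls(**{k: v for k, v in raw.items() if k != "schema"})
        cfg.validate()
        return cfg

    def validate(self) -> None:
        problems = []
        if not isinstance(self.conditions, list) or not self.conditions:
            problems.append("conditions must be a non-empty list")
        allowed = {"drugs", "frequency_hz", "iso_fraction", "ko_mM",
                   "dv_act_mV", "dv_inact_mV", "label"}
        for i, c in enumerate(self.conditions or []):
            if not isinstance(c, dict):
                problems.append(f"conditions[{i}] must be a mapping")
                continue
            extra = set(c) - allowed
            if extra:
                problems.append(f"conditions[{i}]: unknown keys {sorted(extra)}")
            if not 0.0 <= c.get("iso_fraction", 0.0) <= 1.0:
                problems.append(f"conditions[{i}]: iso_fraction outside [0,1]")
        if self.population is not None:
            if not isinstance(self.population, dict):
                problems.append("population must be a mapping")
            elif self.population.get("n_models", 0) < 1:
                problems.append("population.n_models must be >= 1")
        if problems:
            raise ConfigError("; ".join(problems))

    def build(self):
        """Materialize (base params, conditions, protocol, iso set, library)."""
        library = load_drug_library(self.drug_table)
        iso_set = load_iso_effects(self.iso_table)
        base = ModelParameters(**self.model)
        proto = PacingProtocol(**self.protocol) if self.protocol else PacingProtocol()
        conds = []
        for c in self.conditions:
            names = c.get("drugs", [])
            try:
                drugs = tuple(library[n] for n in names)
            except KeyError as e:
                raise ConfigError(f"unknown drug {e.args[0]!r} in condition") from None
            conds.append(Condition(
                drugs=drugs,
                frequency_hz=c.get("frequency_hz", 1.0),
                iso_fraction=c.get("iso_fraction", 0.0),
                ko_mM=c.get("ko_mM", 5.4),
                dv_act_mV=c.get("dv_act_mV", 0.0),
                dv_inact_mV=c.get("dv_inact_mV", 0.0),
                label=c.get("label", ""),
            ))
        return base, conds, proto, iso_set


def _hash_file(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def _write_json(path, obj) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")


def run_experiment(config_path, output_dir) -> Path:
    """Execute the configured single-model (and optional population) runs.

    Writes ``biomarkers.csv``, ``summary.json`` and ``manifest.json`` (plus
    ``population.csv``/``population_baseline.csv`` and per-condition trace
    CSVs when requested) into ``output_dir`` and returns that path.
    """
    config_path = Path(config_path)
    cfg = ExperimentConfig.from_file(config_path)
    base, conds, proto, iso_set = cfg.build()
    out = Path(output_dir)
    out.mkdir(parents=True, exist_ok=True)

    y0 = steady_state()
    rows = []
    for cond in conds:
        trace, bm = run_condition(base, cond, proto, iso_set=iso_set, y0=y0)
        rows.append({"condition": cond.describe(), "frequency_hz": cond.frequency_hz,
                     **bm.as_dict()})
        if cfg.save_traces:
            tdf = pd.DataFrame({"time_ms": trace.time_ms})
            for b in range(trace.n_beats):
                tdf[f"v_mV_beat{b}"] = trace.v_mV[b]
                tdf[f"cai_mM_beat{b}"] = trace.cai_mM[b]
            safe = cond.describe().replace(" ", "_").replace("/", "-")
            tdf.to_csv(out / f"trace_{safe}.csv", index=False)
    biomarkers = pd.DataFrame(rows)
    biomarkers.to_csv(out / "biomarkers.csv", index=False)

    summary = {
        "schema": "cardiopop/summary-v1",
        "seed": cfg.seed,
        "single_model": rows,
        "population": None,
    }
    if cfg.population is not None:
        pspec = pop.PopulationSpec(
            n_models=int(cfg.population["n_models"]),
            sigma=float(cfg.population.get("sigma", 0.2)),
            mean=float(cfg.population.get("mean", 1.0)),
            seed=int(cfg.population.get("seed", cfg.seed)),
        )
        variants = pop.sample_population(pspec)
        ranges = pop.load_calibration_ranges(cfg.calibration_ranges)
        summ, table, baseline = pop.run_population(
            base, variants, conds, proto, iso_set=iso_set, ranges=ranges,
            seed=pspec.seed,
        )
        table.to_csv(out / "population.csv", index=False)
        baseline.to_csv(out / "population_baseline.csv", index=False)
        summary["population"] = summ.as_dict()

    _write_json(out / "summary.json", summary)
    _write_json(out / "manifest.json", {
        "schema": "cardiopop/manifest-v1",
        "package_version": __version__,
        "config_file": config_path.name,
        "config_sha256": _hash_file(config_path),
        "seed": cfg.seed,
        "solver": asdict(proto.solver),
        "protocol": {"n_prepace": proto.n_prepace, "n_record": proto.n_record,
                     "steady_state_tol_ms": proto.steady_state_tol_ms,
                     "min_prepace": proto.min_prepace},
    })
    return out


def _load_expected(path=None) -> dict:
    from importlib import resources

    if path is None:
        with resources.files("cardiopop").joinpath("data", "expected_values.json").open() as fh:
            return json.load(fh)["values"]
    with open(path) as fh:
        return json.load(fh)["values"]


_GROUP_ORDER = ("control", "CQ", "AZM", "CQ+AZM")


def summarize_results(result_dir, expected_path=None) -> str:
    """Human-readable report for a result bundle: per-condition biomarkers
    (grouped control, CQ, AZM, combined) plus derived drug-effect metrics
    compared against the packaged expected values with pass/fail."""
    result_dir = Path(result_dir)
    spath = result_dir / "summary.json"
    if not spath.exists():
        raise FileNotFoundError(f"no summary.json in {result_dir}")
    with open(spath) as fh:
        summary = json.load(fh)
    rows = summary.get("single_model", [])
    if not rows:
        raise ValueError(f"{spath}: empty result bundle")

    def group(label):
        name = label.split()[0]
        return _GROUP_ORDER.index(name) if name in _GROUP_ORDER else len(_GROUP_ORDER)

    rows = sorted(rows, key=lambda r: (group(r["condition"]), r["frequency_hz"]))
    lines = ["condition                     APD90(ms)  RMP(mV)  EAD  RF  alternans"]
    apd = {}
    for r in rows:
        apd[r["condition"]] = r["apd90_ms"]
        lines.append(
            f"{r['condition']:28s} {r['apd90_ms']:9.1f} {r['rmp_mV']:8.2f}"
            f"  {'Y' if r['ead'] else '.'}    {'Y' if r['rf'] else '.'}   {'Y' if r['alternans'] else '.'}"
        )

    derived = {}
    if "control 1Hz" in apd:
        a0 = apd["control 1Hz"]
        if "CQ 1Hz" in apd:
            derived["cq_apd_prolongation_pct"] = 100.0 * (apd["CQ 1Hz"] - a0) / a0
        if "AZM 1Hz" in apd:
            derived["azm_apd_prolongation_pct"] = 100.0 * (apd["AZM 1Hz"] - a0) / a0
        if "CQ+AZM 1Hz" in apd:
            derived["combined_apd_prolongation_ms"] = apd["CQ+AZM 1Hz"] - a0
        if "control 2Hz ISO1" in apd:
            derived["control_iso_reduction_pct"] = 100.0 * (a0 - apd["control 2Hz ISO1"]) / a0
    if "CQ+AZM 1Hz" in apd and "CQ+AZM 2Hz" in apd:
        derived["combined_rate_reduction_pct"] = (
            100.0 * (apd["CQ+AZM 1Hz"] - apd["CQ+AZM 2Hz"]) / apd["CQ+AZM 1Hz"]
        )
    if derived:
        expected = _load_expected(expected_path)
        lines.append("")
        lines.append("derived metric                     value  expected  status")
        for key, val in derived.items():
            if key in expected:
                ref, rtol = expected[key]["value"], expected[key]["rtol"]
                ok = abs(val - ref) <= rtol * abs(ref)
                status = "pass" if ok else "FAIL"
                lines.append(f"{key:32s} {val:8.1f} {ref:9.1f}  {status}")
            else:
                lines.append(f"{key:32s} {val:8.1f}       n/a  -")
    if summary.get("population"):
        p = summary["population"]
        lines.append("")
        lines.append(f"population: n={p['n_models']} included={p['n_included']} "
                     f"excluded={p['n_excluded']} failed={p['n_failed']} seed={p['seed']}")
        for k, v in p["conditions"].items():
            lines.append(
                f"  {k:28s} median dAPD90 {v['median_d_apd90_ms']:7.1f} ms "
                f"IQR [{v['iqr_d_apd90_ms'][0]:.1f}, {v['iqr_d_apd90_ms'][1]:.1f}] "
                f"EAD/RF {v['ead_rf_incidence_pct']:.1f}%"
            )
    return "\n".join(lines)
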