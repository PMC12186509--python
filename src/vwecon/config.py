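"""Run configuration: YAML loading with strict key checking.

A config file carries the cost parameters, per-payer rate schedules, named
payer mixes, sensitivity grids, and the seed.  Every key is optional; the
defaults reproduce the base-case study conditions.  Unknown keys are
rejected so typos fail loudly instead of silently running the base case.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import yaml

from .accounting import CostParameters, PayerClass
from .revenue import MedicareRateSchedule, PerDiemRate, RateSchedules
from .scenarios import VARIABLE_COST_GRID, PayerMix
from .payer import TOTAL_COST_GRID
from . import study

__all__ = ["RunConfig", "load_config", "default_config"]


@dataclass(frozen=True)
class RunConfig:
    costs: CostParameters = field(default_factory=CostParameters)
    rate_schedules: RateSchedules = field(default_factory=dict)
    mixes: dict[str, PayerMix] = field(
        default_factory=lambda: {
            name: PayerMix(m) for name, m in study.NAMED_MIXES.items()
        }
    )
    variable_cost_grid: tuple[float, ...] = VARIABLE_COST_GRID
    total_cost_grid: tuple[float, ...] = TOTAL_COST_GRID
    n_scenario_patients: int = 1000
    seed: int = 0

    def digest(self) -> str:
        """Stable hash of the configuration, for run manifests."""
        payload = {
            "costs": [self.costs.daily_variable_cost, self.costs.staffing_cost,
                      self.costs.dme_total],
            "rates": {
                p.value: sorted(vars(s).items())
                for p, s in sorted(self.rate_schedules.items(), key=lambda kv: kv[0].value)
            },
            "mixes": {
                name: {p.value: f for p, f in mix.fractions.items()}
                for name, mix in sorted(self.mixes.items())
            },
            "variable_cost_grid": list(self.variable_cost_grid),
            "total_cost_grid": list(self.total_cost_grid),
            "n_scenario_patients": self.n_scenario_patients,
            "seed": self.seed,
        }
        blob = json.dumps(payload, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()


def default_config() -> RunConfig:
    return RunConfig()


_TOP_KEYS = {
    "costs", "rates", "mixes", "variable_cost_grid", "total_cost_grid",
    "n_scenario_patients", "seed",
}
_COST_KEYS = {"daily_variable", "staffing", "dme"}


def _check_keys(mapping: Mapping[str, Any], allowed: set[str], where: str) -> None:
    unknown = set(mapping) - allowed
    if unknown:
        raise ValueError(f"unknown config key(s) in {where}: {sorted(unknown)}")


def _parse_costs(block: Mapping[str, Any]) -> CostParameters:
    _check_keys(block, _COST_KEYS, "costs")
    return CostParameters(
        daily_variable_cost=float(block.get("daily_variable", 2945)),
        staffing_cost=float(block.get("staffing", 518_000)),
        dme_total=float(block.get("dme", 164_547)),
    )


def _parse_rates(block: Mapping[str, Any]) -> dict[PayerClass, MedicareRateSchedule | PerDiemRate]:
    out: dict[PayerClass, MedicareRateSchedule | PerDiemRate] = {}
    for key, val in block.items():
        payer = PayerClass(key)
        if payer is PayerClass.MEDICARE:
            _check_keys(val, {"base_payment_rate", "drg_relative_weight",
                              "dsh_addon", "per_diem"}, f"rates.{key}")
            out[payer] = MedicareRateSchedule(**{k: float(v) for k, v in val.items()})
        else:
            if isinstance(val, Mapping):
                _check_keys(val, {"rate"}, f"rates.{key}")
                out[payer] = PerDiemRate(float(val["rate"]))
            else:
                out[payer] = PerDiemRate(float(val))
    return out


def _parse_mixes(block: Mapping[str, Any]) -> dict[str, PayerMix]:
    return {
        name: PayerMix({PayerClass(p): float(f) for p, f in fracs.items()})
        for name, fracs in block.items()
    }


def load_config(path: str | Path) -> RunConfig:
    """Load a YAML run configuration, falling back to base-case defaults."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, Mapping):
        raise ValueError("config root must be a mapping")
    _check_keys(raw, _TOP_KEYS, "config")
    base = default_config()
    return RunConfig(
        costs=_parse_costs(raw["costs"]) if "costs" in raw else base.costs,
        rate_schedules=_parse_rates(raw.get("rates", {})) or base.rate_schedules,
        mixes=_parse_mixes(raw["mixes"]) if "mixes" in raw else base.mixes,
        variable_cost_grid=tuple(raw.get("variable_cost_grid", VARIABLE_COST_GRID)),
        total_cost_grid=tuple(raw.get("total_cost_grid", TOTAL_COST_GRID)),
        n_scenario_patients=int(raw.get("n_scenario_patients", 1000)),
        seed=int(raw.get("seed", 0)),
    )
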