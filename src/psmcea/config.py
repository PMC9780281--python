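"""Analysis configuration: schema-validated YAML in, model objects out.

A configuration bundles everything one population's analysis needs: the
per-arm OS/PFS distribution specs, the cost and utility tables, the
grade 3-4 adverse-event profile, the cohort-model settings and the
sensitivity-analysis settings. Three baseline configurations ship with the
package (``ITT``, ``ESCC``, ``CPS10``), pre-filled with the published
second-line esophageal-carcinoma inputs.

Adverse-event management costs are shared across arms by event name (the
cost of managing anemia does not depend on which drug caused it); risks are
per arm. Sensitivity analyses address every tunable quantity through flat
dotted names (``cost.pembrolizumab``, ``utility.pd``,
``ae_risk.chemotherapy.anemia``, ``ae_cost.anemia``, ...).
"""

from __future__ import annotations

import copy
from dataclasses import dataclass
from importlib import resources
from typing import Iterator, Mapping

import yaml

from .cohort import (
    AdverseEvent,
    ModelSettings,
    PartitionedSurvivalCEA,
    StrategyInputs,
    UtilityInputs,
)
from .distributions import SurvivalDistribution

ARMS = ("pembrolizumab", "chemotherapy")
CHEMO_DRUGS = ("paclitaxel", "docetaxel", "irinotecan")
BASELINE_POPULATIONS = ("ITT", "ESCC", "CPS10")

_COST_KEYS = (
    "pembrolizumab",
    "paclitaxel",
    "docetaxel",
    "irinotecan",
    "administration",
    "laboratory",
    "follow_up",
    "best_supportive_care",
)

_SETTINGS_KEYS = {
    "cycle_length_days": float,
    "horizon_years": float,
    "annual_discount": float,
    "wtp": float,
    "half_cycle_correction": bool,
    "days_per_month": float,
}

_SENSITIVITY_DEFAULTS = {
    "range_fraction": 0.2,
    "n_iterations": 10_000,
    "seed": 2022,
    "psa_interval_z": 1.96,
    "wtp_grid": {"start": 0.0, "stop": 300_000.0, "step": 5_000.0},
}


class ConfigError(ValueError):
    """A configuration failed schema validation; the message names the field."""


def _require_mapping(node, where: str) -> dict:
    if not isinstance(node, Mapping):
        raise ConfigError(f"{where}: expected a mapping")
    return dict(node)


def _reject_unknown(node: Mapping, allowed, where: str) -> None:
    unknown = set(node) - set(allowed)
    if unknown:
        raise ConfigError(f"{where}: unknown key(s) {sorted(unknown)}")


def _number(node: Mapping, key: str, where: str, lo=None, hi=None) -> float:
    if key not in node:
        raise ConfigError(f"{where}.{key}: missing required field")
    value = node[key]
    if isinstance(value, bool) or not isinstance(value, (int, float)):
        raise ConfigError(f"{where}.{key}: expected a number, got {value!r}")
    value = float(value)
    if lo is not None and value < lo:
        raise ConfigError(f"{where}.{key}: must be >= {lo}, got {value}")
    if hi is not None and value > hi:
        raise ConfigError(f"{where}.{key}: must be <= {hi}, got {value}")
    return value


@dataclass(frozen=True)
class AnalysisConfig:
    """Validated analysis configuration for one population."""

    data: dict

    # -- construction ------------------------------------------------------

    @classmethod
    def from_dict(cls, raw: Mapping) -> "AnalysisConfig":
        data = _validate(copy.deepcopy(dict(raw)))
        return cls(data=data)

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if raw is None:
            raise ConfigError(f"{path}: empty configuration")
        return cls.from_dict(raw)

    def to_dict(self) -> dict:
        return copy.deepcopy(self.data)

    def to_yaml(self, path=None) -> str:
        text = yaml.safe_dump(self.data, sort_keys=True, default_flow_style=False)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    # -- typed accessors ---------------------------------------------------

    @property
    def population(self) -> str:
        return self.data["population"]

    @property
    def settings(self) -> ModelSettings:
        return ModelSettings(**self.data["settings"])

    @property
    def utilities(self) -> UtilityInputs:
        u = self.data["utilities"]
        return UtilityInputs(pfs=u["pfs"], pd=u["pd"], death=u["death"])

    @property
    def chemo_drug_cost(self) -> float:
        """Per-cycle chemotherapy drug cost: mean of the three single
        agents (clinician's choice is modelled as an even mix)."""
        costs = self.data["costs"]
        return sum(costs[d] for d in CHEMO_DRUGS) / len(CHEMO_DRUGS)

    def distribution(self, arm: str, endpoint: str) -> SurvivalDistribution:
        return SurvivalDistribution.from_dict(self.data["survival"][arm][endpoint.lower()])

    def ae_profile(self, arm: str) -> tuple[AdverseEvent, ...]:
        ae = self.data["adverse_events"]
        return tuple(
            AdverseEvent(name=name, incidence=risk, cost=ae["costs"][name])
            for name, risk in ae["risks"][arm].items()
        )

    def strategy_inputs(self, arm: str) -> StrategyInputs:
        if arm not in ARMS:
            raise ConfigError(f"unknown arm {arm!r}")
        costs = self.data["costs"]
        drug = costs["pembrolizumab"] if arm == "pembrolizumab" else self.chemo_drug_cost
        return StrategyInputs(
            name=arm,
            os=self.distribution(arm, "os"),
            pfs=self.distribution(arm, "pfs"),
            drug_cost_per_cycle=drug,
            admin_cost=costs["administration"],
            lab_cost=costs["laboratory"],
            followup_cost=costs["follow_up"],
            bsc_cost=costs["best_supportive_care"],
            third_line_drug_cost_per_cycle=self.chemo_drug_cost,
            ae_profile=self.ae_profile(arm),
        )

    def model(self) -> PartitionedSurvivalCEA:
        return PartitionedSurvivalCEA(
            intervention=self.strategy_inputs("pembrolizumab"),
            comparator=self.strategy_inputs("chemotherapy"),
            utilities=self.utilities,
            settings=self.settings,
        )

    @property
    def sensitivity(self) -> dict:
        return copy.deepcopy(self.data["sensitivity"])

    # -- flat parameter space ---------------------------------------------

    def parameter_names(self) -> list[str]:
        """Every tunable scalar, as dotted names, in a stable order."""
        names = [f"cost.{k}" for k in _COST_KEYS]
        names += ["utility.pfs", "utility.pd"]
        ae = self.data["adverse_events"]
        for arm in ARMS:
            names += [f"ae_risk.{arm}.{n}" for n in ae["risks"][arm]]
        names += [f"ae_cost.{n}" for n in ae["costs"]]
        return names

    def _resolve(self, name: str, data: dict):
        parts = name.split(".")
        try:
            if parts[0] == "cost" and len(parts) == 2:
                return data["costs"], parts[1]
            if parts[0] == "utility" and len(parts) == 2:
                return data["utilities"], parts[1]
            if parts[0] == "ae_cost" and len(parts) == 2:
                return data["adverse_events"]["costs"], parts[1]
            if parts[0] == "ae_risk" and len(parts) == 3:
                return data["adverse_events"]["risks"][parts[1]], parts[2]
        except KeyError:
            pass
        raise ConfigError(f"unknown parameter name {name!r}")

    def get_value(self, name: str) -> float:
        container, key = self._resolve(name, self.data)
        if key not in container:
            raise ConfigError(f"unknown parameter name {name!r}")
        return float(container[key])

    def with_values(self, values: Mapping[str, float]) -> "AnalysisConfig":
        """New config with the named scalars replaced (re-validated)."""
        data = copy.deepcopy(self.data)
        for name, value in values.items():
            container, key = self._resolve(name, data)
            if key not in container:
                raise ConfigError(f"unknown parameter name {name!r}")
            container[key] = float(value)
        return AnalysisConfig.from_dict(data)


def _validate(raw: dict) -> dict:
    raw = _require_mapping(raw, "config")
    _reject_unknown(
        raw,
        ("population", "settings", "survival", "costs", "utilities", "adverse_events", "sensitivity"),
        "config",
    )
    out: dict = {}

    if "population" not in raw or not isinstance(raw["population"], str):
        raise ConfigError("population: missing or not a string")
    out["population"] = raw["population"]

    # settings (all optional, defaulted from ModelSettings)
    defaults = ModelSettings()
    settings_in = _require_mapping(raw.get("settings", {}), "settings")
    _reject_unknown(settings_in, _SETTINGS_KEYS, "settings")
    settings = {}
    for key, typ in _SETTINGS_KEYS.items():
        if key in settings_in:
            value = settings_in[key]
            if typ is bool:
                if not isinstance(value, bool):
                    raise ConfigError(f"settings.{key}: expected a boolean")
            else:
                value = _number(settings_in, key, "settings")
            settings[key] = value
        else:
            settings[key] = getattr(defaults, key)
    try:
        ModelSettings(**settings)
    except ValueError as exc:
        raise ConfigError(f"settings: {exc}") from exc
    out["settings"] = settings

    # survival
    surv_in = _require_mapping(raw.get("survival"), "survival")
    _reject_unknown(surv_in, ARMS, "survival")
    out["survival"] = {}
    for arm in ARMS:
        if arm not in surv_in:
            raise ConfigError(f"survival.{arm}: missing required section")
        arm_in = _require_mapping(surv_in[arm], f"survival.{arm}")
        _reject_unknown(arm_in, ("os", "pfs"), f"survival.{arm}")
        out["survival"][arm] = {}
        for ep in ("os", "pfs"):
            if ep not in arm_in:
                raise ConfigError(f"survival.{arm}.{ep}: missing required section")
            try:
                spec = SurvivalDistribution.from_dict(arm_in[ep])
            except ValueError as exc:
                raise ConfigError(f"survival.{arm}.{ep}: {exc}") from exc
            out["survival"][arm][ep] = spec.to_dict()

    # costs
    costs_in = _require_mapping(raw.get("costs"), "costs")
    _reject_unknown(costs_in, _COST_KEYS, "costs")
    out["costs"] = {k: _number(costs_in, k, "costs", lo=0.0) for k in _COST_KEYS}

    # utilities
    util_in = _require_mapping(raw.get("utilities"), "utilities")
    _reject_unknown(util_in, ("pfs", "pd", "death"), "utilities")
    utilities = {
        "pfs": _number(util_in, "pfs", "utilities", lo=0.0, hi=1.0),
        "pd": _number(util_in, "pd", "utilities", lo=0.0, hi=1.0),
        "death": _number({"death": util_in.get("death", 0.0)}, "death", "utilities", lo=0.0, hi=1.0),
    }
    try:
        UtilityInputs(**utilities)
    except ValueError as exc:
        raise ConfigError(f"utilities: {exc}") from exc
    out["utilities"] = utilities

    # adverse events
    ae_in = _require_mapping(raw.get("adverse_events"), "adverse_events")
    _reject_unknown(ae_in, ("costs", "risks"), "adverse_events")
    ae_costs_in = _require_mapping(ae_in.get("costs"), "adverse_events.costs")
    ae_costs = {
        name: _number(ae_costs_in, name, "adverse_events.costs", lo=0.0)
        for name in ae_costs_in
    }
    risks_in = _require_mapping(ae_in.get("risks"), "adverse_events.risks")
    _reject_unknown(risks_in, ARMS, "adverse_events.risks")
    ae_risks: dict = {}
    for arm in ARMS:
        arm_risks = _require_mapping(risks_in.get(arm, {}), f"adverse_events.risks.{arm}")
        ae_risks[arm] = {}
        for name in arm_risks:
            if name not in ae_costs:
                raise ConfigError(
                    f"adverse_events.risks.{arm}.{name}: no matching entry in adverse_events.costs"
                )
            ae_risks[arm][name] = _number(
                arm_risks, name, f"adverse_events.risks.{arm}", lo=0.0, hi=1.0
            )
    out["adverse_events"] = {"costs": ae_costs, "risks": ae_risks}

    # sensitivity settings
    sens_in = _require_mapping(raw.get("sensitivity", {}), "sensitivity")
    _reject_unknown(sens_in, _SENSITIVITY_DEFAULTS, "sensitivity")
    sens = copy.deepcopy(_SENSITIVITY_DEFAULTS)
    for key in ("range_fraction", "psa_interval_z"):
        if key in sens_in:
            sens[key] = _number(sens_in, key, "sensitivity", lo=0.0)
    for key in ("n_iterations", "seed"):
        if key in sens_in:
            value = sens_in[key]
            if isinstance(value, bool) or not isinstance(value, int):
                raise ConfigError(f"sensitivity.{key}: expected an integer")
            if key == "n_iterations" and value < 1:
                raise ConfigError("sensitivity.n_iterations: must be >= 1")
            sens[key] = value
    if "wtp_grid" in sens_in:
        grid_in = _require_mapping(sens_in["wtp_grid"], "sensitivity.wtp_grid")
        _reject_unknown(grid_in, ("start", "stop", "step"), "sensitivity.wtp_grid")
        grid = dict(sens["wtp_grid"])
        for key in ("start", "stop", "step"):
            if key in grid_in:
                grid[key] = _number(grid_in, key, "sensitivity.wtp_grid", lo=0.0)
        if grid["step"] <= 0 or grid["stop"] <= grid["start"]:
            raise ConfigError("sensitivity.wtp_grid: need step > 0 and stop > start")
        sens["wtp_grid"] = grid
    out["sensitivity"] = sens
    return out


def baseline_config_names() -> tuple[str, ...]:
    return BASELINE_POPULATIONS


def load_baseline(population: str) -> AnalysisConfig:
    """Load a packaged baseline configuration (``ITT``, ``ESCC``, ``CPS10``)."""
    key = population.upper().replace("≥", "").replace(" ", "")
    if key in ("CPS10", "CPS>=10"):
        key = "CPS10"
    if key not in BASELINE_POPULATIONS:
        raise ConfigError(
            f"unknown baseline population {population!r}; choose from {BASELINE_POPULATIONS}"
        )
    ref = resources.files("psmcea.configs").joinpath(f"{key.lower()}.yaml")
    with resources.as_file(ref) as path:
        return AnalysisConfig.from_yaml(path)


def load_config(path) -> AnalysisConfig:
    """Load and validate a configuration from a YAML file path."""
    return AnalysisConfig.from_yaml(path)


def iter_baselines() -> Iterator[tuple[str, AnalysisConfig]]:
    for name in BASELINE_POPULATIONS:
        yield name, load_baseline(name)


def run_population(config: AnalysisConfig):
    """End-to-end deterministic run for one population; returns
    :class:`~psmcea.cohort.CEAResults`."""
    return config.model().run()
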