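"""Deterministic (tornado) and probabilistic sensitivity analysis.

One-way analysis reruns the full deterministic model with each parameter
pushed to its low and high bound (default +/-20% of baseline) while all
others stay at base, and ranks parameters by the spread of the resulting
ICER per QALY.

The probabilistic analysis redraws every cost, utility and adverse-event
risk jointly each iteration — beta distributions for quantities bounded in
[0, 1], gamma for costs — with method-of-moments hyperparameters that treat
the one-way range as a 95% interval (sd = (high - low) / (2 * 1.96) by
default). Survival-curve parameters stay at their point estimates, so the
state occupancies are fixed across draws and each iteration revalues the
precomputed discounted occupancy streams. Cost-effectiveness acceptability
curves report, per willingness-to-pay value, the fraction of iterations
with positive incremental net monetary benefit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort import CEAResult, StrategyTotals, accrue, build_trace, compare
from .config import ARMS, CHEMO_DRUGS, AnalysisConfig, ConfigError


@dataclass(frozen=True)
class ParamDef:
    """One sensitivity-analysis parameter.

    ``psa_family`` is ``beta`` (bounded quantities), ``gamma`` (costs) or
    ``fixed`` (excluded from probabilistic draws).
    """

    name: str
    base: float
    low: float = None
    high: float = None
    psa_family: str = "fixed"

    def __post_init__(self) -> None:
        if self.low is None:
            object.__setattr__(self, "low", 0.8 * self.base)
        if self.high is None:
            object.__setattr__(self, "high", 1.2 * self.base)
        if not self.low <= self.base <= self.high:
            raise ValueError(f"{self.name}: require low <= base <= high")
        if self.psa_family not in ("beta", "gamma", "fixed"):
            raise ValueError(f"{self.name}: unknown psa_family {self.psa_family!r}")
        if self.psa_family == "beta" and not 0.0 < self.base < 1.0:
            raise ValueError(f"{self.name}: beta requires base in (0, 1)")


def default_param_defs(config: AnalysisConfig) -> list[ParamDef]:
    """Every tunable scalar of a configuration as a :class:`ParamDef`:
    gamma for dollar amounts, beta for utilities and AE risks."""
    frac = config.sensitivity["range_fraction"]
    defs = []
    for name in config.parameter_names():
        base = config.get_value(name)
        family = "gamma" if name.startswith(("cost.", "ae_cost.")) else "beta"
        if base <= 0.0 or (family == "beta" and base >= 1.0):
            family = "fixed"
        defs.append(
            ParamDef(
                name=name,
                base=base,
                low=(1.0 - frac) * base,
                high=(1.0 + frac) * base,
                psa_family=family,
            )
        )
    return defs


# -- probabilistic samplers --------------------------------------------------


def make_psa_dist(p: ParamDef, interval_z: float = 1.96):
    """Sampler ``f(rng, size) -> draws`` for one parameter.

    Hyperparameters by method of moments with mean = base and
    sd = (high - low) / (2 * interval_z): beta with
    ``alpha = m (m(1-m)/v - 1)``, ``beta = alpha (1-m)/m``; gamma with
    ``shape = m^2/v``, ``rate = m/v``.
    """
    if p.psa_family == "fixed":
        return lambda rng, size=None: (
            p.base if size is None else np.full(size, p.base)
        )
    sd = (p.high - p.low) / (2.0 * interval_z)
    if sd <= 0:
        return lambda rng, size=None: (
            p.base if size is None else np.full(size, p.base)
        )
    v = sd * sd
    m = p.base
    if p.psa_family == "beta":
        if v >= m * (1.0 - m):
            raise ValueError(
                f"{p.name}: variance {v:.3g} too large for a beta with mean {m:.3g}"
            )
        alpha = m * (m * (1.0 - m) / v - 1.0)
        beta = alpha * (1.0 - m) / m
        return lambda rng, size=None: rng.beta(alpha, beta, size=size)
    shape = m * m / v
    scale = v / m  # 1 / rate
    return lambda rng, size=None: rng.gamma(shape, scale, size=size)


# -- deterministic model under perturbed parameters --------------------------


def _run_with_values(config: AnalysisConfig, values: dict[str, float]) -> CEAResult:
    cfg = config.with_values(values) if values else config
    return cfg.model().run().result


@dataclass(frozen=True)
class TornadoEntry:
    name: str
    base: float
    low: float
    high: float
    icer_at_low: float
    icer_at_high: float

    @property
    def spread(self) -> float:
        return abs(self.icer_at_high - self.icer_at_low)


def one_way_sa(
    config: AnalysisConfig, param_defs: list[ParamDef] | None = None
) -> list[TornadoEntry]:
    """Tornado analysis: entries sorted by descending ICER-per-QALY spread."""
    param_defs = param_defs if param_defs is not None else default_param_defs(config)
    entries = []
    for p in param_defs:
        icer_lo = _run_with_values(config, {p.name: p.low}).icer_per_qaly
        icer_hi = _run_with_values(config, {p.name: p.high}).icer_per_qaly
        entries.append(
            TornadoEntry(
                name=p.name,
                base=p.base,
                low=p.low,
                high=p.high,
                icer_at_low=icer_lo,
                icer_at_high=icer_hi,
            )
        )
    return sorted(entries, key=lambda e: e.spread, reverse=True)


def tornado_frame(entries: list[TornadoEntry]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "parameter": e.name,
                "base": e.base,
                "low": e.low,
                "high": e.high,
                "icer_at_low": e.icer_at_low,
                "icer_at_high": e.icer_at_high,
                "spread": e.spread,
            }
            for e in entries
        ]
    )


# -- probabilistic sensitivity analysis --------------------------------------


@dataclass
class PSAResult:
    """Monte-Carlo draws of the incremental comparison.

    ``delta_cost`` / ``delta_qaly`` are per-iteration increments of the
    intervention over the comparator; ``seed`` reproduces the run.
    """

    delta_cost: np.ndarray
    delta_ly: np.ndarray
    delta_qaly: np.ndarray
    seed: int
    wtp: float
    base_result: CEAResult

    @property
    def iterations(self) -> int:
        return int(self.delta_cost.size)

    def prob_cost_effective(self, wtp: float | None = None) -> float:
        """Fraction of iterations with positive incremental net monetary
        benefit ``wtp * dQALY - dCost`` at the given threshold."""
        wtp = self.wtp if wtp is None else wtp
        nmb = wtp * self.delta_qaly - self.delta_cost
        return float(np.mean(nmb > 0.0))

    def ceac(self, wtp_grid) -> pd.DataFrame:
        grid = np.asarray(wtp_grid, dtype=float)
        probs = [self.prob_cost_effective(w) for w in grid]
        return pd.DataFrame({"wtp": grid, "prob_cost_effective": probs})

    def draws_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "iteration": np.arange(self.iterations),
                "delta_cost": self.delta_cost,
                "delta_ly": self.delta_ly,
                "delta_qaly": self.delta_qaly,
            }
        )


@dataclass
class _ArmStreams:
    """Discounted occupancy streams that are invariant across PSA draws."""

    pfs_time: float  # sum over cycles of disc * pfs occupancy (cycle units)
    pd_time: float
    ly: float  # discounted life-years (utility-free)
    ae_risks: dict[str, float] = field(default_factory=dict)

    @classmethod
    def from_config(cls, config: AnalysisConfig, arm: str) -> "_ArmStreams":
        settings = config.settings
        strat = config.strategy_inputs(arm)
        trace = build_trace(strat, settings)
        # accrual occupancies (honours half-cycle correction) via accrue's
        # helper path: rebuild them directly to avoid cost coupling
        from .cohort import _accrual_occupancy

        pfs, pd_ = _accrual_occupancy(trace, strat)
        c = trace.frame["cycle"].to_numpy()
        disc = (1.0 + settings.annual_discount) ** (-c * settings.cycle_years)
        return cls(
            pfs_time=float((pfs * disc).sum()),
            pd_time=float((pd_ * disc).sum()),
            ly=float(((pfs + pd_) * settings.cycle_years * disc).sum()),
            ae_risks={ae.name: ae.incidence for ae in strat.ae_profile},
        )


def _totals_from_streams(
    arm: str,
    streams: _ArmStreams,
    values: dict[str, float],
    cycle_years: float,
) -> StrategyTotals:
    chemo_drug = sum(values[f"cost.{d}"] for d in CHEMO_DRUGS) / len(CHEMO_DRUGS)
    drug = values["cost.pembrolizumab"] if arm == "pembrolizumab" else chemo_drug
    admin = values["cost.administration"]
    pfs_cost = drug + admin + values["cost.laboratory"] + values["cost.follow_up"]
    pd_cost = values["cost.best_supportive_care"] + chemo_drug + admin
    ae_cost = sum(
        values[f"ae_risk.{arm}.{name}"] * values[f"ae_cost.{name}"]
        for name in streams.ae_risks
    )
    cost = streams.pfs_time * pfs_cost + streams.pd_time * pd_cost + ae_cost
    qaly = (
        streams.pfs_time * values["utility.pfs"] + streams.pd_time * values["utility.pd"]
    ) * cycle_years
    return StrategyTotals(name=arm, cost=float(cost), ly=streams.ly, qaly=float(qaly))


def run_psa(
    config: AnalysisConfig,
    param_defs: list[ParamDef] | None = None,
    n_iter: int | None = None,
    seed: int | None = None,
) -> PSAResult:
    """Monte-Carlo probabilistic sensitivity analysis.

    Each iteration draws every non-fixed parameter from its assigned
    distribution and recomputes both strategies' discounted totals; the
    result records the per-iteration increments. Reproducible under
    ``seed`` (default: the configuration's sensitivity seed).
    """
    sens = config.sensitivity
    param_defs = param_defs if param_defs is not None else default_param_defs(config)
    n_iter = int(n_iter if n_iter is not None else sens["n_iterations"])
    seed = int(seed if seed is not None else sens["seed"])
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    rng = np.random.default_rng(seed)
    interval_z = sens["psa_interval_z"]

    base_names = set(config.parameter_names())
    for p in param_defs:
        if p.name not in base_names:
            raise ConfigError(f"unknown parameter name {p.name!r}")

    settings = config.settings
    streams = {arm: _ArmStreams.from_config(config, arm) for arm in ARMS}
    base_result = config.model().run().result

    # draw matrix: parameters not listed stay at their configured base value
    values0 = {name: config.get_value(name) for name in base_names}
    draws = {name: np.full(n_iter, values0[name]) for name in values0}
    for p in param_defs:
        sampler = make_psa_dist(p, interval_z=interval_z)
        draws[p.name] = np.asarray(sampler(rng, size=n_iter), dtype=float)

    delta_cost = np.empty(n_iter)
    delta_ly = np.empty(n_iter)
    delta_qaly = np.empty(n_iter)
    for i in range(n_iter):
        values = {name: draws[name][i] for name in draws}
        totals = {
            arm: _totals_from_streams(arm, streams[arm], values, settings.cycle_years)
            for arm in ARMS
        }
        delta_cost[i] = totals["pembrolizumab"].cost - totals["chemotherapy"].cost
        delta_ly[i] = totals["pembrolizumab"].ly - totals["chemotherapy"].ly
        delta_qaly[i] = totals["pembrolizumab"].qaly - totals["chemotherapy"].qaly

    return PSAResult(
        delta_cost=delta_cost,
        delta_ly=delta_ly,
        delta_qaly=delta_qaly,
        seed=seed,
        wtp=settings.wtp,
        base_result=base_result,
    )


def ceac(psa: PSAResult, wtp_grid=None) -> pd.DataFrame:
    """Cost-effectiveness acceptability curve over a WTP grid."""
    if wtp_grid is None:
        wtp_grid = np.arange(0.0, 300_000.0 + 1, 5_000.0)
    return psa.ceac(wtp_grid)


def wtp_grid_from_config(config: AnalysisConfig) -> np.ndarray:
    grid = config.sensitivity["wtp_grid"]
    return np.arange(grid["start"], grid["stop"] + grid["step"] / 2, grid["step"])
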