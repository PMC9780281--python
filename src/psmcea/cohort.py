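"""Three-state partitioned-survival cohort model and incremental CEA.

State occupancy at model time t is read directly off the two fitted
survival curves of each strategy:

    alive progression-free   pfs(t)  = min(S_PFS(t), S_OS(t))
    progressed disease       pd(t)   = S_OS(t) - pfs(t)
    dead                     dead(t) = 1 - S_OS(t)

The cohort starts entirely progression-free. Costs (drug, administration,
laboratory, follow-up while progression-free; best supportive care,
third-line chemotherapy and administration after progression; grade 3-4
adverse-event management once at entry) and quality-adjusted life accrue
per cycle and are discounted continuously-in-cycles at an annual rate.

Incremental results (cost per life-year and per QALY) come out of
:class:`PartitionedSurvivalCEA`, whose ``run()`` returns a
:class:`CEAResults` carrying per-strategy totals, increments, ICERs and a
summary table.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .distributions import SurvivalDistribution

DAYS_PER_YEAR = 365.25


@dataclass(frozen=True)
class ModelSettings:
    """Global decision-model settings.

    Defaults: 3-week (21-day) cycles over a 10-year horizon, 3% annual
    discount on both costs and effects, willingness-to-pay $150,000/QALY.
    ``half_cycle_correction`` accrues each cycle at the average of its
    start- and end-of-cycle occupancies instead of the start occupancy.
    """

    cycle_length_days: float = 21.0
    horizon_years: float = 10.0
    annual_discount: float = 0.03
    wtp: float = 150_000.0
    half_cycle_correction: bool = False
    days_per_month: float = 30.4375

    def __post_init__(self) -> None:
        if not 0.0 <= self.annual_discount < 1.0:
            raise ValueError("annual_discount must lie in [0, 1)")
        if not self.horizon_years * DAYS_PER_YEAR > self.cycle_length_days > 0:
            raise ValueError("horizon must exceed one positive cycle")
        if self.wtp < 0:
            raise ValueError("wtp must be non-negative")

    @property
    def cycle_months(self) -> float:
        return self.cycle_length_days / self.days_per_month

    @property
    def cycle_years(self) -> float:
        return self.cycle_length_days / DAYS_PER_YEAR

    @property
    def n_cycles(self) -> int:
        return int(np.floor(self.horizon_years * DAYS_PER_YEAR / self.cycle_length_days))


@dataclass(frozen=True)
class AdverseEvent:
    """One grade 3-4 adverse event: incidence as a proportion and a
    one-off management cost in dollars."""

    name: str
    incidence: float
    cost: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.incidence <= 1.0:
            raise ValueError(f"AE {self.name}: incidence must lie in [0, 1]")
        if self.cost < 0:
            raise ValueError(f"AE {self.name}: cost must be non-negative")


@dataclass(frozen=True)
class StrategyInputs:
    """One treatment strategy: survival curves plus its cost profile.

    Per-cycle dollar amounts; the progression-free state accrues
    ``drug + administration + laboratory + follow-up`` and the progressed
    state ``best supportive care + third-line drug + administration``.
    """

    name: str
    os: SurvivalDistribution
    pfs: SurvivalDistribution
    drug_cost_per_cycle: float
    admin_cost: float = 69.81
    lab_cost: float = 87.6
    followup_cost: float = 51.5
    bsc_cost: float = 117.1
    third_line_drug_cost_per_cycle: float = 75.83333333333333
    ae_profile: tuple[AdverseEvent, ...] = ()

    def __post_init__(self) -> None:
        for fname in (
            "drug_cost_per_cycle",
            "admin_cost",
            "lab_cost",
            "followup_cost",
            "bsc_cost",
            "third_line_drug_cost_per_cycle",
        ):
            if getattr(self, fname) < 0:
                raise ValueError(f"{self.name}: {fname} must be non-negative")
        object.__setattr__(self, "ae_profile", tuple(self.ae_profile))

    @property
    def ae_cost_total(self) -> float:
        """Expected one-off adverse-event cost: sum of incidence x cost."""
        return float(sum(ae.incidence * ae.cost for ae in self.ae_profile))

    @property
    def pfs_cost_per_cycle(self) -> float:
        return (
            self.drug_cost_per_cycle + self.admin_cost + self.lab_cost + self.followup_cost
        )

    @property
    def pd_cost_per_cycle(self) -> float:
        return self.bsc_cost + self.third_line_drug_cost_per_cycle + self.admin_cost


@dataclass(frozen=True)
class UtilityInputs:
    """Health-state utilities (progression-free, progressed, dead)."""

    pfs: float = 0.741
    pd: float = 0.581
    death: float = 0.0

    def __post_init__(self) -> None:
        for fname in ("pfs", "pd", "death"):
            if not 0.0 <= getattr(self, fname) <= 1.0:
                raise ValueError(f"utility {fname} must lie in [0, 1]")
        if self.pfs < self.pd:
            raise ValueError("utility of PFS must be at least the utility of PD")


@dataclass
class CohortTrace:
    """Per-cycle state occupancy and (after accrual) discounted streams."""

    strategy: str
    settings: ModelSettings
    frame: pd.DataFrame  # cycle, time_months, pfs, pd, dead [+ accrual columns]

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index=False)


@dataclass(frozen=True)
class StrategyTotals:
    name: str
    cost: float
    ly: float
    qaly: float


@dataclass(frozen=True)
class CEAResult:
    """Incremental comparison of an intervention against a comparator."""

    intervention: StrategyTotals
    comparator: StrategyTotals
    wtp: float

    @property
    def delta_cost(self) -> float:
        return self.intervention.cost - self.comparator.cost

    @property
    def delta_ly(self) -> float:
        return self.intervention.ly - self.comparator.ly

    @property
    def delta_qaly(self) -> float:
        return self.intervention.qaly - self.comparator.qaly

    @property
    def icer_per_ly(self) -> float:
        return self.delta_cost / self.delta_ly if self.delta_ly > 0 else np.nan

    @property
    def icer_per_qaly(self) -> float:
        return self.delta_cost / self.delta_qaly if self.delta_qaly > 0 else np.nan

    @property
    def dominant(self) -> bool:
        """Intervention cheaper and more effective."""
        return self.delta_cost < 0 and self.delta_qaly > 0

    @property
    def dominated(self) -> bool:
        """Intervention costlier and less effective."""
        return self.delta_cost > 0 and self.delta_qaly < 0

    @property
    def cost_effective(self) -> bool:
        if self.dominant:
            return True
        if self.delta_qaly > 0:
            return self.icer_per_qaly < self.wtp
        return False

    def summary(self) -> pd.DataFrame:
        """Two-row table in the conventional CEA layout."""
        comp, intv = self.comparator, self.intervention
        rows = [
            {
                "strategy": comp.name,
                "overall_cost": comp.cost,
                "overall_ly": comp.ly,
                "overall_qaly": comp.qaly,
                "incremental_cost": np.nan,
                "incremental_ly": np.nan,
                "incremental_qaly": np.nan,
                "icer_per_ly": np.nan,
                "icer_per_qaly": np.nan,
            },
            {
                "strategy": intv.name,
                "overall_cost": intv.cost,
                "overall_ly": intv.ly,
                "overall_qaly": intv.qaly,
                "incremental_cost": self.delta_cost,
                "incremental_ly": self.delta_ly,
                "incremental_qaly": self.delta_qaly,
                "icer_per_ly": self.icer_per_ly,
                "icer_per_qaly": self.icer_per_qaly,
            },
        ]
        return pd.DataFrame(rows)

    def to_dict(self) -> dict:
        return {
            "intervention": asdict(self.intervention),
            "comparator": asdict(self.comparator),
            "delta_cost": self.delta_cost,
            "delta_ly": self.delta_ly,
            "delta_qaly": self.delta_qaly,
            "icer_per_ly": None if np.isnan(self.icer_per_ly) else self.icer_per_ly,
            "icer_per_qaly": None if np.isnan(self.icer_per_qaly) else self.icer_per_qaly,
            "wtp": self.wtp,
            "dominant": self.dominant,
            "dominated": self.dominated,
            "cost_effective": self.cost_effective,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)
            fh.write("\n")


def build_trace(strategy: StrategyInputs, settings: ModelSettings) -> CohortTrace:
    """Occupancy of the three states at the start of each cycle.

    Cycle ``c`` sits at model time ``t_c = c * cycle_months``; cycle 0 is
    the whole cohort progression-free. Where the fitted PFS curve exceeds
    the OS curve, PFS occupancy is clamped to OS (with a warning) so that
    occupancies stay within [0, 1] and conserve mass.
    """
    c = np.arange(settings.n_cycles)
    t = c * settings.cycle_months
    s_os = np.asarray(strategy.os.survival(t), dtype=float)
    s_pfs = np.asarray(strategy.pfs.survival(t), dtype=float)
    if np.any(s_pfs > s_os + 1e-12):
        warnings.warn(
            f"{strategy.name}: PFS survival exceeds OS at "
            f"{int((s_pfs > s_os + 1e-12).sum())} cycle(s); clamping to OS",
            RuntimeWarning,
            stacklevel=2,
        )
    pfs = np.minimum(s_pfs, s_os)
    frame = pd.DataFrame(
        {
            "cycle": c,
            "time_months": t,
            "pfs": pfs,
            "pd": s_os - pfs,
            "dead": 1.0 - s_os,
        }
    )
    return CohortTrace(strategy=strategy.name, settings=settings, frame=frame)


def _accrual_occupancy(trace: CohortTrace, strategy: StrategyInputs) -> tuple[np.ndarray, np.ndarray]:
    """Per-cycle (pfs, pd) occupancy used for accrual; with half-cycle
    correction, the mean of start- and end-of-cycle occupancies."""
    settings = trace.settings
    pfs = trace.frame["pfs"].to_numpy()
    pd_ = trace.frame["pd"].to_numpy()
    if settings.half_cycle_correction:
        t_end = (trace.frame["cycle"].to_numpy() + 1) * settings.cycle_months
        s_os_end = np.asarray(strategy.os.survival(t_end), dtype=float)
        pfs_end = np.minimum(np.asarray(strategy.pfs.survival(t_end), dtype=float), s_os_end)
        pfs = 0.5 * (pfs + pfs_end)
        pd_ = 0.5 * (pd_ + (s_os_end - pfs_end))
    return pfs, pd_


def accrue(
    trace: CohortTrace,
    strategy: StrategyInputs,
    utilities: UtilityInputs,
    settings: ModelSettings,
) -> StrategyTotals:
    """Discounted totals (cost, life-years, QALYs) for one strategy.

    Per cycle: cost = pfs*(drug+admin+lab+follow-up) + pd*(BSC+third-line
    +admin); life-years = (pfs+pd)*cycle_years; QALYs weight the states by
    their utilities. Streams are discounted by ``(1+r)^(-c*cycle_years)``;
    the expected adverse-event cost enters once, undiscounted, at cycle 0.
    The trace also gains ``disc_cost`` / ``disc_ly`` / ``disc_qaly`` columns.
    """
    if settings != trace.settings:
        raise ValueError("trace was built under different model settings")
    if strategy.name != trace.strategy:
        raise ValueError(f"trace belongs to {trace.strategy!r}, not {strategy.name!r}")
    pfs, pd_ = _accrual_occupancy(trace, strategy)
    c = trace.frame["cycle"].to_numpy()
    disc = (1.0 + settings.annual_discount) ** (-c * settings.cycle_years)
    cost = (pfs * strategy.pfs_cost_per_cycle + pd_ * strategy.pd_cost_per_cycle) * disc
    cost[0] += strategy.ae_cost_total
    ly = (pfs + pd_) * settings.cycle_years * disc
    qaly = (pfs * utilities.pfs + pd_ * utilities.pd) * settings.cycle_years * disc
    trace.frame["disc_cost"] = cost
    trace.frame["disc_ly"] = ly
    trace.frame["disc_qaly"] = qaly
    return StrategyTotals(
        name=strategy.name,
        cost=float(cost.sum()),
        ly=float(ly.sum()),
        qaly=float(qaly.sum()),
    )


def compare(
    intervention: StrategyTotals, comparator: StrategyTotals, settings: ModelSettings
) -> CEAResult:
    """Incremental statistics of ``intervention`` over ``comparator``."""
    return CEAResult(intervention=intervention, comparator=comparator, wtp=settings.wtp)


@dataclass
class CEAResults:
    """Results object for a full two-strategy partitioned-survival run."""

    result: CEAResult
    traces: dict[str, CohortTrace]
    settings: ModelSettings

    @property
    def icer_per_qaly(self) -> float:
        return self.result.icer_per_qaly

    @property
    def icer_per_ly(self) -> float:
        return self.result.icer_per_ly

    def summary(self) -> pd.DataFrame:
        return self.result.summary()


class PartitionedSurvivalCEA:
    """Two-strategy partitioned-survival cost-effectiveness model.

    Build from the intervention and comparator :class:`StrategyInputs`, a
    :class:`UtilityInputs` and :class:`ModelSettings`; ``run()`` traces both
    cohorts, accrues discounted streams and returns :class:`CEAResults`.
    """

    def __init__(
        self,
        intervention: StrategyInputs,
        comparator: StrategyInputs,
        utilities: UtilityInputs | None = None,
        settings: ModelSettings | None = None,
    ):
        self.intervention = intervention
        self.comparator = comparator
        self.utilities = utilities or UtilityInputs()
        self.settings = settings or ModelSettings()

    def run(self) -> CEAResults:
        traces = {}
        totals = {}
        for strat in (self.intervention, self.comparator):
            trace = build_trace(strat, self.settings)
            totals[strat.name] = accrue(trace, strat, self.utilities, self.settings)
            traces[strat.name] = trace
        result = compare(
            totals[self.intervention.name], totals[self.comparator.name], self.settings
        )
        return CEAResults(result=result, traces=traces, settings=self.settings)
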