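"""Synthetic individual patient data (IPD) and Kaplan-Meier estimation.

The cohort analysis takes its survival curves from published parametric
fits rather than from patient-level trial data. To make the fitting and
model-selection stage testable end to end, this module simulates the kind
of right-censored time-to-event data those fits presume: event times drawn
from a parametric family, censored by the earlier of an administrative
cut-off and exponential dropout.

Records travel as a pandas DataFrame with columns
``time, event, arm, endpoint, population`` (the CSV interchange format).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter

from .distributions import SurvivalDistribution

IPD_COLUMNS = ("time", "event", "arm", "endpoint", "population")

ARMS = ("pembrolizumab", "chemotherapy")
ENDPOINTS = ("OS", "PFS")
POPULATIONS = ("ITT", "ESCC", "CPS10")

#: Trial sample sizes per analysis population.
POPULATION_SIZES = {"ITT": 628, "ESCC": 401, "CPS10": 222}


@dataclass(frozen=True)
class CensoringModel:
    """Right-censoring process: administrative cut plus random dropout.

    ``admin_time`` is the follow-up cut-off in months (``inf`` disables it);
    ``dropout_rate`` is the exponential dropout hazard per month (0 disables).
    Defaults emulate roughly 30 months of trial follow-up with light dropout.
    """

    admin_time: float = 30.0
    dropout_rate: float = 0.005

    def __post_init__(self) -> None:
        if not self.admin_time > 0:
            raise ValueError("admin_time must be positive (use inf to disable)")
        if self.dropout_rate < 0:
            raise ValueError("dropout_rate must be non-negative")


def simulate_ipd(
    spec: SurvivalDistribution,
    n: int,
    censoring: CensoringModel | None = None,
    rng: np.random.Generator | int | None = None,
    arm: str = "pembrolizumab",
    endpoint: str = "OS",
    population: str = "ITT",
) -> pd.DataFrame:
    """Simulate ``n`` right-censored records from ``spec``.

    The observed time is ``min(event_time, censor_time)`` where the censor
    time is the minimum of the administrative cut and an exponential dropout
    draw; ``event`` is True when the event precedes censoring. Reproducible
    for a fixed integer seed or seeded Generator.
    """
    if n < 1:
        raise ValueError("n must be at least 1")
    censoring = censoring or CensoringModel()
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng

    event_time = spec.sample(n, rng=rng)
    censor_time = np.full(n, float(censoring.admin_time))
    if censoring.dropout_rate > 0:
        dropout = rng.exponential(1.0 / censoring.dropout_rate, size=n)
        censor_time = np.minimum(censor_time, dropout)
    observed = np.minimum(event_time, censor_time)
    event = event_time <= censor_time
    # guard against zero-time records (possible only for degenerate draws)
    observed = np.maximum(observed, np.finfo(float).tiny)
    return pd.DataFrame(
        {
            "time": observed,
            "event": event,
            "arm": arm,
            "endpoint": endpoint,
            "population": population,
        }
    )


@dataclass
class KMCurve:
    """A Kaplan-Meier product-limit curve.

    ``times`` are the ascending distinct event times; ``survival`` the
    step-function value just after each time; ``at_risk`` the risk-set size
    just before it.
    """

    times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray
    n_events: np.ndarray = field(default=None)

    def evaluate(self, t) -> np.ndarray | float:
        """Step-function lookup S(t) (right-continuous; S=1 before the
        first event time)."""
        t = np.asarray(t, dtype=float)
        idx = np.searchsorted(self.times, t, side="right")
        padded = np.concatenate(([1.0], self.survival))
        out = padded[idx]
        return out if out.ndim else float(out)


def km_estimate(records: pd.DataFrame) -> KMCurve:
    """Product-limit estimate from an IPD frame (``time`` and ``event``
    columns); with no censoring it equals the empirical survival function."""
    if len(records) == 0:
        raise ValueError("no records to estimate from")
    fitter = KaplanMeierFitter()
    fitter.fit(records["time"].to_numpy(), records["event"].to_numpy(dtype=bool))
    table = fitter.event_table.iloc[1:] if fitter.event_table.index[0] == 0 else fitter.event_table
    event_rows = table[table["observed"] > 0]
    times = event_rows.index.to_numpy(dtype=float)
    surv = fitter.survival_function_at_times(times).to_numpy(dtype=float)
    at_risk = event_rows["at_risk"].to_numpy(dtype=int)
    n_events = event_rows["observed"].to_numpy(dtype=int)
    return KMCurve(times=times, survival=surv, at_risk=at_risk, n_events=n_events)


def write_ipd(records: pd.DataFrame, path) -> None:
    records.loc[:, list(IPD_COLUMNS)].to_csv(path, index=False)


def read_ipd(path) -> pd.DataFrame:
    frame = pd.read_csv(path)
    missing = set(IPD_COLUMNS) - set(frame.columns)
    if missing:
        raise ValueError(f"IPD file missing columns: {sorted(missing)}")
    frame["event"] = frame["event"].astype(bool)
    if (frame["time"] <= 0).any():
        raise ValueError("IPD times must be positive")
    return frame
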