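"""Closed-form survival machinery for the six candidate parametric families.

Six time-to-event families are supported, in the parameterizations standard
in survival extrapolation work (those of R's ``flexsurv``), with time in
months:

==============  ==================  =======================================
family          parameters          survival function S(t)
==============  ==================  =======================================
exponential     rate                exp(-rate * t)
weibull         shape, scale        exp(-(t / scale) ** shape)
gamma           shape, rate         1 - P(shape, rate * t)   [regularized]
lognormal       meanlog, sdlog      1 - Phi((ln t - meanlog) / sdlog)
loglogistic     shape, scale        1 / (1 + (t / scale) ** shape)
gompertz        shape, rate         exp(-(rate/shape) * (exp(shape*t) - 1))
==============  ==================  =======================================

All scale/rate/shape/sdlog parameters must be strictly positive except
``meanlog`` (any real) and the Gompertz ``shape`` (any real; a negative
shape gives a defective distribution whose survival plateaus at
``exp(rate / shape)``, the usual cure-fraction behaviour of that family).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
from scipy import stats


FAMILIES: tuple[str, ...] = (
    "exponential",
    "weibull",
    "gamma",
    "lognormal",
    "loglogistic",
    "gompertz",
)

#: Parameter names, in canonical order, per family.
PARAM_NAMES: dict[str, tuple[str, ...]] = {
    "exponential": ("rate",),
    "weibull": ("shape", "scale"),
    "gamma": ("shape", "rate"),
    "lognormal": ("meanlog", "sdlog"),
    "loglogistic": ("shape", "scale"),
    "gompertz": ("shape", "rate"),
}

# Parameters that may take any real value; all others must be > 0.
_UNRESTRICTED: dict[str, frozenset[str]] = {
    "lognormal": frozenset({"meanlog"}),
    "gompertz": frozenset({"shape"}),
}

_GOMPERTZ_TINY_SHAPE = 1e-12


class DistributionError(ValueError):
    """Invalid family, parameters, or evaluation domain."""


def _scipy_frozen(family: str, p: Mapping[str, float]):
    if family == "exponential":
        return stats.expon(scale=1.0 / p["rate"])
    if family == "weibull":
        return stats.weibull_min(p["shape"], scale=p["scale"])
    if family == "gamma":
        return stats.gamma(p["shape"], scale=1.0 / p["rate"])
    if family == "lognormal":
        return stats.lognorm(p["sdlog"], scale=np.exp(p["meanlog"]))
    if family == "loglogistic":
        return stats.fisk(p["shape"], scale=p["scale"])
    return None  # gompertz handled by hand (scipy lacks the negative-shape case)


@dataclass(frozen=True)
class SurvivalDistribution:
    """A parametric time-to-event distribution, time measured in months.

    Parameters
    ----------
    family
        One of :data:`FAMILIES`.
    params
        Mapping from parameter name to value, with the names required by
        :data:`PARAM_NAMES` for the family.
    """

    family: str
    params: Mapping[str, float]

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise DistributionError(
                f"unknown family {self.family!r}; expected one of {FAMILIES}"
            )
        names = PARAM_NAMES[self.family]
        got = tuple(self.params)
        if set(got) != set(names):
            raise DistributionError(
                f"{self.family} requires parameters {names}, got {got}"
            )
        free = _UNRESTRICTED.get(self.family, frozenset())
        for name in names:
            value = float(self.params[name])
            if not np.isfinite(value):
                raise DistributionError(f"{self.family} {name} must be finite")
            if name not in free and value <= 0.0:
                raise DistributionError(
                    f"{self.family} {name} must be strictly positive, got {value}"
                )
        object.__setattr__(self, "params", {n: float(self.params[n]) for n in names})

    # -- internal helpers -------------------------------------------------

    def _check_t(self, t) -> np.ndarray:
        arr = np.asarray(t, dtype=float)
        if np.any(arr < 0):
            raise DistributionError("time must be non-negative")
        return arr

    @property
    def param_values(self) -> tuple[float, ...]:
        return tuple(self.params[n] for n in PARAM_NAMES[self.family])

    # -- core functions ---------------------------------------------------

    def cumulative_hazard(self, t) -> np.ndarray | float:
        """H(t) = -ln S(t), vectorized over ``t`` (months)."""
        t = self._check_t(t)
        p = self.params
        if self.family == "gompertz":
            a, b = p["shape"], p["rate"]
            if abs(a) < _GOMPERTZ_TINY_SHAPE:
                out = b * t  # shape -> 0 limit is exponential
            else:
                with np.errstate(over="ignore"):
                    out = (b / a) * np.expm1(a * t)
        else:
            frozen = _scipy_frozen(self.family, p)
            with np.errstate(divide="ignore"):
                out = -np.log(frozen.sf(t))
        return out if out.ndim else float(out)

    def survival(self, t) -> np.ndarray | float:
        """S(t), the probability of surviving beyond ``t`` months."""
        t = self._check_t(t)
        if self.family == "gompertz":
            out = np.exp(-self.cumulative_hazard(t))
            out = np.asarray(out, dtype=float)
        else:
            out = np.asarray(_scipy_frozen(self.family, self.params).sf(t))
        return out if out.ndim else float(out)

    def hazard(self, t) -> np.ndarray | float:
        """Instantaneous hazard h(t) = f(t) / S(t)."""
        t = self._check_t(t)
        if self.family == "gompertz":
            a, b = self.params["shape"], self.params["rate"]
            out = np.asarray(b * np.exp(a * t))
        else:
            frozen = _scipy_frozen(self.family, self.params)
            out = np.asarray(frozen.pdf(t) / frozen.sf(t))
        return out if out.ndim else float(out)

    def density(self, t) -> np.ndarray | float:
        """Probability density f(t); integrates to 1 over [0, inf) for
        non-defective members (Gompertz with negative shape is defective)."""
        t = self._check_t(t)
        if self.family == "gompertz":
            with np.errstate(over="ignore"):
                out = np.asarray(np.exp(self.log_density(t)))
        else:
            out = np.asarray(_scipy_frozen(self.family, self.params).pdf(t))
        return out if out.ndim else float(out)

    def log_density(self, t) -> np.ndarray | float:
        t = self._check_t(t)
        if self.family == "gompertz":
            a, b = self.params["shape"], self.params["rate"]
            out = np.asarray(np.log(b) + a * t - self.cumulative_hazard(t))
        else:
            out = np.asarray(_scipy_frozen(self.family, self.params).logpdf(t))
        return out if out.ndim else float(out)

    def log_survival(self, t) -> np.ndarray | float:
        out = np.asarray(-self.cumulative_hazard(t))
        return out if out.ndim else float(out)

    def quantile(self, p) -> np.ndarray | float:
        """Inverse CDF: the time t with 1 - S(t) = p, for p in (0, 1).

        For a defective Gompertz (negative shape) probabilities beyond the
        eventual-event fraction ``1 - exp(rate/shape)`` return ``inf``.
        """
        arr = np.asarray(p, dtype=float)
        if np.any((arr <= 0) | (arr >= 1)):
            raise DistributionError("quantile probability must lie in (0, 1)")
        if self.family == "gompertz":
            a, b = self.params["shape"], self.params["rate"]
            target = -np.log1p(-arr)  # H(t) = -ln(1 - p)
            if abs(a) < _GOMPERTZ_TINY_SHAPE:
                out = target / b
            else:
                inner = 1.0 + a * target / b
                with np.errstate(invalid="ignore", divide="ignore"):
                    out = np.where(inner > 0, np.log(np.maximum(inner, 1e-300)) / a, np.inf)
            out = np.asarray(out, dtype=float)
        else:
            out = np.asarray(_scipy_frozen(self.family, self.params).ppf(arr))
        return out if out.ndim else float(out)

    def median(self) -> float:
        return float(self.quantile(0.5))

    def mean(self) -> float:
        """Unrestricted mean E[T] (``inf`` for heavy-tailed log-logistic with
        shape <= 1 and for defective Gompertz)."""
        p = self.params
        if self.family == "loglogistic":
            c = p["shape"]
            if c <= 1:
                return float("inf")
            x = np.pi / c
            return float(p["scale"] * x / np.sin(x))
        if self.family == "gompertz":
            if p["shape"] < 0:
                return float("inf")
            from scipy.integrate import quad

            return float(quad(lambda t: self.survival(t), 0, np.inf, limit=200)[0])
        return float(_scipy_frozen(self.family, p).mean())

    def sample(self, n: int, rng: np.random.Generator | int | None = None) -> np.ndarray:
        """Draw ``n`` event times by inverse-transform sampling.

        Reproducible when ``rng`` is a seeded Generator or an integer seed.
        """
        if n < 0:
            raise DistributionError("sample size must be non-negative")
        if n == 0:
            return np.empty(0)
        rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
        u = rng.uniform(low=np.finfo(float).tiny, high=1.0, size=n)
        return np.asarray(self.quantile(u), dtype=float)

    # -- serialization ----------------------------------------------------

    def to_dict(self) -> dict:
        return {"family": self.family, "params": dict(self.params)}

    @classmethod
    def from_dict(cls, d: Mapping) -> "SurvivalDistribution":
        try:
            family, params = d["family"], d["params"]
        except (KeyError, TypeError) as exc:
            raise DistributionError(
                "distribution mapping must have 'family' and 'params'"
            ) from exc
        return cls(family=family, params=dict(params))

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        inner = ", ".join(f"{k}={v:g}" for k, v in self.params.items())
        return f"SurvivalDistribution({self.family}, {inner})"


def survival(spec: SurvivalDistribution, t):
    """Functional alias for :meth:`SurvivalDistribution.survival`."""
    return spec.survival(t)


def density(spec: SurvivalDistribution, t):
    return spec.density(t)


def quantile(spec: SurvivalDistribution, p):
    return spec.quantile(p)


def sample(spec: SurvivalDistribution, n: int, seed=None):
    return spec.sample(n, rng=seed)
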