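"""Parametric laws for the real (true) lifespan after the onset of senescence.

Two families are supported, both written as hazard models on age ``x >= 0``
measured from the onset of senescence (commonly the age at first
reproduction):

* Weibull with an optional age-independent term:
  ``m(x) = m0 + (c/b) * (x/b)**(c-1)``.  The shape ``c`` governs how the
  mortality risk changes with age (``c < 1`` decreasing, ``c = 1`` constant,
  ``c = 2`` linear increase, ``c > 2`` accelerating); ``b`` is the scale in
  time units.
* Gompertz-Makeham: ``m(x) = m0 + theta * exp(lam * x)`` with ``theta`` the
  mortality at onset and ``lam`` the (exponential) aging rate.

``m0`` is the Makeham / age-independent component in both families.  With
``m0 = 0`` the Weibull law reduces to the textbook two-parameter Weibull and
the Gompertz-Makeham law to the two-parameter Gompertz.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Any

import numpy as np
from scipy import integrate, optimize, special

__all__ = [
    "AgingModel",
    "Weibull",
    "Gompertz",
    "model_from_dict",
    "model_from_json",
]


def _validate_age(x: np.ndarray, allow_zero: bool = True) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if np.any(x < 0) or not np.all(np.isfinite(x)):
        raise ValueError("ages must be finite and non-negative")
    if not allow_zero and np.any(x == 0):
        raise ValueError(
            "age 0 is outside the domain of this model's hazard "
            "(Weibull hazard diverges at the onset when c < 1)"
        )
    return x


class AgingModel:
    """Common interface of the real-lifespan laws.

    Subclasses provide the closed-form ``hazard``, ``survival`` and log
    survival; ``pdf``, ``cdf``, quantiles, the mean and exact sampling are
    derived here.
    """

    family: str = ""
    m0: float = 0.0

    # -- closed forms supplied by subclasses --------------------------------
    def hazard(self, x) -> np.ndarray | float:
        raise NotImplementedError

    def cumulative_hazard(self, x) -> np.ndarray | float:
        raise NotImplementedError

    def _quantile_m0_zero(self, q) -> np.ndarray | float:
        """Inverse CDF of the law with the age-independent term removed."""
        raise NotImplementedError

    # -- derived quantities -------------------------------------------------
    def survival(self, x) -> np.ndarray | float:
        """Survivorship s(x) = exp(-integral of the hazard up to x)."""
        x = _validate_age(x)
        return np.exp(-self.cumulative_hazard(x))

    def pdf(self, x) -> np.ndarray | float:
        """Lifespan density f(x) = m(x) * s(x)."""
        x = _validate_age(x, allow_zero=self._hazard_finite_at_zero())
        return self.hazard(x) * np.exp(-self.cumulative_hazard(x))

    def cdf(self, x) -> np.ndarray | float:
        return 1.0 - self.survival(x)

    def _hazard_finite_at_zero(self) -> bool:
        return True

    def quantile(self, q) -> np.ndarray | float:
        """Age at which the CDF reaches ``q`` (inverse CDF)."""
        q = np.asarray(q, dtype=float)
        if np.any((q < 0) | (q >= 1)):
            raise ValueError("quantile levels must lie in [0, 1)")
        if self.m0 == 0:
            return self._quantile_m0_zero(q)

        # With m0 > 0 the cumulative hazard is a sum of two increasing terms;
        # invert by bracketed root search on the log scale.
        def solve_one(qi: float) -> float:
            if qi == 0:
                return 0.0
            target = -np.log1p(-qi)  # cumulative hazard at the quantile
            hi = 1.0
            while self.cumulative_hazard(hi) < target:
                hi *= 2.0
                if hi > 1e12:  # pragma: no cover - pathological parameters
                    raise RuntimeError("quantile bracket search failed")
            return optimize.brentq(
                lambda x: self.cumulative_hazard(x) - target, 0.0, hi, xtol=1e-14, rtol=1e-14
            )

        return np.vectorize(solve_one)(q)[()]

    def mean_lifespan(self) -> float:
        """Expected lifespan, integral of the survivorship over [0, inf).

        Uses adaptive quadrature truncated where survivorship drops below
        1e-12 (the integrand decays at least exponentially there).
        """
        upper = float(self.quantile(1.0 - 1e-12))
        val, _ = integrate.quad(lambda x: self.survival(x), 0.0, upper, epsabs=1e-9, epsrel=1e-9, limit=200)
        return val

    def sample_lifespans(self, n: int, seed: int | np.random.Generator) -> np.ndarray:
        """Draw ``n`` i.i.d. real lifespans.

        With ``m0 = 0`` sampling is by exact inverse-CDF transform.  With
        ``m0 > 0`` the hazards are additive, so a draw is the minimum of an
        exponential(m0) variate and an inverse-CDF draw from the ``m0 = 0``
        law — an exact competing-risks construction.
        """
        n = int(n)
        if n < 0:
            raise ValueError("sample size must be non-negative")
        rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
        u = rng.random(n)
        x = self._quantile_m0_zero(u)
        if self.m0 > 0:
            x = np.minimum(x, rng.exponential(scale=1.0 / self.m0, size=n))
        return np.asarray(x, dtype=float)

    # -- serialization ------------------------------------------------------
    def to_dict(self) -> dict[str, Any]:
        raise NotImplementedError

    def to_json(self) -> str:
        import json

        return json.dumps(self.to_dict())


@dataclass(frozen=True)
class Weibull(AgingModel):
    """Weibull lifespan law with optional age-independent hazard ``m0``.

    Parameters
    ----------
    m0 : age-independent mortality risk per unit time, >= 0.
    b : scale parameter in time units, > 0.
    c : dimensionless shape parameter, > 0.
    """

    m0: float = 0.0
    b: float = 1.0
    c: float = 1.0
    family = "weibull"

    def __post_init__(self) -> None:
        for name in ("m0", "b", "c"):
            v = getattr(self, name)
            if not np.isfinite(v):
                raise ValueError(f"{name} must be finite")
        if self.m0 < 0:
            raise ValueError("m0 must be non-negative")
        if self.b <= 0 or self.c <= 0:
            raise ValueError("b and c must be positive")

    def _hazard_finite_at_zero(self) -> bool:
        return self.c >= 1

    def hazard(self, x):
        x = _validate_age(x, allow_zero=self.c >= 1)
        with np.errstate(divide="ignore"):
            age_term = (self.c / self.b) * (x / self.b) ** (self.c - 1.0)
        return self.m0 + age_term

    def cumulative_hazard(self, x):
        x = np.asarray(x, dtype=float)
        return self.m0 * x + (x / self.b) ** self.c

    def _quantile_m0_zero(self, q):
        q = np.asarray(q, dtype=float)
        return self.b * (-np.log1p(-q)) ** (1.0 / self.c)

    def mean_lifespan(self) -> float:
        if self.m0 == 0:
            return self.b * float(special.gamma(1.0 + 1.0 / self.c))
        return super().mean_lifespan()

    def to_dict(self):
        return {"family": "weibull", "m0": self.m0, "b": self.b, "c": self.c}


@dataclass(frozen=True)
class Gompertz(AgingModel):
    """Gompertz-Makeham lifespan law.

    Parameters
    ----------
    m0 : Makeham (age-independent) mortality risk per unit time, >= 0.
    theta : mortality at the onset of senescence, per unit time, > 0.
    lam : aging rate (exponential rate of hazard increase), per unit time, > 0.
    """

    m0: float = 0.0
    theta: float = 0.2
    lam: float = 0.1
    family = "gompertz"

    def __post_init__(self) -> None:
        for name in ("m0", "theta", "lam"):
            v = getattr(self, name)
            if not np.isfinite(v):
                raise ValueError(f"{name} must be finite")
        if self.m0 < 0:
            raise ValueError("m0 must be non-negative")
        if self.theta <= 0 or self.lam <= 0:
            raise ValueError("theta and lam must be positive")

    def hazard(self, x):
        x = _validate_age(x)
        return self.m0 + self.theta * np.exp(self.lam * x)

    def cumulative_hazard(self, x):
        x = np.asarray(x, dtype=float)
        return self.m0 * x + (self.theta / self.lam) * np.expm1(self.lam * x)

    def _quantile_m0_zero(self, q):
        q = np.asarray(q, dtype=float)
        return np.log1p(-(self.lam / self.theta) * np.log1p(-q)) / self.lam

    def to_dict(self):
        return {
            "family": "gompertz",
            "m0": self.m0,
            "theta": self.theta,
            "lambda": self.lam,
        }


def model_from_dict(d: dict[str, Any]) -> AgingModel:
    """Build a model from its JSON-style dict representation."""
    family = d.get("family")
    if family == "weibull":
        return Weibull(m0=float(d.get("m0", 0.0)), b=float(d["b"]), c=float(d["c"]))
    if family == "gompertz":
        return Gompertz(
            m0=float(d.get("m0", 0.0)),
            theta=float(d["theta"]),
            lam=float(d.get("lambda", d.get("lam"))),
        )
    raise ValueError(f"unknown model family: {family!r}")


def model_from_json(s: str) -> AgingModel:
    import json

    return model_from_dict(json.loads(s))
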