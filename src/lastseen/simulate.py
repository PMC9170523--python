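"""Cohort simulation: real lifespans and their uniformly reported counterparts."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .models import AgingModel, Gompertz, Weibull

__all__ = ["Cohort", "SweepConfig", "sample_reported", "make_cohort", "make_sweep", "parameter_grid"]


@dataclass(frozen=True)
class Cohort:
    """Paired real and reported lifespans with generating provenance.

    ``real`` may be ``None`` for field data in which only last-seen ages are
    known; every reported value is bounded by its real counterpart when both
    are present.
    """

    reported: np.ndarray
    real: np.ndarray | None = None
    model: AgingModel | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        reported = np.asarray(self.reported, dtype=float)
        object.__setattr__(self, "reported", reported)
        if np.any(reported < 0):
            raise ValueError("reported lifespans must be non-negative")
        if self.real is not None:
            real = np.asarray(self.real, dtype=float)
            object.__setattr__(self, "real", real)
            if real.shape != reported.shape:
                raise ValueError("real and reported arrays must have equal length")
            if np.any(real < 0):
                raise ValueError("real lifespans must be non-negative")
            if np.any(reported > real):
                raise ValueError("reported lifespan exceeds real lifespan")

    @property
    def n(self) -> int:
        return int(self.reported.size)


def sample_reported(real, seed: int | np.random.Generator) -> np.ndarray:
    """Draw one uniformly distributed last-seen age per real lifespan.

    The reported age of an individual with real lifespan ``x`` is uniform on
    ``(0, x)``; a zero lifespan maps to a zero report.
    """
    real = np.asarray(real, dtype=float)
    if np.any(real < 0):
        raise ValueError("real lifespans must be non-negative")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return rng.uniform(0.0, real)


def make_cohort(model: AgingModel, n: int, seed: int) -> Cohort:
    """Simulate ``n`` individuals: real lifespans plus uniform reports."""
    if n < 1:
        raise ValueError("cohort size must be at least 1")
    rng = np.random.default_rng(seed)
    real = model.sample_lifespans(n, rng)
    reported = sample_reported(real, rng)
    return Cohort(reported=reported, real=real, model=model, seed=int(seed))


def parameter_grid(start: float, stop: float, step: float) -> np.ndarray:
    """Closed grid from ``start`` to ``stop`` inclusive.

    The grid is built in integer step counts so that labels land exactly on
    the intended values (1.0 + 90 steps of 0.1 is exactly 10.0).
    """
    if step <= 0:
        raise ValueError("step must be positive")
    k = int(round((stop - start) / step))
    if k < 0 or abs(start + k * step - stop) > 1e-9 * max(1.0, abs(stop)):
        raise ValueError("stop must equal start plus a whole number of steps")
    decimals = max(0, int(np.ceil(-np.log10(step))) + 6)
    return np.round(start + step * np.arange(k + 1), decimals)


@dataclass(frozen=True)
class SweepConfig:
    """Grid of generating parameters for a bias-assessment sweep.

    One cohort of ``n`` individuals is generated per grid value of the swept
    parameter (Weibull shape ``c`` or Gompertz aging rate ``lam``), with the
    remaining parameters held fixed.  Per-set seeds are ``base_seed + index``
    so any single set can be regenerated in isolation.
    """

    family: str
    start: float
    stop: float
    step: float
    n: int = 10_000
    base_seed: int = 0
    m0: float = 0.0
    b: float = 1.0
    theta: float = 0.2

    def __post_init__(self) -> None:
        if self.family not in ("weibull", "gompertz"):
            raise ValueError("family must be 'weibull' or 'gompertz'")
        if self.n < 1:
            raise ValueError("n must be positive")
        self.grid()  # validates start/stop/step

    def grid(self) -> np.ndarray:
        return parameter_grid(self.start, self.stop, self.step)

    def model_at(self, value: float) -> AgingModel:
        if self.family == "weibull":
            return Weibull(m0=self.m0, b=self.b, c=float(value))
        return Gompertz(m0=self.m0, theta=self.theta, lam=float(value))


def make_sweep(config: SweepConfig) -> list[Cohort]:
    """Generate one cohort per grid value of the swept parameter."""
    return [
        make_cohort(config.model_at(v), config.n, config.base_seed + i)
        for i, v in enumerate(config.grid())
    ]
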