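"""Temperature regimes, productivity, and climate summary metrics.

The environmental driver is a dual-timescale temperature process: a
long-term (block) mean redrawn every ``t_span`` steps around the ambient
mean, and short-term per-step Gaussian noise around the current block
mean.  Block means can alternatively follow a sine wave whose amplitude
is matched so that its standard deviation over whole periods equals the
long-term SD, making the Gaussian and sine regimes comparable.

Temperature maps to productivity through a unimodal "tent" multiplier
(zero at cold/hot extremes, peaking at an optimum), which scales both
carrying capacity and per-step fecundity.

Climate metrics (annual mean, diurnal temperature range DTR, seasonal
temperature range STR) summarize logger-style time series the same way
field deployments are summarized.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import pandas as pd

__all__ = [
    "EnvironmentConfig",
    "TemperatureSeries",
    "ProductivityModel",
    "ClimateMetrics",
    "sample_temperature_series",
    "productivity_multiplier",
    "carrying_capacity",
    "climate_metrics",
]


class ConfigurationError(ValueError):
    """Raised for invalid environment or productivity parameters."""


@dataclass(frozen=True)
class EnvironmentConfig:
    """Parameters of the dual-timescale temperature process.

    Parameters
    ----------
    t_mean
        Mean ambient temperature (degC).
    sigma_short
        SD of the per-step draw around the current block mean (degC);
        "short-term variability".
    sigma_long
        SD of the block means around ``t_mean`` (degC); "long-term
        variability".
    t_span
        Number of steps between block-mean updates.
    mode
        ``"gaussian"`` (block means drawn iid) or ``"sine"`` (block
        means follow a sine wave).
    sine_period
        Period of the sine wave, in blocks (sine mode only).
    """

    t_mean: float = 18.0
    sigma_short: float = 2.5
    sigma_long: float = 0.0
    t_span: int = 250
    mode: str = "gaussian"
    sine_period: int = 4

    def __post_init__(self) -> None:
        for name in ("t_mean", "sigma_short", "sigma_long"):
            v = getattr(self, name)
            if not math.isfinite(v):
                raise ConfigurationError(f"{name} must be finite, got {v!r}")
        if self.sigma_short < 0 or self.sigma_long < 0:
            raise ConfigurationError("sigma_short and sigma_long must be >= 0")
        if self.t_span < 1:
            raise ConfigurationError("t_span must be >= 1")
        if self.mode not in ("gaussian", "sine"):
            raise ConfigurationError(f"unknown mode {self.mode!r}")
        if self.mode == "sine" and self.sine_period < 2:
            raise ConfigurationError("sine_period must be >= 2 in sine mode")


@dataclass(frozen=True)
class TemperatureSeries:
    """Realized temperatures: one value per step, one mean per block."""

    values: np.ndarray
    block_means: np.ndarray
    t_span: int


@dataclass(frozen=True)
class ProductivityModel:
    """Unimodal temperature-to-productivity mapping.

    The multiplier rises linearly from 0 at ``t_zero_low`` to 1 at
    ``t_opt`` and falls linearly back to 0 at ``t_zero_high`` (a tent
    function).  ``k0`` is the maximum carrying capacity and ``r_max``
    the maximum per-capita fecundity per step; both are scaled by the
    multiplier.  When the productivity link is disabled the multiplier
    is the constant ``constant_mode_level`` at every temperature.
    """

    t_opt: float = 30.0
    t_zero_low: float = 0.0
    t_zero_high: float = 40.0
    k0: float = 2000.0
    r_max: float = 0.4
    constant_mode_level: float = 0.6

    def __post_init__(self) -> None:
        if not (self.t_zero_low < self.t_opt < self.t_zero_high):
            raise ConfigurationError(
                "require t_zero_low < t_opt < t_zero_high, got "
                f"{self.t_zero_low}, {self.t_opt}, {self.t_zero_high}"
            )
        if self.k0 <= 0 or self.r_max <= 0:
            raise ConfigurationError("k0 and r_max must be > 0")
        if not 0 <= self.constant_mode_level:
            raise ConfigurationError("constant_mode_level must be >= 0")


class ClimateMetrics(NamedTuple):
    annual_mean: float
    dtr: float
    str_: float


def sample_temperature_series(
    cfg: EnvironmentConfig,
    n_steps: int,
    seed: int | np.random.SeedSequence | np.random.Generator | None = None,
) -> TemperatureSeries:
    """Draw a realized temperature series of ``n_steps`` values.

    Gaussian mode: block means ~ Normal(t_mean, sigma_long^2), redrawn
    every ``t_span`` steps; each step adds Normal(0, sigma_short^2)
    noise around its block mean.  Sine mode: block means follow
    ``t_mean + sqrt(2) * sigma_long * sin(2 pi b / sine_period)`` over
    block index ``b`` (amplitude chosen so the SD over whole periods
    equals ``sigma_long``).
    """
    if n_steps < 1:
        raise ValueError("n_steps must be >= 1")
    rng = np.random.default_rng(seed)
    n_blocks = -(-n_steps // cfg.t_span)  # ceil division
    if cfg.mode == "gaussian":
        block_means = rng.normal(cfg.t_mean, cfg.sigma_long, size=n_blocks)
    else:
        b = np.arange(n_blocks)
        block_means = cfg.t_mean + math.sqrt(2.0) * cfg.sigma_long * np.sin(
            2.0 * np.pi * b / cfg.sine_period
        )
    values = np.repeat(block_means, cfg.t_span)[:n_steps]
    values = values + rng.normal(0.0, cfg.sigma_short, size=n_steps)
    return TemperatureSeries(values=values, block_means=block_means, t_span=cfg.t_span)


def productivity_multiplier(
    model: ProductivityModel,
    temperature: float | np.ndarray,
    productivity_link: bool = True,
):
    """Dimensionless productivity multiplier in [0, 1] at ``temperature``.

    Tent-shaped when the productivity link is on; the constant
    ``constant_mode_level`` when it is off.
    """
    t = np.asarray(temperature, dtype=float)
    if not productivity_link:
        out = np.full_like(t, model.constant_mode_level)
        return float(out) if np.isscalar(temperature) else out
    xp = [model.t_zero_low, model.t_opt, model.t_zero_high]
    fp = [0.0, 1.0, 0.0]
    out = np.interp(t, xp, fp, left=0.0, right=0.0)
    return float(out) if np.isscalar(temperature) else out


def carrying_capacity(
    model: ProductivityModel,
    cfg: EnvironmentConfig,
    productivity_link: bool = True,
) -> int:
    """Carrying capacity K = round(k0 * multiplier(t_mean)), in individuals."""
    mult = productivity_multiplier(model, cfg.t_mean, productivity_link)
    return int(round(model.k0 * mult))


def climate_metrics(records: pd.DataFrame) -> ClimateMetrics:
    """Annual mean, DTR and STR from a logger-style temperature series.

    ``records`` needs a ``timestamp`` column (datetime-coercible) and a
    ``temp_c`` column.  Annual mean is the mean of daily mean
    temperatures; DTR the mean over days of (daily max - daily min);
    STR the mean daily maximum of the warmest month minus the mean
    daily minimum of the coldest month, with warmest/coldest identified
    by monthly mean temperature (ties broken by earliest calendar
    month).  The result is invariant to record order.
    """
    if records is None or len(records) == 0:
        raise ValueError("empty temperature record")
    for col in ("timestamp", "temp_c"):
        if col not in records.columns:
            raise ValueError(f"missing required column {col!r}")
    df = records[["timestamp", "temp_c"]].copy()
    df["timestamp"] = pd.to_datetime(df["timestamp"], errors="raise")
    if df["temp_c"].isna().any() or df["timestamp"].isna().any():
        raise ValueError("temperature record contains missing values")
    df = df.sort_values("timestamp").set_index("timestamp")

    daily = df["temp_c"].resample("D").agg(["mean", "max", "min"]).dropna()
    if daily.empty:
        raise ValueError("no complete day in temperature record")
    annual_mean = float(daily["mean"].mean())
    dtr = float((daily["max"] - daily["min"]).mean())

    period = daily.index.to_period("M")
    monthly = daily.groupby(period).agg(
        t_mean=("mean", "mean"), t_max=("max", "mean"), t_min=("min", "mean")
    )
    # tie-break: earliest calendar month, then earliest period
    order = sorted(monthly.index, key=lambda p: (p.month, p.year))
    warmest = max(order, key=lambda p: monthly.loc[p, "t_mean"])
    coldest = min(order, key=lambda p: monthly.loc[p, "t_mean"])
    str_ = float(monthly.loc[warmest, "t_max"] - monthly.loc[coldest, "t_min"])
    return ClimateMetrics(annual_mean=annual_mean, dtr=dtr, str_=str_)
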