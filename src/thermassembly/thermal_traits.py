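"""Thermal performance curves and the specialist-generalist trade-off.

A species' thermal performance curve (TPC) maps temperature to a
fecundity-relevant performance output.  Performance is zero at and
outside the critical thermal limits CTmin and CTmax, and strictly
positive between them.  The default shape is the symmetric unit
parabola ``P(T) = h * 6 u (1 - u)`` with ``u = (T - CTmin) / width``:
smooth, zero at both limits, unit integral on [0, 1], analytic peak
``1.5 h`` at the range midpoint.

In *constrained* mode every curve has the same total performance area
A0 (``h = A0 / width``), so narrow-range specialists peak high and
wide-range generalists peak low — the specialization-generalization
trade-off.  In *relaxed* mode the height is free and the trade-off is
removed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "ThermalPerformanceCurve",
    "TraitPrior",
    "TraitError",
    "make_tpc",
    "tt_range",
    "draw_immigrant",
    "mutate_species",
]

#: Default total performance area (performance * degC) in constrained mode.
DEFAULT_A0 = 20.0

#: Minimum tolerance width (degC) allowed for mutants.
WIDTH_FLOOR = 1.0


class TraitError(ValueError):
    """Raised for invalid thermal trait parameters."""


@dataclass(frozen=True)
class ThermalPerformanceCurve:
    """A species' performance-vs-temperature function.

    ``height`` is the scale ``h`` of the parabola; the integral of the
    curve over its support equals ``height * width``.
    """

    ctmin: float
    ctmax: float
    height: float
    mode: str = "constrained"

    def __post_init__(self) -> None:
        if not self.ctmin < self.ctmax:
            raise TraitError(f"require ctmin < ctmax, got {self.ctmin} >= {self.ctmax}")
        if self.height <= 0:
            raise TraitError("height must be > 0")

    @property
    def width(self) -> float:
        return self.ctmax - self.ctmin

    @property
    def area(self) -> float:
        """Total performance area, the integral of P over [ctmin, ctmax]."""
        return self.height * self.width

    @property
    def peak(self) -> float:
        """Maximum performance, attained at the range midpoint."""
        return 1.5 * self.height

    def performance(self, temperature):
        """Performance at ``temperature`` (scalar or array); 0 outside limits."""
        t = np.asarray(temperature, dtype=float)
        u = (t - self.ctmin) / self.width
        p = np.where((u > 0) & (u < 1), 6.0 * self.height * u * (1.0 - u), 0.0)
        return float(p) if np.isscalar(temperature) else p

    def __call__(self, temperature):
        return self.performance(temperature)


@dataclass(frozen=True)
class TraitPrior:
    """Trait distribution for immigrant species.

    CTmin ~ Uniform(ctmin_low, ctmin_high); width ~ Uniform(width_low,
    width_high); CTmax = CTmin + width.  Constrained priors fix the
    area at ``a0``; relaxed priors draw height ~ Uniform(height_low,
    height_high) independently of the width.
    """

    ctmin_low: float = -10.0
    ctmin_high: float = 35.0
    width_low: float = 2.0
    width_high: float = 30.0
    relaxed_mode: bool = False
    a0: float = DEFAULT_A0
    height_low: float = DEFAULT_A0 / 30.0
    height_high: float = DEFAULT_A0 / 2.0

    def __post_init__(self) -> None:
        if self.ctmin_low > self.ctmin_high or self.width_low > self.width_high:
            raise TraitError("prior bounds must satisfy low <= high")
        if self.width_low <= 0:
            raise TraitError("width_low must be > 0")
        if self.relaxed_mode and self.height_low > self.height_high:
            raise TraitError("height bounds must satisfy low <= high")
        if not self.relaxed_mode and self.a0 <= 0:
            raise TraitError("a0 must be > 0")


def make_tpc(
    ctmin: float,
    ctmax: float,
    mode: str = "constrained",
    a0_or_height: float = DEFAULT_A0,
) -> ThermalPerformanceCurve:
    """Build a TPC from its critical limits.

    Constrained mode interprets ``a0_or_height`` as the fixed total
    area A0 and sets ``height = A0 / width``; relaxed mode takes it as
    the height directly.
    """
    if not ctmin < ctmax:
        raise TraitError(f"require ctmin < ctmax, got {ctmin} >= {ctmax}")
    if a0_or_height <= 0:
        raise TraitError("a0_or_height must be > 0")
    if mode == "constrained":
        height = a0_or_height / (ctmax - ctmin)
    elif mode == "relaxed":
        height = a0_or_height
    else:
        raise TraitError(f"unknown mode {mode!r}")
    return ThermalPerformanceCurve(ctmin=ctmin, ctmax=ctmax, height=height, mode=mode)


def tt_range(tpc: ThermalPerformanceCurve) -> float:
    """Thermal tolerance range TTrange = CTmax - CTmin (degC)."""
    return tpc.width


def draw_immigrant(
    prior: TraitPrior,
    seed: int | np.random.Generator | np.random.SeedSequence | None = None,
) -> ThermalPerformanceCurve:
    """Draw one immigrant species' TPC from the prior."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    ctmin = rng.uniform(prior.ctmin_low, prior.ctmin_high)
    width = rng.uniform(prior.width_low, prior.width_high)
    if prior.relaxed_mode:
        height = rng.uniform(prior.height_low, prior.height_high)
        return make_tpc(ctmin, ctmin + width, mode="relaxed", a0_or_height=height)
    return make_tpc(ctmin, ctmin + width, mode="constrained", a0_or_height=prior.a0)


def mutate_species(
    parent: ThermalPerformanceCurve,
    sigma_mut_ctmin: float,
    sigma_mut_width: float,
    seed: int | np.random.Generator | np.random.SeedSequence | None = None,
    width_floor: float = WIDTH_FLOOR,
) -> ThermalPerformanceCurve:
    """Mutate a parent TPC into an offspring species (sympatric speciation).

    Offspring CTmin and width get independent Gaussian offsets; the
    width is clamped to ``width_floor`` to avoid degenerate curves.
    Constrained parents produce constrained offspring (same area);
    relaxed parents pass their height on unchanged.
    """
    if sigma_mut_ctmin < 0 or sigma_mut_width < 0:
        raise TraitError("mutation SDs must be >= 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    ctmin = parent.ctmin + rng.normal(0.0, sigma_mut_ctmin)
    width = max(width_floor, parent.width + rng.normal(0.0, sigma_mut_width))
    if parent.mode == "constrained":
        return make_tpc(ctmin, ctmin + width, mode="constrained", a0_or_height=parent.area)
    return make_tpc(ctmin, ctmin + width, mode="relaxed", a0_or_height=parent.height)
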