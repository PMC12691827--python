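"""Liposome formulation assay calculations.

Two small, exact computations accompany the imaging pipeline:

* encapsulation efficiency — the percentage of cargo introduced during
  liposome preparation that is retained after dialysis,

      EE% = 100 · C_A / C_At

  with C_A the cargo concentration in the dialysed liposomes and C_At the
  concentration initially introduced (any consistent units);

* ligand grafting yield — an unknown sample's ligand amount read off a
  linear calibration curve built from serial-dilution standards, expressed
  as a percentage of the total ligand input (input normalized to 100 %).

The calibration regresses intensity on amount and inverts (classical
calibration); regressing amount on intensity directly (inverse calibration)
is available as an option.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "EncapsulationInput",
    "CalibrationCurve",
    "encapsulation_efficiency",
    "fit_calibration",
    "grafting_yield",
]


@dataclass(frozen=True)
class EncapsulationInput:
    """Cargo concentrations before (c_at) and after (c_a) dialysis."""

    c_a: float
    c_at: float

    def __post_init__(self) -> None:
        if self.c_at <= 0:
            raise ValueError("initial concentration c_at must be positive")
        if self.c_a < 0:
            raise ValueError("dialysed concentration c_a must be non-negative")


@dataclass(frozen=True)
class CalibrationCurve:
    """Linear standards fit: intensity = slope · amount + intercept."""

    standards: tuple[tuple[float, float], ...]
    slope: float
    intercept: float
    r_squared: float
    direction: str = "classical"  # intensity-on-amount


def encapsulation_efficiency(inp: EncapsulationInput) -> float:
    """Entrapment percentage: 100 · c_a / c_at."""
    return 100.0 * inp.c_a / inp.c_at


def fit_calibration(standards, direction: str = "classical") -> CalibrationCurve:
    """Ordinary least-squares calibration line through the standards.

    ``standards`` is an iterable of ``(amount, intensity)`` pairs with at
    least two distinct amounts.  ``direction="classical"`` regresses
    intensity on amount (the stored slope/intercept are then in
    intensity-per-amount units); ``"inverse"`` regresses amount on intensity
    and stores the re-expressed intensity-on-amount coefficients so that
    :func:`grafting_yield` can invert either curve the same way.
    """
    pairs = [(float(a), float(i)) for a, i in standards]
    amounts = np.array([p[0] for p in pairs])
    intensities = np.array([p[1] for p in pairs])
    if np.unique(amounts).size < 2:
        raise ValueError("calibration needs at least 2 distinct amounts")
    if direction == "classical":
        res = stats.linregress(amounts, intensities)
        slope, intercept = float(res.slope), float(res.intercept)
    elif direction == "inverse":
        res = stats.linregress(intensities, amounts)
        if res.slope == 0:
            raise ValueError("inverse calibration has zero slope")
        # re-express amount = m·intensity + c as intensity = (amount − c)/m
        slope, intercept = 1.0 / float(res.slope), -float(res.intercept) / float(res.slope)
    else:
        raise ValueError(f"unknown calibration direction {direction!r}")
    r2 = float(res.rvalue**2) if np.isfinite(res.rvalue) else 0.0
    return CalibrationCurve(
        standards=tuple(pairs), slope=slope, intercept=intercept, r_squared=r2, direction=direction
    )


def grafting_yield(sample_intensity: float, curve: CalibrationCurve, input_amount: float) -> float:
    """Calibrated ligand amount as a percentage of the total input.

    The sample amount is ``(intensity − intercept) / slope``; negative
    calibrated amounts are clipped to zero with a warning.  Yields above
    100 % are reported as computed (with a warning) since measurement noise
    can legitimately exceed the nominal input.
    """
    if curve.slope == 0:
        raise ValueError("calibration slope is zero; cannot invert")
    if input_amount <= 0:
        raise ValueError("input_amount must be positive")
    amount = (sample_intensity - curve.intercept) / curve.slope
    if amount < 0:
        logger.warning("calibrated amount %.4g is negative; clipping to 0", amount)
        amount = 0.0
    yield_pct = 100.0 * amount / input_amount
    if yield_pct > 100.0:
        logger.warning("grafting yield %.4g%% exceeds 100%% of input", yield_pct)
    return yield_pct
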