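"""Crush-pattern classification: three-phase (foam-like) vs gradual.

A curve is labelled ``three_phase`` when either tentative criterion holds:

* the area under the stress-strain curve over strains 0-0.5, measured above
  the 0.02 N/mm^2 preload baseline, is at least 0.7 of the rectangle with
  height from 0.02 to the stress at strain 0.5 and width 0.5 (a plateau
  fills its bounding rectangle; a convex gradual rise does not), or
* the stress decreases between any two consecutive 0.05-grid points inside
  the strain window [0.05, 0.5] (serration from microfracture events).

Both criteria are evaluated on the 0.05-gridded curve: raw serration at the
machine's +/-0.1 N accuracy would trigger the slope criterion on noise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InsufficientStrainError
from .mechanics import StressStrainCurve
from .types import PRELOAD_THRESHOLD

AREA_RATIO_THRESHOLD = 0.7
SLOPE_WINDOW = (0.05, 0.5)

THREE_PHASE = "three_phase"
GRADUAL = "gradual"


@dataclass(frozen=True)
class PhaseResult:
    """Classification outcome for one nodule's curve."""

    nodule_id: str
    area_ratio: float
    negative_slope_found: bool
    label: str


def _require_half_strain(curve: StressStrainCurve) -> None:
    if curve.max_strain < 0.5 - 1e-9:
        raise InsufficientStrainError(
            f"nodule '{curve.nodule_id}': classification needs strain 0.5, "
            f"achieved {curve.max_strain:.3f} (unclassifiable)"
        )


def area_ratio(
    curve: StressStrainCurve, baseline: float = PRELOAD_THRESHOLD
) -> float:
    """Plateau fill factor over strains [0, 0.5].

    Numerator: trapezoidal integral of max(sigma - baseline, 0);
    denominator: (sigma(0.5) - baseline) * 0.5.  Returns NaN (undefined)
    when the stress at strain 0.5 does not exceed the baseline.
    """
    _require_half_strain(curve)
    mask = curve.strain <= 0.5 + 1e-9
    eps = curve.strain[mask]
    sigma = curve.stress_mpa[mask]
    sigma_half = float(np.interp(0.5, curve.strain, curve.stress_mpa))
    denom = (sigma_half - baseline) * 0.5
    if denom <= 0:
        return float("nan")
    num = float(np.trapezoid(np.maximum(sigma - baseline, 0.0), eps))
    return num / denom


def has_negative_slope(
    curve: StressStrainCurve, window: tuple[float, float] = SLOPE_WINDOW
) -> bool:
    """True iff stress decreases between consecutive grid points whose
    strains both lie inside ``window``."""
    _require_half_strain(curve)
    lo, hi = window
    mask = (curve.strain >= lo - 1e-9) & (curve.strain <= hi + 1e-9)
    sigma = curve.stress_mpa[mask]
    return bool(np.any(np.diff(sigma) < 0))


def classify(
    curve: StressStrainCurve,
    area_threshold: float = AREA_RATIO_THRESHOLD,
    baseline: float = PRELOAD_THRESHOLD,
    window: tuple[float, float] = SLOPE_WINDOW,
) -> PhaseResult:
    """Label a gridded curve three-phase or gradual.

    Raises :class:`InsufficientStrainError` when the curve ends before
    strain 0.5 (unclassifiable; the caller records a missing label).
    """
    ratio = area_ratio(curve, baseline)
    negative = has_negative_slope(curve, window)
    label = (
        THREE_PHASE
        if (not np.isnan(ratio) and ratio >= area_threshold) or negative
        else GRADUAL
    )
    return PhaseResult(
        nodule_id=curve.nodule_id,
        area_ratio=ratio,
        negative_slope_found=negative,
        label=label,
    )
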