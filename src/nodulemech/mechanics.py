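"""Stress-strain reconstruction and stiffness metrics for crushed nodules.

A nodule flattens and spreads as it is crushed, so nominal stress
``F / A0`` misrepresents the true loading conditions.  The correction used
here assumes the initial volume ``V0 = A0 * H0`` is conserved, giving a
volume-conserving cross-section ``V0 / H`` at current height
``H = H0 * (1 - eps)``, of which only a fraction ``Rc`` touches the
platens:

    Rc(eps) = min(0.5 + eps, 1.0)
    A(eps)  = Rc * V0 / H = Rc * A0 / (1 - eps)
    sigma   = F / A            [MPa]
    eps     = L / H0           [dimensionless]

with displacement ``L`` re-zeroed at the contact origin, defined as the
first sample whose preload exceeds 0.02 N/mm^2 of the initial area.

Two stiffness parameters summarise each curve:

* Compression Strength  CS(s) — the peak stress over strains [0, s], MPa.
* Compression Energy    CE(s) — the area under the stress-strain curve over
  [0, s].  MPa times dimensionless strain is MJ/m^3 = J/cm^3, so no unit
  conversion is applied.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .errors import GeometryError, InsufficientStrainError, NoContactError
from .types import PRELOAD_THRESHOLD, NoduleRecord, TestRecording

#: Strain at which samples are discarded: beyond this the conserved-volume
#: area correction diverges and the specimen is fully densified.
MAX_STRAIN = 0.95

#: Standard gravity used to express stress in gram-force per mm^2.
_G_STANDARD = 9.80665

#: Stiffness reporting levels: 10% ... 50% strain.
DEFAULT_LEVELS = (0.1, 0.2, 0.3, 0.4, 0.5)


def contact_ratio(strain: np.ndarray | float) -> np.ndarray | float:
    """Platen contact ratio: 0.5 at first contact, ramping linearly to 1.0
    at half the original height, clamped at 1.0 beyond."""
    return np.minimum(0.5 + np.asarray(strain, dtype=float), 1.0)


def loading_area(strain: np.ndarray | float, a0_mm2: float) -> np.ndarray | float:
    """Corrected loading area A = Rc * A0 / (1 - eps) in mm^2."""
    eps = np.asarray(strain, dtype=float)
    return contact_ratio(eps) * a0_mm2 / (1.0 - eps)


def mpa_to_gf_mm2(stress_mpa: float | np.ndarray) -> float | np.ndarray:
    """Convert stress from MPa (= N/mm^2) to gram-force per mm^2."""
    return np.asarray(stress_mpa) * 1000.0 / _G_STANDARD


@dataclass
class StressStrainCurve:
    """Origin-corrected stress-strain samples for one nodule."""

    strain: np.ndarray
    stress_mpa: np.ndarray
    nodule_id: str = ""
    a0_mm2: float = float("nan")
    h0_mm: float = float("nan")
    origin_index: int = 0
    grid_increment: float | None = None  # set when resampled to a regular grid

    def __post_init__(self) -> None:
        self.strain = np.asarray(self.strain, dtype=float)
        self.stress_mpa = np.asarray(self.stress_mpa, dtype=float)
        if self.strain.size != self.stress_mpa.size:
            raise ValueError("strain and stress series must have equal length")

    def __len__(self) -> int:
        return self.strain.size

    @property
    def max_strain(self) -> float:
        return float(self.strain[-1]) if self.strain.size else 0.0

    @property
    def contact_ratio(self) -> np.ndarray:
        return contact_ratio(self.strain)

    @property
    def loading_area_mm2(self) -> np.ndarray:
        return loading_area(self.strain, self.a0_mm2)


def find_origin(
    rec: TestRecording,
    a0_mm2: float,
    threshold: float = PRELOAD_THRESHOLD,
) -> tuple[int, np.ndarray]:
    """Locate the compression-distance origin of a recording.

    The origin is the first sample whose preload per initial area exceeds
    ``threshold`` (N/mm^2).  The threshold is referred to the *initial*
    projected area because no other area is measurable before deformation.

    Returns the origin index and the displacement series re-zeroed at it.

    Raises
    ------
    NoContactError
        if the preload never surpasses the threshold.
    """
    if a0_mm2 <= 0:
        raise GeometryError(f"A0 must be positive, got {a0_mm2}")
    if len(rec) == 0:
        raise NoContactError("empty recording: no contact point")
    over = rec.load_n / a0_mm2 > threshold
    if not over.any():
        raise NoContactError(
            f"recording '{rec.nodule_id}': preload never exceeded "
            f"{threshold} N/mm^2 over A0 = {a0_mm2} mm^2 (no contact)"
        )
    idx = int(np.argmax(over))
    return idx, rec.displacement_mm - rec.displacement_mm[idx]


def to_stress_strain(
    rec: TestRecording,
    nodule: NoduleRecord,
    threshold: float = PRELOAD_THRESHOLD,
) -> StressStrainCurve:
    """Convert a raw recording into an origin-corrected stress-strain curve.

    Samples at strain >= 0.95 are discarded (area correction diverges).
    A recorded displacement implying strain >= 1.0 means the platens would
    have met through the specimen: the measured height is then suspect and
    a :class:`GeometryError` is raised.
    """
    origin, disp = find_origin(rec, nodule.a0_mm2, threshold)
    eps = disp[origin:] / nodule.h0_mm
    force = rec.load_n[origin:]
    if eps.size and float(eps.max()) >= 1.0:
        raise GeometryError(
            f"nodule '{nodule.nodule_id}': displacement reaches the initial height "
            f"(strain >= 1.0); check H0 = {nodule.h0_mm} mm"
        )
    keep = eps < MAX_STRAIN
    eps, force = eps[keep], force[keep]
    # Displacement jitter at machine accuracy can step backwards; the
    # crosshead cannot.  Running max keeps strain non-decreasing (flat
    # segments replace reversals) and clamps negatives at the origin.
    eps = np.maximum.accumulate(np.maximum(eps, 0.0))
    sigma = force / loading_area(eps, nodule.a0_mm2)
    return StressStrainCurve(
        strain=eps,
        stress_mpa=sigma,
        nodule_id=nodule.nodule_id,
        a0_mm2=nodule.a0_mm2,
        h0_mm=nodule.h0_mm,
        origin_index=origin,
    )


def resample_to_grid(
    curve: StressStrainCurve, increment: float = 0.05
) -> StressStrainCurve:
    """Linearly interpolate the curve onto a regular strain grid.

    The grid runs from 0 to the largest multiple of ``increment`` not
    exceeding the maximum achieved strain.  Cohort tables are built on this
    grid; stiffness metrics use the raw curve.
    """
    if increment <= 0:
        raise ValueError("grid increment must be positive")
    if len(curve) < 2:
        raise InsufficientStrainError(
            f"nodule '{curve.nodule_id}': need >= 2 samples to resample"
        )
    # Guard the floor against float error at exact multiples.
    n_steps = int(np.floor(curve.max_strain / increment + 1e-9))
    grid = np.arange(n_steps + 1) * increment
    sigma = np.interp(grid, curve.strain, curve.stress_mpa)
    return StressStrainCurve(
        strain=grid,
        stress_mpa=sigma,
        nodule_id=curve.nodule_id,
        a0_mm2=curve.a0_mm2,
        h0_mm=curve.h0_mm,
        origin_index=curve.origin_index,
        grid_increment=increment,
    )


def _check_level(curve: StressStrainCurve, level: float) -> None:
    if level <= 0:
        raise ValueError("strain level must be positive")
    if curve.max_strain < level:
        raise InsufficientStrainError(
            f"nodule '{curve.nodule_id}': achieved strain {curve.max_strain:.3f} "
            f"is below requested level {level}"
        )


def compression_strength(curve: StressStrainCurve, level: float) -> float:
    """Compression Strength CS(level): peak stress over strains [0, level], MPa.

    Evaluated on the curve as given (raw sampling resolution for machine
    recordings).  Raises :class:`InsufficientStrainError` when the test ended
    before ``level``; values are never extrapolated.
    """
    _check_level(curve, level)
    in_range = curve.strain <= level + 1e-12
    peak = float(curve.stress_mpa[in_range].max())
    # The interpolated stress at the level itself can exceed every sample
    # below it on a rising segment.
    at_level = float(np.interp(level, curve.strain, curve.stress_mpa))
    return max(peak, at_level)


def compression_energy(curve: StressStrainCurve, level: float) -> float:
    """Compression Energy CE(level): area under the stress-strain curve over
    [0, level], in J/cm^3 (numerically equal to MPa x strain).

    Trapezoidal rule on the piecewise-linear data model, with the segment up
    to ``level`` closed by linear interpolation.
    """
    _check_level(curve, level)
    in_range = curve.strain < level
    eps = np.append(curve.strain[in_range], level)
    sig = np.append(
        curve.stress_mpa[in_range], np.interp(level, curve.strain, curve.stress_mpa)
    )
    if eps[0] > 0.0:
        # Close the integral at zero strain with the first corrected stress.
        eps = np.insert(eps, 0, 0.0)
        sig = np.insert(sig, 0, sig[0])
    return float(np.trapezoid(sig, eps))


@dataclass
class StiffnessProfile:
    """CS/CE values of one nodule at a set of strain levels.

    Levels the test did not reach carry NaN, never an extrapolation.
    """

    nodule_id: str
    levels: tuple[float, ...]
    cs_mpa: dict[float, float] = field(default_factory=dict)
    ce_j_cm3: dict[float, float] = field(default_factory=dict)
    max_strain: float = float("nan")
    pattern: str | None = None  # filled by the phase classifier

    def cs(self, level: float) -> float:
        return self.cs_mpa.get(level, float("nan"))

    def ce(self, level: float) -> float:
        return self.ce_j_cm3.get(level, float("nan"))


def stiffness_profile(
    curve: StressStrainCurve,
    levels: Sequence[float] = DEFAULT_LEVELS,
) -> StiffnessProfile:
    """Compute CS and CE at each requested strain level on the raw curve."""
    profile = StiffnessProfile(
        nodule_id=curve.nodule_id,
        levels=tuple(levels),
        max_strain=curve.max_strain,
    )
    for level in levels:
        try:
            profile.cs_mpa[level] = compression_strength(curve, level)
            profile.ce_j_cm3[level] = compression_energy(curve, level)
        except InsufficientStrainError:
            profile.cs_mpa[level] = float("nan")
            profile.ce_j_cm3[level] = float("nan")
    return profile
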