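"""Shared domain containers: machine metadata, raw recordings, nodule records.

Units follow the testing-machine conventions throughout: time in ms, load in
N, displacement in mm, areas in mm^2, heights in mm, stresses in MPa
(= N/mm^2), CT attenuation in Hounsfield units (HU).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np

from .errors import GeometryError, RecordingFormatError, SpecValidationError

#: Preload stress (N/mm^2) defining the compression-distance origin.
PRELOAD_THRESHOLD = 0.02


@dataclass(frozen=True)
class MachineSpec:
    """Load-testing machine configuration.

    Defaults correspond to a uniaxial tester driven at 2.00 mm/min,
    sampling every 20 ms, with a 2000 N load cut-off and stated
    accuracies of +/-0.1 N and +/-0.01 mm.
    """

    sampling_interval_ms: float = 20.0
    speed_mm_min: float = 2.00
    load_limit_n: float = 2000.0
    load_accuracy_n: float = 0.1
    disp_accuracy_mm: float = 0.01

    def __post_init__(self) -> None:
        for name in (
            "sampling_interval_ms",
            "speed_mm_min",
            "load_limit_n",
            "load_accuracy_n",
            "disp_accuracy_mm",
        ):
            if getattr(self, name) <= 0:
                raise SpecValidationError(f"MachineSpec.{name} must be positive")

    @property
    def speed_mm_per_ms(self) -> float:
        return self.speed_mm_min / 60000.0


@dataclass
class TestRecording:
    """Raw machine samples for one compression test.

    ``meta`` carries provenance (e.g. the simulator's ground-truth contact
    index and crush pattern) and is never consulted by the analysis stages.
    """

    time_ms: np.ndarray
    load_n: np.ndarray
    displacement_mm: np.ndarray
    machine: MachineSpec = field(default_factory=MachineSpec)
    nodule_id: str = ""
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.time_ms = np.asarray(self.time_ms, dtype=float)
        self.load_n = np.asarray(self.load_n, dtype=float)
        self.displacement_mm = np.asarray(self.displacement_mm, dtype=float)
        self.validate()

    def __len__(self) -> int:
        return self.time_ms.size

    def validate(self) -> None:
        n = self.time_ms.size
        if self.load_n.size != n or self.displacement_mm.size != n:
            raise RecordingFormatError(
                f"recording '{self.nodule_id}': series lengths differ "
                f"(time {n}, load {self.load_n.size}, displacement {self.displacement_mm.size})"
            )
        if n == 0:
            raise RecordingFormatError(f"recording '{self.nodule_id}': empty recording")
        dt = np.diff(self.time_ms)
        if np.any(dt <= 0):
            row = int(np.argmax(dt <= 0)) + 1
            raise RecordingFormatError(
                f"recording '{self.nodule_id}': time not strictly increasing at row {row + 1}"
            )
        if np.any(self.load_n < 0):
            row = int(np.argmax(self.load_n < 0))
            raise RecordingFormatError(
                f"recording '{self.nodule_id}': negative load at row {row + 1}"
            )
        # Displacement may jitter backwards within the stated machine accuracy.
        dd = np.diff(self.displacement_mm)
        tol = self.machine.disp_accuracy_mm
        if np.any(dd < -tol):
            row = int(np.argmax(dd < -tol)) + 1
            raise RecordingFormatError(
                f"recording '{self.nodule_id}': displacement decreases by more than "
                f"{tol} mm at row {row + 1}"
            )


@dataclass
class NoduleRecord:
    """Geometry, imaging and clinical covariates of one calcified nodule.

    ``a0_mm2`` is the projected (frontal-view) area, ``h0_mm`` the caliper
    height; the initial volume ``v0_mm3 = a0_mm2 * h0_mm`` is treated as
    conserved during crushing when reconstructing the loading area.
    """

    nodule_id: str
    a0_mm2: float
    h0_mm: float
    patient_id: str = ""
    ct_hu: float = float("nan")
    dialysis: bool | None = None
    cusp: str | None = None
    pattern_truth: str | None = None
    extra: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not np.isfinite(self.a0_mm2) or self.a0_mm2 <= 0:
            raise GeometryError(
                f"nodule '{self.nodule_id}': initial projected area A0 must be > 0 "
                f"(got {self.a0_mm2})"
            )
        if not np.isfinite(self.h0_mm) or self.h0_mm <= 0:
            raise GeometryError(
                f"nodule '{self.nodule_id}': initial height H0 must be > 0 "
                f"(got {self.h0_mm})"
            )
        if self.cusp is not None and self.cusp not in ("L", "R", "N"):
            raise SpecValidationError(
                f"nodule '{self.nodule_id}': cusp must be one of L/R/N, got {self.cusp!r}"
            )

    @property
    def v0_mm3(self) -> float:
        """Initial volume, the product of projected area and height."""
        return self.a0_mm2 * self.h0_mm
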