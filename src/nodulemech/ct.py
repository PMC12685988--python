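"""CT densitometry of calcified regions: slab MIP and thresholded ROI means.

The calcium density of a nodule's source region is measured on a maximum
intensity projection (MIP) through a 15-20 mm slab: every projection pixel
is the maximum voxel value along the projection axis within the slab.  A
polygonal region of interest drawn on the MIP is then averaged over its
high-density pixels only (CT number >= 600 HU, threshold inclusive).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .errors import SpecValidationError

#: Calcification segmentation threshold (inclusive), HU.
CALCIUM_THRESHOLD_HU = 600.0

#: Recommended slab thickness range, mm.
SLAB_RANGE_MM = (15.0, 20.0)


@dataclass
class MIPImage:
    """Maximum-intensity projection through a slab of a CT volume."""

    pixels_hu: np.ndarray  # 2-D, [row, col]
    pixel_spacing_mm: tuple[float, float]
    slab_thickness_mm: float
    projection_axis: int


@dataclass(frozen=True)
class ROIMeasurement:
    """Mean CT number over high-density pixels inside a polygon.

    ``mean_hu`` is NaN (flagged missing, never zero) when no pixel inside
    the polygon reaches the threshold.
    """

    n_pixels_over_threshold: int
    mean_hu: float
    threshold_hu: float

    @property
    def missing(self) -> bool:
        return self.n_pixels_over_threshold == 0


def make_mip(
    volume_hu: np.ndarray,
    axis: int,
    slab_bounds_mm: tuple[float, float],
    spacing_mm: Sequence[float] = (1.0, 1.0, 1.0),
) -> MIPImage:
    """Project the voxelwise maximum along ``axis`` restricted to the slab
    ``slab_bounds_mm`` (measured from the volume edge along that axis).

    Warns when the slab thickness falls outside the 15-20 mm convention.
    """
    volume_hu = np.asarray(volume_hu, dtype=float)
    if volume_hu.ndim != 3:
        raise SpecValidationError("CT volume must be a 3-D array")
    if axis not in (0, 1, 2):
        raise SpecValidationError("projection axis must be 0, 1 or 2")
    lo_mm, hi_mm = slab_bounds_mm
    step = spacing_mm[axis]
    # Voxel i occupies [i*step, (i+1)*step): include voxels whose centers lie in the slab.
    centers = (np.arange(volume_hu.shape[axis]) + 0.5) * step
    sel = np.flatnonzero((centers >= lo_mm) & (centers <= hi_mm))
    if sel.size == 0:
        raise SpecValidationError(
            f"slab [{lo_mm}, {hi_mm}] mm contains no voxel along axis {axis}"
        )
    thickness = hi_mm - lo_mm
    if not SLAB_RANGE_MM[0] <= thickness <= SLAB_RANGE_MM[1]:
        warnings.warn(
            f"slab thickness {thickness:g} mm is outside the usual "
            f"{SLAB_RANGE_MM[0]:g}-{SLAB_RANGE_MM[1]:g} mm range",
            stacklevel=2,
        )
    slab = np.take(volume_hu, sel, axis=axis)
    pixels = slab.max(axis=axis)
    plane_axes = [ax for ax in range(3) if ax != axis]
    return MIPImage(
        pixels_hu=pixels,
        pixel_spacing_mm=(spacing_mm[plane_axes[0]], spacing_mm[plane_axes[1]]),
        slab_thickness_mm=thickness,
        projection_axis=axis,
    )


def polygon_mask(
    shape: tuple[int, int], polygon: Sequence[tuple[float, float]]
) -> np.ndarray:
    """Boolean mask of pixels whose centers lie inside the polygon.

    Polygon vertices are ``(x, y) = (column, row)`` in 0-based pixel units;
    containment is decided for pixel centers (integer coordinates) under the
    even-odd rule, so vertex order does not matter.
    """
    if len(polygon) < 3:
        raise SpecValidationError("ROI polygon needs at least 3 vertices")
    rows, cols = shape
    poly = np.asarray(polygon, dtype=float)
    yy, xx = np.mgrid[0:rows, 0:cols]
    px = xx.ravel().astype(float)
    py = yy.ravel().astype(float)
    inside = np.zeros(px.size, dtype=bool)
    n = poly.shape[0]
    # Even-odd ray cast: count edge crossings of a horizontal ray to +x.
    for i in range(n):
        x1, y1 = poly[i]
        x2, y2 = poly[(i + 1) % n]
        straddles = (y1 > py) != (y2 > py)
        if not straddles.any():
            continue
        with np.errstate(divide="ignore", invalid="ignore"):
            x_cross = x1 + (py - y1) * (x2 - x1) / (y2 - y1)
        inside ^= straddles & (px < x_cross)
    return inside.reshape(rows, cols)


def mean_ct_number(
    mip: MIPImage,
    roi: Sequence[tuple[float, float]],
    threshold: float = CALCIUM_THRESHOLD_HU,
) -> ROIMeasurement:
    """Average the MIP over high-density pixels (>= ``threshold``) inside
    the ROI polygon."""
    mask = polygon_mask(mip.pixels_hu.shape, roi)
    values = mip.pixels_hu[mask]
    qualifying = values[values >= threshold]
    if qualifying.size == 0:
        return ROIMeasurement(0, float("nan"), threshold)
    return ROIMeasurement(int(qualifying.size), float(qualifying.mean()), threshold)


def read_ct_volume(path: str | Path) -> tuple[np.ndarray, tuple[float, float, float]]:
    """Load a CT volume and voxel spacing from NIfTI (.nii/.nii.gz) or from
    a .npy array with a JSON sidecar ``{"spacing_mm": [sx, sy, sz]}``."""
    path = Path(path)
    if path.suffix in (".nii", ".gz") or path.name.endswith(".nii.gz"):
        import nibabel as nib

        img = nib.load(str(path))
        vol = np.asanyarray(img.dataobj, dtype=float)
        spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
        return vol, spacing
    if path.suffix == ".npy":
        vol = np.load(path)
        sidecar = path.with_suffix(".json")
        spacing = (1.0, 1.0, 1.0)
        if sidecar.exists():
            meta = json.loads(sidecar.read_text())
            spacing = tuple(float(s) for s in meta.get("spacing_mm", spacing))
        return vol.astype(float), spacing
    raise SpecValidationError(f"unsupported CT volume format: {path.name}")
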