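"""Shared in-memory containers for calibrated images and segmented objects.

A :class:`CalibratedImage` couples a 2-D intensity grid with its physical
pixel size (µm per pixel) and the cultivation metadata (sampling time in
hours, talc microparticle concentration in g L⁻¹) that every downstream
stage needs. A :class:`ObjectMask` is one 8-connected segmented object,
stored as explicit pixel coordinates so shape descriptors can be computed
without re-rasterising.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

__all__ = ["CalibratedImage", "ObjectMask", "EIGHT_CONN"]

#: 3x3 structuring element for 8-connectivity.
EIGHT_CONN = np.ones((3, 3), dtype=bool)


@dataclass(frozen=True)
class CalibratedImage:
    """Grayscale image with µm-per-pixel calibration and sample metadata.

    Parameters
    ----------
    data:
        2-D array of finite intensities. Stored as float64.
    calibration_um_per_px:
        Physical side length of one pixel in µm; must be positive.
    time_h:
        Sampling time of the culture in hours.
    talc_g_per_l:
        Talc microparticle concentration of the cultivation in g L⁻¹.
    image_id:
        Free-form identifier used in output tables.
    """

    data: np.ndarray
    calibration_um_per_px: float
    time_h: float = 0.0
    talc_g_per_l: float = 0.0
    image_id: str = ""

    def __post_init__(self) -> None:
        arr = np.asarray(self.data, dtype=np.float64)
        if arr.ndim != 2 or arr.shape[0] < 3 or arr.shape[1] < 3:
            raise ValueError("image must be 2-D and at least 3x3 pixels")
        if not np.all(np.isfinite(arr)):
            raise ValueError("image contains non-finite intensities")
        if not self.calibration_um_per_px > 0:
            raise ValueError("calibration must be positive (µm per pixel)")
        object.__setattr__(self, "data", arr)

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def with_data(self, data: np.ndarray) -> "CalibratedImage":
        """Return a copy with new pixel data and identical metadata."""
        return CalibratedImage(
            data=data,
            calibration_um_per_px=self.calibration_um_per_px,
            time_h=self.time_h,
            talc_g_per_l=self.talc_g_per_l,
            image_id=self.image_id,
        )


@dataclass(frozen=True)
class ObjectMask:
    """One segmented connected object as an explicit pixel set.

    ``pixels`` is an ``(N, 2)`` integer array of (row, col) coordinates,
    0-based. The set must be non-empty and 8-connected; both are enforced
    on construction.
    """

    pixels: np.ndarray
    calibration_um_per_px: float
    object_id: int = 0
    touches_border: bool = False

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 2 or px.shape[1] != 2 or px.shape[0] == 0:
            raise ValueError("pixels must be a non-empty (N, 2) array")
        if not np.issubdtype(px.dtype, np.integer):
            rounded = np.rint(px)
            if not np.allclose(px, rounded):
                raise ValueError("pixel coordinates must be integral")
            px = rounded.astype(np.int64)
        else:
            px = px.astype(np.int64)
        # canonical ordering makes equality and hashing of outputs stable
        order = np.lexsort((px[:, 1], px[:, 0]))
        px = px[order]
        if not self.calibration_um_per_px > 0:
            raise ValueError("calibration must be positive (µm per pixel)")
        object.__setattr__(self, "pixels", px)
        if not self._is_connected(px):
            raise ValueError("object mask is not 8-connected")

    @staticmethod
    def _is_connected(px: np.ndarray) -> bool:
        if px.shape[0] == 1:
            return True
        rmin, cmin = px.min(axis=0)
        patch = np.zeros(
            (int(px[:, 0].max() - rmin) + 1, int(px[:, 1].max() - cmin) + 1),
            dtype=bool,
        )
        patch[px[:, 0] - rmin, px[:, 1] - cmin] = True
        _, n = ndimage.label(patch, structure=EIGHT_CONN)
        return n == 1

    @property
    def n_pixels(self) -> int:
        return int(self.pixels.shape[0])

    def bounding_box(self) -> tuple[int, int, int, int]:
        """(rmin, cmin, rmax, cmax), inclusive."""
        rmin, cmin = self.pixels.min(axis=0)
        rmax, cmax = self.pixels.max(axis=0)
        return int(rmin), int(cmin), int(rmax), int(cmax)

    def to_patch(self) -> tuple[np.ndarray, tuple[int, int]]:
        """Boolean raster of the bounding box and its (rmin, cmin) offset."""
        rmin, cmin, rmax, cmax = self.bounding_box()
        patch = np.zeros((rmax - rmin + 1, cmax - cmin + 1), dtype=bool)
        patch[self.pixels[:, 0] - rmin, self.pixels[:, 1] - cmin] = True
        return patch, (rmin, cmin)

    def translated(self, dr: int, dc: int, object_id: int | None = None) -> "ObjectMask":
        return ObjectMask(
            pixels=self.pixels + np.array([dr, dc]),
            calibration_um_per_px=self.calibration_um_per_px,
            object_id=self.object_id if object_id is None else object_id,
            touches_border=self.touches_border,
        )
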