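"""Pre-segmentation filtering and segmentation of calibrated microscopy images.

The segmentation pipeline mirrors the semiautomatic particle-analysis
workflow used for phase-contrast images of filamentous cultures: a median
filter suppresses shot noise, an automatic bimodal (Otsu) threshold on
the filtered intensity separates dark objects from the bright background,
the Sobel gradient magnitude refines object boundaries by pulling in
edge-band pixels contiguous with a detected object, holes are filled,
8-connected components are labelled, and components below a minimum
physical area (µm²) are discarded. Objects touching the image border are
excluded by default because their area, diameter and elongation are
biased; a flag-only policy is available.

All window operations use reflect padding so no artificial edges are
introduced at the image border.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd
import tifffile
from PIL import Image as _PILImage
from scipy import ndimage
from skimage.filters import threshold_otsu

from .containers import EIGHT_CONN, CalibratedImage, ObjectMask

__all__ = [
    "CalibratedImage",
    "ObjectMask",
    "SegmentationConfig",
    "median_filter",
    "sobel_magnitude",
    "segment_objects",
    "read_image",
    "write_labeled_masks",
    "masks_to_frame",
]

_SOBEL_X = np.array([[1, 0, -1], [2, 0, -2], [1, 0, -1]], dtype=float)


@dataclass(frozen=True)
class SegmentationConfig:
    """Parameters of the segmentation pipeline.

    ``threshold`` is either ``"otsu"`` (automatic bimodal threshold) or a
    fixed numeric value, useful for exactly reproducible runs.
    ``min_area_um2`` removes labelled components below that physical
    area; the default 20 µm² suppresses noise specks while retaining
    small hyphal fragments. Raising it to 100 µm² additionally removes
    10 µm talc microparticle distractors (disk area π·5² ≈ 78.5 µm²).
    ``polarity`` states whether objects are darker or brighter than the
    background; the generator renders dark-on-bright.
    """

    median_window: int = 3
    threshold: float | Literal["otsu"] = "otsu"
    min_area_um2: float = 20.0
    fill_holes: bool = True
    border_policy: Literal["exclude", "flag"] = "exclude"
    polarity: Literal["dark", "bright"] = "dark"
    edge_refinement: bool = True

    def __post_init__(self) -> None:
        if self.median_window < 1 or self.median_window % 2 == 0:
            raise ValueError("median window must be odd and >= 1")
        if self.min_area_um2 < 0:
            raise ValueError("minimum object area must be >= 0")
        if self.border_policy not in ("exclude", "flag"):
            raise ValueError("border policy must be 'exclude' or 'flag'")
        if self.polarity not in ("dark", "bright"):
            raise ValueError("polarity must be 'dark' or 'bright'")


def median_filter(image: CalibratedImage, window: int) -> CalibratedImage:
    """Median filter with a square window and reflect padding.

    ``window`` must be odd, positive and no larger than either image
    dimension. ``window == 1`` is the identity. Calibration and metadata
    are preserved.
    """
    if window < 1 or window % 2 == 0:
        raise ValueError("median window must be odd and >= 1")
    if window > min(image.shape):
        raise ValueError("median window exceeds image size")
    if window == 1:
        return image.with_data(image.data.copy())
    return image.with_data(
        ndimage.median_filter(image.data, size=window, mode="reflect")
    )


def sobel_magnitude(image: CalibratedImage) -> CalibratedImage:
    """Gradient magnitude √(gx² + gy²) with the standard 3×3 Sobel kernels.

    Kernel weights are 1-2-1 smoothing across, ±1 differencing along
    each axis; borders use reflect padding. The output is non-negative
    and zero on constant images.
    """
    gx = ndimage.correlate(image.data, _SOBEL_X, mode="reflect")
    gy = ndimage.correlate(image.data, _SOBEL_X.T, mode="reflect")
    return image.with_data(np.hypot(gx, gy))


def _foreground(filtered: np.ndarray, config: SegmentationConfig) -> np.ndarray | None:
    """Polarity-aware threshold of the filtered image; None if degenerate."""
    if filtered.max() == filtered.min():
        return None
    if config.threshold == "otsu":
        thr = threshold_otsu(filtered)
        # Otsu's objective is flat across an empty histogram gap and the
        # returned bin centre can hug the object class; one isodata step
        # (midpoint of the class means) recentres the cut in the gap
        lo = filtered[filtered <= thr]
        hi = filtered[filtered > thr]
        if lo.size and hi.size:
            thr = 0.5 * (lo.mean() + hi.mean())
    else:
        thr = float(config.threshold)
    fg = filtered <= thr if config.polarity == "dark" else filtered >= thr
    if not fg.any() or fg.all():
        return None
    return fg


def segment_objects(
    image: CalibratedImage, config: SegmentationConfig = SegmentationConfig()
) -> list[ObjectMask]:
    """Segment an image into object masks.

    Pipeline: median filter → polarity-aware threshold of the filtered
    intensity → Sobel edge-band refinement (edge pixels whose intensity
    lies on the object side of the class-mean midpoint are added where
    contiguous with a detected object) → optional hole filling →
    8-connected labelling → minimum-area filter → border policy.

    Returns masks sorted by descending pixel count, relabelled 1..k.
    An image with no foreground (including a degenerate uniform image)
    yields an empty list; that is not an error.
    """
    filtered = median_filter(image, config.median_window).data
    fg = _foreground(filtered, config)
    if fg is None:
        return []

    if config.edge_refinement:
        sob = sobel_magnitude(image.with_data(filtered)).data
        if sob.max() > 0:
            edge_thr = threshold_otsu(sob)
            mu_fg = filtered[fg].mean()
            mu_bg = filtered[~fg].mean()
            mid = 0.5 * (mu_fg + mu_bg)
            on_object_side = filtered <= mid if config.polarity == "dark" else filtered >= mid
            candidate = fg | ((sob > edge_thr) & on_object_side)
            fg = ndimage.binary_propagation(fg, mask=candidate, structure=EIGHT_CONN)

    if config.fill_holes:
        fg = ndimage.binary_fill_holes(fg)

    labels, n = ndimage.label(fg, structure=EIGHT_CONN)
    if n == 0:
        return []

    min_px = config.min_area_um2 / image.calibration_um_per_px**2
    counts = np.bincount(labels.ravel())[1:]  # per-label pixel counts

    border = np.zeros_like(fg)
    border[0, :] = border[-1, :] = True
    border[:, 0] = border[:, -1] = True
    border_labels = set(np.unique(labels[border & fg])) - {0}

    keep: list[tuple[int, int, bool]] = []  # (label, count, touches_border)
    for lab in range(1, n + 1):
        cnt = int(counts[lab - 1])
        if cnt < min_px:
            continue
        touches = lab in border_labels
        if touches and config.border_policy == "exclude":
            continue
        keep.append((lab, cnt, touches))

    keep.sort(key=lambda t: (-t[1], t[0]))
    masks: list[ObjectMask] = []
    for new_id, (lab, _cnt, touches) in enumerate(keep, start=1):
        rr, cc = np.nonzero(labels == lab)
        masks.append(
            ObjectMask(
                pixels=np.column_stack((rr, cc)),
                calibration_um_per_px=image.calibration_um_per_px,
                object_id=new_id,
                touches_border=touches,
            )
        )
    return masks


# ---------------------------------------------------------------------------
# I/O

def read_image(
    path: str | Path,
    calibration_um_per_px: float,
    time_h: float = 0.0,
    talc_g_per_l: float = 0.0,
    image_id: str | None = None,
) -> CalibratedImage:
    """Read an 8/16-bit grayscale TIFF or PNG as a CalibratedImage.

    Integer intensities are rescaled to [0, 1] by the dtype maximum so
    that downstream thresholds are bit-depth independent.
    """
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        arr = tifffile.imread(path)
    else:
        arr = np.asarray(_PILImage.open(path).convert("I"))
    arr = np.asarray(arr)
    if arr.ndim == 3:  # RGB(A): luminance
        arr = arr[..., :3].mean(axis=-1)
    if np.issubdtype(arr.dtype, np.integer):
        info = np.iinfo(arr.dtype) if arr.dtype.itemsize <= 2 else np.iinfo(np.uint16)
        arr = arr.astype(np.float64) / max(info.max, int(arr.max()) or 1)
    return CalibratedImage(
        data=arr,
        calibration_um_per_px=calibration_um_per_px,
        time_h=time_h,
        talc_g_per_l=talc_g_per_l,
        image_id=image_id if image_id is not None else path.stem,
    )


def write_labeled_masks(
    path: str | Path, masks: list[ObjectMask], shape: tuple[int, int]
) -> None:
    """Write a 16-bit labelled TIFF: 0 = background, k = object k."""
    label_img = np.zeros(shape, dtype=np.uint16)
    for m in masks:
        label_img[m.pixels[:, 0], m.pixels[:, 1]] = m.object_id
    tifffile.imwrite(Path(path), label_img)


def masks_to_frame(masks: list[ObjectMask], image_id: str = "") -> pd.DataFrame:
    """Per-image object table: image_id, object_id, n_pixels, touches_border."""
    return pd.DataFrame(
        [
            {
                "image_id": image_id,
                "object_id": m.object_id,
                "n_pixels": m.n_pixels,
                "touches_border": m.touches_border,
            }
            for m in masks
        ],
        columns=["image_id", "object_id", "n_pixels", "touches_border"],
    )
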