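"""Shape descriptors and morphology-number classification for segmented objects.

Four descriptors are computed per object, following the conventions of
particle-analysis software for filamentous microorganisms:

* projected area ``A`` — pixel count × calibration² (µm²);
* elongation ``E`` — squared ratio of the longitudinal to the transversal
  standard deviation of the pixel coordinates about the object's principal
  (orthogonal-regression) axis; 1 for a disk, large for hyphae;
* solidity ``S`` (identical to roughness ``R``) — object area divided by
  the area of its convex hull; 1 for convex shapes;
* maximum diameter ``D`` — the maximum Feret diameter, i.e. the largest
  pairwise distance between corner points of the object's pixel squares,
  in µm.

These combine into the dimensionless morphology number

    Mo = 2·√A·S / (√π·D·E),

which is 1 for a perfect circle and decreases towards 0 for elongated or
irregular objects. The isodiametric inequality (A ≤ π·(D/2)²) together
with S ≤ 1 and E ≥ 1 bounds Mo by 1 for any planar object, up to a small
rasterisation tolerance.

Geometric conventions: area-bearing quantities treat each pixel as a unit
square, so the convex hull is taken over pixel-square *corner* points
(a pixel-centre hull would systematically understate the area of thin
objects), and a single pixel has D = calibration·√2 (its diagonal).
Elongation uses pixel centres, matching its definition as a moment of the
pixel population.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy import ndimage
from scipy.spatial import ConvexHull

from .containers import EIGHT_CONN, ObjectMask
from .stats import SampleSummary, mean_sd_ci

__all__ = [
    "MorphoRecord",
    "GroupSummary",
    "ClassThresholds",
    "DegenerateObjectError",
    "projected_area",
    "elongation",
    "solidity",
    "max_diameter",
    "morphology_number",
    "measure",
    "classify",
    "summarize",
    "RASTER_TOL",
]

#: relative tolerance granted to S and Mo for rasterisation effects
RASTER_TOL = 0.02

#: transversal-variance floor (px²) below which elongation is undefined
_DEGENERATE_VAR = 1e-9

PARAMETERS = ("A", "E", "S", "D", "Mo")


class DegenerateObjectError(ValueError):
    """Raised when a shape descriptor is undefined for the pixel set."""


def _hull(mask: ObjectMask) -> ConvexHull:
    """Convex hull of the pixel-square corner points, in pixel units.

    Only boundary pixels contribute hull vertices, so the corner cloud is
    restricted to them for speed.
    """
    patch, (rmin, cmin) = mask.to_patch()
    if mask.n_pixels > 1:
        interior = ndimage.binary_erosion(patch, structure=EIGHT_CONN)
        boundary = patch & ~interior
    else:
        boundary = patch
    rr, cc = np.nonzero(boundary)
    centers = np.column_stack((rr + rmin, cc + cmin)).astype(float)
    offsets = np.array([[-0.5, -0.5], [-0.5, 0.5], [0.5, -0.5], [0.5, 0.5]])
    corners = (centers[:, None, :] + offsets[None, :, :]).reshape(-1, 2)
    return ConvexHull(corners)


def projected_area(mask: ObjectMask) -> float:
    """Projected area A in µm²: pixel count × calibration²."""
    return mask.n_pixels * mask.calibration_um_per_px**2


def elongation(mask: ObjectMask) -> float:
    """Elongation E = (σ_longitudinal / σ_transversal)² ≥ 1.

    The axes are the principal axes of the pixel-centre coordinates (the
    orthogonal regression line and its normal); σ are the standard
    deviations of the coordinates projected on them. Dimensionless, so
    the calibration cancels.

    Raises
    ------
    DegenerateObjectError
        If fewer than 3 pixels, or the transversal deviation vanishes
        (e.g. a one-pixel-wide straight line).
    """
    pts = mask.pixels.astype(float)
    if pts.shape[0] < 3:
        raise DegenerateObjectError("elongation needs at least 3 pixels")
    centred = pts - pts.mean(axis=0)
    cov = centred.T @ centred / pts.shape[0]
    evals = np.linalg.eigvalsh(cov)  # ascending
    if evals[0] <= _DEGENERATE_VAR:
        raise DegenerateObjectError(
            "transversal deviation vanishes; elongation undefined"
        )
    return float(evals[1] / evals[0])


def solidity(mask: ObjectMask) -> float:
    """Solidity S (= roughness R): object area over convex-hull area.

    Both areas use the pixel-square convention, so S is dimensionless and
    lies in (0, 1] up to rasterisation tolerance.
    """
    hull_area = _hull(mask).volume  # 2-D ConvexHull: volume == area
    return float(mask.n_pixels / hull_area)


def max_diameter(mask: ObjectMask) -> float:
    """Maximum Feret diameter D in µm.

    The largest pairwise distance between the convex-hull vertices of the
    pixel-square corners, scaled by the calibration. A single pixel has
    D = calibration·√2.
    """
    hull = _hull(mask)
    verts = hull.points[hull.vertices]
    diff = verts[:, None, :] - verts[None, :, :]
    d = np.sqrt((diff**2).sum(axis=-1)).max()
    return float(d * mask.calibration_um_per_px)


def morphology_number(A: float, S: float, D: float, E: float) -> float:
    """Morphology number Mo = 2·√A·S / (√π·D·E).

    Validates its inputs (A, D > 0; S ∈ (0, 1]; E ≥ 1, each up to the
    rasterisation tolerance) and the output bound Mo ≤ 1 + tolerance.
    A value beyond the bound indicates a descriptor bug upstream, so it
    raises rather than clamps.
    """
    if not A > 0 or not D > 0:
        raise ValueError("projected area and maximum diameter must be positive")
    if not 0 < S <= 1 + RASTER_TOL:
        raise ValueError(f"solidity {S!r} outside (0, 1 + {RASTER_TOL}]")
    if E < 1 - RASTER_TOL:
        raise ValueError(f"elongation {E!r} below 1")
    mo = 2.0 * math.sqrt(A) * S / (math.sqrt(math.pi) * D * E)
    if mo > 1 + RASTER_TOL:
        raise ValueError(
            f"morphology number {mo:.4f} exceeds 1 beyond rasterisation "
            "tolerance; descriptor inputs are inconsistent"
        )
    return mo


@dataclass(frozen=True)
class ClassThresholds:
    """Area thresholds (µm²) of the morphological-group decision rule.

    The study reports group ranges (clumps/hyphae ≤ 164 µm², pellets
    10⁴–10⁶ µm²) but no decision rule; these defaults place the
    pellet/clump boundary in the geometric gap between the groups, with
    the boundary inclusive on the clump side. Spores are recognised only
    at inoculation time (0 h), below a small-area cap; anything under the
    debris floor is labelled debris.
    """

    debris_floor_um2: float = 20.0
    spore_cap_um2: float = 300.0
    pellet_boundary_um2: float = 1000.0


@dataclass(frozen=True)
class MorphoRecord:
    """Per-object morphometric record: A, E, S (= R), D, Mo plus class."""

    object_id: int
    A: float
    E: float
    S: float
    D: float
    Mo: float
    class_label: str
    time_h: float = 0.0
    talc_g_per_l: float = 0.0
    image_id: str = ""

    def as_dict(self) -> dict:
        return {
            "image_id": self.image_id,
            "object_id": self.object_id,
            "time_h": self.time_h,
            "talc_g_per_L": self.talc_g_per_l,
            "A_um2": self.A,
            "E": self.E,
            "S": self.S,
            "D_um": self.D,
            "Mo": self.Mo,
            "class": self.class_label,
        }


def classify(
    record: "MorphoRecord | float",
    time_h: float,
    thresholds: ClassThresholds = ClassThresholds(),
) -> str:
    """Assign a morphological group from projected area and sampling time.

    Accepts a :class:`MorphoRecord` or a bare projected area in µm².
    Every object receives a label: ``debris`` below the floor; ``spore``
    for small objects at 0 h; otherwise ``clump_hyphae`` up to and
    including the pellet boundary and ``pellet`` above it.
    """
    A = record.A if isinstance(record, MorphoRecord) else float(record)
    if A < thresholds.debris_floor_um2:
        return "debris"
    if time_h == 0 and A <= thresholds.spore_cap_um2:
        return "spore"
    if A <= thresholds.pellet_boundary_um2:
        return "clump_hyphae"
    return "pellet"


def measure(
    mask: ObjectMask,
    time_h: float = 0.0,
    talc_g_per_l: float = 0.0,
    image_id: str = "",
    thresholds: ClassThresholds = ClassThresholds(),
) -> MorphoRecord:
    """Run the full descriptor chain on one mask and classify the object."""
    A = projected_area(mask)
    E = elongation(mask)
    S = solidity(mask)
    D = max_diameter(mask)
    Mo = morphology_number(A, S, D, E)
    return MorphoRecord(
        object_id=mask.object_id,
        A=A, E=E, S=S, D=D, Mo=Mo,
        class_label=classify(A, time_h, thresholds),
        time_h=time_h,
        talc_g_per_l=talc_g_per_l,
        image_id=image_id,
    )


@dataclass(frozen=True)
class GroupSummary:
    """Mean/SD/confidence-band summary of one morphological group.

    ``sufficient_n`` is true when the group holds at least 30 objects,
    the sample size the study treats as adequate for group means.
    """

    class_label: str
    time_h: float
    talc_g_per_l: float
    n: int
    stats: dict[str, SampleSummary]
    sufficient_n: bool

    def as_dict(self) -> dict:
        row = {
            "class": self.class_label,
            "time_h": self.time_h,
            "talc_g_per_L": self.talc_g_per_l,
            "n": self.n,
            "sufficient_n": self.sufficient_n,
        }
        for p, s in self.stats.items():
            row[f"{p}_mean"] = s.mean
            row[f"{p}_sd"] = s.sd if s.sd is not None else np.nan
            row[f"{p}_ci_lo"] = s.ci_low if s.ci_low is not None else np.nan
            row[f"{p}_ci_hi"] = s.ci_high if s.ci_high is not None else np.nan
        return row


MIN_GROUP_N = 30


def summarize(
    records: Iterable[MorphoRecord],
    class_label: str,
    time_h: float,
    talc_g_per_l: float,
    alpha: float = 0.05,
) -> GroupSummary:
    """Summarise A, E, S, D, Mo over the records matching one group.

    Raises on an empty group; a single object yields means with SD and
    band unavailable.
    """
    group = [
        r
        for r in records
        if r.class_label == class_label
        and r.time_h == time_h
        and r.talc_g_per_l == talc_g_per_l
    ]
    if not group:
        raise ValueError(
            f"no records for class={class_label!r} t={time_h} talc={talc_g_per_l}"
        )
    stats = {
        p: mean_sd_ci([getattr(r, p) for r in group], alpha=alpha) for p in PARAMETERS
    }
    return GroupSummary(
        class_label=class_label,
        time_h=time_h,
        talc_g_per_l=talc_g_per_l,
        n=len(group),
        stats=stats,
        sufficient_n=len(group) >= MIN_GROUP_N,
    )
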