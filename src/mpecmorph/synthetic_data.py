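"""Synthetic microscopy scenes and culture time series with known ground truth.

No raw images or chromatograms are distributed with morphology studies of
this kind, so every downstream stage is exercised on generated data whose
truth is known by construction. The generator emulates the statistical
structure of a talc microparticle-enhanced *Streptomyces* cultivation:

* images contain spores (small disks, present at 0 h), pellets (large
  star-convex blobs whose boundary roughness and elongation can be dialed
  up to mimic the talc dose response), clumps/hyphae (thin, possibly
  branched filaments with projected area below the ~164 µm² cap observed
  for that group), and optional 10 µm talc disks as segmentation
  distractors — all rendered dark on a bright, phase-contrast-like
  background with additive Gaussian noise;
* replicate time series follow the study layout (five sampling times
  0–96 h every 24 h, four replicates, talc at 0/0.5/5/10/12 g L⁻¹) with
  multiplicative lognormal replicate noise on metabolite amounts and a
  per-condition monotone glucose depletion curve from 22 g L⁻¹.

Every output is a pure function of (spec, seed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import tifffile

from .containers import CalibratedImage, ObjectMask
from .metabolics import CultureTimeSeries

__all__ = [
    "SceneSpec",
    "ObjectTruth",
    "SceneGroundTruth",
    "TimeSeriesSpec",
    "make_pellet_mask",
    "make_filament_mask",
    "make_scene",
    "make_timeseries",
    "random_mask_suite",
    "write_scene",
    "DEFAULT_METABOLITES",
    "DEFAULT_CONDITIONS",
    "DEFAULT_TIMES",
]

DEFAULT_CONDITIONS = (0.0, 0.5, 5.0, 10.0, 12.0)
DEFAULT_TIMES = (0.0, 24.0, 48.0, 72.0, 96.0)
DEFAULT_METABOLITES = (
    "oxytetracycline",
    "2-acetyl-2-decarboxamido-oxytetracycline",
    "rimocidin",
    "rimocidin CE108",
    "rimocidin (27-ethyl)",
    "milbemycin A3+4[O]",
    "milbemycin b11+4[O]",
)

_TALC_DIAMETER_UM = 10.0  # manufacturer mean particle diameter


# ---------------------------------------------------------------------------
# Scene specification and ground truth

@dataclass(frozen=True)
class SceneSpec:
    """Parameters of one synthetic scene.

    Shape-parameter ranges are (low, high) tuples sampled uniformly per
    object. Defaults keep generated pellets inside the 10⁴–10⁶ µm²
    projected-area band and clumps/hyphae below 164 µm², the group
    ranges observed for *S. rimosus*.
    """

    image_shape: tuple[int, int] = (1024, 1024)
    calibration_um_per_px: float = 1.0
    time_h: float = 24.0
    talc_g_per_l: float = 0.0
    n_spores: int = 0
    n_pellets: int = 3
    n_clumps: int = 6
    n_talc: int = 0
    spore_radius_um: tuple[float, float] = (3.0, 6.0)
    pellet_radius_um: tuple[float, float] = (60.0, 250.0)
    pellet_roughness: tuple[float, float] = (0.05, 0.25)
    pellet_aspect: tuple[float, float] = (1.0, 2.5)
    clump_length_um: tuple[float, float] = (15.0, 38.0)
    clump_width_um: tuple[float, float] = (1.8, 2.6)
    branch_probability: float = 0.2
    background: float = 0.85
    object_intensity: float = 0.35
    talc_intensity: float = 0.15
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.calibration_um_per_px > 0:
            raise ValueError("calibration must be positive")
        for name in ("n_spores", "n_pellets", "n_clumps", "n_talc"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.pellet_aspect[0] < 1:
            raise ValueError("pellet aspect ratio must be >= 1")
        if not 0 <= self.pellet_roughness[0] <= self.pellet_roughness[1] < 1:
            raise ValueError("roughness amplitude must lie in [0, 1)")
        if not 0 <= self.branch_probability <= 1:
            raise ValueError("branch probability must lie in [0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise sd must be >= 0")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["image_shape"] = list(self.image_shape)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SceneSpec":
        d = dict(d)
        for key, val in d.items():
            if isinstance(val, list):
                d[key] = tuple(val)
        return cls(**d)


@dataclass(frozen=True)
class ObjectTruth:
    """Generator-side truth for one rendered object."""

    object_id: int
    class_label: str  # spore | pellet | clump_hyphae | talc
    true_area_um2: float
    true_aspect_ratio: float
    centroid_rc: tuple[float, float]


@dataclass(frozen=True)
class SceneGroundTruth:
    objects: tuple[ObjectTruth, ...]
    spec: SceneSpec

    def of_class(self, label: str) -> list[ObjectTruth]:
        return [o for o in self.objects if o.class_label == label]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "object_id": o.object_id,
                    "class": o.class_label,
                    "true_area_um2": o.true_area_um2,
                    "true_aspect_ratio": o.true_aspect_ratio,
                    "centroid_row": o.centroid_rc[0],
                    "centroid_col": o.centroid_rc[1],
                }
                for o in self.objects
            ]
        )


# ---------------------------------------------------------------------------
# Mask generators

def _pellet_radial(rng: np.random.Generator, amplitude: float):
    """Periodic radial perturbation r(θ)/r0 = 1 + a·f(θ).

    f is a sum of low-order harmonics (k = 2..6) with random amplitudes
    and phases, normalised to max |f| = 1 so the radius stays positive
    for any amplitude < 1.
    """
    orders = np.arange(2, 7)
    coeff = rng.normal(size=orders.size)
    phase = rng.uniform(0, 2 * np.pi, size=orders.size)

    def f(theta: np.ndarray) -> np.ndarray:
        return np.sum(
            coeff[:, None] * np.cos(orders[:, None] * theta[None, :] + phase[:, None]),
            axis=0,
        )

    dense = np.linspace(0, 2 * np.pi, 720, endpoint=False)
    norm = np.abs(f(dense)).max()
    if norm == 0 or amplitude == 0:
        return (lambda theta: np.ones_like(theta)), 1.0
    a = amplitude

    def radial(theta: np.ndarray) -> np.ndarray:
        return 1.0 + a * f(theta) / norm

    # analytic area factor: area = r0² · ½∫(r/r0)² dθ / π · π = r0²·mean(radial²)·π
    area_factor = float(np.mean(radial(dense) ** 2))
    return radial, area_factor


def _make_pellet(
    radius_um: float,
    roughness_amplitude: float,
    aspect_ratio: float,
    calibration: float,
    seed: int,
) -> tuple[ObjectMask, float]:
    """Build a pellet mask; returns (mask, analytic area in µm²)."""
    if radius_um <= 0:
        raise ValueError("pellet radius must be positive")
    if not 0 <= roughness_amplitude < 1:
        raise ValueError("roughness amplitude must lie in [0, 1)")
    if aspect_ratio < 1:
        raise ValueError("aspect ratio must be >= 1")
    r0 = radius_um / calibration
    if r0 < 1:
        raise ValueError("pellet radius below one pixel at this calibration")
    rng = np.random.default_rng(seed)
    radial, area_factor = _pellet_radial(rng, roughness_amplitude)
    phi = rng.uniform(0, 2 * np.pi)  # scene orientation
    sx = math.sqrt(aspect_ratio)
    sy = 1.0 / sx
    half = int(math.ceil(r0 * (1 + roughness_amplitude) * sx)) + 1
    ax = np.arange(-half, half + 1, dtype=float)
    x, y = np.meshgrid(ax, ax)  # x: col, y: row
    if roughness_amplitude == 0 and aspect_ratio == 1:
        phi = 0.0  # rotating a disk only shuffles boundary rounding
    cp, sp = math.cos(phi), math.sin(phi)
    u = (cp * x + sp * y) / sx
    v = (-sp * x + cp * y) / sy
    theta = np.arctan2(v, u)
    rho = np.hypot(u, v)
    inside = rho <= r0 * radial(theta.ravel()).reshape(theta.shape)
    rr, cc = np.nonzero(inside)
    mask = ObjectMask(
        pixels=np.column_stack((rr, cc)), calibration_um_per_px=calibration
    )
    true_area = math.pi * radius_um**2 * area_factor  # stretch preserves area
    return mask, true_area


def make_pellet_mask(
    radius_um: float,
    roughness_amplitude: float,
    aspect_ratio: float,
    calibration: float,
    seed: int,
) -> ObjectMask:
    """Connected pellet mask with a periodic rough boundary.

    With zero roughness and aspect ratio 1 this is a rasterised disk of
    the given radius. The boundary perturbation is a seed-reproducible
    sum of low-order harmonics; the aspect stretch preserves area.
    """
    mask, _ = _make_pellet(radius_um, roughness_amplitude, aspect_ratio, calibration, seed)
    return mask


def _stamp_offsets(radius_px: float) -> np.ndarray:
    r = max(int(math.floor(radius_px)), 0)
    ax = np.arange(-r, r + 1)
    dx, dy = np.meshgrid(ax, ax)
    inside = dx**2 + dy**2 <= radius_px**2
    return np.column_stack((dy[inside], dx[inside]))  # (row, col)


def _filament_path(
    length_px: float, rng: np.random.Generator, max_tries: int = 20
) -> np.ndarray:
    """Gently curved polyline of total arc length length_px.

    Heading drift is kept small enough that the chord (end-to-end
    distance) stays above 0.82·length, retrying with fresh draws in the
    rare case it does not.
    """
    n = max(int(length_px / 0.4), 8)
    step = length_px / n
    for _ in range(max_tries):
        theta0 = rng.uniform(0, 2 * np.pi)
        turns = rng.normal(0.0, 0.25 / math.sqrt(n), size=n)
        headings = theta0 + np.cumsum(turns)
        dx = step * np.cos(headings)
        dy = step * np.sin(headings)
        pts = np.column_stack((np.cumsum(dy), np.cumsum(dx)))
        pts = np.vstack(([[0.0, 0.0]], pts))
        if np.hypot(*(pts[-1] - pts[0])) >= 0.82 * length_px:
            return pts
    raise RuntimeError("could not draw a sufficiently straight filament path")


def make_filament_mask(
    length_um: float,
    width_um: float,
    branch_probability: float,
    calibration: float,
    seed: int,
) -> ObjectMask:
    """Connected filament (hypha/clump) mask.

    A gently curved main path of the given arc length is stamped with a
    disk of diameter ``width_um``; with probability
    ``branch_probability`` one short side branch (15–25% of the main
    length) is attached at an interior point. The maximum diameter of
    the result is at least 0.8·length (curvature allowance).
    """
    if not length_um >= width_um > 0:
        raise ValueError("need length >= width > 0")
    if not 0 <= branch_probability <= 1:
        raise ValueError("branch probability must lie in [0, 1]")
    length_px = length_um / calibration
    width_px = width_um / calibration
    if width_px < 1:
        raise ValueError("filament width below one pixel at this calibration")
    rng = np.random.default_rng(seed)
    pts = _filament_path(length_px, rng)
    paths = [pts]
    if rng.uniform() < branch_probability:
        i = rng.integers(pts.shape[0] // 4, 3 * pts.shape[0] // 4)
        base = pts[i]
        heading = math.atan2(*(pts[i + 1] - pts[i - 1]))
        side = rng.choice([-1.0, 1.0])
        ang = heading + side * rng.uniform(math.radians(40), math.radians(70))
        blen = rng.uniform(0.15, 0.25) * length_px
        nb = max(int(blen / 0.4), 4)
        s = np.linspace(0, blen, nb)
        branch = base + np.column_stack((s * math.sin(ang), s * math.cos(ang)))
        paths.append(branch)
    allpts = np.vstack(paths)
    offsets = _stamp_offsets(width_px / 2.0)
    centers = np.rint(allpts).astype(np.int64)
    stamped = (centers[:, None, :] + offsets[None, :, :]).reshape(-1, 2)
    stamped -= stamped.min(axis=0)
    pix = np.unique(stamped, axis=0)
    return ObjectMask(pixels=pix, calibration_um_per_px=calibration)


# ---------------------------------------------------------------------------
# Scene assembly

def _place(
    occupancy: np.ndarray,
    mask: ObjectMask,
    rng: np.random.Generator,
    max_tries: int = 100,
) -> tuple[int, int] | None:
    """Find a non-overlapping offset for a mask; None if placement fails."""
    H, W = occupancy.shape
    rmin, cmin, rmax, cmax = mask.bounding_box()
    h, w = rmax - rmin + 1, cmax - cmin + 1
    if h + 2 >= H or w + 2 >= W:
        return None
    local = mask.pixels - np.array([rmin, cmin])
    for _ in range(max_tries):
        r0 = int(rng.integers(1, H - h - 1))
        c0 = int(rng.integers(1, W - w - 1))
        rr = local[:, 0] + r0
        cc = local[:, 1] + c0
        if not occupancy[rr, cc].any():
            return r0 - rmin, c0 - cmin
    return None


def _occupy(occupancy: np.ndarray, pixels: np.ndarray, margin: int = 2) -> None:
    """Mark pixels (with a dilation margin) as occupied."""
    H, W = occupancy.shape
    for dr in range(-margin, margin + 1):
        for dc in range(-margin, margin + 1):
            rr = np.clip(pixels[:, 0] + dr, 0, H - 1)
            cc = np.clip(pixels[:, 1] + dc, 0, W - 1)
            occupancy[rr, cc] = True


def make_scene(spec: SceneSpec) -> tuple[CalibratedImage, SceneGroundTruth]:
    """Render one scene and its per-object ground truth.

    Objects are generated class by class (pellets, clumps, spores, talc)
    and placed without overlap by bounded rejection sampling; a spec
    whose objects cannot fit raises, naming the class and how many were
    placed. Identical spec (including seed) yields bit-identical output.
    """
    rng = np.random.default_rng(spec.seed)
    cal = spec.calibration_um_per_px
    H, W = spec.image_shape
    occupancy = np.zeros((H, W), dtype=bool)
    image = np.full((H, W), float(spec.background))
    truths: list[ObjectTruth] = []
    oid = 0

    def add(mask: ObjectMask, label: str, true_area: float, aspect: float, intensity: float):
        nonlocal oid
        offset = _place(occupancy, mask, rng)
        if offset is None:
            raise RuntimeError(
                f"could not place {label} object after bounded retries "
                f"({len(truths)} objects placed so far)"
            )
        placed = mask.translated(*offset)
        _occupy(occupancy, placed.pixels)
        oid += 1
        jitter = float(rng.normal(0, 0.02))
        image[placed.pixels[:, 0], placed.pixels[:, 1]] = np.clip(
            intensity + jitter, 0.0, 1.0
        )
        centroid = placed.pixels.mean(axis=0)
        truths.append(
            ObjectTruth(
                object_id=oid,
                class_label=label,
                true_area_um2=true_area,
                true_aspect_ratio=aspect,
                centroid_rc=(float(centroid[0]), float(centroid[1])),
            )
        )

    for _ in range(spec.n_pellets):
        radius = rng.uniform(*spec.pellet_radius_um)
        rough = rng.uniform(*spec.pellet_roughness)
        aspect = rng.uniform(*spec.pellet_aspect)
        child = int(rng.integers(2**31))
        mask, true_area = _make_pellet(radius, rough, aspect, cal, child)
        add(mask, "pellet", true_area, aspect, spec.object_intensity)

    for _ in range(spec.n_clumps):
        length = rng.uniform(*spec.clump_length_um)
        width = rng.uniform(*spec.clump_width_um)
        child = int(rng.integers(2**31))
        mask = make_filament_mask(length, width, spec.branch_probability, cal, child)
        # thin rasterised filaments have no closed analytic area; the
        # rendered pixel area is the truth used to score segmentation
        add(mask, "clump_hyphae", mask.n_pixels * cal**2, length / width,
            spec.object_intensity)

    for _ in range(spec.n_spores):
        radius = rng.uniform(*spec.spore_radius_um)
        child = int(rng.integers(2**31))
        mask, true_area = _make_pellet(radius, 0.0, 1.0, cal, child)
        add(mask, "spore", true_area, 1.0, spec.object_intensity)

    talc_r = _TALC_DIAMETER_UM / 2.0
    for _ in range(spec.n_talc):
        child = int(rng.integers(2**31))
        mask, true_area = _make_pellet(talc_r, 0.0, 1.0, cal, child)
        add(mask, "talc", true_area, 1.0, spec.talc_intensity)

    if spec.noise_sd > 0:
        image = image + rng.normal(0.0, spec.noise_sd, size=image.shape)
    image = np.clip(image, 0.0, 1.0)

    cimg = CalibratedImage(
        data=image,
        calibration_um_per_px=cal,
        time_h=spec.time_h,
        talc_g_per_l=spec.talc_g_per_l,
        image_id=f"scene_t{spec.time_h:g}_talc{spec.talc_g_per_l:g}_s{spec.seed}",
    )
    return cimg, SceneGroundTruth(objects=tuple(truths), spec=spec)


def write_scene(
    image: CalibratedImage, truth: SceneGroundTruth, out_dir: str | Path
) -> tuple[Path, Path]:
    """Write a 16-bit grayscale TIFF and the ground-truth CSV."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    tif = out_dir / f"{image.image_id}.tiff"
    tifffile.imwrite(tif, np.round(image.data * 65535).astype(np.uint16))
    csv = out_dir / f"{image.image_id}_truth.csv"
    truth.to_frame().to_csv(csv, index=False)
    return tif, csv


# ---------------------------------------------------------------------------
# Randomised mask suite (for shape-descriptor bound checks)

def random_mask_suite(
    n_masks: int = 500, calibration: float = 1.0, seed: int = 0
) -> list[ObjectMask]:
    """Seeded suite of masks spanning the generator's shape repertoire.

    Cycles through four families — plain disks, smooth ellipses,
    rough-boundary (possibly elongated) pellets, and branched filaments —
    with parameters drawn across the full default ranges. Used to probe
    descriptor bounds (e.g. 0 < Mo ≤ 1) over diverse shapes.
    """
    rng = np.random.default_rng(seed)
    masks: list[ObjectMask] = []
    while len(masks) < n_masks:
        child = int(rng.integers(2**31))
        family = len(masks) % 4
        if family == 0:  # disk
            r = rng.uniform(5, 80)
            masks.append(make_pellet_mask(r, 0.0, 1.0, calibration, child))
        elif family == 1:  # ellipse
            r = rng.uniform(5, 80)
            aspect = rng.uniform(1.0, 3.0)
            masks.append(make_pellet_mask(r, 0.0, aspect, calibration, child))
        elif family == 2:  # rough pellet
            r = rng.uniform(10, 120)
            rough = rng.uniform(0.05, 0.3)
            aspect = rng.uniform(1.0, 2.5)
            masks.append(make_pellet_mask(r, rough, aspect, calibration, child))
        else:  # filament
            length = rng.uniform(15, 120)
            width = rng.uniform(2.0, 4.0)
            branch = rng.uniform(0.0, 0.5)
            masks.append(
                make_filament_mask(length, width, branch, calibration, child)
            )
    return masks


# ---------------------------------------------------------------------------
# Time-series generator

def _default_ef_table() -> dict[str, dict[float, float]]:
    """Peak enhancement factor (reached at 72/96 h) per metabolite/condition.

    Stated peaks follow the reported dose response (oxytetracycline up to
    9-fold at 5 g/L talc, its 2-acetyl-2-decarboxamido derivative up to
    7-fold, milbemycin A3+4[O] above 3-fold at 10 g/L, rimocidin CE108 up
    to 1.5-fold, rimocidin unchanged, the remaining two suppressed);
    intermediate conditions are filled with modest plausible values.
    """
    return {
        "oxytetracycline": {0.5: 2.0, 5.0: 9.0, 10.0: 3.0, 12.0: 2.5},
        "2-acetyl-2-decarboxamido-oxytetracycline": {0.5: 1.8, 5.0: 7.0, 10.0: 2.5, 12.0: 2.0},
        "rimocidin": {0.5: 1.0, 5.0: 1.0, 10.0: 1.0, 12.0: 1.0},
        "rimocidin CE108": {0.5: 1.1, 5.0: 1.2, 10.0: 1.5, 12.0: 1.3},
        "rimocidin (27-ethyl)": {0.5: 0.9, 5.0: 0.7, 10.0: 0.6, 12.0: 0.6},
        "milbemycin A3+4[O]": {0.5: 1.2, 5.0: 1.5, 10.0: 3.2, 12.0: 2.0},
        "milbemycin b11+4[O]": {0.5: 0.9, 5.0: 0.8, 10.0: 0.7, 12.0: 0.7},
    }


def _default_control_means() -> dict[str, tuple[float, ...]]:
    """Control-run mean amount per metabolite over the default time grid.

    Oxytetracycline in mg L⁻¹ (reaching the reported ~0.7 mg L⁻¹ control
    level by 72 h); the others are ion-peak areas in arbitrary units with
    a generic late-rising production profile.
    """
    generic = (0.5, 2.0, 15.0, 45.0, 50.0)
    table = {m: generic for m in DEFAULT_METABOLITES}
    table["oxytetracycline"] = (0.01, 0.05, 0.3, 0.7, 0.7)
    table["2-acetyl-2-decarboxamido-oxytetracycline"] = (0.5, 2.0, 15.0, 40.0, 42.0)
    return table


def _default_glucose_params() -> dict[float, tuple[float, float]]:
    """(final concentration g/L, power-law exponent) per talc condition.

    Finals follow the reported 96 h concentrations. Exponents give the
    qualitative dose response — the control and 0.5 g/L runs consume
    glucose late and fast (cubic depletion), the talc-slowed runs are
    near-linear — while keeping the curves smooth enough that a cubic
    spline through the 24 h sampling grid stays monotone.
    """
    return {
        0.0: (7.45, 3.0),
        0.5: (7.47, 3.0),
        5.0: (10.56, 1.2),
        10.0: (10.95, 1.1),
        12.0: (11.44, 1.0),
    }


@dataclass(frozen=True)
class TimeSeriesSpec:
    """Design of the synthetic cultivation time series.

    ``ef_table`` holds the true peak enhancement factor per metabolite
    and condition, reached at 72 h and held to 96 h (EF ramps from 1
    before 48 h through the midpoint at 48 h). ``cv`` is the replicate
    coefficient of variation of the multiplicative lognormal noise on
    amounts. Glucose depletes from ``glucose_initial`` along a
    per-condition power law; ``glucose_noise_sd`` is additive (g L⁻¹),
    clipped at zero.
    """

    metabolites: tuple[str, ...] = DEFAULT_METABOLITES
    conditions: tuple[float, ...] = DEFAULT_CONDITIONS
    times_h: tuple[float, ...] = DEFAULT_TIMES
    replicates: int = 4
    ef_table: dict[str, dict[float, float]] = field(default_factory=_default_ef_table)
    control_means: dict[str, tuple[float, ...]] = field(default_factory=_default_control_means)
    cv: float = 0.15
    glucose_initial: float = 22.0
    glucose_params: dict[float, tuple[float, float]] = field(default_factory=_default_glucose_params)
    glucose_noise_sd: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.replicates < 1:
            raise ValueError("need at least one replicate")
        if self.cv < 0:
            raise ValueError("CV must be >= 0")
        for m in self.metabolites:
            means = np.asarray(self.control_means[m], dtype=float)
            if means.shape != (len(self.times_h),) or np.any(means <= 0):
                raise ValueError(f"control means for {m!r} must be positive per time")
            for cond, peak in self.ef_table.get(m, {}).items():
                if peak <= 0:
                    raise ValueError(f"true EF for {m!r} at {cond} g/L must be > 0")

    def true_ef(self, condition: float, metabolite: str, time_h: float) -> float:
        """Noise-free EF at a given condition/metabolite/time."""
        if condition == 0.0:
            return 1.0
        peak = self.ef_table.get(metabolite, {}).get(condition, 1.0)
        if time_h < 48.0:
            return 1.0
        if time_h < 72.0:
            return 1.0 + 0.5 * (peak - 1.0)
        return peak

    def glucose_curve(self, condition: float, times: np.ndarray) -> np.ndarray:
        """Noise-free, non-increasing glucose concentration (g L⁻¹)."""
        final, p = self.glucose_params.get(condition, (self.glucose_initial / 2, 1.5))
        tmax = max(self.times_h)
        frac = np.clip(np.asarray(times, dtype=float) / tmax, 0.0, 1.0)
        return self.glucose_initial - (self.glucose_initial - final) * frac**p


def make_timeseries(spec: TimeSeriesSpec) -> list[CultureTimeSeries]:
    """Generate the full replicate collection for all conditions.

    Each amount is ``control mean × true EF × lognormal multiplier``
    where the multiplier has unit mean and the stated CV, so the
    expected treatment/control ratio of means equals the true EF.
    Glucose gets additive Gaussian noise, clipped at zero.
    """
    rng = np.random.default_rng(spec.seed)
    times = np.asarray(spec.times_h, dtype=float)
    if spec.cv > 0:
        sigma = math.sqrt(math.log(1.0 + spec.cv**2))
        mu = -0.5 * sigma**2
    else:
        sigma = mu = 0.0
    out: list[CultureTimeSeries] = []
    for cond in spec.conditions:
        clean_glu = spec.glucose_curve(cond, times)
        for rep in range(1, spec.replicates + 1):
            amounts = {}
            for m in spec.metabolites:
                base = np.asarray(spec.control_means[m], dtype=float)
                ef = np.array([spec.true_ef(cond, m, t) for t in times])
                noise = (
                    np.exp(rng.normal(mu, sigma, size=times.size))
                    if sigma > 0
                    else np.ones(times.size)
                )
                amounts[m] = base * ef * noise
            glu = clean_glu + (
                rng.normal(0.0, spec.glucose_noise_sd, size=times.size)
                if spec.glucose_noise_sd > 0
                else 0.0
            )
            out.append(
                CultureTimeSeries(
                    talc_g_per_l=cond,
                    replicate=rep,
                    times_h=times,
                    amounts=amounts,
                    glucose_g_per_l=np.clip(glu, 0.0, None),
                )
            )
    return out
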