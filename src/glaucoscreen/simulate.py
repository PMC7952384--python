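"""Synthetic optic-nerve-head simulator with rule-based GON grades.

Generates seeded fundus-like images of the optic nerve head together with
exact ground-truth masks (optic disc, optic cup, RNFL defect wedges) and a
glaucomatous-optic-neuropathy (GON) grade derived from the generative
parameters by the clinical grading rules (unlikely / probable / definite,
with referable = probable-or-definite).

The generative model is deliberately minimal: an elliptical disc, a cup
bounded by an analytic 360-degree cup-to-disc ratio (CDR) profile, optional
rim defects (localized notches, localized or general rim thinning), optional
wedge-shaped RNFL defects radiating from the disc, and optional distractors
(peripapillary atrophy, disc hemorrhage).  Normal eyes receive an
ISNT-conforming rim: the CDR profile dips most deeply at the inferior pole,
next at the superior pole, and is highest temporally, giving the bimodal
profile shape typical of healthy rims.

Geometry is defined on a canonical 512x512 canvas in the canonical
right-eye frame (0 deg = superior, clockwise, 90 deg = nasal); rendering at
other canvas sizes rescales, and left eyes are mirrored at render time.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.ndimage import gaussian_filter

from .geometry import MaskSet

__all__ = [
    "GRADE_CATEGORIES",
    "GONGrade",
    "RimDefect",
    "Wedge",
    "EyeTruth",
    "RenderConfig",
    "EyeRecord",
    "Cohort",
    "grade_gon",
    "sample_eye_truth",
    "render_eye",
    "generate_dataset",
]

GRADE_CATEGORIES = ("unlikely", "probable", "definite")

#: canonical canvas edge, pixels
CANONICAL_CANVAS = 512

#: rim-ratio dip depth that qualifies as a localized notch (definite GON)
NOTCH_DEPTH = 0.15

#: rim-ratio dip depth that qualifies as rim thinning (probable GON)
THINNING_DEPTH = 0.10

#: angular width below which a rim defect counts as localized, degrees
LOCALIZED_WIDTH = 60.0

#: clock-hour sectors in which localized thinning is a probable-GON sign:
#: 11-to-1 o'clock (superior) and 5-to-7 o'clock (inferior)
SUPERIOR_SECTOR = (330.0, 30.0)
INFERIOR_SECTOR = (150.0, 210.0)

#: RNFLD wedges extend radially from the disc edge out to this multiple
WEDGE_OUTER_SCALE = 2.2


def _ang_diff(theta: np.ndarray | float, center: float) -> np.ndarray | float:
    """Signed circular difference theta - center wrapped to [-180, 180)."""
    return (np.asarray(theta, float) - center + 180.0) % 360.0 - 180.0


def _in_sector(angle: float, sector: tuple[float, float]) -> bool:
    lo, hi = sector
    a = angle % 360.0
    if lo <= hi:
        return lo <= a <= hi
    return a >= lo or a <= hi


def _bump(theta, center: float, width: float):
    """Raised-cosine bump of unit height centred at ``center`` (degrees)."""
    d = _ang_diff(theta, center)
    inside = np.abs(d) < width / 2.0
    return np.where(inside, 0.5 * (1.0 + np.cos(2.0 * np.pi * d / width)), 0.0)


@dataclass(frozen=True)
class GONGrade:
    """GON grade category with its referability flag."""

    category: str

    def __post_init__(self) -> None:
        if self.category not in GRADE_CATEGORIES:
            raise ValueError(f"unknown GON grade category {self.category!r}")

    @property
    def referable(self) -> bool:
        return self.category in ("probable", "definite")


@dataclass(frozen=True)
class RimDefect:
    """A localized elevation of the CDR profile (a rim-width dip).

    width < 60 deg with depth >= NOTCH_DEPTH is a localized notch;
    shallower localized dips model focal rim thinning, and widths >= 60 deg
    model general rim thinning.
    """

    center_deg: float
    width_deg: float
    depth: float


@dataclass(frozen=True)
class Wedge:
    """A wedge-shaped RNFL defect radiating from the disc margin."""

    center_deg: float
    width_deg: float
    present: bool = True


@dataclass(frozen=True)
class EyeTruth:
    """Generative parameters of one synthetic eye plus derived ground truth.

    The CDR profile is ``base_level`` plus ISNT dips (superior, inferior)
    and a temporal boost, plus the defect bumps, clipped to [0, 1].
    ``vcdr_true`` is derived from the final profile as the mean of its
    values at the superior (0 deg) and inferior (180 deg) poles, which
    equals the vertical extent ratio of the implied cup and disc.
    """

    disc_center: tuple[float, float]  # (row, col) on the canonical canvas
    disc_radii: tuple[float, float]  # (a horizontal, b vertical) semi-axes
    base_level: float
    dip_superior: tuple[float, float]  # (depth, width deg)
    dip_inferior: tuple[float, float]
    boost_temporal: tuple[float, float]
    defects: tuple[RimDefect, ...] = ()
    rnfld_wedges: tuple[Wedge, ...] = ()
    hemorrhage: bool = False
    hemorrhage_angle: float = 45.0
    atrophy: bool = False
    laterality: str = "right"
    vcdr_true: float = field(init=False)
    grade: GONGrade = field(init=False)

    def __post_init__(self) -> None:
        if self.laterality not in ("left", "right"):
            raise ValueError("laterality must be 'left' or 'right'")
        a, b = self.disc_radii
        cy, cx = self.disc_center
        if min(cy - b, cx - a) < 10 or max(cy + b, cx + a) > CANONICAL_CANVAS - 10:
            raise ValueError("disc must fit inside the canonical canvas with >=10 px margin")
        vcdr = float((self.rim_profile(0.0) + self.rim_profile(180.0)) / 2.0)
        object.__setattr__(self, "vcdr_true", vcdr)
        object.__setattr__(self, "grade", grade_gon(self))

    def rim_profile(self, theta_deg):
        """Cup-to-disc radial ratio at angle(s) ``theta_deg`` (canonical frame)."""
        theta = np.asarray(theta_deg, dtype=float)
        value = np.full(theta.shape, self.base_level)
        d_s, w_s = self.dip_superior
        d_i, w_i = self.dip_inferior
        d_t, w_t = self.boost_temporal
        value = value - d_s * _bump(theta, 0.0, w_s) - d_i * _bump(theta, 180.0, w_i)
        value = value + d_t * _bump(theta, 270.0, w_t)
        for defect in self.defects:
            value = value + defect.depth * _bump(theta, defect.center_deg, defect.width_deg)
        return np.clip(value, 0.0, 1.0)

    @property
    def profile_360(self) -> np.ndarray:
        return self.rim_profile(np.arange(360.0))

    def with_base_level(self, base_level: float) -> "EyeTruth":
        """Same eye with the overall cup scale changed (all else fixed)."""
        return dataclasses.replace(self, base_level=base_level)


def grade_gon(truth: EyeTruth) -> GONGrade:
    """Apply the clinical GON grading rules to the generative parameters.

    definite: VCDR >= 0.85, or a localized notch (rim dip of depth >=
    NOTCH_DEPTH over < 60 deg, with or without a corresponding RNFL wedge).
    probable: 0.7 <= VCDR < 0.85; general rim thinning over >= 60 deg;
    localized rim thinning < 60 deg in the 11-1 or 5-7 o'clock sectors; any
    RNFL-defect wedge; or a disc hemorrhage.  Definite takes precedence.
    """
    vcdr = float((truth.rim_profile(0.0) + truth.rim_profile(180.0)) / 2.0)
    notch = any(
        d.width_deg < LOCALIZED_WIDTH and d.depth >= NOTCH_DEPTH for d in truth.defects
    )
    if vcdr >= 0.85 or notch:
        return GONGrade("definite")
    general_thinning = any(
        d.width_deg >= LOCALIZED_WIDTH and d.depth >= THINNING_DEPTH for d in truth.defects
    )
    localized_thinning = any(
        d.width_deg < LOCALIZED_WIDTH
        and d.depth >= THINNING_DEPTH
        and (_in_sector(d.center_deg, SUPERIOR_SECTOR) or _in_sector(d.center_deg, INFERIOR_SECTOR))
        for d in truth.defects
    )
    any_wedge = any(w.present for w in truth.rnfld_wedges)
    if (
        0.7 <= vcdr < 0.85
        or general_thinning
        or localized_thinning
        or any_wedge
        or truth.hemorrhage
    ):
        return GONGrade("probable")
    return GONGrade("unlikely")


@dataclass(frozen=True)
class RenderConfig:
    """Rendering parameters for :func:`render_eye`."""

    canvas_size: int = CANONICAL_CANVAS
    noise_sd: float = 5.0
    vessel_count: int = 6
    background_texture: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.canvas_size < 128:
            raise ValueError("canvas_size must be at least 128")


def _sample_geometry(rng: np.random.Generator) -> dict:
    a = rng.uniform(75.0, 105.0)
    b = a * rng.uniform(1.0, 1.15)
    cy = 256.0 + rng.uniform(-35.0, 35.0)
    cx = 256.0 + rng.uniform(-35.0, 35.0)
    return {"disc_center": (cy, cx), "disc_radii": (a, b)}


def _sample_isnt_shape(rng: np.random.Generator) -> dict:
    """ISNT-conforming rim shape terms: inferior dip deepest, temporal boost."""
    d_i = rng.uniform(0.10, 0.16)
    d_s = d_i * rng.uniform(0.55, 0.85)
    return {
        "dip_superior": (d_s, rng.uniform(120.0, 150.0)),
        "dip_inferior": (d_i, rng.uniform(120.0, 150.0)),
        "boost_temporal": (rng.uniform(0.03, 0.07), rng.uniform(80.0, 110.0)),
    }


def _sample_flat_shape(rng: np.random.Generator) -> dict:
    """Rim shape with the ISNT structure largely lost (glaucomatous habit)."""
    d_i = rng.uniform(0.0, 0.04)
    d_s = rng.uniform(0.0, 0.04)
    return {
        "dip_superior": (d_s, rng.uniform(120.0, 150.0)),
        "dip_inferior": (d_i, rng.uniform(120.0, 150.0)),
        "boost_temporal": (rng.uniform(0.0, 0.03), rng.uniform(80.0, 110.0)),
    }


def _base_for_vcdr(vcdr: float, shape: dict) -> float:
    # profile(0) = m - d_s, profile(180) = m - d_i (dips never overlap the
    # opposite pole, widths < 300 deg), so vcdr = m - (d_s + d_i)/2
    return vcdr + (shape["dip_superior"][0] + shape["dip_inferior"][0]) / 2.0


def _sample_defect(rng: np.random.Generator, *, localized: bool, depth_range: tuple[float, float],
                   vertical_sector: bool) -> RimDefect:
    if vertical_sector:
        pole = rng.choice([0.0, 180.0])
        center = float((pole + rng.uniform(-25.0, 25.0)) % 360.0)
    else:
        center = float(rng.uniform(0.0, 360.0))
    width = rng.uniform(28.0, 55.0) if localized else rng.uniform(65.0, 120.0)
    return RimDefect(center_deg=center, width_deg=float(width), depth=float(rng.uniform(*depth_range)))


MAX_SAMPLE_ATTEMPTS = 200


def sample_eye_truth(target_grade: str, seed: int, mcdr_range: tuple[float, float] | None = None) -> EyeTruth:
    """Draw a random :class:`EyeTruth` whose rule-based grade is ``target_grade``.

    Sampling is seeded and deterministic; the draw is verified against
    :func:`grade_gon` (and the optional MCDR window) and re-drawn up to
    ``MAX_SAMPLE_ATTEMPTS`` times before failing.
    """
    if target_grade not in GRADE_CATEGORIES:
        raise ValueError(f"unknown GON grade category {target_grade!r}")
    rng = np.random.default_rng(seed)
    for _ in range(MAX_SAMPLE_ATTEMPTS):
        truth = _draw_candidate(target_grade, rng)
        if truth is None:
            continue
        if mcdr_range is not None:
            # shift the whole profile toward a target MCDR inside the window
            target = rng.uniform(*mcdr_range)
            shift = target - float(truth.profile_360.mean())
            truth = _try_truth_shift(truth, shift)
            if truth is None:
                continue
            mcdr = float(truth.profile_360.mean())
            if not (mcdr_range[0] <= mcdr <= mcdr_range[1]):
                continue
        if truth.grade.category != target_grade:
            continue
        return truth
    raise RuntimeError(
        f"could not sample an eye with grade {target_grade!r} in "
        f"{MAX_SAMPLE_ATTEMPTS} attempts"
    )


def _draw_candidate(target_grade: str, rng: np.random.Generator) -> EyeTruth | None:
    geom = _sample_geometry(rng)
    laterality = "left" if rng.random() < 0.5 else "right"
    common = {**geom, "laterality": laterality}

    if target_grade == "unlikely":
        shape = _sample_isnt_shape(rng)
        base = _base_for_vcdr(rng.uniform(0.35, 0.62), shape)
        return _try_truth(base_level=base, **shape, **common)

    if target_grade == "probable":
        mechanism = rng.choice(
            ["moderate_vcdr", "wedge", "thinning_local", "thinning_general", "hemorrhage"],
            p=[0.35, 0.30, 0.15, 0.10, 0.10],
        )
        if mechanism == "moderate_vcdr":
            shape = _sample_flat_shape(rng) if rng.random() < 0.5 else _sample_isnt_shape(rng)
            base = _base_for_vcdr(rng.uniform(0.70, 0.84), shape)
            return _try_truth(base_level=base, **shape, **common)
        if mechanism == "wedge":
            shape = _sample_isnt_shape(rng)
            base = _base_for_vcdr(rng.uniform(0.40, 0.66), shape)
            wedge = Wedge(
                center_deg=float(rng.uniform(0.0, 360.0)),
                width_deg=float(rng.uniform(12.0, 30.0)),
            )
            return _try_truth(base_level=base, rnfld_wedges=(wedge,), **shape, **common)
        if mechanism == "thinning_local":
            shape = _sample_isnt_shape(rng)
            defect = _sample_defect(
                rng, localized=True, depth_range=(THINNING_DEPTH, NOTCH_DEPTH - 0.01),
                vertical_sector=True,
            )
            base = _base_for_vcdr(rng.uniform(0.40, 0.58), shape)
            return _try_truth(base_level=base, defects=(defect,), **shape, **common)
        if mechanism == "thinning_general":
            shape = _sample_flat_shape(rng)
            defect = _sample_defect(
                rng, localized=False, depth_range=(THINNING_DEPTH, 0.14), vertical_sector=False,
            )
            base = _base_for_vcdr(rng.uniform(0.40, 0.60), shape)
            return _try_truth(base_level=base, defects=(defect,), **shape, **common)
        shape = _sample_isnt_shape(rng)
        base = _base_for_vcdr(rng.uniform(0.40, 0.62), shape)
        return _try_truth(
            base_level=base, hemorrhage=True,
            hemorrhage_angle=float(rng.uniform(0.0, 360.0)), **shape, **common,
        )

    # definite
    mechanism = rng.choice(["high_vcdr", "notch", "notch_with_wedge"], p=[0.4, 0.3, 0.3])
    if mechanism == "high_vcdr":
        shape = _sample_flat_shape(rng)
        base = _base_for_vcdr(rng.uniform(0.85, 0.95), shape)
        return _try_truth(base_level=base, **shape, **common)
    shape = _sample_flat_shape(rng) if rng.random() < 0.6 else _sample_isnt_shape(rng)
    notch = _sample_defect(
        rng, localized=True, depth_range=(NOTCH_DEPTH, 0.30), vertical_sector=rng.random() < 0.7,
    )
    wedges = ()
    if mechanism == "notch_with_wedge":
        wedges = (
            Wedge(
                center_deg=float((notch.center_deg + rng.uniform(-8.0, 8.0)) % 360.0),
                width_deg=float(rng.uniform(12.0, 30.0)),
            ),
        )
    base = _base_for_vcdr(rng.uniform(0.45, 0.75), shape)
    return _try_truth(base_level=base, defects=(notch,), rnfld_wedges=wedges, **shape, **common)


def _try_truth(**kwargs) -> EyeTruth | None:
    try:
        return EyeTruth(**kwargs)
    except ValueError:
        return None


def _try_truth_shift(truth: EyeTruth, shift: float) -> EyeTruth | None:
    try:
        return truth.with_base_level(truth.base_level + shift)
    except ValueError:
        return None


def _ellipse_polar_radius(d_row: np.ndarray, d_col: np.ndarray, r: np.ndarray,
                          a: float, b: float) -> np.ndarray:
    """Distance from the ellipse centre to its boundary along each pixel ray."""
    with np.errstate(divide="ignore", invalid="ignore"):
        u_row = np.where(r > 0, d_row / r, 1.0)
        u_col = np.where(r > 0, d_col / r, 0.0)
        return 1.0 / np.sqrt((u_col / a) ** 2 + (u_row / b) ** 2)


def render_eye(truth: EyeTruth, config: RenderConfig | None = None) -> tuple[np.ndarray, MaskSet]:
    """Render one eye to an 8-bit RGB image and its exact ground-truth masks.

    Masks are rasterized directly from the generative geometry; the image
    adds the intensity model (disc brighter than background, cup brighter
    than rim, RNFLD darker than surround), vessels, distractors, Gaussian
    noise and a slight blur.  Deterministic for a fixed (truth, config).
    """
    if config is None:
        config = RenderConfig()
    n = config.canvas_size
    s = n / CANONICAL_CANVAS
    cy, cx = truth.disc_center[0] * s, truth.disc_center[1] * s
    a, b = truth.disc_radii[0] * s, truth.disc_radii[1] * s
    if min(cy - b, cx - a) < 2 or max(cy + b, cx + a) > n - 2:
        raise ValueError("disc geometry exceeds the requested canvas")

    rows, cols = np.mgrid[0:n, 0:n]
    d_row = rows - cy
    d_col = cols - cx
    r = np.hypot(d_row, d_col)
    # canonical right-eye angles; a left eye is mirrored at the very end
    theta = np.degrees(np.arctan2(d_col, -d_row)) % 360.0

    r_disc = _ellipse_polar_radius(d_row, d_col, r, a, b)
    disc = r <= r_disc
    # the rim profile only matters inside the disc bounding box
    r0 = max(int(cy - b) - 2, 0)
    r1 = min(int(cy + b) + 3, n)
    c0 = max(int(cx - a) - 2, 0)
    c1 = min(int(cx + a) + 3, n)
    cup = np.zeros((n, n), dtype=bool)
    cdr_win = truth.rim_profile(theta[r0:r1, c0:c1])
    cup[r0:r1, c0:c1] = r[r0:r1, c0:c1] <= cdr_win * r_disc[r0:r1, c0:c1]

    rnfld = np.zeros((n, n), dtype=bool)
    for wedge in truth.rnfld_wedges:
        if not wedge.present:
            continue
        in_angle = np.abs(_ang_diff(theta, wedge.center_deg)) <= wedge.width_deg / 2.0
        rnfld |= in_angle & (r > r_disc) & (r <= WEDGE_OUTER_SCALE * r_disc)

    rng = np.random.default_rng(config.seed)
    img = _render_appearance(
        truth, config, rng,
        grids=(rows, cols, r, theta, r_disc), masks=(disc, cup, rnfld),
        scale=s, center=(cy, cx),
    )

    if truth.laterality == "left":
        img = img[:, ::-1].copy()
        disc = disc[:, ::-1].copy()
        cup = cup[:, ::-1].copy()
        rnfld = rnfld[:, ::-1].copy()

    masks = MaskSet(disc=disc, cup=cup, rnfld=rnfld, laterality=truth.laterality,
                    provenance={"source": "oracle"})
    return img, masks


def _render_appearance(truth, config, rng, *, grids, masks, scale, center):
    rows, cols, r, theta, r_disc = grids
    disc, cup, rnfld = masks
    n = config.canvas_size
    img = np.empty((n, n, 3), dtype=float)
    img[..., 0] = 178.0
    img[..., 1] = 84.0
    img[..., 2] = 58.0
    # gentle illumination falloff toward the corners
    falloff = 1.0 - 0.25 * (r / r.max()) ** 2
    img *= falloff[..., None]
    if config.background_texture:
        # smooth mottle, generated coarse and upsampled for speed
        coarse = n // 8 + 2
        texture = gaussian_filter(rng.normal(0.0, 1.0, (coarse, coarse)), sigma=1.5 * scale)
        texture = ndimage.zoom(texture, n / coarse, order=1)[:n, :n]
        texture /= max(np.abs(texture).max(), 1e-9)
        img += 12.0 * texture[..., None]

    # RNFL defect wedges: darker than the surrounding retina
    img[rnfld] *= 0.72

    if truth.atrophy:
        halo = (~disc) & (r <= 1.22 * r_disc) & (np.abs(_ang_diff(theta, 270.0)) < 80.0)
        img[halo] = img[halo] * 0.35 + np.array([215.0, 185.0, 150.0]) * 0.65

    img[disc] = (225.0, 168.0, 92.0)
    img[cup] = (248.0, 214.0, 138.0)

    if truth.hemorrhage:
        ang = truth.hemorrhage_angle
        hr = center[0] - np.cos(np.deg2rad(ang)) * r_disc * 1.0
        hc = center[1] + np.sin(np.deg2rad(ang)) * r_disc * 1.0
        blob = np.hypot(rows - hr, cols - hc) <= 0.22 * truth.disc_radii[0] * scale
        img[blob] = (95.0, 18.0, 18.0)

    _draw_vessels(img, truth, config, rng, scale, center)

    img = gaussian_filter(img, sigma=(1.2 * scale, 1.2 * scale, 0.0))
    if config.noise_sd > 0:
        img += rng.normal(0.0, config.noise_sd, img.shape)
    return np.clip(img, 0.0, 255.0).astype(np.uint8)


def _draw_vessels(img, truth, config, rng, scale, center):
    """Stamp a few dark arcuate vessel paths emanating from the disc."""
    n = config.canvas_size
    cy, cx = center
    half_w = max(int(round(2.0 * scale)), 1)
    for _ in range(config.vessel_count):
        ang = rng.choice([0.0, 180.0]) + rng.uniform(-30.0, 30.0)
        curve = rng.uniform(-60.0, 60.0)
        t = np.linspace(0.0, 1.0, 160)
        radial = t * 0.95 * n / 2.0
        angles = np.deg2rad(ang + curve * t**1.5)
        rr = np.rint(cy - np.cos(angles) * radial).astype(int)
        cc = np.rint(cx + np.sin(angles) * radial).astype(int)
        keep = (rr >= 0) & (rr < n) & (cc >= 0) & (cc < n)
        for dr in range(-half_w, half_w + 1):
            for dc in range(-half_w, half_w + 1):
                r2 = np.clip(rr[keep] + dr, 0, n - 1)
                c2 = np.clip(cc[keep] + dc, 0, n - 1)
                img[r2, c2] = img[r2, c2] * 0.45 + np.array([70.0, 18.0, 16.0]) * 0.55


@dataclass
class EyeRecord:
    """One simulated eye: image, exact masks, and the generating truth."""

    id: str
    image: np.ndarray
    masks: MaskSet
    truth: EyeTruth | None
    seed: int
    referable_label: bool | None = None  # for cohorts read back from disk

    @property
    def referable(self) -> bool:
        if self.truth is not None:
            return self.truth.grade.referable
        if self.referable_label is None:
            raise ValueError("no truth or referable label available for this eye")
        return bool(self.referable_label)


@dataclass
class Cohort:
    """A simulated cohort with its manifest table."""

    eyes: list[EyeRecord]
    manifest: pd.DataFrame

    def __len__(self) -> int:
        return len(self.eyes)

    @property
    def images(self) -> list[np.ndarray]:
        return [e.image for e in self.eyes]

    @property
    def referable_labels(self) -> np.ndarray:
        return np.array([e.referable for e in self.eyes], dtype=bool)


def _grade_counts(n: int, class_mix: dict[str, float]) -> dict[str, int]:
    fractions = {g: float(class_mix.get(g, 0.0)) for g in GRADE_CATEGORIES}
    if any(v < 0 for v in fractions.values()) or abs(sum(fractions.values()) - 1.0) > 1e-9:
        raise ValueError("class_mix fractions must be non-negative and sum to 1")
    counts = {g: int(np.floor(n * fractions[g])) for g in GRADE_CATEGORIES}
    remainder = n - sum(counts.values())
    by_frac = sorted(
        GRADE_CATEGORIES,
        key=lambda g: (n * fractions[g]) - counts[g],
        reverse=True,
    )
    for g in by_frac[:remainder]:
        counts[g] += 1
    return counts


def generate_dataset(
    n: int,
    class_mix: dict[str, float],
    seed: int,
    config: RenderConfig | None = None,
    mcdr_range: tuple[float, float] | None = None,
) -> Cohort:
    """Simulate a cohort of ``n`` eyes with grade proportions ``class_mix``.

    Per-eye seeds are derived deterministically from the master seed, so
    identical arguments reproduce a byte-identical manifest.
    """
    if n < 1:
        raise ValueError("n must be at least 1")
    if config is None:
        config = RenderConfig()
    counts = _grade_counts(n, class_mix)
    grades = [g for g in GRADE_CATEGORIES for _ in range(counts[g])]
    rng = np.random.default_rng(seed)
    rng.shuffle(grades)
    child_seeds = rng.integers(0, 2**31 - 1, size=2 * n)

    eyes: list[EyeRecord] = []
    rows = []
    for i, grade in enumerate(grades):
        eye_seed = int(child_seeds[2 * i])
        truth = sample_eye_truth(grade, eye_seed, mcdr_range=mcdr_range)
        render_cfg = dataclasses.replace(config, seed=int(child_seeds[2 * i + 1]))
        image, masks = render_eye(truth, render_cfg)
        eye_id = f"eye_{i:04d}"
        eyes.append(EyeRecord(id=eye_id, image=image, masks=masks, truth=truth, seed=eye_seed))
        rows.append(
            {
                "id": eye_id,
                "laterality": truth.laterality,
                "grade": truth.grade.category,
                "referable": truth.grade.referable,
                "vcdr_true": round(truth.vcdr_true, 6),
                "seed": eye_seed,
            }
        )
    manifest = pd.DataFrame(rows, columns=["id", "laterality", "grade", "referable", "vcdr_true", "seed"])
    return Cohort(eyes=eyes, manifest=manifest)
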