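"""Neuroretinal rim geometry from optic disc / optic cup masks.

The interpretable feature layer of the screening pipeline: a 360-degree
cup-to-disc ratio (CDR) profile measured radially from the disc centroid,
its mean (MCDR), the vertical cup-to-disc ratio (VCDR), and the ISNT score
-- the dimension-normalised inner product between the standardized CDR
profile of an eye and a standardized baseline profile averaged over normal
eyes.  A large ISNT score means the rim follows the normal ISNT ordering
(inferior rim widest, then superior, nasal, temporal); glaucomatous rims
lose that structure and score low.

Angle convention (canonical right-eye frame): 0 deg = superior (12
o'clock), angles increase clockwise, 90 deg = nasal, 180 deg = inferior,
270 deg = temporal.  Profiles of left eyes are mirrored into this frame on
computation so that one baseline serves both lateralities.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "MaskSet",
    "CDRProfile",
    "BaselineVector",
    "RimFeatures",
    "compute_cdr_profile",
    "mean_cdr",
    "vertical_cdr",
    "standardize_profile",
    "build_baseline",
    "isnt_score",
]

#: radial sampling step, in pixels, for boundary-crossing searches
RAY_STEP = 0.25

#: profiles with standard deviation below this are treated as constant
DEGENERACY_TOL = 1e-12


@dataclass
class MaskSet:
    """Co-registered binary rasters for one eye.

    ``cup`` is intersected with ``disc`` on construction so that the cup
    containment invariant holds regardless of where the masks came from.
    """

    disc: np.ndarray
    cup: np.ndarray
    rnfld: np.ndarray
    laterality: str = "right"
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.disc = np.asarray(self.disc, dtype=bool)
        self.cup = np.asarray(self.cup, dtype=bool)
        self.rnfld = np.asarray(self.rnfld, dtype=bool)
        if not (self.disc.shape == self.cup.shape == self.rnfld.shape):
            raise ValueError("disc, cup and rnfld masks must share one shape")
        if self.disc.ndim != 2:
            raise ValueError("masks must be 2-D rasters")
        if self.laterality not in ("left", "right"):
            raise ValueError(f"laterality must be 'left' or 'right', got {self.laterality!r}")
        self.cup = self.cup & self.disc

    @property
    def shape(self) -> tuple[int, int]:
        return self.disc.shape


@dataclass(frozen=True)
class CDRProfile:
    """Per-degree cup-to-disc radius ratios in the canonical right-eye frame."""

    values: np.ndarray
    laterality_canonicalized: bool = True

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.shape != (360,):
            raise ValueError("a CDR profile has exactly 360 components")
        if np.any(values < -1e-9) or np.any(values > 1 + 1e-9):
            raise ValueError("CDR profile values must lie in [0, 1]")
        object.__setattr__(self, "values", np.clip(values, 0.0, 1.0))


@dataclass(frozen=True)
class BaselineVector:
    """Standardized average CDR profile of a cohort of normal eyes."""

    values: np.ndarray
    n_source_eyes: int

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.shape != (360,):
            raise ValueError("a baseline vector has exactly 360 components")
        object.__setattr__(self, "values", values)


@dataclass(frozen=True)
class RimFeatures:
    """The interpretable feature triple driving the final diagnosis."""

    mcdr: float
    isnt_score: float
    rnfld_present: bool


def _ray_directions(laterality: str) -> np.ndarray:
    """Unit (row, col) directions for integer degrees in the canonical frame.

    0 deg points up (superior); clockwise positive.  For left eyes the
    column component is negated, which mirrors the eye into the canonical
    right frame.
    """
    theta = np.deg2rad(np.arange(360.0))
    d_row = -np.cos(theta)
    d_col = np.sin(theta)
    if laterality == "left":
        d_col = -d_col
    return np.stack([d_row, d_col], axis=1)


def _outermost_crossing(mask: np.ndarray, origin: tuple[float, float],
                        dirs: np.ndarray, radii: np.ndarray) -> np.ndarray:
    """Distance to the outermost mask-to-background transition per ray.

    Nearest-neighbour sampling at ``RAY_STEP`` increments; rays that never
    meet the mask return 0.
    """
    rows = np.rint(origin[0] + radii[None, :] * dirs[:, 0:1]).astype(int)
    cols = np.rint(origin[1] + radii[None, :] * dirs[:, 1:2]).astype(int)
    inside = (
        (rows >= 0) & (rows < mask.shape[0]) & (cols >= 0) & (cols < mask.shape[1])
    )
    hit = np.zeros(inside.shape, dtype=bool)
    hit[inside] = mask[rows[inside], cols[inside]]
    any_hit = hit.any(axis=1)
    # index of the outermost True sample along each ray
    last = hit.shape[1] - 1 - np.argmax(hit[:, ::-1], axis=1)
    dist = np.where(any_hit, radii[np.clip(last, 0, None)], 0.0)
    return dist


def compute_cdr_profile(masks: MaskSet) -> CDRProfile:
    """Compute the 360-dimensional CDR profile of one eye.

    For every integer degree a ray is cast from the disc-mask centroid; the
    profile value is the distance to the outermost cup-boundary crossing
    divided by the distance to the outermost disc-boundary crossing,
    clipped to [0, 1], and 0 where the ray meets no cup pixel.
    """
    if not masks.disc.any():
        raise ValueError("cannot compute a CDR profile from an empty disc mask")
    rr, cc = np.nonzero(masks.disc)
    origin = (float(rr.mean()), float(cc.mean()))
    if not masks.disc[int(round(origin[0])), int(round(origin[1]))]:
        raise ValueError(
            "disc centroid falls outside the disc mask; the mask is too "
            "non-convex for a radial profile"
        )
    r_max = float(np.hypot(rr - origin[0], cc - origin[1]).max()) + 2.0
    radii = np.arange(RAY_STEP, r_max, RAY_STEP)
    dirs = _ray_directions(masks.laterality)
    disc_dist = _outermost_crossing(masks.disc, origin, dirs, radii)
    cup_dist = _outermost_crossing(masks.cup, origin, dirs, radii)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(disc_dist > 0, cup_dist / np.maximum(disc_dist, 1e-12), 0.0)
    return CDRProfile(values=np.clip(ratio, 0.0, 1.0))


def mean_cdr(profile: CDRProfile | np.ndarray) -> float:
    """MCDR: the arithmetic mean of the 360 profile values."""
    values = profile.values if isinstance(profile, CDRProfile) else np.asarray(profile)
    return float(np.mean(values))


def vertical_cdr(masks: MaskSet) -> float:
    """VCDR measured along the image column through the disc centroid.

    Ratio of the vertical pixel extents (last row minus first row plus one)
    of the cup and disc masks on that column; 0 when the cup is absent on
    the column.
    """
    if not masks.disc.any():
        raise ValueError("cannot compute VCDR from an empty disc mask")
    rr, cc = np.nonzero(masks.disc)
    col = int(round(float(cc.mean())))
    disc_col = np.nonzero(masks.disc[:, col])[0]
    if disc_col.size == 0:
        raise ValueError("disc mask is empty on its centroid column")
    cup_col = np.nonzero(masks.cup[:, col])[0]
    if cup_col.size == 0:
        return 0.0
    disc_extent = disc_col.max() - disc_col.min() + 1
    cup_extent = cup_col.max() - cup_col.min() + 1
    return float(min(cup_extent / disc_extent, 1.0))


def standardize_profile(profile: CDRProfile | np.ndarray) -> tuple[np.ndarray, bool]:
    """Standardize a profile to mean 0, population standard deviation 1.

    Returns ``(vector, degenerate)``.  A profile whose standard deviation
    is below ``DEGENERACY_TOL`` (a constant profile) maps to the all-zero
    vector with the degeneracy flag set.
    """
    values = profile.values if isinstance(profile, CDRProfile) else np.asarray(profile, float)
    sd = float(values.std())  # population convention, divisor 360
    if sd < DEGENERACY_TOL:
        return np.zeros_like(values), True
    return (values - values.mean()) / sd, False


def build_baseline(normal_profiles: list[CDRProfile | np.ndarray]) -> BaselineVector:
    """Average the raw CDR profiles of normal eyes and standardize the result."""
    if len(normal_profiles) == 0:
        raise ValueError("cannot build a baseline from an empty profile list")
    stack = np.stack(
        [p.values if isinstance(p, CDRProfile) else np.asarray(p, float) for p in normal_profiles]
    )
    avg = stack.mean(axis=0)
    z, _ = standardize_profile(avg)
    return BaselineVector(values=z, n_source_eyes=len(normal_profiles))


def isnt_score(profile: CDRProfile | np.ndarray, baseline: BaselineVector) -> float:
    """ISNT conformity score of one eye against the normal baseline.

    The standardized profile is projected onto the baseline and the inner
    product divided by the dimension, giving a correlation-like quantity in
    [-1, 1]; a degenerate (constant) profile scores 0.
    """
    z, degenerate = standardize_profile(profile)
    if degenerate:
        return 0.0
    return float(np.dot(z, baseline.values) / 360.0)
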