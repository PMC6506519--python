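"""Seeded generator of fundus-like images with known disc/cup geometry.

The generator does not aim at photorealism.  It reproduces the few image
properties the segmentation pipeline actually relies on:

* a bright circular optic disc whose contrast against the background is
  strongest in the red channel;
* a brighter, possibly offset, cup region whose contrast against the disc
  rim is strongest in the green channel;
* dark vessel curves radiating from the disc that partially occlude it;
* soft region edges (Gaussian blur) and additive Gaussian noise.

Every image comes with exact ground truth: the disc and cup circles and
their pixel-center rasterizations.  All randomness flows from the spec seed,
so a fixed spec yields bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
from scipy.ndimage import gaussian_filter
from skimage.draw import disk as draw_disk

from .clinical_geometry import Circle
from .errors import InvalidArgumentError

__all__ = [
    "SyntheticSpec",
    "GroundTruth",
    "circle_mask",
    "generate_fundus_image",
    "generate_cohort",
    "generate_severity_cohort",
    "severity_cohort_specs",
    "DEFAULT_CHANNEL_INTENSITIES",
]

# Per-channel (R, G, B) mean levels of the three regions.  Chosen so that the
# disc/background contrast is largest in red (0.85 vs 0.45) and the cup/rim
# contrast is largest in green (0.75 vs 0.45), mirroring real fundus imagery
# where the disc is brightest in red and the cup stands out in green.
DEFAULT_CHANNEL_INTENSITIES = {
    "background": (0.45, 0.30, 0.15),
    "disc": (0.85, 0.45, 0.25),
    "cup": (0.88, 0.75, 0.40),
}

_VESSEL_DARKENING = 0.55  # fractional intensity drop at the vessel core


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of one synthetic fundus draw (ranges are inclusive).

    ``cup_offset_fraction`` is the offset of the cup center from the disc
    center, as a fraction of the disc radius.  Unless ``allow_rim_absence``
    is set, cup_radius_fraction + cup_offset_fraction may not exceed 1, so
    the cup stays inside the disc and some rim remains everywhere.
    """

    width: int = 256
    height: int = 256
    disc_center_range: tuple = ((108.0, 148.0), (108.0, 148.0))  # (x range, y range)
    disc_radius_range: tuple = (20.0, 30.0)
    cup_radius_fraction_range: tuple = (0.35, 0.75)
    cup_offset_fraction_range: tuple = (0.0, 0.25)
    channel_intensities: dict = field(
        default_factory=lambda: {k: tuple(v) for k, v in DEFAULT_CHANNEL_INTENSITIES.items()}
    )
    edge_softness: float = 1.0
    n_vessels: int = 4
    vessel_width: float = 3.0
    noise_sigma: float = 0.02
    allow_rim_absence: bool = False
    seed: int = 0

    def validate(self) -> None:
        if self.width < 8 or self.height < 8:
            raise InvalidArgumentError("image must be at least 8x8 pixels")
        for name, rng_ in (
            ("disc_center_range[0]", self.disc_center_range[0]),
            ("disc_center_range[1]", self.disc_center_range[1]),
            ("disc_radius_range", self.disc_radius_range),
            ("cup_radius_fraction_range", self.cup_radius_fraction_range),
            ("cup_offset_fraction_range", self.cup_offset_fraction_range),
        ):
            lo, hi = rng_
            if not (lo <= hi):
                raise InvalidArgumentError(f"empty range for {name}: {rng_}")
        if self.disc_radius_range[0] <= 0:
            raise InvalidArgumentError("disc radius must be positive")
        cf_lo, cf_hi = self.cup_radius_fraction_range
        of_lo, of_hi = self.cup_offset_fraction_range
        if not (0 < cf_lo and cf_hi < 1.5):
            raise InvalidArgumentError("cup radius fraction must lie in (0, 1.5)")
        if not (0 <= of_lo and of_hi < 1):
            raise InvalidArgumentError("cup offset fraction must lie in [0, 1)")
        if not self.allow_rim_absence and cf_hi + of_hi > 1.0 + 1e-12:
            raise InvalidArgumentError(
                "cup_radius_fraction + cup_offset_fraction may exceed 1 only "
                "with allow_rim_absence=True"
            )
        for key in ("background", "disc", "cup"):
            vals = self.channel_intensities.get(key)
            if vals is None or len(vals) != 3 or not all(0.0 <= v <= 1.0 for v in vals):
                raise InvalidArgumentError(
                    f"channel_intensities[{key!r}] must be three means in [0, 1]"
                )
        # the disc must fit inside the image for every sampled combination
        (x_lo, x_hi), (y_lo, y_hi) = self.disc_center_range
        r_hi = self.disc_radius_range[1]
        if x_lo - r_hi < 0 or y_lo - r_hi < 0 or x_hi + r_hi > self.width - 1 \
                or y_hi + r_hi > self.height - 1:
            raise InvalidArgumentError("disc cannot fit fully inside the image bounds")
        if self.noise_sigma < 0 or self.n_vessels < 0 or self.vessel_width <= 0:
            raise InvalidArgumentError("noise_sigma/n_vessels/vessel_width out of range")


@dataclass(frozen=True)
class GroundTruth:
    """True geometry behind a rendered image."""

    disc: Circle
    cup: Circle
    disc_mask: np.ndarray
    cup_mask: np.ndarray
    laterality: str

    def to_dict(self) -> dict:
        return {
            "disc": {"cx": self.disc.cx, "cy": self.disc.cy, "r": self.disc.r},
            "cup": {"cx": self.cup.cx, "cy": self.cup.cy, "r": self.cup.r},
            "laterality": self.laterality,
        }


def circle_mask(circle: Circle, height: int, width: int) -> np.ndarray:
    """Pixel-center rasterization of a circle.

    Pixel (row i, col j) is set iff its center (x=j, y=i) lies within
    ``circle.r`` of the circle center.  Returns a boolean height x width mask.
    """
    if height <= 0 or width <= 0:
        raise InvalidArgumentError("mask dimensions must be positive")
    if not (circle.r > 0):
        raise InvalidArgumentError("circle radius must be positive")
    yy = np.arange(height, dtype=float)[:, None]
    xx = np.arange(width, dtype=float)[None, :]
    d2 = (xx - circle.cx) ** 2 + (yy - circle.cy) ** 2
    return d2 <= circle.r * circle.r


def _draw_vessels(rng: np.random.Generator, height: int, width: int,
                  center: tuple, n_vessels: int, vessel_width: float) -> np.ndarray:
    """Random-walk polylines emanating from the disc center.

    Each vessel starts at the disc center with a random heading and wanders
    with small angular jitter until it leaves the frame.  Returns a boolean
    occupancy mask of the vessel footprints.
    """
    mask = np.zeros((height, width), dtype=bool)
    half_w = max(0.5, vessel_width / 2.0)
    for _ in range(n_vessels):
        angle = rng.uniform(0.0, 2.0 * np.pi)
        x, y = float(center[0]), float(center[1])
        for _ in range(600):
            angle += rng.normal(0.0, 0.18)
            x += 2.0 * np.cos(angle)
            y += 2.0 * np.sin(angle)
            if not (0 <= x < width and 0 <= y < height):
                break
            rr, cc = draw_disk((y, x), half_w, shape=(height, width))
            mask[rr, cc] = True
    return mask


def _sample_geometry(spec: SyntheticSpec, rng: np.random.Generator):
    (x_lo, x_hi), (y_lo, y_hi) = spec.disc_center_range
    cx = rng.uniform(x_lo, x_hi)
    cy = rng.uniform(y_lo, y_hi)
    r = rng.uniform(*spec.disc_radius_range)
    cup_frac = rng.uniform(*spec.cup_radius_fraction_range)
    off_frac = rng.uniform(*spec.cup_offset_fraction_range)
    if not spec.allow_rim_absence:
        off_frac = min(off_frac, max(0.0, 1.0 - cup_frac))
    off_angle = rng.uniform(0.0, 2.0 * np.pi)
    laterality = "right" if rng.integers(0, 2) == 0 else "left"
    disc = Circle(cx, cy, r)
    cup = Circle(cx + off_frac * r * np.cos(off_angle),
                 cy + off_frac * r * np.sin(off_angle),
                 cup_frac * r)
    return disc, cup, laterality


def generate_fundus_image(spec: SyntheticSpec) -> tuple[np.ndarray, GroundTruth]:
    """Render one synthetic fundus image and its exact ground truth.

    Returns a float64 (height, width, 3) RGB image with values in [0, 1].
    Deterministic for a fixed spec (including its seed).
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    disc, cup, laterality = _sample_geometry(spec, rng)

    h, w = spec.height, spec.width
    disc_m = circle_mask(disc, h, w)
    cup_m = circle_mask(cup, h, w)

    bg = spec.channel_intensities["background"]
    dv = spec.channel_intensities["disc"]
    cv = spec.channel_intensities["cup"]
    img = np.empty((h, w, 3), dtype=np.float64)
    for c in range(3):
        chan = np.full((h, w), bg[c], dtype=np.float64)
        chan[disc_m] = dv[c]
        # In red the disc margin dominates: pallor reaching past the margin
        # (rim-absence geometry) shows up in green/blue but not in red.
        chan[(cup_m & disc_m) if c == 0 else cup_m] = cv[c]
        if spec.edge_softness > 0:
            chan = gaussian_filter(chan, spec.edge_softness, mode="nearest")
        img[:, :, c] = chan

    if spec.n_vessels > 0:
        vmask = _draw_vessels(rng, h, w, (disc.cx, disc.cy), spec.n_vessels,
                              spec.vessel_width)
        vsoft = gaussian_filter(vmask.astype(np.float64), 0.7, mode="nearest")
        img *= (1.0 - _VESSEL_DARKENING * np.clip(vsoft, 0.0, 1.0))[:, :, None]

    if spec.noise_sigma > 0:
        img = img + rng.normal(0.0, spec.noise_sigma, size=img.shape)

    np.clip(img, 0.0, 1.0, out=img)
    truth = GroundTruth(disc=disc, cup=cup, disc_mask=disc_m, cup_mask=cup_m,
                        laterality=laterality)
    return img, truth


def generate_cohort(n: int, spec: Optional[SyntheticSpec] = None,
                    seed: Optional[int] = None) -> list:
    """Draw ``n`` independent synthetic images from the spec's ranges.

    Per-image parameters are sampled uniformly from the ranges; the whole
    cohort is reproducible from ``seed`` (defaults to ``spec.seed``).
    """
    if n < 1:
        raise InvalidArgumentError(f"cohort size must be >= 1, got {n}")
    spec = spec if spec is not None else SyntheticSpec()
    spec.validate()
    master = np.random.default_rng(spec.seed if seed is None else seed)
    out = []
    for _ in range(n):
        child_seed = int(master.integers(0, 2**31 - 1))
        out.append(generate_fundus_image(replace(spec, seed=child_seed)))
    return out


def severity_cohort_specs() -> dict:
    """Generator settings spanning the three DDLS severity grades.

    * ``normal``: moderate cups well inside the disc — for concentric
      geometry the rim-to-disc ratio is (1 - cup_fraction) / 2, so fractions
      up to ~0.6 stay in the normal DDLS bands.
    * ``moderate``: large, nearly rim-filling cups (fraction + offset close
      to or just past 1) — narrow rims (RDR < 0.10) or small rim-absence
      arcs (< 90 deg).
    * ``severe``: cups reaching well past the disc boundary, with
      rim-absence arcs of 90 deg and beyond.
    """
    base = SyntheticSpec()
    return {
        "normal": replace(base, cup_radius_fraction_range=(0.35, 0.60),
                          cup_offset_fraction_range=(0.0, 0.15)),
        "moderate": replace(base, cup_radius_fraction_range=(0.72, 0.82),
                            cup_offset_fraction_range=(0.12, 0.18)),
        "severe": replace(base, cup_radius_fraction_range=(0.95, 1.10),
                          cup_offset_fraction_range=(0.20, 0.30),
                          allow_rim_absence=True),
    }


def generate_severity_cohort(n: int, seed: int = 0) -> list:
    """A cohort of ``n`` images cycling through the three severity settings.

    Returns a list of (image, GroundTruth) tuples; reproducible from ``seed``.
    """
    if n < 1:
        raise InvalidArgumentError(f"cohort size must be >= 1, got {n}")
    specs = list(severity_cohort_specs().values())
    master = np.random.default_rng(seed)
    out = []
    for i in range(n):
        child_seed = int(master.integers(0, 2**31 - 1))
        out.append(generate_fundus_image(replace(specs[i % 3], seed=child_seed)))
    return out
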