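"""Optic-cup segmentation: multilevel Otsu coarse extraction + active-disc refinement.

The cup is extracted from the green channel, which carries the strongest
cup/rim contrast.  Pixels inside the fitted disc are clustered by exact
multilevel Otsu thresholding (four classes work well: disc tissue, two
transition bands, cup); the brightest class, restricted to the disc and
reduced to its largest connected component, provides the initial circle for
an active-disc fit that is constrained to keep the cup center inside the
disc and the cup no larger than the disc (the cup boundary may still cross
the disc boundary, which is exactly the zero-rim configuration the late
DDLS stages describe).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.ndimage import gaussian_filter
from skimage.measure import label, regionprops
from skimage.morphology import closing, disk

from .active_disc import SQRT2, ActiveDiscParams, FitOptions, FitResult, fit_active_disc
from .clinical_geometry import Circle
from .errors import (
    DegenerateHistogramError,
    InvalidArgumentError,
    NoCupFoundError,
)
from .synthetic_fundus import circle_mask

__all__ = [
    "ThresholdSet",
    "otsu_multilevel",
    "preprocess_green",
    "coarse_cup_mask",
    "segment_optic_cup",
]

_N_BINS = 256
_MIN_INIT_RADIUS = 2.0  # px; smaller coarse candidates are treated as "no cup"


@dataclass(frozen=True)
class ThresholdSet:
    """k-class partition of an intensity histogram: k-1 increasing thresholds."""

    thresholds: tuple
    k: int

    def classify(self, values) -> np.ndarray:
        """Class index (0 = darkest) for each value."""
        return np.digitize(np.asarray(values), self.thresholds)


def _histogram(data: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """256-bin histogram of raster/sample data plus the bin-center values."""
    data = data.ravel()
    lo, hi = float(data.min()), float(data.max())
    if hi <= lo:
        hi = lo + 1.0  # single level; degenerate cases are caught later
    counts, edges = np.histogram(data, bins=_N_BINS, range=(lo, hi))
    centers = 0.5 * (edges[:-1] + edges[1:])
    return counts.astype(np.float64), centers


def otsu_multilevel(channel, k: int = 4) -> ThresholdSet:
    """Exact multilevel Otsu thresholds maximizing the between-class variance.

    ``channel`` may be a 2-D grayscale raster (binned to 256 levels over its
    intensity range), a 1-D sample of intensities, or a pair
    ``(counts, bin_centers)`` giving a precomputed histogram.  The maximizer
    is found by dynamic programming over all (k-1)-threshold partitions of
    the binned histogram — equivalent to exhaustive search, with ties broken
    toward the lexicographically smallest threshold tuple.  Thresholds are
    returned in intensity units, halfway between the adjacent occupied bins.
    """
    if k < 2:
        raise InvalidArgumentError("need at least k=2 classes")
    if isinstance(channel, tuple) and len(channel) == 2:
        counts = np.asarray(channel[0], dtype=np.float64)
        centers = np.asarray(channel[1], dtype=np.float64)
        if counts.shape != centers.shape or counts.ndim != 1:
            raise InvalidArgumentError("histogram must be (counts, bin_centers) 1-D arrays")
    else:
        arr = np.asarray(channel, dtype=np.float64)
        counts, centers = _histogram(arr)
    occupied = np.flatnonzero(counts > 0)
    if len(occupied) < k:
        raise DegenerateHistogramError(
            f"only {len(occupied)} occupied intensity levels for k={k} classes"
        )

    # collapse to occupied bins; a cut between occupied bins determines the class
    c = counts[occupied]
    v = centers[occupied]
    m = len(c)
    w_cum = np.concatenate([[0.0], np.cumsum(c)])
    s_cum = np.concatenate([[0.0], np.cumsum(c * v)])

    def seg(a: int, b: int) -> float:
        # contribution sum^2/weight of bins a..b-1; maximizing the total over a
        # partition is equivalent to maximizing the between-class variance
        wgt = w_cum[b] - w_cum[a]
        if wgt <= 0:
            return 0.0
        s = s_cum[b] - s_cum[a]
        return s * s / wgt

    NEG = -math.inf
    best = np.full((k + 1, m + 1), NEG)
    split = np.zeros((k + 1, m + 1), dtype=int)
    for b in range(1, m + 1):
        best[1][b] = seg(0, b)
    for c_i in range(2, k + 1):
        for b in range(c_i, m + 1):
            val = NEG
            arg = -1
            for mcut in range(c_i - 1, b):
                cand = best[c_i - 1][mcut] + seg(mcut, b)
                if cand > val:  # strict: keeps the earliest (smallest) cuts
                    val = cand
                    arg = mcut
            best[c_i][b] = val
            split[c_i][b] = arg

    cuts = []
    b = m
    for c_i in range(k, 1, -1):
        b = split[c_i][b]
        cuts.append(b)
    cuts.reverse()
    thresholds = tuple(0.5 * (v[cut - 1] + v[cut]) for cut in cuts)
    return ThresholdSet(thresholds=thresholds, k=k)


def preprocess_green(green, vessel_closing_radius: float = 4.0,
                     smooth_sigma: float = 1.0) -> np.ndarray:
    """Suppress vessels and noise on the green channel before cup extraction.

    Retinal vessels are thin dark curves that fragment the bright cup into
    pieces, derailing both the Otsu clustering and the active-disc basin.
    Grey-level morphological closing with a disc element slightly wider than
    the vessel caliber fills them in, and a light Gaussian tames sensor
    noise.  Both steps are optional (radius/sigma of 0 disables them).
    """
    g = np.asarray(green, dtype=np.float64)
    if vessel_closing_radius > 0:
        g = closing(g, disk(int(round(vessel_closing_radius))))
    if smooth_sigma > 0:
        g = gaussian_filter(g, smooth_sigma, mode="nearest")
    return g


def coarse_cup_mask(green_roi, disc: Circle, k: int = 4) -> tuple[np.ndarray, Circle]:
    """Coarse cup candidate inside the disc, plus its initializing circle.

    Thresholds are computed over the pixels inside the disc only (the cup is
    the brightest class locally); the mask is the top intensity class
    intersected with the disc, reduced to its largest connected component
    (ties by smallest centroid row, then column).  The initial circle is the
    component centroid with the equivalent radius ``sqrt(area / pi)``.
    """
    green = np.asarray(green_roi, dtype=np.float64)
    if green.ndim != 2:
        raise InvalidArgumentError("green_roi must be a 2-D raster")
    h, w = green.shape
    disc_m = circle_mask(disc, h, w)
    if not disc_m.any():
        raise InvalidArgumentError("disc circle does not overlap the raster")
    try:
        ts = otsu_multilevel(green[disc_m], k=k)
    except DegenerateHistogramError as exc:
        raise NoCupFoundError(f"no intensity structure inside the disc: {exc}") from exc
    top = (green > ts.thresholds[-1]) & disc_m
    if not top.any():
        raise NoCupFoundError("top intensity class inside the disc is empty")

    labels = label(top, connectivity=2)
    regions = regionprops(labels)
    regions.sort(key=lambda rg: (-rg.area, rg.centroid[0], rg.centroid[1]))
    best = regions[0]
    mask = labels == best.label
    cy, cx = best.centroid
    r_eq = math.sqrt(best.area / math.pi)
    if r_eq < _MIN_INIT_RADIUS:
        raise NoCupFoundError(
            f"largest cup candidate has equivalent radius {r_eq:.2f} px (< {_MIN_INIT_RADIUS})"
        )
    return mask, Circle(float(cx), float(cy), r_eq)


def _cup_constraint(disc: Circle):
    """Projection keeping the cup center inside the disc and R_cup <= R_disc."""

    max_outer = SQRT2 * disc.r

    def project(p: ActiveDiscParams) -> ActiveDiscParams:
        R = min(p.R, max_outer)
        dx, dy = p.xc - disc.cx, p.yc - disc.cy
        d = math.hypot(dx, dy)
        if d > disc.r:
            scale = disc.r / d
            return ActiveDiscParams(R, disc.cx + dx * scale, disc.cy + dy * scale)
        return ActiveDiscParams(R, p.xc, p.yc)

    return project


def segment_optic_cup(rgb, disc: Circle, opts: Optional[FitOptions] = None,
                      vessel_closing_radius: float = 4.0,
                      smooth_sigma: float = 1.0) -> FitResult:
    """Segment the optic cup on the green channel, given the fitted disc.

    The channel is vessel-suppressed (:func:`preprocess_green`), the active
    disc is initialized from :func:`coarse_cup_mask` and fitted at full
    resolution with the containment constraint projected after every step,
    so the returned cup center always lies inside the disc and the cup is
    never larger than the disc.
    """
    opts = opts or FitOptions()
    img = np.asarray(rgb, dtype=np.float64)
    if img.ndim != 3 or img.shape[2] < 3:
        raise InvalidArgumentError("expected an RGB raster of shape (H, W, 3)")
    green = preprocess_green(img[:, :, 1], vessel_closing_radius, smooth_sigma)
    _, init_circle = coarse_cup_mask(green, disc)
    init = ActiveDiscParams(max(2.0, SQRT2 * init_circle.r),
                            init_circle.cx, init_circle.cy)
    return fit_active_disc(green, init, opts, constraint=_cup_constraint(disc))
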