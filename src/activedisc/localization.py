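"""Automatic optic-disc localization by a multiscale matched filter.

A three-level Gaussian pyramid is built from the red channel (where the disc
is brightest).  At the coarsest level the normalized cross-correlation with a
bright-blob disc template is computed; the correlation peak, mapped back to
full resolution, initializes the active-disc fit and defines a region of
interest.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy.ndimage import gaussian_filter

from .errors import AmbiguousLocalizationError, InvalidArgumentError

__all__ = [
    "Pyramid",
    "LocalizationResult",
    "build_pyramid",
    "disc_template",
    "normalized_cross_correlation",
    "localize_disc",
]

_MAX_TIES_LISTED = 16


@dataclass(frozen=True)
class Pyramid:
    """Grayscale pyramid from full resolution (levels[0]) to coarsest."""

    levels: tuple
    scale_factor: int = 2

    @property
    def n_levels(self) -> int:
        return len(self.levels)


def build_pyramid(channel, n_levels: int = 3, sigma: float = 1.0) -> Pyramid:
    """Low-pass (Gaussian, ``sigma``) and decimate-by-2 repeatedly.

    Level k+1 has dimensions ``ceil(level_k / 2)``.
    """
    chan = np.asarray(channel, dtype=np.float64)
    if chan.ndim != 2:
        raise InvalidArgumentError("channel must be a 2-D grayscale raster")
    if n_levels < 1:
        raise InvalidArgumentError("n_levels must be >= 1")
    min_side = 2 ** (n_levels - 1)
    if min(chan.shape) < min_side:
        raise InvalidArgumentError(
            f"image of shape {chan.shape} too small for {n_levels} pyramid levels"
        )
    levels = [chan]
    for _ in range(n_levels - 1):
        smoothed = gaussian_filter(levels[-1], sigma, mode="nearest")
        levels.append(smoothed[::2, ::2])
    return Pyramid(levels=tuple(levels))


def disc_template(radius: float) -> np.ndarray:
    """Default matched-filter template: a soft bright disc of given radius.

    A hard disc blurred by ``radius / 4`` on a square support of half-width
    ``2 * radius``; values in [0, 1].  Stands in for a 'natural' optic disc
    patch while staying fully reproducible.
    """
    if radius <= 0:
        raise InvalidArgumentError("template radius must be positive")
    half = max(2, int(math.ceil(2.0 * radius)))
    coords = np.arange(-half, half + 1, dtype=np.float64)
    d2 = coords[:, None] ** 2 + coords[None, :] ** 2
    tmpl = (d2 <= radius * radius).astype(np.float64)
    return gaussian_filter(tmpl, max(0.5, radius / 4.0), mode="nearest")


def _box_sums(arr: np.ndarray, th: int, tw: int) -> np.ndarray:
    """Sum of every th x tw window (valid positions), via an integral image."""
    ii = np.zeros((arr.shape[0] + 1, arr.shape[1] + 1), dtype=np.float64)
    np.cumsum(np.cumsum(arr, axis=0), axis=1, out=ii[1:, 1:])
    return (ii[th:, tw:] - ii[:-th, tw:] - ii[th:, :-tw] + ii[:-th, :-tw])


def normalized_cross_correlation(channel, template) -> np.ndarray:
    """Zero-mean, unit-norm correlation map over all valid window positions.

    ``map[i, j]`` is the normalized correlation of the template with the
    image window whose top-left pixel is (row i, col j); values lie in
    [-1, 1].  Windows (or templates) with negligible variance get 0.
    """
    im = np.asarray(channel, dtype=np.float64)
    t = np.asarray(template, dtype=np.float64)
    if im.ndim != 2 or t.ndim != 2:
        raise InvalidArgumentError("image and template must be 2-D")
    th, tw = t.shape
    if th > im.shape[0] or tw > im.shape[1]:
        raise InvalidArgumentError("template must be no larger than the image")
    n = th * tw
    tz = t - t.mean()
    t_energy = float(np.sum(tz * tz))

    windows = sliding_window_view(im, (th, tw))
    num = np.einsum("ijkl,kl->ij", windows, tz)  # = sum (w - w_mean)(t - t_mean)
    win_sum = _box_sums(im, th, tw)
    win_sq = _box_sums(im * im, th, tw)
    win_var = win_sq - win_sum * win_sum / n  # n * variance

    scale = max(np.abs(im).max(), np.abs(t).max(), 1e-30)
    floor = 1e-10 * n * scale * scale
    denom = np.sqrt(np.clip(win_var, 0.0, None) * t_energy)
    valid = (win_var > floor) & (t_energy > floor)
    out = np.zeros_like(num)
    np.divide(num, denom, out=out, where=valid & (denom > 0))
    return np.clip(out, -1.0, 1.0)


@dataclass(frozen=True)
class LocalizationResult:
    """Disc location estimate in full-resolution pixel coordinates."""

    x_p: float
    y_p: float
    peak_score: float
    roi_box: tuple  # (x0, y0, x1, y1), clipped to the image


def localize_disc(rgb, template=None, n_levels: int = 3,
                  template_radius: Optional[float] = None) -> LocalizationResult:
    """Locate the optic disc by matched filtering at the coarsest pyramid level.

    The red channel is used (the disc is brightest there and vessels are
    de-emphasized).  The correlation argmax at the coarsest level is mapped
    to full resolution by the pyramid scale factor; ties are broken by the
    smallest row then the smallest column, and an exactly tied peak (e.g. on
    a flat image) raises :class:`AmbiguousLocalizationError`.

    ``template_radius`` is the expected disc radius at full resolution
    (default: 10% of the smaller image side); the default template is
    :func:`disc_template` shrunk to the coarsest scale.
    """
    img = np.asarray(rgb, dtype=np.float64)
    if img.ndim != 3 or img.shape[2] < 3:
        raise InvalidArgumentError("expected an RGB raster of shape (H, W, 3)")
    red = img[:, :, 0]
    h, w = red.shape
    scale = 2 ** (n_levels - 1)
    r_full = template_radius if template_radius is not None else 0.10 * min(h, w)
    if template is None:
        template = disc_template(r_full / scale)
    pyr = build_pyramid(red, n_levels)
    coarse = pyr.levels[-1]
    # pad by the template half-size (median fill) so discs near the border can
    # still be window centers; the map is then indexed by center position
    th, tw = np.asarray(template).shape
    padded = np.pad(coarse, ((th // 2, th // 2), (tw // 2, tw // 2)), mode="median")
    cmap = normalized_cross_correlation(padded, template)

    peak = float(cmap.max())
    tied = np.argwhere(cmap == peak)
    if len(tied) > 1:
        positions = [(float(j * scale), float(i * scale))
                     for i, j in tied[:_MAX_TIES_LISTED]]
        raise AmbiguousLocalizationError(
            f"{len(tied)} positions tie for the correlation peak", positions
        )
    i, j = (int(v) for v in tied[0])
    x_p = min(float(w - 1), j * float(scale))
    y_p = min(float(h - 1), i * float(scale))

    half = 2.0 * r_full  # ROI is a square of side 4 * template radius
    x0 = max(0.0, x_p - half)
    y0 = max(0.0, y_p - half)
    x1 = min(float(w - 1), x_p + half)
    y1 = min(float(h - 1), y_p + half)
    return LocalizationResult(x_p=x_p, y_p=y_p, peak_score=peak,
                              roi_box=(x0, y0, x1, y1))
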