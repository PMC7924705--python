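"""Pupil and limbic boundary localization by circular Hough voting.

The segmentation runs in two passes.  The pupil pass builds an isotropic
gradient edge map and votes over the whole image for the pupil circle; the
iris pass re-derives the edge map with extra weight on vertical edges (the
limbic boundary presents mostly vertical arcs, while eyelids are
horizontally aligned and would otherwise dominate) and searches for the
limbic circle with its center constrained near the pupil center.

Voting rule: an edge pixel at (y, x) votes for accumulator cell
(yc, xc, r) exactly when ``rint(hypot(y - yc, x - xc)) == r``, with numpy's
round-half-to-even convention.  This makes the accumulator a well-defined
integer object that a brute-force per-cell counter reproduces cell for
cell, which the tests exploit.  Ties at the accumulator maximum are broken
by smallest radius, then row-major center order.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import binary_dilation, gaussian_filter

from .geometry import Circle
from .imgio import HoughConfig


class SegmentationError(RuntimeError):
    """Segmentation could not produce a consistent pupil/iris pair."""

    def __init__(self, msg: str, pupil: Circle | None = None, iris: Circle | None = None):
        super().__init__(msg)
        self.pupil = pupil
        self.iris = iris


@dataclass
class EdgeMap:
    """Binary edge mask plus the gradient magnitude it was thresholded from.

    Gradient convention: centered finite differences, ``gy`` along rows
    (increasing downward), ``gx`` along columns; the combined magnitude is
    ``hypot(vertical_weight * gx, gy)`` so that vertical edges (large
    ``gx``) can be emphasised.
    """

    mask: np.ndarray  # bool, same shape as source
    magnitude: np.ndarray  # float, >= 0
    threshold: float


@dataclass
class SegmentationResult:
    pupil: Circle
    iris: Circle
    pupil_votes: int
    iris_votes: int

    def as_dict(self) -> dict:
        return {
            "pupil": self.pupil.as_dict(),
            "iris": self.iris.as_dict(),
            "pupil_votes": self.pupil_votes,
            "iris_votes": self.iris_votes,
        }


def edge_map(
    image: np.ndarray,
    thresh_quantile: float = 0.95,
    vertical_weight: float = 1.0,
    smooth_sigma: float = 1.5,
) -> EdgeMap:
    """Gradient edge map: magnitude above a quantile of nonzero magnitudes.

    ``vertical_weight > 1`` multiplies the column-derivative component so
    vertical edges dominate the threshold (used for the limbic pass).  A
    constant image yields an empty mask, not an error.
    """
    img = np.asarray(image, dtype=np.float64)
    if img.ndim != 2 or min(img.shape) < 16:
        raise ValueError("image must be 2-D and at least 16x16")
    if smooth_sigma > 0:
        img = gaussian_filter(img, smooth_sigma)
    gy, gx = np.gradient(img)
    mag = np.hypot(vertical_weight * gx, gy)
    nz = mag[mag > 0]
    if nz.size == 0:
        return EdgeMap(np.zeros_like(mag, dtype=bool), mag, np.inf)
    thr = float(np.quantile(nz, thresh_quantile))
    # >= keeps ties: a uniform-gradient edge would otherwise mask to nothing
    return EdgeMap(mag >= thr, mag, thr)


def _radius_offsets(r_min: int, r_max: int) -> dict[int, np.ndarray]:
    """For each integer radius, the (dy, dx) offsets with rint(hypot)==r."""
    span = np.arange(-r_max, r_max + 1)
    dy, dx = np.meshgrid(span, span, indexing="ij")
    rr = np.rint(np.hypot(dy, dx)).astype(np.int64)
    out = {}
    for r in range(r_min, r_max + 1):
        sel = rr == r
        out[r] = np.stack([dy[sel], dx[sel]], axis=1)
    return out


def hough_accumulator(
    mask: np.ndarray,
    r_range: tuple[int, int],
    center_window: tuple[int, int, int, int] | None = None,
) -> np.ndarray:
    """Integer vote counts over (r, yc, xc).

    With ``center_window = (y0, y1, x0, x1)`` (half-open) only centers in the
    window are scored; the returned accumulator then has shape
    ``(n_r, y1 - y0, x1 - x0)``.  Both code paths implement the same voting
    rule, one by scattering votes from edge pixels, one by distance counting.
    """
    mask = np.asarray(mask, dtype=bool)
    h, w = mask.shape
    r_min, r_max = int(r_range[0]), int(r_range[1])
    if r_min < 1 or r_max >= max(h, w):
        raise ValueError(f"radius range {r_range} invalid for {h}x{w} image")
    ys, xs = np.nonzero(mask)
    n_r = r_max - r_min + 1

    if center_window is not None:
        y0, y1, x0, x1 = center_window
        cy = np.arange(y0, y1)
        cx = np.arange(x0, x1)
        gy, gx = np.meshgrid(cy, cx, indexing="ij")
        centers = np.stack([gy.ravel(), gx.ravel()], axis=1)
        acc = np.zeros((n_r, len(cy), len(cx)), dtype=np.int64)
        if ys.size:
            d = np.hypot(
                centers[:, 0][:, None] - ys[None, :],
                centers[:, 1][:, None] - xs[None, :],
            )
            ri = np.rint(d).astype(np.int64) - r_min
            valid = (ri >= 0) & (ri < n_r)
            cell = np.repeat(np.arange(centers.shape[0]), xs.size).reshape(ri.shape)
            flat = np.bincount(
                (cell[valid] * n_r + ri[valid]),
                minlength=centers.shape[0] * n_r,
            )
            acc = flat.reshape(len(cy), len(cx), n_r).transpose(2, 0, 1).copy()
        return acc

    acc = np.zeros((n_r, h, w), dtype=np.int64)
    if ys.size == 0:
        return acc
    offsets = _radius_offsets(r_min, r_max)
    for r in range(r_min, r_max + 1):
        off = offsets[r]
        oy = ys[:, None] + off[None, :, 0]
        ox = xs[:, None] + off[None, :, 1]
        ok = (oy >= 0) & (oy < h) & (ox >= 0) & (ox < w)
        idx = oy[ok] * w + ox[ok]
        acc[r - r_min] += np.bincount(idx, minlength=h * w).reshape(h, w)
    return acc


def hough_circles(
    mask: np.ndarray,
    r_range: tuple[int, int],
    center_window: tuple[int, int, int, int] | None = None,
) -> tuple[Circle, int, np.ndarray]:
    """Peak circle of the Hough accumulator.

    Returns (circle, vote count, accumulator).  Requires at least 8 edge
    pixels.  Ties at the maximum break toward the smallest radius, then
    row-major center order — ``argmax`` on the (r, yc, xc) layout does
    exactly that.
    """
    mask = np.asarray(mask, dtype=bool)
    if int(mask.sum()) < 8:
        raise SegmentationError("too few edge pixels for Hough voting")
    acc = hough_accumulator(mask, r_range, center_window)
    flat_idx = int(np.argmax(acc))
    ri, yi, xi = np.unravel_index(flat_idx, acc.shape)
    votes = int(acc[ri, yi, xi])
    if votes <= 0:
        raise SegmentationError("no votes cast in the radius window")
    y_off = x_off = 0
    if center_window is not None:
        y_off, _, x_off, _ = center_window
    circle = Circle(xc=float(xi + x_off), yc=float(yi + y_off), r=float(ri + r_range[0]))
    return circle, votes, acc


def _clip_window(cy: float, cx: float, half: int, h: int, w: int) -> tuple[int, int, int, int]:
    return (
        max(int(cy) - half, 0),
        min(int(cy) + half + 1, h),
        max(int(cx) - half, 0),
        min(int(cx) + half + 1, w),
    )


def segment_iris(image: np.ndarray, cfg: HoughConfig | None = None) -> SegmentationResult:
    """Two-pass pupil + limbic circle localization.

    The pupil pass exploits the pupil being the darkest structure in the
    eye: edge pixels are restricted to the (dilated) dark region, which
    discards iris-texture edges that would otherwise out-vote the small
    pupil circle, and centers are searched near the dark-region centroid.
    If the image has no dark region the pass falls back to an unrestricted
    full-image search.  The iris pass uses vertically weighted edges and a
    center window around the found pupil.

    On a pupil-not-inside-iris inconsistency the whole procedure is retried
    once with the edge threshold quantile halved (more edge pixels); if the
    geometry is still inconsistent a :class:`SegmentationError` carrying
    both candidate circles is raised.
    """
    cfg = cfg or HoughConfig()
    cfg.validate()
    img = np.asarray(image)
    h, w = img.shape
    smooth = gaussian_filter(np.asarray(img, dtype=np.float64), max(cfg.smooth_sigma, 1.0))
    dark = smooth < cfg.pupil_dark_thresh

    def attempt(quantile: float) -> tuple[Circle, int, Circle, int]:
        pupil_edges = edge_map(img, quantile, 1.0, cfg.smooth_sigma)
        pupil_mask = pupil_edges.mask
        window = None
        if dark.any():
            near_dark = binary_dilation(dark, iterations=3)
            restricted = pupil_mask & near_dark
            if int(restricted.sum()) >= 8:
                pupil_mask = restricted
                ys, xs = np.nonzero(dark)
                window = _clip_window(
                    ys.mean(), xs.mean(), cfg.pupil_center_window, h, w
                )
        pupil, pv, _ = hough_circles(pupil_mask, cfg.pupil_r_range, window)
        iris_edges = edge_map(img, quantile, cfg.vertical_weight, cfg.smooth_sigma)
        iwin = _clip_window(pupil.yc, pupil.xc, cfg.center_window, h, w)
        iris, iv, _ = hough_circles(iris_edges.mask, cfg.iris_r_range, iwin)
        return pupil, pv, iris, iv

    pupil, pv, iris, iv = attempt(cfg.edge_thresh_quantile)
    if not iris.contains_circle(pupil):
        pupil, pv, iris, iv = attempt(cfg.edge_thresh_quantile / 2.0)
        if not iris.contains_circle(pupil):
            raise SegmentationError(
                f"pupil {pupil} not inside iris {iris} after relaxed retry",
                pupil=pupil,
                iris=iris,
            )
    return SegmentationResult(pupil=pupil, iris=iris, pupil_votes=pv, iris_votes=iv)
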