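"""Rubber-sheet unwrapping of the iris annulus to a fixed polar rectangle.

Every segmented iris, regardless of pupil dilation or eye size, maps to the
same radial_res x angular_res grid so templates are directly comparable.
Column j samples angle theta_j = 2*pi*j/angular_res (half-open); row i
samples the radial fraction t_i = i/(radial_res-1) from the pupil boundary
(row 0) to the limbic boundary (last row).  Non-concentric circles are
handled by blending the two boundary points at each angle:

    s(i, j) = (1 - t_i) * P(theta_j) + t_i * L(theta_j)

with P/L the pupil/limbic boundary points.  Angles run counter-clockwise in
(x, y) with y along increasing row index; intensities are sampled with
bilinear interpolation, and rare out-of-image samples are clamped to the
border and counted in the template metadata.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import map_coordinates

from .geometry import Circle
from .segment import SegmentationResult


@dataclass
class PolarTemplate:
    """Normalized iris: (radial_res, angular_res) float intensities in [0, 255]."""

    values: np.ndarray
    pupil: Circle | None = None
    iris: Circle | None = None
    clamped: int = 0  # samples that fell outside the image and were clamped

    @property
    def radial_res(self) -> int:
        return self.values.shape[0]

    @property
    def angular_res(self) -> int:
        return self.values.shape[1]


def rubber_sheet(
    image: np.ndarray,
    seg: SegmentationResult,
    radial_res: int = 60,
    angular_res: int = 300,
) -> PolarTemplate:
    if radial_res < 2 or angular_res < 8:
        raise ValueError("radial_res >= 2 and angular_res >= 8 required")
    img = np.asarray(image, dtype=np.float64)
    h, w = img.shape
    pupil, iris = seg.pupil, seg.iris
    if not iris.contains_circle(pupil):
        raise ValueError("pupil circle must lie strictly inside the iris circle")

    theta = 2.0 * np.pi * np.arange(angular_res) / angular_res
    t = np.arange(radial_res) / (radial_res - 1)

    px = pupil.xc + pupil.r * np.cos(theta)
    py = pupil.yc + pupil.r * np.sin(theta)
    lx = iris.xc + iris.r * np.cos(theta)
    ly = iris.yc + iris.r * np.sin(theta)

    X = (1.0 - t)[:, None] * px[None, :] + t[:, None] * lx[None, :]
    Y = (1.0 - t)[:, None] * py[None, :] + t[:, None] * ly[None, :]

    outside = (X < 0) | (X > w - 1) | (Y < 0) | (Y > h - 1)
    clamped = int(np.count_nonzero(outside))
    Xc = np.clip(X, 0, w - 1)
    Yc = np.clip(Y, 0, h - 1)

    values = map_coordinates(img, [Yc, Xc], order=1, mode="nearest")
    return PolarTemplate(values=values, pupil=pupil, iris=iris, clamped=clamped)


def rotate_template(t: PolarTemplate, shift: int) -> PolarTemplate:
    """Circular column shift — compensates in-plane eye rotation."""
    if abs(shift) >= t.angular_res:
        raise ValueError("|shift| must be smaller than angular_res")
    return PolarTemplate(
        values=np.roll(t.values, shift, axis=1),
        pupil=t.pupil,
        iris=t.iris,
        clamped=t.clamped,
    )
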