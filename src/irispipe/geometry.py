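"""Basic geometric primitives shared across the pipeline."""

from __future__ import annotations

from dataclasses import dataclass


class GeometryError(ValueError):
    """Raised when circles or image bounds are inconsistent."""


@dataclass(frozen=True)
class Circle:
    """A circle in pixel coordinates.

    ``xc`` is the column coordinate, ``yc`` the row coordinate (0-based,
    row-major image convention), ``r`` the radius.  All in pixels.
    """

    xc: float
    yc: float
    r: float

    def __post_init__(self) -> None:
        if self.r <= 0:
            raise GeometryError(f"circle radius must be positive, got {self.r}")

    def contains_circle(self, other: "Circle") -> bool:
        """True if ``other`` lies strictly inside this circle."""
        d = ((self.xc - other.xc) ** 2 + (self.yc - other.yc) ** 2) ** 0.5
        return d + other.r < self.r

    def inside_image(self, height: int, width: int) -> bool:
        return (
            self.xc - self.r >= 0
            and self.yc - self.r >= 0
            and self.xc + self.r <= width - 1
            and self.yc + self.r <= height - 1
        )

    def as_dict(self) -> dict:
        return {"xc": self.xc, "yc": self.yc, "r": self.r}

    @classmethod
    def from_dict(cls, d: dict) -> "Circle":
        return cls(xc=d["xc"], yc=d["yc"], r=d["r"])
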