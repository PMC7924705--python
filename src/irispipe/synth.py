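"""Synthetic eye-image generator with known ground-truth geometry.

Real iris imagery is gated behind dataset licenses, so every stage of the
pipeline is exercised on procedurally generated eyes: a dark near-circular
pupil inside a textured iris annulus inside a bright sclera.  The iris
texture is a band-limited sum of radial/angular sinusoids whose phases and
frequencies are seeded per subject, so two subjects have distinct but
individually reproducible patterns — the property the pipeline is supposed
to exploit.  Additive Gaussian pixel noise and an optional horizontal
bright-band occlusion (a crude stand-in for eyelids) degrade the images.

Rendering is bit-exact reproducible from the :class:`EyeSpec` alone.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.ndimage import gaussian_filter

from .geometry import Circle, GeometryError

# Base intensities (8-bit scale) for the three regions.  The pupil is dark,
# the sclera bright, and the iris sits mid-range so subject texture of
# amplitude ~±45 never collides with either neighbour.
PUPIL_LEVEL = 30.0
IRIS_LEVEL = 130.0
SCLERA_LEVEL = 220.0
OCCLUSION_LEVEL = 200.0
_TEXTURE_CLIP = 60.0


@dataclass(frozen=True)
class EyeSpec:
    """Complete recipe for one synthetic eye image."""

    subject_id: int
    pupil: Circle
    iris: Circle
    image_size: tuple[int, int] = (280, 320)  # (height, width) px
    texture_seed: int = 0
    noise_sigma: float = 0.0  # sd of additive Gaussian noise, 0-255 scale
    noise_seed: int = 0  # distinguishes captures of the same subject
    occlusion_fraction: float = 0.0  # fraction of iris vertical extent covered

    def validate(self) -> None:
        h, w = self.image_size
        if not self.iris.contains_circle(self.pupil):
            raise GeometryError(
                f"pupil {self.pupil} not strictly inside iris {self.iris}"
            )
        if not self.iris.inside_image(h, w):
            raise GeometryError(f"iris {self.iris} not inside {h}x{w} image")
        if self.noise_sigma < 0:
            raise GeometryError("noise_sigma must be >= 0")
        if not 0.0 <= self.occlusion_fraction <= 0.4:
            raise GeometryError("occlusion_fraction must be in [0, 0.4]")

    def as_dict(self) -> dict:
        return {
            "subject_id": self.subject_id,
            "pupil": self.pupil.as_dict(),
            "iris": self.iris.as_dict(),
            "image_size": list(self.image_size),
            "texture_seed": self.texture_seed,
            "noise_sigma": self.noise_sigma,
            "noise_seed": self.noise_seed,
            "occlusion_fraction": self.occlusion_fraction,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "EyeSpec":
        return cls(
            subject_id=d["subject_id"],
            pupil=Circle.from_dict(d["pupil"]),
            iris=Circle.from_dict(d["iris"]),
            image_size=tuple(d["image_size"]),
            texture_seed=d["texture_seed"],
            noise_sigma=d["noise_sigma"],
            noise_seed=d.get("noise_seed", 0),
            occlusion_fraction=d.get("occlusion_fraction", 0.0),
        )


@dataclass
class GroundTruth:
    """A rendered eye image together with the spec that produced it."""

    spec: EyeSpec
    image: np.ndarray  # uint8, shape image_size


@dataclass
class CohortRecord:
    path: str
    subject_id: int


def _iris_texture(spec: EyeSpec, rho: np.ndarray, phi: np.ndarray) -> np.ndarray:
    """Band-limited procedural texture, deterministic in (subject_id, texture_seed).

    A sum of 3-6 radial/angular sinusoids with subject-seeded frequencies and
    phases plus a seeded smooth noise field.  ``rho`` is the distance from the
    iris center in px, ``phi`` the angle.
    """
    ss = np.random.SeedSequence(
        entropy=int(spec.texture_seed) & 0x7FFFFFFF,
        spawn_key=(int(spec.subject_id),),
    )
    rng = np.random.default_rng(ss)
    n_waves = int(rng.integers(3, 7))
    tex = np.zeros_like(rho)
    for _ in range(n_waves):
        amp = rng.uniform(8.0, 16.0)
        k_r = rng.uniform(0.08, 0.30)  # radial frequency, cycles/px
        m = int(rng.integers(2, 13))  # angular harmonic
        ph_r = rng.uniform(0, 2 * np.pi)
        ph_a = rng.uniform(0, 2 * np.pi)
        tex += amp * np.cos(2 * np.pi * k_r * rho + ph_r) * np.cos(m * phi + ph_a)
    smooth = gaussian_filter(rng.standard_normal(rho.shape), sigma=4.0)
    tex += 12.0 * smooth / max(np.std(smooth), 1e-12)
    return np.clip(tex, -_TEXTURE_CLIP, _TEXTURE_CLIP)


def render_eye(spec: EyeSpec) -> GroundTruth:
    """Render a synthetic eye image from its spec.

    Raises :class:`GeometryError` if the spec geometry is inconsistent.
    """
    spec.validate()
    h, w = spec.image_size
    yy, xx = np.mgrid[0:h, 0:w].astype(np.float64)

    d_pupil = np.hypot(yy - spec.pupil.yc, xx - spec.pupil.xc)
    d_iris = np.hypot(yy - spec.iris.yc, xx - spec.iris.xc)
    phi = np.arctan2(yy - spec.iris.yc, xx - spec.iris.xc)

    img = np.full((h, w), SCLERA_LEVEL)
    in_iris = (d_iris <= spec.iris.r) & (d_pupil > spec.pupil.r)
    img[in_iris] = IRIS_LEVEL + _iris_texture(spec, d_iris, phi)[in_iris]
    img[d_pupil <= spec.pupil.r] = PUPIL_LEVEL

    if spec.occlusion_fraction > 0:
        band = spec.occlusion_fraction * spec.iris.r  # px per band (top+bottom)
        top = int(round(spec.iris.yc - spec.iris.r + band))
        bot = int(round(spec.iris.yc + spec.iris.r - band))
        img[: max(top, 0), :] = OCCLUSION_LEVEL
        img[max(bot, 0):, :] = OCCLUSION_LEVEL

    if spec.noise_sigma > 0:
        nss = np.random.SeedSequence(
            entropy=int(spec.noise_seed) & 0x7FFFFFFF,
            spawn_key=(int(spec.subject_id), int(spec.texture_seed) & 0x7FFFFFFF),
        )
        nrng = np.random.default_rng(nss)
        img = img + nrng.normal(0.0, spec.noise_sigma, size=img.shape)

    img = np.clip(np.rint(img), 0, 255).astype(np.uint8)
    return GroundTruth(spec=spec, image=img)


def make_cohort(
    n_subjects: int,
    images_per_subject: int,
    master_seed: int,
    *,
    noise_sigma: float = 8.0,
    occlusion_fraction: float = 0.0,
    image_size: tuple[int, int] = (280, 320),
    out_dir: str | Path | None = None,
) -> tuple[list[GroundTruth], list[CohortRecord]]:
    """Generate a reproducible multi-capture cohort.

    Per subject the captures share the texture seed (same iris) but differ in
    noise realization and in a small (<=3 px) whole-eye center jitter, which
    emulates repeated acquisition of the same eye.  Geometry is drawn per
    subject: pupil radius in [15, 35] px, iris radius in [55, 90] px, centers
    near the image center.  If ``out_dir`` is given, PNG images and a
    ``manifest.csv`` with header ``path,subject_id`` are written there.
    """
    if n_subjects < 2:
        raise ValueError("need at least 2 subjects")
    if images_per_subject < 1:
        raise ValueError("need at least 1 image per subject")
    h, w = image_size
    rng = np.random.default_rng(int(master_seed) & 0x7FFFFFFF)

    truths: list[GroundTruth] = []
    records: list[CohortRecord] = []
    for sid in range(n_subjects):
        pupil_r = int(rng.integers(15, 36))
        iris_r = int(rng.integers(55, 91))
        cy = h // 2 + int(rng.integers(-10, 11))
        cx = w // 2 + int(rng.integers(-10, 11))
        # small fixed pupil decentration, kept well inside the annulus
        pdy, pdx = int(rng.integers(-2, 3)), int(rng.integers(-2, 3))
        for img_idx in range(images_per_subject):
            jy, jx = int(rng.integers(-3, 4)), int(rng.integers(-3, 4))
            spec = EyeSpec(
                subject_id=sid,
                pupil=Circle(xc=cx + pdx + jx, yc=cy + pdy + jy, r=pupil_r),
                iris=Circle(xc=cx + jx, yc=cy + jy, r=iris_r),
                image_size=image_size,
                texture_seed=int(master_seed) & 0x7FFFFFFF,
                noise_sigma=noise_sigma,
                noise_seed=int(rng.integers(0, 2**31)),
                occlusion_fraction=occlusion_fraction,
            )
            truths.append(render_eye(spec))
            records.append(
                CohortRecord(path=f"s{sid:03d}_i{img_idx:02d}.png", subject_id=sid)
            )

    if out_dir is not None:
        from .imgio import write_gray  # local import to avoid cycle

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for gt, rec in zip(truths, records):
            write_gray(out / rec.path, gt.image)
        with open(out / "manifest.csv", "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["path", "subject_id"])
            for rec in records:
                writer.writerow([rec.path, rec.subject_id])
    return truths, records
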