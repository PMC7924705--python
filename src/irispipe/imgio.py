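"""Readers and writers: images, manifests, templates, models, run config.

Images go through Pillow (PNG/PGM/JPEG); color inputs are collapsed to
luminance with the ITU-R 601 weights (Pillow's ``convert("L")``).  Arrays
are stored as NPY with an optional JSON metadata sidecar; the PCA and SVM
models as NPZ bundles.  The run configuration is YAML, with every field
given a default so an empty file is a valid config.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml
from PIL import Image


class FormatError(ValueError):
    """Raised when a serialized artifact does not match its contract."""


class ManifestError(ValueError):
    pass


# ---------------------------------------------------------------------------
# images


def read_gray(path: str | Path) -> np.ndarray:
    """Read an image as an 8-bit grayscale matrix.

    Color inputs are converted by ITU-R 601 luminance weighting; grayscale
    inputs pass through unchanged.
    """
    path = Path(path)
    try:
        with Image.open(path) as im:
            if im.mode != "L":
                im = im.convert("L")
            arr = np.asarray(im, dtype=np.uint8)
    except FileNotFoundError:
        raise
    except Exception as exc:  # PIL raises a zoo of decode errors
        raise OSError(f"cannot read image {path}: {exc}") from exc
    if arr.ndim != 2:
        raise OSError(f"cannot read image {path}: not a 2-D image")
    return arr


def write_gray(path: str | Path, image: np.ndarray) -> None:
    """Write an 8-bit grayscale matrix as PNG/PGM/JPEG (by extension)."""
    arr = np.asarray(image)
    if arr.ndim != 2:
        raise ValueError("expected a 2-D grayscale matrix")
    Image.fromarray(arr.astype(np.uint8), mode="L").save(Path(path))


# ---------------------------------------------------------------------------
# manifests


@dataclass
class Manifest:
    """Rows of (image path, integer subject id)."""

    records: list[tuple[str, int]]

    def __post_init__(self) -> None:
        paths = [p for p, _ in self.records]
        if len(set(paths)) != len(paths):
            raise ManifestError("manifest paths are not unique")

    @property
    def subject_ids(self) -> list[int]:
        return sorted({sid for _, sid in self.records})

    def __len__(self) -> int:
        return len(self.records)


def read_manifest(path: str | Path) -> Manifest:
    path = Path(path)
    records: list[tuple[str, int]] = []
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        if header is None or [h.strip() for h in header[:2]] != ["path", "subject_id"]:
            raise ManifestError(f"{path}: expected header 'path,subject_id'")
        for row in reader:
            if not row:
                continue
            records.append((row[0], int(row[1])))
    if not records:
        raise ManifestError(f"{path}: empty manifest")
    return Manifest(records)


def write_manifest(path: str | Path, manifest: Manifest) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["path", "subject_id"])
        for rec_path, sid in manifest.records:
            writer.writerow([rec_path, sid])


# ---------------------------------------------------------------------------
# configuration


@dataclass
class HoughConfig:
    pupil_r_range: tuple[int, int] = (12, 40)  # px, inclusive
    iris_r_range: tuple[int, int] = (50, 95)  # px, inclusive
    edge_thresh_quantile: float = 0.95  # fraction of nonzero gradient magnitudes
    vertical_weight: float = 4.0  # emphasis on vertical edges in the iris pass
    smooth_sigma: float = 1.5  # Gaussian presmoothing, px
    center_window: int = 15  # iris center must lie within this of pupil center
    pupil_dark_thresh: float = 80.0  # intensity below which a pixel is "pupil-dark"
    pupil_center_window: int = 40  # pupil center search half-width around dark centroid

    def validate(self) -> None:
        if not (self.pupil_r_range[0] <= self.pupil_r_range[1]):
            raise ValueError("empty pupil radius range")
        if not (self.iris_r_range[0] <= self.iris_r_range[1]):
            raise ValueError("empty iris radius range")
        if self.pupil_r_range[1] >= self.iris_r_range[0]:
            raise ValueError("pupil radius range must lie below iris radius range")
        if not 0 < self.edge_thresh_quantile < 1:
            raise ValueError("edge_thresh_quantile must be in (0,1)")
        if self.vertical_weight < 1:
            raise ValueError("vertical_weight must be >= 1")


@dataclass
class PipelineConfig:
    """All pipeline parameters, with the defaults used throughout.

    The normalized template is 60 radial x 300 angular samples and its
    one-level DWT approximation band is therefore 30 x 150.
    """

    radial_res: int = 60
    angular_res: int = 300
    wavelet: str = "haar"
    pca_components: float | int = 0.95  # variance fraction, or an int count
    svm_c: float = 1.0
    hough: HoughConfig = field(default_factory=HoughConfig)

    def validate(self) -> None:
        if self.radial_res < 2:
            raise ValueError("radial_res must be >= 2")
        if self.angular_res < 8:
            raise ValueError("angular_res must be >= 8")
        if self.svm_c <= 0:
            raise ValueError("svm_c must be positive")
        self.hough.validate()

    def as_dict(self) -> dict:
        d = asdict(self)
        d["hough"]["pupil_r_range"] = list(self.hough.pupil_r_range)
        d["hough"]["iris_r_range"] = list(self.hough.iris_r_range)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d or {})
        hough_d = dict(d.pop("hough", {}) or {})
        for key in ("pupil_r_range", "iris_r_range"):
            if key in hough_d:
                hough_d[key] = tuple(hough_d[key])
        cfg = cls(**{**d, "hough": HoughConfig(**hough_d)})
        cfg.validate()
        return cfg


def read_config(path: str | Path | None) -> PipelineConfig:
    """Load a YAML config; missing file/fields fall back to defaults."""
    if path is None:
        return PipelineConfig()
    with open(path) as fh:
        data = yaml.safe_load(fh)
    return PipelineConfig.from_dict(data or {})


def write_config(path: str | Path, config: PipelineConfig) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.as_dict(), fh, sort_keys=False)


# ---------------------------------------------------------------------------
# arrays, templates, models


def save_array(path: str | Path, arr: np.ndarray, meta: dict | None = None) -> None:
    """Save an array as NPY with an optional JSON sidecar (``.json`` suffix)."""
    arr = np.asarray(arr)
    if arr.size == 0:
        raise FormatError("refusing to save an empty array")
    if np.issubdtype(arr.dtype, np.floating) and not np.all(np.isfinite(arr)):
        raise FormatError("array contains non-finite values")
    path = Path(path)
    np.save(path, arr)
    if meta is not None:
        sidecar = path.with_suffix(path.suffix + ".json")
        with open(sidecar, "w") as fh:
            json.dump(meta, fh, indent=1)


def load_array(path: str | Path, expect_shape: tuple[int, ...] | None = None):
    """Load an NPY array (+ sidecar meta if present). Returns (array, meta)."""
    path = Path(path)
    arr = np.load(path)
    if expect_shape is not None and arr.shape != expect_shape:
        raise FormatError(f"{path}: expected shape {expect_shape}, got {arr.shape}")
    meta = None
    sidecar = path.with_suffix(path.suffix + ".json")
    if sidecar.exists():
        with open(sidecar) as fh:
            meta = json.load(fh)
    return arr, meta


def save_pca_model(path: str | Path, model) -> None:
    np.savez(
        Path(path),
        mean=model.mean,
        eigenvalues=model.eigenvalues,
        eigenvectors=model.eigenvectors,
        k=np.array(model.k),
        n_train=np.array(model.n_train),
    )


def load_pca_model(path: str | Path):
    from .features import PCAModel

    with np.load(Path(path)) as data:
        try:
            return PCAModel(
                mean=data["mean"],
                eigenvalues=data["eigenvalues"],
                eigenvectors=data["eigenvectors"],
                k=int(data["k"]),
                n_train=int(data["n_train"]),
            )
        except KeyError as exc:
            raise FormatError(f"{path}: missing PCA model field {exc}") from exc


def save_svm_model(path: str | Path, model) -> None:
    sids = sorted(model.hyperplanes)
    W = np.stack([model.hyperplanes[s][0] for s in sids])
    b = np.array([model.hyperplanes[s][1] for s in sids])
    np.savez(
        Path(path),
        subject_ids=np.array(sids),
        weights=W,
        biases=b,
        c=np.array(model.c),
        threshold=np.array(model.threshold),
    )


def load_svm_model(path: str | Path):
    from .matcher import SVMModel

    with np.load(Path(path)) as data:
        try:
            sids = data["subject_ids"]
            W = data["weights"]
            b = data["biases"]
            hyper = {int(s): (W[i].copy(), float(b[i])) for i, s in enumerate(sids)}
            return SVMModel(
                hyperplanes=hyper,
                c=float(data["c"]),
                kernel="linear",
                threshold=float(data["threshold"]),
            )
        except KeyError as exc:
            raise FormatError(f"{path}: missing SVM model field {exc}") from exc
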