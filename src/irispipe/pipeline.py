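"""End-to-end orchestration: enroll a cohort, then verify a test cohort.

Enrollment: read image -> segment -> rubber-sheet normalize -> DWT LL; fit
PCA on the enrolled LL vectors, project them, and train the one-vs-rest
SVMs.  Testing: same per-image chain with the frozen PCA model, then the
genuine/impostor trial protocol.  Per-image segmentation failures are
logged and skipped; a run aborts only if more than 20% of its images fail.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .features import PCAModel, ll_vector, pca_fit, pca_project
from .imgio import Manifest, PipelineConfig, read_gray
from .matcher import EvalReport, SVMModel, evaluate, svm_train
from .normalize import rubber_sheet
from .segment import SegmentationError, segment_iris


class PipelineError(RuntimeError):
    pass


@dataclass
class RunRecord:
    """Accounting for one pipeline run: per-image status and stage timings."""

    mode: str
    config: dict
    statuses: dict[str, str] = field(default_factory=dict)  # path -> ok|failed
    timings: dict[str, float] = field(default_factory=dict)  # stage -> seconds
    report: EvalReport | None = None

    @property
    def n_ok(self) -> int:
        return sum(1 for s in self.statuses.values() if s == "ok")

    @property
    def n_failed(self) -> int:
        return sum(1 for s in self.statuses.values() if s != "ok")

    def as_dict(self) -> dict:
        d = {
            "mode": self.mode,
            "config": self.config,
            "statuses": self.statuses,
            "timings": self.timings,
        }
        if self.report is not None:
            d["report"] = self.report.as_dict()
        return d


def _extract_ll_vectors(
    manifest: Manifest,
    config: PipelineConfig,
    base_dir: Path,
    record: RunRecord,
    images: dict[str, np.ndarray] | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Segment + normalize + DWT every manifest image; returns (LL matrix, ids)."""
    vecs, ids = [], []
    t0 = time.perf_counter()
    for path, sid in manifest.records:
        try:
            img = images[path] if images is not None else read_gray(base_dir / path)
            seg = segment_iris(img, config.hough)
            tmpl = rubber_sheet(img, seg, config.radial_res, config.angular_res)
            vecs.append(ll_vector(tmpl, config.wavelet))
            ids.append(sid)
            record.statuses[path] = "ok"
        except (SegmentationError, OSError) as exc:
            record.statuses[path] = f"failed: {exc}"
    record.timings["segment_normalize_dwt"] = time.perf_counter() - t0
    if record.n_failed > 0.2 * len(manifest):
        raise PipelineError(
            f"{record.n_failed}/{len(manifest)} images failed segmentation"
        )
    if not vecs:
        raise PipelineError("no images survived the per-image stages")
    return np.stack(vecs), np.array(ids)


def enroll(
    manifest: Manifest,
    config: PipelineConfig | None = None,
    base_dir: str | Path = ".",
    images: dict[str, np.ndarray] | None = None,
) -> tuple[PCAModel, SVMModel, np.ndarray, np.ndarray, RunRecord]:
    """Train the PCA projection and per-subject SVMs from an enrollment set.

    ``images`` may supply in-memory arrays keyed by manifest path, bypassing
    disk reads (used by the synthetic benchmarks).
    """
    config = config or PipelineConfig()
    config.validate()
    if len(manifest) == 0:
        raise PipelineError("empty manifest")
    record = RunRecord(mode="enroll", config=config.as_dict())
    X_ll, ids = _extract_ll_vectors(manifest, config, Path(base_dir), record, images)

    t0 = time.perf_counter()
    pca = pca_fit(X_ll, components=config.pca_components)
    feats = np.stack([pca_project(pca, v) for v in X_ll])
    record.timings["pca_fit_project"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    svm = svm_train(feats, ids, c=config.svm_c)
    record.timings["svm_train"] = time.perf_counter() - t0
    return pca, svm, feats, ids, record


def run_test(
    manifest: Manifest,
    pca: PCAModel,
    svm: SVMModel,
    config: PipelineConfig | None = None,
    base_dir: str | Path = ".",
    images: dict[str, np.ndarray] | None = None,
    impostor_seed: int = 0,
) -> RunRecord:
    """Verify a test set against trained models; returns the filled RunRecord."""
    config = config or PipelineConfig()
    config.validate()
    if len(manifest) == 0:
        raise PipelineError("empty manifest")
    record = RunRecord(mode="test", config=config.as_dict())
    X_ll, ids = _extract_ll_vectors(manifest, config, Path(base_dir), record, images)
    feats = np.stack([pca_project(pca, v) for v in X_ll])
    report = evaluate(svm, feats, ids, impostor_seed=impostor_seed)
    record.timings["classification"] = report.classification_seconds
    record.report = report
    return record
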