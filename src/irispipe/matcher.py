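"""SVM verification of iris feature vectors and FAR/FRR evaluation.

Verification is framed one-vs-rest: enrollment trains one soft-margin
linear SVM per subject (that subject's feature vectors against everyone
else's), giving a hyperplane w.x + b = 0 per identity.  A claim of
identity s with feature f is accepted iff w_s . f + b_s exceeds the
decision threshold (default 0, the canonical SVM rule).

Error rates follow the standard verification conventions:

    FAR = impostor_accept / (impostor_accept + impostor_reject) * 100
    FRR = genuine_reject  / (genuine_accept + genuine_reject)  * 100
    accuracy = (genuine_accept + impostor_reject) / all trials * 100

The default trial protocol pairs each test vector with one genuine claim
(its true identity) and one seeded impostor claim (a uniformly drawn wrong
enrolled identity).
"""

from __future__ import annotations

import time
from dataclasses import dataclass

import numpy as np
from sklearn.svm import SVC


class MatcherError(ValueError):
    pass


@dataclass
class SVMModel:
    """Per-subject linear hyperplanes (w, b) plus the decision threshold."""

    hyperplanes: dict[int, tuple[np.ndarray, float]]
    c: float = 1.0
    kernel: str = "linear"
    threshold: float = 0.0

    @property
    def subject_ids(self) -> list[int]:
        return sorted(self.hyperplanes)


@dataclass
class Decision:
    claimed_subject: int
    accepted: bool
    score: float


@dataclass
class EvalReport:
    genuine_accept: int
    genuine_reject: int
    impostor_accept: int
    impostor_reject: int
    classification_seconds: float = 0.0

    @property
    def accuracy(self) -> float:
        total = (
            self.genuine_accept
            + self.genuine_reject
            + self.impostor_accept
            + self.impostor_reject
        )
        if total == 0:
            raise MatcherError("no trials")
        return 100.0 * (self.genuine_accept + self.impostor_reject) / total

    @property
    def far(self) -> float | None:
        n = self.impostor_accept + self.impostor_reject
        return None if n == 0 else 100.0 * self.impostor_accept / n

    @property
    def frr(self) -> float | None:
        n = self.genuine_accept + self.genuine_reject
        return None if n == 0 else 100.0 * self.genuine_reject / n

    def as_dict(self) -> dict:
        return {
            "accuracy_pct": self.accuracy,
            "far_pct": self.far,
            "frr_pct": self.frr,
            "counts": {
                "genuine_accept": self.genuine_accept,
                "genuine_reject": self.genuine_reject,
                "impostor_accept": self.impostor_accept,
                "impostor_reject": self.impostor_reject,
            },
            "classification_seconds": self.classification_seconds,
        }


def svm_train(
    features: np.ndarray,
    subject_ids: np.ndarray,
    c: float = 1.0,
    tol: float = 1e-6,
    threshold: float = 0.0,
) -> SVMModel:
    """Train one-vs-rest linear SVMs, one hyperplane per enrolled subject.

    Deterministic given the input order and penalty ``c``.
    """
    X = np.asarray(features, dtype=np.float64)
    y = np.asarray(subject_ids)
    if X.ndim != 2 or X.shape[0] != y.shape[0]:
        raise MatcherError("features must be (N, k) with one subject id per row")
    subjects = sorted(set(int(s) for s in y))
    if len(subjects) < 2:
        raise MatcherError("need at least 2 enrolled subjects")
    if c <= 0:
        raise MatcherError("penalty c must be positive")
    hyper: dict[int, tuple[np.ndarray, float]] = {}
    for sid in subjects:
        labels = np.where(y == sid, 1.0, -1.0)
        clf = SVC(kernel="linear", C=c, tol=tol)
        clf.fit(X, labels)
        # libsvm orders classes ascending (-1, +1); coef_ is for the +1 side
        hyper[sid] = (clf.coef_[0].copy(), float(clf.intercept_[0]))
    return SVMModel(hyperplanes=hyper, c=c, threshold=threshold)


def verify(model: SVMModel, f: np.ndarray, claimed_subject: int) -> Decision:
    """Accept/reject a claimed identity: accept iff w.f + b > threshold."""
    if claimed_subject not in model.hyperplanes:
        raise KeyError(f"subject {claimed_subject} is not enrolled")
    w, b = model.hyperplanes[claimed_subject]
    f = np.asarray(f, dtype=np.float64).ravel()
    if f.shape[0] != w.shape[0]:
        raise MatcherError(f"feature length {f.shape[0]} != model dim {w.shape[0]}")
    score = float(w @ f + b)
    return Decision(
        claimed_subject=claimed_subject,
        accepted=score > model.threshold,
        score=score,
    )


def evaluate(
    model: SVMModel,
    features: np.ndarray,
    true_ids: np.ndarray,
    impostor_seed: int = 0,
) -> EvalReport:
    """Run the genuine + seeded-impostor trial protocol and tally the rates.

    Each test vector makes one genuine claim (its true id) and one impostor
    claim with a uniformly drawn wrong enrolled id.  The classification
    stage is wall-clock timed; the timing is informational only.
    """
    X = np.asarray(features, dtype=np.float64)
    y = np.asarray(true_ids)
    if X.shape[0] == 0:
        raise MatcherError("empty test set")
    enrolled = model.subject_ids
    for tid in y:
        if int(tid) not in model.hyperplanes:
            raise KeyError(f"test subject {int(tid)} is not enrolled")
    # Impostor ids are drawn in a canonical (content-sorted) order so the
    # tally is invariant to permutations of the test set for a fixed seed.
    rng = np.random.default_rng(int(impostor_seed) & 0x7FFFFFFF)
    canonical = np.lexsort(tuple(X.T) + (y.astype(np.int64),))
    impostor_of = np.empty(X.shape[0], dtype=np.int64)
    for i in canonical:
        others = [s for s in enrolled if s != int(y[i])]
        impostor_of[i] = int(rng.choice(others)) if others else -1
    trials: list[tuple[int, int, bool]] = []  # (row, claimed, is_genuine)
    for i in range(X.shape[0]):
        trials.append((i, int(y[i]), True))
        if impostor_of[i] >= 0:
            trials.append((i, int(impostor_of[i]), False))

    ga = gr = ia = ir = 0
    t0 = time.perf_counter()
    for i, claimed, is_genuine in trials:
        dec = verify(model, X[i], claimed)
        if is_genuine:
            ga, gr = ga + dec.accepted, gr + (not dec.accepted)
        else:
            ia, ir = ia + dec.accepted, ir + (not dec.accepted)
    elapsed = time.perf_counter() - t0
    return EvalReport(
        genuine_accept=ga,
        genuine_reject=gr,
        impostor_accept=ia,
        impostor_reject=ir,
        classification_seconds=elapsed,
    )
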