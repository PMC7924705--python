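"""Feature extraction: one-level 2-D DWT, keep the LL band, project by PCA.

The normalized template (default 60 x 300) is decomposed into the four
one-level wavelet sub-bands LL/LH/HL/HH (default Haar, each 30 x 150).
Only the approximation band LL is kept: it carries the coarse iris
structure at a quarter of the pixel count, which is what makes the
subsequent PCA and classification cheap.  The flattened LL vectors are
then projected onto the leading eigenvectors of the (unnormalized) scatter
matrix C = Xz^T Xz of the mean-centered training set.

Because the dimension d (4500 by default) far exceeds the number of
enrollment images N, the eigenproblem is solved through the N x N Gram
matrix Xz Xz^T — the classical snapshot/eigenface route — and the
eigenvectors are mapped back to d-space and renormalized.  Eigenvalues of
the two routes coincide on the nonzero spectrum; the tests check this.

Conventions pinned for reproducibility: C has no 1/N factor (eigenvectors
are unaffected; eigenvalues are documented as unnormalized), eigenpairs are
sorted by descending eigenvalue, each eigenvector's largest-magnitude entry
is made positive, and LL is flattened row-major.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pywt

from .imgio import PipelineConfig
from .normalize import PolarTemplate

_DWT_MODE = "periodization"  # keeps sub-bands at ceil(m/2) and conserves energy


class FitError(ValueError):
    pass


@dataclass
class SubbandSet:
    """The four one-level DWT sub-bands of a template."""

    ll: np.ndarray  # approximation
    lh: np.ndarray  # horizontal detail
    hl: np.ndarray  # vertical detail
    hh: np.ndarray  # diagonal detail
    wavelet: str = "haar"

    @property
    def bands(self) -> dict[str, np.ndarray]:
        return {"LL": self.ll, "LH": self.lh, "HL": self.hl, "HH": self.hh}

    def reconstruct(self) -> np.ndarray:
        return pywt.idwt2((self.ll, (self.lh, self.hl, self.hh)), self.wavelet, mode=_DWT_MODE)


@dataclass
class PCAModel:
    """Mean, eigenvalues (descending, unnormalized) and orthonormal eigenvectors.

    ``eigenvectors`` has shape (d, n_kept); ``k`` is the number of retained
    components used at projection time, ``k <= n_kept <= n_train``.
    """

    mean: np.ndarray
    eigenvalues: np.ndarray
    eigenvectors: np.ndarray
    k: int
    n_train: int

    @property
    def explained_fraction(self) -> np.ndarray:
        total = float(self.eigenvalues.sum())
        if total <= 0:
            return np.zeros_like(self.eigenvalues)
        return np.cumsum(self.eigenvalues) / total


def dwt_level1(values: np.ndarray | PolarTemplate, wavelet: str = "haar") -> SubbandSet:
    """One-level separable 2-D DWT.

    Odd input dimensions are handled by the transform's periodized extension
    (sub-band shapes are ceil(m/2) x ceil(n/2)); the default 60 x 300
    template yields four 30 x 150 bands.
    """
    arr = values.values if isinstance(values, PolarTemplate) else np.asarray(values)
    arr = arr.astype(np.float64)
    if arr.ndim != 2:
        raise ValueError("expected a 2-D template")
    ll, (lh, hl, hh) = pywt.dwt2(arr, wavelet, mode=_DWT_MODE)
    return SubbandSet(ll=ll, lh=lh, hl=hl, hh=hh, wavelet=wavelet)


def _fix_signs(e: np.ndarray) -> np.ndarray:
    """Force each column's largest-magnitude entry positive (deterministic)."""
    if e.size == 0:
        return e
    idx = np.argmax(np.abs(e), axis=0)
    signs = np.sign(e[idx, np.arange(e.shape[1])])
    signs[signs == 0] = 1.0
    return e * signs


def pca_fit(
    vectors: np.ndarray,
    components: float | int = 0.95,
    zero_tol: float = 1e-10,
) -> PCAModel:
    """Fit the eigen-decomposition of the scatter matrix of training vectors.

    ``vectors`` is (N, d) with N >= 2.  ``components`` selects k: an int is
    a fixed count, a float in (0, 1) keeps the smallest k explaining that
    fraction of the total eigenvalue mass, capped at N - 1.  When d > N the
    decomposition runs through the N x N Gram matrix.  Zero-variance data
    is valid and yields an empty spectrum (k = 0).
    """
    X = np.asarray(vectors, dtype=np.float64)
    if X.ndim != 2 or X.shape[0] < 2:
        raise FitError("need at least 2 training vectors of equal length")
    n, d = X.shape
    mean = X.mean(axis=0)
    Xz = X - mean

    if d <= n:
        C = Xz.T @ Xz
        gamma, e = np.linalg.eigh(C)
        order = np.argsort(gamma)[::-1]
        gamma, e = gamma[order], e[:, order]
    else:
        G = Xz @ Xz.T  # Gram (snapshot) matrix, same nonzero spectrum
        gamma, u = np.linalg.eigh(G)
        order = np.argsort(gamma)[::-1]
        gamma, u = gamma[order], u[:, order]
        keep = gamma > max(zero_tol, zero_tol * abs(gamma[0]) if gamma.size else zero_tol)
        gamma = np.where(keep, gamma, 0.0)
        e = np.zeros((d, n))
        nz = np.nonzero(keep)[0]
        if nz.size:
            e[:, nz] = (Xz.T @ u[:, nz]) / np.sqrt(gamma[nz])

    gamma = np.clip(gamma, 0.0, None)
    scale = gamma[0] if gamma.size and gamma[0] > 0 else 1.0
    nonzero = int(np.count_nonzero(gamma > zero_tol * scale))
    gamma = gamma[:max(nonzero, 0)] if nonzero else gamma[:0]
    e = _fix_signs(e[:, : gamma.size])

    if gamma.size == 0:
        k = 0
    elif isinstance(components, (int, np.integer)) and not isinstance(components, bool):
        k = int(min(components, gamma.size))
    else:
        frac = float(components)
        if not 0 < frac <= 1:
            raise FitError("variance fraction must be in (0, 1]")
        cum = np.cumsum(gamma) / gamma.sum()
        k = int(np.searchsorted(cum, frac) + 1)
        k = min(k, max(n - 1, 1), gamma.size)
    return PCAModel(mean=mean, eigenvalues=gamma, eigenvectors=e, k=k, n_train=n)


def pca_project(model: PCAModel, v: np.ndarray, k: int | None = None) -> np.ndarray:
    """Project a vector onto the retained eigenvectors: f = e^T (v - mean)."""
    v = np.asarray(v, dtype=np.float64).ravel()
    if v.shape[0] != model.mean.shape[0]:
        raise ValueError(
            f"vector length {v.shape[0]} != model dimension {model.mean.shape[0]}"
        )
    kk = model.k if k is None else min(int(k), model.eigenvectors.shape[1])
    return model.eigenvectors[:, :kk].T @ (v - model.mean)


def ll_vector(template: PolarTemplate | np.ndarray, wavelet: str = "haar") -> np.ndarray:
    """Flattened (row-major) LL band of a template."""
    return dwt_level1(template, wavelet).ll.ravel()


def extract(
    template: PolarTemplate | np.ndarray,
    model: PCAModel,
    config: PipelineConfig | None = None,
) -> np.ndarray:
    """Template -> DWT LL -> PCA feature vector (the full extraction chain)."""
    wavelet = config.wavelet if config is not None else "haar"
    return pca_project(model, ll_vector(template, wavelet))
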