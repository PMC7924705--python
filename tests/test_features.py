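import numpy as np
import pytest

from irispipe import dwt_level1, extract, ll_vector, pca_fit, pca_project
from irispipe.features import FitError
from irispipe.imgio import PipelineConfig
from irispipe.normalize import rubber_sheet
from irispipe.segment import SegmentationResult


def haar_block_oracle(x):
    """Independent one-level Haar: explicit 2x2 block sums/differences.

    For each block [[a, b], [c, d]]: LL=(a+b+c+d)/2, LH=(a+b-c-d)/2,
    HL=(a-b+c-d)/2, HH=(a-b-c+d)/2 (orthonormal scaling).
    """
    a = x[0::2, 0::2]
    b = x[0::2, 1::2]
    c = x[1::2, 0::2]
    d = x[1::2, 1::2]
    return (
        (a + b + c + d) / 2,
        (a + b - c - d) / 2,
        (a - b + c - d) / 2,
        (a - b - c + d) / 2,
    )


class TestDWT:
    def test_60x300_template_gives_30x150_subbands(self):
        s = dwt_level1(np.random.default_rng(0).uniform(0, 255, (60, 300)))
        assert set(s.bands) == {"LL", "LH", "HL", "HH"}
        for band in s.bands.values():
            assert band.shape == (30, 150)

    def test_constant_input_haar(self):
        s = dwt_level1(np.full((8, 8), 5.0), "haar")
        assert np.allclose(s.ll, 10.0)  # orthonormal Haar scales constants by 2
        for b in (s.lh, s.hl, s.hh):
            assert np.allclose(b, 0.0)

    def test_matches_block_oracle(self):
        x = np.random.default_rng(1).normal(size=(4, 4))
        s = dwt_level1(x, "haar")
        ll, lh, hl, hh = haar_block_oracle(x)
        assert np.allclose(s.ll, ll, atol=1e-10)
        assert np.allclose(s.lh, lh, atol=1e-10)
        assert np.allclose(s.hl, hl, atol=1e-10)
        assert np.allclose(s.hh, hh, atol=1e-10)

    def test_energy_conservation(self):
        x = np.random.default_rng(2).uniform(0, 255, (60, 300))
        s = dwt_level1(x, "haar")
        band_energy = sum(np.sum(v**2) for v in s.bands.values())
        assert band_energy == pytest.approx(np.sum(x**2), rel=1e-6)

    def test_inverse_reconstruction(self):
        x = np.random.default_rng(3).uniform(0, 255, (60, 300))
        s = dwt_level1(x, "db2")
        assert np.allclose(s.reconstruct(), x, atol=1e-8)

    def test_odd_dimensions_ceil_shapes(self):
        x = np.random.default_rng(4).normal(size=(7, 9))
        s = dwt_level1(x, "haar")
        assert s.ll.shape == (4, 5)
        assert np.allclose(s.reconstruct()[:7, :9], x, atol=1e-8)


def char_poly_eigenvalues_3x3(C):
    """Independent eigenvalue oracle: roots of the characteristic cubic,
    with coefficients from trace, principal 2x2 minors, and determinant."""
    tr = C[0, 0] + C[1, 1] + C[2, 2]
    m01 = C[0, 0] * C[1, 1] - C[0, 1] * C[1, 0]
    m02 = C[0, 0] * C[2, 2] - C[0, 2] * C[2, 0]
    m12 = C[1, 1] * C[2, 2] - C[1, 2] * C[2, 1]
    det = (
        C[0, 0] * (C[1, 1] * C[2, 2] - C[1, 2] * C[2, 1])
        - C[0, 1] * (C[1, 0] * C[2, 2] - C[1, 2] * C[2, 0])
        + C[0, 2] * (C[1, 0] * C[2, 1] - C[1, 1] * C[2, 0])
    )
    roots = np.roots([1.0, -tr, m01 + m02 + m12, -det])
    return np.sort(np.real(roots))[::-1]


class TestPCAFit:
    def test_rank_one_pair(self):
        v = np.array([3.0, 4.0, 0.0])
        model = pca_fit(np.stack([v, -v]), components=2)
        assert model.eigenvalues.shape[0] == 1
        assert model.eigenvalues[0] == pytest.approx(2 * 25.0)  # 2*||v||^2
        assert np.allclose(np.abs(model.eigenvectors[:, 0]), v / 5.0)
        assert model.eigenvectors[np.argmax(np.abs(model.eigenvectors[:, 0])), 0] > 0

    def test_eigenvalues_match_characteristic_polynomial(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(3, 3))
        Xz = X - X.mean(axis=0)
        C = Xz.T @ Xz
        expected = char_poly_eigenvalues_3x3(C)
        model = pca_fit(X)
        got = np.zeros(3)
        got[: model.eigenvalues.size] = model.eigenvalues
        assert np.allclose(got, expected, atol=1e-8)

    def test_identical_vectors_zero_spectrum(self):
        X = np.tile(np.array([1.0, 2.0, 3.0]), (4, 1))
        model = pca_fit(X)
        assert model.eigenvalues.size == 0 and model.k == 0

    def test_gram_and_direct_routes_agree(self):
        rng = np.random.default_rng(6)
        X = rng.normal(size=(10, 50))  # d > N: implementation takes Gram route
        model = pca_fit(X, components=9)
        Xz = X - X.mean(axis=0)
        direct = np.sort(np.linalg.eigvalsh(Xz.T @ Xz))[::-1]
        n = model.eigenvalues.size
        assert np.allclose(model.eigenvalues, direct[:n], atol=1e-8)
        # eigenvectors orthonormal and satisfying the eigen-equation
        E = model.eigenvectors
        assert np.allclose(E.T @ E, np.eye(n), atol=1e-8)
        C = Xz.T @ Xz
        scale = np.linalg.norm(C)
        for i in range(n):
            resid = np.linalg.norm(C @ E[:, i] - model.eigenvalues[i] * E[:, i])
            assert resid <= 1e-6 * scale

    def test_variance_fraction_selects_k(self):
        rng = np.random.default_rng(7)
        base = rng.normal(size=(20, 8)) * np.array([10, 5, 1, 0.1, 0.1, 0.1, 0.1, 0.1])
        model = pca_fit(base, components=0.95)
        cum = model.explained_fraction
        assert cum[model.k - 1] >= 0.95
        assert model.k == 1 or cum[model.k - 2] < 0.95
        assert model.k <= 19

    def test_single_vector_rejected(self):
        with pytest.raises(FitError):
            pca_fit(np.ones((1, 4)))


class TestPCAProject:
    def test_mean_projects_to_zero(self):
        rng = np.random.default_rng(8)
        model = pca_fit(rng.normal(size=(6, 12)))
        f = pca_project(model, model.mean)
        assert np.allclose(f, 0.0, atol=1e-12)

    def test_full_rank_reconstruction(self):
        rng = np.random.default_rng(9)
        X = rng.normal(size=(5, 30))
        model = pca_fit(X, components=4)
        v = X[2]
        f = pca_project(model, v, k=model.eigenvalues.size)
        recon = model.mean + model.eigenvectors[:, : f.size] @ f
        assert np.allclose(recon, v, atol=1e-6)

    def test_rank_one_projection_is_signed_norm(self):
        v = np.array([3.0, 4.0, 0.0])
        model = pca_fit(np.stack([v, -v]), components=1)
        e = model.eigenvectors[:, 0]
        f = pca_project(model, v)
        assert f.shape == (1,)
        assert f[0] == pytest.approx(np.sign(e @ v) * 5.0)

    def test_length_mismatch(self):
        model = pca_fit(np.random.default_rng(10).normal(size=(4, 6)))
        with pytest.raises(ValueError):
            pca_project(model, np.zeros(5))


class TestExtract:
    def _templates(self, cohort):
        truths, _ = cohort
        out = {}
        for gt in truths:
            seg = SegmentationResult(gt.spec.pupil, gt.spec.iris, 1, 1)
            out.setdefault(gt.spec.subject_id, []).append(
                rubber_sheet(gt.image.astype(float), seg)
            )
        return out

    def test_projection_dim_bounded_by_train_count(self, small_cohort):
        templates = self._templates(small_cohort)
        X = np.stack([ll_vector(ts[0]) for ts in templates.values()])
        model = pca_fit(X, components=0.95)
        f = pca_project(model, X[0])
        assert f.size == model.k <= X.shape[0]
        assert X.shape[1] == 30 * 150  # flattened LL of the 60x300 template

    def test_extract_deterministic_and_discriminative(self, small_cohort):
        templates = self._templates(small_cohort)
        cfg = PipelineConfig()
        X = np.stack([ll_vector(ts[0]) for ts in templates.values()])
        model = pca_fit(X, components=0.95)
        sids = sorted(templates)
        f_again = extract(templates[sids[0]][0], model, cfg)
        assert np.array_equal(extract(templates[sids[0]][0], model, cfg), f_again)
        # same-subject captures closer in feature space than other subjects
        within, between = [], []
        feats = {
            s: [extract(t, model, cfg) for t in ts] for s, ts in templates.items()
        }
        for s in sids:
            within.append(np.linalg.norm(feats[s][0] - feats[s][1]))
        for i, s in enumerate(sids):
            for s2 in sids[i + 1:]:
                between.append(np.linalg.norm(feats[s][0] - feats[s2][0]))
        assert np.mean(within) < np.min(between)
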