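import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from napctraj import BulkExpressionTable, NormalizedMatrix, UMICountMatrix
from napctraj.preprocess import bulk_pca, normalize_log, pca, scale_center, select_hvg


def _umi(mat):
    mat = np.asarray(mat)
    return UMICountMatrix(
        sp.csr_matrix(mat), [f"g{i}" for i in range(mat.shape[0])],
        [f"c{i}" for i in range(mat.shape[1])],
    )


def _norm(values):
    values = np.asarray(values, dtype=float)
    return NormalizedMatrix(
        sp.csr_matrix(values), np.array([f"g{i}" for i in range(values.shape[0])],
                                        dtype=object),
        np.array([f"c{i}" for i in range(values.shape[1])], dtype=object),
    )


class TestNormalizeLog:
    def test_formula(self):
        # one cell with counts (1,1,2): total 4, scale 1e4
        norm = normalize_log(_umi([[1], [1], [2]]), scale_factor=1e4)
        vals = norm.values.toarray().ravel()
        assert vals == pytest.approx(
            [np.log(1 + 2500), np.log(1 + 2500), np.log(1 + 5000)]
        )

    def test_all_zero_gene_stays_zero(self):
        norm = normalize_log(_umi([[0, 0], [1, 2]]))
        assert norm.values.toarray()[0].tolist() == [0.0, 0.0]

    def test_depth_invariance(self):
        a = normalize_log(_umi([[1], [3], [6]]))
        b = normalize_log(_umi([[2], [6], [12]]))
        assert np.allclose(a.values.toarray(), b.values.toarray())

    def test_zero_total_cell_rejected(self):
        with pytest.raises(ValueError, match="QC"):
            normalize_log(_umi([[1, 0], [1, 0]]))


class TestSelectHVG:
    def test_count_and_exclusions(self):
        rng = np.random.default_rng(0)
        vals = np.log1p(rng.gamma(2.0, 2.0, size=(40, 50)))
        vals[5] = 1.0  # constant gene: zero dispersion, never selected
        norm = _norm(vals)
        sel = select_hvg(norm, n_top=10, n_mean_bins=4)
        assert len(sel) == 10
        assert "g5" not in sel

    def test_high_dispersion_gene_ranks_first(self):
        """Brute-force z-score oracle on a 30-gene toy."""
        rng = np.random.default_rng(1)
        base = rng.gamma(5.0, 1.0, size=(30, 80))
        base[7] *= rng.choice([0.1, 10.0], size=80)  # inflate dispersion only
        norm = _norm(np.log1p(base))

        # oracle: dispersion of expm1, z-score of log dispersion in mean bins
        expm1 = np.expm1(norm.values.toarray())
        mean, var = expm1.mean(axis=1), expm1.var(axis=1)
        disp = np.log(var / mean)
        n_bins = 4
        order = np.argsort(mean, kind="stable")
        bins = np.empty(30, int)
        bins[order] = (np.arange(30) * n_bins) // 30
        z = np.empty(30)
        for b in range(n_bins):
            m = bins == b
            z[m] = (disp[m] - disp[m].mean()) / disp[m].std()
        assert np.argmax(z) == 7

        sel = select_hvg(norm, n_top=5, n_mean_bins=n_bins)
        assert sel[0] == "g7"

    def test_too_many_requested(self):
        with pytest.raises(ValueError, match="non-constant"):
            select_hvg(_norm(np.ones((3, 4))), n_top=2)


class TestScaleCenter:
    def test_rows_standardized(self):
        rng = np.random.default_rng(2)
        norm = _norm(rng.gamma(2, 1, (10, 40)))
        scaled = scale_center(norm, [f"g{i}" for i in range(10)])
        assert np.allclose(scaled.values.mean(axis=1), 0, atol=1e-8)
        assert np.allclose(scaled.values.var(axis=1, ddof=1), 1, atol=1e-6)

    def test_analytic_zscores(self):
        norm = _norm([[0.0, 0.0, 3.0]])
        scaled = scale_center(norm, ["g0"])
        x = np.array([0.0, 0.0, 3.0])
        expected = (x - 1.0) / x.std(ddof=1)
        assert np.allclose(scaled.values.ravel(), expected)

    def test_idempotence(self):
        rng = np.random.default_rng(3)
        norm = _norm(rng.gamma(2, 1, (5, 30)))
        once = scale_center(norm, [f"g{i}" for i in range(5)])
        # feed the standardized values back through (shift to >=0 for container)
        shifted = NormalizedMatrix(
            sp.csr_matrix(once.values - once.values.min()),
            once.gene_ids, once.cell_barcodes,
        )
        twice = scale_center(shifted, list(once.gene_ids))
        assert np.allclose(twice.values, once.values, atol=1e-10)

    def test_constant_genes_dropped_with_warning(self):
        norm = _norm([[1.0, 1.0, 1.0], [0.0, 1.0, 2.0]])
        with pytest.warns(UserWarning, match="constant"):
            scaled = scale_center(norm, ["g0", "g1"])
        assert list(scaled.gene_ids) == ["g1"]
        with pytest.raises(ValueError, match="constant"):
            scale_center(norm, ["g0"])


class TestPCA:
    def _scaled(self, mat):
        norm = _norm(mat - mat.min() + 0.1)
        return scale_center(norm, [f"g{i}" for i in range(mat.shape[0])])

    def test_rank_one_explains_everything(self):
        u = np.linspace(-1, 1, 12)
        v = np.array([1.0, -2.0, 0.5, 3.0])
        scaled = self._scaled(np.outer(v, u))
        res = pca(scaled, n_pcs=3)
        assert res.explained_variance_ratio[0] == pytest.approx(1.0, abs=1e-8)

    def test_explained_variance_non_increasing_and_orthonormal(self):
        rng = np.random.default_rng(4)
        scaled = self._scaled(rng.normal(size=(20, 30)))
        res = pca(scaled, n_pcs=10)
        assert (np.diff(res.explained_variance_ratio) <= 1e-12).all()
        gram = res.loadings @ res.loadings.T
        assert np.allclose(gram, np.eye(10), atol=1e-6)

    def test_eigendecomposition_oracle(self):
        """Singular values^2/(n-1) match dense covariance eigenvalues."""
        rng = np.random.default_rng(5)
        scaled = self._scaled(rng.normal(size=(10, 8)))
        res = pca(scaled, n_pcs=7)
        X = scaled.values.T  # cells x genes, column-centered
        cov = X.T @ X / (X.shape[0] - 1)
        eig = np.sort(np.linalg.eigvalsh(cov))[::-1]
        sv2 = (res.coords**2).sum(axis=0) / (X.shape[0] - 1)
        assert np.allclose(sv2, eig[:7], atol=1e-8)

    def test_deterministic_sign_convention(self):
        rng = np.random.default_rng(6)
        scaled = self._scaled(rng.normal(size=(12, 15)))
        res = pca(scaled, n_pcs=5)
        for k in range(5):
            assert res.loadings[k, np.argmax(np.abs(res.loadings[k]))] > 0

    def test_n_pcs_too_large(self):
        rng = np.random.default_rng(7)
        with pytest.raises(ValueError, match="n_pcs"):
            pca(self._scaled(rng.normal(size=(4, 6))), n_pcs=5)


class TestBulkPCA:
    def _bulk(self, mat):
        mat = np.asarray(mat, dtype=float)
        tpm = mat * (1e6 / mat.sum(axis=0))
        return BulkExpressionTable(
            pd.DataFrame(tpm, index=[f"g{i}" for i in range(mat.shape[0])],
                         columns=[f"s{i}" for i in range(mat.shape[1])])
        )

    def test_duplicated_samples_have_zero_separation(self):
        rng = np.random.default_rng(8)
        col = rng.gamma(2, 1, 30)
        bulk = self._bulk(np.column_stack([col] * 4 + [rng.gamma(2, 1, 30)] * 1))
        res = bulk_pca(bulk, mean_percentile=0.0, n_pcs=2)
        assert np.allclose(res.coords[0], res.coords[1], atol=1e-8)

    def test_percentile_zero_uses_all_nonconstant_genes(self):
        rng = np.random.default_rng(9)
        bulk = self._bulk(rng.gamma(2, 1, (25, 6)))
        res = bulk_pca(bulk, mean_percentile=0.0, n_pcs=3)
        assert len(res.gene_ids) == 25

    def test_two_group_separation_matches_oracle(self):
        rng = np.random.default_rng(10)
        base = rng.gamma(5, 1, (40, 6))
        base[:10, 3:] *= 6.0  # group effect on high genes
        bulk = self._bulk(base)
        res = bulk_pca(bulk, mean_percentile=0.0, n_pcs=2)
        # PC1 separates the two triplets
        g1, g2 = res.coords[:3, 0], res.coords[3:, 0]
        assert (g1.max() < g2.min()) or (g2.max() < g1.min())
        # eigenvalue oracle on the standardized matrix
        X = np.log1p(bulk.values.to_numpy())
        sd = X.std(axis=1, ddof=1, keepdims=True)
        keep = sd.ravel() > 0
        Z = ((X - X.mean(axis=1, keepdims=True)) / sd)[keep].T
        eig = np.sort(np.linalg.eigvalsh(Z.T @ Z))[::-1]
        sv2 = (res.coords**2).sum(axis=0)
        assert np.allclose(sv2, eig[:2], atol=1e-6)

    def test_requires_two_samples(self):
        bulk = BulkExpressionTable(pd.DataFrame({"s1": [1e6]}, index=["g1"]))
        with pytest.raises(ValueError, match="2 samples"):
            bulk_pca(bulk)
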