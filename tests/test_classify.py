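"""Standardization, PCA, Ward clustering, and the cell-type workflows."""

import numpy as np
import pandas as pd
import pytest

from raphephys import classify, features, synth
from raphephys.classify import (
    DegenerateFeatureError,
    FeatureMatrix,
    PCAWardCluster,
    classify_two_types,
    matrix_from_panels,
    pca,
    standardize,
    ward_cluster,
)


def fm(arr, cols=None):
    arr = np.asarray(arr, dtype=float)
    cols = cols or [f"f{i}" for i in range(arr.shape[1])]
    return FeatureMatrix(pd.DataFrame(arr, columns=cols))


class TestStandardize:
    def test_arithmetic_sequence_maps_to_unit_z(self):
        z = standardize(fm([[1.0], [2.0], [3.0]]))
        assert np.allclose(z.data.to_numpy().ravel(), [-1.0, 0.0, 1.0])

    def test_idempotent_on_standardized_input(self):
        rng = np.random.default_rng(0)
        z1 = standardize(fm(rng.normal(size=(20, 3))))
        z2 = standardize(z1)
        assert np.allclose(z1.data.to_numpy(), z2.data.to_numpy(), atol=1e-12)

    def test_zero_variance_column_is_named(self):
        with pytest.raises(DegenerateFeatureError, match="f1"):
            standardize(fm([[1.0, 5.0], [2.0, 5.0], [3.0, 5.0]]))

    def test_missing_entries_stay_missing(self):
        z = standardize(fm([[1.0], [2.0], [np.nan], [3.0]]))
        assert z.data.isna().sum().iloc[0] == 1


class TestPCA:
    def test_line_data_loads_entirely_on_pc1(self):
        x = np.linspace(-1, 1, 40)
        scores, loadings, evr = pca(standardize(fm(np.column_stack([x, x]))))
        assert evr[0] == pytest.approx(1.0, abs=1e-12)
        assert evr[1] == pytest.approx(0.0, abs=1e-12)

    def test_isotropic_cloud_has_near_equal_variances(self):
        rng = np.random.default_rng(42)
        scores, loadings, evr = pca(standardize(fm(rng.normal(size=(500, 3)))))
        assert np.all(np.abs(evr - 1.0 / 3.0) < 1.0 / 30.0)

    def test_reconstruction_from_all_components(self):
        rng = np.random.default_rng(1)
        z = standardize(fm(rng.normal(size=(30, 4))))
        X = z.data.to_numpy()
        scores, loadings, _ = pca(z)
        assert np.allclose(scores @ loadings.T + X.mean(axis=0), X, atol=1e-10)

    def test_loadings_orthonormal(self):
        rng = np.random.default_rng(2)
        _, loadings, _ = pca(standardize(fm(rng.normal(size=(25, 5)))))
        assert np.allclose(loadings.T @ loadings, np.eye(loadings.shape[1]), atol=1e-10)

    def test_matches_eigendecomposition_oracle(self):
        # independent route: eigenvectors of the correlation matrix
        rng = np.random.default_rng(3)
        z = standardize(fm(rng.normal(size=(60, 4)) @ rng.normal(size=(4, 4))))
        X = z.data.to_numpy()
        _, loadings, evr = pca(z)
        w, v = np.linalg.eigh(np.cov(X.T))
        order = np.argsort(w)[::-1]
        w, v = w[order], v[:, order]
        assert np.allclose(evr, w / w.sum(), atol=1e-10)
        for j in range(4):
            dot = abs(v[:, j] @ loadings[:, j])
            assert dot == pytest.approx(1.0, abs=1e-8)

    def test_fewer_than_two_cells_raises(self):
        with pytest.raises(ValueError):
            pca(fm([[1.0, 2.0]]))


class TestWardCluster:
    def test_two_point_masses_recovered_exactly(self):
        pts = np.vstack([np.zeros((10, 2)), np.full((10, 2), 5.0)])
        res = ward_cluster(pts, n_components=2, k=2)
        labels = res.labels
        assert len(set(labels[:10])) == 1
        assert len(set(labels[10:])) == 1
        assert labels[0] != labels[-1]

    def test_duplicated_point_merges_at_zero_height(self):
        pts = np.zeros((8, 2))
        res = ward_cluster(pts, n_components=2, k=2)
        assert np.allclose(res.linkage[:, 2], 0.0)

    def test_merge_heights_monotone(self):
        rng = np.random.default_rng(4)
        res = ward_cluster(rng.normal(size=(40, 3)), n_components=3, k=4)
        heights = res.linkage[:, 2]
        assert np.all(np.diff(heights) >= -1e-12)

    def test_matches_sklearn_agglomerative_oracle(self):
        from sklearn.cluster import AgglomerativeClustering
        from scipy.optimize import linear_sum_assignment

        rng = np.random.default_rng(5)
        pts = np.vstack([rng.normal(0, 1, (20, 2)), rng.normal(6, 1, (25, 2))])
        ours = ward_cluster(pts, n_components=2, k=2).labels
        ref = AgglomerativeClustering(n_clusters=2, linkage="ward").fit_predict(pts)
        tab = pd.crosstab(ours, ref).to_numpy()
        r, c = linear_sum_assignment(-tab)
        assert tab[r, c].sum() == len(pts)

    def test_k_larger_than_n_raises(self):
        with pytest.raises(ValueError):
            ward_cluster(np.zeros((3, 2)), n_components=2, k=5)


def quick_panels(n_a=8, n_b=8, seed=0):
    cells = synth.make_typed_cohort(
        {"serotonergic": n_a, "dopaminergic": n_b}, seed=seed, include_zero=False
    )
    panels = [
        features.extract_panel(c.bundle, target_rate=c.params.target_rate_hz)
        for c in cells
    ]
    for p, c in zip(panels, cells):
        p.putative_type = c.phenotype
    return panels


class TestTwoTypeWorkflow:
    def test_simulated_cohort_separates_with_high_purity(self):
        res = classify_two_types(quick_panels(10, 10, seed=21))
        assert len(set(res.labels)) == 2
        assert res.purity() >= 0.95

    def test_identical_cells_raise_variance_error(self):
        panels = quick_panels(6, 0, seed=1)
        clones = [panels[0]] * 6
        with pytest.raises(DegenerateFeatureError):
            classify_two_types(clones)

    def test_cell_order_permutation_permutes_labels(self):
        panels = [
            p for p in quick_panels(6, 6, seed=2)
            if all(p.present(f) for f in classify.FIVE_FEATURES)
        ]
        res = classify_two_types(panels)
        rng = np.random.default_rng(0)
        perm = rng.permutation(len(panels))
        res2 = classify_two_types([panels[i] for i in perm])
        ids1 = dict(zip(res.cell_ids, res.labels))
        ids2 = dict(zip(res2.cell_ids, res2.labels))
        # same partition up to label renaming
        pairs = {(ids1[c], ids2[c]) for c in ids1}
        assert len({a for a, _ in pairs}) == len({b for _, b in pairs}) == len(pairs)

    def test_too_few_cells_raise(self):
        with pytest.raises(ValueError):
            classify_two_types(quick_panels(2, 0, seed=3)[:2])


class TestFourTypeWorkflow:
    def test_forced_split_of_three_point_masses(self):
        # k = 4 on 3 distinct masses: one mass must split; heights reported
        rng = np.random.default_rng(7)
        X = np.vstack([
            rng.normal(0, 0.01, (6, 3)),
            rng.normal(5, 0.01, (6, 3)),
            rng.normal(10, 0.01, (6, 3)),
        ])
        est = PCAWardCluster(n_components=3, n_clusters=4).fit(X)
        assert len(set(est.labels_)) == 4
        assert est.linkage_.shape == (17, 4)

    def test_deterministic_under_fixed_input(self):
        panels = quick_panels(6, 6, seed=9)
        a = classify_two_types(panels)
        b = classify_two_types(panels)
        assert np.array_equal(a.labels, b.labels)
        assert np.allclose(a.scores, b.scores)


class TestMatrixFromPanels:
    def test_spont_rate_or_zero_distinguishes_silent_from_missing(self):
        p1 = features.FeaturePanel(cell_id="a", spontaneous=True, spont_rate=1.5)
        p2 = features.FeaturePanel(cell_id="b", spontaneous=False)
        p3 = features.FeaturePanel(cell_id="c")  # zero epoch absent
        m = matrix_from_panels([p1, p2, p3], features=("spont_rate_or_zero",))
        col = m.data["spont_rate_or_zero"]
        assert col.loc["a"] == 1.5
        assert col.loc["b"] == 0.0
        assert np.isnan(col.loc["c"])
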