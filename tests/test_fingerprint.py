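"""Scaling, clustered image maps and PLS-DA (NIPALS) with closed-form
and independent-library oracles."""

import numpy as np
import pandas as pd
import pytest

import chondroprint as cp
from chondroprint.fingerprint import scale_center


def _toy_xy(n=24, p=6, seed=0, informative=(0, 1)):
    rng = np.random.default_rng(seed)
    y = np.repeat([0, 1], n // 2)
    X = rng.normal(0, 1, (n, p))
    for j in informative:
        X[:, j] += (2.0 - 0.5 * j) * y
    X = pd.DataFrame(X, columns=[f"f{j}" for j in range(p)])
    return scale_center(X)[0], y


class TestScaleCenter:
    def test_zscore_definition(self):
        rng = np.random.default_rng(1)
        X = pd.DataFrame(rng.lognormal(0, 1, (15, 4)))
        z, params = scale_center(X)
        assert np.allclose(z.mean(), 0, atol=1e-12)
        assert np.allclose(z.std(ddof=1), 1, atol=1e-12)
        back = params.inverse(z)
        assert np.allclose(back.values, X.values)

    def test_idempotence(self):
        rng = np.random.default_rng(2)
        X = pd.DataFrame(rng.normal(0, 1, (10, 3)))
        z1, _ = scale_center(X)
        z2, _ = scale_center(z1)
        assert np.allclose(z1.values, z2.values, atol=1e-12)

    def test_two_rows_give_symmetric_pairs(self):
        X = pd.DataFrame({"a": [1.0, 5.0], "b": [10.0, 2.0]})
        z, _ = scale_center(X)
        # closed form at n=2 (ddof=1): entries are ±1/√2 per column
        assert np.allclose(np.abs(z.values), 1.0 / np.sqrt(2))
        assert np.allclose(z.sum(), 0)

    def test_constant_columns_dropped_with_warning(self):
        X = pd.DataFrame({"a": [1.0, 2.0, 3.0], "b": [7.0, 7.0, 7.0]})
        with pytest.warns(UserWarning):
            z, _ = scale_center(X)
        assert list(z.columns) == ["a"]
        with pytest.raises(ValueError):
            scale_center(X[["b"]])


class TestCIM:
    def test_block_structure_recovered_by_two_cluster_cut(self):
        rng = np.random.default_rng(3)
        a = rng.normal(0, 0.1, (5, 4)) + [5, 5, 0, 0]
        b = rng.normal(0, 0.1, (5, 4)) + [0, 0, 5, 5]
        X = pd.DataFrame(np.vstack([a, b]))
        res = cp.cim(X)
        clusters = res.row_clusters(2)
        assert len(set(clusters[:5])) == 1
        assert len(set(clusters[5:])) == 1
        assert clusters[0] != clusters[-1]

    def test_duplicated_row_merges_first_at_distance_zero(self):
        rng = np.random.default_rng(4)
        X = pd.DataFrame(rng.normal(0, 1, (6, 5)))
        X.iloc[5] = X.iloc[0]
        res = cp.cim(X)
        first_merge = res.row_linkage[0]
        assert first_merge[2] == pytest.approx(0.0)
        assert {int(first_merge[0]), int(first_merge[1])} == {0, 5}

    def test_zscore_columns_of_result(self):
        rng = np.random.default_rng(5)
        X = pd.DataFrame(rng.lognormal(0, 1, (8, 5)))
        res = cp.cim(X)
        assert np.allclose(res.z.mean(), 0, atol=1e-9)
        assert np.allclose(res.z.std(ddof=1), 1, atol=1e-9)

    def test_too_few_rows_rejected(self):
        with pytest.raises(ValueError):
            cp.cim(pd.DataFrame(np.eye(2)))

    def test_default_experiment_two_cluster_split_tracks_classes(self):
        """On the default synthetic inflammation experiment, the 2-cluster
        row split misassigns at most 2 of 16 samples."""
        _, table = cp.build_experiment(cp.get_preset("human-oa"), seed=21,
                                       field_size=(500.0, 500.0),
                                       pixel_size=1.5)
        feats = [*cp.DESCRIPTOR_NAMES, *cp.GENES]
        X = table.set_index("sample_id")[feats]
        res = cp.cim(X, row_classes=table.set_index("sample_id")["condition"])
        tab = res.cluster_vs_class
        # best alignment of clusters to classes
        correct = max(tab.iloc[0, 0] + tab.iloc[1, 1]
                      if tab.shape == (2, 2) else 0,
                      tab.iloc[0, 1] + tab.iloc[1, 0]
                      if tab.shape == (2, 2) else 0)
        assert 16 - correct <= 2


class TestPLSDA:
    def test_single_component_weight_closed_form(self):
        """Component-1 weight equals normalized Xᵀ(y − ȳ) exactly."""
        X, y = _toy_xy()
        model = cp.plsda_fit(X, y, ncomp=1)
        Xc = X.values - X.values.mean(axis=0)
        w_oracle = Xc.T @ (y - y.mean())
        w_oracle /= np.linalg.norm(w_oracle)
        assert np.allclose(np.abs(model.weights[:, 0]),
                           np.abs(w_oracle), atol=1e-10)

    def test_matches_sklearn_pls_regression(self):
        """Scores and loadings agree with an independent PLS implementation
        (up to per-component sign)."""
        from sklearn.cross_decomposition import PLSRegression

        X, y = _toy_xy(seed=7)
        model = cp.plsda_fit(X, y, ncomp=2)
        sk = PLSRegression(n_components=2, scale=False).fit(
            X.values, (y - y.mean()).astype(float))
        for a in range(2):
            sign = np.sign(model.scores[0, a] * sk.x_scores_[0, a]) or 1.0
            assert np.allclose(model.scores[:, a],
                               sign * sk.x_scores_[:, a], atol=1e-8)
            assert np.allclose(model.x_loadings[:, a],
                               sign * sk.x_loadings_[:, a], atol=1e-8)

    def test_score_orthogonality_and_variance_budget(self):
        X, y = _toy_xy(seed=8)
        model = cp.plsda_fit(X, y, ncomp=3)
        T = model.scores
        for a in range(3):
            for b in range(a + 1, 3):
                assert abs(T[:, a] @ T[:, b]) < 1e-8
        assert model.x_variance_explained.sum() <= 1.0 + 1e-9

    def test_full_rank_reconstruction(self):
        rng = np.random.default_rng(9)
        X = pd.DataFrame(rng.normal(0, 1, (8, 5)))
        z, _ = scale_center(X)
        y = np.array([0, 1, 0, 1, 0, 1, 0, 1])
        model = cp.plsda_fit(z, y, ncomp=5)
        recon = model.scores @ model.x_loadings.T
        Xc = z.values - z.values.mean(axis=0)
        assert np.allclose(recon, Xc, atol=1e-6)

    def test_pure_noise_feature_has_smallest_loading_in_expectation(self):
        mags = []
        for seed in range(30):
            X, y = _toy_xy(seed=seed, p=4, informative=(0, 1, 2))
            model = cp.plsda_fit(X, y, ncomp=1)
            mags.append(np.abs(model.x_loadings[:, 0]))
        mean_mag = np.mean(mags, axis=0)
        assert np.argmin(mean_mag) == 3  # the uninformative feature

    def test_two_feature_toy_ranks_separating_feature_first(self):
        y = np.repeat([0, 1], 6)
        X = pd.DataFrame({
            "sep": y * 2.0 + np.linspace(0, 0.1, 12),
            "noise": np.tile([0.3, -0.2, 0.1], 4),
        })
        z, _ = scale_center(X)
        model = cp.plsda_fit(z, y, ncomp=1)
        ranking = cp.rank_discriminative_features(model)
        assert ranking.iloc[0]["feature"] == "sep"
        assert ranking.iloc[0]["marks_class"] == 1

    def test_label_flip_flips_assignments_not_ranking(self):
        X, y = _toy_xy(seed=11)
        m1 = cp.plsda_fit(X, y, ncomp=1)
        m2 = cp.plsda_fit(X, 1 - y, ncomp=1)
        r1 = cp.rank_discriminative_features(m1)
        r2 = cp.rank_discriminative_features(m2)
        assert list(r1["feature"]) == list(r2["feature"])
        merged = r1.merge(r2, on="feature", suffixes=("_a", "_b"))
        assert (merged["marks_class_a"] == 1 - merged["marks_class_b"]).all()

    def test_degenerate_inputs_rejected(self):
        X, y = _toy_xy()
        with pytest.raises(ValueError):
            cp.plsda_fit(X, np.zeros_like(y))
        with pytest.raises(ValueError):
            cp.plsda_fit(X, y, ncomp=40)


@pytest.fixture(scope="module")
def ranking():
    _, table = cp.build_experiment(cp.get_preset("human-oa"), seed=33,
                                   field_size=(500.0, 500.0),
                                   pixel_size=1.5)
    feats = [*cp.DESCRIPTOR_NAMES, *cp.GENES]
    z, _ = scale_center(table.set_index("sample_id")[feats])
    model = cp.plsda_fit(z, table["condition"].to_numpy(), ncomp=2)
    return cp.rank_discriminative_features(model)


class TestExperimentFingerprint:
    """Feature-importance pattern on the default synthetic experiment."""

    def test_inflammatory_genes_rank_top_for_treated_class(self, ranking):
        r = ranking.set_index("feature")
        genes = ["COL1A2", "COL2A1", "SOX9", "ACAN", "IL-6", "IL-8"]
        treated_genes = ranking[ranking.feature.isin(genes)
                                & (ranking.marks_class == 1)]
        assert list(treated_genes.head(2)["feature"]) in (
            ["IL-6", "IL-8"], ["IL-8", "IL-6"])
        assert r.loc["IL-6", "marks_class"] == 1
        assert r.loc["IL-8", "marks_class"] == 1

    def test_matrix_genes_mark_control_class(self, ranking):
        r = ranking.set_index("feature")
        for g in ("COL2A1", "ACAN", "SOX9"):
            assert r.loc[g, "marks_class"] == 0

    def test_roundness_marks_control_and_size_marks_treated(self, ranking):
        r = ranking.set_index("feature")
        assert r.loc["roundness", "marks_class"] == 0
        assert r.loc["aspect_ratio", "marks_class"] == 1
        assert r.loc["area", "marks_class"] == 0 or \
            r.loc["length", "marks_class"] == 1

    def test_large_effect_rankings_stable_across_seeds(self):
        """Class assignments of the strong-effect features are identical
        across 10 replicate experiments."""
        tops = []
        for seed in range(10):
            _, table = cp.build_experiment(
                cp.get_preset("human-oa"), seed=100 + seed,
                field_size=(450.0, 450.0), pixel_size=1.5)
            feats = [*cp.DESCRIPTOR_NAMES, *cp.GENES]
            z, _ = scale_center(table.set_index("sample_id")[feats])
            model = cp.plsda_fit(z, table["condition"].to_numpy(), ncomp=2)
            r = cp.rank_discriminative_features(model).set_index("feature")
            tops.append((
                r.loc["IL-6", "marks_class"], r.loc["IL-8", "marks_class"],
                r.loc["COL2A1", "marks_class"], r.loc["ACAN", "marks_class"],
                r.loc["roundness", "marks_class"],
                r.loc["aspect_ratio", "marks_class"],
            ))
        assert len(set(tops)) == 1
        assert tops[0] == (1, 1, 0, 0, 0, 1)
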