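"""Signature derivation, PCA/region geometry, forest classification and the
no-leakage guarantee of the stratification pipeline."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from sklearn.metrics import adjusted_rand_score

from phosphostrat import SimulationConfig, simulate_cohort, stratify_cohort
from phosphostrat.errors import ValidationError
from phosphostrat.signature import (
    Region,
    assign_by_region,
    classify,
    define_region,
    feature_importance,
    fit_pca,
    project,
    select_features,
    train_classifier,
)

from conftest import toy_matrix


def _ray_casting_contains(vertices, x, y):
    """Independent even-odd point-in-polygon oracle (open boundary)."""
    inside = False
    n = len(vertices)
    for i in range(n):
        x1, y1 = vertices[i]
        x2, y2 = vertices[(i + 1) % n]
        if (y1 > y) != (y2 > y):
            xc = x1 + (y - y1) / (y2 - y1) * (x2 - x1)
            if x < xc:
                inside = not inside
    return inside


class TestSelectFeatures:
    def test_k_defaults_to_half_training(self):
        rng = np.random.default_rng(0)
        m = toy_matrix(rng.normal(size=(100, 36)))
        sig = select_features(m, m.sample_ids[:12], m.sample_ids[12:], min_obs=2)
        assert sig.k == 18 and len(sig.feature_ids) == 18

    @pytest.mark.parametrize("n_train", [4, 9, 17, 36, 60])
    def test_k_rule_across_cohort_sizes(self, n_train):
        rng = np.random.default_rng(n_train)
        m = toy_matrix(rng.normal(size=(80, n_train)))
        half = n_train // 2
        sig = select_features(m, m.sample_ids[:2], m.sample_ids[2:], min_obs=2)
        assert len(sig.feature_ids) == half

    def test_degenerate_one_vs_one_rejected(self):
        m = toy_matrix(np.zeros((10, 2)))
        with pytest.raises(ValidationError):
            select_features(m, [m.sample_ids[0]], [m.sample_ids[1]], min_obs=2)

    def test_k_larger_than_tested_features_rejected(self):
        rng = np.random.default_rng(1)
        m = toy_matrix(rng.normal(size=(5, 10)))
        with pytest.raises(ValidationError, match="tested features"):
            select_features(m, m.sample_ids[:5], m.sample_ids[5:], k=6, min_obs=2)

    def test_planted_features_selected_in_most_replicates(self):
        hits, n_rep = 0, 100
        for seed in range(n_rep):
            cfg = SimulationConfig(n_features=400, n_signature_features=18,
                                   effect_size=2.0, noise_sd=0.5, missing_rate=0.0,
                                   n_kinases=5, substrates_per_kinase=10, seed=seed)
            c = simulate_cohort(cfg)
            mllga = list(c.metadata.index[c.metadata["group"] == "MLLGA"])
            rest = list(c.metadata.index[c.metadata["group"] != "MLLGA"])
            sig = select_features(c.phospho, mllga, rest, k=18, min_obs=2)
            hits += set(sig.feature_ids) == set(c.truth.planted_features)
        assert hits >= 0.95 * n_rep


class TestPca:
    def test_rank_one_data_explained_by_pc1(self):
        rng = np.random.default_rng(2)
        base = rng.normal(size=10)
        m = toy_matrix(np.outer(np.arange(1, 5.0), base).T)  # features x samples
        sig = select_features(m, m.sample_ids[:2], m.sample_ids[2:], k=5, min_obs=2)
        model = fit_pca(m, sig, m.sample_ids)
        assert model.explained_variance_ratio[0] == pytest.approx(1.0)

    def test_projection_reproduces_fitted_scores(self, small_cohort):
        c = small_cohort
        mllga = list(c.metadata.index[c.metadata["group"] == "MLLGA"])
        rest = list(c.metadata.index[c.metadata["group"] != "MLLGA"])
        sig = select_features(c.phospho, mllga, rest)
        model = fit_pca(c.phospho, sig, c.phospho.sample_ids)
        scores = project(model, c.phospho)
        pd.testing.assert_frame_equal(scores, model.scores, atol=1e-9, rtol=0)

    def test_two_feature_loadings_match_analytic_eigenvectors(self):
        rng = np.random.default_rng(3)
        cov = np.array([[4.0, 1.5], [1.5, 1.0]])
        x = rng.multivariate_normal([0, 0], cov, size=500)
        m = toy_matrix(x.T)
        sig = select_features(m, m.sample_ids[:250], m.sample_ids[250:], k=2, min_obs=2)
        model = fit_pca(m, sig, m.sample_ids)
        emp_cov = np.cov(x, rowvar=False)
        w, v = np.linalg.eigh(emp_cov)
        lead = v[:, np.argmax(w)]
        got = model.loadings["PC1"].reindex(["f0", "f1"]).to_numpy()
        cosine = abs(np.dot(lead, got))
        assert cosine == pytest.approx(1.0, abs=1e-8)

    def test_absent_feature_raises_listing_it(self, small_cohort):
        c = small_cohort
        mllga = list(c.metadata.index[c.metadata["group"] == "MLLGA"])
        rest = list(c.metadata.index[c.metadata["group"] != "MLLGA"])
        sig = select_features(c.phospho, mllga, rest)
        model = fit_pca(c.phospho, sig, mllga + rest)
        reduced = c.phospho.subset(features=[f for f in c.phospho.feature_ids
                                             if f != sig.feature_ids[0]])
        with pytest.raises(ValidationError, match=sig.feature_ids[0]):
            project(model, reduced)


class TestRegion:
    def test_eight_near_two_far(self):
        rng = np.random.default_rng(4)
        near = rng.normal(0, 0.3, size=(8, 2))
        far = np.array([[10.0, 10.0], [11.0, 9.0]])
        scores = pd.DataFrame(np.vstack([near, far]), columns=["PC1", "PC2"],
                              index=[f"s{i}" for i in range(10)])
        region, report = define_region(scores)
        assert report["in_region_cluster"].sum() == 8
        for i in range(8):
            assert region.contains(*near[i])
        for p in far:
            assert not region.contains(*p)

    def test_identical_points_make_margin_square(self):
        scores = pd.DataFrame([[1.0, 2.0]] * 4, columns=["PC1", "PC2"],
                              index=list("abcd"))
        region, _ = define_region(scores, margin=0.5)
        assert region.contains(1.0, 2.0)
        assert region.contains(1.49, 2.49)
        assert not region.contains(1.6, 2.0)
        assert len(region.vertices) == 4

    def test_collinear_points_thicken_to_rectangle(self):
        scores = pd.DataFrame([[0.0, 0.0], [1.0, 0.0], [2.0, 0.0]],
                              columns=["PC1", "PC2"], index=list("abc"))
        region, _ = define_region(scores, margin=0.2)
        assert region.contains(1.0, 0.1)
        assert not region.contains(1.0, 0.5)

    def test_two_separated_blobs_cut_exactly(self):
        rng = np.random.default_rng(5)
        a = rng.normal(0, 1, size=(7, 2))
        b = rng.normal(30, 1, size=(5, 2))
        scores = pd.DataFrame(np.vstack([a, b]), columns=["PC1", "PC2"],
                              index=[f"s{i}" for i in range(12)])
        _, report = define_region(scores)
        # 2-means oracle: assign to nearer blob centre
        oracle = np.array([0] * 7 + [1] * 5)
        got = report["cluster"].to_numpy()
        assert adjusted_rand_score(oracle, got) == 1.0
        assert report["in_region_cluster"].to_numpy()[:7].all()

    def test_fewer_than_three_points_rejected(self):
        scores = pd.DataFrame([[0, 0], [1, 1]], columns=["PC1", "PC2"], index=list("ab"))
        with pytest.raises(ValidationError):
            define_region(scores)

    def test_assignment_against_ray_casting_oracle(self):
        rng = np.random.default_rng(6)
        pts = rng.normal(0, 1, size=(9, 2))
        scores = pd.DataFrame(pts, columns=["PC1", "PC2"],
                              index=[f"s{i}" for i in range(9)])
        region, _ = define_region(scores, margin=0.1)
        queries = rng.uniform(-4, 4, size=(10_000, 2))
        qdf = pd.DataFrame(queries, columns=["PC1", "PC2"],
                           index=[f"q{i}" for i in range(len(queries))])
        got = assign_by_region(qdf, region)["label"] == "MLLGA"
        expected = np.array([
            _ray_casting_contains(region.vertices, x, y) for x, y in queries
        ])
        assert (got.to_numpy() == expected).all()

    def test_centroid_inside_far_point_outside(self):
        tri = Region(vertices=np.array([[0.0, 0.0], [2.0, 0.0], [1.0, 2.0]]), margin=0.1)
        cx, cy = tri.vertices.mean(axis=0)
        assign = assign_by_region(
            pd.DataFrame([[cx, cy], [10.0, 10.0]], columns=["PC1", "PC2"],
                         index=["in", "out"]), tri)
        assert assign.loc["in", "label"] == "MLLGA"
        assert assign.loc["out", "label"] == "No-MLLGA"


@pytest.fixture(scope="module")
def trained(small_cohort):
    c = small_cohort
    mllga = list(c.metadata.index[c.metadata["group"] == "MLLGA"])
    rest = list(c.metadata.index[c.metadata["group"] != "MLLGA"])
    sig = select_features(c.phospho, mllga, rest)
    labels = pd.Series(["MLLGA"] * len(mllga) + ["No-MLLGA"] * len(rest),
                       index=mllga + rest)
    clf = train_classifier(c.phospho, sig, labels, seed=1, n_trees=200)
    return c, sig, labels, clf


class TestClassifier:
    def test_training_labels_recovered_with_high_oob(self, trained):
        c, sig, labels, clf = trained
        assert clf.oob_accuracy >= 0.9
        pred = classify(clf, c.phospho, list(labels.index))
        assert (pred["label"] == labels).all()

    def test_probabilities_valid_and_ties_go_positive(self, trained):
        c, _, _, clf = trained
        pred = classify(clf, c.phospho)
        assert ((pred["probability_mllga"] >= 0) & (pred["probability_mllga"] <= 1)).all()
        at_half = pred["probability_mllga"] >= 0.5
        assert (pred.loc[at_half, "label"] == "MLLGA").all()
        assert (pred.loc[~at_half, "label"] == "No-MLLGA").all()

    def test_deterministic_given_seed(self, trained):
        c, sig, labels, clf = trained
        clf2 = train_classifier(c.phospho, sig, labels, seed=1, n_trees=200)
        p1 = classify(clf, c.phospho)["probability_mllga"]
        p2 = classify(clf2, c.phospho)["probability_mllga"]
        pd.testing.assert_series_equal(p1, p2)

    def test_single_class_labels_rejected(self, trained):
        c, sig, labels, _ = trained
        bad = pd.Series("MLLGA", index=labels.index)
        with pytest.raises(ValidationError, match="single class"):
            train_classifier(c.phospho, sig, bad, seed=0)

    def test_importances_sum_to_one_sorted(self, trained):
        _, _, _, clf = trained
        imp = feature_importance(clf)
        assert imp["importance"].sum() == pytest.approx(1.0)
        assert (np.diff(imp["importance"].to_numpy()) <= 1e-12).all()

    def test_single_informative_feature_ranks_first(self):
        rng = np.random.default_rng(7)
        hits = 0
        for seed in range(20):
            x = rng.normal(size=(20, 24))
            x[0, :12] += 4.0  # one informative feature
            m = toy_matrix(x)
            sig = select_features(m, m.sample_ids[:12], m.sample_ids[12:], k=10, min_obs=2)
            labels = pd.Series(["MLLGA"] * 12 + ["No-MLLGA"] * 12, index=m.sample_ids)
            clf = train_classifier(m, sig, labels, seed=seed, n_trees=200)
            hits += feature_importance(clf).iloc[0]["feature_id"] == "f0"
        assert hits >= 19

    def test_permuting_top_feature_degrades_oob(self, trained):
        c, sig, labels, clf = trained
        top = feature_importance(clf).iloc[0]["feature_id"]
        perturbed = c.phospho.values.copy()
        rng = np.random.default_rng(0)
        train_ids = list(labels.index)
        perm = rng.permutation(perturbed.loc[top, train_ids].to_numpy())
        perturbed.loc[top, train_ids] = perm
        m2 = toy_matrix(perturbed.to_numpy(), feature_ids=list(perturbed.index),
                        sample_ids=list(perturbed.columns))
        clf2 = train_classifier(m2, sig, labels, seed=1, n_trees=200)
        assert clf2.oob_accuracy <= clf.oob_accuracy


class TestStratify:
    def test_planted_subgroup_recovered(self, small_cohort):
        c = small_cohort
        res = stratify_cohort(c.phospho, c.metadata, seed=0, n_trees=300)
        truth = (c.metadata["group"] == "MLLGA").to_numpy()
        pred = (res.assignments.loc[c.metadata.index, "label"] == "MLLGA").to_numpy()
        assert adjusted_rand_score(truth, pred) >= 0.9

    def test_null_effect_gives_arbitrary_subgroup_split(self):
        """Without planted signal the derived split of KMT2Ar cases carries
        no information about the nominal subgroups."""
        aris = []
        for seed in range(8):
            cfg = SimulationConfig(effect_size=0.0, noise_sd=1.0, n_features=300,
                                   n_kinases=5, substrates_per_kinase=10, seed=seed)
            c = simulate_cohort(cfg)
            res = stratify_cohort(c.phospho, c.metadata, seed=seed, n_trees=100)
            km = c.metadata.index[c.metadata["karyotype"] == "KMT2Ar"]
            truth = (c.metadata.loc[km, "group"] == "MLLGA").to_numpy()
            pred = (res.assignments.loc[km, "label"] == "MLLGA").to_numpy()
            aris.append(adjusted_rand_score(truth, pred))
        assert abs(float(np.mean(aris))) < 0.25

    def test_no_leakage_from_non_training_samples(self):
        cfg = SimulationConfig(n_features=300, n_kinases=5, substrates_per_kinase=10,
                               validation_fraction=0.25, seed=13)
        c = simulate_cohort(cfg)
        res = stratify_cohort(c.phospho, c.metadata, seed=2, n_trees=100)
        val = c.metadata.index[c.metadata["split"] == "validation"]
        assert len(val) > 0
        perturbed = c.phospho.values.copy()
        perturbed.loc[:, val] = perturbed.loc[:, val] + 100.0
        m2 = toy_matrix(perturbed.to_numpy(), feature_ids=list(perturbed.index),
                        sample_ids=list(perturbed.columns))
        res2 = stratify_cohort(m2, c.metadata, seed=2, n_trees=100)
        assert res.signature.feature_ids == res2.signature.feature_ids
        pd.testing.assert_series_equal(res.signature.selection_p,
                                       res2.signature.selection_p, check_names=False)
        pd.testing.assert_frame_equal(res.pca.loadings, res2.pca.loadings)
        pd.testing.assert_series_equal(res.pca.mean, res2.pca.mean)
        np.testing.assert_array_equal(res.region.vertices, res2.region.vertices)
        train = c.metadata.index[c.metadata["split"] == "train"]
        pd.testing.assert_frame_equal(res.assignments.loc[train],
                                      res2.assignments.loc[train])
        pd.testing.assert_frame_equal(res.importances, res2.importances)

    def test_region_and_classifier_agree_on_training_when_separated(self, small_cohort):
        c = small_cohort
        res = stratify_cohort(c.phospho, c.metadata, seed=0, n_trees=300)
        train = c.metadata.index[c.metadata["split"] == "train"]
        region_lab = res.region_assignments.loc[train, "label"]
        clf_lab = res.assignments.loc[train, "label"]
        assert adjusted_rand_score(region_lab, clf_lab) == 1.0
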