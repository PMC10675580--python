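"""Sparse PLS-DA: NIPALS fit, keepX selection, distances, CV, holdout."""
import warnings

import numpy as np
import pandas as pd
import pytest

from ovorisk import (
    classification_report, cross_validate, error_rates, evaluate_holdout,
    plsda_fit, plsda_predict, soft_threshold_weights,
)


def separable_blobs(n_per=15, seed=0, delta=6.0):
    """Three classes, one marker variable each, plus one noise column."""
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((3 * n_per, 4))
    X[:n_per, 0] += delta
    X[n_per:2 * n_per, 1] += delta
    X[2 * n_per:, 2] += delta
    y = np.array(["a"] * n_per + ["b"] * n_per + ["c"] * n_per)
    return X, y


class TestSoftThreshold:
    def test_hand_computed_example(self):
        out = soft_threshold_weights(np.array([0.9, 0.5, 0.1]), keepx=2)
        assert out == pytest.approx([0.8944271909999159, 0.4472135954999579, 0.0])

    def test_keepx_equal_p_is_identity_up_to_norm(self):
        w = np.array([0.9, 0.5, 0.1])
        out = soft_threshold_weights(w, keepx=3)
        assert out == pytest.approx(w / np.linalg.norm(w))

    def test_exact_sparsity(self):
        rng = np.random.default_rng(0)
        w = rng.standard_normal(50)
        for k in (1, 5, 17):
            assert np.count_nonzero(soft_threshold_weights(w, k)) == k


class TestFit:
    def test_full_keepx_matches_pls2_oracle(self):
        PLSRegression = pytest.importorskip(
            "sklearn.cross_decomposition").PLSRegression
        rng = np.random.default_rng(1)
        for _ in range(6):
            n, p = int(rng.integers(15, 41)), int(rng.integers(3, 9))
            K = int(rng.integers(2, 4))
            X = rng.standard_normal((n, p))
            y = rng.integers(0, K, n)
            if len(np.unique(y)) < K:
                continue
            ncomp = int(min(3, p - 1))
            model = plsda_fit(X, y, ncomp=ncomp)  # keepx=None: unpenalized
            from ovorisk import transform
            Yhat = (transform(model, X) @ model.y_weights_.T + model.y_mean_)
            classes = np.unique(y)
            Y = (y[:, None] == classes[None, :]).astype(float)
            Xs = (X - X.mean(0)) / X.std(0, ddof=1)
            ref = PLSRegression(n_components=ncomp, scale=False,
                                tol=1e-12, max_iter=100000).fit(Xs, Y)
            assert np.abs(Yhat - ref.predict(Xs)).max() < 1e-6

    def test_sparsity_bound_and_orthogonality(self):
        X, y = separable_blobs(seed=2)
        model = plsda_fit(X, y, ncomp=2, keepx=[2, 1])
        for h, k in enumerate(model.keepx):
            assert np.count_nonzero(model.x_weights_[:, h]) <= k
        G = model.x_scores_.T @ model.x_scores_
        assert abs(G[0, 1]) < 1e-8 * max(G[0, 0], G[1, 1])
        assert np.allclose(np.linalg.norm(model.x_weights_, axis=0), 1.0)

    def test_single_separating_variable_selected(self):
        rng = np.random.default_rng(3)
        X = rng.standard_normal((30, 5)) * 0.1
        y = np.array(["a", "b"] * 15)
        X[y == "b", 3] += 5.0
        model = plsda_fit(X, y, ncomp=1, keepx=1)
        assert model.selected(0) == ["3"]

    def test_degenerate_inputs_rejected(self):
        X = np.random.default_rng(0).standard_normal((10, 3))
        with pytest.raises(ValueError, match="classes"):
            plsda_fit(X, ["a"] * 10, ncomp=1)
        with pytest.raises(ValueError, match="ncomp"):
            plsda_fit(X, ["a", "b"] * 5, ncomp=5)
        with pytest.raises(ValueError, match="keepX"):
            plsda_fit(X, ["a", "b"] * 5, ncomp=1, keepx=7)


class TestPredict:
    def test_training_points_recovered_on_separable_data(self):
        X, y = separable_blobs(seed=4)
        model = plsda_fit(X, y, ncomp=2)
        for dist in ("max", "centroid", "mahalanobis"):
            assert (plsda_predict(model, X, distance=dist) == y).all()

    def test_symmetric_midpoint_warns_on_tie(self):
        X = np.array([[-1.0, -1.0], [-1.2, -0.8], [1.0, 1.0], [1.2, 0.8]])
        y = np.array(["a", "a", "b", "b"])
        model = plsda_fit(X, y, ncomp=1)
        with pytest.warns(UserWarning, match="tie"):
            labels = plsda_predict(model, np.array([[0.0, 0.0]]),
                                   distance="centroid")
        assert labels[0] == "a"  # first class in sorted order

    def test_column_mismatch_lists_variables(self):
        X = pd.DataFrame(np.random.default_rng(0).standard_normal((10, 3)),
                         columns=["Na", "K", "Ca"])
        model = plsda_fit(X, ["a", "b"] * 5, ncomp=1)
        bad = X.rename(columns={"Ca": "Sr"})
        with pytest.raises(ValueError, match="Ca"):
            plsda_predict(model, bad)

    def test_unknown_distance(self):
        X, y = separable_blobs()
        model = plsda_fit(X, y, ncomp=1)
        with pytest.raises(ValueError, match="distance"):
            plsda_predict(model, X, distance="cosine")


class TestErrorRates:
    def test_ber_is_mean_per_class_error(self):
        y = np.array(["a"] * 5 + ["b"] * 5 + ["c"] * 5)
        pred = y.copy()
        pred[[0, 5, 10]] = ["b", "c", "a"]  # one error per class: 0.2 each
        oer, ber = error_rates(y, pred, np.unique(y))
        assert ber == pytest.approx(0.2)
        assert oer == pytest.approx(3 / 15)

    def test_ber_invariant_to_class_duplication(self):
        y = np.array(["a"] * 4 + ["b"] * 8)
        pred = np.array(["a", "a", "b", "b"] + ["b"] * 7 + ["a"])
        _, ber = error_rates(y, pred, np.unique(y))
        y2 = np.concatenate([y, y[:4]])
        pred2 = np.concatenate([pred, pred[:4]])
        _, ber2 = error_rates(y2, pred2, np.unique(y2))
        assert ber2 == pytest.approx(ber)


class TestCrossValidate:
    def test_separable_classes_reach_zero_ber(self):
        X, y = separable_blobs(seed=5, delta=10.0)
        cv = cross_validate(X, y, ncomp_grid=[2], keepx_grid=[2, 4],
                            folds=5, repeats=2, seed=0)
        assert cv.best["ber"] == 0.0
        # the centroid-based rules are error-free at every grid point; the
        # max rule can err on 3-class boundaries in a 2-dim latent space
        geo = cv.grid[cv.grid.distance != "max"]
        assert (geo["ber"] == 0).all()

    def test_seeded_cv_is_bit_reproducible(self):
        X, y = separable_blobs(seed=6, delta=1.0)
        cv1 = cross_validate(X, y, ncomp_grid=[1, 2], keepx_grid=[2],
                             folds=3, repeats=2, seed=9)
        cv2 = cross_validate(X, y, ncomp_grid=[1, 2], keepx_grid=[2],
                             folds=3, repeats=2, seed=9)
        assert cv1.grid.equals(cv2.grid)
        assert cv1.best == cv2.best

    def test_permuted_balanced_labels_give_chance_ber(self):
        bers = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            X = rng.standard_normal((40, 5))
            y = np.array(["a", "b"] * 20)
            rng.shuffle(y)
            cv = cross_validate(X, y, ncomp_grid=[1], keepx_grid=[5],
                                folds=5, repeats=2, seed=seed,
                                distances=("centroid",))
            bers.append(cv.grid["ber"].iloc[0])
        assert np.mean(bers) == pytest.approx(0.5, abs=0.1)

    def test_small_class_suggests_fewer_folds(self):
        X, y = separable_blobs(n_per=3)
        with pytest.raises(ValueError, match="fewer folds"):
            cross_validate(X, y, ncomp_grid=[1], keepx_grid=[2], folds=5)


class TestHoldout:
    def test_confusion_derived_metrics(self):
        y_true = np.array(["a"] * 10 + ["b"] * 20)
        y_pred = np.array(
            ["a"] * 8 + ["b"] * 2 + ["a"] * 3 + ["b"] * 17)
        rep = classification_report(y_true, y_pred)
        assert rep.confusion.to_numpy().tolist() == [[8, 2], [3, 17]]
        assert rep.accuracy == pytest.approx(0.8333, abs=5e-5)
        assert rep.sensitivity == pytest.approx(0.80)
        assert rep.specificity == pytest.approx(0.85)

    def test_perfect_predictions(self):
        y = np.array(["a", "b", "c"] * 4)
        rep = classification_report(y, y)
        assert rep.accuracy == 1.0
        assert np.all(np.diag(rep.confusion.to_numpy()) == 4)

    def test_holdout_on_separable_data(self):
        X, y = separable_blobs(n_per=20, seed=8)
        rep, model = evaluate_holdout(X, y, ncomp=2, keepx=2,
                                      distance="centroid", seed=0)
        assert rep.accuracy == 1.0
        # 70/30 stratified: 6 test samples per class
        assert rep.confusion.to_numpy().sum() == 18

    def test_seed_changes_split_not_contract(self):
        X, y = separable_blobs(n_per=10, seed=9, delta=1.5)
        r1, _ = evaluate_holdout(X, y, ncomp=1, seed=1)
        r2, _ = evaluate_holdout(X, y, ncomp=1, seed=2)
        assert r1.confusion.to_numpy().sum() == r2.confusion.to_numpy().sum()


class TestMarkerRecovery:
    def test_informative_elements_dominate_selection(self):
        from ovorisk import (
            DEFAULT_MARKERS, StructureSpec, SyntheticConfig, generate,
            inject_structure, substitute_nondetects,
        )
        hits = 0
        n_runs = 20
        for seed in range(n_runs):
            table = generate(SyntheticConfig(seed=200 + seed))
            table = inject_structure(table, StructureSpec(shift_sd=0.5))
            table = substitute_nondetects(table, "zero")
            X = table.matrix()
            y = table.data["system"].to_numpy()
            model = plsda_fit(X, y, ncomp=3, keepx=[7, 5, 5])
            sel = set(model.selected())
            hits += len(sel & set(DEFAULT_MARKERS)) / len(sel) >= 0.5
        assert hits >= n_runs / 2
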