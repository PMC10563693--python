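"""PCA/PLS-DA/SVM behavior: variance accounting, separability, the
cross-validated Q2 contract, permutation diagnostics and grid search."""

import numpy as np
import pytest

from mircos.chemometrics import (
    SVMConfig,
    pca_fit,
    plsda_evaluate,
    plsda_fit,
    plsda_permutation_test,
    svm_grid_search,
)


def _two_clusters(n_per=30, p=12, sep=6.0, noise=1.0, seed=0):
    rng = np.random.default_rng(seed)
    mu = np.zeros(p)
    mu2 = mu.copy()
    mu2[:3] += sep
    X = np.vstack(
        [rng.normal(mu, noise, (n_per, p)), rng.normal(mu2, noise, (n_per, p))]
    )
    y = np.array(["cultivated"] * n_per + ["wild"] * n_per)
    return X, y


# ------------------------------- PCA ----------------------------------- #


def test_pca_collinear_points_put_all_variance_on_pc1(rng):
    t = rng.normal(size=20)
    X = np.column_stack([t, 2 * t])
    res = pca_fit(X, 2)
    np.testing.assert_allclose(res.explained_variance_ratio, [1.0, 0.0], atol=1e-12)


def test_pca_ratios_sum_to_one_and_are_nonincreasing(rng):
    X = rng.normal(size=(15, 6))
    res = pca_fit(X, 6)
    assert abs(res.explained_variance_ratio.sum() - 1.0) < 1e-10
    assert np.all(np.diff(res.explained_variance_ratio) <= 1e-12)


def test_pca_full_reconstruction_and_orthonormal_loadings(rng):
    X = rng.normal(size=(12, 5))
    res = pca_fit(X, 5)
    np.testing.assert_allclose(
        res.loadings.T @ res.loadings, np.eye(5), atol=1e-8
    )
    np.testing.assert_allclose(
        res.scores @ res.loadings.T + res.mean, X, atol=1e-9
    )


def test_pca_k_bound():
    with pytest.raises(ValueError):
        pca_fit(np.random.default_rng(0).normal(size=(5, 3)), 5)


# ------------------------------ PLS-DA --------------------------------- #


def test_plsda_separable_clusters_train_at_100_percent():
    X, y = _two_clusters()
    model, m = plsda_fit(X, y, n_components=1, cv_folds=5)
    assert m.acc_train == 100.0
    assert m.r2y > 0.5


def test_plsda_q2_never_exceeds_r2y():
    for seed in range(3):
        X, y = _two_clusters(sep=2.0, seed=seed)
        _, m = plsda_fit(X, y, n_components=2, cv_folds=5, seed=seed)
        assert m.q2 <= m.r2y + 1e-9


def test_plsda_pure_noise_has_nonpositive_q2_in_expectation():
    q2s = []
    for seed in range(5):
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(60, 15))
        y = np.array(["wild", "cultivated"] * 30)
        _, m = plsda_fit(X, y, n_components=2, cv_folds=5, seed=seed)
        q2s.append(m.q2)
    assert np.mean(q2s) <= 0.0


def test_plsda_single_class_rejected():
    X = np.random.default_rng(0).normal(size=(10, 4))
    with pytest.raises(ValueError):
        plsda_fit(X, np.array(["wild"] * 10), 1, 3)


def test_rmsep_equals_rmsee_when_test_is_train():
    X, y = _two_clusters(n_per=20)
    model, m = plsda_fit(X, y, 2, 5)
    m, _ = plsda_evaluate(model, m, X, y)
    assert abs(m.rmsep - m.rmsee) < 1e-12
    assert m.acc_test == m.acc_train


def test_label_flip_complements_accuracy():
    X, y = _two_clusters(sep=1.0, noise=2.0, seed=3)
    model, m = plsda_fit(X, y, 2, 5)
    m, _ = plsda_evaluate(model, m, X, y)
    flipped = np.where(y == "wild", "cultivated", "wild")
    m2, _ = plsda_evaluate(model, m, X, flipped)
    assert abs(m.acc_test + m2.acc_test - 100.0) < 1e-9


def test_plsda_full_rank_matches_least_squares(rng):
    """With as many latent variables as the rank of centered X, PLS
    predictions coincide with ordinary least squares on the indicators."""
    n, p = 12, 4
    X = rng.normal(size=(n, p))
    y = np.array(["wild"] * 6 + ["cultivated"] * 6)
    model, _ = plsda_fit(X, y, n_components=p, cv_folds=3)
    Y = np.column_stack([(y == c).astype(float) for c in model.classes])
    Xc = X - X.mean(axis=0)
    Yc = Y - Y.mean(axis=0)
    beta = np.linalg.lstsq(Xc, Yc, rcond=None)[0]
    ols_pred = Xc @ beta + Y.mean(axis=0)
    np.testing.assert_allclose(model.decision_values(X), ols_pred, atol=1e-6)


def test_null_effect_external_accuracy_at_chance():
    """With equal class multipliers the generator carries no class signal:
    external accuracy over >= 200 pooled evaluations stays within binomial
    error of the 50% balanced-class baseline."""
    from mircos.simulate import SyntheticConfig, default_band_table, generate_spectra
    from mircos.split import stratified_split

    correct = total = 0
    for seed in range(4):
        cfg = SyntheticConfig(
            n_per_class={"cultivated": 90, "wild": 90},
            grid=(4000, 450, 20),
            peaks=default_band_table(contrast=1.0),
            replicates=1,
            seed=seed,
        )
        sp = generate_spectra(cfg)
        split = stratified_split(sp, 0.7)
        train = sp.select_samples(split.train_ids)
        test = sp.select_samples(split.test_ids)
        model, m = plsda_fit(train.absorbance, np.asarray(train.labels), 2, 5, seed)
        pred = model.predict(test.absorbance)
        correct += int(np.sum(pred == np.asarray(test.labels)))
        total += test.n_records
    assert total >= 200
    acc = correct / total
    # 3 standard errors of a fair coin at the pooled sample size, plus a
    # margin for within-split correlation of predictions
    assert abs(acc - 0.5) < 3 * np.sqrt(0.25 / total) + 0.06


# --------------------------- permutation test --------------------------- #


def test_permutation_strong_signal_negative_q2_intercept():
    """Across seeds, a well-separated problem keeps its Q2 intercept below
    zero and is never flagged as overfitting."""
    for seed in range(5):
        X, y = _two_clusters(n_per=20, p=10, sep=5.0, seed=seed)
        res = plsda_permutation_test(X, y, n_permutations=30, n_components=2,
                                     cv_folds=4, seed=seed)
        assert res.q2_intercept < 0
        assert not res.overfit_flag


def test_permutation_noise_labels_flag_overfitting():
    rng = np.random.default_rng(1)
    X = rng.normal(size=(40, 10))
    y = np.array(["wild", "cultivated"] * 20)
    res = plsda_permutation_test(X, y, n_permutations=30, n_components=2,
                                 cv_folds=4, seed=1)
    assert res.overfit_flag


def test_permutation_returns_requested_rounds():
    X, y = _two_clusters(n_per=15, p=6)
    res = plsda_permutation_test(X, y, n_permutations=200, n_components=1,
                                 cv_folds=3, seed=0)
    assert len(res.correlations) == 201  # 200 permutations + the original
    assert res.correlations[0] == 1.0
    with pytest.raises(ValueError):
        plsda_permutation_test(X, y, n_permutations=5)


# -------------------------------- SVM ----------------------------------- #


def test_svm_separable_reaches_full_cv_accuracy():
    X, y = _two_clusters(n_per=25, sep=8.0)
    clf, best, table, (mu, sd) = svm_grid_search(
        X, y, ([0.25, 1.0, 4.0, 16.0], [2.0**-6, 2.0**-3, 1.0]), cv_folds=4, seed=0
    )
    accs = [acc for _, _, acc in table]
    assert max(accs) == 1.0
    # the winner attains the grid maximum
    best_acc = max(acc for c, g, acc in table)
    won = [t for t in table if t[0] == best.c and t[1] == best.g][0]
    assert won[2] == best_acc


def test_svm_tie_breaks_to_smallest_c_then_g():
    X, y = _two_clusters(n_per=25, sep=10.0)
    _, best, table, _ = svm_grid_search(
        X, y, ([1.0, 4.0], [0.01, 0.1]), cv_folds=4, seed=0
    )
    best_acc = max(acc for *_, acc in table)
    winners = [(c, g) for c, g, acc in table if acc == best_acc]
    assert (best.c, best.g) == min(winners)


def test_svm_single_cell_grid():
    X, y = _two_clusters(n_per=15)
    _, best, table, _ = svm_grid_search(X, y, ([2.0], [0.125]), cv_folds=3, seed=0)
    assert (best.c, best.g) == (2.0, 0.125)
    assert len(table) == 1


def test_svm_config_validation():
    with pytest.raises(ValueError):
        SVMConfig(c=-1.0, g=0.1)
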