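"""PLS identities, orthogonalization, VIP, CV protocol, permutation test."""

import numpy as np
import pytest
from cytoconn import pls


def _latent_data(rng, n=30, p=15, noise=0.0, n_signal=3):
    """X with one latent direction driving y through ``n_signal`` columns."""
    t = rng.normal(size=n)
    X = rng.normal(size=(n, p))
    for j in range(n_signal):
        X[:, j] = t + 0.1 * rng.normal(size=n)
    y = t + noise * rng.normal(size=n)
    return X, y


def _rank_one_data(rng, n=30, p=12):
    """Exactly one latent direction: X = t p' + tiny noise, y = t."""
    t = rng.normal(size=n)
    load = rng.uniform(0.5, 1.5, size=p)
    X = np.outer(t, load) + 1e-6 * rng.normal(size=(n, p))
    return X, t


class TestZScore:
    def test_train_applied_to_self(self, rng):
        X = rng.normal(3, 2, size=(20, 4))
        Z, _ = pls.zscore_fit_apply(X)
        np.testing.assert_allclose(Z.mean(0), 0, atol=1e-12)
        np.testing.assert_allclose(Z.std(0), 1, atol=1e-12)

    def test_single_row_uses_train_stats(self, rng):
        X = rng.normal(size=(20, 3))
        mu, sd = pls.zscore_fit(X)
        row = rng.normal(size=(1, 3))
        np.testing.assert_allclose(pls.zscore_apply(row, mu, sd),
                                   (row - mu) / sd, atol=1e-12)

    def test_round_trip(self, rng):
        X = rng.normal(size=(15, 4))
        mu, sd = pls.zscore_fit(X)
        Z = pls.zscore_apply(X, mu, sd)
        np.testing.assert_allclose(Z * sd + mu, X, atol=1e-12)

    def test_constant_column_named(self):
        X = np.ones((10, 2))
        X[:, 0] = np.arange(10)
        with pytest.raises(ValueError, match="IL-6"):
            pls.zscore_fit(X, names=["IL-2", "IL-6"])


class TestFitPLS:
    def test_noiseless_single_latent_r2(self, rng):
        X, y = _rank_one_data(rng)
        m = pls.fit_pls(X, y, A=1)
        pred = pls.predict(m, X)
        ss_res = np.sum((pred - y) ** 2)
        ss_tot = np.sum((y - y.mean()) ** 2)
        assert 1 - ss_res / ss_tot >= 0.999

    def test_orthogonal_response_gives_null_loading(self, rng):
        # construct y exactly orthogonal to every column of X
        X = rng.normal(size=(20, 5))
        y = rng.normal(size=20)
        y -= y.mean()
        Xc = X - X.mean(0)
        beta, *_ = np.linalg.lstsq(Xc, y, rcond=None)
        y = y - Xc @ beta          # residual orthogonal to all columns
        try:
            m = pls.fit_pls(X, y, A=1)
        except np.linalg.LinAlgError:
            return                 # degenerate covariance also acceptable
        assert abs(m.q[0]) < 1e-8

    def test_separable_classes_perfect_training_accuracy(self, rng):
        n = 30
        labels = np.array(["WT"] * 15 + ["5xFAD"] * 15)
        X = rng.normal(size=(n, 20))
        X[labels == "5xFAD", :3] += 5.0
        m = pls.fit_pls(X, labels, A=1, mode="da")
        pred = pls.classify(m, X)
        enc = np.where(labels == "WT", 1.0, -1.0)   # last level sorted = WT
        assert np.all(pred == enc)

    def test_scores_orthogonal(self, rng):
        X, y = _latent_data(rng, noise=0.5)
        m = pls.fit_pls(X, y, A=3)
        G = m.T.T @ m.T
        off = G - np.diag(np.diag(G))
        assert np.max(np.abs(off)) < 1e-8

    def test_excessive_components_rejected(self, rng):
        X, y = _latent_data(rng, n=5, p=3)
        with pytest.raises(ValueError, match="out of range"):
            pls.fit_pls(X, y, A=5)


class TestOrthogonalize:
    def test_single_lv_identity_on_predictions(self, rng):
        X, y = _latent_data(rng, noise=0.3)
        m = pls.fit_pls(X, y, A=1)
        om = pls.orthogonalize(m)
        np.testing.assert_allclose(pls.predict(om, X), pls.predict(m, X),
                                   atol=1e-8)

    @pytest.mark.parametrize("A", [2, 3])
    def test_prediction_invariance(self, rng, A):
        X, y = _latent_data(rng, noise=0.5)
        m = pls.fit_pls(X, y, A=A)
        om = pls.orthogonalize(m)
        np.testing.assert_allclose(pls.predict(om, X), pls.predict(m, X),
                                   atol=1e-8)
        X_new = rng.normal(size=(10, X.shape[1]))
        np.testing.assert_allclose(pls.predict(om, X_new),
                                   pls.predict(m, X_new), atol=1e-8)

    def test_orthogonal_scores_uncorrelated_with_response(self, rng):
        X, y = _latent_data(rng, noise=0.5)
        om = pls.orthogonalize(pls.fit_pls(X, y, A=3))
        yc = y - y.mean()
        for a in range(om.T_orth.shape[1]):
            assert abs(om.T_orth[:, a] @ yc) < 1e-8

    def test_lv1_concentrates_covariance(self, rng):
        # planted response-orthogonal structure: LV1 of the orthogonalized
        # model carries at least the covariance of either original LV
        X, y = _latent_data(rng, n=40, p=12, noise=0.4)
        X[:, -3:] += np.outer(rng.normal(size=40), np.ones(3))  # y-orthogonal-ish
        m = pls.fit_pls(X, y, A=2)
        om = pls.orthogonalize(m)
        yc = om.y_train
        cov_orig = [abs(m.T[:, a] @ yc) / np.linalg.norm(m.T[:, a])
                    for a in range(2)]
        cov_lv1 = abs(om.T[:, 0] @ yc) / np.linalg.norm(om.T[:, 0])
        assert cov_lv1 >= max(cov_orig) - 1e-8


class TestVIP:
    def test_uniform_weights_give_unit_vip(self):
        rng = np.random.default_rng(5)
        # all columns identical copies of the latent driver + tiny noise:
        # weights equal by symmetry, VIP -> 1 each
        t = rng.normal(size=40)
        X = np.tile(t[:, None], (1, 6)) + 1e-8 * rng.normal(size=(40, 6))
        m = pls.fit_pls(X, t, A=1)
        np.testing.assert_allclose(pls.vip_scores(m), 1.0, atol=1e-3)

    def test_mean_squared_vip_is_one(self, rng):
        for A in (1, 2, 3):
            X = rng.normal(size=(25, 10))
            y = rng.normal(size=25)
            m = pls.fit_pls(X, y, A=A)
            assert np.mean(pls.vip_scores(m) ** 2) == pytest.approx(1.0,
                                                                    abs=1e-8)

    def test_signal_analyte_exceeds_one(self, rng):
        hits = 0
        for _ in range(50):
            X = rng.normal(size=(30, 15))
            t = rng.normal(size=30)
            X[:, 0] = t + 0.3 * rng.normal(size=30)
            m = pls.fit_pls(X, t, A=1)
            hits += pls.vip_scores(m)[0] > 1
        assert hits >= 48   # >= 95% of simulations


class TestChooseK:
    @pytest.mark.parametrize("n,k", [(31, 3), (29, 5), (30, 5), (100, 3)])
    def test_fold_rule(self, n, k):
        assert pls.choose_k(n) == k

    def test_too_few_samples(self):
        with pytest.raises(ValueError):
            pls.choose_k(5)


class TestCrossValidate:
    def test_perfect_predictions_zero_rmsecv(self, rng):
        X, y = _rank_one_data(rng, n=24)
        cv = pls.cross_validate(X, y, repeats=5, seed=1)
        assert cv.mean_statistic[cv.candidates.index(cv.chosen_A)] < 0.01

    def test_rmsecv_formula_cases(self):
        # perfect predictions -> 0; constant offset c -> |c|
        y = np.arange(6.0)
        assert np.sqrt(np.mean((y - y) ** 2)) == 0.0
        c = 0.7
        assert np.sqrt(np.mean(((y + c) - y) ** 2)) == pytest.approx(abs(c))

    def test_deterministic_given_seed(self, rng):
        X, y = _latent_data(rng, noise=0.5)
        cv1 = pls.cross_validate(X, y, repeats=8, seed=42)
        cv2 = pls.cross_validate(X, y, repeats=8, seed=42)
        np.testing.assert_array_equal(cv1.statistics, cv2.statistics)
        assert cv1.chosen_A == cv2.chosen_A

    def test_pure_noise_prefers_few_components(self, rng):
        chosen = []
        for i in range(50):
            X = rng.normal(size=(20, 10))
            y = rng.normal(size=20)
            cv = pls.cross_validate(X, y, repeats=10, seed=i)
            chosen.append(cv.chosen_A)
        assert np.mean(np.array(chosen) == 1) >= 0.4

    def test_global_scaling_compatibility_flag(self, rng):
        X, y = _latent_data(rng, noise=0.5)
        a = pls.cross_validate(X, y, repeats=5, seed=2)
        b = pls.cross_validate(X, y, repeats=5, seed=2, global_scaling=True)
        # both run and agree closely; fold-refit is the default
        assert abs(a.mean_statistic[0] - b.mean_statistic[0]) < 0.2

    def test_da_requires_both_classes_in_training(self, rng):
        X = rng.normal(size=(12, 5))
        labels = np.array(["a"] * 6 + ["b"] * 6)
        cv = pls.cross_validate(X, labels, mode="da", repeats=5, seed=3)
        assert 0 <= cv.mean_statistic.max() <= 1


class TestPermutation:
    def test_z_formula_closed_forms(self):
        z, p = pls.z_and_p(1.0, 1.0, 0.5, "regression")
        assert z == 0.0 and p == pytest.approx(0.5)
        z, p = pls.z_and_p(0.9, 0.8, 0.05, "da")   # accuracy 2 sd above null
        assert z == pytest.approx(2.0)
        assert p == pytest.approx(0.0228, abs=5e-4)

    def test_degenerate_null_flagged(self):
        z, p = pls.z_and_p(1.0, 1.0, 0.0, "regression")
        assert np.isnan(z) and np.isnan(p)

    def test_signal_model_significant(self, rng):
        X, y = _latent_data(rng, n=26, p=12, noise=0.3)
        res = pls.permutation_test(X, y, chosen_A=1, n_perm=100, cv_repeats=3,
                                   seed=7)
        assert res.z < -2
        assert res.p < 0.05

    def test_deterministic_given_seed(self, rng):
        X, y = _latent_data(rng, n=20, p=8, noise=0.5)
        r1 = pls.permutation_test(X, y, 1, n_perm=30, cv_repeats=2, seed=9)
        r2 = pls.permutation_test(X, y, 1, n_perm=30, cv_repeats=2, seed=9)
        assert r1.z == r2.z and r1.p == r2.p
        np.testing.assert_array_equal(r1.null_values, r2.null_values)


class TestSignatureReport:
    def _orthogonal_model(self, rng):
        X, y = _latent_data(rng, n=30, p=10, noise=0.3)
        return pls.orthogonalize(pls.fit_pls(
            X, y, A=2, names=[f"A{i}" for i in range(10)]))

    def test_planted_upregulated_analyte_positive_loading(self, rng):
        om = self._orthogonal_model(rng)
        sig = pls.signature_report(om)
        row = sig[sig["analyte"] == "A0"]
        assert len(row) == 1
        assert row["lv1_loading"].iloc[0] > 0
        assert row["direction"].iloc[0] == "up"

    def test_infinite_threshold_empty(self, rng):
        assert len(pls.signature_report(self._orthogonal_model(rng),
                                        threshold=np.inf)) == 0

    def test_zero_threshold_all_sorted(self, rng):
        sig = pls.signature_report(self._orthogonal_model(rng), threshold=0.0)
        assert len(sig) == 10
        assert np.all(np.diff(sig["vip"]) <= 1e-12)


def test_predictions_match_sklearn_reference(rng):
    """Cross-check NIPALS predictions against an independent implementation."""
    sklearn = pytest.importorskip("sklearn.cross_decomposition")
    X, y = _latent_data(rng, n=30, p=12, noise=0.5)
    for A in (1, 2, 3):
        ours = pls.fit_pls(X, y, A=A)
        ref = sklearn.PLSRegression(n_components=A, scale=True).fit(X, y)
        np.testing.assert_allclose(pls.predict(ours, X),
                                   ref.predict(X).ravel(), atol=1e-8)
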