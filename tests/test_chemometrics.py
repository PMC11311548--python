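import numpy as np
import pytest
from sklearn.cross_decomposition import PLSRegression

from oxishelf.chemometrics import (
    auto_predict,
    flag_outliers,
    loocv,
    pca,
    pls_fit,
    pls_predict,
    select_bands,
    suggest_n_lv,
    vip_scores,
    VIPResult,
)
from oxishelf.config import SyntheticConfig
from oxishelf.preprocess import preprocess
from oxishelf.synthetic import make_study


def naive_nipals_pls1(X, y, n_lv):
    """Deliberately plain re-implementation used as an oracle."""
    X = np.asarray(X, float).copy()
    y = np.asarray(y, float).copy()
    xm, ym = X.mean(0), y.mean()
    E, f = X - xm, y - ym
    W, P, q = [], [], []
    for _ in range(n_lv):
        w = E.T @ f
        w = w / np.linalg.norm(w)
        t = E @ w
        p = E.T @ t / (t @ t)
        q.append(f @ t / (t @ t))
        E = E - np.outer(t, p)
        W.append(w)
        P.append(p)
    W, P, q = np.array(W).T, np.array(P).T, np.array(q)
    b = W @ np.linalg.solve(P.T @ W, q)
    return lambda Xn: (np.atleast_2d(Xn) - xm) @ b + ym


def random_problem(seed, n=20, p=50):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, p))
    f = rng.normal(size=(p, 2))
    y = 0.5 * X @ f[:, 0] + 0.2 * X @ f[:, 1] + 0.1 * rng.normal(size=n)
    return X, y


class TestPLSFit:
    def test_single_column_collinear(self):
        x = np.array([[1.0], [2.0], [3.0], [4.0]])
        y = 2.0 * x.ravel()
        model = pls_fit(x, y, 1)
        assert np.allclose(model.fitted, y, atol=1e-12)
        assert model.regression_vector[0] == pytest.approx(2.0)

    def test_full_rank_equals_least_squares(self):
        X, y = random_problem(3, n=12, p=5)
        model = pls_fit(X, y, 5)
        Xc = np.column_stack([np.ones(12), X - X.mean(0)])
        beta, *_ = np.linalg.lstsq(Xc, y, rcond=None)
        assert np.max(np.abs(model.fitted - Xc @ beta)) <= 1e-8

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_reference_implementation(self, seed):
        X, y = random_problem(seed)
        rng = np.random.default_rng(seed + 1000)
        X_new = rng.normal(size=(6, X.shape[1]))
        model = pls_fit(X, y, 5)
        sk = PLSRegression(n_components=5, scale=False).fit(X, y)
        assert np.max(np.abs(pls_predict(model, X_new) - sk.predict(X_new).ravel())) <= 1e-6

    def test_score_orthogonality(self):
        X, y = random_problem(7)
        model = pls_fit(X, y, 8)
        T = model.scores
        norms = np.linalg.norm(T, axis=0)
        G = np.abs(T.T @ T) / np.outer(norms, norms)
        np.fill_diagonal(G, 0.0)
        assert G.max() <= 1e-8

    def test_excessive_lv_rejected(self):
        X, y = random_problem(0, n=6, p=4)
        with pytest.raises(ValueError, match="n_lv"):
            pls_fit(X, y, 6)

    def test_zero_variance_y_rejected(self):
        X, _ = random_problem(0)
        with pytest.raises(ValueError, match="variance"):
            pls_fit(X, np.ones(X.shape[0]), 2)

    def test_rank_exhaustion_reports_maximum(self):
        rng = np.random.default_rng(2)
        base = rng.normal(size=(10, 2))
        X = base @ rng.normal(size=(2, 30))  # rank 2
        y = X[:, 0]
        with pytest.raises(ValueError, match="at most 2"):
            pls_fit(X, y, 5)


class TestPLSPredict:
    def test_training_set_reproduced(self):
        X, y = random_problem(1)
        model = pls_fit(X, y, 4)
        assert np.allclose(pls_predict(model, X), model.fitted, atol=1e-12)

    def test_mean_row_predicts_mean(self):
        X, y = random_problem(2)
        model = pls_fit(X, y, 4)
        assert pls_predict(model, model.x_mean[None, :])[0] == pytest.approx(
            model.y_mean, abs=1e-10
        )

    def test_duplicated_row_duplicated_prediction(self):
        X, y = random_problem(4)
        model = pls_fit(X, y, 3)
        preds = pls_predict(model, np.vstack([X[0], X[0]]))
        assert preds[0] == preds[1]

    def test_channel_mismatch_rejected(self):
        X, y = random_problem(5)
        model = pls_fit(X, y, 3)
        with pytest.raises(ValueError, match="channels"):
            pls_predict(model, np.zeros((1, X.shape[1] + 1)))


class TestCV:
    def test_perfect_linear_data(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(15, 4))
        y = X @ np.array([1.0, -2.0, 0.5, 3.0])
        cv = loocv(X, y, 4)
        assert cv.rmse <= 1e-8
        assert cv.r_squared == pytest.approx(1.0, abs=1e-10)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_naive_double_loop(self, seed):
        X, y = random_problem(seed, n=8, p=6)
        cv = loocv(X, y, 3)
        preds = np.empty(8)
        for i in range(8):
            mask = np.arange(8) != i
            predict = naive_nipals_pls1(X[mask], y[mask], 3)
            preds[i] = predict(X[i])[0]
        assert np.max(np.abs(cv.predictions - preds)) <= 1e-10

    def test_auto_never_worse_than_loocv(self):
        for seed in range(10):
            X, y = random_problem(seed, n=25, p=40)
            assert auto_predict(X, y, 5).r_squared >= loocv(X, y, 5).r_squared

    def test_rpd_definition(self):
        X, y = random_problem(9)
        cv = loocv(X, y, 3)
        assert cv.rpd == pytest.approx(np.std(y, ddof=1) / cv.rmse)

    def test_prediction_shift_and_scale_invariance(self):
        X, y = random_problem(11)
        base = loocv(X, y, 3)
        shifted = loocv(X, y + 7.0, 3)
        assert np.allclose(shifted.predictions, base.predictions + 7.0, atol=1e-8)
        scaled = loocv(X, 3.0 * y, 3)
        assert scaled.rmse == pytest.approx(3.0 * base.rmse, rel=1e-8)

    def test_too_few_samples_rejected(self):
        X, y = random_problem(0, n=6, p=10)
        with pytest.raises(ValueError, match="n_lv \\+ 2"):
            loocv(X, y, 5)

    def test_synthetic_tbars_loocv_r2(self, default_study):
        processed = preprocess(default_study.spectra)
        y = default_study.truth["TBARS"].to_numpy()
        cv = loocv(processed.absorbance, y, 10)
        assert cv.r_squared >= 0.8


class TestVIP:
    def test_single_channel_is_one(self):
        x = np.linspace(0, 1, 8)[:, None]
        model = pls_fit(x, 2 * x.ravel() + 1, 1)
        vip = vip_scores(model)
        assert vip.scores[0] == pytest.approx(1.0)

    def test_mean_squared_is_one(self):
        for seed in range(10):
            X, y = random_problem(seed)
            model = pls_fit(X, y, 5)
            vip = vip_scores(model)
            assert np.mean(vip.scores**2) == pytest.approx(1.0, abs=1e-8)
            assert np.all(vip.scores >= 0)

    def test_planted_informative_channel_dominates(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(30, 20))
        y = X[:, 7].copy()
        model = pls_fit(X, y, 3)
        vip = vip_scores(model)
        assert np.argmax(vip.scores) == 7
        assert vip.scores[7] > 1.0


class TestSelectBands:
    def test_empty_when_all_below(self):
        wn = np.linspace(400.0, 4000.0, 10)
        vip = VIPResult(scores=np.full(10, 0.5), threshold=1.0)
        assert select_bands(vip, wn) == []

    def test_single_run(self):
        wn = np.arange(2800.0, 3050.0, 25.0)  # 10 channels
        scores = np.where((wn >= 2850.0) & (wn <= 3000.0), 1.5, 0.2)
        vip = VIPResult(scores=scores, threshold=1.0)
        assert select_bands(vip, wn) == [(2850.0, 3000.0)]

    def test_runs_reported_descending(self):
        wn = np.arange(0.0, 100.0, 10.0)
        scores = np.array([1.5, 1.5, 0, 0, 1.2, 1.2, 0, 0, 2.0, 2.0])
        vip = VIPResult(scores=scores, threshold=1.0)
        bands = select_bands(vip, wn)
        assert bands == [(80.0, 90.0), (40.0, 50.0), (0.0, 10.0)]

    def test_grid_mismatch_rejected(self):
        vip = VIPResult(scores=np.ones(5), threshold=1.0)
        with pytest.raises(ValueError):
            select_bands(vip, np.arange(4.0))


class TestPCA:
    def test_rank_one_explains_everything(self):
        u = np.linspace(-1, 1, 12)[:, None]
        v = np.random.default_rng(0).normal(size=(1, 30))
        result = pca(u @ v, 3)
        assert result.explained_variance_pct[0] == pytest.approx(100.0)

    def test_matches_eigendecomposition_oracle(self):
        X, _ = random_problem(6, n=25, p=12)
        result = pca(X, 6)
        C = np.cov(X, rowvar=False)
        eigvals = np.sort(np.linalg.eigvalsh(C))[::-1]
        expected = 100.0 * eigvals / eigvals.sum()
        assert np.allclose(result.explained_variance_pct, expected[:6], atol=1e-8)

    def test_explained_nonincreasing_and_bounded(self):
        X, _ = random_problem(8)
        result = pca(X, 8)
        pct = result.explained_variance_pct
        assert np.all(np.diff(pct) <= 1e-12)
        assert pct.sum() <= 100.0 + 1e-9

    def test_low_noise_study_dominated_by_two_components(self):
        cfg = SyntheticConfig(
            seed=4, scatter_sd=0.005, baseline_slope_sd=0.0, spectral_noise_sd=0.0005
        )
        study = make_study(cfg)
        processed = preprocess(study.spectra)
        aug = np.hstack(
            [processed.absorbance, study.truth[["PV", "TBARS"]].to_numpy()]
        )
        result = pca(aug, 5)
        assert result.explained_variance_pct[:2].sum() > 95.0

    def test_excessive_components_rejected(self):
        X, _ = random_problem(0, n=5, p=10)
        with pytest.raises(ValueError):
            pca(X, 5)


class TestExtras:
    def test_flag_outliers_finds_planted(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(30, 10))
        y = X @ rng.normal(size=10) + 0.01 * rng.normal(size=30)
        y[4] += 10.0  # gross outlier
        cv = loocv(X, y, 3)
        flagged = flag_outliers(cv, y)
        assert 4 in flagged

    def test_suggest_n_lv_reasonable(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(30, 15))
        y = X[:, 0] + 0.05 * rng.normal(size=30)
        lv = suggest_n_lv(X, y, max_lv=6)
        assert 1 <= lv <= 6
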