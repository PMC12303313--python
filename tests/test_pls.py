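import numpy as np
import pandas as pd
import pytest

import phycomet as pm
from phycomet.errors import DegenerateDataError, ValidationError
from phycomet.pls_select import predict_components, stratified_folds


def planted_xy(n_informative=1, seed=0, n=12, p=10, effect=4.0):
    rng = np.random.default_rng(seed)
    y = np.array([-1.0] * 8 + [1.0] * 4)
    X = rng.normal(size=(n, p))
    X[:, :n_informative] += effect * y[:, None] / 2.0
    return X, y


class TestFitPls:
    def test_rank_one_signal_concentrates_weight(self):
        rng = np.random.default_rng(0)
        y = np.array([-1.0, -1, -1, 1, 1, 1])
        X = np.zeros((6, 5))
        X[:, 2] = 3.0 * y  # only column 2 carries signal
        model = pm.fit_pls(X, y, 1)
        assert abs(model.W[2, 0]) == pytest.approx(1.0)
        assert np.abs(np.delete(model.W[:, 0], 2)).max() < 1e-12

    def test_scores_orthogonal_weights_unit(self):
        X, y = planted_xy(seed=3)
        model = pm.fit_pls(X, y, 4)
        T = model.T
        gram = T.T @ T
        off = gram - np.diag(np.diag(gram))
        assert np.abs(off).max() < 1e-8 * np.diag(gram).max()
        np.testing.assert_allclose(np.linalg.norm(model.W, axis=0), 1.0, rtol=1e-12)

    def test_component_count_beyond_rank_errors(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(6, 10))
        y = np.array([-1.0, -1, -1, 1, 1, 1])
        with pytest.raises((ValidationError, DegenerateDataError)):
            pm.fit_pls(X, y, 6)  # min(n_samples - 1, p) = 5

    def test_single_class_errors(self):
        X = np.random.default_rng(0).normal(size=(6, 4))
        with pytest.raises(DegenerateDataError):
            pm.fit_pls(X, np.ones(6), 1)

    def test_first_weight_matches_eigenvector_oracle(self):
        """w_1 equals the dominant eigenvector of X'y y'X (brute force)."""
        rng = np.random.default_rng(42)
        for _ in range(25):
            X = rng.normal(size=(6, 10))
            y = rng.choice([-1.0, 1.0], size=6)
            while np.unique(y).size < 2:
                y = rng.choice([-1.0, 1.0], size=6)
            model = pm.fit_pls(X, y, 1)
            Xc = X - X.mean(axis=0)
            yc = y - y.mean()
            M = np.outer(Xc.T @ yc, Xc.T @ yc)
            eigval, eigvec = np.linalg.eigh(M)
            v = eigvec[:, -1]
            cos = abs(v @ model.W[:, 0]) / np.linalg.norm(v)
            assert cos > 1 - 1e-8

    def test_matches_sklearn_first_component(self):
        from sklearn.cross_decomposition import PLSRegression

        X, y = planted_xy(seed=7, n_informative=3)
        model = pm.fit_pls(X, y, 2)
        sk = PLSRegression(n_components=2, scale=False).fit(X, y)
        w_sk = sk.x_weights_[:, 0]
        cos = abs(w_sk @ model.W[:, 0]) / np.linalg.norm(w_sk)
        assert cos > 1 - 1e-10


class TestVip:
    def test_equal_weights_give_unit_vip(self):
        y = np.array([-1.0, -1, 1, 1])
        X = np.tile(y[:, None], (1, 4)).astype(float)  # every column identical
        model = pm.fit_pls(X, y, 1)
        np.testing.assert_allclose(pm.vip_scores(model), 1.0, rtol=1e-12)

    def test_single_informative_column_vip(self):
        y = np.array([-1.0, -1, -1, 1, 1, 1])
        X = np.zeros((6, 9))
        X[:, 4] = y
        model = pm.fit_pls(X, y, 1)
        vip = pm.vip_scores(model)
        assert vip[4] == pytest.approx(np.sqrt(9))
        assert np.abs(np.delete(vip, 4)).max() < 1e-10

    def test_sum_of_squares_identity(self):
        for seed in range(10):
            X, y = planted_xy(seed=seed, n_informative=2)
            model = pm.fit_pls(X, y, 3)
            vip = pm.vip_scores(model)
            assert (vip ** 2).sum() == pytest.approx(X.shape[1], rel=1e-8)


class TestTuning:
    def test_fold_sizes_for_eight_samples(self):
        y = np.array([-1.0] * 4 + [1.0] * 4)
        folds = stratified_folds(y, folds=5, seed=0)
        sizes = sorted(len(f) for f in folds)
        assert sizes == [1, 1, 2, 2, 2]
        # every training complement keeps both classes
        for f in folds:
            rest = np.setdiff1d(np.arange(8), f)
            assert np.unique(y[rest]).size == 2

    def test_rank_bound_caps_search(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(8, 30))
        y = np.array([-1.0] * 5 + [1.0] * 3)
        a = pm.tune_ncomp(X, y, max_components=10, folds=4, seed=0)
        assert 1 <= a <= 7  # at most n_train - 1 components are identifiable

    def test_single_informative_component_recovered(self):
        """A* = 1 in >= 90% of seeds when the truth is rank one."""
        hits = 0
        n_seeds = 30
        for seed in range(n_seeds):
            rng = np.random.default_rng(1000 + seed)
            y = np.array([-1.0] * 6 + [1.0] * 6)
            X = rng.normal(size=(12, 40), scale=0.3)
            X += np.outer(y, rng.normal(size=40))  # one strong shared direction
            a = pm.tune_ncomp(X, y, max_components=5, folds=4, seed=seed)
            hits += a == 1
        assert hits / n_seeds >= 0.9

    def test_infeasible_folds_error_mentions_loo(self):
        X, y = planted_xy()
        with pytest.raises(ValidationError, match="leave-one-out"):
            pm.tune_ncomp(X, y, folds=20)


class TestSelectFeatures:
    def _frame(self, X):
        return pd.DataFrame(X, index=[f"s{i}" for i in range(X.shape[0])],
                            columns=[f"F{j}" for j in range(X.shape[1])])

    def test_quantile_bounds_selection_count(self):
        rng = np.random.default_rng(0)
        X = self._frame(rng.normal(size=(12, 100)))
        labels = ["mono"] * 8 + ["co"] * 4
        sel = pm.select_features(X, labels, seed=0)
        assert len(sel.selected) <= 5  # 100 features, 0.95 quantile, no ties

    def test_constant_labels_error(self):
        X = self._frame(np.random.default_rng(0).normal(size=(8, 10)))
        with pytest.raises(DegenerateDataError):
            pm.select_features(X, ["mono"] * 8)

    def test_zero_variance_features_dropped(self):
        rng = np.random.default_rng(3)
        X = self._frame(rng.normal(size=(12, 20)))
        X["F0"] = 1.0
        labels = ["mono"] * 8 + ["co"] * 4
        with pytest.warns(UserWarning, match="zero-variance"):
            sel = pm.select_features(X, labels, seed=0)
        assert sel.dropped_zero_variance == ["F0"]
        assert "F0" not in sel.vip.index

    def test_feature_order_invariance(self):
        rng = np.random.default_rng(12)
        X = self._frame(rng.normal(size=(12, 50)))
        labels = ["mono"] * 8 + ["co"] * 4
        sel1 = pm.select_features(X, labels, seed=0)
        perm = rng.permutation(X.columns)
        sel2 = pm.select_features(X[perm], labels, seed=0)
        assert set(sel1.selected) == set(sel2.selected)
        assert sel1.threshold == pytest.approx(sel2.threshold)

    def test_direction_reflects_class_means(self):
        rng = np.random.default_rng(8)
        X = self._frame(rng.normal(size=(12, 30), scale=0.2))
        labels = ["mono"] * 8 + ["co"] * 4
        X.iloc[8:, 0] += 5.0   # co-enriched
        X.iloc[:8, 1] += 5.0   # mono-enriched
        sel = pm.select_features(X, labels, seed=0)
        assert sel.direction.loc["F0"] == "co-enriched"
        assert sel.direction.loc["F1"] == "mono-enriched"

    def test_sensitivity_monotone_in_effect_size(self):
        """Median recovery of planted features never drops as the shift grows."""
        medians = []
        for effect in (0.5, 1.5, 3.0):
            sens = []
            for seed in range(15):
                cfg = pm.GeneratorConfig(
                    n_features=200, n_differential=10, effect_size=effect,
                    zero_inflation=0.0, exchange_design={},
                    design_seed=seed, noise_seed=2000 + seed,
                )
                table, pheno, truth = pm.generate_feature_dataset(cfg)
                cols = pheno.samples_for(species="SM", compartment="exo")
                X = pm.log_transform(table).intensities[cols].T
                sel = pm.select_features(X, pheno.table.loc[cols, "culture"], seed=seed)
                planted = set(truth.differential[("SM", "exo")])
                sens.append(len(planted & set(sel.selected)) / len(planted))
            medians.append(np.median(sens))
        assert medians == sorted(medians)
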