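"""PLS fitting and the validation battery against independent oracles."""

import math

import numpy as np
import pytest

from pbbqsar.pls import (PlsError, ValidationReport, external_validation,
                         field_contributions, final_metrics, fit_pls, loo_q2,
                         progressive_scrambling, regression_f,
                         scrambling_profile, select_components,
                         split_train_test)


def brute_force_loo(X, y, n_components):
    """Independent leave-one-out loop: refit and predict each held-out row."""
    press = 0.0
    n = len(y)
    for i in range(n):
        keep = np.ones(n, dtype=bool)
        keep[i] = False
        model = fit_pls(X[keep], y[keep], n_components)
        press += (model.predict(X[i:i + 1])[0] - y[i]) ** 2
    return 1.0 - press / np.sum((y - y.mean()) ** 2), math.sqrt(press / n)


class TestFit:
    def test_exact_fit_of_linear_response(self, rng):
        X = rng.normal(size=(15, 4))
        beta = rng.normal(size=4)
        y = X @ beta + 2.0
        model = fit_pls(X, y, 4)
        assert np.abs(model.predict(X) - y).max() < 1e-8

    def test_full_rank_equals_least_squares(self, rng):
        """At full component count PLS reproduces the OLS solution."""
        X = rng.normal(size=(10, 6))
        y = rng.normal(size=10)
        model = fit_pls(X, y, 6)
        A = np.column_stack([np.ones(10), X])
        beta = np.linalg.solve(A.T @ A, A.T @ y)   # normal equations
        assert np.abs(model.predict(X) - A @ beta).max() < 1e-8

    def test_row_permutation_invariance(self, rng):
        X = rng.normal(size=(12, 5))
        y = rng.normal(size=12)
        perm = rng.permutation(12)
        a = fit_pls(X, y, 3)
        b = fit_pls(X[perm], y[perm], 3)
        assert np.abs(a.coef - b.coef).max() < 1e-10

    def test_error_conditions(self, rng):
        X = rng.normal(size=(8, 3))
        with pytest.raises(PlsError):
            fit_pls(X, np.ones(8), 2)           # constant response
        with pytest.raises(PlsError):
            fit_pls(X, rng.normal(size=8), 7)   # exceeds rank

    def test_score_orthogonality(self, rng):
        X = rng.normal(size=(20, 8))
        y = X @ rng.normal(size=8) + 0.1 * rng.normal(size=20)
        model = fit_pls(X, y, 4)
        gram = model.x_scores.T @ model.x_scores
        off = gram - np.diag(np.diag(gram))
        assert np.abs(off).max() < 1e-8


class TestLoo:
    def test_matches_brute_force(self, rng):
        X = rng.normal(size=(20, 10))
        y = X @ rng.normal(size=10) + rng.normal(size=20)
        for k in (1, 3, 5):
            q2, sdep = loo_q2(X, y, k)
            q2_bf, sdep_bf = brute_force_loo(X, y, k)
            assert q2 == pytest.approx(q2_bf, abs=1e-12)
            assert sdep == pytest.approx(sdep_bf, abs=1e-12)

    def test_perfect_model_q2_one(self, rng):
        X = rng.normal(size=(15, 3))
        y = X @ np.array([1.0, -2.0, 0.5])
        q2, sdep = loo_q2(X, y, 3)
        assert q2 == pytest.approx(1.0, abs=1e-8)
        assert sdep == pytest.approx(0.0, abs=1e-6)

    def test_pure_noise_negative_in_expectation(self):
        """Monte-Carlo: response independent of X gives q2 <= 0 on average."""
        q2s = []
        for rep in range(100):
            r = np.random.default_rng(5000 + rep)
            X = r.normal(size=(12, 5))
            y = r.normal(size=12)
            q2s.append(loo_q2(X, y, 2)[0])
        assert np.mean(q2s) < 0.0


class TestComponentSelection:
    def test_recovers_planted_latent_dimension(self, rng):
        """Three-factor simulation: the q2-optimal n lands near 3."""
        T = rng.normal(size=(40, 3))
        P = rng.normal(size=(3, 25))
        X = T @ P + 0.05 * rng.normal(size=(40, 25))
        y = T @ np.array([2.0, -1.5, 1.0]) + 0.05 * rng.normal(size=40)
        n, q2 = select_components(X, y, max_components=8)
        assert 2 <= n <= 5
        assert q2 > 0.9

    def test_tie_break_prefers_small_n(self, rng, monkeypatch):
        # a perfectly flat q2 profile must resolve to the smallest n
        import pbbqsar.pls as plsmod
        X = rng.normal(size=(20, 6))
        y = rng.normal(size=20)
        monkeypatch.setattr(plsmod, "loo_q2",
                            lambda X, y, k, preprocessor=None: (0.7, 0.1))
        n, q2 = plsmod.select_components(X, y, max_components=5)
        assert n == 1
        assert q2 == 0.7


class TestFinalMetrics:
    def test_perfect_fit_limits(self, rng):
        X = rng.normal(size=(12, 4))
        y = X @ rng.normal(size=4)
        model = fit_pls(X, y, 4)
        r2, see, f = final_metrics(model, X, y)
        assert r2 == pytest.approx(1.0, abs=1e-10)
        assert see == pytest.approx(0.0, abs=1e-7)
        assert f == math.inf

    def test_f_convention_reproduces_published_pair(self):
        """With N=35 and n=8 an R2 rounding to 0.95 gives F rounding to
        67.79 under the (n, N-n-1) regression-F convention."""
        hits = [r2 for r2 in np.arange(0.945, 0.955, 1e-5)
                if round(regression_f(float(r2), 35, 8), 2) == 67.79]
        assert hits
        assert all(round(r2, 2) == 0.95 for r2 in hits)

    def test_r2_affine_invariance(self, rng):
        X = rng.normal(size=(20, 5))
        y = X @ rng.normal(size=5) + rng.normal(size=20)
        r2a = final_metrics(fit_pls(X, y, 3), X, y)[0]
        y2 = 5.0 * y - 7.0
        r2b = final_metrics(fit_pls(X, y2, 3), X, y2)[0]
        assert r2a == pytest.approx(r2b, abs=1e-10)


class TestContributions:
    def test_single_block_takes_all(self):
        model = _toy_model(coef=np.array([0.0, 0.0, 1.5, -2.0]))
        blocks = np.array(["steric", "steric", "electrostatic",
                           "electrostatic"])
        out = field_contributions(model, blocks, np.ones(4))
        assert out["steric"] == 0.0
        assert out["electrostatic"] == 100.0

    def test_symmetric_blocks_split_evenly(self):
        model = _toy_model(coef=np.array([1.0, -2.0, 1.0, -2.0]))
        blocks = np.array(["steric", "steric", "electrostatic",
                           "electrostatic"])
        out = field_contributions(model, blocks, np.ones(4))
        assert out["steric"] == pytest.approx(50.0)
        assert out["electrostatic"] == pytest.approx(50.0)

    def test_normalization(self, rng):
        model = _toy_model(coef=rng.normal(size=6))
        blocks = np.array(["steric"] * 2 + ["electrostatic"] * 4)
        out = field_contributions(model, blocks, rng.uniform(0.5, 2, 6))
        assert out["steric"] + out["electrostatic"] == pytest.approx(100.0,
                                                                     abs=1e-6)


def _toy_model(coef):
    from pbbqsar.pls import PlsModel
    p = len(coef)
    return PlsModel(n_components=1, coef=np.asarray(coef, float),
                    x_mean=np.zeros(p), y_mean=0.0,
                    x_scores=np.zeros((1, 1)), x_weights=np.zeros((p, 1)),
                    x_loadings=np.zeros((p, 1)), y_loadings=np.zeros((1, 1)))


class TestExternalValidation:
    def test_perfect_and_mean_predictions(self, rng):
        y_test = rng.normal(size=6)
        r2, sep = external_validation(y_test, y_test, y_test.mean() + 1.0)
        assert r2 == 1.0 and sep == 0.0
        mean = 0.37
        r2, _ = external_validation(np.full(6, mean), y_test, mean)
        assert r2 == pytest.approx(0.0, abs=1e-12)

    def test_direct_formula_oracle(self, rng):
        y_test = rng.normal(size=8)
        y_pred = y_test + rng.normal(size=8) * 0.3
        mean = 0.2
        r2, sep = external_validation(y_pred, y_test, mean)
        press = sum((a - b) ** 2 for a, b in zip(y_test, y_pred))
        sd = sum((v - mean) ** 2 for v in y_test)
        assert r2 == pytest.approx(1 - press / sd, abs=1e-12)
        assert sep == pytest.approx(math.sqrt(press / 8), abs=1e-12)

    def test_degenerate_test_set(self):
        with pytest.raises(PlsError):
            external_validation(np.ones(3), np.full(3, 2.0), 2.0)


class TestProgressiveScrambling:
    def _signal_data(self, seed=7, n=16, p=6):
        r = np.random.default_rng(seed)
        X = r.normal(size=(n, p))
        y = X @ r.normal(size=p) + 0.1 * r.normal(size=n)
        return X, y

    def test_unscrambled_limit_reproduces_loo(self):
        X, y = self._signal_data()
        r2, q2, sdep = scrambling_profile(X, y, 2, bins=range(2, 4),
                                          replicates=2, seed=0)
        q2_ref, sdep_ref = loo_q2(X, y, 2)
        assert r2[0] == 1.0
        assert q2[0] == pytest.approx(q2_ref, abs=1e-8)
        assert sdep[0] == pytest.approx(sdep_ref, abs=1e-8)

    def test_deterministic_given_seed(self):
        X, y = self._signal_data()
        a = progressive_scrambling(X, y, 2, bins=range(2, 5), replicates=3,
                                   seed=42)
        b = progressive_scrambling(X, y, 2, bins=range(2, 5), replicates=3,
                                   seed=42)
        assert a == b

    def test_pure_noise_slope_near_zero(self):
        """Monte-Carlo: with y independent of X the q2-vs-r2yy' profile is
        flat, so the slope statistic stays near zero on average."""
        slopes = []
        for rep in range(10):
            r = np.random.default_rng(900 + rep)
            X = r.normal(size=(14, 5))
            y = r.normal(size=14)
            slopes.append(progressive_scrambling(
                X, y, 2, bins=range(2, 5), replicates=3, seed=rep)[2])
        assert abs(np.mean(slopes)) < 0.3

    def test_too_few_rows(self, rng):
        with pytest.raises(PlsError):
            progressive_scrambling(rng.normal(size=(6, 3)),
                                   rng.normal(size=6), 1)


class TestSplitAndGates:
    def test_split_sizes_and_determinism(self):
        ids = [f"PBB-{i}" for i in range(45)]
        train, test = split_train_test(ids, 35, seed=3)
        assert len(train) == 35 and len(test) == 10
        assert not set(train) & set(test)
        assert (train, test) == split_train_test(ids, 35, seed=3)
        train2, test2 = split_train_test(ids, 44, seed=0)
        assert len(test2) == 1
        with pytest.raises(PlsError):
            split_train_test(ids, 45, seed=0)

    def test_quality_gate_boundaries(self):
        """Flags fire exactly at the acceptance thresholds."""
        good = ValidationReport(q2=0.51, n_components=8, see=0.94, r2=0.91,
                                f=50.0, r2_pred=0.61, sep=0.2,
                                dq2_dr2yy=1.19)
        assert not any(good.quality_flags().values())
        at_threshold = ValidationReport(q2=0.5, n_components=8, see=0.95,
                                        r2=0.9, f=50.0, r2_pred=0.6, sep=0.2,
                                        dq2_dr2yy=1.2)
        assert all(at_threshold.quality_flags().values())
        partial = ValidationReport(q2=0.76, n_components=8, see=0.06,
                                   r2=0.95, f=67.79, r2_pred=0.65, sep=0.19,
                                   dq2_dr2yy=1.17)
        assert not any(partial.quality_flags().values())
        missing = ValidationReport(q2=0.4, n_components=2, see=0.1, r2=0.99,
                                   f=10.0)
        flags = missing.quality_flags()
        assert flags["q2"] and not flags["r2"]
        assert "r2_pred" not in flags  # not computed, not judged
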