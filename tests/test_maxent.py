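"""Penalized maximum-entropy model: features, solver oracles, selection, evaluation."""

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize_scalar
from scipy.special import logsumexp

from batwind import maxent as M

from conftest import make_raster


def _toy_design(rng, n=60, J=3):
    return rng.random((n, J))


def _manual_fit(lam, specs=None, log_Z=0.0, H=0.0, m=10, B=10):
    lam = np.asarray(lam, float)
    return M.MaxentFit(
        lam=lam, feature_specs=specs or [], schema=M.RegularizationSchema(),
        betas=np.zeros_like(lam), log_Z=log_Z, H=H, m=m, B=B,
        objective=0.0, converged=True, kkt_residual=0.0)


class TestFeatures:
    def test_lqp_combinatorics_two_continuous(self, rng):
        vals = {"a": rng.random(30), "b": rng.random(30)}
        X, specs = M.build_features(vals, {"a": "continuous", "b": "continuous"})
        kinds = [s.kind for s in specs]
        assert kinds.count("linear") == 2
        assert kinds.count("quadratic") == 2
        assert kinds.count("product") == 1
        assert X.shape == (30, 5)

    def test_scaling_and_clamping(self, rng):
        train = {"a": np.array([2.0, 4.0, 6.0])}
        _, specs = M.build_features(train, {"a": "continuous"},
                                    feature_kinds=("linear",))
        X_eval = M.design_from_specs({"a": np.array([1.0, 2.0, 4.0, 6.0, 9.0])},
                                     specs)
        np.testing.assert_allclose(X_eval[:, 0], [0.0, 0.0, 0.5, 1.0, 1.0])

    def test_categorical_indicators_partition(self, rng):
        vals = {"lc": rng.integers(1, 5, 50)}
        X, specs = M.build_features(vals, {"lc": "categorical"})
        assert len(specs) == len(np.unique(vals["lc"]))
        np.testing.assert_allclose(X.sum(axis=1), 1.0)

    def test_zero_variance_variable_dropped(self):
        vals = {"flat": np.full(20, 3.0), "ok": np.arange(20.0)}
        with pytest.warns(UserWarning, match="zero-variance"):
            _, specs = M.build_features(vals, {"flat": "continuous",
                                               "ok": "continuous"})
        assert all("flat" not in s.variables for s in specs)


class TestBackground:
    def test_exactly_b_valid_cells_returns_all(self, grid_small, rng):
        env = {"v": make_raster(grid_small, rng.random(grid_small.shape))}
        bg = M.sample_background(env, B=100, seed=0)
        assert len(bg) == 100

    def test_seeded_and_subsampled(self, grid_small, rng):
        env = {"v": make_raster(grid_small, rng.random(grid_small.shape))}
        a = M.sample_background(env, B=40, seed=7)
        b = M.sample_background(env, B=40, seed=7)
        assert a.equals(b) and len(a) == 40

    def test_no_valid_cells_is_error(self, grid_small):
        env = {"v": make_raster(grid_small, np.full(grid_small.shape, -9999.0))}
        with pytest.raises(ValueError):
            M.sample_background(env, B=10, seed=0)


class TestFit:
    def test_no_signal_large_rm_gives_null_model(self, rng):
        Xb = _toy_design(rng, 200, 2)
        Xp = Xb[rng.choice(200, 50, replace=False)]
        specs = [M.FeatureSpec("linear", ("a",), (0,), (1,)),
                 M.FeatureSpec("linear", ("b",), (0,), (1,))]
        f = M.fit(Xp, Xb, specs, M.RegularizationSchema(rm=50.0))
        assert np.all(f.lam == 0.0)
        raw = M.raw_at(f, Xb)
        np.testing.assert_allclose(raw, 1.0 / 200, atol=1e-12)

    def test_single_binary_feature_matches_golden_section_oracle(self):
        """All presences f=1, half the background f=1, beta=0.05: the fitted
        coefficient must match 1-D golden-section maximization of the gain."""
        B = 200
        Xb = np.zeros((B, 1))
        Xb[: B // 2, 0] = 1.0
        Xp = np.ones((40, 1))
        specs = [M.FeatureSpec("linear", ("f",), (0,), (1,))]
        beta = 0.05

        def neg_gain(lam):
            return -(lam - logsumexp(Xb[:, 0] * lam) + np.log(B)
                     - beta * abs(lam))

        oracle = minimize_scalar(neg_gain, bracket=(0.0, 5.0), method="golden")
        f = M.fit(Xp, Xb, specs, betas=np.array([beta]))
        assert f.converged
        assert f.lam[0] == pytest.approx(oracle.x, abs=1e-3)

    def test_kkt_contract_on_random_data(self, rng):
        Xb = _toy_design(rng, 300, 4)
        Xp = _toy_design(rng, 60, 4) ** 2  # presences shifted low
        specs = [M.FeatureSpec("linear", (f"v{j}",), (0,), (1,))
                 for j in range(4)]
        f = M.fit(Xp, Xb, specs, M.RegularizationSchema(rm=1.0), tol=1e-6)
        assert f.converged and f.kkt_residual <= 1e-6

    def test_grid_search_oracle_two_features(self, rng):
        """Iterated dense grid search over (λ1, λ2) agrees with the solver."""
        Xb = _toy_design(rng, 80, 2)
        Xp = np.clip(_toy_design(rng, 25, 2) + 0.3, 0, 1)
        specs = [M.FeatureSpec("linear", ("a",), (0,), (1,)),
                 M.FeatureSpec("linear", ("b",), (0,), (1,))]
        schema = M.RegularizationSchema(rm=1.0)
        betas = schema.betas(specs, Xp)
        pmean = Xp.mean(axis=0)

        def gain(l1, l2):
            lam = np.array([l1, l2])
            return (pmean @ lam - logsumexp(Xb @ lam) + np.log(len(Xb))
                    - betas @ np.abs(lam))

        lo, hi = np.array([-4.0, -4.0]), np.array([4.0, 4.0])
        best = np.zeros(2)
        for _ in range(6):  # coarse-to-fine refinement keeps it brute-force
            g1 = np.linspace(lo[0], hi[0], 41)
            g2 = np.linspace(lo[1], hi[1], 41)
            vals = np.array([[gain(a, b) for b in g2] for a in g1])
            i, j = np.unravel_index(vals.argmax(), vals.shape)
            best = np.array([g1[i], g2[j]])
            span = (hi - lo) / 8
            lo, hi = best - span, best + span

        f = M.fit(Xp, Xb, specs, schema)
        np.testing.assert_allclose(f.lam, best, atol=1e-3)

    def test_nonconvergence_warns_and_flags(self, rng):
        Xb = _toy_design(rng, 100, 3)
        Xp = np.clip(_toy_design(rng, 30, 3) + 0.4, 0, 1)
        specs = [M.FeatureSpec("linear", (f"v{j}",), (0,), (1,)) for j in range(3)]
        with pytest.warns(UserWarning, match="did not converge"):
            f = M.fit(Xp, Xb, specs, M.RegularizationSchema(rm=0.1), max_iter=1)
        assert not f.converged

    def test_unpenalized_gain_nonincreasing_along_rm_path(self, rng):
        Xb = _toy_design(rng, 150, 3)
        Xp = np.clip(_toy_design(rng, 40, 3) + 0.25, 0, 1)
        specs = [M.FeatureSpec("linear", (f"v{j}",), (0,), (1,)) for j in range(3)]
        pmean = Xp.mean(axis=0)
        gains = []
        for rm in (0.5, 1.0, 2.0, 4.0):
            f = M.fit(Xp, Xb, specs, M.RegularizationSchema(rm=rm))
            gains.append(pmean @ f.lam - (logsumexp(Xb @ f.lam) - np.log(len(Xb))))
        assert all(g1 >= g2 - 1e-9 for g1, g2 in zip(gains, gains[1:]))


class TestOutputScales:
    def test_null_model_logistic_half(self, rng):
        Xb = _toy_design(rng, 120, 2)
        Xp = Xb[:30]
        specs = [M.FeatureSpec("linear", ("a",), (0,), (1,)),
                 M.FeatureSpec("linear", ("b",), (0,), (1,))]
        f = M.fit(Xp, Xb, specs, M.RegularizationSchema(rm=30.0))
        assert np.all(f.lam == 0.0)
        np.testing.assert_allclose(M.logistic_at(f, Xb), 0.5, atol=1e-12)

    def test_raw_sums_to_one_over_background(self, rng):
        Xb = _toy_design(rng, 150, 3)
        Xp = np.clip(_toy_design(rng, 30, 3) + 0.3, 0, 1)
        specs = [M.FeatureSpec("linear", (f"v{j}",), (0,), (1,)) for j in range(3)]
        f = M.fit(Xp, Xb, specs)
        assert M.raw_at(f, Xb).sum() == pytest.approx(1.0, abs=1e-9)

    def test_three_cell_toy_hand_computed(self):
        """Scalar-arithmetic oracle for raw/logistic on a 3-cell background."""
        lam = 0.7
        fvals = np.array([0.2, 0.5, 0.9])
        Z = np.exp(lam * fvals).sum()
        raw = np.exp(lam * fvals) / Z
        H = -(raw * np.log(raw)).sum()
        expected = raw * np.exp(H) / (1 + raw * np.exp(H))
        fit_ = _manual_fit([lam], log_Z=np.log(Z), H=H, B=3)
        got = M.logistic_at(fit_, fvals[:, None])
        np.testing.assert_allclose(got, expected, atol=1e-12)

    def test_logistic_monotone_in_score(self):
        fit_ = _manual_fit([1.0], log_Z=0.0, H=0.3)
        scores = np.linspace(-3, 3, 50)[:, None]
        out = M.logistic_at(fit_, scores)
        assert np.all(np.diff(out) > 0) and np.all((out > 0) & (out < 1))


class TestAICc:
    def test_direct_formula_evaluation(self):
        # engineered so lnL = -20 with k=2, m=10: AICc = 4 + 40 + 12/7
        fit_ = _manual_fit([1.0, 1.0])
        Xp = np.zeros((10, 2))
        ext = np.ones((1, 2))
        got = M.aicc(fit_, Xp, ext)
        assert got == pytest.approx(4 + 40 + 12 / 7, abs=1e-9)

    def test_k_equals_m_minus_one_undefined(self):
        fit_ = _manual_fit([1.0, 1.0, 1.0])  # k=3, m=4 -> undefined
        assert np.isnan(M.aicc(fit_, np.zeros((4, 3)), np.ones((1, 3))))

    def test_k_zero_undefined(self):
        fit_ = _manual_fit([0.0, 0.0])
        assert np.isnan(M.aicc(fit_, np.zeros((10, 2)), np.ones((1, 2))))

    def test_monotone_in_k_at_fixed_likelihood(self):
        # appending an all-zero design column leaves lnL unchanged, raises k
        vals = []
        for k in (1, 2, 3):
            lam = np.concatenate([np.ones(1), 1e-6 * np.ones(k - 1)])
            Xp = np.zeros((10, k))
            ext = np.concatenate([np.ones(1), np.zeros(k - 1)])[None, :]
            vals.append(M.aicc(_manual_fit(lam), Xp, ext))
        assert vals[0] < vals[1] < vals[2]


class TestSelectRM:
    def test_default_grid_is_ten_half_steps(self):
        assert len(M.DEFAULT_RM_GRID) == 10
        assert M.DEFAULT_RM_GRID[0] == 0.5 and M.DEFAULT_RM_GRID[-1] == 5.0

    def test_returns_argmin_of_table(self, rng):
        Xb = _toy_design(rng, 150, 3)
        Xp = np.clip(_toy_design(rng, 30, 3) + 0.3, 0, 1)
        specs = [M.FeatureSpec("linear", (f"v{j}",), (0,), (1,)) for j in range(3)]
        best_rm, table, best_fit = M.select_rm(Xp, Xb, specs,
                                               candidates=(0.5, 1.0, 2.0))
        defined = table[np.isfinite(table["aicc"])]
        assert best_rm == defined.loc[defined["aicc"].idxmin(), "rm"]
        assert best_fit.schema.rm == best_rm

    def test_sparse_fit_with_cheap_likelihood_prefers_large_rm(self):
        """One strong feature plus uninformative ones: the larger multiplier
        drops the noise coefficients at almost no likelihood cost, so AICc
        picks the sparsest (largest-rm) candidate."""
        rng = np.random.default_rng(1)
        B, m = 400, 30
        Xb = rng.random((B, 4))
        Xp = np.column_stack([rng.uniform(0.5, 1.0, m), rng.random((m, 3))])
        specs = [M.FeatureSpec("linear", (f"v{j}",), (0,), (1,)) for j in range(4)]
        candidates = (0.5, 1.0, 2.0)
        best_rm, table, _ = M.select_rm(Xp, Xb, specs, candidates=candidates)
        defined = table[np.isfinite(table["aicc"])]
        assert best_rm == defined.loc[defined["aicc"].idxmin(), "rm"]
        # sparsity strictly increases along the candidate grid here
        assert table["k"].tolist() == sorted(table["k"], reverse=True)
        assert best_rm == max(defined["rm"])


class TestAUC:
    def test_perfect_separation(self):
        assert M.auc([3, 4, 5], [0, 1, 2]) == 1.0

    def test_identical_multisets_half(self):
        assert M.auc([1, 2, 3], [1, 2, 3]) == 0.5

    def test_matches_all_pairs_enumeration(self, rng):
        p = rng.random(20)
        b = rng.random(20)
        b[:5] = p[:5]  # force ties
        wins = sum(1.0 if x > y else 0.5 if x == y else 0.0
                   for x in p for y in b)
        assert M.auc(p, b) == pytest.approx(wins / (20 * 20), abs=1e-12)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            M.auc([], [1.0])


class TestCrossValidation:
    def _separable(self, rng, m=40, B=200):
        # strongly separated but with overlapping supports, so the penalized
        # gain stays bounded and the solver converges
        Xp = np.column_stack([rng.uniform(0.8, 1.0, m)])
        Xb = np.column_stack([np.r_[rng.uniform(0.0, 0.5, B - 12),
                                    rng.uniform(0.85, 1.0, 12)]])
        specs = [M.FeatureSpec("linear", ("v",), (0,), (1,))]
        return Xp, Xb, specs

    def test_separable_scene_high_auc(self, rng):
        Xp, Xb, specs = self._separable(rng)
        report = M.cross_validate(Xp, Xb, specs, k=5, seed=4)
        assert report.mean >= 0.95

    def test_same_seed_same_report(self, rng):
        Xp, Xb, specs = self._separable(rng)
        a = M.cross_validate(Xp, Xb, specs, k=5, seed=9)
        b = M.cross_validate(Xp, Xb, specs, k=5, seed=9)
        assert a == b

    def test_leave_one_out_fold_structure(self, rng):
        Xp, Xb, specs = self._separable(rng, m=8)
        report = M.cross_validate(Xp, Xb, specs, k=8, seed=1)
        assert len(report.fold_aucs) == 8


class TestResponseCurves:
    def test_uninformative_variable_flat_near_half(self, rng):
        pv = {"v": rng.normal(10, 2, 150)}
        bv = {"v": rng.normal(10, 2, 800)}
        curves = M.response_curves(pv, bv, {"v": "continuous"})
        assert np.all(np.abs(curves["v"].logistic - 0.5) < 0.1)

    def test_curves_bounded_and_categorical_per_class(self, rng):
        pv = {"v": rng.normal(12, 2, 100), "lc": rng.integers(1, 5, 100)}
        bv = {"v": rng.normal(10, 2, 500), "lc": rng.integers(1, 5, 500)}
        curves = M.response_curves(pv, bv, {"v": "continuous",
                                            "lc": "categorical"})
        assert np.all((curves["v"].logistic > 0) & (curves["v"].logistic < 1))
        assert curves["lc"].categorical
        assert len(curves["lc"].values) == 4


class TestContribution:
    def test_single_variable_gets_everything(self, rng):
        Xb = np.column_stack([np.r_[np.ones(100), np.zeros(100)]])
        Xp = np.ones((30, 1))
        specs = [M.FeatureSpec("linear", ("only",), (0,), (1,))]
        f = M.fit(Xp, Xb, specs)
        report = M.variable_contribution(f, Xp, Xb, seed=0)
        assert report.percentages["only"] == pytest.approx(100.0, abs=1e-9)

    def test_percentages_sum_to_hundred(self, rng):
        Xb = _toy_design(rng, 200, 3)
        Xp = np.clip(_toy_design(rng, 50, 3) + 0.3, 0, 1)
        specs = [M.FeatureSpec("linear", (f"v{j}",), (0,), (1,)) for j in range(3)]
        f = M.fit(Xp, Xb, specs)
        report = M.variable_contribution(f, Xp, Xb, seed=1)
        assert sum(report.percentages.values()) == pytest.approx(100.0, abs=1e-9)

    def test_pure_noise_variable_contributes_little(self, rng):
        m, B = 60, 400
        signal_p = rng.uniform(0.7, 1.0, m)
        signal_b = np.r_[rng.uniform(0.0, 0.6, B - 25), rng.uniform(0.7, 1.0, 25)]
        noise_p = rng.random(m)
        noise_b = rng.random(B)
        specs = [M.FeatureSpec("linear", ("signal",), (0,), (1,)),
                 M.FeatureSpec("linear", ("noise",), (0,), (1,))]
        f = M.fit(np.column_stack([signal_p, noise_p]),
                  np.column_stack([signal_b, noise_b]), specs)
        report = M.variable_contribution(
            f, np.column_stack([signal_p, noise_p]),
            np.column_stack([signal_b, noise_b]), seed=2)
        assert report.percentages["noise"] < 5.0


class TestCollinearity:
    def test_layer_with_itself_flagged(self, rng):
        v = rng.random(100)
        report = M.collinearity_screen(pd.DataFrame({"a": v, "a_copy": v}))
        assert report.flagged and report.flagged[0][2] == pytest.approx(1.0)

    def test_five_point_toy_matches_formula_oracle(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        y = np.array([4.0, 1.0, 5.0, 0.0, 2.0])
        # independent Pearson computation from the covariance formula
        r_manual = (((x - x.mean()) * (y - y.mean())).sum()
                    / np.sqrt(((x - x.mean()) ** 2).sum()
                              * ((y - y.mean()) ** 2).sum()))
        report = M.collinearity_screen(pd.DataFrame({"x": x, "y": y}))
        assert report.correlations.loc["x", "y"] == pytest.approx(r_manual,
                                                                  abs=1e-12)

    def test_independent_noise_uncorrelated(self, rng):
        frame = pd.DataFrame(rng.random((10_000, 3)), columns=list("abc"))
        report = M.collinearity_screen(frame)
        off = report.correlations.to_numpy()[~np.eye(3, dtype=bool)]
        assert np.all(np.abs(off) < 0.05)
        assert report.flagged == []

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            M.collinearity_screen(pd.DataFrame({"a": [1.0, 2.0]}))


class TestSerialization:
    def test_round_trip(self, rng, tmp_path):
        Xb = _toy_design(rng, 100, 2)
        Xp = np.clip(_toy_design(rng, 20, 2) + 0.3, 0, 1)
        specs = [M.FeatureSpec("linear", ("a",), (0.0,), (1.0,)),
                 M.FeatureSpec("quadratic", ("b",), (0.0,), (1.0,))]
        f = M.fit(Xp, Xb, specs)
        M.save_fit(f, tmp_path / "fit.json")
        g = M.load_fit(tmp_path / "fit.json")
        np.testing.assert_array_equal(f.lam, g.lam)
        assert g.feature_specs == f.feature_specs
        assert g.log_Z == f.log_Z and g.H == f.H
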