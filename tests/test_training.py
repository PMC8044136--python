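import numpy as np
import pandas as pd
import pytest

from ckdphen.astage_training import (
    PairedDataset,
    build_pairs,
    cross_validate,
    fit_ordinal,
    ordinal_nll,
    predict_stages,
)
from ckdphen.synthetic import simulate_ordinal_responses

BASE = pd.Timestamp("2015-01-01")


def _d(day):
    return BASE + pd.Timedelta(days=day)


def _labs(rows):
    return pd.DataFrame(rows, columns=["patient_id", "date", "concept", "value", "scale"])


class TestBuildPairs:
    def test_same_day_requirement(self):
        labs = _labs(
            [("p", _d(10), "uacr", 150.0, None), ("p", _d(11), "upcr", 400.0, None)]
        )
        assert len(build_pairs(labs, "upcr")) == 0

    def test_gold_label_from_uacr_only(self):
        labs = _labs(
            [("p", _d(10), "uacr", 150.0, None), ("p", _d(10), "upcr", 400.0, None)]
        )
        data = build_pairs(labs, "upcr")
        assert len(data) == 1
        assert data.y[0] == 1  # A2 from the UACR, not A3 from the UPCR
        assert data.X[0, 0] == pytest.approx(np.log(400.0))

    def test_dsp_rows_require_same_day_sg(self):
        rows = [
            ("p", _d(10), "uacr", 150.0, None),
            ("p", _d(10), "dsp", 3.0, "scale1"),
            ("q", _d(20), "uacr", 10.0, None),
            ("q", _d(20), "dsp", 1.0, "scale1"),
            ("q", _d(20), "specific_gravity", 1.020, None),
        ]
        data = build_pairs(_labs(rows), "dsp_scale1")
        assert len(data) == 1
        assert data.X[0, 0] == 1.0
        assert data.X[0, 1] == pytest.approx(20.0)  # SG milliunits

    def test_scales_kept_separate(self):
        rows = [
            ("p", _d(10), "uacr", 150.0, None),
            ("p", _d(10), "dsp", 3.0, "scale2"),
            ("p", _d(10), "specific_gravity", 1.020, None),
        ]
        assert len(build_pairs(_labs(rows), "dsp_scale1")) == 0
        assert len(build_pairs(_labs(rows), "dsp_scale2")) == 1


def _grid_search_mle(X, y, theta1_grid, theta2_grid, beta_grid):
    """Independent dense grid-search MLE (oracle)."""
    best = (np.inf, None)
    for t1 in theta1_grid:
        for t2 in theta2_grid:
            if t2 <= t1:
                continue
            for b in beta_grid:
                # evaluate the raw likelihood directly, not via the package's
                # reparameterized objective
                eta = X[:, 0] * b
                c1 = 1.0 / (1.0 + np.exp(-(t1 - eta)))
                c2 = 1.0 / (1.0 + np.exp(-(t2 - eta)))
                p = np.where(y == 0, c1, np.where(y == 1, c2 - c1, 1.0 - c2))
                nll = -np.sum(np.log(np.maximum(p, 1e-300)))
                if nll < best[0]:
                    best = (nll, (t1, t2, b))
    return best


class TestFitOrdinal:
    def _tiny_data(self, n=30, seed=42):
        rng = np.random.default_rng(seed)
        X = rng.uniform(0, 6, n)[:, None]
        y = simulate_ordinal_responses((1.5, 3.5), 1.0, X, seed + 1)
        return PairedDataset("upcr", X, y)

    def test_matches_grid_search_oracle(self):
        data = self._tiny_data()
        model = fit_ordinal(data)
        # two-stage refinement around the coarse optimum
        nll_grid, (t1, t2, b) = _grid_search_mle(
            data.X, data.y, np.linspace(-2, 6, 65), np.linspace(-1, 8, 73),
            np.linspace(0, 3, 61),
        )
        step = 0.15
        nll_grid, params = _grid_search_mle(
            data.X, data.y, np.linspace(t1 - step, t1 + step, 31),
            np.linspace(t2 - step, t2 + step, 31), np.linspace(b - step, b + step, 31),
        )
        assert model.metadata["log_likelihood"] == pytest.approx(-nll_grid, abs=1e-3)
        assert -model.metadata["log_likelihood"] <= nll_grid + 1e-9  # MLE at least as good
        assert model.thetas[0] == pytest.approx(params[0], abs=0.02)
        assert model.thetas[1] == pytest.approx(params[1], abs=0.02)
        assert model.betas[0] == pytest.approx(params[2], abs=0.02)

    def test_matches_statsmodels_ordered_model(self):
        from statsmodels.miscmodels.ordinal_model import OrderedModel

        data = self._tiny_data(n=200, seed=3)
        model = fit_ordinal(data)
        sm_fit = OrderedModel(data.y, data.X, distr="logit").fit(disp=False)
        # statsmodels maximizes the same likelihood
        assert model.metadata["log_likelihood"] == pytest.approx(
            sm_fit.llf, abs=1e-4
        )
        assert model.betas[0] == pytest.approx(float(sm_fit.params[0]), abs=1e-3)

    def test_parameter_recovery_at_n5000(self):
        rng = np.random.default_rng(12)
        X = rng.uniform(0, 8, 5000)[:, None]
        y = simulate_ordinal_responses((2.0, 5.5), 1.0, X, 13)
        model = fit_ordinal(PairedDataset("upcr", X, y))
        assert model.thetas[0] == pytest.approx(2.0, rel=0.1)
        assert model.thetas[1] == pytest.approx(5.5, rel=0.1)
        assert model.betas[0] == pytest.approx(1.0, rel=0.1)

    def test_label_reversal_symmetry(self):
        data = self._tiny_data(n=200, seed=8)
        fwd = fit_ordinal(data)
        rev = fit_ordinal(PairedDataset("upcr", -data.X, 2 - data.y))
        assert rev.thetas[0] == pytest.approx(-fwd.thetas[1], abs=1e-4)
        assert rev.thetas[1] == pytest.approx(-fwd.thetas[0], abs=1e-4)
        assert rev.betas[0] == pytest.approx(fwd.betas[0], abs=1e-4)

    def test_duplication_leaves_parameters_doubles_loglik(self):
        data = self._tiny_data(n=100, seed=5)
        single = fit_ordinal(data)
        doubled = fit_ordinal(
            PairedDataset("upcr", np.vstack([data.X, data.X]), np.tile(data.y, 2))
        )
        assert doubled.thetas[0] == pytest.approx(single.thetas[0], abs=1e-4)
        assert doubled.betas[0] == pytest.approx(single.betas[0], abs=1e-4)
        assert doubled.metadata["log_likelihood"] == pytest.approx(
            2 * single.metadata["log_likelihood"], rel=1e-5
        )

    def test_analytic_gradient_matches_finite_differences(self):
        data = self._tiny_data(n=50, seed=9)
        p0 = np.array([0.7, 1.2, -0.3])
        _, grad = ordinal_nll(p0, data.X, data.y)
        eps = 1e-6
        for i in range(3):
            dp = np.zeros(3)
            dp[i] = eps
            f_plus, _ = ordinal_nll(p0 + dp, data.X, data.y)
            f_minus, _ = ordinal_nll(p0 - dp, data.X, data.y)
            assert grad[i] == pytest.approx((f_plus - f_minus) / (2 * eps), rel=1e-4)

    def test_complete_separation_flagged(self):
        X = np.concatenate([np.zeros(10), np.ones(10), 2 * np.ones(10)])[:, None]
        y = np.concatenate([np.zeros(10), np.ones(10), 2 * np.ones(10)]).astype(int)
        model = fit_ordinal(PairedDataset("upcr", X, y), maxiter=100)
        assert model.metadata["converged"] is False

    def test_fewer_than_two_stages_rejected(self):
        with pytest.raises(ValueError, match="two distinct stages"):
            fit_ordinal(PairedDataset("upcr", np.ones((5, 1)), np.zeros(5, int)))

    def test_irrelevant_feature_barely_changes_predictions(self):
        rng = np.random.default_rng(17)
        x = rng.uniform(0, 8, 5000)
        noise = rng.normal(size=5000)
        y = simulate_ordinal_responses((2.0, 5.5), 1.0, x[:, None], 18)
        base = fit_ordinal(PairedDataset("upcr", x[:, None], y))
        extended = fit_ordinal(
            PairedDataset("upcr", np.column_stack([x, noise]), y)
        )
        grid = np.linspace(0, 8, 400)
        p_base = predict_stages(base, grid[:, None])
        p_ext = predict_stages(extended, np.column_stack([grid, np.zeros(400)]))
        assert np.mean(p_base != p_ext) < 0.02


class TestCrossValidate:
    def _data(self, n=400, seed=2):
        rng = np.random.default_rng(seed)
        X = rng.uniform(0, 8, n)[:, None]
        y = simulate_ordinal_responses((2.0, 5.5), 1.0, X, seed + 100)
        return PairedDataset("upcr", X, y)

    def test_folds_partition_disjoint_and_balanced(self):
        data = self._data(n=403)
        rep = cross_validate(data, k=10, seed=7)
        sizes = np.bincount(rep.fold_assignments, minlength=10)
        assert sizes.sum() == 403
        assert sizes.max() - sizes.min() <= 1

    def test_same_seed_same_report(self):
        data = self._data()
        r1 = cross_validate(data, k=10, seed=7)
        r2 = cross_validate(data, k=10, seed=7)
        assert np.array_equal(r1.fold_assignments, r2.fold_assignments)
        assert r1.error_rate.fold_values == r2.error_rate.fold_values

    def test_different_seed_different_partition(self):
        data = self._data()
        r1 = cross_validate(data, k=10, seed=7)
        r2 = cross_validate(data, k=10, seed=8)
        assert not np.array_equal(r1.fold_assignments, r2.fold_assignments)

    def test_truth_oracle_gives_perfect_metrics_with_zero_width_cis(self):
        data = self._data()
        rep = cross_validate(
            data, k=10, seed=1, predict_fn=lambda Xtr, ytr, Xte, yte: yte
        )
        assert rep.error_rate.mean == 0.0
        assert rep.error_rate.halfwidth == 0.0
        for stage in ("A1", "A2", "A3"):
            acc = rep.per_stage[stage]["accuracy"]
            assert acc.mean == 1.0 and acc.halfwidth == 0.0

    def test_interval_arithmetic_on_known_fold_errors(self):
        # fold error rates {0.0, 0.2} x 5: mean 0.1, sd of the 10 values
        y = np.arange(100) % 3
        X = y[:, None].astype(float)
        data = PairedDataset("upcr", X, y)
        flips = {f: (f % 2 == 1) for f in range(10)}
        assignment = {}

        def predictor(Xtr, ytr, Xte, yte):
            fold = predictor.calls
            predictor.calls += 1
            pred = yte.copy()
            if flips[fold]:
                n_wrong = len(yte) // 5
                pred[:n_wrong] = (pred[:n_wrong] + 1) % 3
            return pred

        predictor.calls = 0
        # seed 1 puts all three stages in every size-10 fold
        rep = cross_validate(data, k=10, seed=1, predict_fn=predictor)
        values = np.asarray(rep.error_rate.fold_values)
        expected_hw = 1.96 * np.std(values, ddof=1) / np.sqrt(10)
        assert rep.error_rate.mean == pytest.approx(np.mean(values))
        assert rep.error_rate.halfwidth == pytest.approx(expected_hw)
        assert sorted(set(np.round(values, 10))) == [0.0, 0.2]

    def test_stratified_folds_cover_all_stages(self):
        data = self._data(n=200, seed=4)
        rep = cross_validate(data, k=10, seed=4, stratified=True)
        for fold in range(10):
            fold_y = data.y[rep.fold_assignments == fold]
            assert set(fold_y) == {0, 1, 2}

    def test_missing_stage_in_fold_warns_and_excludes(self):
        y = np.array([0] * 50 + [2] * 5)  # A2 never present
        X = y[:, None].astype(float)
        data = PairedDataset("upcr", X, y)
        with pytest.warns(UserWarning, match="sensitivity undefined"):
            rep = cross_validate(
                data, k=5, seed=0, predict_fn=lambda Xtr, ytr, Xte, yte: yte
            )
        assert np.isnan(rep.per_stage["A2"]["sensitivity"].fold_values).all()

    def test_n_below_k_rejected(self):
        with pytest.raises(ValueError, match="at least"):
            cross_validate(self._data(n=5), k=10, seed=0)
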