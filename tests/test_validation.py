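"""Bounds, metrics, CV/RUB schemes, permutation harness, sweeps."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from sulcalml import (
    ConcentrationBoundSpec,
    ConfusionMatrix,
    LinearSeparator,
    PacBayesSpec,
    SimulationConfig,
    balanced_permutation_harness,
    balanced_subsample,
    compute_metrics,
    concentration_bound,
    confusion_from_predictions,
    pac_bayes_bound,
    rub_validate,
    simulate_table,
    stratified_kfold_validate,
    sweep_components,
    sweep_sample_size,
)
from sulcalml.validation import default_lambda_grid


class TestConcentrationBound:
    def test_d1_reduces_to_hoeffding(self):
        for n in (20, 112, 200, 1000):
            hoeffding = math.sqrt(math.log(2 / 0.05) / (2 * n))
            assert concentration_bound(n=n, d=1) == pytest.approx(hoeffding, abs=1e-12)

    def test_log_space_equals_exact_integers(self):
        for n in (10, 50, 112, 500):
            for d in (1, 2, min(9, n // 2), min(20, n // 2)):
                a = concentration_bound(n=n, d=d, exact=False)
                b = concentration_bound(n=n, d=d, exact=True)
                assert a == pytest.approx(b, abs=1e-12)

    def test_strictly_increasing_in_d(self):
        vals = [concentration_bound(n=112, d=d) for d in range(1, 21)]
        assert all(a < b for a, b in zip(vals, vals[1:]))

    def test_decreasing_in_n(self):
        for d in (1, 4, 9):
            vals = [concentration_bound(n=n, d=d) for n in (20, 30, 40, 64, 88, 112)]
            assert all(a > b for a, b in zip(vals, vals[1:]))

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            ConcentrationBoundSpec(n=10, d=11)
        with pytest.raises(ValueError):
            ConcentrationBoundSpec(n=10, d=0)
        with pytest.raises(ValueError):
            ConcentrationBoundSpec(n=1, d=1)
        with pytest.raises(ValueError):
            ConcentrationBoundSpec(n=10, d=2, eta=0.0)


class TestPacBayesBound:
    def test_matches_brute_force_grid_oracle(self):
        spec = PacBayesSpec(n=112, L_hat=0.3, theta_norm_sq=4.0, alpha=0.5,
                            lambda_grid=default_lambda_grid(20))
        lam = spec.lambda_grid
        k = len(lam)
        terms = [
            (1 / (1 - 1 / (2 * li))) * spec.L_hat
            + (1 / (1 - 1 / (2 * li)))
            * (li * spec.L_max / spec.n)
            * (((1 - spec.alpha) / 2) * spec.theta_norm_sq + math.log(k / spec.eta))
            for li in lam
        ]
        assert pac_bayes_bound(spec) == pytest.approx(min(terms), abs=1e-10)

    def test_alpha_one_eliminates_parameter_norm(self):
        a = pac_bayes_bound(PacBayesSpec(n=50, L_hat=0.2, theta_norm_sq=100.0, alpha=1.0))
        b = pac_bayes_bound(PacBayesSpec(n=50, L_hat=0.2, theta_norm_sq=0.0, alpha=1.0))
        assert a == pytest.approx(b, abs=1e-12)
        lam = default_lambda_grid(20)
        k = len(lam)
        closed = np.min(
            (1 / (1 - 1 / (2 * lam))) * (0.2 + lam * math.log(k / 0.05) / 50)
        )
        assert a == pytest.approx(float(closed), abs=1e-12)

    def test_zero_loss_zero_norm_still_positive(self):
        assert pac_bayes_bound(PacBayesSpec(n=100, L_hat=0.0, theta_norm_sq=0.0)) > 0

    @given(
        n=st.integers(10, 500),
        L=st.floats(0.0, 1.0),
        t2=st.floats(0.0, 50.0),
        a=st.floats(0.0, 1.0),
    )
    @settings(max_examples=50, deadline=None)
    def test_never_below_empirical_loss(self, n, L, t2, a):
        mu = pac_bayes_bound(PacBayesSpec(n=n, L_hat=L, theta_norm_sq=t2, alpha=a))
        assert mu >= L

    def test_monotone_decreasing_in_alpha(self):
        vals = [
            pac_bayes_bound(PacBayesSpec(n=112, L_hat=0.3, theta_norm_sq=8.0, alpha=a))
            for a in (0.0, 0.25, 0.5, 0.75, 0.95)
        ]
        assert all(x >= y for x, y in zip(vals, vals[1:]))

    def test_bad_lambda_grid(self):
        with pytest.raises(ValueError):
            PacBayesSpec(n=10, L_hat=0.1, theta_norm_sq=1.0,
                         lambda_grid=np.array([0.4, 1.0]))
        with pytest.raises(ValueError):
            PacBayesSpec(n=10, L_hat=0.1, theta_norm_sq=1.0,
                         lambda_grid=np.array([]))


class TestMetrics:
    def test_perfect_classifier(self):
        cm = ConfusionMatrix(TP=5, TN=5, FP=0, FN=0)
        m = compute_metrics(cm, np.array([1, 1, 1, 1, 1, -1, -1, -1, -1, -1.0]),
                            np.array([1] * 5 + [0] * 5))
        assert m.sensitivity == m.specificity == m.balanced_accuracy == m.auc == 1.0

    def test_direct_arithmetic(self):
        cm = ConfusionMatrix(TP=40, FN=18, TN=40, FP=16)
        m = compute_metrics(cm)
        assert m.sensitivity == pytest.approx(0.6897, abs=1e-4)
        assert m.specificity == pytest.approx(0.7143, abs=1e-4)
        assert m.balanced_accuracy == pytest.approx(0.7020, abs=1e-4)

    def test_constant_decision_values_auc_half(self):
        cm = ConfusionMatrix(TP=2, TN=2, FP=1, FN=1)
        m = compute_metrics(cm, np.zeros(6), np.array([1, 1, 1, 0, 0, 0]))
        assert m.auc == 0.5

    def test_single_class_error(self):
        with pytest.raises(ValueError):
            compute_metrics(ConfusionMatrix(TP=3, FN=1, TN=0, FP=0))

    def test_balanced_accuracy_equals_accuracy_when_balanced(self, rng):
        y = np.repeat([0, 1], 25)
        pred = rng.integers(0, 2, 50)
        cm = confusion_from_predictions(y, pred)
        assert compute_metrics(cm).balanced_accuracy == pytest.approx(
            (pred == y).mean()
        )

    @given(st.integers(0, 10_000))
    @settings(max_examples=25, deadline=None)
    def test_auc_invariant_under_monotone_transform(self, seed):
        rng = np.random.default_rng(seed)
        y = rng.integers(0, 2, 30)
        if len(np.unique(y)) < 2:
            y[0] = 1 - y[0]
        dv = rng.normal(size=30)
        cm = confusion_from_predictions(y, (dv > 0).astype(int))
        a1 = compute_metrics(cm, dv, y).auc
        a2 = compute_metrics(cm, np.exp(dv), y).auc
        assert a1 == pytest.approx(a2, abs=1e-12)


class TestRub:
    def test_correction_is_subtraction(self, rng):
        X = np.vstack([rng.normal(-2, 0.3, (20, 2)), rng.normal(2, 0.3, (20, 2))])
        y = np.repeat([0, 1], 20)
        rep = rub_validate(X, y, LinearSeparator, 0.2675)
        emp = rep.train_metrics[0]
        assert emp.balanced_accuracy == 1.0
        assert rep.corrected.balanced_accuracy == pytest.approx(1.0 - 0.2675)
        assert rep.corrected.sensitivity == pytest.approx(emp.sensitivity - 0.2675)

    def test_no_flooring_below_chance(self, rng):
        X = rng.normal(size=(40, 2))
        y = np.repeat([0, 1], 20)
        rep = rub_validate(X, y, LinearSeparator,
                           ConcentrationBoundSpec(n=40, d=2))
        assert rep.corrected.balanced_accuracy == pytest.approx(
            rep.train_metrics[0].balanced_accuracy - rep.bound_value
        )
        # the bound at n=40 is large; sub-chance corrected values survive as-is
        assert rep.bound_value > 0.3

    def test_corrected_accuracy_approaches_one_for_large_n(self, rng):
        X = np.vstack([rng.normal(-3, 0.3, (500, 1)), rng.normal(3, 0.3, (500, 1))])
        y = np.repeat([0, 1], 500)
        rep = rub_validate(X, y, LinearSeparator,
                           ConcentrationBoundSpec(n=1000, d=1))
        assert rep.corrected.balanced_accuracy > 0.95

    def test_pac_bayes_spec_filled_from_model(self, rng):
        X = np.vstack([rng.normal(-2, 0.3, (30, 2)), rng.normal(2, 0.3, (30, 2))])
        y = np.repeat([0, 1], 30)
        rep = rub_validate(
            X, y, LinearSeparator,
            PacBayesSpec(n=60, L_hat=0.0, theta_norm_sq=0.0, alpha=0.5),
        )
        assert rep.bound_value > 0
        assert rep.corrected.balanced_accuracy == pytest.approx(
            1.0 - rep.bound_value
        )


class TestStratifiedKfold:
    def test_fold_sizes_and_stratification_114(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(114, 3))
        y = np.array([1] * 58 + [0] * 56)
        from sklearn.model_selection import StratifiedKFold

        skf = StratifiedKFold(n_splits=10, shuffle=True, random_state=0)
        seen = np.zeros(114, dtype=int)
        for _, te in skf.split(X, y):
            assert len(te) in (11, 12)
            frac = y[te].sum() / len(te)
            assert abs(y[te].sum() - len(te) * 58 / 114) <= 1
            seen[te] += 1
        assert (seen == 1).all()  # partition: every subject in exactly one fold

    def test_deterministic_given_seed(self, clean_table):
        X, y = clean_table.values[:, :4], clean_table.labels
        r1 = stratified_kfold_validate(X, y, LinearSeparator, k=5, seed=3)
        r2 = stratified_kfold_validate(X, y, LinearSeparator, k=5, seed=3)
        for a, b in zip(r1.test_metrics, r2.test_metrics):
            assert a == b

    def test_separable_data_near_perfect_test_accuracy(self, rng):
        X = np.vstack([rng.normal(-3, 0.3, (30, 2)), rng.normal(3, 0.3, (30, 2))])
        y = np.repeat([0, 1], 30)
        rep = stratified_kfold_validate(X, y, LinearSeparator, k=5, seed=0)
        mean_acc = np.mean([m.balanced_accuracy for m in rep.test_metrics])
        assert mean_acc > 0.95

    def test_class_smaller_than_k_errors(self, rng):
        X = rng.normal(size=(12, 2))
        y = np.array([1] * 3 + [0] * 9)
        with pytest.raises(ValueError):
            stratified_kfold_validate(X, y, LinearSeparator, k=5)


class TestBalancedHarness:
    def test_subsample_is_balanced_and_within_data(self, rng):
        y = np.array([1] * 58 + [0] * 56)
        idx = balanced_subsample(y, rng)
        assert len(idx) == 112
        assert y[idx].sum() == 56
        assert len(np.unique(idx)) == 112

    def test_single_permutation(self, clean_table):
        X, y = clean_table.values[:, :3], clean_table.labels

        def ev(Xs, ys, seed):
            rep = rub_validate(Xs, ys, LinearSeparator,
                               ConcentrationBoundSpec(n=len(ys), d=3))
            return {"rub": rep.corrected}

        out = balanced_permutation_harness(X, y, ev, n_permutations=1, seed=0)
        assert out["rub"]["balanced_accuracy"][1] == 0.0  # SD convention

    def test_label_shuffled_cv_at_chance(self, rng):
        X = rng.normal(size=(60, 3))
        y = np.repeat([0, 1], 30)  # labels independent of X by construction

        def ev(Xs, ys, seed):
            rep = stratified_kfold_validate(Xs, ys, LinearSeparator, k=5,
                                            seed=seed % (2**31))
            accs = [m.balanced_accuracy for m in rep.test_metrics]
            from sulcalml import MetricSet

            return {"cv": MetricSet(float(np.mean(accs)), 0.5, 0.5, 0.5)}

        out = balanced_permutation_harness(X, y, ev, n_permutations=30, seed=1)
        mean, sd = out["cv"]["balanced_accuracy"]
        se = max(sd, 0.05) / np.sqrt(30)
        assert abs(mean - 0.5) < max(3 * se, 0.1)

    def test_mean_stable_across_master_seeds(self, clean_table):
        X, y = clean_table.values[:, :2], clean_table.labels

        def ev(Xs, ys, seed):
            rep = rub_validate(Xs, ys, LinearSeparator,
                               ConcentrationBoundSpec(n=len(ys), d=2))
            return {"rub": rep.train_metrics[0]}

        means = []
        for seed in (1, 2):
            out = balanced_permutation_harness(X, y, ev, n_permutations=60,
                                               seed=seed)
            means.append(out["rub"]["balanced_accuracy"][0])
        assert abs(means[0] - means[1]) < 0.02


class TestSweeps:
    def test_bound_curve_and_rub_decay_over_components(self, clean_table):
        df = sweep_components(clean_table, [1, 4, 12], LinearSeparator, seed=0)
        assert df.bound.is_monotonic_increasing
        # once empirical accuracy plateaus, growth of the bound wins
        assert df.rub_corrected_acc.iloc[1] > df.rub_corrected_acc.iloc[2]

    def test_zero_components_rejected(self, clean_table):
        with pytest.raises(ValueError):
            sweep_components(clean_table, [0], LinearSeparator)

    def test_sample_size_sweep_improves_rub(self):
        def make(n_total, seed):
            cfg = SimulationConfig(
                n_per_class=n_total // 2, n_regions=4,
                heavy_tail_fraction=0.0,
                effect_features=[(0, 1.5), (3, 1.2)], seed=seed,
            )
            from sulcalml import apply_exclusions

            t, _ = apply_exclusions(simulate_table(cfg))
            return t

        df = sweep_sample_size(make, [20, 64, 112], LinearSeparator, d=2,
                               n_draws=3, seed=5)
        assert df.bound.is_monotonic_decreasing
        assert df.rub_corrected_acc.iloc[-1] > df.rub_corrected_acc.iloc[0]

    def test_odd_or_tiny_sizes_rejected(self):
        with pytest.raises(ValueError):
            sweep_sample_size(lambda n, s: None, [2], LinearSeparator)
        with pytest.raises(ValueError):
            sweep_sample_size(lambda n, s: None, [21], LinearSeparator)
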