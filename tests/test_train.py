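"""Stepwise Wilks'-lambda LDA: selection, canonical statistics, Fisher rule, LOO.

Independent oracles used here:
- brute-force Wilks' lambda from explicitly looped scatter sums and np.linalg.det;
- Mahalanobis nearest-centroid classification with prior offsets;
- the canonical-projection midpoint rule;
- scikit-learn's LinearDiscriminantAnalysis predictions;
- exhaustive same-size best-subset search for the stepwise selector;
- closed-form two-class Bayes accuracy Phi(delta / 2 sigma).
"""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import norm
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

from somnoscreen import bank as B
from somnoscreen import train as T
from somnoscreen.features import FEATURE_NAMES

# Published per-age-group discriminant statistics used as identity-check
# inputs: (group, n, eigenvalue, canonical R, Wilks lambda, chi2, df)
DISCRIMINANT_STATS = [
    (1, 37, 0.628, 0.621, 0.614, 16.804, 1),
    (2, 168, 0.502, 0.578, 0.666, 67.111, 2),
    (3, 687, 0.299, 0.480, 0.770, 178.292, 6),
    (4, 786, 0.298, 0.479, 0.770, 204.112, 4),
    (5, 4138, 0.352, 0.510, 0.740, 1246.358, 6),
    (6, 626, 0.299, 0.480, 0.770, 162.944, 3),
    (7, 407, 0.164, 0.376, 0.859, 61.390, 3),
    (8, 149, 0.963, 0.700, 0.509, 98.128, 3),
]


def brute_force_wilks(X, y):
    """det(W)/det(T) from explicitly looped scatter sums."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] == len(y) or X.ndim == 1:
        X = X.reshape(len(y), -1)
    p = X.shape[1]
    mu = X.mean(axis=0)
    T_mat = np.zeros((p, p))
    W_mat = np.zeros((p, p))
    for xi in X:
        T_mat += np.outer(xi - mu, xi - mu)
    for c in np.unique(y):
        Xc = X[np.asarray(y) == c]
        mc = Xc.mean(axis=0)
        for xi in Xc:
            W_mat += np.outer(xi - mc, xi - mc)
    return np.linalg.det(W_mat) / np.linalg.det(T_mat)


def mahalanobis_labels(X, y, Xnew, priors=(0.5, 0.5)):
    """Nearest centroid in Mahalanobis distance with prior offsets."""
    X = np.asarray(X, float)
    y = np.asarray(y)
    n = len(y)
    classes = np.sort(np.unique(y))
    means = np.array([X[y == c].mean(axis=0) for c in classes])
    W = np.zeros((X.shape[1], X.shape[1]))
    for c, m in zip(classes, means):
        Xc = X[y == c] - m
        W += Xc.T @ Xc
    cov = W / (n - 2)
    inv = np.linalg.inv(cov)
    scores = []
    for m, pr in zip(means, priors):
        d2 = np.einsum("ij,jk,ik->i", Xnew - m, inv, Xnew - m)
        scores.append(-0.5 * d2 + np.log(pr))
    return classes[np.argmax(scores, axis=0)]


def random_two_class(rng, n, p, shift_scale=0.8):
    y = rng.integers(0, 2, size=n)
    while np.unique(y).size < 2:
        y = rng.integers(0, 2, size=n)
    delta = rng.normal(0, shift_scale, size=p)
    X = rng.normal(size=(n, p)) + np.outer(y, delta)
    return X, y


class TestWilksLambda:
    def test_hand_example_one_fifth(self):
        # groups {1,2} vs {3,4}: SSW = 1, SST = 5
        X = np.array([1.0, 2.0, 3.0, 4.0])
        y = np.array([0, 0, 1, 1])
        assert T.wilks_lambda(X, y) == pytest.approx(0.2)

    def test_identical_group_means_give_unity(self):
        X = np.array([1.0, 3.0, 1.0, 3.0])
        y = np.array([0, 0, 1, 1])
        assert T.wilks_lambda(X, y) == pytest.approx(1.0)

    def test_bounded_in_unit_interval(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            X, y = random_two_class(rng, 30, 3)
            lam = T.wilks_lambda(X, y)
            assert 0.0 < lam <= 1.0 + 1e-12

    def test_matches_brute_force_to_1e10(self):
        rng = np.random.default_rng(1)
        for _ in range(200):
            n = int(rng.integers(10, 51))
            p = int(rng.integers(1, 4))
            X, y = random_two_class(rng, n, p)
            assert T.wilks_lambda(X, y) == pytest.approx(
                brute_force_wilks(X, y), abs=1e-10)

    def test_singular_scatter_raises(self):
        X = np.column_stack([np.arange(8.0), np.arange(8.0)])  # collinear
        y = np.array([0, 0, 0, 0, 1, 1, 1, 1])
        with pytest.raises(T.TrainError, match="singular"):
            T.wilks_lambda(X, y)


class TestCanonicalIdentities:
    def test_hand_lambda_gives_eigenvalue_four(self):
        X = np.array([1.0, 2.0, 3.0, 4.0])
        y = np.array([0, 0, 1, 1])
        model = T.fit_lda(X, y, with_loo=False)
        assert model.eigenvalue == pytest.approx(4.0)
        assert model.canonical_correlation == pytest.approx(0.8944, abs=1e-4)
        assert model.wilks == pytest.approx(0.2)

    def test_identical_means_zero_eigenvalue(self):
        X = np.array([1.0, 3.0, 1.0, 3.0, 2.0, 2.0])
        y = np.array([0, 0, 1, 1, 0, 1])
        model = T.fit_lda(X, y, with_loo=False)
        assert model.eigenvalue == pytest.approx(0.0, abs=1e-12)
        assert model.canonical_correlation == pytest.approx(0.0, abs=1e-6)

    @pytest.mark.parametrize("gid,n,eig,can_r,wilks,chi2,df", DISCRIMINANT_STATS)
    def test_published_statistics_are_internally_consistent(
            self, gid, n, eig, can_r, wilks, chi2, df):
        """lambda -> Wilks -> R -> Bartlett chi2 reproduce the printed columns."""
        wilks_hat = 1.0 / (1.0 + eig)
        r_hat = np.sqrt(eig / (1.0 + eig))
        assert wilks_hat == pytest.approx(wilks, abs=2e-3)
        assert r_hat == pytest.approx(can_r, abs=2e-3)
        chi2_hat, df_hat, p = T.bartlett_chi_square(wilks_hat, n, df)
        assert df_hat == df
        assert chi2_hat == pytest.approx(chi2, rel=2e-3)
        assert p < 0.001


class TestBartlett:
    def test_unity_lambda_gives_zero(self):
        chi2, df, p = T.bartlett_chi_square(1.0, 100, 3)
        assert chi2 == 0.0
        assert p == pytest.approx(1.0)

    def test_too_small_sample_raises(self):
        with pytest.raises(T.TrainError, match="too small"):
            T.bartlett_chi_square(0.5, 3, 4)

    def test_invalid_lambda_raises(self):
        with pytest.raises(T.TrainError):
            T.bartlett_chi_square(0.0, 100, 2)


class TestFisherFunctions:
    def test_closed_form_one_dimensional(self):
        # means 0 and 1, pooled variance 1, equal priors
        rng = np.random.default_rng(3)
        half = 200
        x0 = rng.normal(0, 1, half)
        x1 = rng.normal(0, 1, half) + 1.0
        x0 = (x0 - x0.mean()) / x0.std(ddof=0)          # exact moments
        x1 = (x1 - x1.mean()) / x1.std(ddof=0) + 1.0
        X = np.concatenate([x0, x1])
        # force pooled variance (W / (n-2)) to exactly 1
        scale = np.sqrt((2 * half - 2) / (2 * half))
        X = np.concatenate([(x0 * scale), (x1 - 1.0) * scale + 1.0])
        y = np.array([0] * half + [1] * half)
        clf = T.fisher_functions(X, y)
        assert clf.coef_y0[0] == pytest.approx(0.0, abs=1e-9)
        assert clf.coef_y1[0] == pytest.approx(1.0, abs=1e-9)
        assert clf.const_y0 == pytest.approx(np.log(0.5), abs=1e-9)
        assert clf.const_y1 == pytest.approx(-0.5 + np.log(0.5), abs=1e-9)
        # decision boundary at x = 0.5
        y0, y1 = B.fisher_scores(clf, {clf.variables[0]: 0.5})
        assert y0 == pytest.approx(y1, abs=1e-9)

    def test_equal_means_decided_by_priors_alone(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=100)
        X = np.concatenate([x, x])
        y = np.array([0] * 100 + [1] * 100)
        clf = T.fisher_functions(X, y, priors=(0.9, 0.1))
        assert clf.coef_y0[0] == pytest.approx(clf.coef_y1[0])
        assert clf.const_y0 > clf.const_y1          # majority prior wins

    def test_matches_mahalanobis_nearest_centroid(self):
        rng = np.random.default_rng(5)
        for _ in range(100):
            X, y = random_two_class(rng, 40, 3)
            clf = T.fisher_functions(X, y)
            ours = T._classify_rows(clf, X)
            oracle = mahalanobis_labels(X, y, X)
            assert (ours == oracle).all()

    def test_matches_canonical_midpoint_rule(self):
        rng = np.random.default_rng(6)
        for _ in range(100):
            X, y = random_two_class(rng, 40, 3)
            model = T.fit_lda(X, y, with_loo=False)
            proj = X @ model.canonical_coef
            m0 = proj[y == 0].mean()
            m1 = proj[y == 1].mean()
            midpoint = 0.5 * (m0 + m1)
            oracle = ((proj - midpoint) * np.sign(m1 - m0) > 0).astype(int)
            ours = T._classify_rows(model.classifier, X)
            assert (ours == oracle).all()

    def test_matches_sklearn_lda_predictions(self):
        rng = np.random.default_rng(7)
        for _ in range(25):
            X, y = random_two_class(rng, 60, 3)
            clf = T.fisher_functions(X, y)
            ours = T._classify_rows(clf, X)
            ref = LinearDiscriminantAnalysis(priors=[0.5, 0.5]).fit(X, y)
            assert (ours == ref.predict(X)).all()


class TestStepwise:
    def test_informative_variable_entered_first(self):
        rng = np.random.default_rng(8)
        n = 200
        y = np.array([0] * 100 + [1] * 100)
        X = rng.normal(size=(n, 6))
        X[:, 2] += 3.0 * y                      # group means 3 SD apart
        names = [f"v{i}" for i in range(6)]
        trace = T.stepwise_select(X, y, names)
        assert trace.steps[0].action == "enter"
        assert trace.steps[0].variable == "v2"

    def test_all_noise_selection_matches_type_one_rate(self):
        rng = np.random.default_rng(9)
        n, p, reps = 200, 5, 200
        n_selected = 0
        for _ in range(reps):
            X, y = random_two_class(rng, n, p, shift_scale=0.0)
            if T.stepwise_select(X, y).selected:
                n_selected += 1
        expected = 1.0 - (1.0 - 0.051) ** p     # max-of-p entry events
        assert n_selected / reps == pytest.approx(expected, abs=0.1)

    def test_matches_exhaustive_same_size_best_subset(self):
        from itertools import combinations
        rng = np.random.default_rng(10)
        n, p, reps = 60, 4, 200
        agree = 0
        for _ in range(reps):
            X, y = random_two_class(rng, n, p, shift_scale=0.4)
            selected = T.stepwise_select(X, y).selected
            k = len(selected)
            if k == 0:
                agree += 1
                continue
            lam_sel = T.wilks_lambda(X[:, [int(v[1:]) for v in selected]], y)
            best = min(T.wilks_lambda(X[:, list(cols)], y)
                       for cols in combinations(range(p), k))
            agree += int(abs(lam_sel - best) < 1e-10)
        assert agree / reps >= 0.95

    def test_trace_invariants(self):
        rng = np.random.default_rng(11)
        for _ in range(20):
            X, y = random_two_class(rng, 80, 6)
            trace = T.stepwise_select(X, y)
            assert len(trace.steps) <= 20
            lam_before = 1.0
            for s in trace.steps:
                if s.action == "enter":
                    assert s.wilks <= lam_before + 1e-12
                lam_before = s.wilks


class TestLeaveOneOut:
    def test_separated_clusters_perfect(self):
        rng = np.random.default_rng(12)
        X = np.concatenate([rng.normal(0, 1, 20), rng.normal(10, 1, 20)])
        y = np.array([0] * 20 + [1] * 20)
        assert T.loo_accuracy(X, y) == 1.0

    def test_permuted_labels_near_majority_rate(self):
        rng = np.random.default_rng(13)
        n = 200
        X = rng.normal(size=(n, 3))
        y = np.array([0] * 120 + [1] * 80)
        rng.shuffle(y)
        acc = T.loo_accuracy(X, y, priors="proportional")
        assert acc == pytest.approx(0.6, abs=0.1)

    def test_six_point_dataset_matches_fold_by_fold_enumeration(self):
        X = np.array([0.0, 1.0, 2.0, 5.0, 6.0, 10.0])
        y = np.array([0, 0, 0, 1, 1, 1])
        # oracle: per fold, refit means/pooled variance by hand and classify
        correct = 0
        for i in range(6):
            rest = np.arange(6) != i
            Xr, yr = X[rest], y[rest]
            m0, m1 = Xr[yr == 0].mean(), Xr[yr == 1].mean()
            s2 = (np.sum((Xr[yr == 0] - m0) ** 2)
                  + np.sum((Xr[yr == 1] - m1) ** 2)) / (len(Xr) - 2)
            s0 = -0.5 * (X[i] - m0) ** 2 / s2
            s1 = -0.5 * (X[i] - m1) ** 2 / s2
            correct += int(int(s1 > s0) == y[i])
        assert T.loo_accuracy(X, y) == pytest.approx(correct / 6)

    def test_single_class_fold_raises(self):
        X = np.array([0.0, 1.0, 2.0, 3.0])
        y = np.array([0, 1, 1, 1])
        with pytest.raises(T.TrainError, match="single-class"):
            T.loo_accuracy(X, y)

    def test_accuracy_tracks_analytic_bayes_rate(self):
        """One informative variable: LOO within 5 points of Phi(delta/2sigma)."""
        rng = np.random.default_rng(14)
        n_per = 800
        delta, sigma = 1.0, 0.5
        X = np.concatenate([rng.normal(0, sigma, n_per),
                            rng.normal(delta, sigma, n_per)])
        y = np.array([0] * n_per + [1] * n_per)
        bayes = norm.cdf(delta / (2 * sigma))
        assert T.loo_accuracy(X, y) == pytest.approx(bayes, abs=0.05)


class TestTrainBank:
    def _features_frame(self, rng, groups, n_per_class=30,
                        bed_means=(23.0, 21.4), bed_sd=0.3):
        rows = []
        labels = {}
        for gid in groups:
            lo, hi = B.AGE_GROUPS[gid]
            for label in (0, 1):
                for i in range(n_per_class):
                    labels[f"g{gid}l{label}i{i}"] = label
                    row = {
                        "child_id": f"g{gid}l{label}i{i}",
                        "age_months": int(rng.integers(lo, hi + 1)),
                        "wake_up_time": 6.84, "wake_up_time_variation": 0.26,
                        "bed_time": rng.normal(bed_means[label], bed_sd),
                        "bed_time_variation": -0.27,
                        "total_sleep_duration": 11.27,
                        "nocturnal_sleep_duration": 9.18,
                        "night_wakings": 0.14, "evening_nap": 0.11,
                        "breakfast": 0.94, "self_awake": 0.69,
                    }
                    rows.append(row)
        return pd.DataFrame(rows), labels

    def test_bed_time_only_separation_selects_bed_time(self):
        rng = np.random.default_rng(15)
        df, labels = self._features_frame(rng, groups=range(1, 9))
        report = T.train_bank(df, labels)
        assert sorted(report.models) == list(range(1, 9))
        for gid, model in report.models.items():
            assert model.variables == ("bed_time",)
            assert model.loo_accuracy > 0.9
            assert model.trace is not None and len(model.trace.steps) <= 20

    def test_single_class_group_skipped_with_reason(self):
        rng = np.random.default_rng(16)
        df, labels = self._features_frame(rng, groups=[1, 2])
        for cid in df.loc[df["age_months"] <= 5, "child_id"]:
            labels[cid] = 1                      # group 1 loses class 0
        report = T.train_bank(df, labels)
        assert 1 in report.skipped
        assert "one class" in report.skipped[1]
        assert 2 in report.models

    def test_trained_bank_round_trips_and_screens(self, tmp_path):
        rng = np.random.default_rng(17)
        df, labels = self._features_frame(rng, groups=[5])
        report = T.train_bank(df, labels)
        path = tmp_path / "bank.csv"
        B.save_bank(report.bank(), path)
        bank = B.load_bank(path)
        features = {name: df.iloc[0][name] for name in FEATURE_NAMES}
        features["bed_time"] = 21.4
        assert B.classify(features, 30, bank).label == 1
        features["bed_time"] = 23.0
        assert B.classify(features, 30, bank).label == 0

    def test_report_is_json_serializable(self):
        import json
        rng = np.random.default_rng(18)
        df, labels = self._features_frame(rng, groups=[5])
        report = T.train_bank(df, labels)
        text = json.dumps(T.report_to_dict(report))
        assert "bed_time" in text
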