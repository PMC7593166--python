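"""Assessment battery vs independent brute-force oracles."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from ttrsdm import evaluation as ev


def brute_force_auc(scores, labels):
    """O(n^2) concordant-pair fraction with half credit for ties."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


class TestMetrics:
    def test_formula_example(self):
        m = ev.metrics(ev.ConfusionMatrix(tp=50, fn=0, tn=40, fp=10))
        assert m["sensitivity"] == 1.0
        assert m["specificity"] == pytest.approx(0.8)
        assert m["prevalence"] == pytest.approx(0.6)
        assert m["bias"] == pytest.approx(0.1)

    def test_perfect_classifier(self):
        m = ev.metrics(ev.ConfusionMatrix(tp=30, fn=0, tn=30, fp=0))
        assert (m["sensitivity"], m["specificity"], m["tss"], m["bias"]) == \
            (1.0, 1.0, 1.0, 0.0)

    def test_all_positive_predictor_on_balanced_data(self):
        m = ev.metrics(ev.ConfusionMatrix(tp=50, fn=0, tn=0, fp=50))
        assert m["sensitivity"] == 1.0 and m["specificity"] == 0.0
        assert m["tss"] == 0.0 and m["bias"] == pytest.approx(0.5)

    def test_printed_tss_compatibility_flag(self):
        cm = ev.ConfusionMatrix(tp=40, fn=10, tn=35, fp=15)
        assert ev.metrics(cm, printed_tss=True)["tss"] == pytest.approx(
            ev.metrics(cm)["sensitivity"] - ev.metrics(cm)["specificity"])

    def test_undefined_ratio_is_nan_not_zero(self):
        m = ev.metrics(ev.ConfusionMatrix(tp=0, fn=0, tn=5, fp=5))
        assert np.isnan(m["sensitivity"])

    def test_algebraic_identities_on_random_matrices(self, rng):
        for _ in range(100):
            tp, fp, tn, fn = rng.integers(1, 100, 4)
            m = ev.metrics(ev.ConfusionMatrix(int(tp), int(fp), int(tn), int(fn)))
            total = tp + fp + tn + fn
            assert m["bias"] == pytest.approx(
                m["prevalence"] - (tp + fn) / total)
            assert m["tss"] == pytest.approx(
                m["sensitivity"] + m["specificity"] - 1)


class TestThreshold:
    def test_documented_example(self):
        thr = ev.max_sss_threshold([0.9, 0.8, 0.4, 0.3], [1, 1, 0, 0])
        assert thr == 0.8
        m = ev.metrics(ev.confusion([0.9, 0.8, 0.4, 0.3], [1, 1, 0, 0], thr))
        assert m["sensitivity"] == 1.0 and m["specificity"] == 1.0

    def test_inverted_labels_cap(self):
        scores = np.array([0.9, 0.8, 0.4, 0.3])
        labels = np.array([0, 0, 1, 1])
        thr = ev.max_sss_threshold(scores, labels)
        m = ev.metrics(ev.confusion(scores, labels, thr))
        assert m["sensitivity"] + m["specificity"] <= 1.0 + 1e-12

    def test_single_presence_separable(self):
        thr = ev.max_sss_threshold([0.9, 0.1, 0.2, 0.15], [1, 0, 0, 0])
        m = ev.metrics(ev.confusion([0.9, 0.1, 0.2, 0.15], [1, 0, 0, 0], thr))
        assert m["sensitivity"] == 1.0 and m["specificity"] == 1.0

    def test_constant_scores_flagged(self):
        with pytest.raises(ValueError):
            ev.max_sss_threshold([0.5, 0.5, 0.5], [1, 0, 1])

    def test_achieved_sum_dominates_every_candidate(self, rng):
        for _ in range(25):
            n = int(rng.integers(10, 120))
            scores = np.round(rng.random(n), 2)
            labels = rng.integers(0, 2, n)
            if labels.min() == labels.max() or len(np.unique(scores)) < 2:
                continue
            thr = ev.max_sss_threshold(scores, labels)
            m = ev.metrics(ev.confusion(scores, labels, thr))
            best = m["sensitivity"] + m["specificity"]
            for cand in np.unique(scores):
                mc = ev.metrics(ev.confusion(scores, labels, cand))
                assert best >= mc["sensitivity"] + mc["specificity"] - 1e-12


class TestAUC:
    def test_perfect_separation(self):
        assert ev.auc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0]) == 1.0

    def test_random_scores_near_half(self, rng):
        scores = rng.random(10_000)
        labels = rng.integers(0, 2, 10_000)
        assert abs(ev.auc(scores, labels) - 0.5) < 0.02

    def test_matches_brute_force_oracle(self, rng):
        for _ in range(100):
            n = int(rng.integers(5, 200))
            scores = np.round(rng.random(n), 1)  # force ties
            labels = rng.integers(0, 2, n)
            if labels.min() == labels.max():
                continue
            assert ev.auc(scores, labels) == pytest.approx(
                brute_force_auc(scores, labels))

    def test_one_class_undefined(self):
        with pytest.raises(ValueError):
            ev.auc([0.1, 0.2], [1, 1])


class TestSpatialDisagreement:
    def test_identical_and_complementary_maps(self):
        a = np.zeros(100, dtype=int)
        assert ev.spatial_disagreement(a, a) == 0
        assert ev.spatial_disagreement(a, 1 - a) == 100

    def test_constructed_fixture_counts_cells(self, rng):
        a = rng.integers(0, 2, 300)
        b = a.copy()
        flip = rng.choice(300, size=7, replace=False)
        b[flip] = 1 - b[flip]
        assert ev.spatial_disagreement(a, b) == 7
        assert ev.spatial_disagreement(b, a) == 7

    def test_grid_mismatch_rejected(self):
        with pytest.raises(ValueError):
            ev.spatial_disagreement(np.zeros(4), np.zeros(5))


class TestNT2:
    def test_training_mean_scores_zero(self, rng):
        T = rng.normal(size=(200, 3))
        out = ev.nt2(T, T.mean(axis=0))
        assert out.nt2[0] == pytest.approx(0.0, abs=1e-12)

    def test_most_extreme_training_point_scores_one(self, rng):
        T = rng.normal(size=(200, 3))
        scores = ev.nt2(T, T)
        assert scores.nt2.max() == pytest.approx(1.0)

    def test_matches_linear_algebra_oracle(self, rng):
        cov = np.array([[2.0, 1.2], [1.2, 1.5]])
        T = rng.multivariate_normal([1.0, -2.0], cov, size=300)
        Q = rng.multivariate_normal([1.0, -2.0], cov, size=50)
        mu = T.mean(axis=0)
        vi = np.linalg.inv(np.cov(T, rowvar=False))
        d2 = np.array([(q - mu) @ vi @ (q - mu) for q in Q])
        ref = max((t - mu) @ vi @ (t - mu) for t in T)
        np.testing.assert_allclose(ev.nt2(T, Q).nt2, d2 / ref, rtol=1e-10)

    def test_affine_invariance(self, rng):
        T = rng.normal(size=(100, 4))
        Q = rng.normal(size=(20, 4)) * 2
        A = rng.normal(size=(4, 4)) + 4 * np.eye(4)
        b = rng.normal(size=4)
        base = ev.nt2(T, Q).nt2
        mapped = ev.nt2(T @ A + b, Q @ A + b).nt2
        np.testing.assert_allclose(base, mapped, atol=1e-8)

    def test_novel_flag_above_one(self, rng):
        T = rng.normal(size=(100, 2))
        out = ev.nt2(T, np.array([[50.0, 50.0]]))
        assert out.novel[0]

    def test_needs_more_points_than_variables(self, rng):
        with pytest.raises(ValueError):
            ev.nt2(rng.normal(size=(3, 5)), rng.normal(size=(2, 5)))


def simulate_novelty_records(rng, slopes={"A": -2.0, "B": -0.5},
                             intercepts={"A": 2.0, "B": 2.0},
                             n_species=20, n_per=50, species_sd=0.5):
    rows = []
    for s in range(n_species):
        b = rng.normal(0, species_sd)
        for model, slope in slopes.items():
            x = rng.uniform(0, 2, n_per)
            eta = intercepts[model] + slope * x + b
            y = rng.random(n_per) < 1 / (1 + np.exp(-eta))
            rows.append(pd.DataFrame({
                "species": f"s{s}", "model": model, "nt2": x,
                "correct": y.astype(int)}))
    return pd.concat(rows, ignore_index=True)


class TestCorrectnessVsNovelty:
    def test_recovers_model_specific_slopes(self, rng):
        rec = simulate_novelty_records(rng)
        out = ev.correctness_vs_novelty(rec)
        sl = out[out["kind"] == "slope"].set_index("model")
        assert sl.loc["A", "ci_low"] < -2.0 < sl.loc["A", "ci_high"]
        assert sl.loc["B", "ci_low"] < -0.5 < sl.loc["B", "ci_high"]
        assert sl.loc["A", "estimate"] < sl.loc["B", "estimate"]

    def test_null_slopes_covered(self, rng):
        rec = simulate_novelty_records(rng, slopes={"A": 0.0, "B": 0.0},
                                       intercepts={"A": 0.5, "B": 0.5})
        out = ev.correctness_vs_novelty(rec)
        sl = out[out["kind"] == "slope"]
        assert (sl["ci_low"] < 0).all() and (sl["ci_high"] > 0).all()

    def test_single_species_collapses_to_plain_logistic(self, rng):
        rec = simulate_novelty_records(rng, n_species=1, n_per=400,
                                       species_sd=0.0)
        out = ev.correctness_vs_novelty(rec)
        import statsmodels.api as sm

        for model in ("A", "B"):
            sub = rec[rec["model"] == model]
            X = np.column_stack([np.ones(len(sub)), sub["nt2"]])
            ref = sm.GLM(sub["correct"].to_numpy(float), X,
                         family=sm.families.Binomial()).fit()
            got = out[out["model"] == model].set_index("kind")["estimate"]
            assert got["intercept"] == pytest.approx(ref.params[0], abs=1e-6)
            assert got["slope"] == pytest.approx(ref.params[1], abs=1e-6)

    def test_requires_enough_records(self):
        small = pd.DataFrame({"correct": [1, 0], "nt2": [0.1, 0.2],
                              "model": ["A", "A"], "species": ["s", "s"]})
        with pytest.raises(ValueError):
            ev.correctness_vs_novelty(small)


class TestPairedComparison:
    def test_identical_vectors(self):
        out = ev.paired_comparison([0.5, 0.6, 0.7], [0.5, 0.6, 0.7])
        assert out["mean_difference"] == 0.0
        assert out["p"] == 1.0

    def test_constant_offset(self):
        a = np.array([0.5, 0.6, 0.7, 0.8, 0.9])
        out = ev.paired_comparison(a + 0.1, a)
        assert out["mean_difference"] == pytest.approx(0.1)

    def test_matches_textbook_formula(self):
        a = np.array([0.71, 0.64, 0.85, 0.77, 0.60])
        b = np.array([0.55, 0.62, 0.70, 0.66, 0.58])
        d = a - b
        t_manual = d.mean() / (d.std(ddof=1) / np.sqrt(len(d)))
        p_manual = 2 * stats.t.sf(abs(t_manual), df=len(d) - 1)
        out = ev.paired_comparison(a, b)
        assert out["t"] == pytest.approx(t_manual)
        assert out["p"] == pytest.approx(p_manual)
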