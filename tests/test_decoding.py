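"""SVD-LDA decoding: oracle checks, chance calibration, leakage guards,
articulator maps, temporal decoding and spatial sweeps."""

import warnings
from math import ceil

import numpy as np
import pytest
from scipy import stats

import microspeech as ms
from microspeech.bundle import ValidationError
from microspeech.decoding import SVDLDAClassifier, position_effect


def _gaussian_toy(n_per=60, d=8, sep=6.0, seed=0):
    rng = np.random.default_rng(seed)
    X = np.vstack([rng.normal(0, 1, (n_per, d)),
                   rng.normal(sep / np.sqrt(d), 1, (n_per, d))])
    y = np.repeat(["u", "v"], n_per)
    return X, y


class TestSVDLDA:
    def test_separable_two_class_toy(self):
        X, y = _gaussian_toy()
        res = ms.svd_lda_cv(X, y, outer_folds=10)
        assert res.accuracy >= 0.95

    def test_boundary_matches_closed_form_pooled_covariance(self):
        # 2-class LDA: w = Sigma^-1 (mu1 - mu0); compare class predictions
        rng = np.random.default_rng(1)
        n = 30
        X = np.vstack([rng.normal(0, 1, (n, 3)), rng.normal(1.5, 1, (n, 3))])
        y = np.repeat([0, 1], n)
        est = SVDLDAClassifier(var_frac=1.0).fit(X, y)
        mu0, mu1 = X[y == 0].mean(0), X[y == 1].mean(0)
        Xc = np.vstack([X[y == 0] - mu0, X[y == 1] - mu1])
        sigma = Xc.T @ Xc / (len(X) - 2)
        w = np.linalg.solve(sigma, mu1 - mu0)
        b = -0.5 * (mu1 + mu0) @ w  # equal priors
        scores = X @ w + b
        np.testing.assert_array_equal(est.predict(X), (scores > 0).astype(int))
        # decision-function agreement up to scale/sign
        df = est.decision_function(X)
        r = np.corrcoef(df, scores)[0, 1]
        assert abs(r) > 1 - 1e-6

    def test_confusion_rows_normalized_and_accuracy_consistent(self, hg_p1):
        hg, labels = hg_p1
        res = ms.svd_lda_cv(hg, labels, outer_folds=3, seed=0)
        C = res.confusion.to_numpy()
        np.testing.assert_allclose(C.sum(axis=1), 1.0)
        counts = np.array([np.sum(labels == c) for c in res.confusion.index])
        acc = (np.diag(C) * counts).sum() / counts.sum()
        assert np.isclose(acc, res.accuracy)

    def test_model_selection_ignores_test_data(self):
        X, y = _gaussian_toy(n_per=50)
        est = SVDLDAClassifier(var_grid=[0.5, 0.9], inner_folds=5,
                               random_state=0)
        est.fit(X[:80], y[:80])
        vf_clean = est.var_frac_
        # corrupting unseen data must not change the selected model
        X2 = X.copy()
        X2[80:] = 1e6
        est2 = SVDLDAClassifier(var_grid=[0.5, 0.9], inner_folds=5,
                                random_state=0)
        est2.fit(X2[:80], y[:80])
        assert est2.var_frac_ == vf_clean
        np.testing.assert_allclose(est2.svd_.components, est.svd_.components)

    def test_single_class_rejected(self):
        with pytest.raises(ValidationError):
            SVDLDAClassifier().fit(np.random.rand(10, 3), np.zeros(10))

    def test_fold_reduction_warns(self, hg_p1):
        hg, labels = hg_p1
        with pytest.warns(UserWarning, match="folds reduced"):
            ms.svd_lda_cv(hg, labels, outer_folds=20)


class TestChance:
    def test_decoding_above_chance_and_chance_after_permutation(
            self, chance_session):
        c = chance_session
        res = ms.svd_lda_cv(c["X"], c["y"], outer_folds=10, seed=0)
        assert res.p_chance < 0.01
        rng = np.random.default_rng(0)
        resp = ms.svd_lda_cv(c["X"], rng.permutation(c["y"]),
                             outer_folds=10, seed=0)
        lo, hi = stats.binom.interval(0.95, resp.n_trials, 1 / 9)
        assert lo / resp.n_trials <= resp.accuracy <= hi / resp.n_trials

    def test_binomial_tail_values(self):
        # 0.0065537 frozen from an exact rational tail sum
        assert np.isclose(ms.binomial_chance_test(20, 100, 1 / 9),
                          0.006553692667436752, rtol=1e-12)
        assert np.isclose(ms.binomial_chance_test(0, 100, 1 / 9), 1.0)
        assert np.isclose(ms.binomial_chance_test(100, 100, 1 / 9),
                          (1 / 9) ** 100)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValidationError):
            ms.binomial_chance_test(5, 10, 1.5)
        with pytest.raises(ValidationError):
            ms.binomial_chance_test(11, 10, 0.5)


class TestAUCMap:
    def test_uninformative_electrodes_sit_at_half(self):
        rng = np.random.default_rng(0)
        vals = rng.standard_normal((500, 6, 40))
        hg = ms.HGEnvelopeTensor(values=vals, fs_env=200.0,
                                 alignment="p1", window_s=(-0.1, 0.1),
                                 trial_index=np.arange(500))
        labels = rng.choice(list(ms.ARTICULATORS), 500)
        amap = ms.electrode_auc_map(hg, labels, ms.make_array(2, 3, 1.0))
        assert np.abs(amap.auc.to_numpy() - 0.5).max() < 0.06

    def test_contour_size_is_top_decile(self, hg_p1, session52):
        hg, labels = hg_p1
        arts = np.array([ms.PHONEME_ARTICULATOR[p] for p in labels])
        amap = ms.electrode_auc_map(hg, arts, session52["geom"])
        n_top = ceil(0.1 * hg.n_electrodes)
        for c, idx in amap.contours.items():
            assert len(idx) == n_top
            assert amap.areas_mm2[c] == n_top * session52["geom"].pitch_mm ** 2

    def test_auc_values_are_probabilities(self, hg_p1, session52):
        hg, labels = hg_p1
        arts = np.array([ms.PHONEME_ARTICULATOR[p] for p in labels])
        amap = ms.electrode_auc_map(hg, arts, session52["geom"])
        A = amap.auc.to_numpy()
        assert (A >= 0).all() and (A <= 1).all()


class TestTemporalDecode:
    def test_segment_arithmetic_of_the_reference_grid(self):
        # 200 ms windows, 10 ms steps over [-1, 1] s
        n_seg = int(round((1.0 + 1.0 - 0.2) / 0.01)) + 1
        assert n_seg == 181

    def test_sequential_sources_give_ordered_peaks(self, hg_mid_utt):
        hg, labels = hg_mid_utt
        _, acc, peaks = ms.temporal_decode(hg, labels, step_s=0.05,
                                           outer_folds=5, seed=0)
        for pos in labels:
            assert acc[pos].max() > 2 / 9  # decodable somewhere
        assert peaks["p1"] < peaks["p2"] < peaks["p3"]

    def test_shuffled_labels_stay_at_chance(self, hg_utt):
        hg, labels = hg_utt
        rng = np.random.default_rng(0)
        null_labels = {"p1": rng.permutation(labels["p1"])}
        _, acc, _ = ms.temporal_decode(hg, null_labels, step_s=0.2,
                                       outer_folds=3, seed=0)
        n = hg.n_trials
        # family-wise guard: even the max over segments stays within a
        # generous binomial envelope
        hi = stats.binom.ppf(1 - 0.01 / len(acc["p1"]), n, 1 / 9) / n
        assert acc["p1"].max() <= hi + 1e-9


class TestSpatialSweeps:
    def test_resolution_sweep_full_array_consistency(self, hg_p1, session52):
        hg, labels = hg_p1
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            sw = ms.spatial_sweep(hg, session52["geom"], labels, "resolution",
                                  fractions=(1.0,), n_samples=1,
                                  outer_folds=3, seed=0)
        ref = ms.svd_lda_cv(hg, labels, outer_folds=3, seed=0)
        assert sw["conditions"][0]["accuracies"][0] == ref.accuracy

    def test_resolution_monotone_and_pitch_values(self, hg_mid_p1,
                                                   session_mid):
        hg, labels = hg_mid_p1
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            sw = ms.spatial_sweep(hg, session_mid["geom"], labels, "resolution",
                                  fractions=(1.0, 0.5, 0.25, 0.125),
                                  n_samples=4, outer_folds=3, seed=0)
        pitches = [c["pitch_mm"] for c in sw["conditions"]]
        meds = [float(np.median(c["accuracies"])) for c in sw["conditions"]]
        assert pitches == sorted(pitches)  # coarser as fraction shrinks
        rho = stats.spearmanr(pitches, meds).statistic
        assert rho < 0

    def test_coverage_improves_with_subgrid_size(self, hg_mid_p1,
                                                  session_mid):
        hg, labels = hg_mid_p1
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            sw = ms.spatial_sweep(hg, session_mid["geom"], labels, "coverage",
                                  subgrid_dims=((2, 2), (4, 4), (8, 8)),
                                  outer_folds=3, seed=0)
        meds = [float(np.median(c["accuracies"])) for c in sw["conditions"]]
        assert meds[0] <= meds[1] <= meds[2]

    def test_contact_averaging_degrades_accuracy(self, hg_p1, session52):
        hg, labels = hg_p1
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            sw = ms.spatial_sweep(hg, session52["geom"], labels, "contact",
                                  contact_sizes=(1, 2, 4),
                                  referenced=session52["ref"],
                                  bundle=session52["bundle"],
                                  outer_folds=3, seed=0)
        meds = [float(np.median(c["accuracies"])) for c in sw["conditions"]]
        assert meds[0] >= meds[-1]

    def test_unknown_mode_rejected(self, hg_p1, session52):
        hg, labels = hg_p1
        with pytest.raises(ValidationError):
            ms.spatial_sweep(hg, session52["geom"], labels, "frobnicate")


class TestNWay:
    def test_classifier_count_for_four_way(self):
        from math import comb
        assert comb(9, 4) == 126

    def test_fewer_classes_need_coarser_spacing(self, hg_mid_p1,
                                                 session_mid):
        hg, labels = hg_mid_p1
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            out = ms.nway_resolution_threshold(
                hg, session_mid["geom"], labels, N_list=(2, 9),
                fractions=(1.0, 0.5, 0.25), n_samples=3, max_subsets=8,
                outer_folds=3, seed=0)
        full_pitch = out[9]["pitch_mm"].min()
        for N in (2, 9):
            th = out[N]["threshold_spacing_mm"][0.95]
            assert th >= full_pitch - 1e-9  # never finer than the array
        # an N=2 problem tolerates spacing at least as coarse as N=9
        assert out[2]["threshold_spacing_mm"][0.95] >= \
            out[9]["threshold_spacing_mm"][0.95]
        assert (out[2]["median_accuracy"] >= out[9]["median_accuracy"]).all()


def test_position_effect_paired_t():
    p1 = np.array([0.50, 0.55, 0.48, 0.52])
    p2 = np.array([0.45, 0.50, 0.40, 0.47])
    t, p = position_effect(p1, p2)
    assert t > 0 and p < 0.05
    t2, p2_ = position_effect(p2, p1)
    assert p2_ > 0.5
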