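"""Linear phoneme decoding: SVD-LDA with nested cross-validation, chance
testing, per-electrode articulator maps, temporal decoding, and the
spatial resolution / coverage / contact-size sweeps.

:class:`SVDLDAClassifier` is a scikit-learn estimator: the training fold
is column-centred and compressed by economy SVD, the number of retained
components is chosen by an inner stratified cross-validation grid search
over cumulative-variance targets, and a pooled-covariance linear
discriminant is fit on the scores.  Test trials are projected with the
training-fold basis, so no normalization, decomposition, or model
selection ever sees test data.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations
from math import ceil

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, ClassifierMixin, clone
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold, cross_val_predict
from sklearn.utils.validation import check_is_fitted

from .bundle import ArrayGeometry, RecordingBundle, ValidationError, make_array
from .preprocess import HGEnvelopeTensor, extract_hg
from .statespace import poisson_disc_subsample, svd_reduce

__all__ = [
    "SVDLDAClassifier", "DecodeResult", "AUCMap",
    "svd_lda_cv", "binomial_chance_test", "electrode_auc_map",
    "temporal_decode", "spatial_sweep", "nway_resolution_threshold",
    "position_effect",
]


class SVDLDAClassifier(ClassifierMixin, BaseEstimator):
    """LDA on SVD scores with nested selection of the component count.

    Parameters
    ----------
    var_frac : float
        Cumulative explained-variance target when ``var_grid`` is None.
    var_grid : sequence of float or None
        Candidate variance targets for the inner grid search; the value
        with the best inner-CV accuracy on the training fold wins.
    inner_folds : int
        Folds of the inner stratified CV (reduced automatically when a
        class has fewer members).
    random_state : int
        Seed for the inner fold shuffling.
    """

    def __init__(self, var_frac: float = 0.8, var_grid=None,
                 inner_folds: int = 20, random_state: int = 0):
        self.var_frac = var_frac
        self.var_grid = var_grid
        self.inner_folds = inner_folds
        self.random_state = random_state

    # -- internals --------------------------------------------------------

    @staticmethod
    def _fit_lda(scores, y):
        lda = LinearDiscriminantAnalysis(solver="svd")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # collinearity in tiny folds
            try:
                lda.fit(scores, y)
            except np.linalg.LinAlgError:
                lda = LinearDiscriminantAnalysis(solver="lsqr", shrinkage="auto")
                lda.fit(scores, y)
        return lda

    def _inner_select(self, X, y):
        grid = list(self.var_grid)
        classes, counts = np.unique(y, return_counts=True)
        folds = int(min(self.inner_folds, counts.min()))
        if folds < 2:
            return self.var_frac
        skf = StratifiedKFold(folds, shuffle=True, random_state=self.random_state)
        acc = np.zeros(len(grid))
        for tr, te in skf.split(X, y):
            model = svd_reduce(X[tr], var_frac=1.0)
            cum = np.cumsum(model.eigenvalues) / model.eigenvalues.sum()
            for gi, vf in enumerate(grid):
                k = int(np.searchsorted(cum, vf - 1e-12) + 1)
                lda = self._fit_lda(model.transform(X[tr], k), y[tr])
                acc[gi] += (lda.predict(model.transform(X[te], k)) == y[te]).sum()
        return grid[int(np.argmax(acc))]

    # -- estimator API ----------------------------------------------------

    def fit(self, X, y):
        X = np.asarray(X, dtype=np.float64)
        y = np.asarray(y)
        if len(np.unique(y)) < 2:
            raise ValidationError("need at least two classes")
        vf = self._inner_select(X, y) if self.var_grid is not None else self.var_frac
        model = svd_reduce(X, var_frac=vf)
        self.var_frac_ = vf
        self.svd_ = model
        self.n_components_ = model.k
        self.lda_ = self._fit_lda(model.scores, y)
        self.classes_ = self.lda_.classes_
        return self

    def predict(self, X):
        check_is_fitted(self, "lda_")
        return self.lda_.predict(self.svd_.transform(np.asarray(X, dtype=np.float64)))

    def predict_proba(self, X):
        check_is_fitted(self, "lda_")
        return self.lda_.predict_proba(self.svd_.transform(np.asarray(X, dtype=np.float64)))

    def decision_function(self, X):
        check_is_fitted(self, "lda_")
        return self.lda_.decision_function(self.svd_.transform(np.asarray(X, dtype=np.float64)))


@dataclass
class DecodeResult:
    """Cross-validated decoding outcome."""

    accuracy: float
    per_class: dict
    confusion: pd.DataFrame      # row-normalized, rows = true class
    fold_accuracies: np.ndarray
    k_selected: list
    n_trials: int
    n_correct: int
    chance: float
    p_chance: float
    y_true: np.ndarray = field(repr=False, default=None)
    y_pred: np.ndarray = field(repr=False, default=None)

    def to_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "per_class": {str(k): float(v) for k, v in self.per_class.items()},
            "confusion": self.confusion.to_numpy().tolist(),
            "classes": [str(c) for c in self.confusion.index],
            "fold_accuracies": np.asarray(self.fold_accuracies).tolist(),
            "k_selected": [int(k) for k in self.k_selected],
            "n_trials": self.n_trials,
            "n_correct": self.n_correct,
            "chance": self.chance,
            "p_chance": self.p_chance,
        }


def binomial_chance_test(n_correct: int, n_trials: int, chance: float) -> float:
    """Upper-tail exact binomial p-value of ``n_correct`` at ``chance``."""
    if not 0.0 < chance < 1.0:
        raise ValidationError("chance must lie in (0, 1)")
    if not 0 <= n_correct <= n_trials:
        raise ValidationError("n_correct must lie in [0, n_trials]")
    return float(stats.binom.sf(n_correct - 1, n_trials, chance))


def _as_matrix(hg) -> np.ndarray:
    if isinstance(hg, HGEnvelopeTensor):
        return hg.flatten_trials()
    return np.asarray(hg, dtype=np.float64)


def svd_lda_cv(
    hg,
    labels,
    outer_folds: int = 20,
    var_grid=None,
    var_frac: float = 0.8,
    inner_folds: int = 20,
    seed: int = 0,
) -> DecodeResult:
    """Stratified outer-CV decoding with per-fold nested model selection.

    ``hg`` is an :class:`HGEnvelopeTensor` or trials x features matrix.
    When ``var_grid`` is given, every training fold runs its own inner
    grid search for the retained-component count.  Accuracy is pooled
    over outer test folds; chance is 1 / n_classes and tested with the
    exact binomial upper tail.
    """
    X = _as_matrix(hg)
    y = np.asarray(labels)
    classes, counts = np.unique(y, return_counts=True)
    folds = int(min(outer_folds, counts.min()))
    if folds < outer_folds:
        warnings.warn(f"outer folds reduced {outer_folds} -> {folds} "
                      "(smallest class size)")
    if folds < 2:
        raise ValidationError("need >= 2 trials of every class")
    skf = StratifiedKFold(folds, shuffle=True, random_state=seed)
    y_pred = np.empty_like(y)
    fold_acc, k_sel = [], []
    for tr, te in skf.split(X, y):
        est = SVDLDAClassifier(var_frac=var_frac, var_grid=var_grid,
                               inner_folds=inner_folds, random_state=seed)
        est.fit(X[tr], y[tr])
        y_pred[te] = est.predict(X[te])
        fold_acc.append(float((y_pred[te] == y[te]).mean()))
        k_sel.append(est.n_components_)
    n_correct = int((y_pred == y).sum())
    acc = n_correct / len(y)
    C = np.zeros((len(classes), len(classes)))
    cls_index = {c: i for i, c in enumerate(classes)}
    for yt, yp in zip(y, y_pred):
        C[cls_index[yt], cls_index[yp]] += 1
    C = C / C.sum(axis=1, keepdims=True)
    per_class = {c: float(C[i, i]) for i, c in enumerate(classes)}
    chance = 1.0 / len(classes)
    return DecodeResult(
        accuracy=acc, per_class=per_class,
        confusion=pd.DataFrame(C, index=classes, columns=classes),
        fold_accuracies=np.array(fold_acc), k_selected=k_sel,
        n_trials=len(y), n_correct=n_correct, chance=chance,
        p_chance=binomial_chance_test(n_correct, len(y), chance),
        y_true=y, y_pred=y_pred,
    )


# ---------------------------------------------------------------------------
# Articulator maps


@dataclass
class AUCMap:
    """Per-electrode one-vs-rest AUC of the 4-way articulator decoder."""

    auc: pd.DataFrame            # electrodes x articulators
    contours: dict               # articulator -> electrode indices (top decile)
    centroids: dict              # articulator -> (x, y) mm, AUC-weighted
    areas_mm2: dict              # articulator -> contour count * pitch^2


def electrode_auc_map(
    hg: HGEnvelopeTensor,
    articulator_labels,
    geometry: ArrayGeometry,
    score: str = "activation",
    cv: int = 5,
    var_frac: float = 0.8,
    seed: int = 0,
) -> AUCMap:
    """Map each electrode's articulator encoding preference spatially.

    With ``score='activation'`` (default) the per-articulator one-vs-rest
    ROC-AUC is computed from the electrode's mean envelope per trial — a
    univariate decoding value that is spatially specific, since an
    electrode scores high only for the articulator whose source drives
    it.  With ``score='lda'`` a per-electrode 4-way SVD-LDA on the time
    course supplies cross-validated class posteriors as the AUC score;
    note posteriors also encode evidence *against* a class, so distant
    informative electrodes can exceed 0.5 and blur the map.

    The contour per articulator is the top decile of electrodes by AUC
    (``ceil(0.1 * n)``), the centroid their AUC-weighted mean coordinate,
    and the area the contour count times pitch squared.
    """
    y = np.asarray(articulator_labels)
    classes = np.unique(y)
    n_elec = hg.n_electrodes
    auc = np.full((n_elec, len(classes)), 0.5)
    skf = StratifiedKFold(cv, shuffle=True, random_state=seed)
    for e in range(n_elec):
        X = hg.values[:, e, :]
        if np.allclose(X.std(axis=0), 0):
            warnings.warn(f"electrode {e}: constant signal, AUC set to 0.5")
            continue
        if score == "activation":
            act = X.mean(axis=1)
            for ci, c in enumerate(classes):
                auc[e, ci] = roc_auc_score((y == c).astype(int), act)
        elif score == "lda":
            est = SVDLDAClassifier(var_frac=var_frac, random_state=seed)
            proba = cross_val_predict(est, X, y, cv=skf, method="predict_proba")
            for ci, c in enumerate(classes):
                auc[e, ci] = roc_auc_score((y == c).astype(int), proba[:, ci])
        else:
            raise ValidationError(f"unknown score '{score}'")
    coords = geometry.coords_mm
    n_top = ceil(0.1 * n_elec)
    contours, centroids, areas = {}, {}, {}
    for ci, c in enumerate(classes):
        order = np.argsort(auc[:, ci])[::-1]
        top = np.sort(order[:n_top])
        w = auc[top, ci]
        centroids[c] = tuple((coords[top] * w[:, None]).sum(axis=0) / w.sum())
        contours[c] = top
        areas[c] = float(len(top) * geometry.pitch_mm ** 2)
    return AUCMap(auc=pd.DataFrame(auc, columns=classes),
                  contours=contours, centroids=centroids, areas_mm2=areas)


# ---------------------------------------------------------------------------
# Temporal decoding


def temporal_decode(
    hg: HGEnvelopeTensor,
    labels_per_position: dict,
    window_s: float = 0.2,
    step_s: float = 0.01,
    t_range: tuple = (-1.0, 1.0),
    outer_folds: int = 5,
    var_frac: float = 0.8,
    seed: int = 0,
):
    """Train and test an SVD-LDA at every time segment per position.

    ``labels_per_position`` maps position name (e.g. ``p1``) to the trial
    label array.  Segments are ``window_s`` long, advanced by ``step_s``
    over ``t_range`` (both ends relative to the utterance-aligned epoch).
    Returns (segment_centers_s, {position: accuracy array},
    {position: peak_time_s}).
    """
    times = hg.times
    n_seg = int(round((t_range[1] - t_range[0] - window_s) / step_s)) + 1
    starts = t_range[0] + np.arange(n_seg) * step_s
    centers = starts + window_s / 2.0
    acc = {pos: np.zeros(n_seg) for pos in labels_per_position}
    for k, s0 in enumerate(starts):
        sel = (times >= s0 - 1e-9) & (times < s0 + window_s - 1e-9)
        X = hg.values[:, :, sel].reshape(hg.n_trials, -1)
        for pos, y in labels_per_position.items():
            res = svd_lda_cv(X, y, outer_folds=outer_folds,
                             var_frac=var_frac, seed=seed)
            acc[pos][k] = res.accuracy
    peaks = {pos: float(centers[int(np.argmax(a))]) for pos, a in acc.items()}
    return centers, acc, peaks


# ---------------------------------------------------------------------------
# Spatial sweeps


def _decode_acc(hg, labels, outer_folds, var_frac, seed):
    return svd_lda_cv(hg, labels, outer_folds=outer_folds,
                      var_frac=var_frac, seed=seed).accuracy


def spatial_sweep(
    hg: HGEnvelopeTensor,
    geometry: ArrayGeometry,
    labels,
    mode: str,
    *,
    fractions=(1.0, 0.5, 0.25, 0.125),
    n_samples: int = 50,
    subgrid_dims=((2, 4), (4, 8), (8, 16)),
    contact_sizes=(1, 2, 4, 8),
    referenced: np.ndarray | None = None,
    bundle: RecordingBundle | None = None,
    outer_folds: int = 5,
    var_frac: float = 0.8,
    seed: int = 0,
):
    """Decoding accuracy under spatial degradation of the array.

    mode='resolution': Poisson-disc subsamples at each electrode-count
    fraction; the effective pitch follows sqrt(X*Y/n).  mode='coverage':
    every rectangular subgrid of the given dimensions at native
    resolution.  mode='contact': raw voltage spatially averaged within
    k x k blocks (simulating larger contacts) before HG extraction and
    decoding; requires ``referenced`` and ``bundle``.

    Returns a list of condition dicts with the accuracy distribution and
    its spatial parameter, plus the 95%-of-full-array threshold accuracy.
    """
    labels = np.asarray(labels)
    rng = np.random.default_rng(seed)
    conditions = []
    if mode == "resolution":
        for frac in fractions:
            n = max(2, int(round(frac * hg.n_electrodes)))
            accs = []
            if frac == 1.0:
                accs.append(_decode_acc(hg, labels, outer_folds, var_frac, seed))
                pitch = float(np.sqrt(np.prod(geometry.extent_mm) / n))
            else:
                pitch = None
                for _ in range(n_samples):
                    with warnings.catch_warnings():
                        warnings.simplefilter("ignore")
                        sub = poisson_disc_subsample(geometry, n,
                                                     seed=int(rng.integers(2**31)))
                    pitch = sub.pitch_mm
                    accs.append(_decode_acc(hg.select_electrodes(sub.indices),
                                            labels, outer_folds, var_frac, seed))
            conditions.append({"fraction": frac, "n_electrodes": n,
                               "pitch_mm": pitch, "accuracies": np.array(accs)})
    elif mode == "coverage":
        rows, cols = geometry.n_rows, geometry.n_cols
        site_ok = (geometry.active if geometry.active is not None
                   else np.ones(rows * cols, dtype=bool))
        site_to_elec = np.cumsum(site_ok) - 1
        for (dr, dc) in subgrid_dims:
            if dr > rows or dc > cols:
                warnings.warn(f"subgrid {dr}x{dc} exceeds array; skipped")
                continue
            accs = []
            for r0 in range(rows - dr + 1):
                for c0 in range(cols - dc + 1):
                    sites = [(r0 + r) * cols + (c0 + c)
                             for r in range(dr) for c in range(dc)]
                    if not site_ok[sites].all():
                        continue
                    idx = site_to_elec[sites]
                    accs.append(_decode_acc(hg.select_electrodes(idx), labels,
                                            outer_folds, var_frac, seed))
            conditions.append({"dims": (dr, dc), "n_electrodes": dr * dc,
                               "accuracies": np.array(accs)})
    elif mode == "contact":
        if referenced is None or bundle is None:
            raise ValidationError("contact mode needs referenced voltage and bundle")
        if geometry.active is not None:
            raise ValidationError("contact mode requires a fully active lattice")
        rows, cols = geometry.n_rows, geometry.n_cols
        v = referenced.reshape(rows, cols, -1)
        for k in contact_sizes:
            nr, nc = rows // k, cols // k
            if nr < 1 or nc < 1:
                warnings.warn(f"contact size {k} exceeds array; skipped")
                continue
            avg = v[: nr * k, : nc * k].reshape(nr, k, nc, k, -1).mean(axis=(1, 3))
            avg = avg.reshape(nr * nc, -1)
            geom_k = make_array(nr, nc, geometry.pitch_mm * k,
                                geometry.exposed_diameter_mm * k)
            b_k = RecordingBundle(voltage=avg.astype(np.float32), fs=bundle.fs,
                                  geometry=geom_k, events=bundle.events.copy())
            hg_k = extract_hg(avg, b_k, alignment=hg.alignment,
                              window_s=hg.window_s, fs_env=hg.fs_env)
            accs = [_decode_acc(hg_k, labels[hg_k.trial_index], outer_folds,
                                var_frac, seed)]
            conditions.append({"contact_k": k,
                               "contact_size_mm": k * geometry.exposed_diameter_mm,
                               "n_electrodes": nr * nc,
                               "accuracies": np.array(accs)})
    else:
        raise ValidationError(f"unknown sweep mode '{mode}'")
    full = max(float(np.median(c["accuracies"])) for c in conditions)
    return {"mode": mode, "conditions": conditions,
            "threshold_95": 0.95 * full}


def nway_resolution_threshold(
    hg: HGEnvelopeTensor,
    geometry: ArrayGeometry,
    labels,
    N_list=(2, 9),
    fractions=(1.0, 0.5, 0.25, 0.125),
    n_samples: int = 10,
    max_subsets: int | None = 20,
    outer_folds: int = 5,
    var_frac: float = 0.8,
    seed: int = 0,
):
    """Spacing needed to stay within 90%/95% of full-array accuracy per N.

    For every subsample the accuracy is averaged over all (or a random
    ``max_subsets`` of the) C(9, N) N-way classifiers.  The threshold
    spacing per N is linearly interpolated from the median accuracy vs
    pitch curve.
    """
    labels = np.asarray(labels)
    classes = np.unique(labels)
    rng = np.random.default_rng(seed)
    out = {}
    for N in N_list:
        if not 2 <= N <= len(classes):
            raise ValidationError(f"N={N} outside 2..{len(classes)}")
        subsets = list(combinations(classes, N))
        if max_subsets is not None and len(subsets) > max_subsets:
            sel = rng.choice(len(subsets), max_subsets, replace=False)
            subsets = [subsets[i] for i in sel]

        def _nway_acc(h):
            accs = []
            for sub_classes in subsets:
                m = np.isin(labels, sub_classes)
                accs.append(_decode_acc(
                    HGEnvelopeTensor(h.values[m], h.fs_env, h.alignment,
                                     h.window_s, h.trial_index[m]),
                    labels[m], outer_folds, var_frac, seed))
            return float(np.mean(accs))

        pitches, medians = [], []
        for frac in fractions:
            n = max(2, int(round(frac * hg.n_electrodes)))
            if frac == 1.0:
                pitches.append(float(np.sqrt(np.prod(geometry.extent_mm) / n)))
                medians.append(_nway_acc(hg))
                continue
            accs = []
            pitch = None
            for _ in range(n_samples):
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    sub = poisson_disc_subsample(geometry, n,
                                                 seed=int(rng.integers(2**31)))
                pitch = sub.pitch_mm
                accs.append(_nway_acc(hg.select_electrodes(sub.indices)))
            pitches.append(pitch)
            medians.append(float(np.median(accs)))
        pitches, medians = np.array(pitches), np.array(medians)
        order = np.argsort(pitches)
        full_acc = medians[order][0]
        th = {}
        for q in (0.90, 0.95):
            target = q * full_acc
            x, y_ = pitches[order], medians[order]
            spacing = x[-1]  # coarsest if never crossed
            for i in range(len(x) - 1):
                if (y_[i] >= target) != (y_[i + 1] >= target):
                    f = (target - y_[i]) / (y_[i + 1] - y_[i] + 1e-300)
                    spacing = float(x[i] + f * (x[i + 1] - x[i]))
                    break
            else:
                if (y_ >= target).all():
                    spacing = float(x[-1])
            th[q] = spacing
        out[N] = {"pitch_mm": pitches, "median_accuracy": medians,
                  "threshold_spacing_mm": th, "n_classifiers": len(subsets)}
    return out


def position_effect(acc_p1, acc_other):
    """Paired one-sided t-test that first-position accuracy is higher."""
    t, p = stats.ttest_rel(acc_p1, acc_other, alternative="greater")
    return float(t), float(p)
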