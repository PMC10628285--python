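"""Cortical state-space: SVD reduction, t-SNE, silhouette metrics, and
Poisson-disc spatial subsampling with its pitch arithmetic.

The trial matrix H (trials x electrode*time) is column-centred and
decomposed by economy SVD; the eigenvalue spectrum of the feature
covariance follows from the singular values, and the minimal number of
leading components cumulatively explaining 80% of variance is retained.
The explicit electrode*time covariance (potentially ~22,000 square) is
never materialized.

Spatial subsampling draws n electrodes from the lattice with a minimum
pairwise distance r = 2*sqrt(X*Y/(n*3.5)); the effective pitch of a
sample is sqrt(X*Y/n) with X, Y the array footprint in mm.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
from scipy import stats
from sklearn.manifold import TSNE
from sklearn.metrics import silhouette_samples

from .bundle import ArrayGeometry, ValidationError
from .preprocess import HGEnvelopeTensor

__all__ = [
    "StateSpaceModel", "SubsampleSpec",
    "svd_reduce", "tsne_embed", "silhouette_metrics",
    "poisson_disc_subsample", "clustering_vs_resolution",
]


@dataclass
class StateSpaceModel:
    """Economy-SVD state space of a trial x feature matrix."""

    mean: np.ndarray        # column means used for centring
    components: np.ndarray  # features x n_components (orthonormal columns)
    eigenvalues: np.ndarray # covariance eigenvalues, descending (all of them)
    k: int                  # minimal count reaching the variance target
    scores: np.ndarray      # trials x k

    @property
    def explained_variance_ratio(self) -> np.ndarray:
        return self.eigenvalues / self.eigenvalues.sum()

    def transform(self, X: np.ndarray, k: int | None = None) -> np.ndarray:
        k = self.k if k is None else k
        return (np.asarray(X) - self.mean) @ self.components[:, :k]


def svd_reduce(hg, var_frac: float = 0.8) -> StateSpaceModel:
    """Reduce trials to the minimal PC set explaining ``var_frac`` variance.

    ``hg`` is an :class:`HGEnvelopeTensor` or an already-flattened
    trials x features array.  The feature covariance eigen-decomposition
    is obtained from the economy SVD of the centred trial matrix
    (identical spectrum, tractable memory).
    """
    if not 0.0 < var_frac <= 1.0:
        raise ValidationError("var_frac must lie in (0, 1]")
    X = hg.flatten_trials() if isinstance(hg, HGEnvelopeTensor) else hg
    X = np.asarray(X, dtype=np.float64)
    if X.shape[0] < 2:
        raise ValidationError("need at least two trials")
    mean = X.mean(axis=0)
    Xc = X - mean
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    eig = s ** 2 / (X.shape[0] - 1)
    total = eig.sum()
    if total <= 0:
        raise ValidationError("degenerate (constant) trial matrix")
    cum = np.cumsum(eig) / total
    k = int(np.searchsorted(cum, var_frac - 1e-12) + 1)
    scores = Xc @ Vt.T[:, :k]
    return StateSpaceModel(mean=mean, components=Vt.T, eigenvalues=eig,
                           k=k, scores=scores)


def tsne_embed(scores: np.ndarray, perplexity: float = 30.0, seed: int = 0) -> np.ndarray:
    """2-D Barnes-Hut t-SNE of the PC scores, deterministic given seed."""
    X = np.asarray(scores, dtype=np.float64)
    if np.allclose(X.std(axis=0), 0):
        raise ValidationError("degenerate scores: all trials identical")
    n = X.shape[0]
    if n <= 3 * perplexity:
        new_p = max(2.0, (n - 1) / 3.0)
        warnings.warn(f"perplexity lowered {perplexity} -> {new_p:g} for n={n}")
        perplexity = new_p
    ts = TSNE(n_components=2, perplexity=perplexity, method="barnes_hut",
              init="random", random_state=seed)
    return ts.fit_transform(X)


def silhouette_metrics(
    embedding: np.ndarray,
    labels,
    n_shuffles: int = 1000,
    seed: int = 0,
):
    """Silhouette ratio / score and their label-shuffle chance level.

    ratio = fraction of trials with positive silhouette; score = mean
    silhouette over those trials; chance_score = mean score across
    ``n_shuffles`` label permutations.
    """
    labels = np.asarray(labels)
    classes, counts = np.unique(labels, return_counts=True)
    if len(classes) < 2 or counts.min() < 2:
        raise ValidationError("need >= 2 classes with >= 2 trials each")
    X = np.asarray(embedding, dtype=np.float64)

    def _metrics(lab):
        s = silhouette_samples(X, lab, metric="euclidean")
        pos = s > 0
        ratio = pos.mean()
        score = float(s[pos].mean()) if pos.any() else 0.0
        return ratio, score

    ratio, score = _metrics(labels)
    if n_shuffles <= 0:
        return ratio, score, float("nan")
    rng = np.random.default_rng(seed)
    chance = np.array([_metrics(rng.permutation(labels))[1] for _ in range(n_shuffles)])
    return ratio, score, float(chance.mean())


# ---------------------------------------------------------------------------
# Poisson-disc spatial subsampling


@dataclass
class SubsampleSpec:
    """A spatial electrode subsample and its effective pitch."""

    indices: np.ndarray
    n: int
    X_mm: float
    Y_mm: float
    r_mm: float           # final minimum-distance constraint used
    pitch_mm: float       # sqrt(X*Y/n)
    relaxations: int = 0


def poisson_disc_subsample(
    geometry: ArrayGeometry,
    n: int,
    seed: int = 0,
    factor: float = 3.5,
    max_attempts: int = 40,
    max_relaxations: int = 10,
) -> SubsampleSpec:
    """Draw ``n`` electrodes with minimum distance r = 2*sqrt(X*Y/(n*factor)).

    Dart throwing over the lattice sites: candidates are visited in random
    order and accepted when at least ``r`` from every accepted electrode.
    If ``n`` cannot be reached after ``max_attempts`` random orders, ``r``
    is relaxed by 5% (logged), up to ``max_relaxations`` times.
    """
    coords = geometry.coords_mm
    if n > len(coords):
        raise ValidationError(f"n={n} exceeds electrode count {len(coords)}")
    X, Y = geometry.extent_mm
    r = 2.0 * np.sqrt((X * Y) / (n * factor))
    pitch = float(np.sqrt(X * Y / n))
    rng = np.random.default_rng(seed)
    relax = 0
    while True:
        for _ in range(max_attempts):
            order = rng.permutation(len(coords))
            chosen: list[int] = []
            for idx in order:
                if len(chosen) == n:
                    break
                if not chosen:
                    chosen.append(idx)
                    continue
                d = np.linalg.norm(coords[chosen] - coords[idx], axis=1)
                if d.min() >= r:
                    chosen.append(idx)
            if len(chosen) == n:
                return SubsampleSpec(indices=np.sort(np.array(chosen)), n=n,
                                     X_mm=X, Y_mm=Y, r_mm=r, pitch_mm=pitch,
                                     relaxations=relax)
        relax += 1
        if relax > max_relaxations:
            raise ValidationError(
                f"cannot place {n} electrodes at min distance {r:.3f} mm")
        r *= 0.95
        warnings.warn(f"poisson disc: relaxing r to {r:.3f} mm (relaxation {relax})")


def clustering_vs_resolution(
    hg: HGEnvelopeTensor,
    geometry: ArrayGeometry,
    labels,
    fractions=(1.0, 0.5, 0.25, 0.125),
    n_samples: int = 50,
    var_frac: float = 0.8,
    embed: str = "tsne",
    perplexity: float = 30.0,
    n_shuffles: int = 0,
    seed: int = 0,
):
    """Silhouette score distributions across spatial subsampling levels.

    For each fraction of the array, ``n_samples`` Poisson-disc subsamples
    are drawn; each is reduced (SVD) and embedded (t-SNE by default, or
    the top-2 PC scores with ``embed='pca'``) before silhouette scoring.
    Returns a dict with per-fraction score arrays, the one-way ANOVA
    (F, p) across fractions, and Bonferroni-corrected pairwise t-tests.
    """
    labels = np.asarray(labels)
    rng = np.random.default_rng(seed)
    results: dict[float, np.ndarray] = {}
    for frac in fractions:
        n = max(2, int(round(frac * hg.n_electrodes)))
        scores = np.zeros(n_samples)
        for s in range(n_samples):
            sub = poisson_disc_subsample(geometry, n, seed=int(rng.integers(2**31)))
            model = svd_reduce(hg.select_electrodes(sub.indices), var_frac)
            if embed == "tsne":
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    emb = tsne_embed(model.scores, perplexity,
                                     seed=int(rng.integers(2**31)))
            elif embed == "scores":
                emb = model.scores  # all retained components, no embedding
            else:
                emb = model.scores[:, :2]
            _, scores[s], _ = silhouette_metrics(emb, labels,
                                                 n_shuffles=n_shuffles, seed=0)
        results[frac] = scores
    groups = [results[f] for f in fractions]
    if len(groups) < 2:
        return {"scores": results, "anova_F": float("nan"),
                "anova_p": float("nan"), "posthoc": {}}
    F, p = stats.f_oneway(*groups)
    pairs = {}
    n_pairs = len(list(combinations(range(len(fractions)), 2)))
    for (i, j) in combinations(range(len(fractions)), 2):
        t, pp = stats.ttest_ind(groups[i], groups[j])
        pairs[(fractions[i], fractions[j])] = (t, min(1.0, pp * n_pairs))
    return {"scores": results, "anova_F": float(F), "anova_p": float(p),
            "posthoc": pairs}
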