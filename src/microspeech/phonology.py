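"""Phonological feature vectors, Hamming distances, and the error metric.

Each of the 9 task phonemes carries a 17-component binary vector of
distinctive features in the Chomsky-Halle tradition (vocalic,
consonantal, high, back, low, anterior, coronal, round, tense, voice,
continuant, nasal, strident, sonorant, lateral, delayed release,
distributed).  The pairwise Hamming distance in bits quantifies
phonological similarity: /p/ and /b/ differ only in voicing (1 bit),
/p/ and /g/ by 5 bits, and the largest separation on this inventory is
9 bits, between /p/ and /i/.

The packaged table (``data/phonology_spe17.csv``) is a synthetic
reconstruction: individual feature assignments start from canonical
SPE-style values and were adjusted, with class-defining and vowel place
features held fixed, so that the derived distance matrix reproduces the
published pairwise properties above (including a uniform-confusion
chance error of 2.42 bits).  It is a data file, not code, so it can be
corrected without code changes.

The decoding-error metric maps a row-normalized confusion matrix C onto
distances:  e = (1/n) * sum_ij (1/2) * C_ij * D_ij  (bits), with n the
number of classes (9 for the full task).
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
from scipy import stats

from .bundle import ValidationError

__all__ = [
    "PhonologyTable", "load_phonology", "phonology_distance",
    "phoneme_error", "error_vs_distance_fit",
]

N_FEATURES = 17


@dataclass
class PhonologyTable:
    """phoneme -> 17-bit feature vector table."""

    features: pd.DataFrame  # index: phoneme, columns: 17 feature names

    def __post_init__(self):
        if self.features.shape[1] != N_FEATURES:
            raise ValidationError(
                f"feature vectors must have {N_FEATURES} components, "
                f"got {self.features.shape[1]}")
        vals = self.features.to_numpy()
        if not np.isin(vals, [0, 1]).all():
            raise ValidationError("features must be binary")

    @property
    def phonemes(self) -> list[str]:
        return list(self.features.index)

    def vector(self, phoneme: str) -> np.ndarray:
        return self.features.loc[phoneme].to_numpy()


def load_phonology() -> PhonologyTable:
    """Load the packaged 9-phoneme feature table."""
    with resources.files("microspeech.data").joinpath("phonology_spe17.csv").open() as fh:
        df = pd.read_csv(fh, index_col="phoneme")
    return PhonologyTable(df)


def phonology_distance(table: PhonologyTable | None = None) -> pd.DataFrame:
    """Pairwise Hamming distance matrix in bits (symmetric, zero diagonal)."""
    if table is None:
        table = load_phonology()
    X = table.features.to_numpy()
    D = (X[:, None, :] != X[None, :, :]).sum(axis=-1)
    return pd.DataFrame(D, index=table.phonemes, columns=table.phonemes)


def phoneme_error(C, D) -> float:
    """Mean phonological decoding error in bits.

    ``C`` is an n x n row-normalized confusion matrix (rows: true class),
    ``D`` the matching n x n distance matrix in bits.  The 1/9 prefactor
    of the 9-phoneme task generalizes to 1/n for other class counts.
    """
    C = np.asarray(C, dtype=float)
    D = np.asarray(D, dtype=float) if not isinstance(D, pd.DataFrame) else D.to_numpy(dtype=float)
    if C.shape != D.shape or C.shape[0] != C.shape[1]:
        raise ValidationError(f"shape mismatch: C {C.shape} vs D {D.shape}")
    n = C.shape[0]
    return float((0.5 * C * D).sum() / n)


def error_vs_distance_fit(C, D, n_bootstrap: int = 1000, seed: int = 0):
    """Linear fit of off-diagonal misclassification percentage on distance.

    Returns a dict with slope, intercept, the F statistic versus a
    constant model, its p-value, and a bootstrap percentile CI for the
    slope.
    """
    C = np.asarray(C, dtype=float)
    Dm = D.to_numpy(dtype=float) if isinstance(D, pd.DataFrame) else np.asarray(D, float)
    n = C.shape[0]
    off = ~np.eye(n, dtype=bool)
    y = 100.0 * C[off]
    x = Dm[off]
    if np.allclose(y, 0):
        raise ValidationError("degenerate fit: no off-diagonal misclassifications")
    fit = stats.linregress(x, y)
    # F test of the regression vs the constant model (1 regressor)
    dof = len(y) - 2
    F = fit.rvalue ** 2 / (1 - fit.rvalue ** 2 + 1e-300) * dof
    rng = np.random.default_rng(seed)
    slopes = np.empty(n_bootstrap)
    idx = np.arange(len(y))
    for b in range(n_bootstrap):
        s = rng.choice(idx, size=len(y), replace=True)
        if np.ptp(x[s]) == 0:
            slopes[b] = np.nan
            continue
        slopes[b] = stats.linregress(x[s], y[s]).slope
    ci = tuple(np.nanpercentile(slopes, [2.5, 97.5]))
    return {"slope": fit.slope, "intercept": fit.intercept,
            "F": float(F), "p": float(fit.pvalue), "slope_ci": ci}
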