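"""Encoder-decoder recurrent network for utterance-to-phoneme-sequence
decoding.

The model translates a 1 s utterance-centred high-gamma window
(trials x electrodes x 200 samples) into the 3-phoneme sequence of the
spoken non-word:

1. *Temporal convolution* — a linear (no nonlinearity) kernel of width
   50 ms applied at a 50 ms hop, i.e. a non-overlapping linear
   decomposition of each electrode's envelope into 20 frames.
2. *Encoder* — a single bi-directional LSTM layer; the final hidden and
   cell states of the forward and backward passes are averaged.
3. *Decoder* — a unidirectional LSTM initialized with the encoder state,
   fed the one-hot previous phoneme (teacher forcing during training, a
   dedicated start token at position 1), with a dense softmax head per
   position.

Training minimizes categorical cross-entropy with an L2 penalty on the
convolutional and recurrent weights, using Adam (full-batch) for a fixed
number of epochs.  Generation is greedy: the most likely phoneme at each
position becomes the input to the next.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.model_selection import KFold

from ._autodiff import Adam, Tensor, softmax_cross_entropy
from .bundle import ValidationError
from .phonology import phoneme_error
from .preprocess import HGEnvelopeTensor

__all__ = [
    "Seq2SeqConfig", "Seq2SeqClassifier", "SequencePrediction",
    "train_seq2seq", "tune_hyperparameters", "predict_sequence",
    "evaluate_sequences",
]


@dataclass
class Seq2SeqConfig:
    """Hyperparameters of the sequence decoder (defaults = study values)."""

    kernel_width_s: float = 0.05
    hop_s: float = 0.05
    n_kernels: int = 32
    n_rnn_units: int = 64
    l2_penalty: float = 1e-4
    learning_rate: float = 1e-3
    n_epochs: int = 800
    test_fraction: float = 0.2
    tuning: dict = field(default_factory=lambda: dict(
        n_combinations=200, cv_folds=10, cv_repeats=3))

    def __post_init__(self):
        if abs(self.kernel_width_s - self.hop_s) > 1e-12:
            raise ValidationError("kernel width and hop length must be equal")


@dataclass
class SequencePrediction:
    sequences: np.ndarray   # trials x seq_len, predicted phoneme labels
    proba: np.ndarray       # trials x seq_len x n_classes


def _lstm_params(in_dim, h, rng, scale=None):
    scale_w = scale or 1.0 / np.sqrt(in_dim)
    W = Tensor(rng.normal(0, scale_w, (in_dim, 4 * h)), requires_grad=True)
    U = Tensor(rng.normal(0, 1.0 / np.sqrt(h), (h, 4 * h)), requires_grad=True)
    b = np.zeros(4 * h)
    b[h:2 * h] = 1.0  # forget-gate bias
    return W, U, Tensor(b, requires_grad=True)


def _lstm_step(x, h_prev, c_prev, W, U, b, n_units):
    z = x @ W + h_prev @ U + b
    i = z.cols(0, n_units).sigmoid()
    f = z.cols(n_units, 2 * n_units).sigmoid()
    g = z.cols(2 * n_units, 3 * n_units).tanh()
    o = z.cols(3 * n_units, 4 * n_units).sigmoid()
    c = f * c_prev + i * g
    h = o * c.tanh()
    return h, c


class Seq2SeqClassifier(ClassifierMixin, BaseEstimator):
    """Sequence-to-sequence phoneme decoder (scikit-learn estimator).

    ``fit`` expects ``X`` of shape (trials, electrodes, time) — the 1 s
    utterance-centred normalized HG window at 200 Hz — and ``y`` of shape
    (trials, seq_len) with phoneme labels.  ``predict`` runs greedy
    autoregressive generation.
    """

    def __init__(self, n_kernels: int = 32, n_units: int = 64,
                 l2_penalty: float = 1e-4, learning_rate: float = 1e-3,
                 n_epochs: int = 800, kernel_width_s: float = 0.05,
                 hop_s: float = 0.05, fs_env: float = 200.0,
                 state_average: str = "both", random_state: int = 0):
        self.n_kernels = n_kernels
        self.n_units = n_units
        self.l2_penalty = l2_penalty
        self.learning_rate = learning_rate
        self.n_epochs = n_epochs
        self.kernel_width_s = kernel_width_s
        self.hop_s = hop_s
        self.fs_env = fs_env
        self.state_average = state_average
        self.random_state = random_state

    # -- plumbing ---------------------------------------------------------

    def _frames(self, X: np.ndarray) -> np.ndarray:
        """(B, E, T) -> (B, n_frames, E*width): non-overlapping windows."""
        width = int(round(self.kernel_width_s * self.fs_env))
        hop = int(round(self.hop_s * self.fs_env))
        if width != hop:
            raise ValidationError("kernel width and hop length must be equal")
        B, E, T = X.shape
        n_frames = T // width
        x = X[:, :, : n_frames * width].reshape(B, E, n_frames, width)
        return np.transpose(x, (0, 2, 1, 3)).reshape(B, n_frames, E * width)

    def _encode(self, frames_np):
        B, n_frames, _ = frames_np.shape
        H = self.n_units
        zeros = Tensor(np.zeros((B, H)))
        states = {}
        for direction, (W, U, b) in (("fwd", self.enc_fwd_), ("bwd", self.enc_bwd_)):
            order = range(n_frames) if direction == "fwd" else range(n_frames - 1, -1, -1)
            h, c = zeros, zeros
            for t in order:
                xt = Tensor(frames_np[:, t, :]) @ self.conv_W_ + self.conv_b_
                h, c = _lstm_step(xt, h, c, W, U, b, H)
            states[direction] = (h, c)
        hf, cf = states["fwd"]
        hb, cb = states["bwd"]
        h0 = (hf + hb).scale(0.5)
        if self.state_average == "both":
            c0 = (cf + cb).scale(0.5)
        else:  # hidden only; forward cell carries through
            c0 = cf
        return h0, c0

    def _decode_step(self, prev_onehot, h, c):
        x = Tensor(prev_onehot)
        h, c = _lstm_step(x, h, c, *self.dec_, self.n_units)
        logits = h @ self.out_W_ + self.out_b_
        return logits, h, c

    def _params(self):
        ps = [self.conv_W_, self.conv_b_]
        for W, U, b in (self.enc_fwd_, self.enc_bwd_, self.dec_):
            ps += [W, U, b]
        ps += [self.out_W_, self.out_b_]
        return ps

    def _l2_terms(self):
        # penalty on convolutional and recurrent weights (not the softmax head)
        ws = [self.conv_W_]
        for W, U, _ in (self.enc_fwd_, self.enc_bwd_, self.dec_):
            ws += [W, U]
        return ws

    # -- estimator API ----------------------------------------------------

    def fit(self, X, y):
        X = X.values if isinstance(X, HGEnvelopeTensor) else np.asarray(X, float)
        y = np.asarray(y)
        if y.ndim != 2:
            raise ValidationError("y must be (trials, sequence_length)")
        self.seq_len_ = y.shape[1]
        self.classes_ = np.unique(y)
        cls_index = {c: i for i, c in enumerate(self.classes_)}
        Y = np.vectorize(cls_index.get)(y)
        n_cls = len(self.classes_)
        self.start_token_ = n_cls  # extra one-hot slot fed at position 1

        frames = self._frames(X)
        B, n_frames, in_dim = frames.shape
        rng = np.random.default_rng(self.random_state)
        H, K = self.n_units, self.n_kernels
        self.conv_W_ = Tensor(rng.normal(0, 1.0 / np.sqrt(in_dim), (in_dim, K)),
                              requires_grad=True)
        self.conv_b_ = Tensor(np.zeros(K), requires_grad=True)
        self.enc_fwd_ = _lstm_params(K, H, rng)
        self.enc_bwd_ = _lstm_params(K, H, rng)
        self.dec_ = _lstm_params(n_cls + 1, H, rng)
        self.out_W_ = Tensor(rng.normal(0, 1.0 / np.sqrt(H), (H, n_cls)),
                             requires_grad=True)
        self.out_b_ = Tensor(np.zeros(n_cls), requires_grad=True)

        opt = Adam(self._params(), lr=self.learning_rate)
        eye = np.eye(n_cls + 1)
        self.loss_history_ = []
        for _ in range(self.n_epochs):
            h, c = self._encode(frames)
            loss = None
            for pos in range(self.seq_len_):
                if pos == 0:
                    prev = np.repeat(eye[[self.start_token_]], B, axis=0)
                else:  # teacher forcing: ground-truth previous phoneme
                    prev = eye[Y[:, pos - 1]]
                logits, h, c = self._decode_step(prev, h, c)
                ce = softmax_cross_entropy(logits, Y[:, pos])
                loss = ce if loss is None else loss + ce
            loss = loss.scale(1.0 / self.seq_len_)
            if self.l2_penalty > 0:
                for w in self._l2_terms():
                    loss = loss + (w * w).sum().scale(self.l2_penalty)
            loss.backward()
            opt.step()
            self.loss_history_.append(float(loss.data))
        return self

    def predict_proba(self, X) -> np.ndarray:
        X = X.values if isinstance(X, HGEnvelopeTensor) else np.asarray(X, float)
        frames = self._frames(X)
        B = frames.shape[0]
        n_cls = len(self.classes_)
        eye = np.eye(n_cls + 1)
        h, c = self._encode(frames)
        prev = np.repeat(eye[[self.start_token_]], B, axis=0)
        proba = np.zeros((B, self.seq_len_, n_cls))
        for pos in range(self.seq_len_):
            logits, h, c = self._decode_step(prev, h, c)
            z = logits.data - logits.data.max(axis=1, keepdims=True)
            p = np.exp(z)
            p /= p.sum(axis=1, keepdims=True)
            proba[:, pos, :] = p
            prev = eye[np.argmax(p, axis=1)]  # greedy feed-forward
        return proba

    def predict(self, X) -> np.ndarray:
        proba = self.predict_proba(X)
        return self.classes_[np.argmax(proba, axis=2)]


# ---------------------------------------------------------------------------
# Functional wrappers


def train_seq2seq(hg, sequences, config: Seq2SeqConfig = None,
                  seed: int = 0) -> Seq2SeqClassifier:
    """Train the encoder-decoder on utterance-aligned HG epochs."""
    config = config or Seq2SeqConfig()
    est = Seq2SeqClassifier(
        n_kernels=config.n_kernels, n_units=config.n_rnn_units,
        l2_penalty=config.l2_penalty, learning_rate=config.learning_rate,
        n_epochs=config.n_epochs, kernel_width_s=config.kernel_width_s,
        hop_s=config.hop_s, random_state=seed)
    return est.fit(hg, np.asarray(sequences))


def predict_sequence(model: Seq2SeqClassifier, hg) -> SequencePrediction:
    """Greedy autoregressive decoding of each trial's phoneme sequence."""
    proba = model.predict_proba(hg)
    seqs = model.classes_[np.argmax(proba, axis=2)]
    return SequencePrediction(sequences=seqs, proba=proba)


def tune_hyperparameters(
    hg, sequences,
    config: Seq2SeqConfig = None,
    seed: int = 0,
    kernel_range=(8, 64),
    unit_range=(16, 256),
    l2_range=(1e-5, 1e-1),
    n_epochs: int | None = None,
):
    """Random search over (n_kernels, n_rnn_units, l2_penalty).

    Scores each combination by mean per-position validation accuracy
    under repeated K-fold cross-validation on the training set only.
    Returns (best_params, trace DataFrame-like list).
    """
    import pandas as pd

    config = config or Seq2SeqConfig()
    X = hg.values if isinstance(hg, HGEnvelopeTensor) else np.asarray(hg, float)
    Y = np.asarray(sequences)
    rng = np.random.default_rng(seed)
    tcfg = config.tuning
    epochs = n_epochs if n_epochs is not None else config.n_epochs
    trace = []
    for combo in range(int(tcfg["n_combinations"])):
        params = dict(
            n_kernels=int(rng.integers(kernel_range[0], kernel_range[1] + 1)),
            n_units=int(rng.integers(unit_range[0], unit_range[1] + 1)),
            l2_penalty=float(np.exp(rng.uniform(np.log(l2_range[0]),
                                                np.log(l2_range[1])))),
        )
        accs = []
        for rep in range(int(tcfg["cv_repeats"])):
            kf = KFold(int(tcfg["cv_folds"]), shuffle=True,
                       random_state=seed * 1000 + rep)
            for tr, va in kf.split(X):
                est = Seq2SeqClassifier(
                    **params, learning_rate=config.learning_rate,
                    n_epochs=epochs, random_state=seed)
                est.fit(X[tr], Y[tr])
                accs.append(float((est.predict(X[va]) == Y[va]).mean()))
        trace.append({**params, "val_accuracy": float(np.mean(accs))})
    trace = pd.DataFrame(trace)
    best = trace.loc[trace["val_accuracy"].idxmax()]
    best_params = dict(n_kernels=int(best["n_kernels"]),
                       n_units=int(best["n_units"]),
                       l2_penalty=float(best["l2_penalty"]))
    return best_params, trace


def evaluate_sequences(predictions, truth, D) -> dict:
    """Per-position accuracy and pooled phonological error in bits.

    ``predictions``/``truth`` are (trials, seq_len) label arrays (or a
    :class:`SequencePrediction`); ``D`` is the phoneme distance matrix
    (DataFrame indexed by phoneme) used for the error metric on the
    pooled row-normalized confusion matrix.
    """
    import pandas as pd

    if isinstance(predictions, SequencePrediction):
        predictions = predictions.sequences
    pred = np.asarray(predictions)
    true = np.asarray(truth)
    if pred.shape != true.shape:
        raise ValidationError(f"shape mismatch {pred.shape} vs {true.shape}")
    per_position = (pred == true).mean(axis=0)
    classes = list(D.index) if isinstance(D, pd.DataFrame) else None
    if classes is None:
        classes = sorted(set(true.ravel()) | set(pred.ravel()))
        Dm = np.asarray(D, float)
    else:
        Dm = D.to_numpy(dtype=float)
    idx = {c: i for i, c in enumerate(classes)}
    n = len(classes)
    C = np.zeros((n, n))
    for t, p in zip(true.ravel(), pred.ravel()):
        C[idx[t], idx[p]] += 1
    row = C.sum(axis=1, keepdims=True)
    row[row == 0] = 1.0
    C = C / row
    return {
        "per_position_accuracy": per_position,
        "mean_accuracy": float(per_position.mean()),
        "phoneme_error_bits": phoneme_error(C, Dm),
        "confusion": pd.DataFrame(C, index=classes, columns=classes),
    }
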