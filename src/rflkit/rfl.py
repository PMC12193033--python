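"""Hybrid RF + LSTM transfer features (the RFL scheme).

The idea: instead of classifying raw 9-channel sensor rows directly,
first fit two base learners and reuse their *internals* as features —

* a Random Forest, whose averaged per-tree class distribution
  ``P(c|x) = (1/N) * sum_i P_i(c|x)`` gives K probabilistic features
  per row, and
* an LSTM, whose final hidden state ``h_T`` after consuming the row's
  window gives H temporal features per row.

The two blocks are column-concatenated, RF block first, into an
``n x (K + H)`` transfer-feature matrix that downstream classifiers
consume.

Reusing in-sample probabilities of the very rows a forest was trained on
leaks label information into the stacked features and inflates scores.
The transformer therefore supports two modes: ``in_sample`` (fit on all
training rows, transform them directly — the replication path) and
``out_of_fold`` (each training row's features come from extractors
fitted on the other folds — the leakage-safe evaluation default).
Held-out data is always transformed with extractors fitted on training
data only.

The LSTM is implemented natively in numpy: the standard gated cell
(forget / input / output gates, candidate state), trained by
backpropagation through time with a softmax head, Adam, and categorical
cross-entropy.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold
from sklearn.utils.validation import check_is_fitted

from .dataio import FeatureTable

__all__ = [
    "LSTMParams",
    "lstm_cell_step",
    "RFProbabilityExtractor",
    "LSTMFeatureExtractor",
    "RFLTransformer",
    "RFLConfig",
    "TransferFeatures",
    "rfl_transform",
    "fit_rf_extractor",
    "rf_probability_features",
    "fit_lstm_extractor",
    "lstm_temporal_features",
    "transfer_feature_names",
]


# ---------------------------------------------------------------------------
# LSTM cell
# ---------------------------------------------------------------------------

def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


@dataclass
class LSTMParams:
    """Parameters of one gated recurrent cell plus its softmax head.

    Gate weights act on the concatenation ``[h_prev, x_t]`` (hidden part
    first), so each ``W_*`` is ``H x (H + D)`` and each ``b_*`` is ``H``:

    * ``W_f, b_f`` — forget gate,
    * ``W_i, b_i`` — input gate,
    * ``W_C, b_C`` — candidate cell state (tanh),
    * ``W_o, b_o`` — output gate.

    The generic recurrence ``h_t = f(W_h h_{t-1} + W_x x_t + b_h)`` is
    realised by the gate block; its ``W_h``/``W_x``/``b_h`` are exposed
    as the hidden/input slices of the candidate-state weights.
    ``W_y, b_y`` form the classification head used only during training.
    """

    W_f: np.ndarray
    W_i: np.ndarray
    W_C: np.ndarray
    W_o: np.ndarray
    b_f: np.ndarray
    b_i: np.ndarray
    b_C: np.ndarray
    b_o: np.ndarray
    W_y: np.ndarray | None = None
    b_y: np.ndarray | None = None

    @property
    def hidden_size(self) -> int:
        return self.W_f.shape[0]

    @property
    def input_size(self) -> int:
        return self.W_f.shape[1] - self.W_f.shape[0]

    @property
    def W_h(self) -> np.ndarray:
        return self.W_C[:, : self.hidden_size]

    @property
    def W_x(self) -> np.ndarray:
        return self.W_C[:, self.hidden_size:]

    @property
    def b_h(self) -> np.ndarray:
        return self.b_C

    @classmethod
    def initialize(cls, input_size: int, hidden_size: int, n_classes: int,
                   rng: np.random.Generator) -> "LSTMParams":
        """Uniform(-k, k) init with k = 1/sqrt(H), the standard recipe."""
        k = 1.0 / np.sqrt(hidden_size) if hidden_size > 0 else 0.0

        def u(*shape):
            return rng.uniform(-k, k, size=shape)

        hd = hidden_size + input_size
        return cls(
            W_f=u(hidden_size, hd), W_i=u(hidden_size, hd),
            W_C=u(hidden_size, hd), W_o=u(hidden_size, hd),
            b_f=u(hidden_size), b_i=u(hidden_size),
            b_C=u(hidden_size), b_o=u(hidden_size),
            W_y=u(n_classes, hidden_size), b_y=u(n_classes),
        )


def lstm_cell_step(
    x_t: np.ndarray,
    h_prev: np.ndarray,
    c_prev: np.ndarray,
    params: LSTMParams,
) -> tuple[np.ndarray, np.ndarray]:
    """One application of the gated cell; pure function of its inputs.

    Implements, with ``z = [h_prev, x_t]``::

        f_t = sigmoid(W_f @ z + b_f)
        i_t = sigmoid(W_i @ z + b_i)
        g_t = tanh   (W_C @ z + b_C)          # candidate cell state
        c_t = f_t * c_prev + i_t * g_t
        o_t = sigmoid(W_o @ z + b_o)
        h_t = o_t * tanh(c_t)

    Returns ``(h_t, c_t)``.
    """
    x_t = np.asarray(x_t, dtype=float)
    h_prev = np.asarray(h_prev, dtype=float)
    c_prev = np.asarray(c_prev, dtype=float)
    H = params.hidden_size
    if x_t.shape != (params.input_size,):
        raise ValueError(
            f"x_t must have shape ({params.input_size},), got {x_t.shape}"
        )
    if h_prev.shape != (H,) or c_prev.shape != (H,):
        raise ValueError(f"h_prev and c_prev must have shape ({H},)")
    z = np.concatenate([h_prev, x_t])
    f = _sigmoid(params.W_f @ z + params.b_f)
    i = _sigmoid(params.W_i @ z + params.b_i)
    g = np.tanh(params.W_C @ z + params.b_C)
    c_t = f * c_prev + i * g
    o = _sigmoid(params.W_o @ z + params.b_o)
    h_t = o * np.tanh(c_t)
    return h_t, c_t


# ---------------------------------------------------------------------------
# RF probability extractor
# ---------------------------------------------------------------------------

class RFProbabilityExtractor(TransformerMixin, BaseEstimator):
    """Random-Forest probabilistic feature extractor.

    ``transform`` returns, for each row, the forest's averaged per-tree
    class distribution ``(1/N) * sum_i P_i(c|x)`` — K probability
    features whose rows sum to 1.  Defaults follow the tuned forest of
    the reference study: 10 trees, depth cap 10, entropy splits, seed 0.
    """

    def __init__(self, n_estimators: int = 10, max_depth: int | None = 10,
                 criterion: str = "entropy", random_state: int = 0):
        self.n_estimators = n_estimators
        self.max_depth = max_depth
        self.criterion = criterion
        self.random_state = random_state

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if X.shape[0] == 0:
            raise ValueError("cannot fit on an empty matrix")
        if len(np.unique(y)) < 2:
            raise ValueError("need at least 2 classes to fit the forest")
        self.forest_ = RandomForestClassifier(
            n_estimators=self.n_estimators,
            max_depth=self.max_depth,
            criterion=self.criterion,
            random_state=self.random_state,
        )
        self.forest_.fit(X, y)
        self.classes_ = self.forest_.classes_
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X) -> np.ndarray:
        check_is_fitted(self, "forest_")
        X = np.asarray(X, dtype=float)
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"X has {X.shape[1]} features, extractor was fitted with "
                f"{self.n_features_in_}"
            )
        return self.forest_.predict_proba(X)


# ---------------------------------------------------------------------------
# LSTM temporal-feature extractor
# ---------------------------------------------------------------------------

def _build_windows(X: np.ndarray, window_len: int) -> np.ndarray:
    """Stack each row with its ``window_len - 1`` predecessors.

    The table's row order is treated as one time sequence; windows at the
    start are edge-padded by repeating the first row.  Returns an
    ``(n, window_len, d)`` array.
    """
    n = X.shape[0]
    idx = np.arange(n)[:, None] + np.arange(-(window_len - 1), 1)[None, :]
    return X[np.clip(idx, 0, n - 1)]


class LSTMFeatureExtractor(TransformerMixin, BaseEstimator):
    """Temporal-feature extractor: the final hidden state of a trained LSTM.

    A single-layer gated recurrent cell plus a softmax head is trained on
    length-``window_len`` windows (supervision = the window's final-row
    label) with Adam on categorical cross-entropy.  ``transform`` runs the
    recurrence from the zero state over each row's window and returns the
    final hidden state ``h_T`` as that row's ``hidden_size`` features; the
    head is discarded at transform time.

    Training is seeded and deterministic for a given platform/BLAS;
    bit-identical results across platforms are not guaranteed.
    """

    def __init__(self, hidden_size: int = 32, window_len: int = 1,
                 epochs: int = 10, batch_size: int = 256,
                 learning_rate: float = 0.01, random_state: int = 0):
        self.hidden_size = hidden_size
        self.window_len = window_len
        self.epochs = epochs
        self.batch_size = batch_size
        self.learning_rate = learning_rate
        self.random_state = random_state

    # -- forward/backward over a batch of windows --------------------------

    def _forward(self, windows: np.ndarray, params: LSTMParams):
        """Batched recurrence from the zero state; returns h_T and a tape."""
        B, T, D = windows.shape
        H = params.hidden_size
        h = np.zeros((B, H))
        c = np.zeros((B, H))
        tape = []
        for t in range(T):
            z = np.concatenate([h, windows[:, t, :]], axis=1)
            f = _sigmoid(z @ params.W_f.T + params.b_f)
            i = _sigmoid(z @ params.W_i.T + params.b_i)
            g = np.tanh(z @ params.W_C.T + params.b_C)
            o = _sigmoid(z @ params.W_o.T + params.b_o)
            c_new = f * c + i * g
            h_new = o * np.tanh(c_new)
            tape.append((z, f, i, g, o, c, c_new))
            h, c = h_new, c_new
        return h, tape

    def _backward(self, dh_T: np.ndarray, tape, params: LSTMParams) -> dict:
        """BPTT from a gradient on the final hidden state."""
        H = params.hidden_size
        grads = {name: np.zeros_like(getattr(params, name))
                 for name in ("W_f", "W_i", "W_C", "W_o", "b_f", "b_i", "b_C", "b_o")}
        dh = dh_T
        dc = np.zeros_like(dh_T)
        for z, f, i, g, o, c_prev, c_new in reversed(tape):
            tc = np.tanh(c_new)
            do = dh * tc
            dc = dc + dh * o * (1.0 - tc * tc)
            df = dc * c_prev
            di = dc * g
            dg = dc * i
            dc_prev = dc * f
            dzf = df * f * (1.0 - f)
            dzi = di * i * (1.0 - i)
            dzg = dg * (1.0 - g * g)
            dzo = do * o * (1.0 - o)
            grads["W_f"] += dzf.T @ z
            grads["W_i"] += dzi.T @ z
            grads["W_C"] += dzg.T @ z
            grads["W_o"] += dzo.T @ z
            grads["b_f"] += dzf.sum(axis=0)
            grads["b_i"] += dzi.sum(axis=0)
            grads["b_C"] += dzg.sum(axis=0)
            grads["b_o"] += dzo.sum(axis=0)
            dz = (dzf @ params.W_f + dzi @ params.W_i
                  + dzg @ params.W_C + dzo @ params.W_o)
            dh = dz[:, :H]
            dc = dc_prev
        return grads

    # -- training -----------------------------------------------------------

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        n = X.shape[0]
        if n == 0:
            raise ValueError("cannot fit on an empty matrix")
        if self.window_len < 1:
            raise ValueError("window_len must be >= 1")
        if self.window_len > n:
            raise ValueError(
                f"window_len={self.window_len} exceeds the {n} available "
                "contiguous rows"
            )
        rng = np.random.default_rng(self.random_state)
        self.classes_ = np.unique(y)
        K = len(self.classes_)
        class_index = {c: j for j, c in enumerate(self.classes_)}
        y_idx = np.array([class_index[v] for v in y])
        self.n_features_in_ = X.shape[1]
        H = self.hidden_size
        params = LSTMParams.initialize(X.shape[1], H, K, rng)
        self.loss_history_ = []

        if self.epochs > 0 and H > 0:
            windows = _build_windows(X, self.window_len)
            adam_m = {k: np.zeros_like(getattr(params, k)) for k in
                      ("W_f", "W_i", "W_C", "W_o", "b_f", "b_i", "b_C", "b_o",
                       "W_y", "b_y")}
            adam_v = {k: np.zeros_like(v) for k, v in adam_m.items()}
            step = 0
            beta1, beta2, eps = 0.9, 0.999, 1e-8
            for _ in range(self.epochs):
                order = rng.permutation(n)
                epoch_loss = 0.0
                for start in range(0, n, self.batch_size):
                    batch = order[start: start + self.batch_size]
                    B = len(batch)
                    h_T, tape = self._forward(windows[batch], params)
                    logits = h_T @ params.W_y.T + params.b_y
                    logits -= logits.max(axis=1, keepdims=True)
                    p = np.exp(logits)
                    p /= p.sum(axis=1, keepdims=True)
                    onehot = np.zeros_like(p)
                    onehot[np.arange(B), y_idx[batch]] = 1.0
                    epoch_loss += -np.sum(
                        np.log(p[np.arange(B), y_idx[batch]] + 1e-12))
                    dlogits = (p - onehot) / B
                    grads = self._backward(dlogits @ params.W_y, tape, params)
                    grads["W_y"] = dlogits.T @ h_T
                    grads["b_y"] = dlogits.sum(axis=0)
                    step += 1
                    for name, grad in grads.items():
                        adam_m[name] = beta1 * adam_m[name] + (1 - beta1) * grad
                        adam_v[name] = beta2 * adam_v[name] + (1 - beta2) * grad ** 2
                        m_hat = adam_m[name] / (1 - beta1 ** step)
                        v_hat = adam_v[name] / (1 - beta2 ** step)
                        setattr(params, name, getattr(params, name)
                                - self.learning_rate * m_hat / (np.sqrt(v_hat) + eps))
                self.loss_history_.append(epoch_loss / n)

        self.params_ = params
        return self

    def transform(self, X) -> np.ndarray:
        check_is_fitted(self, "params_")
        X = np.asarray(X, dtype=float)
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"X has {X.shape[1]} features, extractor was fitted with "
                f"{self.n_features_in_}"
            )
        if X.shape[0] == 0:
            return np.zeros((0, self.hidden_size))
        windows = _build_windows(X, self.window_len)
        h_T, _ = self._forward(windows, self.params_)
        return h_T

    def head_predict_proba(self, X) -> np.ndarray:
        """Class probabilities from the training head (diagnostics only)."""
        check_is_fitted(self, "params_")
        h_T = self.transform(X)
        logits = h_T @ self.params_.W_y.T + self.params_.b_y
        logits -= logits.max(axis=1, keepdims=True)
        p = np.exp(logits)
        return p / p.sum(axis=1, keepdims=True)

    def head_accuracy(self, X, y) -> float:
        p = self.head_predict_proba(X)
        pred = self.classes_[np.argmax(p, axis=1)]
        return float(np.mean(pred == np.asarray(y)))


# ---------------------------------------------------------------------------
# The combined RFL transformer
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RFLConfig:
    """Settings for the combined transfer-feature transform."""

    n_estimators: int = 10
    max_depth: int | None = 10
    criterion: str = "entropy"
    hidden_size: int = 32
    window_len: int = 1
    epochs: int = 10
    batch_size: int = 256
    learning_rate: float = 0.01
    mode: str = "out_of_fold"
    oof_folds: int = 5
    seed: int = 0


def transfer_feature_names(n_classes: int, hidden_size: int) -> list[str]:
    """Column names encoding roles: rf_p0..rf_p{K-1}, lstm_h0..lstm_h{H-1}."""
    return [f"rf_p{c}" for c in range(n_classes)] + [
        f"lstm_h{j}" for j in range(hidden_size)
    ]


@dataclass
class TransferFeatures:
    """n x (K + H) transfer-feature matrix with column-role bookkeeping."""

    matrix: np.ndarray
    n_classes: int
    hidden_size: int
    mode: str

    @property
    def column_names(self) -> list[str]:
        return transfer_feature_names(self.n_classes, self.hidden_size)

    @property
    def rf_block(self) -> np.ndarray:
        return self.matrix[:, : self.n_classes]

    @property
    def lstm_block(self) -> np.ndarray:
        return self.matrix[:, self.n_classes:]


class RFLTransformer(TransformerMixin, BaseEstimator):
    """Concatenated RF-probability + LSTM-hidden-state transfer features.

    ``fit`` trains the extractors on the training data; ``transform``
    applies them to any matrix (the path for held-out data — it never sees
    labels).  ``fit_transform`` on the training data honours ``mode``:

    * ``"in_sample"``: features of training rows come from extractors
      fitted on all of the training data (replicates the original scheme;
      leaks into stacking),
    * ``"out_of_fold"``: each training row's features come from extractors
      fitted on the other stratified folds (leakage-safe default).  In
      this mode ``transform`` averages the fold extractors' outputs — the
      stacked-generalisation convention — so held-out features follow the
      same distribution the downstream model was trained on.  All fold
      extractors share one configuration and seed.

    ``hidden_size=0`` disables the LSTM block, leaving pure RF
    probabilities.  Column order is fixed: RF block then LSTM block.
    """

    def __init__(self, n_estimators: int = 10, max_depth: int | None = 10,
                 criterion: str = "entropy", hidden_size: int = 32,
                 window_len: int = 1, epochs: int = 10, batch_size: int = 256,
                 learning_rate: float = 0.01, mode: str = "out_of_fold",
                 oof_folds: int = 5, random_state: int = 0):
        self.n_estimators = n_estimators
        self.max_depth = max_depth
        self.criterion = criterion
        self.hidden_size = hidden_size
        self.window_len = window_len
        self.epochs = epochs
        self.batch_size = batch_size
        self.learning_rate = learning_rate
        self.mode = mode
        self.oof_folds = oof_folds
        self.random_state = random_state

    def _make_extractors(self, random_state: int):
        rf = RFProbabilityExtractor(
            n_estimators=self.n_estimators, max_depth=self.max_depth,
            criterion=self.criterion, random_state=random_state,
        )
        lstm = None
        if self.hidden_size > 0:
            lstm = LSTMFeatureExtractor(
                hidden_size=self.hidden_size, window_len=self.window_len,
                epochs=self.epochs, batch_size=self.batch_size,
                learning_rate=self.learning_rate, random_state=random_state,
            )
        return rf, lstm

    def fit(self, X, y):
        if self.mode not in ("in_sample", "out_of_fold"):
            raise ValueError(f"unknown mode {self.mode!r}")
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        self.rf_, self.lstm_ = self._make_extractors(self.random_state)
        self.rf_.fit(X, y)
        if self.lstm_ is not None:
            self.lstm_.fit(X, y)
        self.classes_ = self.rf_.classes_
        self.n_features_in_ = X.shape[1]
        if self.mode == "out_of_fold":
            self._fit_fold_extractors(X, y)
        else:
            self.fold_extractors_ = None
        return self

    def _fit_fold_extractors(self, X: np.ndarray, y: np.ndarray) -> None:
        # every fold re-uses the full-fit configuration and seed so all
        # extractors start from the same initialisation and learn aligned
        # representations (matters for the LSTM hidden-state block)
        skf = StratifiedKFold(
            n_splits=self.oof_folds, shuffle=True, random_state=self.random_state
        )
        self.fold_extractors_ = []
        self._fold_held_indices_ = []
        for fit_idx, held_idx in skf.split(X, y):
            rf, lstm = self._make_extractors(self.random_state)
            rf.fit(X[fit_idx], y[fit_idx])
            if lstm is not None:
                lstm.fit(X[fit_idx], y[fit_idx])
            self.fold_extractors_.append((rf, lstm))
            self._fold_held_indices_.append(held_idx)

    def _apply(self, rf, lstm, X: np.ndarray) -> np.ndarray:
        K = len(self.classes_)
        width = K + (self.hidden_size if self.lstm_ is not None else 0)
        out = np.zeros((X.shape[0], width))
        # map fold-local class order onto the global one; classes absent
        # from a fold's training part get probability 0
        local = rf.transform(X)
        class_col = {c: j for j, c in enumerate(self.classes_)}
        for j, c in enumerate(rf.classes_):
            out[:, class_col[c]] = local[:, j]
        if lstm is not None:
            out[:, K:] = lstm.transform(X)
        return out

    def transform(self, X) -> np.ndarray:
        """Label-free application to new data (the held-out path).

        In ``in_sample`` mode this is the full-fit extractors; in
        ``out_of_fold`` mode it is the average of the fold extractors'
        outputs (the probability block remains row-normalised since it
        averages distributions).
        """
        check_is_fitted(self, "rf_")
        X = np.asarray(X, dtype=float)
        if self.fold_extractors_ is None:
            return self._apply(self.rf_, self.lstm_, X)
        return np.mean(
            [self._apply(rf, lstm, X) for rf, lstm in self.fold_extractors_],
            axis=0,
        )

    def fit_transform(self, X, y=None, **fit_params):
        if y is None:
            raise ValueError("y is required to fit the transfer extractors")
        self.fit(X, y)
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if self.mode == "in_sample":
            return self.transform(X)
        K = len(self.classes_)
        width = K + (self.hidden_size if self.lstm_ is not None else 0)
        out = np.empty((X.shape[0], width))
        for (rf, lstm), held_idx in zip(self.fold_extractors_,
                                        self._fold_held_indices_):
            out[held_idx] = self._apply(rf, lstm, X[held_idx])
        return out


# ---------------------------------------------------------------------------
# Thin operation-style wrappers over the estimators
# ---------------------------------------------------------------------------

def fit_rf_extractor(train: FeatureTable, n_trees: int = 10,
                     max_depth: int | None = 10, criterion: str = "entropy",
                     seed: int = 0) -> RFProbabilityExtractor:
    return RFProbabilityExtractor(
        n_estimators=n_trees, max_depth=max_depth, criterion=criterion,
        random_state=seed,
    ).fit(train.features, train.labels)


def rf_probability_features(extractor: RFProbabilityExtractor,
                            X: FeatureTable) -> np.ndarray:
    return extractor.transform(X.features)


def fit_lstm_extractor(train: FeatureTable, hidden_size: int = 32,
                       window_len: int = 1, epochs: int = 10,
                       seed: int = 0) -> LSTMFeatureExtractor:
    return LSTMFeatureExtractor(
        hidden_size=hidden_size, window_len=window_len, epochs=epochs,
        random_state=seed,
    ).fit(train.features, train.labels)


def lstm_temporal_features(extractor: LSTMFeatureExtractor,
                           X: FeatureTable) -> np.ndarray:
    return extractor.transform(X.features)


def rfl_transform(train: FeatureTable, X: FeatureTable,
                  config: RFLConfig | None = None,
                  mode: str | None = None,
                  oof_folds: int | None = None) -> TransferFeatures:
    """Compute the combined transfer-feature matrix for ``X``.

    ``mode="in_sample"`` fits on all of ``train`` and applies to ``X``.
    ``mode="out_of_fold"`` is defined only when ``X`` is the training
    table itself; each row then gets features from extractors fitted on
    the complementary folds.
    """
    config = config or RFLConfig()
    mode = mode if mode is not None else config.mode
    oof_folds = oof_folds if oof_folds is not None else config.oof_folds
    est = RFLTransformer(
        n_estimators=config.n_estimators, max_depth=config.max_depth,
        criterion=config.criterion, hidden_size=config.hidden_size,
        window_len=config.window_len, epochs=config.epochs,
        batch_size=config.batch_size, learning_rate=config.learning_rate,
        mode=mode, oof_folds=oof_folds, random_state=config.seed,
    )
    if mode == "out_of_fold":
        same = (X is train) or (
            X.features.shape == train.features.shape
            and np.array_equal(X.features, train.features)
            and np.array_equal(X.labels, train.labels)
        )
        if not same:
            raise ValueError(
                "out_of_fold features are defined only for the training "
                "table itself; pass mode='in_sample' for other matrices"
            )
        matrix = est.fit_transform(train.features, train.labels)
    else:
        est.fit(train.features, train.labels)
        matrix = est.transform(X.features)
    return TransferFeatures(
        matrix=matrix,
        n_classes=len(est.classes_),
        hidden_size=config.hidden_size,
        mode=mode,
    )
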