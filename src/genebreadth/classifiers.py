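"""Binary classification engines: a from-scratch LSTM and a random forest.

The LSTM treats each gene's enrichment-score vector as a short sequence of
fixed-size chunks (the vector is split into ``ceil(d / chunk_size)`` pieces,
the last zero-padded).  The forward pass follows the standard gate equations

    f_t = sigmoid(W_f x_t + U_f h_{t-1} + b_f)
    i_t = sigmoid(W_i x_t + U_i h_{t-1} + b_i)
    c_t = f_t * c_{t-1} + i_t * tanh(W_c x_t + U_c h_{t-1} + b_c)
    o_t = sigmoid(W_o x_t + U_o h_{t-1} + b_o)
    h_t = o_t * tanh(c_t)

with h_0 = c_0 = 0, and a linear readout maps h_T to a single logit.
Training is full-batch Adam on binary cross-entropy, which keeps the whole
fit deterministic given the seed.  The random-forest engine wraps
scikit-learn and is used as the fast comparison engine.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.ensemble import RandomForestClassifier

from .errors import DomainError
from .enrichment import FeatureMatrix

ENGINES = ("lstm", "random_forest")

LSTM_DEFAULTS = {
    "hidden_dim": 16,
    "chunk_size": 32,
    "epochs": 200,
    "learning_rate": 0.02,
    "init_scale": None,   # default 1/sqrt(fan_in)
}
RF_DEFAULTS = {"n_estimators": 100}


@dataclass(frozen=True)
class ClassifierSpec:
    """Engine choice plus hyperparameters; the seed is mandatory."""

    engine: str
    seed: int
    hyperparameters: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.engine not in ENGINES:
            raise DomainError(f"unknown engine {self.engine!r}; use {ENGINES}")
        if self.seed is None:
            raise DomainError("a seed is mandatory")

    def resolved(self) -> dict:
        base = dict(LSTM_DEFAULTS if self.engine == "lstm" else RF_DEFAULTS)
        unknown = set(self.hyperparameters) - set(base)
        if unknown:
            raise DomainError(f"unknown hyperparameters for {self.engine}: "
                              f"{sorted(unknown)}")
        base.update(self.hyperparameters)
        return base


@dataclass
class LstmParams:
    """All trainable LSTM parameters (gate weights, biases, readout)."""

    W_f: np.ndarray
    W_i: np.ndarray
    W_c: np.ndarray
    W_o: np.ndarray
    U_f: np.ndarray
    U_i: np.ndarray
    U_c: np.ndarray
    U_o: np.ndarray
    b_f: np.ndarray
    b_i: np.ndarray
    b_c: np.ndarray
    b_o: np.ndarray
    readout_w: np.ndarray
    readout_b: float
    hidden_dim: int
    chunk_size: int

    def __post_init__(self) -> None:
        h, d = self.hidden_dim, self.chunk_size
        for name in ("W_f", "W_i", "W_c", "W_o"):
            if getattr(self, name).shape != (h, d):
                raise DomainError(f"{name} must have shape ({h}, {d})")
        for name in ("U_f", "U_i", "U_c", "U_o"):
            if getattr(self, name).shape != (h, h):
                raise DomainError(f"{name} must have shape ({h}, {h})")
        for name in ("b_f", "b_i", "b_c", "b_o", "readout_w"):
            if getattr(self, name).shape != (h,):
                raise DomainError(f"{name} must have shape ({h},)")
        for name in ("W_f", "W_i", "W_c", "W_o", "U_f", "U_i", "U_c", "U_o",
                     "b_f", "b_i", "b_c", "b_o", "readout_w"):
            if not np.all(np.isfinite(getattr(self, name))):
                raise DomainError(f"{name} contains non-finite values")

    @classmethod
    def init(cls, hidden_dim: int, chunk_size: int, rng: np.random.Generator,
             scale: float | None = None) -> "LstmParams":
        def w(shape, fan_in):
            s = scale if scale is not None else 1.0 / np.sqrt(fan_in)
            return rng.normal(0.0, s, size=shape)

        h, d = hidden_dim, chunk_size
        return cls(
            W_f=w((h, d), d), W_i=w((h, d), d), W_c=w((h, d), d),
            W_o=w((h, d), d),
            U_f=w((h, h), h), U_i=w((h, h), h), U_c=w((h, h), h),
            U_o=w((h, h), h),
            b_f=np.ones(h), b_i=np.zeros(h), b_c=np.zeros(h), b_o=np.zeros(h),
            readout_w=w((h,), h), readout_b=0.0,
            hidden_dim=h, chunk_size=d)

    def flat(self) -> list[np.ndarray]:
        return [self.W_f, self.W_i, self.W_c, self.W_o,
                self.U_f, self.U_i, self.U_c, self.U_o,
                self.b_f, self.b_i, self.b_c, self.b_o,
                self.readout_w, np.atleast_1d(np.float64(self.readout_b))]


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def vector_to_sequence(x: Sequence[float], chunk_size: int) -> np.ndarray:
    """Split a feature vector into a (T, chunk_size) sequence, zero-padded.

    Concatenating the chunks and trimming the padding recovers the vector.
    """
    x = np.asarray(x, dtype=float).ravel()
    if x.size == 0:
        raise DomainError("empty feature vector")
    if chunk_size < 1:
        raise DomainError("chunk_size must be >= 1")
    t = -(-x.size // chunk_size)
    padded = np.zeros(t * chunk_size)
    padded[: x.size] = x
    return padded.reshape(t, chunk_size)


def lstm_forward(params: LstmParams, sequence: np.ndarray) -> np.ndarray:
    """Run the gate recursions over one sequence and return h_T."""
    sequence = np.asarray(sequence, dtype=float)
    if sequence.ndim != 2 or sequence.shape[1] != params.chunk_size:
        raise DomainError(
            f"sequence must be (T, {params.chunk_size}); got {sequence.shape}")
    h = np.zeros(params.hidden_dim)
    c = np.zeros(params.hidden_dim)
    for x_t in sequence:
        f = _sigmoid(params.W_f @ x_t + params.U_f @ h + params.b_f)
        i = _sigmoid(params.W_i @ x_t + params.U_i @ h + params.b_i)
        g = np.tanh(params.W_c @ x_t + params.U_c @ h + params.b_c)
        o = _sigmoid(params.W_o @ x_t + params.U_o @ h + params.b_o)
        c = f * c + i * g
        h = o * np.tanh(c)
    return h


class LstmClassifier:
    """LSTM binary classifier trained by full-batch Adam on cross-entropy."""

    def __init__(self, hidden_dim: int = 16, chunk_size: int = 32,
                 epochs: int = 200, learning_rate: float = 0.02,
                 init_scale: float | None = None, seed: int = 0) -> None:
        self.hidden_dim = hidden_dim
        self.chunk_size = chunk_size
        self.epochs = epochs
        self.learning_rate = learning_rate
        self.init_scale = init_scale
        self.seed = seed
        self.params: LstmParams | None = None

    # -- batched forward with caches -------------------------------------
    def _forward_batch(self, seq: np.ndarray):
        p = self.params
        B, T, _ = seq.shape
        H = p.hidden_dim
        h = np.zeros((B, H))
        c = np.zeros((B, H))
        cache = []
        for t in range(T):
            x = seq[:, t, :]
            f = _sigmoid(x @ p.W_f.T + h @ p.U_f.T + p.b_f)
            i = _sigmoid(x @ p.W_i.T + h @ p.U_i.T + p.b_i)
            g = np.tanh(x @ p.W_c.T + h @ p.U_c.T + p.b_c)
            o = _sigmoid(x @ p.W_o.T + h @ p.U_o.T + p.b_o)
            c_new = f * c + i * g
            tc = np.tanh(c_new)
            h_new = o * tc
            cache.append((x, h, c, f, i, g, o, tc))
            h, c = h_new, c_new
        return h, cache

    def _backward_batch(self, dh_T: np.ndarray, cache: list) -> dict:
        p = self.params
        grads = {k: np.zeros_like(getattr(p, k)) for k in
                 ("W_f", "W_i", "W_c", "W_o", "U_f", "U_i", "U_c", "U_o",
                  "b_f", "b_i", "b_c", "b_o")}
        dh = dh_T
        dc = np.zeros_like(dh_T)
        for x, h_prev, c_prev, f, i, g, o, tc in reversed(cache):
            do = dh * tc
            dc = dc + dh * o * (1.0 - tc ** 2)
            df = dc * c_prev
            di = dc * g
            dg = dc * i
            dc_prev = dc * f
            dz_o = do * o * (1.0 - o)
            dz_f = df * f * (1.0 - f)
            dz_i = di * i * (1.0 - i)
            dz_g = dg * (1.0 - g ** 2)
            for name, dz in (("f", dz_f), ("i", dz_i), ("c", dz_g),
                             ("o", dz_o)):
                grads[f"W_{name}"] += dz.T @ x
                grads[f"U_{name}"] += dz.T @ h_prev
                grads[f"b_{name}"] += dz.sum(axis=0)
            dh = (dz_f @ p.U_f + dz_i @ p.U_i + dz_g @ p.U_c + dz_o @ p.U_o)
            dc = dc_prev
        return grads

    def fit(self, X: np.ndarray, y: np.ndarray) -> "LstmClassifier":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        rng = np.random.default_rng(self.seed)
        self.params = LstmParams.init(self.hidden_dim, self.chunk_size, rng,
                                      self.init_scale)
        # column scaling keeps gate pre-activations in a sane range
        self._mu = X.mean(axis=0)
        self._sd = X.std(axis=0)
        self._sd[self._sd == 0] = 1.0
        Xs = (X - self._mu) / self._sd
        seq = np.stack([vector_to_sequence(row, self.chunk_size) for row in Xs])

        p = self.params
        names = ("W_f", "W_i", "W_c", "W_o", "U_f", "U_i", "U_c", "U_o",
                 "b_f", "b_i", "b_c", "b_o", "readout_w", "readout_b")
        m = {k: np.zeros_like(np.atleast_1d(getattr(p, k)), dtype=float)
             for k in names}
        v = {k: np.zeros_like(np.atleast_1d(getattr(p, k)), dtype=float)
             for k in names}
        b1, b2, eps = 0.9, 0.999, 1e-8
        B = X.shape[0]
        for step in range(1, self.epochs + 1):
            h_T, cache = self._forward_batch(seq)
            logits = h_T @ p.readout_w + p.readout_b
            prob = _sigmoid(logits)
            dlogit = (prob - y) / B                       # dBCE/dlogit
            grads = self._backward_batch(np.outer(dlogit, p.readout_w), cache)
            grads["readout_w"] = h_T.T @ dlogit
            grads["readout_b"] = np.atleast_1d(dlogit.sum())
            for k in names:
                g = np.atleast_1d(grads[k])
                m[k] = b1 * m[k] + (1 - b1) * g
                v[k] = b2 * v[k] + (1 - b2) * g ** 2
                mhat = m[k] / (1 - b1 ** step)
                vhat = v[k] / (1 - b2 ** step)
                upd = self.learning_rate * mhat / (np.sqrt(vhat) + eps)
                if k == "readout_b":
                    p.readout_b = float(p.readout_b - upd[0])
                else:
                    setattr(p, k, getattr(p, k) - upd.reshape(
                        getattr(p, k).shape))
        return self

    def decision_function(self, X: np.ndarray) -> np.ndarray:
        if self.params is None:
            raise DomainError("classifier is not fitted")
        Xs = (np.asarray(X, dtype=float) - self._mu) / self._sd
        seq = np.stack([vector_to_sequence(row, self.chunk_size) for row in Xs])
        h_T, _ = self._forward_batch(seq)
        return h_T @ self.params.readout_w + self.params.readout_b

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        return _sigmoid(self.decision_function(X))

    def predict(self, X: np.ndarray) -> np.ndarray:
        # logit exactly 0 counts as positive (documented tie rule)
        return (self.decision_function(X) >= 0.0).astype(int)


@dataclass
class TrainedClassifier:
    """A fitted engine bound to the exact feature columns it was trained on."""

    spec: ClassifierSpec
    model: object
    feature_ids: tuple[str, ...] | None

    def save(self, path) -> None:
        import joblib

        joblib.dump({"format_version": 1, "spec": self.spec,
                     "model": self.model, "feature_ids": self.feature_ids},
                    path)

    @classmethod
    def load(cls, path) -> "TrainedClassifier":
        import joblib

        blob = joblib.load(path)
        if blob.get("format_version") != 1:
            raise DomainError("unsupported model container version")
        return cls(blob["spec"], blob["model"], blob["feature_ids"])


def _as_array(X, feature_ids_expected: tuple[str, ...] | None):
    if isinstance(X, FeatureMatrix):
        if (feature_ids_expected is not None
                and X.feature_ids != feature_ids_expected):
            missing = set(feature_ids_expected) - set(X.feature_ids)
            extra = set(X.feature_ids) - set(feature_ids_expected)
            raise DomainError(
                f"feature columns mismatch; missing={sorted(missing)[:5]}, "
                f"extra={sorted(extra)[:5]}")
        return X.scores, X.feature_ids
    return np.asarray(X, dtype=float), None


def train(spec: ClassifierSpec, X, y) -> TrainedClassifier:
    """Fit the engine named by ``spec`` on (X, y); deterministic given the seed."""
    Xa, feature_ids = _as_array(X, None)
    y = np.asarray(y)
    if Xa.ndim != 2 or Xa.shape[0] != y.shape[0]:
        raise DomainError("X rows must align with y")
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise DomainError("training labels contain a single class")
    if counts.min() < 2:
        raise DomainError("need at least 2 samples of each class")
    hp = spec.resolved()
    if spec.engine == "lstm":
        model = LstmClassifier(seed=spec.seed, **hp).fit(Xa, y)
    else:
        model = RandomForestClassifier(random_state=spec.seed, n_jobs=1,
                                       **hp).fit(Xa, y)
    return TrainedClassifier(spec, model, feature_ids)


def predict(clf: TrainedClassifier, X) -> np.ndarray:
    """Predict 0/1 labels; column identity is checked for FeatureMatrix input."""
    Xa, _ = _as_array(X, clf.feature_ids)
    n_in = (clf.model.n_features_in_
            if isinstance(clf.model, RandomForestClassifier)
            else clf.model._mu.size)
    if Xa.shape[1] != n_in:
        raise DomainError(
            f"expected {n_in} feature columns, got {Xa.shape[1]}")
    return np.asarray(clf.model.predict(Xa), dtype=int)
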