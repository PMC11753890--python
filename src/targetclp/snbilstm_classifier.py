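"""Self-normalizing bidirectional LSTM classifier (SnBiLSTM), in NumPy.

A fixed-length feature vector is chunked into timesteps (zero-padded tail),
encoded by a recurrent network, and classified by a dense head ending in a
sigmoid unit trained with binary cross-entropy.  "Self-normalizing" means
the dense head uses SELU activations with their paired alpha-dropout and
LeCun-normal initialization, which keeps activations near zero mean / unit
variance without batch normalization; the recurrent cells stay standard.

Baseline variants share the train/predict contract and are selected with the
``variant`` parameter:

* ``snbilstm`` — bidirectional LSTM encoder, SELU dense head (default);
* ``bilstm``   — bidirectional LSTM encoder, ReLU dense head;
* ``lstm`` / ``gru`` — unidirectional recurrent encoders, ReLU head;
* ``cnn``      — 1-D convolution (kernel 3) over timesteps with global max
  pooling, ReLU head.

Training uses decoupled-weight-decay Adam, mini-batches from a seeded
shuffle, and early stopping on the training loss.  Everything is plain
NumPy with hand-derived gradients (backpropagation through time for the
recurrent cells), so training is deterministic given the seed.

The decision rule is strict: a sample is labelled positive iff its predicted
probability exceeds the threshold Th (default 0.5).
"""

from __future__ import annotations

import math

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

# SELU constants (fixed by the self-normalizing property).
_SELU_SCALE = 1.0507009873554804934193349852946
_SELU_ALPHA = 1.6732632423543772848170429916717
_ALPHA_P = -_SELU_SCALE * _SELU_ALPHA  # alpha-dropout saturation value


def reshape_to_sequence(vector: np.ndarray, width: int) -> np.ndarray:
    """Chunk a D-vector into ceil(D/width) timesteps of ``width`` features,
    zero-padding the tail."""
    vector = np.asarray(vector, dtype=float).ravel()
    n_steps = math.ceil(len(vector) / width)
    padded = np.zeros(n_steps * width)
    padded[: len(vector)] = vector
    return padded.reshape(n_steps, width)


def _reshape_batch(X: np.ndarray, width: int) -> np.ndarray:
    """(n, D) -> (T, n, width) with zero-padded tail."""
    n, d = X.shape
    n_steps = math.ceil(d / width)
    padded = np.zeros((n, n_steps * width))
    padded[:, :d] = X
    return padded.reshape(n, n_steps, width).transpose(1, 0, 2)


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-np.clip(x, -60, 60)))


def _selu(x):
    return _SELU_SCALE * np.where(x > 0, x, _SELU_ALPHA * (np.exp(np.minimum(x, 0)) - 1))


def _selu_grad(x):
    return _SELU_SCALE * np.where(x > 0, 1.0, _SELU_ALPHA * np.exp(np.minimum(x, 0)))


# ---------------------------------------------------------------------------
# Recurrent cells (forward + backpropagation through time)
# ---------------------------------------------------------------------------

class _LSTM:
    """Single-direction LSTM; gate order i, f, g, o; forget bias 1."""

    def __init__(self, input_dim: int, hidden: int, rng):
        lim = math.sqrt(6.0 / (input_dim + 4 * hidden))
        self.params = {
            "Wx": rng.uniform(-lim, lim, (input_dim, 4 * hidden)),
            "Wh": rng.uniform(-lim, lim, (hidden, 4 * hidden)),
            "b": np.zeros(4 * hidden),
        }
        self.params["b"][hidden : 2 * hidden] = 1.0
        self.hidden = hidden

    def forward(self, xs):
        """xs: (T, B, I) -> hs: (T, B, H); caches kept for backward."""
        T, B, _ = xs.shape
        H = self.hidden
        h = np.zeros((B, H))
        c = np.zeros((B, H))
        self._cache = []
        hs = np.empty((T, B, H))
        Wx, Wh, b = self.params["Wx"], self.params["Wh"], self.params["b"]
        for t in range(T):
            z = xs[t] @ Wx + h @ Wh + b
            i = _sigmoid(z[:, :H])
            f = _sigmoid(z[:, H : 2 * H])
            g = np.tanh(z[:, 2 * H : 3 * H])
            o = _sigmoid(z[:, 3 * H :])
            c_new = f * c + i * g
            h_new = o * np.tanh(c_new)
            self._cache.append((xs[t], h, c, i, f, g, o, c_new))
            h, c = h_new, c_new
            hs[t] = h
        return hs

    def backward(self, dhs):
        """dhs: (T, B, H) gradients on each output h_t.  Returns (grads, dxs)."""
        H = self.hidden
        Wx, Wh = self.params["Wx"], self.params["Wh"]
        grads = {k: np.zeros_like(v) for k, v in self.params.items()}
        T = len(self._cache)
        B = dhs.shape[1]
        dh = np.zeros((B, H))
        dc = np.zeros((B, H))
        dxs = np.empty((T, B, Wx.shape[0]))
        for t in reversed(range(T)):
            x, h_prev, c_prev, i, f, g, o, c = self._cache[t]
            dh = dh + dhs[t]
            tanh_c = np.tanh(c)
            do = dh * tanh_c
            dc = dc + dh * o * (1 - tanh_c**2)
            di, df, dg = dc * g, dc * c_prev, dc * i
            dz = np.concatenate(
                [di * i * (1 - i), df * f * (1 - f), dg * (1 - g**2), do * o * (1 - o)],
                axis=1,
            )
            grads["Wx"] += x.T @ dz
            grads["Wh"] += h_prev.T @ dz
            grads["b"] += dz.sum(axis=0)
            dxs[t] = dz @ Wx.T
            dh = dz @ Wh.T
            dc = dc * f
        return grads, dxs


class _GRU:
    """Single-direction GRU (update z, reset r, candidate n)."""

    def __init__(self, input_dim: int, hidden: int, rng):
        lim = math.sqrt(6.0 / (input_dim + 3 * hidden))
        self.params = {
            "Wx": rng.uniform(-lim, lim, (input_dim, 3 * hidden)),
            "Wh": rng.uniform(-lim, lim, (hidden, 3 * hidden)),
            "bx": np.zeros(3 * hidden),
            "bh": np.zeros(3 * hidden),
        }
        self.hidden = hidden

    def forward(self, xs):
        T, B, _ = xs.shape
        H = self.hidden
        h = np.zeros((B, H))
        self._cache = []
        hs = np.empty((T, B, H))
        Wx, Wh = self.params["Wx"], self.params["Wh"]
        bx, bh = self.params["bx"], self.params["bh"]
        for t in range(T):
            gx = xs[t] @ Wx + bx
            gh = h @ Wh + bh
            z = _sigmoid(gx[:, :H] + gh[:, :H])
            r = _sigmoid(gx[:, H : 2 * H] + gh[:, H : 2 * H])
            hn = gh[:, 2 * H :]
            n = np.tanh(gx[:, 2 * H :] + r * hn)
            h_new = (1 - z) * n + z * h
            self._cache.append((xs[t], h, z, r, n, hn))
            h = h_new
            hs[t] = h
        return hs

    def backward(self, dhs):
        H = self.hidden
        Wx, Wh = self.params["Wx"], self.params["Wh"]
        grads = {k: np.zeros_like(v) for k, v in self.params.items()}
        T = len(self._cache)
        B = dhs.shape[1]
        dh = np.zeros((B, H))
        dxs = np.empty((T, B, Wx.shape[0]))
        for t in reversed(range(T)):
            x, h_prev, z, r, n, hn = self._cache[t]
            dh = dh + dhs[t]
            dn = dh * (1 - z)
            dz = dh * (h_prev - n)
            dh_prev = dh * z
            dn_pre = dn * (1 - n**2)
            dr = dn_pre * hn
            dz_pre = dz * z * (1 - z)
            dr_pre = dr * r * (1 - r)
            dgx = np.concatenate([dz_pre, dr_pre, dn_pre], axis=1)
            dgh = np.concatenate([dz_pre, dr_pre, dn_pre * r], axis=1)
            grads["Wx"] += x.T @ dgx
            grads["bx"] += dgx.sum(axis=0)
            grads["Wh"] += h_prev.T @ dgh
            grads["bh"] += dgh.sum(axis=0)
            dxs[t] = dgx @ Wx.T
            dh = dh_prev + dgh @ Wh.T
        return grads, dxs


class _Conv1D:
    """Same-padded 1-D convolution (kernel 3) over timesteps + ReLU."""

    KERNEL = 3

    def __init__(self, input_dim: int, filters: int, rng):
        lim = math.sqrt(6.0 / (self.KERNEL * input_dim + filters))
        self.params = {
            "W": rng.uniform(-lim, lim, (self.KERNEL, input_dim, filters)),
            "b": np.zeros(filters),
        }
        self.filters = filters

    def forward(self, xs):
        T, B, I = xs.shape
        pad = self.KERNEL // 2
        xp = np.zeros((T + 2 * pad, B, I))
        xp[pad : pad + T] = xs
        W, b = self.params["W"], self.params["b"]
        pre = np.empty((T, B, self.filters))
        for t in range(T):
            pre[t] = sum(xp[t + k] @ W[k] for k in range(self.KERNEL)) + b
        out = np.maximum(pre, 0.0)
        self._cache = (xp, pre)
        return out

    def backward(self, dout):
        xp, pre = self._cache
        T = pre.shape[0]
        pad = self.KERNEL // 2
        W = self.params["W"]
        grads = {k: np.zeros_like(v) for k, v in self.params.items()}
        dpre = dout * (pre > 0)
        dxp = np.zeros_like(xp)
        for t in range(T):
            for k in range(self.KERNEL):
                grads["W"][k] += xp[t + k].T @ dpre[t]
                dxp[t + k] += dpre[t] @ W[k].T
            grads["b"] += dpre[t].sum(axis=0)
        return grads, dxp[pad : pad + T]


# ---------------------------------------------------------------------------
# Classifier
# ---------------------------------------------------------------------------

class SnBiLSTMClassifier(ClassifierMixin, BaseEstimator):
    """Binary classifier over fixed-length feature vectors.

    Parameters
    ----------
    timestep_width : features per timestep when chunking the input vector.
    hidden_size : recurrent (or convolutional) layer width.
    n_layers : number of stacked encoder layers.
    dense_sizes : widths of the dense head layers.
    dropout : alpha-dropout (SELU variants) or inverted-dropout rate on the
        dense head during training.
    learning_rate, weight_decay : Adam with decoupled weight decay.
    batch_size, max_epochs, patience, tol : training loop; early stopping on
        the training loss.
    seed : drives initialization, shuffling, and dropout.
    threshold : decision threshold Th; label positive iff p > Th (strict).
    variant : "snbilstm", "bilstm", "lstm", "gru" or "cnn".
    class_weight : None or "balanced".
    """

    def __init__(self, timestep_width=64, hidden_size=128, n_layers=1,
                 dense_sizes=(64,), dropout=0.05, learning_rate=1e-3,
                 weight_decay=1e-4, batch_size=32, max_epochs=100,
                 patience=10, tol=1e-4, seed=7, threshold=0.5,
                 variant="snbilstm", class_weight=None):
        self.timestep_width = timestep_width
        self.hidden_size = hidden_size
        self.n_layers = n_layers
        self.dense_sizes = dense_sizes
        self.dropout = dropout
        self.learning_rate = learning_rate
        self.weight_decay = weight_decay
        self.batch_size = batch_size
        self.max_epochs = max_epochs
        self.patience = patience
        self.tol = tol
        self.seed = seed
        self.threshold = threshold
        self.variant = variant
        self.class_weight = class_weight

    # -- architecture ------------------------------------------------------

    def _build(self, rng):
        if self.variant not in ("snbilstm", "bilstm", "lstm", "gru", "cnn"):
            raise ValueError(f"unknown variant {self.variant!r}")
        if not 0 < self.threshold < 1:
            raise ValueError("threshold must be in (0, 1)")
        H = self.hidden_size
        width = self.timestep_width
        self._encoder = []
        in_dim = width
        for _ in range(self.n_layers):
            if self.variant in ("snbilstm", "bilstm"):
                layer = (_LSTM(in_dim, H, rng), _LSTM(in_dim, H, rng))
                in_dim = 2 * H
            elif self.variant == "lstm":
                layer = (_LSTM(in_dim, H, rng),)
                in_dim = H
            elif self.variant == "gru":
                layer = (_GRU(in_dim, H, rng),)
                in_dim = H
            else:
                layer = (_Conv1D(in_dim, H, rng),)
                in_dim = H
            self._encoder.append(layer)
        feat = in_dim
        self._dense = []
        selu = self.variant == "snbilstm"
        for size in self.dense_sizes:
            if selu:  # LeCun normal pairs with SELU
                W = rng.normal(0.0, 1.0 / math.sqrt(feat), (feat, size))
            else:
                lim = math.sqrt(6.0 / (feat + size))
                W = rng.uniform(-lim, lim, (feat, size))
            self._dense.append({"W": W, "b": np.zeros(size)})
            feat = size
        lim = math.sqrt(6.0 / (feat + 1))
        self._out = {"W": rng.uniform(-lim, lim, (feat, 1)), "b": np.zeros(1)}

    def _all_params(self):
        for li, layer in enumerate(self._encoder):
            for di, cell in enumerate(layer):
                for k, v in cell.params.items():
                    yield f"enc{li}_{di}_{k}", cell.params, k
        for i, dense in enumerate(self._dense):
            for k in ("W", "b"):
                yield f"dense{i}_{k}", dense, k
        for k in ("W", "b"):
            yield f"out_{k}", self._out, k

    # -- forward / backward ------------------------------------------------

    def _encode(self, xb):
        """xb: (B, D) -> pooled features (B, F); caches kept per layer."""
        xs = _reshape_batch(xb, self.timestep_width)
        for layer in self._encoder:
            if len(layer) == 2:  # bidirectional
                fwd = layer[0].forward(xs)
                bwd = layer[1].forward(xs[::-1])
                xs = np.concatenate([fwd, bwd[::-1]], axis=2)
            else:
                xs = layer[0].forward(xs)
        self._enc_out_shape = xs.shape
        if self.variant == "cnn":
            self._pool_argmax = np.argmax(xs, axis=0)
            return np.max(xs, axis=0)
        # final state of each direction: forward at t=T-1, backward at t=0
        if self.variant in ("snbilstm", "bilstm"):
            H = self.hidden_size
            return np.concatenate([xs[-1, :, :H], xs[0, :, H:]], axis=1)
        return xs[-1]

    def _encode_backward(self, dfeat):
        T, B, F = self._enc_out_shape
        dxs = np.zeros((T, B, F))
        if self.variant == "cnn":
            cols = np.arange(B)[:, None], np.arange(F)[None, :]
            dxs[self._pool_argmax, cols[0], cols[1]] = dfeat
        elif self.variant in ("snbilstm", "bilstm"):
            H = self.hidden_size
            dxs[-1, :, :H] = dfeat[:, :H]
            dxs[0, :, H:] = dfeat[:, H:]
        else:
            dxs[-1] = dfeat
        grads = {}
        for li in reversed(range(len(self._encoder))):
            layer = self._encoder[li]
            if len(layer) == 2:
                H = self.hidden_size
                g_f, dx_f = layer[0].backward(dxs[:, :, :H])
                g_b, dx_b = layer[1].backward(dxs[::-1, :, H:])
                dxs = dx_f + dx_b[::-1]
                for k, v in g_f.items():
                    grads[f"enc{li}_0_{k}"] = v
                for k, v in g_b.items():
                    grads[f"enc{li}_1_{k}"] = v
            else:
                g, dxs = layer[0].backward(dxs)
                for k, v in g.items():
                    grads[f"enc{li}_0_{k}"] = v
        return grads

    def _head(self, feat, rng=None):
        """Dense head forward; ``rng`` enables dropout (training mode)."""
        selu = self.variant == "snbilstm"
        self._head_cache = []
        x = feat
        for dense in self._dense:
            pre = x @ dense["W"] + dense["b"]
            act = _selu(pre) if selu else np.maximum(pre, 0.0)
            drop = None
            if rng is not None and self.dropout > 0:
                p = self.dropout
                q = 1.0 - p
                mask = rng.random(act.shape) < q
                if selu:  # alpha dropout keeps self-normalization
                    a = (q + _ALPHA_P**2 * q * p) ** -0.5
                    act = a * (np.where(mask, act, _ALPHA_P)) + (-a * p * _ALPHA_P)
                    drop = ("alpha", mask, a)
                else:
                    act = np.where(mask, act / q, 0.0)
                    drop = ("std", mask, q)
            self._head_cache.append((x, pre, drop))
            x = act
        logit = x @ self._out["W"] + self._out["b"]
        self._out_cache = x
        return logit[:, 0]

    def _head_backward(self, dlogit):
        """Backprop through the dense head; stores d(features) for the encoder."""
        grads = {}
        x = self._out_cache
        grads["out_W"] = x.T @ dlogit[:, None]
        grads["out_b"] = np.array([dlogit.sum()])
        dx = dlogit[:, None] @ self._out["W"].T
        selu = self.variant == "snbilstm"
        for i in reversed(range(len(self._dense))):
            inp, pre, drop = self._head_cache[i]
            if drop is not None:
                kind, mask, scale = drop
                dx = dx * mask * (scale if kind == "alpha" else 1.0 / scale)
            dpre = dx * (_selu_grad(pre) if selu else (pre > 0))
            grads[f"dense{i}_W"] = inp.T @ dpre
            grads[f"dense{i}_b"] = dpre.sum(axis=0)
            dx = dpre @ self._dense[i]["W"].T
        self._dfeat = dx
        return grads, None

    # -- training ----------------------------------------------------------

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y).astype(int).ravel()
        if X.ndim != 2:
            raise ValueError("X must be 2-D (n_samples, n_features)")
        classes = np.unique(y)
        if len(classes) < 2:
            raise ValueError("training data contains a single class")
        if not np.isin(classes, (0, 1)).all():
            raise ValueError("labels must be 0/1")
        self.classes_ = np.array([0, 1])
        rng = np.random.default_rng(self.seed)
        self._build(rng)

        sample_w = np.ones(len(y))
        if self.class_weight == "balanced":
            counts = np.bincount(y, minlength=2)
            sample_w = len(y) / (2.0 * counts[y])

        # Adam state
        m_state = {name: np.zeros_like(holder[key]) for name, holder, key in self._all_params()}
        v_state = {name: np.zeros_like(holder[key]) for name, holder, key in self._all_params()}
        beta1, beta2, eps = 0.9, 0.999, 1e-8
        step = 0
        best_loss, stale = np.inf, 0
        self.history_ = []
        n = len(y)
        for epoch in range(self.max_epochs):
            order = rng.permutation(n)
            epoch_loss = 0.0
            for start in range(0, n, self.batch_size):
                idx = order[start : start + self.batch_size]
                xb, yb, wb = X[idx], y[idx], sample_w[idx]
                feat = self._encode(xb)
                logit = self._head(feat, rng=rng)
                p = _sigmoid(logit)
                eps_p = 1e-12
                loss = -np.mean(wb * (yb * np.log(p + eps_p) + (1 - yb) * np.log(1 - p + eps_p)))
                epoch_loss += loss * len(idx)
                dlogit = wb * (p - yb) / len(idx)
                head_grads, _ = self._head_backward(dlogit)
                dfeat = self._dfeat
                enc_grads = self._encode_backward(dfeat)
                grads = {**head_grads, **enc_grads}
                step += 1
                for name, holder, key in self._all_params():
                    g = grads[name]
                    m_state[name] = beta1 * m_state[name] + (1 - beta1) * g
                    v_state[name] = beta2 * v_state[name] + (1 - beta2) * g * g
                    m_hat = m_state[name] / (1 - beta1**step)
                    v_hat = v_state[name] / (1 - beta2**step)
                    holder[key] = holder[key] - self.learning_rate * (
                        m_hat / (np.sqrt(v_hat) + eps) + self.weight_decay * holder[key]
                    )
            epoch_loss /= n
            self.history_.append(epoch_loss)
            if epoch_loss < best_loss - self.tol:
                best_loss, stale = epoch_loss, 0
            else:
                stale += 1
                if stale >= self.patience:
                    break
        self.n_features_in_ = X.shape[1]
        return self

    # -- prediction --------------------------------------------------------

    def predict_proba(self, X):
        check_is_fitted(self, "classes_")
        X = np.asarray(X, dtype=float)
        p = _sigmoid(self._head(self._encode(X), rng=None))
        return np.column_stack([1 - p, p])

    def decision_function(self, X):
        return self.predict_proba(X)[:, 1]

    def predict(self, X):
        p = self.predict_proba(X)[:, 1]
        return (p > self.threshold).astype(int)

    # -- parameter persistence ---------------------------------------------

    def export_params(self) -> dict:
        check_is_fitted(self, "classes_")
        return {name: holder[key].copy() for name, holder, key in self._all_params()}

    def import_params(self, params: dict, n_features: int) -> "SnBiLSTMClassifier":
        """Rebuild the architecture and load trained parameter arrays."""
        rng = np.random.default_rng(self.seed)
        self._build(rng)
        for name, holder, key in self._all_params():
            holder[key] = np.asarray(params[name], dtype=float)
        self.classes_ = np.array([0, 1])
        self.n_features_in_ = n_features
        self.history_ = []
        return self
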