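"""Bidirectional gated-recurrent-unit classifier in plain numpy.

Implements the standard GRU cell

    z_t = sigmoid(W_z x_t + U_z h_{t-1} + b_z)       (update gate)
    r_t = sigmoid(W_r x_t + U_r h_{t-1} + b_r)       (reset gate)
    c_t = tanh(W_h x_t + U_h (r_t . h_{t-1}) + b_h)  (candidate)
    h_t = (1 - z_t) . h_{t-1} + z_t . c_t

stacked in several bidirectional layers: each layer runs one cell left to
right and an independent cell right to left and concatenates the two
hidden sequences. The classifier head is a linear map from the
concatenated final states (forward state at the last step, backward state
at the first) to two logits with a softmax, trained with cross-entropy —
equivalent to binary cross-entropy on the positive-class probability.
Gradients are computed by backpropagation through time and applied with
Adam; inverted dropout acts on the inputs of every layer after the first.
All randomness (init, shuffling, dropout) comes from a single seeded
generator, so training is deterministic per seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


def _sigmoid(a):
    return 1.0 / (1.0 + np.exp(-np.clip(a, -60, 60)))


@dataclass
class GruConfig:
    input_size: int = 36
    hidden_size: int = 89
    n_layers: int = 3
    bidirectional: bool = True
    output_size: int = 2
    dropout: float = 0.5
    batch_size: int = 32
    learning_rate: float = 1e-3
    max_epochs: int = 200
    sequence_len: int = 1   # feature vectors enter as length-1 sequences
    seed: int = 0

    def __post_init__(self) -> None:
        if self.hidden_size < 1:
            raise ValueError("hidden size must be >= 1")
        if not (0 <= self.dropout < 1):
            raise ValueError("dropout must be in [0, 1)")


def wake_config(**kw) -> GruConfig:
    """The wakefulness preset: 21 inputs, 3 x 59 hidden."""
    kw.setdefault("input_size", 21)
    kw.setdefault("hidden_size", 59)
    return GruConfig(**kw)


class _Cell:
    """One direction of one layer."""

    def __init__(self, d_in, h, rng):
        s_in = 1.0 / np.sqrt(d_in)
        s_h = 1.0 / np.sqrt(h)
        self.p = {
            "Wz": rng.uniform(-s_in, s_in, (d_in, h)),
            "Wr": rng.uniform(-s_in, s_in, (d_in, h)),
            "Wh": rng.uniform(-s_in, s_in, (d_in, h)),
            "Uz": rng.uniform(-s_h, s_h, (h, h)),
            "Ur": rng.uniform(-s_h, s_h, (h, h)),
            "Uh": rng.uniform(-s_h, s_h, (h, h)),
            "bz": np.zeros(h), "br": np.zeros(h), "bh": np.zeros(h),
        }

    def forward(self, xs):
        """xs: list of (B, d_in) over time. Returns hidden list + caches."""
        p = self.p
        B = xs[0].shape[0]
        h = np.zeros((B, p["bz"].size))
        hs, caches = [], []
        for x in xs:
            z = _sigmoid(x @ p["Wz"] + h @ p["Uz"] + p["bz"])
            r = _sigmoid(x @ p["Wr"] + h @ p["Ur"] + p["br"])
            c = np.tanh(x @ p["Wh"] + (r * h) @ p["Uh"] + p["bh"])
            h_new = (1 - z) * h + z * c
            caches.append((x, h, z, r, c))
            h = h_new
            hs.append(h)
        return hs, caches

    def backward(self, dhs, caches):
        """dhs: per-step gradients w.r.t. the hidden outputs. Returns
        per-step input gradients and accumulates parameter gradients."""
        p = self.p
        g = {k: np.zeros_like(v) for k, v in p.items()}
        dxs = [None] * len(dhs)
        dh_next = np.zeros_like(dhs[-1])
        for t in range(len(dhs) - 1, -1, -1):
            x, h_prev, z, r, c = caches[t]
            dh = dhs[t] + dh_next
            dz = dh * (c - h_prev)
            dc = dh * z
            dh_prev = dh * (1 - z)
            dac = dc * (1 - c ** 2)
            g["Wh"] += x.T @ dac
            g["Uh"] += (r * h_prev).T @ dac
            g["bh"] += dac.sum(axis=0)
            dx = dac @ p["Wh"].T
            drh = dac @ p["Uh"].T
            dr = drh * h_prev
            dh_prev = dh_prev + drh * r
            daz = dz * z * (1 - z)
            g["Wz"] += x.T @ daz
            g["Uz"] += h_prev.T @ daz
            g["bz"] += daz.sum(axis=0)
            dx += daz @ p["Wz"].T
            dh_prev = dh_prev + daz @ p["Uz"].T
            dar = dr * r * (1 - r)
            g["Wr"] += x.T @ dar
            g["Ur"] += h_prev.T @ dar
            g["br"] += dar.sum(axis=0)
            dx += dar @ p["Wr"].T
            dh_prev = dh_prev + dar @ p["Ur"].T
            dxs[t] = dx
            dh_next = dh_prev
        return dxs, g


class BiGRU:
    """Stacked bidirectional GRU with a 2-way softmax head."""

    def __init__(self, config: GruConfig):
        self.config = config
        self.rng = np.random.default_rng(config.seed)
        h = config.hidden_size
        self.layers = []
        d = config.input_size
        for _ in range(config.n_layers):
            fwd = _Cell(d, h, self.rng)
            bwd = _Cell(d, h, self.rng) if config.bidirectional else None
            self.layers.append((fwd, bwd))
            d = 2 * h if config.bidirectional else h
        s = 1.0 / np.sqrt(d)
        self.Wo = self.rng.uniform(-s, s, (d, config.output_size))
        self.bo = np.zeros(config.output_size)
        self._adam_state: dict = {}
        self._adam_t = 0

    # ---- forward/backward ------------------------------------------------

    def _as_sequence(self, X):
        X = np.asarray(X, dtype=float)
        if X.ndim == 2:
            X = X[:, None, :]  # (B, T=1, d)
        if X.shape[2] != self.config.input_size:
            raise ValueError(
                f"input width {X.shape[2]} does not match configured "
                f"input size {self.config.input_size}")
        return [X[:, t, :] for t in range(X.shape[1])]

    def _forward(self, xs, train=False):
        cache = []
        for li, (fwd, bwd) in enumerate(self.layers):
            if train and self.config.dropout > 0 and li > 0:
                keep = 1.0 - self.config.dropout
                masks = [(self.rng.random(x.shape) < keep) / keep for x in xs]
                xs = [x * m for x, m in zip(xs, masks)]
            else:
                masks = None
            hs_f, cf = fwd.forward(xs)
            if bwd is not None:
                hs_b_rev, cb = bwd.forward(xs[::-1])
                hs_b = hs_b_rev[::-1]
                outs = [np.concatenate([f, b], axis=1)
                        for f, b in zip(hs_f, hs_b)]
            else:
                cb, hs_b = None, None
                outs = hs_f
            cache.append((masks, cf, cb, len(xs)))
            xs = outs
        # head input: forward final state || backward initial-step state
        T = len(xs)
        fwd_final = xs[T - 1][:, :self.config.hidden_size]
        if self.config.bidirectional:
            bwd_final = xs[0][:, self.config.hidden_size:]
            head_in = np.concatenate([fwd_final, bwd_final], axis=1)
        else:
            head_in = xs[T - 1]
        logits = head_in @ self.Wo + self.bo
        logits -= logits.max(axis=1, keepdims=True)
        e = np.exp(logits)
        probs = e / e.sum(axis=1, keepdims=True)
        return probs, head_in, xs, cache

    def predict_proba(self, X):
        probs, *_ = self._forward(self._as_sequence(X), train=False)
        return probs

    def predict_scores(self, X):
        """Positive-class (MCI) probability per row, in [0, 1]."""
        return self.predict_proba(X)[:, 1]

    def _backward(self, probs, y_onehot, head_in, outs, cache):
        B = probs.shape[0]
        dlogits = (probs - y_onehot) / B
        gWo = head_in.T @ dlogits
        gbo = dlogits.sum(axis=0)
        dhead = dlogits @ self.Wo.T
        T = len(outs)
        H = self.config.hidden_size
        douts = [np.zeros_like(o) for o in outs]
        if self.config.bidirectional:
            douts[T - 1][:, :H] += dhead[:, :H]
            douts[0][:, H:] += dhead[:, H:]
        else:
            douts[T - 1] += dhead
        grads = {"Wo": gWo, "bo": gbo}
        dxs = douts
        for li in range(len(self.layers) - 1, -1, -1):
            fwd, bwd = self.layers[li]
            masks, cf, cb, T = cache[li]
            if bwd is not None:
                d_f = [d[:, :H] for d in dxs]
                d_b = [d[:, H:] for d in dxs]
                dx_f, gf = fwd.backward(d_f, cf)
                dx_b_rev, gb = bwd.backward(d_b[::-1], cb)
                dx_b = dx_b_rev[::-1]
                dxs = [a + b for a, b in zip(dx_f, dx_b)]
                for k, v in gb.items():
                    grads[f"l{li}b_{k}"] = v
            else:
                dxs, gf = fwd.backward(dxs, cf)
            for k, v in gf.items():
                grads[f"l{li}f_{k}"] = v
            if masks is not None:
                dxs = [d * m for d, m in zip(dxs, masks)]
        return grads

    # ---- parameter plumbing ---------------------------------------------

    def _params(self):
        out = {"Wo": self.Wo, "bo": self.bo}
        for li, (fwd, bwd) in enumerate(self.layers):
            for k, v in fwd.p.items():
                out[f"l{li}f_{k}"] = v
            if bwd is not None:
                for k, v in bwd.p.items():
                    out[f"l{li}b_{k}"] = v
        return out

    def _adam_step(self, grads, lr, beta1=0.9, beta2=0.999, eps=1e-8):
        self._adam_t += 1
        t = self._adam_t
        params = self._params()
        for k, p in params.items():
            g = grads[k]
            if k not in self._adam_state:
                self._adam_state[k] = [np.zeros_like(p), np.zeros_like(p)]
            m, v = self._adam_state[k]
            m += (1 - beta1) * (g - m)
            v += (1 - beta2) * (g * g - v)
            mhat = m / (1 - beta1 ** t)
            vhat = v / (1 - beta2 ** t)
            p -= lr * mhat / (np.sqrt(vhat) + eps)

    # ---- training --------------------------------------------------------

    def loss_and_grads(self, X, y):
        xs = self._as_sequence(X)
        probs, head_in, outs, cache = self._forward(xs, train=True)
        y = np.asarray(y, dtype=int)
        onehot = np.zeros_like(probs)
        onehot[np.arange(y.size), y] = 1.0
        loss = float(-np.log(probs[np.arange(y.size), y] + 1e-12).mean())
        grads = self._backward(probs, onehot, head_in, outs, cache)
        return loss, grads

    def fit(self, X, y, n_epochs=None, X_val=None, y_val=None):
        """Mini-batch Adam training. Returns a history dict with per-epoch
        mean training loss and (if validation data given) accuracy."""
        cfg = self.config
        n_epochs = n_epochs or cfg.max_epochs
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=int)
        history = {"loss": [], "val_acc": []}
        for _ in range(n_epochs):
            order = self.rng.permutation(len(X))
            losses = []
            for i0 in range(0, len(X), cfg.batch_size):
                idx = order[i0:i0 + cfg.batch_size]
                loss, grads = self.loss_and_grads(X[idx], y[idx])
                self._adam_step(grads, cfg.learning_rate)
                losses.append(loss)
            history["loss"].append(float(np.mean(losses)))
            if X_val is not None:
                pred = (self.predict_scores(X_val) >= 0.5).astype(int)
                acc = float((pred == np.asarray(y_val, dtype=int)).mean())
                history["val_acc"].append(acc)
        return history
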