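"""Minimal seeded LSTM/BiLSTM sequence classifiers in numpy.

Implements exactly what the pipeline's two learned stages need: stacked
(bi)directional LSTM layers with inter-layer dropout, a dense softmax head on
the last valid timestep, masked variable-length batches, Adam, and
backpropagation through time.  Everything is driven by a single
``numpy.random.Generator`` so training is bit-reproducible for a given seed.

Layer specs are lists of tuples::

    [("lstm", 290, False), ("dropout", 0.30), ("lstm", 10, True), ("dropout", 0.40)]

(units, bidirectional flag); the dense softmax head is implicit.
"""

from __future__ import annotations

import numpy as np

from .types import InputError, TrainingError


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-np.clip(x, -50, 50)))


class _LSTMDirection:
    """One direction of an LSTM layer, with masked carry-through updates."""

    def __init__(self, n_in: int, n_hidden: int, rng: np.random.Generator):
        s_x = np.sqrt(6.0 / (n_in + 4 * n_hidden))
        s_h = np.sqrt(6.0 / (n_hidden + 4 * n_hidden))
        self.Wx = rng.uniform(-s_x, s_x, (n_in, 4 * n_hidden))
        self.Wh = rng.uniform(-s_h, s_h, (n_hidden, 4 * n_hidden))
        self.b = np.zeros(4 * n_hidden)
        self.b[n_hidden : 2 * n_hidden] = 1.0  # forget-gate bias
        self.n_hidden = n_hidden

    def params(self):
        return [self.Wx, self.Wh, self.b]

    def forward(self, x, mask):
        """x: (B,T,F); mask: (B,T) in {0,1}.  Returns sequence (B,T,H)."""
        B, T, _ = x.shape
        H = self.n_hidden
        h = np.zeros((B, H))
        c = np.zeros((B, H))
        self.cache = []
        hs = np.empty((B, T, H))
        for t in range(T):
            m = mask[:, t][:, None]
            z = x[:, t] @ self.Wx + h @ self.Wh + self.b
            i = _sigmoid(z[:, :H])
            f = _sigmoid(z[:, H : 2 * H])
            g = np.tanh(z[:, 2 * H : 3 * H])
            o = _sigmoid(z[:, 3 * H :])
            c_tilde = f * c + i * g
            tc = np.tanh(c_tilde)
            h_tilde = o * tc
            c_new = m * c_tilde + (1 - m) * c
            h_new = m * h_tilde + (1 - m) * h
            self.cache.append((x[:, t], h, c, i, f, g, o, c_tilde, tc, m))
            h, c = h_new, c_new
            hs[:, t] = h
        return hs

    def backward(self, dhs):
        """dhs: (B,T,H) gradient on the output sequence.  Returns dx."""
        B, T, H = dhs.shape
        dWx = np.zeros_like(self.Wx)
        dWh = np.zeros_like(self.Wh)
        db = np.zeros_like(self.b)
        dh_next = np.zeros((B, H))
        dc_next = np.zeros((B, H))
        dx = np.empty((B, T, self.Wx.shape[0]))
        for t in range(T - 1, -1, -1):
            x_t, h_prev, c_prev, i, f, g, o, c_tilde, tc, m = self.cache[t]
            dh = dhs[:, t] + dh_next
            dh_t = m * dh
            carry_h = (1 - m) * dh
            dc_t = m * dc_next
            carry_c = (1 - m) * dc_next
            do = dh_t * tc
            dct = dh_t * o * (1 - tc**2) + dc_t
            di = dct * g
            df = dct * c_prev
            dg = dct * i
            dc_prev = dct * f + carry_c
            dz = np.concatenate(
                [di * i * (1 - i), df * f * (1 - f), dg * (1 - g**2), do * o * (1 - o)],
                axis=1,
            )
            dWx += x_t.T @ dz
            dWh += h_prev.T @ dz
            db += dz.sum(axis=0)
            dx[:, t] = dz @ self.Wx.T
            dh_next = dz @ self.Wh.T + carry_h
            dc_next = dc_prev
        self.grads = [dWx, dWh, db]
        return dx


class _LSTMLayer:
    def __init__(self, n_in, n_hidden, bidirectional, rng):
        self.fwd = _LSTMDirection(n_in, n_hidden, rng)
        self.bwd = _LSTMDirection(n_in, n_hidden, rng) if bidirectional else None
        self.n_out = n_hidden * (2 if bidirectional else 1)

    def params(self):
        p = self.fwd.params()
        if self.bwd is not None:
            p = p + self.bwd.params()
        return p

    def grads(self):
        g = self.fwd.grads
        if self.bwd is not None:
            g = g + self.bwd.grads
        return g

    def forward(self, x, mask):
        out = self.fwd.forward(x, mask)
        if self.bwd is not None:
            rev = self.bwd.forward(x[:, ::-1], mask[:, ::-1])[:, ::-1]
            out = np.concatenate([out, rev], axis=2)
        return out

    def backward(self, dout):
        H = self.fwd.n_hidden
        dx = self.fwd.backward(dout[:, :, :H])
        if self.bwd is not None:
            dx = dx + self.bwd.backward(dout[:, ::-1, H:])[:, ::-1]
        return dx


class _Adam:
    def __init__(self, params, lr=1e-2, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads, clip=5.0):
        norm = np.sqrt(sum(float(np.sum(g**2)) for g in grads))
        scale = min(1.0, clip / (norm + 1e-12))
        self.t += 1
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            g = g * scale
            m[:] = self.b1 * m + (1 - self.b1) * g
            v[:] = self.b2 * v + (1 - self.b2) * g**2
            mh = m / (1 - self.b1**self.t)
            vh = v / (1 - self.b2**self.t)
            p -= self.lr * mh / (np.sqrt(vh) + self.eps)


class SequenceClassifier:
    """Stacked (Bi)LSTM -> dense softmax binary classifier.

    Inputs are sequences of shape (T_i, n_features); per-channel z-scoring
    with training-set statistics is applied internally.
    """

    def __init__(self, layers, n_features: int, n_classes: int = 2, seed: int = 0, lr: float = 1e-2):
        self.spec = list(layers)
        self.n_features = n_features
        self.n_classes = n_classes
        self.rng = np.random.default_rng(seed)
        self.lr = lr
        self.layers = []
        self.dropouts = []  # aligned with layers: dropout p after each
        n_in = n_features
        pending_drop = 0.0
        for item in self.spec:
            if item[0] == "lstm":
                _, units, bidir = item
                self.layers.append(_LSTMLayer(n_in, units, bidir, self.rng))
                self.dropouts.append(0.0)
                n_in = self.layers[-1].n_out
            elif item[0] == "dropout":
                self.dropouts[-1] = item[1]
            else:
                raise TrainingError(f"unknown layer kind {item[0]!r}")
        if not self.layers:
            raise TrainingError("need at least one recurrent layer")
        s = np.sqrt(6.0 / (n_in + n_classes))
        self.W_out = self.rng.uniform(-s, s, (n_in, n_classes))
        self.b_out = np.zeros(n_classes)
        self.norm_mean = np.zeros(n_features)
        self.norm_std = np.ones(n_features)

    # -- batching ----------------------------------------------------------

    def _pad(self, seqs):
        lengths = np.array([s.shape[0] for s in seqs])
        T = int(lengths.max())
        B = len(seqs)
        x = np.zeros((B, T, self.n_features))
        mask = np.zeros((B, T))
        for i, s in enumerate(seqs):
            if s.shape[1] != self.n_features:
                raise InputError(
                    f"input has {s.shape[1]} channels, model expects {self.n_features}"
                )
            x[i, : s.shape[0]] = (s - self.norm_mean) / self.norm_std
            mask[i, : s.shape[0]] = 1.0
        return x, mask, lengths

    def _forward(self, x, mask, train):
        self._drop_masks = []
        for layer, p in zip(self.layers, self.dropouts):
            x = layer.forward(x, mask)
            if train and p > 0:
                dm = (self.rng.random(x.shape) >= p) / (1 - p)
                x = x * dm
                self._drop_masks.append(dm)
            else:
                self._drop_masks.append(None)
        # last state per sequence: carry-through masking makes h constant
        # after the last valid step, so the final timestep holds the forward
        # last state; for a bidirectional layer the backward last state sits
        # at timestep 0.
        last = self.layers[-1]
        if last.bwd is not None:
            H = last.fwd.n_hidden
            feat = np.concatenate([x[:, -1, :H], x[:, 0, H:]], axis=1)
        else:
            feat = x[:, -1]
        logits = feat @ self.W_out + self.b_out
        logits -= logits.max(axis=1, keepdims=True)
        e = np.exp(logits)
        probs = e / e.sum(axis=1, keepdims=True)
        return x, feat, probs

    # -- API ---------------------------------------------------------------

    def fit(self, sequences, labels, epochs: int = 10, batch_size: int = 32, sample_weight=None):
        labels = np.asarray(labels, dtype=int)
        if len(np.unique(labels)) < 2:
            raise TrainingError("training data must contain both classes")
        flat = np.concatenate([np.asarray(s, dtype=float) for s in sequences], axis=0)
        self.norm_mean = flat.mean(axis=0)
        self.norm_std = np.maximum(flat.std(axis=0), 1e-8)
        if sample_weight is None:
            # inverse-frequency class weights
            counts = np.bincount(labels, minlength=self.n_classes).astype(float)
            w = len(labels) / (self.n_classes * np.maximum(counts, 1))
            sample_weight = w[labels]
        sample_weight = np.asarray(sample_weight, dtype=float)

        params = [p for layer in self.layers for p in layer.params()] + [self.W_out, self.b_out]
        opt = _Adam(params, lr=self.lr)
        n = len(sequences)
        for _ in range(epochs):
            order = self.rng.permutation(n)
            for lo in range(0, n, batch_size):
                idx = order[lo : lo + batch_size]
                x, mask, _ = self._pad([np.asarray(sequences[i], dtype=float) for i in idx])
                y = labels[idx]
                w = sample_weight[idx]
                seq_out, feat, probs = self._forward(x, mask, train=True)
                # weighted cross-entropy gradient
                dlogits = probs.copy()
                dlogits[np.arange(len(y)), y] -= 1.0
                dlogits *= (w / w.sum())[:, None]
                dW_out = feat.T @ dlogits
                db_out = dlogits.sum(axis=0)
                dfeat = dlogits @ self.W_out.T
                dseq = np.zeros_like(seq_out)
                last = self.layers[-1]
                if last.bwd is not None:
                    H = last.fwd.n_hidden
                    dseq[:, -1, :H] = dfeat[:, :H]
                    dseq[:, 0, H:] = dfeat[:, H:]
                else:
                    dseq[:, -1] = dfeat
                grads_layers = []
                dx = dseq
                for layer, dm in zip(reversed(self.layers), reversed(self._drop_masks)):
                    if dm is not None:
                        dx = dx * dm
                    dx = layer.backward(dx)
                    grads_layers = layer.grads() + grads_layers
                opt.step(grads_layers + [dW_out, db_out])
        return self

    def predict_proba(self, sequences, batch_size: int = 64):
        out = np.empty((len(sequences), self.n_classes))
        for lo in range(0, len(sequences), batch_size):
            batch = [np.asarray(s, dtype=float) for s in sequences[lo : lo + batch_size]]
            x, mask, _ = self._pad(batch)
            _, _, probs = self._forward(x, mask, train=False)
            out[lo : lo + len(batch)] = probs
        return out

    def decision_scores(self, sequences):
        """Posterior probability of class 1 for each input sequence."""
        return self.predict_proba(sequences)[:, 1]
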