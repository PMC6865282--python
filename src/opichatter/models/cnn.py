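"""A small text convolutional network implemented on numpy.

Architecture: embedding layer -> one convolution block with parallel filter
widths (default 3, 4, 5) and ReLU -> global max-pooling -> softmax over the
4 classes.  Trained with Adam on cross-entropy, with optional validation-set
early stopping.  Deliberately dependency-free so the full classifier roster
runs on one CPU.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np

__all__ = ["TextCNN"]


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


class TextCNN:
    def __init__(
        self,
        vocab_size: int,
        n_classes: int = 4,
        embed_dim: int = 50,
        filter_widths: Sequence[int] = (3, 4, 5),
        n_filters: int = 32,
        max_len: int = 30,
        lr: float = 1e-3,
        batch_size: int = 64,
        n_epochs: int = 20,
        patience: int = 3,
        seed: int = 0,
        embedding_init: Optional[np.ndarray] = None,
    ):
        if max_len < max(filter_widths):
            raise ValueError("max_len must cover the widest filter")
        self.vocab_size = vocab_size
        self.n_classes = n_classes
        self.embed_dim = embed_dim
        self.filter_widths = tuple(filter_widths)
        self.n_filters = n_filters
        self.max_len = max_len
        self.lr = lr
        self.batch_size = batch_size
        self.n_epochs = n_epochs
        self.patience = patience
        self.seed = seed
        rng = np.random.default_rng(seed)
        d = embed_dim
        if embedding_init is not None:
            if embedding_init.shape != (vocab_size, d):
                raise ValueError(
                    f"embedding_init shape {embedding_init.shape} != "
                    f"({vocab_size}, {d})"
                )
            E = embedding_init.astype(np.float64).copy()
        else:
            E = rng.normal(0.0, 0.1, size=(vocab_size, d))
            E[0] = 0.0  # pad row
        self.params = {"E": E, "Wo": rng.normal(
            0.0, np.sqrt(2.0 / (len(self.filter_widths) * n_filters)),
            size=(len(self.filter_widths) * n_filters, n_classes),
        ), "bo": np.zeros(n_classes)}
        for w in self.filter_widths:
            self.params[f"W{w}"] = rng.normal(
                0.0, np.sqrt(2.0 / (w * d)), size=(w * d, n_filters)
            )
            self.params[f"b{w}"] = np.zeros(n_filters)
        self._adam = {k: (np.zeros_like(v), np.zeros_like(v)) for k, v in self.params.items()}
        self._adam_t = 0

    # -- forward / backward --------------------------------------------------

    def _forward(self, ids: np.ndarray):
        p = self.params
        X = p["E"][ids]  # (B, L, d)
        B, L, d = X.shape
        cache = {"ids": ids, "X": X, "conv": {}, "argmax": {}}
        pooled = []
        for w in self.filter_widths:
            P = L - w + 1
            conv = np.broadcast_to(p[f"b{w}"], (B, P, self.n_filters)).copy()
            W = p[f"W{w}"]
            for o in range(w):
                conv += X[:, o : o + P, :] @ W[o * d : (o + 1) * d, :]
            conv = np.maximum(conv, 0.0)
            am = conv.argmax(axis=1)  # (B, F)
            cache["conv"][w] = conv
            cache["argmax"][w] = am
            pooled.append(np.take_along_axis(conv, am[:, None, :], axis=1)[:, 0, :])
        h = np.concatenate(pooled, axis=1)
        cache["h"] = h
        logits = h @ p["Wo"] + p["bo"]
        return logits, cache

    def _backward(self, cache, dlogits):
        p = self.params
        grads = {k: np.zeros_like(v) for k, v in p.items()}
        h = cache["h"]
        grads["Wo"] = h.T @ dlogits
        grads["bo"] = dlogits.sum(axis=0)
        dh = dlogits @ p["Wo"].T
        X = cache["X"]
        B, L, d = X.shape
        dX = np.zeros_like(X)
        col = 0
        for w in self.filter_widths:
            F = self.n_filters
            dpool = dh[:, col : col + F]
            col += F
            conv = cache["conv"][w]
            am = cache["argmax"][w]
            P = conv.shape[1]
            dconv = np.zeros_like(conv)
            np.put_along_axis(dconv, am[:, None, :], dpool[:, None, :], axis=1)
            dconv *= conv > 0  # ReLU gate (zero where max was inactive)
            W = p[f"W{w}"]
            for o in range(w):
                grads[f"W{w}"][o * d : (o + 1) * d, :] = np.einsum(
                    "bpd,bpf->df", X[:, o : o + P, :], dconv
                )
                dX[:, o : o + P, :] += dconv @ W[o * d : (o + 1) * d, :].T
            grads[f"b{w}"] = dconv.sum(axis=(0, 1))
        dE = grads["E"]
        np.add.at(dE, cache["ids"].ravel(), dX.reshape(-1, d))
        dE[0] = 0.0  # pad embedding stays fixed
        return grads

    def _adam_step(self, grads):
        self._adam_t += 1
        b1, b2, eps = 0.9, 0.999, 1e-8
        t = self._adam_t
        for k, g in grads.items():
            m, v = self._adam[k]
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            mhat = m / (1 - b1**t)
            vhat = v / (1 - b2**t)
            self.params[k] -= self.lr * mhat / (np.sqrt(vhat) + eps)

    # -- public API ----------------------------------------------------------

    def fit(
        self,
        ids: np.ndarray,
        y: np.ndarray,
        val_ids: Optional[np.ndarray] = None,
        val_y: Optional[np.ndarray] = None,
    ) -> "TextCNN":
        """Train on integer id sequences (n, max_len) and integer class ids."""
        ids = np.asarray(ids, dtype=np.int64)
        y = np.asarray(y, dtype=np.int64)
        if ids.shape[0] != y.shape[0]:
            raise ValueError("ids and labels misaligned")
        rng = np.random.default_rng(self.seed + 1)
        onehot = np.eye(self.n_classes)[y]
        best_score, best_params, stale = -np.inf, None, 0
        for _epoch in range(self.n_epochs):
            order = rng.permutation(ids.shape[0])
            for start in range(0, len(order), self.batch_size):
                batch = order[start : start + self.batch_size]
                logits, cache = self._forward(ids[batch])
                probs = _softmax(logits)
                dlogits = (probs - onehot[batch]) / len(batch)
                self._adam_step(self._backward(cache, dlogits))
            if val_ids is not None and val_y is not None:
                score = float(np.mean(self.predict(val_ids) == np.asarray(val_y)))
                if score > best_score + 1e-9:
                    best_score, stale = score, 0
                    best_params = {k: v.copy() for k, v in self.params.items()}
                else:
                    stale += 1
                    if stale >= self.patience:
                        break
        if best_params is not None:
            self.params = best_params
        return self

    def decision_scores(self, ids: np.ndarray) -> np.ndarray:
        ids = np.asarray(ids, dtype=np.int64)
        out = np.empty((ids.shape[0], self.n_classes))
        for start in range(0, ids.shape[0], 256):
            logits, _ = self._forward(ids[start : start + 256])
            out[start : start + 256] = logits
        return out

    def predict(self, ids: np.ndarray) -> np.ndarray:
        return self.decision_scores(ids).argmax(axis=1)
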