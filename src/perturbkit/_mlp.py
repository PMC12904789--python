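"""Minimal seeded feed-forward classifier used by the MLP perturbation space.

One hidden layer with batch normalization and ReLU, a softmax output, Adam
updates on cross-entropy, class-balanced oversampling per epoch, and early
stopping on a held-out validation split. Implemented directly in numpy so
the penultimate-layer activations (the perturbation-informed cell
embedding) are available without a deep-learning dependency.
"""

from __future__ import annotations

import numpy as np

__all__ = ["MLPClassifier"]


class MLPClassifier:
    def __init__(
        self,
        hidden_units: int = 512,
        batch_size: int = 256,
        max_epochs: int = 40,
        learning_rate: float = 1e-3,
        val_fraction: float = 0.1,
        patience: int = 3,
        seed: int = 0,
    ):
        self.hidden_units = hidden_units
        self.batch_size = batch_size
        self.max_epochs = max_epochs
        self.learning_rate = learning_rate
        self.val_fraction = val_fraction
        self.patience = patience
        self.seed = seed

    # -- internals -------------------------------------------------------
    def _init_params(self, d_in, n_classes, rng):
        h = self.hidden_units
        self.W1 = rng.normal(0, np.sqrt(2.0 / d_in), size=(d_in, h))
        self.b1 = np.zeros(h)
        self.gamma = np.ones(h)
        self.beta = np.zeros(h)
        self.W2 = rng.normal(0, np.sqrt(2.0 / h), size=(h, n_classes))
        self.b2 = np.zeros(n_classes)
        self.running_mean = np.zeros(h)
        self.running_var = np.ones(h)
        self._bn_batches = 0
        self._adam_m = [np.zeros_like(p) for p in self._params()]
        self._adam_v = [np.zeros_like(p) for p in self._params()]
        self._adam_t = 0

    def _params(self):
        return [self.W1, self.b1, self.gamma, self.beta, self.W2, self.b2]

    def _set_params(self, params):
        self.W1, self.b1, self.gamma, self.beta, self.W2, self.b2 = params

    @staticmethod
    def _softmax(z):
        z = z - z.max(axis=1, keepdims=True)
        e = np.exp(z)
        return e / e.sum(axis=1, keepdims=True)

    def _forward_train(self, X, bn_eps=1e-5):
        z1 = X @ self.W1 + self.b1
        mu = z1.mean(axis=0)
        var = z1.var(axis=0)
        # adaptive momentum: first batch adopts the batch stats outright,
        # later batches blend toward a 0.9 exponential average, so inference
        # stats stay calibrated even after very few updates
        t = self._bn_batches
        m = min(0.9, t / (t + 1.0))
        self.running_mean = m * self.running_mean + (1 - m) * mu
        self.running_var = m * self.running_var + (1 - m) * var
        self._bn_batches = t + 1
        z_hat = (z1 - mu) / np.sqrt(var + bn_eps)
        z_bn = self.gamma * z_hat + self.beta
        h = np.maximum(z_bn, 0.0)
        logits = h @ self.W2 + self.b2
        cache = (X, z1, mu, var, z_hat, z_bn, h, bn_eps)
        return logits, cache

    def _backward(self, cache, probs, onehot):
        X, z1, mu, var, z_hat, z_bn, h, bn_eps = cache
        n = X.shape[0]
        dlogits = (probs - onehot) / n
        dW2 = h.T @ dlogits
        db2 = dlogits.sum(axis=0)
        dh = dlogits @ self.W2.T
        dz_bn = dh * (z_bn > 0)
        dgamma = (dz_bn * z_hat).sum(axis=0)
        dbeta = dz_bn.sum(axis=0)
        dz_hat = dz_bn * self.gamma
        inv_std = 1.0 / np.sqrt(var + bn_eps)
        dvar = (dz_hat * (z1 - mu) * -0.5 * inv_std**3).sum(axis=0)
        dmu = (-dz_hat * inv_std).sum(axis=0) + dvar * (-2.0 / n) * (
            z1 - mu
        ).sum(axis=0)
        dz1 = dz_hat * inv_std + dvar * 2.0 * (z1 - mu) / n + dmu / n
        dW1 = X.T @ dz1
        db1 = dz1.sum(axis=0)
        return [dW1, db1, dgamma, dbeta, dW2, db2]

    def _adam_step(self, grads, beta1=0.9, beta2=0.999, eps=1e-8):
        self._adam_t += 1
        params = self._params()
        for i, (p, g) in enumerate(zip(params, grads)):
            self._adam_m[i] = beta1 * self._adam_m[i] + (1 - beta1) * g
            self._adam_v[i] = beta2 * self._adam_v[i] + (1 - beta2) * g**2
            m_hat = self._adam_m[i] / (1 - beta1**self._adam_t)
            v_hat = self._adam_v[i] / (1 - beta2**self._adam_t)
            params[i] = p - self.learning_rate * m_hat / (np.sqrt(v_hat) + eps)
        self._set_params(params)

    # -- public API ------------------------------------------------------
    def fit(self, X, y):
        """Train on cells x features ``X`` with string/int labels ``y``."""
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        self.classes_, y_idx = np.unique(y, return_inverse=True)
        n, d = X.shape
        n_classes = len(self.classes_)
        if n_classes < 2:
            raise ValueError("MLPClassifier needs at least 2 classes")
        rng = np.random.default_rng(self.seed)
        self._init_params(d, n_classes, rng)

        # held-out validation split for early stopping
        n_val = max(1, int(round(self.val_fraction * n))) if n > 4 else 0
        perm = rng.permutation(n)
        val_idx, train_idx = perm[:n_val], perm[n_val:]
        Xtr, ytr = X[train_idx], y_idx[train_idx]
        Xval, yval = X[val_idx], y_idx[val_idx]

        # oversampling pools per class
        class_pools = [np.flatnonzero(ytr == c) for c in range(n_classes)]
        if any(len(p) == 0 for p in class_pools):
            # a class fell entirely into the validation split; train on all
            Xtr, ytr = X, y_idx
            Xval = np.empty((0, d))
            class_pools = [np.flatnonzero(ytr == c) for c in range(n_classes)]
        majority = max(len(p) for p in class_pools)

        best_val = np.inf
        best_params = [p.copy() for p in self._params()]
        best_stats = (self.running_mean.copy(), self.running_var.copy())
        bad_epochs = 0
        for _ in range(self.max_epochs):
            # class-balanced epoch: every class resampled to majority size
            idx = np.concatenate(
                [rng.choice(p, size=majority, replace=True) for p in class_pools]
            )
            rng.shuffle(idx)
            for start in range(0, len(idx), self.batch_size):
                batch = idx[start : start + self.batch_size]
                if len(batch) < 2:
                    continue  # batch norm needs >= 2 rows
                logits, cache = self._forward_train(Xtr[batch])
                probs = self._softmax(logits)
                onehot = np.eye(n_classes)[ytr[batch]]
                grads = self._backward(cache, probs, onehot)
                self._adam_step(grads)

            if len(Xval) > 0:
                val_loss = self._loss(Xval, yval)
                if val_loss < best_val - 1e-6:
                    best_val = val_loss
                    best_params = [p.copy() for p in self._params()]
                    best_stats = (self.running_mean.copy(), self.running_var.copy())
                    bad_epochs = 0
                else:
                    bad_epochs += 1
                    if bad_epochs >= self.patience:
                        break
        if len(Xval) > 0:
            self._set_params(best_params)
            self.running_mean, self.running_var = best_stats
        return self

    def _loss(self, X, y_idx):
        probs = self.predict_proba(X)
        return float(-np.log(probs[np.arange(len(y_idx)), y_idx] + 1e-12).mean())

    def hidden_activations(self, X, bn_eps=1e-5):
        """Penultimate-layer activations (the cell embedding)."""
        X = np.asarray(X, dtype=float)
        z1 = X @ self.W1 + self.b1
        z_hat = (z1 - self.running_mean) / np.sqrt(self.running_var + bn_eps)
        return np.maximum(self.gamma * z_hat + self.beta, 0.0)

    def predict_proba(self, X):
        h = self.hidden_activations(X)
        return self._softmax(h @ self.W2 + self.b2)

    def predict(self, X):
        return self.classes_[self.predict_proba(X).argmax(axis=1)]
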