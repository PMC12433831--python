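"""Small binary multilayer perceptron used as the pixel classifier backend.

One hidden layer with logistic activations, weighted cross-entropy loss and
full-batch gradient descent with backtracking ("bold driver") step control,
so the training loss is non-increasing by construction and every run is
reproducible from its seed. Parameters live in one flat vector for easy
(de)serialization.
"""

from __future__ import annotations

import numpy as np

_L2 = 1e-4  # small ridge penalty for conditioning
_MAX_BACKTRACK = 40


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def _softplus(z: np.ndarray) -> np.ndarray:
    return np.logaddexp(0.0, z)


def init_params(n_in: int, n_hidden: int, seed: int) -> np.ndarray:
    rng = np.random.default_rng(seed)
    w1 = rng.normal(0.0, 1.0 / np.sqrt(n_in), size=(n_in, n_hidden))
    b1 = np.zeros(n_hidden)
    w2 = rng.normal(0.0, 1.0 / np.sqrt(n_hidden), size=n_hidden)
    b2 = np.zeros(1)
    return np.concatenate([w1.ravel(), b1, w2, b2])


def _unpack(theta: np.ndarray, n_in: int, n_hidden: int):
    i = n_in * n_hidden
    w1 = theta[:i].reshape(n_in, n_hidden)
    b1 = theta[i : i + n_hidden]
    w2 = theta[i + n_hidden : i + 2 * n_hidden]
    b2 = theta[-1]
    return w1, b1, w2, b2


def predict_logits(theta: np.ndarray, X: np.ndarray, n_hidden: int) -> np.ndarray:
    w1, b1, w2, b2 = _unpack(theta, X.shape[1], n_hidden)
    h = _sigmoid(X @ w1 + b1)
    return h @ w2 + b2


def predict_proba(theta: np.ndarray, X: np.ndarray, n_hidden: int) -> np.ndarray:
    return _sigmoid(predict_logits(theta, X, n_hidden))


def _loss_grad(theta, X, y, w, n_hidden):
    n_in = X.shape[1]
    w1, b1, w2, b2 = _unpack(theta, n_in, n_hidden)
    a = X @ w1 + b1
    h = _sigmoid(a)
    z = h @ w2 + b2
    wsum = w.sum()
    # weighted binary cross-entropy with logits
    loss = float(np.sum(w * (_softplus(z) - y * z)) / wsum)
    loss += 0.5 * _L2 * float(theta @ theta)

    dz = (_sigmoid(z) - y) * w / wsum
    gw2 = h.T @ dz
    gb2 = dz.sum()
    dh = np.outer(dz, w2)
    da = dh * h * (1.0 - h)
    gw1 = X.T @ da
    gb1 = da.sum(axis=0)
    grad = np.concatenate([gw1.ravel(), gb1, gw2, [gb2]]) + _L2 * theta
    return loss, grad


def train(
    X: np.ndarray,
    y: np.ndarray,
    sample_weight: np.ndarray,
    n_hidden: int,
    epochs: int,
    learning_rate: float,
    seed: int,
    init: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Fit and return (parameter vector, per-epoch loss history).

    Each epoch is one accepted full-batch step; a candidate step that would
    increase the loss is halved until it decreases it, so the recorded loss
    history is non-increasing.
    """
    theta = init_params(X.shape[1], n_hidden, seed) if init is None else init.copy()
    lr = learning_rate
    loss, grad = _loss_grad(theta, X, y, sample_weight, n_hidden)
    history = [loss]
    for _ in range(epochs):
        accepted = False
        for _try in range(_MAX_BACKTRACK):
            cand = theta - lr * grad
            closs, cgrad = _loss_grad(cand, X, y, sample_weight, n_hidden)
            if closs <= loss + 1e-15:
                theta, grad = cand, cgrad
                improvement = loss - closs
                loss = closs
                lr *= 1.1
                accepted = True
                break
            lr *= 0.5
        if not accepted or improvement < 1e-12:
            history.append(loss)
            break
        history.append(loss)
    return theta, np.asarray(history)
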