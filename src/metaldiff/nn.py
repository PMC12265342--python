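"""Minimal dense-network building blocks (numpy, explicit gradients).

The score and confidence models are small multilayer perceptrons applied to
per-edge invariant features; equivariance is obtained architecturally (the
MLPs only ever see distances, types, and time), so plain dense layers with
hand-written backprop are all that is needed.
"""

from __future__ import annotations

import numpy as np

Params = dict[str, np.ndarray]


def mlp_init(
    sizes: list[int], rng: np.random.Generator, prefix: str = "",
    small_output: bool = True,
) -> Params:
    """Xavier-initialized parameters for a tanh MLP with the given layer sizes.

    With ``small_output`` the final linear layer is scaled down 100x so the
    network starts near the trivial (zero) predictor, which keeps early
    training stable when outputs are summed over many edges.
    """
    params: Params = {}
    n_last = len(sizes) - 2
    for i, (n_in, n_out) in enumerate(zip(sizes[:-1], sizes[1:])):
        scale = np.sqrt(2.0 / (n_in + n_out))
        if small_output and i == n_last:
            scale *= 0.01
        params[f"{prefix}W{i}"] = rng.standard_normal((n_in, n_out)) * scale
        params[f"{prefix}b{i}"] = np.zeros(n_out)
    return params


def mlp_forward(
    x: np.ndarray, params: Params, n_layers: int, prefix: str = ""
) -> tuple[np.ndarray, list[np.ndarray]]:
    """Forward pass; tanh on hidden layers, linear output. Returns (out, cache)."""
    cache = [x]
    h = x
    for i in range(n_layers):
        h = h @ params[f"{prefix}W{i}"] + params[f"{prefix}b{i}"]
        if i < n_layers - 1:
            h = np.tanh(h)
        cache.append(h)
    return h, cache


def mlp_backward(
    grad_out: np.ndarray,
    params: Params,
    cache: list[np.ndarray],
    n_layers: int,
    prefix: str = "",
) -> tuple[Params, np.ndarray]:
    """Backprop through :func:`mlp_forward`; returns (param grads, grad wrt input)."""
    grads: Params = {}
    g = grad_out
    for i in reversed(range(n_layers)):
        h_in = cache[i] if i == 0 else cache[i]
        if i < n_layers - 1:
            g = g * (1.0 - cache[i + 1] ** 2)  # through tanh
        grads[f"{prefix}W{i}"] = h_in.T @ g
        grads[f"{prefix}b{i}"] = g.sum(axis=0)
        g = g @ params[f"{prefix}W{i}"].T
    return grads, g


class Adam:
    """Standard Adam over a flat parameter dict."""

    def __init__(self, params: Params, lr: float = 1e-3, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params: Params, grads: Params) -> None:
        self.t += 1
        for k in params:
            g = grads.get(k)
            if g is None:
                continue
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            mhat = self.m[k] / (1 - self.b1**self.t)
            vhat = self.v[k] / (1 - self.b2**self.t)
            params[k] -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def clip_global_norm(grads: Params, max_norm: float) -> float:
    """Scale all gradients so their joint L2 norm is at most max_norm."""
    total = np.sqrt(sum(float((g**2).sum()) for g in grads.values()))
    if total > max_norm > 0:
        scale = max_norm / total
        for k in grads:
            grads[k] = grads[k] * scale
    return total


def accumulate(total: Params, delta: Params, weight: float = 1.0) -> None:
    for k, v in delta.items():
        if k in total:
            total[k] += weight * v
        else:
            total[k] = weight * v


def params_to_jsonable(params: Params) -> dict:
    return {k: v.tolist() for k, v in params.items()}


def params_from_jsonable(blob: dict) -> Params:
    return {k: np.asarray(v, dtype=float) for k, v in blob.items()}
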