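"""Minimal NumPy neural-network core for the adversarial autoencoder.

Fully connected ReLU networks with explicit forward/backward passes and an
Adam optimizer.  The only non-routine piece is the WGAN gradient-penalty
parameter gradient: for a ReLU network the input gradient

    g(z) = W1 M1 W2 M2 ... W_L          (M_k = diag(a_k > 0))

is multilinear in the weights once the activation masks are fixed, and the
masks themselves have zero derivative almost everywhere, so the penalty's
gradient with respect to the weights has the closed form implemented in
:func:`gradient_penalty_param_grads` (bias gradients vanish a.e.).  Every
piece is checked against finite differences in the test suite.

All parameters are float64; all randomness flows through an explicit
``numpy.random.Generator``, so training is bit-reproducible.
"""

from __future__ import annotations

import numpy as np

Params = list[tuple[np.ndarray, np.ndarray]]  # [(W: in x out, b: out), ...]


def init_mlp(widths: list[int], rng: np.random.Generator) -> Params:
    """He-initialised weights, zero biases, for layers widths[i] -> widths[i+1]."""
    params: Params = []
    for fan_in, fan_out in zip(widths[:-1], widths[1:]):
        W = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(fan_in, fan_out))
        params.append((W, np.zeros(fan_out)))
    return params


def mlp_forward(
    params: Params, x: np.ndarray, final_relu: bool
) -> tuple[np.ndarray, dict]:
    """ReLU MLP forward pass.  ``final_relu`` controls the terminal activation."""
    h = np.asarray(x, dtype=float)
    inputs = []   # input to each layer
    masks = []    # ReLU mask per activated layer (None when linear)
    L = len(params)
    for k, (W, b) in enumerate(params):
        inputs.append(h)
        a = h @ W + b
        if k < L - 1 or final_relu:
            mask = a > 0
            h = a * mask
            masks.append(mask)
        else:
            h = a
            masks.append(None)
    return h, {"inputs": inputs, "masks": masks}


def mlp_backward(
    params: Params, cache: dict, grad_out: np.ndarray
) -> tuple[Params, np.ndarray]:
    """Backprop through :func:`mlp_forward`; returns (param grads, input grad)."""
    grads: list = [None] * len(params)
    g = np.asarray(grad_out, dtype=float)
    for k in range(len(params) - 1, -1, -1):
        W, _b = params[k]
        mask = cache["masks"][k]
        if mask is not None:
            g = g * mask
        x_in = cache["inputs"][k]
        grads[k] = (x_in.T @ g, g.sum(axis=0))
        g = g @ W.T
    return grads, g


def critic_score(params: Params, z: np.ndarray) -> np.ndarray:
    """Scalar critic output per row (linear head)."""
    out, _ = mlp_forward(params, z, final_relu=False)
    return out[:, 0]


def critic_input_grad(params: Params, z: np.ndarray) -> np.ndarray:
    """Per-row gradient of the critic score with respect to its input."""
    out, cache = mlp_forward(params, z, final_relu=False)
    ones = np.ones_like(out)
    _, gin = mlp_backward(params, cache, ones)
    return gin


def gradient_penalty_value(
    params: Params, z_hat: np.ndarray, lam: float
) -> float:
    """λ · mean over rows of (‖∇_ẑ D(ẑ)‖₂ − 1)²."""
    if lam < 0:
        raise ValueError("gradient-penalty weight must be non-negative")
    g = critic_input_grad(params, z_hat)
    norms = np.linalg.norm(g, axis=1)
    return float(lam * np.mean((norms - 1.0) ** 2))


def gradient_penalty_param_grads(
    params: Params, z_hat: np.ndarray, lam: float
) -> tuple[float, Params]:
    """Gradient penalty and its gradient w.r.t. the critic weights.

    With fixed ReLU masks the input gradient of sample i is the matrix product
    g_i = W1 M1 ... W_L; differentiating ‖g_i‖ in W_k yields the outer product
    of a forward tangent (started from the unit direction g_i/‖g_i‖) and the
    usual backward delta at layer k.  Bias gradients are zero a.e.
    """
    if lam < 0:
        raise ValueError("gradient-penalty weight must be non-negative")
    n = z_hat.shape[0]
    out, cache = mlp_forward(params, z_hat, final_relu=False)
    L = len(params)
    # backward deltas: delta_L = 1 at the output; delta_k (n x w_k) AFTER mask k
    deltas: list = [None] * (L + 1)
    g = np.ones((n, 1))
    deltas[L] = g
    for k in range(L - 1, 0, -1):
        W_next, _ = params[k]
        g = g @ W_next.T
        mask = cache["masks"][k - 1]
        if mask is not None:
            g = g * mask
        deltas[k] = g
    W1, _ = params[0]
    input_grad = deltas[1] @ W1.T  # n x d0
    norms = np.linalg.norm(input_grad, axis=1)
    gp = float(lam * np.mean((norms - 1.0) ** 2))
    safe = np.where(norms > 0, norms, 1.0)
    scale = 2.0 * lam * (norms - 1.0) / (n * safe)  # d(gp)/d‖g_i‖ per sample
    scale = np.where(norms > 0, scale, 0.0)
    v = input_grad * scale[:, None]  # scaled unit directions
    # forward tangents t_k (n x w_k): t_0 = v; t_k = (t_{k-1} W_k) * mask_k
    grads: Params = []
    t = v
    for k in range(L):
        W, b = params[k]
        grads.append((t.T @ deltas[k + 1], np.zeros_like(b)))
        if k < L - 1:
            t = t @ W
            mask = cache["masks"][k]
            if mask is not None:
                t = t * mask
    return gp, grads


def zeros_like_params(params: Params) -> Params:
    return [(np.zeros_like(W), np.zeros_like(b)) for W, b in params]


def add_params(a: Params, b: Params, scale: float = 1.0) -> Params:
    return [(Wa + scale * Wb, ba + scale * bb) for (Wa, ba), (Wb, bb) in zip(a, b)]


class Adam:
    """Adam optimizer over a flat list of parameter arrays."""

    def __init__(self, arrays: list[np.ndarray], lr: float = 2e-4,
                 beta1: float = 0.5, beta2: float = 0.999, eps: float = 1e-8):
        self.arrays = arrays
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(a) for a in arrays]
        self.v = [np.zeros_like(a) for a in arrays]
        self.t = 0

    def step(self, grads: list[np.ndarray]) -> None:
        self.t += 1
        lr_t = self.lr * np.sqrt(1 - self.b2 ** self.t) / (1 - self.b1 ** self.t)
        for a, g, m, v in zip(self.arrays, grads, self.m, self.v):
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            a -= lr_t * m / (np.sqrt(v) + self.eps)


def flatten(params: Params) -> list[np.ndarray]:
    out: list[np.ndarray] = []
    for W, b in params:
        out.extend((W, b))
    return out
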