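"""AdamW with AMSGrad, and the weighted softmax cross-entropy loss."""

from __future__ import annotations

import numpy as np

from .layers import Parameter

__all__ = ["AdamW", "softmax", "weighted_cross_entropy"]


class AdamW:
    """Adam with decoupled weight decay; AMSGrad keeps the running maximum of
    the second-moment estimate for the denominator.

    Weight decay is applied multiplicatively to the parameter itself
    (decoupled from the gradient), to every parameter.
    """

    def __init__(self, params, lr: float = 0.01, betas=(0.9, 0.999),
                 eps: float = 1e-8, weight_decay: float = 0.01,
                 amsgrad: bool = True):
        self.params: list[Parameter] = list(params)
        self.lr = lr
        self.beta1, self.beta2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.amsgrad = amsgrad
        self.t = 0
        self._m = [np.zeros_like(p.data) for p in self.params]
        self._v = [np.zeros_like(p.data) for p in self.params]
        self._vmax = [np.zeros_like(p.data) for p in self.params]

    def step(self) -> None:
        self.t += 1
        bc1 = 1.0 - self.beta1 ** self.t
        bc2 = 1.0 - self.beta2 ** self.t
        for p, m, v, vmax in zip(self.params, self._m, self._v, self._vmax):
            g = p.grad
            p.data *= 1.0 - self.lr * self.weight_decay
            m *= self.beta1
            m += (1.0 - self.beta1) * g
            v *= self.beta2
            v += (1.0 - self.beta2) * g * g
            if self.amsgrad:
                np.maximum(vmax, v, out=vmax)
                denom = np.sqrt(vmax / bc2) + self.eps
            else:
                denom = np.sqrt(v / bc2) + self.eps
            p.data -= self.lr * (m / bc1) / denom

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad[...] = 0.0


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def weighted_cross_entropy(logits: np.ndarray, targets: np.ndarray,
                           sample_weights: np.ndarray):
    """Per-sample-weighted cross entropy.

    Returns ``(loss, dlogits)`` where loss = sum_i w_i * ce_i / sum_i w_i
    (the standard weighted-mean reduction, so loss scale is comparable
    across batches with different class mixes).
    """
    probs = softmax(logits)
    n = logits.shape[0]
    wsum = sample_weights.sum()
    ce = -np.log(np.clip(probs[np.arange(n), targets], 1e-12, None))
    loss = float((sample_weights * ce).sum() / wsum)
    dlogits = probs.copy()
    dlogits[np.arange(n), targets] -= 1.0
    dlogits *= (sample_weights / wsum)[:, None]
    return loss, dlogits
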