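"""AdamW: Adam with decoupled weight decay."""

from __future__ import annotations

from typing import Dict, List

import numpy as np

from .autodiff import Tensor


class AdamW:
    """Decoupled-weight-decay Adam over a list of parameter tensors.

    beta1 is the gradient momentum coefficient; weight decay multiplies
    parameters directly by ``(1 - lr * wd)`` each step rather than
    entering the gradient.
    """

    def __init__(self, params: List[Tensor], lr: float = 1e-4,
                 beta1: float = 0.9, beta2: float = 0.999,
                 eps: float = 1e-8, weight_decay: float = 0.01):
        self.params = params
        self.lr, self.beta1, self.beta2 = lr, beta1, beta2
        self.eps, self.weight_decay = eps, weight_decay
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bc1 = 1.0 - b1 ** self.t
        bc2 = 1.0 - b2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            g = p.grad
            m += (1.0 - b1) * (g - m)
            v += (1.0 - b2) * (g * g - v)
            mhat = m / bc1
            vhat = v / bc2
            if self.weight_decay:
                p.data *= 1.0 - self.lr * self.weight_decay
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    # -- checkpoint support ---------------------------------------------------
    def state_dict(self) -> Dict[str, np.ndarray]:
        state = {"t": np.array(self.t)}
        for i, (m, v) in enumerate(zip(self.m, self.v)):
            state[f"m{i}"] = m.copy()
            state[f"v{i}"] = v.copy()
        return state

    def load_state_dict(self, state: Dict[str, np.ndarray]) -> None:
        self.t = int(state["t"])
        for i in range(len(self.m)):
            self.m[i][...] = state[f"m{i}"]
            self.v[i][...] = state[f"v{i}"]
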