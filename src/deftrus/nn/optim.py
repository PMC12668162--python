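"""Adam optimizer with optional linear learning-rate decay."""

from __future__ import annotations

import numpy as np

__all__ = ["Adam"]


class Adam:
    def __init__(self, params, lr=2e-4, betas=(0.5, 0.999), eps=1e-8):
        self.params = list(params)
        self.lr = lr
        self.beta1, self.beta2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bc1 = 1.0 - b1 ** self.t
        bc2 = 1.0 - b2 ** self.t
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad.astype(p.data.dtype)
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * (g * g)
            mhat = self.m[i] / bc1
            vhat = self.v[i] / bc2
            p.data = p.data - self.lr * mhat / (np.sqrt(vhat) + self.eps)

    # checkpointing -----------------------------------------------------------
    def state_dict(self) -> dict:
        state = {"t": self.t, "lr": self.lr}
        for i in range(len(self.params)):
            state[f"m{i}"] = self.m[i]
            state[f"v{i}"] = self.v[i]
        return state

    def load_state_dict(self, state: dict):
        self.t = int(state["t"])
        self.lr = float(state["lr"])
        for i in range(len(self.params)):
            self.m[i] = np.asarray(state[f"m{i}"])
            self.v[i] = np.asarray(state[f"v{i}"])
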