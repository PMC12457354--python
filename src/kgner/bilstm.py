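"""Bidirectional LSTM over fused character representations.

Per timestep the gates are computed jointly from the concatenated input and
previous hidden state,

    [i_t; o_t; f_t; c~_t] = [sigma; sigma; sigma; tanh](W [x_t; h_{t-1}] + b)
    c_t = f_t * c_{t-1} + i_t * c~_t
    h_t = o_t * tanh(c_t)

and the forward/backward passes are concatenated position-wise:
``h_t = [h_t-> ; h_t<-]``.  Variable-length batches are handled by carrying
the previous state through padded steps, so the backward direction never
leaks padding into real positions.
"""

from __future__ import annotations

import numpy as np

from .nn import Module, Tensor, concat, dropout, parameter, stack, unstack, where, xavier


class LSTMDirection(Module):
    def __init__(self, d_in: int, hidden: int, rng: np.random.Generator):
        self.hidden = hidden
        self.W = parameter(xavier(rng, d_in + hidden, 4 * hidden))
        b = np.zeros(4 * hidden, dtype=np.float32)
        b[2 * hidden:3 * hidden] = 1.0  # forget-gate bias init
        self.b = parameter(b)

    def __call__(self, xs: Tensor, valid: np.ndarray, reverse: bool = False) -> Tensor:
        """xs: (B, L, d_in); valid: (B, L) boolean. Returns (B, L, hidden)."""
        bsz, length, _ = xs.shape
        hid = self.hidden
        steps = unstack(xs, axis=1)
        order = range(length - 1, -1, -1) if reverse else range(length)
        h = Tensor(np.zeros((bsz, hid), dtype=np.float32))
        c = Tensor(np.zeros((bsz, hid), dtype=np.float32))
        outputs: dict[int, Tensor] = {}
        for t in order:
            gates = concat([steps[t], h], axis=-1) @ self.W + self.b
            gi = gates[:, 0 * hid:1 * hid].sigmoid()
            go = gates[:, 1 * hid:2 * hid].sigmoid()
            gf = gates[:, 2 * hid:3 * hid].sigmoid()
            cand = gates[:, 3 * hid:4 * hid].tanh()
            c_new = gf * c + gi * cand
            h_new = go * c_new.tanh()
            m = valid[:, t:t + 1]
            c = where(m, c_new, c)
            h = where(m, h_new, h)
            outputs[t] = h * Tensor(m.astype(np.float32))
        return stack([outputs[t] for t in range(length)], axis=1)


class BiLSTM(Module):
    """Stack of bidirectional layers; output width is 2 * hidden."""

    def __init__(self, d_in: int, hidden: int, layers: int, rng: np.random.Generator,
                 p_drop: float = 0.0):
        self.layers = []
        width = d_in
        for _ in range(layers):
            self.layers.append(LSTMDirection(width, hidden, rng))  # forward
            self.layers.append(LSTMDirection(width, hidden, rng))  # backward
            width = 2 * hidden
        self.p_drop = p_drop

    def __call__(self, xs: Tensor, valid: np.ndarray,
                 rng: np.random.Generator | None = None,
                 training: bool = False) -> Tensor:
        out = xs
        for i in range(0, len(self.layers), 2):
            fwd = self.layers[i](out, valid, reverse=False)
            bwd = self.layers[i + 1](out, valid, reverse=True)
            out = concat([fwd, bwd], axis=-1)
            if i + 2 < len(self.layers):
                out = dropout(out, self.p_drop, rng, training)
        return out


def bilstm_forward(inputs: Tensor | np.ndarray, model: BiLSTM,
                   lengths: np.ndarray | None = None) -> Tensor:
    """Run a BiLSTM over (B, L, width) or a single (L, width) sequence."""
    x = inputs if isinstance(inputs, Tensor) else Tensor(np.asarray(inputs, dtype=np.float32))
    single = x.ndim == 2
    if single:
        x = x.reshape(1, *x.shape)
    bsz, length, _ = x.shape
    if lengths is None:
        lengths = np.full(bsz, length)
    valid = np.arange(length)[None, :] < np.asarray(lengths)[:, None]
    out = model(x, valid)
    return out.reshape(*out.shape[1:]) if single else out
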