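"""Prediction heads for fine-tuning.

Every head consumes per-position H-dimensional vectors — the encoder's
final layer in "+Med-BERT" conditions, the raw (trainable) multi-level
embeddings in base conditions, or frozen static code vectors in the
static-embedding comparison — and produces one scalar risk logit per
sequence.

* ``ffl``   — sum over real positions, one feed-forward layer, affine.
* ``gru``   — gated recurrent unit rolled left-to-right; last real state.
* ``bigru`` — forward and backward GRUs; concatenated last states.
* ``retain``— the two-level attention recurrent architecture: two GRUs run
  in reverse time produce a scalar visit-level attention (softmax over real
  positions) and a vector gate; the context is the attention- and gate-
  weighted sum of the input vectors.
"""

from __future__ import annotations

import numpy as np

from .nn import Tensor, concat, softmax, stack
from .nn.optim import truncated_normal

HEAD_KINDS = ("ffl", "gru", "bigru", "retain")


def _dense(shape, rng):
    return Tensor(truncated_normal(shape, rng), requires_grad=True)


def _zeros(shape):
    return Tensor(np.zeros(shape), requires_grad=True)


def init_head_params(kind: str, hidden: int, rng: np.random.Generator) -> dict[str, Tensor]:
    H = hidden
    if kind == "ffl":
        return {
            "ffl_w1": _dense((H, H), rng),
            "ffl_b1": _zeros((H,)),
            "ffl_w2": _dense((H, 1), rng),
            "ffl_b2": _zeros((1,)),
        }
    if kind in ("gru", "bigru"):
        dirs = ("fw",) if kind == "gru" else ("fw", "bw")
        params: dict[str, Tensor] = {}
        for d in dirs:
            for gate in ("z", "r", "h"):
                params[f"{d}_W{gate}"] = _dense((H, H), rng)
                params[f"{d}_U{gate}"] = _dense((H, H), rng)
                params[f"{d}_b{gate}"] = _zeros((H,))
        width = H * len(dirs)
        params["out_w"] = _dense((width, 1), rng)
        params["out_b"] = _zeros((1,))
        return params
    if kind == "retain":
        params = {}
        for stream in ("a", "b"):  # alpha (scalar attention) and beta (gates)
            for gate in ("z", "r", "h"):
                params[f"{stream}_W{gate}"] = _dense((H, H), rng)
                params[f"{stream}_U{gate}"] = _dense((H, H), rng)
                params[f"{stream}_b{gate}"] = _zeros((H,))
        params["alpha_w"] = _dense((H, 1), rng)
        params["alpha_b"] = _zeros((1,))
        params["beta_w"] = _dense((H, H), rng)
        params["beta_b"] = _zeros((H,))
        params["out_w"] = _dense((H, 1), rng)
        params["out_b"] = _zeros((1,))
        return params
    raise ValueError(f"unknown head kind {kind!r}; expected one of {HEAD_KINDS}")


def _gru_roll(
    x: Tensor, mask: np.ndarray, params: dict[str, Tensor], prefix: str, reverse: bool = False
) -> tuple[list[Tensor], Tensor]:
    """Roll a GRU over (B, T, H); masked positions leave the state unchanged.

    Returns (per-step states, last state).
    """
    B, T, H = x.shape
    Wz, Uz, bz = params[f"{prefix}_Wz"], params[f"{prefix}_Uz"], params[f"{prefix}_bz"]
    Wr, Ur, br = params[f"{prefix}_Wr"], params[f"{prefix}_Ur"], params[f"{prefix}_br"]
    Wh, Uh, bh = params[f"{prefix}_Wh"], params[f"{prefix}_Uh"], params[f"{prefix}_bh"]
    h = Tensor(np.zeros((B, H)))
    states: list[Tensor] = []
    steps = range(T - 1, -1, -1) if reverse else range(T)
    for t in steps:
        xt = x[:, t]
        m = mask[:, t][:, None]  # (B,1): 1 keeps the update, 0 carries state
        z = (xt @ Wz + h @ Uz + bz).sigmoid()
        r = (xt @ Wr + h @ Ur + br).sigmoid()
        cand = (xt @ Wh + (r * h) @ Uh + bh).tanh()
        h_new = (1.0 - z) * h + z * cand
        h = h_new * m + h * (1.0 - m)
        states.append(h)
    if reverse:
        states = states[::-1]
    return states, h


def head_logit(
    kind: str,
    params: dict[str, Tensor],
    x: Tensor,
    mask: np.ndarray,
) -> Tensor:
    """Scalar logit per sequence for any head kind; (B,) output."""
    if kind == "ffl":
        pooled = (x * mask[:, :, None]).sum(axis=1)
        h = (pooled @ params["ffl_w1"] + params["ffl_b1"]).tanh()
        return (h @ params["ffl_w2"] + params["ffl_b2"]).reshape(-1)
    if kind == "gru":
        _, last = _gru_roll(x, mask, params, "fw")
        return (last @ params["out_w"] + params["out_b"]).reshape(-1)
    if kind == "bigru":
        _, last_f = _gru_roll(x, mask, params, "fw")
        _, last_b = _gru_roll(x, mask, params, "bw", reverse=True)
        both = concat([last_f, last_b], axis=-1)
        return (both @ params["out_w"] + params["out_b"]).reshape(-1)
    if kind == "retain":
        a_states, _ = _gru_roll(x, mask, params, "a", reverse=True)
        b_states, _ = _gru_roll(x, mask, params, "b", reverse=True)
        g = stack(a_states, axis=1)  # (B,T,H)
        e = (g @ params["alpha_w"] + params["alpha_b"]).reshape(x.shape[0], x.shape[1])
        e = e + Tensor((1.0 - mask) * -1e9)
        alpha = softmax(e, axis=-1)  # (B,T), zero on PAD
        beta = (stack(b_states, axis=1) @ params["beta_w"] + params["beta_b"]).tanh()
        ctx = (x * beta * alpha.reshape(x.shape[0], x.shape[1], 1)).sum(axis=1)
        return (ctx @ params["out_w"] + params["out_b"]).reshape(-1)
    raise ValueError(f"unknown head kind {kind!r}")


__all__ = ["HEAD_KINDS", "init_head_params", "head_logit"]
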