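"""NumPy implementation of the two-branch TCR-HLA classifier.

Architecture (one forward pass):

* HLA branch: the encoded pseudo sequence is flattened and passed through
  one ReLU dense layer.
* TCR branch: the encoded (27 x channels) CDR3 tensor passes through a 1-D
  convolution + ReLU + global max-pool (a non-position-specific motif
  detector); the pooled vector is concatenated with the CDR3-length one-hot
  and the flat encodings of CDR1/CDR2/CDR2.5/CDR3, then one ReLU dense
  layer.
* Head: branch outputs are concatenated, pass through one or two ReLU
  dense layers, dropout, and a single sigmoid unit.

Training minimises binary cross-entropy with Adam.  Gradients are written
by hand; all parameters are plain float64 arrays in a dict, which keeps
runs bit-reproducible for a fixed seed and single thread of execution.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = ["init_params", "forward", "loss_and_grads", "AdamState", "adam_step"]


def _he(rng: np.random.Generator, fan_in: int, shape) -> np.ndarray:
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape)


def pooled_groups(conv_positions: int, pool_size: int | None) -> int:
    """Number of max-pool groups over the convolution output."""
    if pool_size is None or pool_size >= conv_positions:
        return 1
    return -(-conv_positions // pool_size)


def init_params(rng: np.random.Generator, *, hla_flat_dim: int, cdr3_channels: int,
                flat_dim: int, len_dim: int, conv_filters: int, conv_kernel: int,
                cdr3_positions: int, pool_size: int | None,
                hla_dense_units: int, tcr_dense_units: int,
                head_units: tuple[int, ...]) -> dict[str, np.ndarray]:
    """He-initialised parameter dict for the architecture above."""
    params: dict[str, np.ndarray] = {}
    params["Wh"] = _he(rng, hla_flat_dim, (hla_flat_dim, hla_dense_units))
    params["bh"] = np.zeros(hla_dense_units)
    params["Wc"] = _he(rng, conv_kernel * cdr3_channels,
                       (conv_kernel, cdr3_channels, conv_filters))
    params["bc"] = np.zeros(conv_filters)
    groups = pooled_groups(cdr3_positions - conv_kernel + 1, pool_size)
    tcr_in = groups * conv_filters + len_dim + flat_dim
    params["Wt"] = _he(rng, tcr_in, (tcr_in, tcr_dense_units))
    params["bt"] = np.zeros(tcr_dense_units)
    width = hla_dense_units + tcr_dense_units
    for i, units in enumerate(head_units, start=1):
        params[f"W{i}"] = _he(rng, width, (width, units))
        params[f"b{i}"] = np.zeros(units)
        width = units
    params["Wo"] = rng.normal(0.0, np.sqrt(1.0 / width), (width, 1))
    params["bo"] = np.zeros(1)
    return params


def forward(params: dict, batch: dict, *, pool_size: int | None = None,
            dropout_p: float = 0.0,
            train: bool = False, rng: np.random.Generator | None = None,
            return_cache: bool = False):
    """Compute prediction scores in (0, 1); optionally return the cache
    needed for the backward pass.

    ``batch`` carries ``hla`` (n, P, D), ``cdr3`` (n, 27, D),
    ``cdr_flat`` (n, F) and ``cdr3_len_onehot`` (n, 27).
    """
    n = batch["hla"].shape[0]
    xh = batch["hla"].reshape(n, -1).astype(np.float64)

    h_pre = xh @ params["Wh"] + params["bh"]
    h = np.maximum(h_pre, 0.0)

    kernel = params["Wc"].shape[0]
    windows = sliding_window_view(batch["cdr3"].astype(np.float64),
                                  kernel, axis=1)       # (n, T, D, K)
    z_pre = np.einsum("ntdk,kdf->ntf", windows, params["Wc"]) + params["bc"]
    z = np.maximum(z_pre, 0.0)

    n_pos, n_filt = z.shape[1], z.shape[2]
    groups = pooled_groups(n_pos, pool_size)
    width = -(-n_pos // groups)
    padded = np.full((n, groups * width, n_filt), -np.inf)
    padded[:, :n_pos, :] = z
    grouped = padded.reshape(n, groups, width, n_filt)
    local_amax = grouped.argmax(axis=2)                  # (n, G, F)
    amax = local_amax + width * np.arange(groups)[None, :, None]
    c = np.take_along_axis(grouped, local_amax[:, :, None, :],
                           axis=2)[:, :, 0, :].reshape(n, groups * n_filt)

    t_in = np.concatenate([c, batch["cdr3_len_onehot"].astype(np.float64),
                           batch["cdr_flat"].astype(np.float64)], axis=1)
    t_pre = t_in @ params["Wt"] + params["bt"]
    t = np.maximum(t_pre, 0.0)

    u = np.concatenate([h, t], axis=1)
    head_cache = []
    i = 1
    while f"W{i}" in params:
        u_in = u
        u_pre = u_in @ params[f"W{i}"] + params[f"b{i}"]
        u = np.maximum(u_pre, 0.0)
        head_cache.append((u_in, u_pre))
        i += 1

    if train and dropout_p > 0.0:
        if rng is None:
            raise ValueError("dropout in training mode requires an rng")
        mask = (rng.random(u.shape) >= dropout_p) / (1.0 - dropout_p)
        u_drop = u * mask
    else:
        mask = None
        u_drop = u

    logit = u_drop @ params["Wo"] + params["bo"]
    score = 1.0 / (1.0 + np.exp(-logit[:, 0]))

    if not return_cache:
        return score
    cache = {"xh": xh, "h_pre": h_pre, "h": h, "windows": windows,
             "z_pre": z_pre, "amax": amax, "groups": groups,
             "t_in": t_in, "t_pre": t_pre,
             "t": t, "head": head_cache, "mask": mask, "u_drop": u_drop,
             "score": score, "n_head": len(head_cache)}
    return score, cache


def loss_and_grads(params: dict, batch: dict, labels: np.ndarray, *,
                   pool_size: int | None = None, dropout_p: float = 0.0,
                   rng: np.random.Generator | None = None):
    """Mean binary cross-entropy and its gradient w.r.t. every parameter."""
    y = np.asarray(labels, dtype=np.float64)
    score, cache = forward(params, batch, pool_size=pool_size,
                           dropout_p=dropout_p, train=True,
                           rng=rng, return_cache=True)
    eps = 1e-12
    loss = float(-np.mean(y * np.log(score + eps)
                          + (1.0 - y) * np.log(1.0 - score + eps)))

    n = y.shape[0]
    grads: dict[str, np.ndarray] = {}
    dlogit = ((score - y) / n)[:, None]                   # sigmoid+BCE shortcut

    grads["Wo"] = cache["u_drop"].T @ dlogit
    grads["bo"] = dlogit.sum(axis=0)
    du = dlogit @ params["Wo"].T
    if cache["mask"] is not None:
        du = du * cache["mask"]

    for i in range(cache["n_head"], 0, -1):
        u_in, u_pre = cache["head"][i - 1]
        du_pre = du * (u_pre > 0.0)
        grads[f"W{i}"] = u_in.T @ du_pre
        grads[f"b{i}"] = du_pre.sum(axis=0)
        du = du_pre @ params[f"W{i}"].T

    n_h = params["bh"].shape[0]
    dh, dt = du[:, :n_h], du[:, n_h:]

    dh_pre = dh * (cache["h_pre"] > 0.0)
    grads["Wh"] = cache["xh"].T @ dh_pre
    grads["bh"] = dh_pre.sum(axis=0)

    dt_pre = dt * (cache["t_pre"] > 0.0)
    grads["Wt"] = cache["t_in"].T @ dt_pre
    grads["bt"] = dt_pre.sum(axis=0)
    dt_in = dt_pre @ params["Wt"].T

    n_f = params["bc"].shape[0]
    groups = cache["groups"]
    dc = dt_in[:, :groups * n_f].reshape(-1, groups, n_f)  # (n, G, F)
    dz = np.zeros_like(cache["z_pre"])
    np.put_along_axis(dz, cache["amax"], dc, axis=1)
    dz *= cache["z_pre"] > 0.0
    grads["Wc"] = np.einsum("ntdk,ntf->kdf", cache["windows"], dz)
    grads["bc"] = dz.sum(axis=(0, 1))
    return loss, grads


class AdamState:
    """First/second moment accumulators for Adam."""

    def __init__(self, params: dict):
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0


def adam_step(params: dict, grads: dict, state: AdamState, *,
              lr: float = 1e-3, beta1: float = 0.9, beta2: float = 0.999,
              eps: float = 1e-8, weight_decay: float = 0.0) -> None:
    """In-place Adam update with decoupled (AdamW-style) weight decay.

    Decay applies to weight matrices only, never biases.
    """
    state.t += 1
    b1t = 1.0 - beta1 ** state.t
    b2t = 1.0 - beta2 ** state.t
    for k, g in grads.items():
        state.m[k] = beta1 * state.m[k] + (1.0 - beta1) * g
        state.v[k] = beta2 * state.v[k] + (1.0 - beta2) * g * g
        params[k] -= lr * (state.m[k] / b1t) / (np.sqrt(state.v[k] / b2t) + eps)
        if weight_decay and k.startswith("W"):
            params[k] -= lr * weight_decay * params[k]
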