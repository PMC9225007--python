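"""Discretized gLV baseline trained with the same stochastic-gradient loop
as the recurrent model.

The multiplicative one-step map is used exactly as written,

    x_i(t+1) = x_i(t) * (r_i + sum_j a_ij x_j(t)),

with no added "1 +" or explicit time step: a species at a fixed point of the
map satisfies r_i + sum_j a_ij x_j = 1, not 0.  Metabolite concentrations at
step t+1 are predicted by a feed-forward network applied to x(t+1).  Inputs
are scaled to [0, 1] per feature and per time step by the training-data
maximum, and r, A are initialized to zero before fitting.
"""

from __future__ import annotations

import numpy as np

from .nn import FFN, Adam
from .types import GLVParams, TrajectoryTable


def step_glv_discrete(params: "GLVParams | tuple[np.ndarray, np.ndarray]",
                      x_t: np.ndarray) -> np.ndarray:
    """One application of the multiplicative update (no metabolites).

    Accepts a :class:`GLVParams` or a bare ``(r, A)`` pair — the discrete
    map has no self-limitation requirement, unlike the ODE system.
    """
    if isinstance(params, GLVParams):
        r, A = params.r, params.A
    else:
        r, A = (np.asarray(v, dtype=float) for v in params)
    x = np.asarray(x_t, dtype=float)
    if np.any(x < 0):
        raise ValueError("discrete gLV update requires nonnegative abundances")
    return x * (r + x @ A.T)


class DiscreteGLVModel:
    """Fitted discrete gLV map plus optional metabolite head and its scalers."""

    def __init__(self, r: np.ndarray, A: np.ndarray, head: FFN | None,
                 x_max: np.ndarray, c_max: np.ndarray | None):
        self.r = r
        self.A = A
        self.head = head
        self.x_max = x_max  # (T, S) per-timestep feature maxima
        self.c_max = c_max  # (T, M) or None
        self.loss_history: list[float] = []

    def predict(self, x0: np.ndarray) -> tuple[np.ndarray, np.ndarray | None]:
        """Roll the fitted map from a raw initial state; returns raw-scale
        abundance trajectory (T, S) and metabolite trajectory (T, M) or None
        (the metabolite row at time 0 is the head applied to x(0))."""
        T = self.x_max.shape[0]
        xs = np.zeros((T, self.r.shape[0]))
        xs[0] = np.asarray(x0, dtype=float) / self.x_max[0]
        for t in range(T - 1):
            xs[t + 1] = xs[t] * (self.r + self.A @ xs[t])
        X = xs * self.x_max
        C = None
        if self.head is not None:
            C = np.stack([self.head(xs[t][None, :])[0] * self.c_max[t]
                          for t in range(T)])
        return X, C


def fit_glv_discrete_with_head(
    tables: list[TrajectoryTable],
    head_hidden: tuple[int, ...] = (64,),
    epochs: int = 200,
    learning_rate: float = 0.005,
    batch_size: int = 20,
    weight_decay: float = 1e-5,
    seed: int = 0,
    with_metabolites: bool = True,
) -> DiscreteGLVModel:
    """Fit the discrete map (and metabolite head) by Adam on the free-running
    rollout loss, backpropagating through the multiplicative updates."""
    X = np.stack([tb.X for tb in tables])  # (N, T, S)
    N, T, S = X.shape
    x_max = np.maximum(X.max(axis=0), 1e-12)
    Xs = X / x_max
    head = None
    Cs = None
    c_max = None
    if with_metabolites:
        for tb in tables:
            if tb.C is None:
                raise ValueError("tables are missing metabolite columns")
        C = np.stack([tb.C for tb in tables])
        c_max = np.maximum(C.max(axis=0), 1e-12)
        Cs = C / c_max
        M = C.shape[2]
        head = FFN([S, *head_hidden, M], seed=seed + 1)

    r = np.zeros(S)
    A = np.zeros((S, S))
    params: dict[str, np.ndarray] = {"r": r, "A": A}
    if head is not None:
        params.update({f"head.{k}": v for k, v in head.params.items()})
    adam = Adam(params, lr=learning_rate, weight_decay=weight_decay)
    rng = np.random.default_rng(seed)
    history = []
    for _epoch in range(epochs):
        perm = rng.permutation(N)
        epoch_loss = 0.0
        for start in range(0, N, batch_size):
            idx = perm[start:start + batch_size]
            xb = Xs[idx]  # (B, T, S)
            B = len(idx)
            xs = [xb[:, 0]]
            for t in range(T - 1):
                xs.append(xs[t] * (r + xs[t] @ A.T))
            pred = np.stack(xs, axis=1)
            err_x = pred[:, 1:] - xb[:, 1:]
            loss = float(np.mean(err_x ** 2))
            dxs = np.zeros((B, T, S))
            dxs[:, 1:] = (2.0 / err_x.size) * err_x
            head_grads_total = None
            if head is not None:
                cb = Cs[idx]
                flat = pred.reshape(B * T, S)
                c_pred, hc = head.forward(flat)
                err_c = c_pred.reshape(B, T, -1)[:, 1:] - cb[:, 1:]
                loss += float(np.mean(err_c ** 2))
                d_c = np.zeros((B, T, err_c.shape[2]))
                d_c[:, 1:] = (2.0 / err_c.size) * err_c
                head_grads_total, d_flat = head.backward(hc, d_c.reshape(B * T, -1))
                dxs += d_flat.reshape(B, T, S)
            if not np.isfinite(loss):
                raise RuntimeError("NaN loss in discrete gLV training")
            dr = np.zeros(S)
            dA = np.zeros((S, S))
            carry = np.zeros((B, S))
            for t in reversed(range(T - 1)):
                dnext = dxs[:, t + 1] + carry
                xt = xs[t]
                u = r + xt @ A.T
                dr += (dnext * xt).sum(axis=0)
                dA += np.einsum("bi,bj->ij", dnext * xt, xt)
                carry = dnext * u + (dnext * xt) @ A
            grads = {"r": dr, "A": dA}
            if head_grads_total is not None:
                grads.update({f"head.{k}": v for k, v in head_grads_total.items()})
            adam.step(grads)
            epoch_loss += loss * B
        history.append(epoch_loss / N)
    model = DiscreteGLVModel(r, A, head, x_max, c_max)
    model.loss_history = history
    return model
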