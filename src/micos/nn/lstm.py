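"""LSTM unit, shared-weight rollout with teacher forcing, and backprop.

One LSTM unit maps the (standardized) community state at time t to the state
at time t+1.  The gate equations are

    i_t = sigmoid(W_ii x_t + b_ii + W_hi h_{t-1} + b_hi)
    f_t = sigmoid(W_if x_t + b_if + W_hf h_{t-1} + b_hf)
    g_t = tanh  (W_ig x_t + b_ig + W_hg h_{t-1} + b_hg)
    o_t = sigmoid(W_io x_t + b_io + W_ho h_{t-1} + b_ho)
    c_t = f_t * c_{t-1} + i_t * g_t
    h_t = o_t * tanh(c_t)

and the output map reads the next state off the output gate:

    y_t = W_yo o_t + b_yo

y_t is fed back as the input of the next unit (free running) unless teacher
forcing substitutes the observed state at that step.  All weights are shared
across time steps.  Gradients are propagated through the feedback path, so
training with teacher forcing probability 0 optimizes the full multi-step
rollout while probability 1 reduces to independent one-step regression.
"""

from __future__ import annotations

import numpy as np

#: parameter names of one LSTM unit plus the linear output map
GATE_NAMES = ("i", "f", "g", "o")

LSTMWeights = dict[str, np.ndarray]


def init_lstm(input_dim: int, hidden_dim: int, seed: int = 0) -> LSTMWeights:
    """Uniform fan-in initialization, U(-1/sqrt(H), 1/sqrt(H)), seeded."""
    rng = np.random.default_rng(seed)
    k = 1.0 / np.sqrt(hidden_dim)
    W: LSTMWeights = {}
    for gate in GATE_NAMES:
        W[f"W_i{gate}"] = rng.uniform(-k, k, size=(hidden_dim, input_dim))
        W[f"W_h{gate}"] = rng.uniform(-k, k, size=(hidden_dim, hidden_dim))
        W[f"b_i{gate}"] = rng.uniform(-k, k, size=hidden_dim)
        W[f"b_h{gate}"] = rng.uniform(-k, k, size=hidden_dim)
    W["W_yo"] = rng.uniform(-k, k, size=(input_dim, hidden_dim))
    W["b_yo"] = rng.uniform(-k, k, size=input_dim)
    return W


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def lstm_cell_step(x_t: np.ndarray, h_prev: np.ndarray, c_prev: np.ndarray,
                   W: LSTMWeights) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """One evaluation of the gate equations.

    Accepts (batch, dim) or (dim,) arrays; returns (h_t, c_t, o_t).
    """
    squeeze = x_t.ndim == 1
    x = np.atleast_2d(x_t)
    h = np.atleast_2d(h_prev)
    c = np.atleast_2d(c_prev)
    if x.shape[1] != W["W_ii"].shape[1]:
        raise ValueError(f"input dim {x.shape[1]} != weight dim {W['W_ii'].shape[1]}")
    if h.shape[1] != W["W_hi"].shape[1]:
        raise ValueError(f"hidden dim {h.shape[1]} != weight dim {W['W_hi'].shape[1]}")
    i = _sigmoid(x @ W["W_ii"].T + W["b_ii"] + h @ W["W_hi"].T + W["b_hi"])
    f = _sigmoid(x @ W["W_if"].T + W["b_if"] + h @ W["W_hf"].T + W["b_hf"])
    g = np.tanh(x @ W["W_ig"].T + W["b_ig"] + h @ W["W_hg"].T + W["b_hg"])
    o = _sigmoid(x @ W["W_io"].T + W["b_io"] + h @ W["W_ho"].T + W["b_ho"])
    c_t = f * c + i * g
    h_t = o * np.tanh(c_t)
    if squeeze:
        return h_t[0], c_t[0], o[0]
    return h_t, c_t, o


def lstm_forward(W: LSTMWeights, X: np.ndarray,
                 teacher_mask: np.ndarray | None = None
                 ) -> tuple[np.ndarray, dict]:
    """Roll the unit over *n_steps* transitions.

    Parameters
    ----------
    X : (batch, n_steps, dim) standardized observed states; ``X[:, 0]`` is
        always the first input, and ``X[:, t]`` (t >= 1) is used as the input
        of step t wherever ``teacher_mask[:, t]`` is True.
    teacher_mask : (batch, n_steps) boolean; column 0 is ignored. None means
        fully free-running (all predictions forecast from the state at time 0).

    Returns
    -------
    ys : (batch, n_steps, dim) outputs; ``ys[:, t]`` predicts time t+1.
    cache : intermediates for :func:`lstm_backward`.
    """
    B, T, D = X.shape
    H = W["W_hi"].shape[0]
    if teacher_mask is None:
        teacher_mask = np.zeros((B, T), dtype=bool)
    h = np.zeros((B, H))
    c = np.zeros((B, H))
    ys = np.zeros((B, T, D))
    steps = []
    y_prev = None
    for t in range(T):
        if t == 0:
            u = X[:, 0]
        else:
            u = np.where(teacher_mask[:, t, None], X[:, t], y_prev)
        i = _sigmoid(u @ W["W_ii"].T + W["b_ii"] + h @ W["W_hi"].T + W["b_hi"])
        f = _sigmoid(u @ W["W_if"].T + W["b_if"] + h @ W["W_hf"].T + W["b_hf"])
        g = np.tanh(u @ W["W_ig"].T + W["b_ig"] + h @ W["W_hg"].T + W["b_hg"])
        o = _sigmoid(u @ W["W_io"].T + W["b_io"] + h @ W["W_ho"].T + W["b_ho"])
        c_new = f * c + i * g
        tanh_c = np.tanh(c_new)
        h_new = o * tanh_c
        y = o @ W["W_yo"].T + W["b_yo"]
        steps.append({"u": u, "h_prev": h, "c_prev": c, "i": i, "f": f,
                      "g": g, "o": o, "c": c_new, "tanh_c": tanh_c})
        h, c = h_new, c_new
        ys[:, t] = y
        y_prev = y
    cache = {"steps": steps, "teacher_mask": teacher_mask, "shape": (B, T, D, H)}
    return ys, cache


def lstm_backward(W: LSTMWeights, cache: dict, dYs: np.ndarray
                  ) -> tuple[LSTMWeights, np.ndarray]:
    """Backprop through the rollout.

    dYs : (batch, n_steps, dim) gradient of the loss wrt each output y_t
    (including any gradient injected by a downstream head at the last step).

    Returns (weight gradients, dX) where dX[:, t] is the gradient wrt the
    *observed* input actually consumed at step t (zero wherever the model
    fed back its own prediction instead).  dX[:, 0] is the gradient wrt the
    initial state, the quantity used for sensitivity analysis.
    """
    B, T, D, H = cache["shape"]
    steps = cache["steps"]
    mask = cache["teacher_mask"]
    grads: LSTMWeights = {k: np.zeros_like(v) for k, v in W.items()}
    dX = np.zeros((B, T, D))
    dh_next = np.zeros((B, H))
    dc_next = np.zeros((B, H))
    dy_feedback = np.zeros((B, D))  # grad flowing into y_t via step t+1's input
    for t in reversed(range(T)):
        st = steps[t]
        dy = dYs[:, t] + dy_feedback
        do = dy @ W["W_yo"]
        grads["W_yo"] += dy.T @ st["o"]
        grads["b_yo"] += dy.sum(axis=0)
        # h_t = o * tanh(c_t) feeds the next step's gates
        dh = dh_next
        do = do + dh * st["tanh_c"]
        dc = dc_next + dh * st["o"] * (1.0 - st["tanh_c"] ** 2)
        di = dc * st["g"]
        dg = dc * st["i"]
        df = dc * st["c_prev"]
        dc_prev = dc * st["f"]
        da_i = di * st["i"] * (1 - st["i"])
        da_f = df * st["f"] * (1 - st["f"])
        da_g = dg * (1 - st["g"] ** 2)
        da_o = do * st["o"] * (1 - st["o"])
        u, h_prev = st["u"], st["h_prev"]
        du = np.zeros((B, D))
        dh_prev = np.zeros((B, H))
        for gate, da in zip(GATE_NAMES, (da_i, da_f, da_g, da_o)):
            grads[f"W_i{gate}"] += da.T @ u
            grads[f"W_h{gate}"] += da.T @ h_prev
            s = da.sum(axis=0)
            grads[f"b_i{gate}"] += s
            grads[f"b_h{gate}"] += s
            du += da @ W[f"W_i{gate}"]
            dh_prev += da @ W[f"W_h{gate}"]
        if t == 0:
            dX[:, 0] = du
            dy_feedback = np.zeros((B, D))
        else:
            used_truth = mask[:, t, None]
            dX[:, t] = np.where(used_truth, du, 0.0)
            dy_feedback = np.where(used_truth, 0.0, du)
        dh_next = dh_prev
        dc_next = dc_prev
    return grads, dX
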