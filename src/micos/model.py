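"""High-level recurrent models of community dynamics.

Three model flavors are provided, mirroring how the framework is used:

* **abundance** — an LSTM rolled over the sampling grid, trained with
  randomized teacher forcing on species abundances alone;
* **endpoint** — a single LSTM transition from initial to final abundance
  with a feed-forward head mapping the endpoint abundance to the four
  metabolite concentrations, trained end to end (the community-design
  workhorse);
* **joint** — the concatenated species+metabolite state (e.g. 29 = 25 + 4
  features) propagated through the same recurrent unit, so metabolite
  trajectories evolve as a function of both abundances and concentrations.

All training is full-precision CPU numpy and bitwise reproducible for a
given configuration seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .nn import FFN, Adam, init_lstm, lstm_backward, lstm_forward
from .scaling import FeatureScaler
from .types import METABOLITES, CommunityDesign, TrajectoryTable
from .glv import INOCULUM_OD


@dataclass
class TrainingConfig:
    """Hyperparameters of the Adam training loop.

    Defaults follow the reference schedule: learning-rate decay of 0.25
    every 25 epochs, L2 weight decay 1e-5, mini-batches of 10-20.  The
    full-scale hidden dimension is 2048 (abundance-only) or 4096 (joint);
    scaled-down studies use smaller values.
    """

    hidden_dim: int = 2048
    learning_rate: float = 0.005
    lr_decay: float = 0.25
    lr_decay_every: int = 25
    weight_decay: float = 1e-5
    batch_size: int = 20
    epochs: int = 100
    teacher_forcing_prob: float = 0.5
    seed: int = 0
    normalize_all: bool = False

    def __post_init__(self) -> None:
        if not (0.0 <= self.teacher_forcing_prob <= 1.0):
            raise ValueError("teacher_forcing_prob must be in [0, 1]")
        for name in ("hidden_dim", "learning_rate", "batch_size", "epochs"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    def lr_at(self, epoch: int) -> float:
        return self.learning_rate * self.lr_decay ** (epoch // self.lr_decay_every)


def tables_to_array(tables: list[TrajectoryTable],
                    with_metabolites: bool = False) -> tuple[np.ndarray, np.ndarray]:
    """Stack tables sharing a common time grid into (N, T, D); returns
    (data, times).  D is n_species, plus 4 when *with_metabolites*."""
    if not tables:
        raise ValueError("no tables supplied")
    times = tables[0].times
    for tb in tables:
        if tb.times.shape != times.shape or not np.allclose(tb.times, times):
            raise ValueError("all tables must share the same time grid")
    X = np.stack([tb.X for tb in tables])
    if not with_metabolites:
        return X, times
    for tb in tables:
        if tb.C is None:
            raise ValueError("tables are missing metabolite columns")
    C = np.stack([tb.C for tb in tables])
    return np.concatenate([X, C], axis=2), times


def fit_scaler(tables: list[TrajectoryTable], with_metabolites: bool = False,
               extra_tables: list[TrajectoryTable] | None = None,
               normalize_all: bool = False, eps: float = 1e-8) -> FeatureScaler:
    """Fit the per-timepoint scaler on training tables.

    With ``normalize_all`` and *extra_tables* given, statistics are computed
    over the union (the optional convention of pooling hold-out data); the
    default uses training data only.
    """
    pool = list(tables)
    if normalize_all and extra_tables:
        pool += list(extra_tables)
    data, _ = tables_to_array(pool, with_metabolites)
    return FeatureScaler(eps=eps).fit(data)


class LSTMModel:
    """A trained recurrent model plus its scaler and optional metabolite head."""

    def __init__(self, weights: dict, scaler: FeatureScaler, config: TrainingConfig,
                 n_species: int, n_metabolites: int = 0, mode: str = "abundance",
                 head: FFN | None = None, metab_scaler: FeatureScaler | None = None,
                 times: np.ndarray | None = None,
                 pool: tuple[str, ...] | None = None):
        self.weights = weights
        self.scaler = scaler
        self.config = config
        self.n_species = n_species
        self.n_metabolites = n_metabolites
        self.mode = mode
        self.head = head
        self.metab_scaler = metab_scaler
        self.times = times
        self.pool = pool
        self.loss_history: list[float] = []

    @property
    def n_features(self) -> int:
        return self.n_species + (self.n_metabolites if self.mode == "joint" else 0)

    # -- inference ---------------------------------------------------------

    def rollout(self, x0: np.ndarray, n_steps: int | None = None) -> np.ndarray:
        """Free-running forecast from the raw initial state.

        Returns the de-standardized sequence of shape (n_steps+1, D)
        including the initial state; every prediction is forecast from time
        0 only.  ``n_steps=0`` returns x0 unchanged.
        """
        if self.scaler is None:
            raise RuntimeError("model has no fitted scaler")
        x0 = np.asarray(x0, dtype=float)
        if n_steps is None:
            n_steps = self.scaler.n_timepoints - 1
        if n_steps == 0:
            return x0[None, :].copy()
        if n_steps > self.scaler.n_timepoints - 1:
            raise ValueError("n_steps exceeds the scaler's time grid")
        z0 = self.scaler.transform_at(0, x0)
        X = np.zeros((1, n_steps, x0.shape[0]))
        X[0, 0] = z0
        ys, _ = lstm_forward(self.weights, X, teacher_mask=None)
        out = np.zeros((n_steps + 1, x0.shape[0]))
        out[0] = x0
        for t in range(n_steps):
            out[t + 1] = self.scaler.inverse_transform_at(t + 1, ys[0, t])
        return out

    def predict_tables(self, tables: list[TrajectoryTable]) -> list[np.ndarray]:
        """Rollout for each table from its observed initial state."""
        with_met = self.mode == "joint"
        data, _ = tables_to_array(tables, with_metabolites=with_met)
        return [self.rollout(row[0]) for row in data]

    def predict_endpoint(self, design_or_x0: CommunityDesign | np.ndarray
                         ) -> tuple[np.ndarray, np.ndarray]:
        """Endpoint-mode prediction: (final abundances, final metabolites).

        Accepts a community design (inoculated at OD 0.0066 per present
        species) or a raw initial-abundance vector.
        """
        if self.mode != "endpoint" or self.head is None:
            raise RuntimeError("model was not trained in endpoint mode")
        if isinstance(design_or_x0, CommunityDesign):
            x0 = design_or_x0.mask().astype(float) * INOCULUM_OD
        else:
            x0 = np.asarray(design_or_x0, dtype=float)
        ab, met = self.predict_endpoint_batch(x0[None, :])
        return ab[0], met[0]

    def predict_endpoint_batch(self, X0: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Vectorized endpoint prediction for a (N, n_species) batch."""
        Z0 = self.scaler.transform_at(0, X0)
        ys, _ = lstm_forward(self.weights, Z0[:, None, :], teacher_mask=None)
        y = ys[:, 0]
        ab = self.scaler.inverse_transform_at(1, y)
        met_std = self.head(y)
        met = self.metab_scaler.inverse_transform_at(0, met_std)
        return ab, met

    def input_gradient(self, x0: np.ndarray, output_index: int,
                       output_step: int | None = None,
                       raw_scale: bool = True) -> np.ndarray:
        """d(output at *output_step*) / d(initial state), one backward pass.

        Weights stay frozen; only the input gradient is returned.  With
        *raw_scale* the derivative is chain-ruled back to original units
        (output sigma over input sigma).
        """
        x0 = np.asarray(x0, dtype=float)
        n_steps = self.scaler.n_timepoints - 1
        if output_step is None:
            output_step = n_steps - 1
        z0 = self.scaler.transform_at(0, x0)
        X = np.zeros((1, n_steps, x0.shape[0]))
        X[0, 0] = z0
        ys, cache = lstm_forward(self.weights, X, teacher_mask=None)
        dYs = np.zeros_like(ys)
        dYs[0, output_step, output_index] = 1.0
        _, dX = lstm_backward(self.weights, cache, dYs)
        grad = dX[0, 0]
        if raw_scale:
            sig_out = self.scaler.sigma[output_step + 1, output_index]
            grad = grad * sig_out / self.scaler.sigma[0]
        return grad

    # -- persistence -------------------------------------------------------

    def save(self, path: str | Path) -> None:
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        arrays = {f"lstm__{k}": v for k, v in self.weights.items()}
        arrays["scaler__mu"] = self.scaler.mu
        arrays["scaler__sigma"] = self.scaler.sigma
        if self.head is not None:
            arrays.update({f"head__{k}": v for k, v in self.head.params.items()})
            arrays["metab__mu"] = self.metab_scaler.mu
            arrays["metab__sigma"] = self.metab_scaler.sigma
        if self.times is not None:
            arrays["times"] = np.asarray(self.times)
        np.savez(path / "weights.npz", **arrays)
        meta = {
            "mode": self.mode,
            "n_species": self.n_species,
            "n_metabolites": self.n_metabolites,
            "pool": list(self.pool) if self.pool else None,
            "metabolites": list(METABOLITES)[: self.n_metabolites],
            "head_dims": self.head.layer_dims if self.head else None,
            "config": {k: (v.item() if isinstance(v, np.generic) else v)
                       for k, v in vars(self.config).items()},
        }
        (path / "model.yaml").write_text(yaml.safe_dump(meta))

    @classmethod
    def load(cls, path: str | Path) -> "LSTMModel":
        path = Path(path)
        meta = yaml.safe_load((path / "model.yaml").read_text())
        data = np.load(path / "weights.npz")
        weights = {k.split("__", 1)[1]: data[k] for k in data.files
                   if k.startswith("lstm__")}
        scaler = FeatureScaler()
        scaler.mu, scaler.sigma = data["scaler__mu"], data["scaler__sigma"]
        config = TrainingConfig(**meta["config"])
        head = None
        metab_scaler = None
        if meta["head_dims"]:
            head = FFN(meta["head_dims"], seed=0)
            head.params = {k.split("__", 1)[1]: data[k] for k in data.files
                           if k.startswith("head__")}
            metab_scaler = FeatureScaler()
            metab_scaler.mu = data["metab__mu"]
            metab_scaler.sigma = data["metab__sigma"]
        model = cls(weights, scaler, config, meta["n_species"],
                    meta["n_metabolites"], meta["mode"], head, metab_scaler,
                    times=data["times"] if "times" in data.files else None,
                    pool=tuple(meta["pool"]) if meta["pool"] else None)
        return model


# ---------------------------------------------------------------------------
# training loops
# ---------------------------------------------------------------------------


def train_teacher_forcing(tables: list[TrajectoryTable], config: TrainingConfig,
                          with_metabolites: bool = False,
                          extra_tables: list[TrajectoryTable] | None = None
                          ) -> LSTMModel:
    """Train a sequence model with randomized (per-step Bernoulli) teacher
    forcing: at each transition of each sequence the observed standardized
    state replaces the previous prediction as input with probability
    ``config.teacher_forcing_prob``.  Loss is the MSE on standardized
    outputs at all observed time points.
    """
    data, times = tables_to_array(tables, with_metabolites)
    N, T, D = data.shape
    if T < 2:
        raise ValueError("teacher forcing needs intermediate observations")
    scaler = fit_scaler(tables, with_metabolites, extra_tables, config.normalize_all)
    Z = scaler.transform(data)
    X_in = Z[:, :-1]
    targets = Z[:, 1:]
    n_steps = T - 1

    rng = np.random.default_rng(config.seed)
    weights = init_lstm(D, config.hidden_dim, seed=config.seed)
    adam = Adam(weights, lr=config.learning_rate, weight_decay=config.weight_decay)
    history: list[float] = []
    for epoch in range(config.epochs):
        adam.lr = config.lr_at(epoch)
        perm = rng.permutation(N)
        epoch_loss = 0.0
        for start in range(0, N, config.batch_size):
            idx = perm[start:start + config.batch_size]
            Xb, Yb = X_in[idx], targets[idx]
            tf_mask = rng.random((len(idx), n_steps)) < config.teacher_forcing_prob
            tf_mask[:, 0] = False  # step 0 always consumes the initial state
            ys, cache = lstm_forward(weights, Xb, tf_mask)
            err = ys - Yb
            loss = float(np.mean(err ** 2))
            if not np.isfinite(loss):
                raise RuntimeError(f"NaN loss at epoch {epoch}")
            dYs = (2.0 / err.size) * err
            grads, _ = lstm_backward(weights, cache, dYs)
            adam.step(grads)
            epoch_loss += loss * len(idx)
        history.append(epoch_loss / N)
    mode = "joint" if with_metabolites else "abundance"
    n_species = len(tables[0].design.pool)
    model = LSTMModel(weights, scaler, config, n_species,
                      n_metabolites=(D - n_species), mode=mode,
                      times=times, pool=tables[0].design.pool)
    model.loss_history = history
    return model


def train_joint_model(tables: list[TrajectoryTable], config: TrainingConfig,
                      extra_tables: list[TrajectoryTable] | None = None) -> LSTMModel:
    """Train the concatenated species+metabolite sequence model (for a
    25-species pool this is the 29-dimensional variant)."""
    return train_teacher_forcing(tables, config, with_metabolites=True,
                                 extra_tables=extra_tables)


def build_joint_model(n_species: int = 25, n_metabolites: int = 4,
                      config: TrainingConfig | None = None,
                      seed: int = 0) -> LSTMModel:
    """Construct an untrained joint model operating on the concatenated
    (n_species + n_metabolites)-dimensional state."""
    config = config or TrainingConfig(hidden_dim=4096, seed=seed)
    weights = init_lstm(n_species + n_metabolites, config.hidden_dim, seed=seed)
    return LSTMModel(weights, FeatureScaler(), config, n_species,
                     n_metabolites=n_metabolites, mode="joint")


def attach_metabolite_head(model: LSTMModel, head_layers: list[int],
                           seed: int = 0) -> LSTMModel:
    """Attach a feed-forward species-to-metabolite head to the final unit.

    *head_layers* lists all layer sizes; its first entry must equal the
    species count.  The head is trained end to end by
    :func:`train_endpoint_model`; attaching to an already trained model
    switches it to endpoint mode with an untrained head.
    """
    if head_layers[0] != model.n_species:
        raise ValueError(
            f"head input dim {head_layers[0]} != species count {model.n_species}")
    model.head = FFN(head_layers, seed=seed)
    model.mode = "endpoint"
    if model.metab_scaler is None:
        model.metab_scaler = FeatureScaler()
    return model


def train_endpoint_model(tables: list[TrajectoryTable], config: TrainingConfig,
                         head_hidden: tuple[int, ...] = (64,)) -> LSTMModel:
    """Train the endpoint design model: one LSTM transition from initial to
    final abundance plus a feed-forward head predicting the four endpoint
    metabolite concentrations, all weights learned simultaneously.

    Tables must carry metabolites; only the first and last time points are
    used.  The joint loss is the sum of the abundance MSE and metabolite MSE
    on standardized scales (equal weighting — standardization already
    equalizes units).
    """
    for tb in tables:
        if tb.C is None:
            raise ValueError("endpoint training requires metabolite columns")
    n_species = len(tables[0].design.pool)
    X = np.stack([np.stack([tb.X[0], tb.X[-1]]) for tb in tables])  # (N,2,S)
    C = np.stack([tb.C[-1] for tb in tables])                       # (N,4)
    N = X.shape[0]
    scaler = FeatureScaler().fit(X)
    metab_scaler = FeatureScaler().fit(C[:, None, :])
    Z0 = scaler.transform_at(0, X[:, 0])
    Zf = scaler.transform_at(1, X[:, 1])
    Cz = metab_scaler.transform_at(0, C)

    weights = init_lstm(n_species, config.hidden_dim, seed=config.seed)
    head = FFN([n_species, *head_hidden, C.shape[1]], seed=config.seed + 1)
    params = {f"lstm.{k}": v for k, v in weights.items()}
    params.update({f"head.{k}": v for k, v in head.params.items()})
    adam = Adam(params, lr=config.learning_rate, weight_decay=config.weight_decay)

    rng = np.random.default_rng(config.seed)
    history = []
    for epoch in range(config.epochs):
        adam.lr = config.lr_at(epoch)
        perm = rng.permutation(N)
        epoch_loss = 0.0
        for start in range(0, N, config.batch_size):
            idx = perm[start:start + config.batch_size]
            zb = Z0[idx][:, None, :]
            ys, cache = lstm_forward(weights, zb, teacher_mask=None)
            y = ys[:, 0]
            met_pred, head_cache = head.forward(y)
            err_ab = y - Zf[idx]
            err_met = met_pred - Cz[idx]
            loss = float(np.mean(err_ab ** 2) + np.mean(err_met ** 2))
            if not np.isfinite(loss):
                raise RuntimeError(f"NaN loss at epoch {epoch}")
            d_met = (2.0 / err_met.size) * err_met
            head_grads, dy_head = head.backward(head_cache, d_met)
            dYs = ((2.0 / err_ab.size) * err_ab + dy_head)[:, None, :]
            lstm_grads, _ = lstm_backward(weights, cache, dYs)
            grads = {f"lstm.{k}": v for k, v in lstm_grads.items()}
            grads.update({f"head.{k}": v for k, v in head_grads.items()})
            adam.step(grads)
            epoch_loss += loss * len(idx)
        history.append(epoch_loss / N)
    model = LSTMModel(weights, scaler, config, n_species,
                      n_metabolites=C.shape[1], mode="endpoint", head=head,
                      metab_scaler=metab_scaler,
                      times=np.array([tables[0].times[0], tables[0].times[-1]]),
                      pool=tables[0].design.pool)
    model.loss_history = history
    return model
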