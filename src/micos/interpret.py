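"""Model interpretation: local surrogate explanations, gradient sensitivity,
training-size curves and the pairwise prediction-sensitivity statistic.

Two complementary views of a trained black-box community model are
implemented.  Local surrogate (LIME-style) explanations perturb the species
presence/absence vector around one community, query the model, and fit an
exponentially kernel-weighted ridge surrogate whose coefficients are the
per-species impacts on the chosen output.  Gradient sensitivity instead
differentiates the frozen model directly: one reverse pass yields the
partial derivative of any output variable at any time with respect to every
input variable.

Prediction-sensitivity statistics quantify how hold-out accuracy (Pearson
R²) depends on training-set size and on the presence of species pairs.  The
pairwise sensitivity is

    100 / N_species² · Σ_i Σ_{j≠i} (R²_ij − R²_i) / R²_i

where R²_i is the accuracy over communities initially containing species i
and R²_ij over those containing both i and j.  The N² normalizer is used as
defined (the double sum has N(N−1) terms); a flag switches to N(N−1).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.linear_model import Ridge

from .metrics import pearson_r2
from .model import LSTMModel
from .types import CommunityDesign


@dataclass
class Explanation:
    """Per-species local surrogate weights for one community and one target."""

    instance: CommunityDesign
    target: str
    weights: np.ndarray
    intercept: float = 0.0

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if not np.all(np.isfinite(self.weights)):
            raise ValueError("explanation weights must be finite")
        if self.weights.shape[0] != len(self.instance.pool):
            raise ValueError("one weight per pool species required")


def lime_explain(
    predict_fn,
    instance: CommunityDesign,
    target: str = "output",
    n_perturbations: int = 5000,
    seed: int = 0,
    kernel_width: float | None = None,
    ridge_alpha: float = 1.0,
) -> Explanation:
    """Local surrogate explanation of a presence/absence model.

    *predict_fn* maps a binary (N, n_species) presence matrix to (N,) output
    values (e.g. a predicted endpoint metabolite concentration).  Binary
    perturbations of the instance's presence vector are drawn uniformly,
    weighted by an exponential kernel on the Hamming distance to the
    instance (width 0.75·sqrt(d) by default), and a ridge surrogate is fit;
    its coefficients are returned in the units of the target.
    """
    if instance.richness == 0:
        raise ValueError("cannot explain an empty community")
    d = len(instance.pool)
    if kernel_width is None:
        kernel_width = 0.75 * np.sqrt(d)
    rng = np.random.default_rng(seed)
    base = np.array(instance.present, dtype=float)
    # flip a uniformly drawn number of bits so the sampled neighbourhood
    # spans all Hamming distances (dense Bernoulli sampling would leave the
    # exponential kernel with no effective near-instance samples)
    Z = np.tile(base, (n_perturbations, 1))
    n_flips = rng.integers(0, d + 1, size=n_perturbations)
    n_flips[0] = 0  # include the instance itself
    for row, k in enumerate(n_flips):
        if k:
            cols = rng.choice(d, size=k, replace=False)
            Z[row, cols] = 1.0 - Z[row, cols]
    # guard against all-absent rows, which are not valid communities
    empty = Z.sum(axis=1) == 0
    if np.any(empty):
        cols = rng.integers(0, d, size=int(empty.sum()))
        Z[np.where(empty)[0], cols] = 1.0
    y = np.asarray(predict_fn(Z), dtype=float)
    dist = np.abs(Z - np.array(instance.present)).sum(axis=1)
    w = np.exp(-(dist ** 2) / kernel_width ** 2)
    surrogate = Ridge(alpha=ridge_alpha)
    surrogate.fit(Z, y, sample_weight=w)
    return Explanation(instance=instance, target=target,
                       weights=surrogate.coef_, intercept=float(surrogate.intercept_))


@dataclass
class ExplanationNetwork:
    """Signed species→(metabolite | species) edges distilled from explanations."""

    edges: pd.DataFrame  # columns: source, target, median_weight, sign, threshold
    thresholds: dict = field(default_factory=dict)
    eligible_targets: tuple[str, ...] = ()

    def to_graphml(self, path) -> None:
        import networkx as nx
        G = nx.DiGraph()
        for _, row in self.edges.iterrows():
            G.add_edge(row["source"], row["target"],
                       weight=float(row["median_weight"]), sign=int(row["sign"]))
        nx.write_graphml(G, path)


def build_explanation_network(
    explanations: list[Explanation],
    cv_r2: dict[str, float],
    metabolite_targets: tuple[str, ...] = ("butyrate", "lactate", "acetate", "succinate"),
    metabolite_threshold: float = 5.0,
    species_threshold: float = 0.2,
    r2_gate: float = 0.5,
) -> ExplanationNetwork:
    """Aggregate per-community explanations into a thresholded network.

    Edge weight is the median explanation across communities.  Targets only
    qualify if their cross-validated R² exceeds *r2_gate*.  Species-target
    weights are divided by the target species' self-impact (the median
    weight of a species' own presence on its own abundance) before the
    0.2 threshold; metabolite edges are thresholded in mM.
    """
    eligible = tuple(t for t, r2 in cv_r2.items() if r2 > r2_gate)
    by_target: dict[str, list[Explanation]] = {}
    for ex in explanations:
        by_target.setdefault(ex.target, []).append(ex)
    rows = []
    for target, exs in by_target.items():
        if target not in eligible:
            continue
        pool = exs[0].instance.pool
        med = np.median(np.stack([ex.weights for ex in exs]), axis=0)
        is_metab = target in metabolite_targets
        if is_metab:
            weights = med
            thr = metabolite_threshold
        else:
            t_idx = pool.index(target)
            self_impact = med[t_idx]
            if self_impact == 0:
                raise ZeroDivisionError(
                    f"zero self-impact for species {target}; cannot normalize")
            weights = med / abs(self_impact)
            thr = species_threshold
        for sp, wgt in zip(pool, weights):
            if abs(wgt) >= thr:
                rows.append({"source": sp, "target": target,
                             "median_weight": float(wgt),
                             "sign": 1 if wgt > 0 else -1, "threshold": thr})
    edges = pd.DataFrame(rows, columns=["source", "target", "median_weight",
                                        "sign", "threshold"])
    return ExplanationNetwork(edges=edges,
                              thresholds={"metabolite": metabolite_threshold,
                                          "species": species_threshold,
                                          "r2_gate": r2_gate},
                              eligible_targets=eligible)


def gradient_sensitivity(model: LSTMModel, x0: np.ndarray,
                         output_indices: list[int] | None = None,
                         raw_scale: bool = True) -> np.ndarray:
    """Exact reverse-mode sensitivities of a trained sequence model.

    Returns an array of shape (n_steps, n_outputs, n_inputs):
    ``out[t, a, b]`` is the derivative of output variable *a* at prediction
    step t (time grid point t+1) with respect to input variable *b* at time
    0, with the model weights frozen.  Everything flows through the model's
    own free-running rollout, so one backward pass per (output, step).
    """
    if not isinstance(model, LSTMModel):
        raise TypeError("gradient sensitivity requires a differentiable LSTMModel")
    D = model.n_features
    if output_indices is None:
        output_indices = list(range(D))
    n_steps = model.scaler.n_timepoints - 1
    out = np.zeros((n_steps, len(output_indices), D))
    for t in range(n_steps):
        for ai, a in enumerate(output_indices):
            out[t, ai] = model.input_gradient(x0, a, output_step=t,
                                              raw_scale=raw_scale)
    return out


def subsample_sensitivity(
    X: np.ndarray,
    Y: np.ndarray,
    output_names: list[str],
    fractions: tuple[float, ...] = (0.5, 0.6, 0.7, 0.8, 0.9, 1.0),
    n_repeats: int = 30,
    cv_folds: int = 20,
    seed: int = 0,
    estimator_factory=None,
) -> pd.DataFrame:
    """Hold-out accuracy versus training-set size.

    For each fraction and repeat, a random subsample is drawn and subjected
    to k-fold cross-validation; the per-output Pearson R² is computed on the
    pooled out-of-fold predictions.  Returns a tidy frame with columns
    output, fraction, mean_r2, sd_r2.
    """
    X = np.asarray(X, dtype=float)
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    if Y.shape[0] == X.shape[0] and Y.ndim == 2 and Y.shape[1] == len(output_names):
        pass
    else:
        Y = Y.T
    n = X.shape[0]
    if n < cv_folds:
        raise ValueError("dataset smaller than the number of CV folds")
    if estimator_factory is None:
        estimator_factory = lambda: Ridge(alpha=1e-6)
    rng = np.random.default_rng(seed)
    rows = []
    for frac in fractions:
        m = int(round(frac * n))
        if m < cv_folds:
            raise ValueError(f"fraction {frac} yields {m} < {cv_folds} samples")
        r2s = np.zeros((n_repeats, len(output_names)))
        for rep in range(n_repeats):
            idx = rng.choice(n, size=m, replace=False) if m < n else rng.permutation(n)
            fold_of = np.arange(m) % cv_folds
            fold_of = fold_of[rng.permutation(m)]
            preds = np.zeros((m, len(output_names)))
            for f in range(cv_folds):
                tr, te = fold_of != f, fold_of == f
                for oi in range(len(output_names)):
                    est = estimator_factory()
                    est.fit(X[idx][tr], Y[idx][tr, oi])
                    preds[te, oi] = est.predict(X[idx][te])
            for oi in range(len(output_names)):
                r2s[rep, oi] = pearson_r2(preds[:, oi], Y[idx][:, oi])
        for oi, name in enumerate(output_names):
            rows.append({"output": name, "fraction": frac,
                         "mean_r2": float(r2s[:, oi].mean()),
                         "sd_r2": float(r2s[:, oi].std(ddof=1))})
    return pd.DataFrame(rows)


@dataclass
class SensitivityReport:
    """Per-species and per-pair hold-out accuracy plus the pairwise statistic."""

    r2_single: np.ndarray        # (S,)
    r2_pair: np.ndarray          # (S, S), nan off the evaluated set
    n_single: np.ndarray
    n_pair: np.ndarray
    pairwise_sensitivity: float
    skipped_pairs: list[tuple[int, int]]


def pairwise_sensitivity(
    cv_predictions: np.ndarray,
    truths: np.ndarray,
    presence: np.ndarray,
    use_pair_count_normalizer: bool = False,
) -> SensitivityReport:
    """Average percent change in accuracy between single-species and
    species-pair community subsets.

    *cv_predictions* and *truths* are per-community out-of-fold predicted
    and measured values of one output; *presence* is the (N, S) binary
    initial-presence matrix.  Pairs whose subset is empty or too small for a
    defined correlation are skipped with a warning and excluded from the
    sum.  The default normalizer is N_species² as defined; the flag switches
    to the number of evaluated ordered pairs.
    """
    pred = np.asarray(cv_predictions, dtype=float)
    true = np.asarray(truths, dtype=float)
    Z = np.asarray(presence)
    S = Z.shape[1]
    r2_single = np.full(S, np.nan)
    n_single = np.zeros(S, dtype=int)
    for i in range(S):
        sel = Z[:, i] == 1
        n_single[i] = int(sel.sum())
        try:
            r2_single[i] = pearson_r2(pred[sel], true[sel])
        except ValueError:
            pass
    r2_pair = np.full((S, S), np.nan)
    n_pair = np.zeros((S, S), dtype=int)
    skipped: list[tuple[int, int]] = []
    total = 0.0
    n_terms = 0
    for i in range(S):
        for j in range(S):
            if j == i:
                continue
            sel = (Z[:, i] == 1) & (Z[:, j] == 1)
            n_pair[i, j] = int(sel.sum())
            ok = np.isfinite(r2_single[i]) and r2_single[i] > 0
            if ok:
                try:
                    r2_pair[i, j] = pearson_r2(pred[sel], true[sel])
                except ValueError:
                    ok = False
            if not ok:
                skipped.append((i, j))
                continue
            total += (r2_pair[i, j] - r2_single[i]) / r2_single[i]
            n_terms += 1
    if skipped:
        warnings.warn(f"skipped {len(skipped)} species pairs with undefined "
                      "subset accuracy")
    denom = n_terms if use_pair_count_normalizer else S * S
    value = 100.0 * total / denom if denom else float("nan")
    return SensitivityReport(r2_single=r2_single, r2_pair=r2_pair,
                             n_single=n_single, n_pair=n_pair,
                             pairwise_sensitivity=float(value),
                             skipped_pairs=skipped)
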