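"""Generalized Lotka-Volterra ground-truth simulator and community sampling.

This module generates the in-silico "ground truth" against which both the
recurrent network and a refitted pairwise gLV model are benchmarked: gLV
dynamics with optional third-order interaction terms, batch-culture and
serial-passaging simulation, randomized community sampling designs, additive
observation noise, and a gradient-based pairwise gLV fitter.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import least_squares

from .types import DEFAULT_POOL, CommunityDesign, GLVParams, TrajectoryTable, _admissible_mask

#: Experimental inoculum density per species (OD units).
INOCULUM_OD = 0.0066

THIRD_ORDER_LEVELS = {"none": 0.0, "mild": 0.25, "moderate": 0.50}


class SimulationError(RuntimeError):
    """Raised when integration produces a non-finite state."""


def generate_ground_truth(
    n_species: int,
    third_order: str = "none",
    seed: int = 0,
    *,
    r_range: tuple[float, float] = (0.1, 0.8),
    a_offdiag_sd: float = 0.4,
    a_offdiag_mean: float = 0.0,
    a_diag_range: tuple[float, float] = (-1.5, -0.5),
    sparsity: float = 0.0,
) -> GLVParams:
    """Draw a random ground-truth parameter set.

    Growth rates are Uniform(*r_range*) 1/h; off-diagonal pairwise
    coefficients Normal(*a_offdiag_mean*, *a_offdiag_sd*) — a negative mean
    yields predominantly competitive communities whose high-richness
    assemblies stay bounded; diagonals Uniform(*a_diag_range*)
    (always negative, bounding each species). Third-order coefficients, when
    requested, are uniform on ±fraction·max|a| where the fraction is 0.25
    ("mild") or 0.50 ("moderate") of the largest pairwise magnitude;
    *sparsity* optionally zeroes that fraction of admissible entries.
    Deterministic given *seed*.
    """
    if n_species < 1:
        raise ValueError("n_species must be >= 1")
    if third_order not in THIRD_ORDER_LEVELS:
        raise ValueError(
            f"unknown third-order level {third_order!r}; "
            f"choose from {sorted(THIRD_ORDER_LEVELS)}"
        )
    rng = np.random.default_rng(seed)
    n = n_species
    r = rng.uniform(*r_range, size=n)
    A = rng.normal(a_offdiag_mean, a_offdiag_sd, size=(n, n))
    A[np.diag_indices(n)] = rng.uniform(*a_diag_range, size=n)

    frac = THIRD_ORDER_LEVELS[third_order]
    B = None
    if frac > 0.0:
        bound = frac * np.max(np.abs(A))
        B = rng.uniform(-bound, bound, size=(n, n, n))
        mask = _admissible_mask(n)
        if sparsity > 0.0:
            keep = rng.random(size=(n, n, n)) >= sparsity
            mask = mask & keep
        B[~mask] = 0.0
    return GLVParams(r=r, A=A, B=B)


def glv_rhs(params: GLVParams, x: np.ndarray) -> np.ndarray:
    """dx/dt for the full system (absent species handled by x=0)."""
    growth = params.r + params.A @ x
    if params.B is not None:
        growth = growth + np.einsum("ijk,j,k->i", params.B, x, x)
    return growth * x


def initial_state(design: CommunityDesign, x0_total: float | None = None) -> np.ndarray:
    """Equal split of *x0_total* over present species.

    Default total echoes the experimental protocol of inoculating each
    species at OD 0.0066, i.e. total = 0.0066 · richness.
    """
    m = design.mask()
    if x0_total is None:
        x0_total = INOCULUM_OD * design.richness
    x0 = np.zeros(len(design.pool))
    x0[m] = x0_total / design.richness
    return x0


def _integrate(params: GLVParams, x0: np.ndarray, mask: np.ndarray,
               t0: float, t1: float, t_eval: np.ndarray,
               rtol: float = 1e-6, atol: float = 1e-9) -> tuple[np.ndarray, np.ndarray]:
    """Integrate the present-species subsystem from t0 to t1.

    Returns (states at t_eval, state at t1). Absent species stay exactly 0.
    """
    idx = np.where(mask)[0]
    r = params.r[idx]
    A = params.A[np.ix_(idx, idx)]
    B = params.B[np.ix_(idx, idx, idx)] if params.B is not None else None

    def rhs(t, x):
        growth = r + A @ x
        if B is not None:
            growth = growth + np.einsum("ijk,j,k->i", B, x, x)
        return growth * x

    if len(t_eval) == 0 or t_eval[-1] < t1:
        t_all = np.concatenate([t_eval, [t1]])
    else:
        t_all = np.asarray(t_eval, dtype=float)
    sol = solve_ivp(rhs, (t0, t1), x0[idx], t_eval=t_all,
                    method="RK45", rtol=rtol, atol=atol)
    if not sol.success or not np.all(np.isfinite(sol.y)):
        bad = np.argwhere(~np.isfinite(sol.y))
        if bad.size:
            sp_i, t_i = bad[0]
            raise SimulationError(
                f"non-finite abundance for species index {idx[sp_i]} "
                f"near t={sol.t[t_i]:.2f} h (likely blow-up)"
            )
        raise SimulationError(f"integration failed: {sol.message}")
    y = np.clip(sol.y.T, 0.0, None)  # guard tiny negative overshoot
    out = np.zeros((len(t_eval), len(x0)))
    out[:, idx] = y[: len(t_eval)]
    final = np.zeros(len(x0))
    final[idx] = y[-1]
    return out, final


def simulate_glv(
    params: GLVParams,
    design: CommunityDesign,
    x0_total: float | None = None,
    times: np.ndarray | None = None,
    sample_id: str = "sim",
) -> TrajectoryTable:
    """Integrate the gLV system for one community and sample it at *times*.

    Initial abundance is an equal split of *x0_total* over present species;
    the default grid is every 8 h over 48 h. Raises :class:`SimulationError`
    naming the offending species on blow-up.
    """
    if times is None:
        times = np.arange(0.0, 48.0 + 1e-9, 8.0)
    times = np.asarray(times, dtype=float)
    if np.any(np.diff(times) <= 0):
        raise ValueError("times must be strictly increasing")
    x0 = initial_state(design, x0_total)
    X, _ = _integrate(params, x0, design.mask(), times[0], times[-1], times)
    if times[0] == 0.0:
        X[0] = x0
    return TrajectoryTable(sample_id=sample_id, design=design, times=times, X=X)


def simulate_with_passaging(
    params: GLVParams,
    design: CommunityDesign,
    x0_total: float | None = None,
    horizon: float = 72.0,
    dilution_fold: float = 20.0,
    period: float = 24.0,
    sample_every: float = 12.0,
    sample_id: str = "sim",
) -> TrajectoryTable:
    """Simulate serial batch culture: every *period* hours the whole community
    is diluted *dilution_fold*-fold into fresh medium and growth continues.

    The sampling grid (every *sample_every* h from 0 to *horizon*) is
    independent of the passage times; a sample that coincides with a passage
    reports the pre-dilution state.
    """
    if dilution_fold <= 1:
        raise ValueError("dilution_fold must be > 1")
    times = np.arange(0.0, horizon + 1e-9, sample_every)
    passages = np.arange(period, horizon, period)
    mask = design.mask()
    x = initial_state(design, x0_total)
    X = np.zeros((len(times), len(x)))
    if times[0] == 0.0:
        X[0] = x
    segment_edges = np.concatenate([[0.0], passages, [horizon]])
    for t0, t1 in zip(segment_edges[:-1], segment_edges[1:]):
        sel = (times > t0 + 1e-12) & (times <= t1 + 1e-12)
        t_eval = times[sel]
        seg, x = _integrate(params, x, mask, t0, t1, t_eval)
        X[sel] = seg
        if t1 < horizon:  # passage event
            x = x / dilution_fold
    return TrajectoryTable(sample_id=sample_id, design=design, times=times, X=X)


def add_observation_noise(table: TrajectoryTable, sigma: float = 0.1,
                          seed: int = 0) -> TrajectoryTable:
    """Multiplicative log-normal noise on sampled abundances.

    Zeros (absent species, washed-out species) stay exactly zero; metabolite
    columns, if present, are left untouched.
    """
    rng = np.random.default_rng(seed)
    noise = rng.lognormal(mean=0.0, sigma=sigma, size=table.X.shape)
    X = table.X * noise
    return TrajectoryTable(sample_id=table.sample_id, design=table.design,
                           times=table.times.copy(), X=X,
                           C=None if table.C is None else table.C.copy())


def metabolites_from_abundances(table: TrajectoryTable, W: np.ndarray,
                                b: np.ndarray | None = None,
                                mode: str = "cumulative") -> TrajectoryTable:
    """Attach synthetic metabolite trajectories driven by the abundances.

    ``mode="instant"`` sets C(t) = W x(t) + b (concentrations track current
    abundance linearly); ``mode="cumulative"`` treats W as net
    production/consumption rates, C(t) = b + trapezoidal integral of W x(s)
    over [0, t] — the more realistic fermentation-product picture.  W is
    (4, n_species); concentrations are clipped at 0.
    """
    X, t = table.X, table.times
    b = np.zeros(W.shape[0]) if b is None else np.asarray(b, dtype=float)
    rates = X @ W.T  # (T, 4)
    if mode == "instant":
        C = rates + b
    elif mode == "cumulative":
        C = np.zeros_like(rates)
        C[0] = b
        for k in range(1, len(t)):
            C[k] = C[k - 1] + 0.5 * (rates[k] + rates[k - 1]) * (t[k] - t[k - 1])
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return TrajectoryTable(sample_id=table.sample_id, design=table.design,
                           times=t.copy(), X=X.copy(), C=np.clip(C, 0.0, None))


# ---------------------------------------------------------------------------
# community sampling designs
# ---------------------------------------------------------------------------

_MAX_REJECTION = 10**6


def _random_k_designs(pool: tuple[str, ...], k: int, count: int,
                      rng: np.random.Generator,
                      taken: set[tuple[int, ...]]) -> list[CommunityDesign]:
    n = len(pool)
    from math import comb
    if count > comb(n, k) :
        raise ValueError(f"requested {count} distinct {k}-member designs, "
                         f"only {comb(n, k)} exist")
    out: list[CommunityDesign] = []
    attempts = 0
    while len(out) < count:
        attempts += 1
        if attempts > _MAX_REJECTION:
            raise RuntimeError("duplicate-exhaustion: rejection sampling cap hit")
        members = tuple(sorted(rng.choice(n, size=k, replace=False)))
        if members in taken:
            continue
        taken.add(members)
        present = tuple(1 if i in members else 0 for i in range(n))
        out.append(CommunityDesign(present, pool))
    return out


def design_training_communities(
    pool_size: int = 25,
    n3: int = 100,
    n5: int = 100,
    n6: int = 99,
    seed: int = 0,
    pool: tuple[str, ...] | None = None,
) -> list[CommunityDesign]:
    """The low-richness training design: all monocultures, all pairs, and
    random distinct 3-, 5- and 6-member communities (defaults give
    25 + 300 + 100 + 100 + 99 = 624 for a 25-species pool).
    """
    pool = tuple(pool) if pool is not None else DEFAULT_POOL[:pool_size]
    if len(pool) != pool_size:
        raise ValueError("pool length must equal pool_size")
    rng = np.random.default_rng(seed)
    designs: list[CommunityDesign] = []
    for i in range(pool_size):
        present = tuple(1 if j == i else 0 for j in range(pool_size))
        designs.append(CommunityDesign(present, pool))
    for i, j in itertools.combinations(range(pool_size), 2):
        present = tuple(1 if m in (i, j) else 0 for m in range(pool_size))
        designs.append(CommunityDesign(present, pool))
    for k, count in ((3, n3), (5, n5), (6, n6)):
        taken: set[tuple[int, ...]] = set()
        designs.extend(_random_k_designs(pool, k, count, rng, taken))
    return designs


def design_test_communities(
    pool_size: int = 25,
    n: int = 3299,
    min_richness: int = 10,
    seed: int = 0,
    exclude: list[CommunityDesign] | None = None,
    pool: tuple[str, ...] | None = None,
) -> list[CommunityDesign]:
    """*n* distinct uniform-random designs with richness >= *min_richness*,
    disjoint from *exclude*.

    Uniformity over qualifying designs is achieved by drawing the richness k
    with probability proportional to C(pool, k) and then a uniform k-subset.
    """
    from math import comb
    pool = tuple(pool) if pool is not None else DEFAULT_POOL[:pool_size]
    if len(pool) != pool_size:
        raise ValueError("pool length must equal pool_size")
    richnesses = np.arange(min_richness, pool_size + 1)
    counts = np.array([comb(pool_size, int(k)) for k in richnesses], dtype=float)
    n_excluded = 0
    taken: set[tuple[int, ...]] = set()
    if exclude:
        for d in exclude:
            if d.richness >= min_richness:
                n_excluded += 1
            taken.add(tuple(np.where(d.mask())[0]))
    if n > counts.sum() - n_excluded:
        raise ValueError(f"requested {n} designs; only "
                         f"{int(counts.sum()) - n_excluded} candidates exist")
    rng = np.random.default_rng(seed)
    probs = counts / counts.sum()
    out: list[CommunityDesign] = []
    attempts = 0
    while len(out) < n:
        attempts += 1
        if attempts > _MAX_REJECTION:
            raise RuntimeError("duplicate-exhaustion: rejection sampling cap hit")
        k = int(rng.choice(richnesses, p=probs))
        members = tuple(sorted(rng.choice(pool_size, size=k, replace=False)))
        if members in taken:
            continue
        taken.add(members)
        present = tuple(1 if i in members else 0 for i in range(pool_size))
        out.append(CommunityDesign(present, pool))
    return out


# ---------------------------------------------------------------------------
# pairwise gLV fitting (trajectory least squares)
# ---------------------------------------------------------------------------


def rk4_simulate_batch(r: np.ndarray, A: np.ndarray, X0: np.ndarray,
                       times: np.ndarray, dt: float = 0.25,
                       x_cap: float = 1e3) -> np.ndarray:
    """Fixed-step RK4 integration of the pairwise gLV system, vectorized over
    a batch of communities.

    X0 is (batch, n); returns (batch, T, n). Species at exactly zero stay
    zero (multiplicative dynamics). The state is clipped to [0, x_cap] after
    each step so that a bad parameter draw yields large-but-finite residuals
    instead of overflow.
    """
    times = np.asarray(times, dtype=float)

    def f(x):
        return (r + x @ A.T) * x

    out = np.zeros((X0.shape[0], len(times), X0.shape[1]))
    x = X0.copy()
    t = times[0]
    out[:, 0] = x
    for ti in range(1, len(times)):
        t_target = times[ti]
        n_steps = max(1, int(np.ceil((t_target - t) / dt - 1e-12)))
        h = (t_target - t) / n_steps
        for _ in range(n_steps):
            k1 = f(x)
            k2 = f(np.clip(x + 0.5 * h * k1, 0.0, x_cap))
            k3 = f(np.clip(x + 0.5 * h * k2, 0.0, x_cap))
            k4 = f(np.clip(x + h * k3, 0.0, x_cap))
            x = x + (h / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)
            x = np.clip(x, 0.0, x_cap)
        t = t_target
        out[:, ti] = x
    return out


def _gradient_matching_init(tables: list[TrajectoryTable], n: int,
                            ridge: float = 1e-3) -> tuple[np.ndarray, np.ndarray]:
    """Initialize (r, A) by ridge-regressing d(log x_i)/dt on abundances.

    Uses midpoint abundances between consecutive samples; rows where the
    species is absent or near zero are dropped.
    """
    feats: list[list[np.ndarray]] = [[] for _ in range(n)]
    targs: list[list[float]] = [[] for _ in range(n)]
    eps = 1e-8
    for tb in tables:
        X, t = tb.X, tb.times
        for a, b in zip(range(len(t) - 1), range(1, len(t))):
            dt_ = t[b] - t[a]
            xm = 0.5 * (X[a] + X[b])
            for i in range(n):
                if X[a, i] > eps and X[b, i] > eps:
                    dlog = (np.log(X[b, i]) - np.log(X[a, i])) / dt_
                    feats[i].append(xm)
                    targs[i].append(dlog)
    r = np.full(n, 0.3)
    A = -0.5 * np.eye(n)
    for i in range(n):
        if len(targs[i]) < 2:
            continue
        Phi = np.column_stack([np.ones(len(targs[i])), np.array(feats[i])])
        y = np.array(targs[i])
        coef = np.linalg.solve(Phi.T @ Phi + ridge * np.eye(n + 1), Phi.T @ y)
        r[i] = coef[0]
        A[i] = coef[1:]
        A[i, i] = min(A[i, i], -1e-2)
    return r, A


def fit_glv(
    tables: list[TrajectoryTable],
    n_starts: int = 4,
    seed: int = 0,
    dt: float = 0.25,
    max_nfev: int = 60,
    perturb_scale: float = 0.3,
) -> GLVParams:
    """Fit a pairwise-only gLV model to observed trajectories by multistart
    trajectory least squares.

    The loss is the squared error between fixed-step RK4 simulations started
    from each table's observed initial state and the observed abundances at
    all later sample times. The first start is a log-derivative
    gradient-matching initializer; remaining starts perturb it. Diagonal
    interaction terms are bounded negative. Returns the best-of-starts
    parameter set (third-order tensor is None).
    """
    if not tables:
        raise ValueError("no tables supplied")
    n = len(tables[0].design.pool)
    for tb in tables:
        if tb.n_times < 2:
            raise ValueError("each table needs >= 2 time points")

    # group tables by identical time grids for batched simulation
    groups: dict[tuple[float, ...], list[TrajectoryTable]] = {}
    for tb in tables:
        groups.setdefault(tuple(tb.times), []).append(tb)
    batches = []
    for tgrid, tbs in groups.items():
        X0 = np.stack([tb.X[0] for tb in tbs])
        obs = np.stack([tb.X for tb in tbs])
        masks = np.stack([tb.design.mask() for tb in tbs])
        batches.append((np.array(tgrid), X0, obs, masks))

    def residuals(theta):
        r = theta[:n]
        A = theta[n:].reshape(n, n)
        res = []
        for tgrid, X0, obs, masks in batches:
            sim = rk4_simulate_batch(r, A, X0, tgrid, dt=dt)
            diff = (sim[:, 1:] - obs[:, 1:]) * masks[:, None, :]
            res.append(diff.ravel())
        return np.concatenate(res)

    r0, A0 = _gradient_matching_init(tables, n)
    theta0 = np.concatenate([r0, A0.ravel()])
    lb = np.full(n + n * n, -np.inf)
    ub = np.full(n + n * n, np.inf)
    diag_idx = n + np.arange(n) * (n + 1)
    ub[diag_idx] = -1e-3

    rng = np.random.default_rng(seed)
    best = None
    for s in range(n_starts):
        start = theta0.copy()
        if s > 0:
            start = start * (1 + perturb_scale * rng.standard_normal(start.shape))
            start[diag_idx] = np.minimum(start[diag_idx], -1e-2)
        start = np.clip(start, lb, ub - 0.0)
        start[diag_idx] = np.minimum(start[diag_idx], -1e-3)
        try:
            sol = least_squares(residuals, start, bounds=(lb, ub),
                                method="trf", max_nfev=max_nfev)
        except Exception as exc:  # pragma: no cover - defensive
            warnings.warn(f"fit start {s} failed: {exc}")
            continue
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None:
        raise RuntimeError("gLV fit did not converge in any multistart")
    r = best.x[:n]
    A = best.x[n:].reshape(n, n)
    A[np.diag_indices(n)] = np.minimum(np.diag(A), -1e-3)
    return GLVParams(r=r, A=A, B=None)


def predict_glv(params: GLVParams, tables: list[TrajectoryTable],
                dt: float = 0.25) -> list[np.ndarray]:
    """Simulate a fitted pairwise gLV forward from each table's initial state
    on that table's time grid; returns one (T, n) array per table."""
    out = []
    for tb in tables:
        sim = rk4_simulate_batch(params.r, params.A, tb.X[0][None, :],
                                 tb.times, dt=dt)[0]
        sim = sim * tb.design.mask()[None, :]
        out.append(sim)
    return out
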