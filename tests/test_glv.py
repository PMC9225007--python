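"""gLV simulator: generator bounds, integrator oracles, passaging, designs,
noise and parameter recovery."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

import micos
from micos.glv import (SimulationError, add_observation_noise,
                       design_test_communities, design_training_communities,
                       fit_glv, generate_ground_truth, glv_rhs,
                       metabolites_from_abundances, simulate_glv,
                       simulate_with_passaging)
from micos.types import CommunityDesign, GLVParams, _admissible_mask

from conftest import STABLE


# ---------------------------------------------------------------------- truth


class TestGroundTruthGenerator:
    def test_none_level_gives_zero_tensor(self):
        p = generate_ground_truth(25, "none", seed=1)
        assert p.B is None

    @pytest.mark.parametrize("level,frac", [("mild", 0.25), ("moderate", 0.50)])
    def test_third_order_bound_is_fraction_of_max_pairwise(self, level, frac):
        p = generate_ground_truth(25, level, seed=1)
        assert np.max(np.abs(p.B)) <= frac * np.max(np.abs(p.A)) + 1e-15

    def test_inadmissible_tensor_entries_are_exactly_zero(self):
        p = generate_ground_truth(6, "moderate", seed=2)
        mask = _admissible_mask(6)
        assert np.all(p.B[~mask] == 0.0)

    def test_tensor_entries_uniform_on_stated_support(self):
        # pool the admissible entries of several draws (~10^4 values) and
        # KS-test against the uniform distribution on +/- 0.5 max|a|
        vals = []
        for seed in range(4):
            p = generate_ground_truth(15, "moderate", seed=seed)
            bound = 0.5 * np.max(np.abs(p.A))
            vals.append(p.B[_admissible_mask(15)] / bound)
        vals = np.concatenate(vals)
        assert vals.size >= 10_000
        assert stats.kstest(vals, stats.uniform(loc=-1, scale=2).cdf).pvalue > 0.01

    def test_deterministic_given_seed(self):
        a = generate_ground_truth(8, "mild", seed=9)
        b = generate_ground_truth(8, "mild", seed=9)
        assert np.array_equal(a.r, b.r) and np.array_equal(a.B, b.B)

    def test_unknown_level_rejected(self):
        with pytest.raises(ValueError, match="unknown third-order level"):
            generate_ground_truth(5, "extreme", seed=0)


# ----------------------------------------------------------------- integrator


def rk4_reference(params, x0, t_grid, dt=1e-3):
    """Independent fixed-step RK4 oracle (loops, no shared code path)."""
    out = [np.array(x0, dtype=float)]
    x = np.array(x0, dtype=float)
    for t0, t1 in zip(t_grid[:-1], t_grid[1:]):
        n = int(round((t1 - t0) / dt))
        h = (t1 - t0) / n
        for _ in range(n):
            k1 = glv_rhs(params, x)
            k2 = glv_rhs(params, x + 0.5 * h * k1)
            k3 = glv_rhs(params, x + 0.5 * h * k2)
            k4 = glv_rhs(params, x + h * k3)
            x = x + h / 6.0 * (k1 + 2 * k2 + 2 * k3 + k4)
        out.append(x.copy())
    return np.stack(out)


class TestSimulateGLV:
    def test_logistic_fixed_point(self):
        p = GLVParams(r=np.array([0.5]), A=np.array([[-1.0]]))
        d = CommunityDesign((1,), ("PC",))
        tb = simulate_glv(p, d, x0_total=0.1, times=np.arange(0, 49, 8.0))
        assert abs(tb.X[-1, 0] - 0.5) < 1e-3  # fixed point -r/a

    def test_uncoupled_species_match_their_monocultures(self):
        r = np.array([0.4, 0.7])
        A = np.array([[-1.2, 0.0], [0.0, -0.8]])
        p = GLVParams(r=r, A=A)
        pool = ("PC", "PJ")
        times = np.arange(0, 49, 8.0)
        pair = simulate_glv(p, CommunityDesign((1, 1), pool), x0_total=0.2,
                            times=times)
        for i in range(2):
            present = tuple(1 if j == i else 0 for j in range(2))
            mono = simulate_glv(p, CommunityDesign(present, pool),
                                x0_total=0.1, times=times)
            assert np.allclose(pair.X[:, i], mono.X[:, i], atol=1e-9)

    def test_matches_rk4_oracle_with_third_order_term(self):
        r = np.array([0.4, 0.5, 0.3])
        A = np.array([[-1.0, 0.1, -0.2], [0.2, -0.9, 0.1], [-0.1, 0.3, -1.1]])
        B = np.zeros((3, 3, 3))
        B[0, 1, 2] = 0.3  # one admissible third-order coefficient
        p = GLVParams(r=r, A=A, B=B)
        d = CommunityDesign((1, 1, 1), ("PC", "PJ", "BV"))
        times = np.arange(0, 49, 8.0)
        tb = simulate_glv(p, d, x0_total=0.3, times=times)
        ref = rk4_reference(p, tb.X[0], times)
        rel = np.abs(tb.X[1:] - ref[1:]) / np.maximum(np.abs(ref[1:]), 1e-6)
        assert rel.max() < 1e-4

    def test_blowup_reports_species_and_time(self):
        p = GLVParams(r=np.array([1.0, 1.0]),
                      A=np.array([[-0.01, 5.0], [5.0, -0.01]]))  # runaway mutualism
        d = CommunityDesign((1, 1), ("PC", "PJ"))
        with pytest.raises(SimulationError):
            simulate_glv(p, d, x0_total=0.5, times=np.arange(0, 49, 8.0))

    def test_absent_species_stay_exactly_zero(self, truth5):
        d = CommunityDesign((1, 0, 1, 0, 1), micos.DEFAULT_POOL[:5])
        tb = simulate_glv(truth5, d)
        assert np.all(tb.X[:, [1, 3]] == 0.0)


class TestPassaging:
    def test_dilution_definition_and_no_growth_staircase(self):
        # r=0, A~0-: no growth, so the trajectory is a 20-fold staircase
        p = GLVParams(r=np.array([0.0]), A=np.array([[-1e-12]]))
        d = CommunityDesign((1,), ("PC",))
        tb = simulate_with_passaging(p, d, x0_total=1.0, horizon=72,
                                     sample_every=12)
        # samples at passage times report the pre-dilution state
        assert tb.X[2, 0] == pytest.approx(1.0, rel=1e-9)        # t=24-
        assert tb.X[3, 0] == pytest.approx(1.0 / 20, rel=1e-6)   # t=36
        assert tb.X[5, 0] == pytest.approx(1.0 / 400, rel=1e-6)  # t=60

    def test_logistic_limit_cycle_matches_rk4_oracle(self):
        p = GLVParams(r=np.array([0.5]), A=np.array([[-1.0]]))
        d = CommunityDesign((1,), ("PC",))
        tb = simulate_with_passaging(p, d, x0_total=0.1, horizon=240,
                                     sample_every=12)
        # period-24h cycle: late samples repeat
        assert tb.X[-1, 0] == pytest.approx(tb.X[-3, 0], rel=1e-5)
        # oracle: RK4 with explicit dilution events
        x = 0.1
        samples = {0.0: x}
        t = 0.0
        dt = 1e-3
        while t < 240 - 1e-9:
            k1 = 0.5 * x - x * x
            xm = x + 0.5 * dt * k1
            k2 = 0.5 * xm - xm * xm
            xm2 = x + 0.5 * dt * k2
            k3 = 0.5 * xm2 - xm2 * xm2
            xe = x + dt * k3
            k4 = 0.5 * xe - xe * xe
            x = x + dt / 6 * (k1 + 2 * k2 + 2 * k3 + k4)
            t = round(t + dt, 9)
            if abs(t / 12 - round(t / 12)) < 1e-9:
                samples[round(t, 6)] = x
            if abs(t / 24 - round(t / 24)) < 1e-9 and t < 240 - 1e-9:
                x = x / 20
        for ti, tv in enumerate(tb.times):
            if tv in samples and tv > 0:
                assert tb.X[ti, 0] == pytest.approx(samples[tv], rel=1e-4)

    def test_dilution_fold_must_exceed_one(self, truth5):
        d = CommunityDesign((1, 1, 1, 1, 1), micos.DEFAULT_POOL[:5])
        with pytest.raises(ValueError, match="dilution_fold"):
            simulate_with_passaging(truth5, d, dilution_fold=1.0)


# -------------------------------------------------------------------- designs


class TestSamplingDesigns:
    def test_default_training_design_counts(self):
        designs = design_training_communities(seed=0)
        assert len(designs) == 624
        by_k = {}
        for d in designs:
            by_k[d.richness] = by_k.get(d.richness, 0) + 1
        assert by_k == {1: 25, 2: 300, 3: 100, 5: 100, 6: 99}
        assert len({d.present for d in designs}) == 624

    def test_small_pool_enumeration_by_hand(self):
        designs = design_training_communities(pool_size=3, n3=1, n5=0, n6=0,
                                              seed=0)
        assert len(designs) == 7  # 3 singles + 3 pairs + 1 triple

    def test_training_design_determinism(self):
        a = design_training_communities(seed=5)
        b = design_training_communities(seed=5)
        assert [d.present for d in a] == [d.present for d in b]

    def test_test_communities_full_pool_forced(self):
        designs = design_test_communities(pool_size=5, n=1, min_richness=5,
                                          seed=0)
        assert designs[0].present == (1, 1, 1, 1, 1)

    def test_too_many_requested_rejected(self):
        with pytest.raises(ValueError, match="only"):
            design_test_communities(pool_size=5, n=40, min_richness=1, seed=0)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10**6))
    def test_test_communities_respect_richness_floor(self, seed):
        designs = design_test_communities(pool_size=12, n=30, min_richness=7,
                                          seed=seed)
        assert len({d.present for d in designs}) == 30
        assert all(d.richness >= 7 for d in designs)


# ---------------------------------------------------------------------- noise


def test_noise_preserves_absence_and_is_multiplicative(truth5):
    d = CommunityDesign((1, 0, 1, 1, 0), micos.DEFAULT_POOL[:5])
    tb = simulate_glv(truth5, d)
    noisy = add_observation_noise(tb, sigma=0.2, seed=3)
    assert np.all(noisy.X[:, [1, 4]] == 0.0)
    present = tb.X[:, [0, 2, 3]] > 0
    ratio = noisy.X[:, [0, 2, 3]][present] / tb.X[:, [0, 2, 3]][present]
    assert np.all(ratio > 0)
    assert not np.allclose(ratio, 1.0)


def test_cumulative_metabolites_monotone_for_positive_rates(tables5):
    W = np.full((4, 5), 0.5)
    tb = metabolites_from_abundances(tables5[-1], W, mode="cumulative")
    assert np.all(np.diff(tb.C, axis=0) >= 0)


# ------------------------------------------------------------------- fitting


class TestFitGLV:
    def test_single_species_logistic_recovery(self):
        p = GLVParams(r=np.array([0.5]), A=np.array([[-1.0]]))
        d = CommunityDesign((1,), ("PC",))
        tb = simulate_glv(p, d, x0_total=0.05, times=np.arange(0, 49, 4.0))
        fit = fit_glv([tb], n_starts=2, seed=0)
        assert fit.r[0] / fit.A[0, 0] == pytest.approx(-0.5, rel=0.01)

    def test_three_species_recovery_within_5pct(self):
        truth = generate_ground_truth(3, "none", seed=3, **STABLE)
        designs = design_training_communities(pool_size=3, n3=1, n5=0, n6=0,
                                              seed=0)
        times = np.arange(0, 49, 4.0)
        tables = [simulate_glv(truth, dd, times=times, sample_id=f"t{i}")
                  for i, dd in enumerate(designs)]
        fit = fit_glv(tables, n_starts=2, seed=0)
        assert np.all(np.abs(fit.r - truth.r) / np.abs(truth.r) < 0.05)
        assert np.all(np.abs(fit.A - truth.A) / np.abs(truth.A) < 0.05)

    def test_pairwise_fit_degrades_under_third_order_truth(self):
        # same sampling design, pairwise-only vs moderate third-order truth;
        # the pairwise refit must explain the third-order data less well
        times = np.arange(0, 49, 8.0)
        designs = design_training_communities(pool_size=6, n3=15, n5=0, n6=0,
                                              seed=2)
        holdout = design_test_communities(6, n=20, min_richness=4, seed=7)
        r2 = {}
        for level in ("none", "moderate"):
            truth = generate_ground_truth(6, level, seed=11, **STABLE)
            train = [simulate_glv(truth, dd, times=times, sample_id=f"a{i}")
                     for i, dd in enumerate(designs)]
            test = [simulate_glv(truth, dd, times=times, sample_id=f"b{i}")
                    for i, dd in enumerate(holdout)]
            fit = fit_glv(train, n_starts=1, seed=0, dt=0.5, max_nfev=30)
            pred = np.stack([p[-1] for p in micos.predict_glv(fit, test, dt=0.5)])
            true = np.stack([tb.X[-1] for tb in test])
            r2[level] = micos.pearson_r2(pred.ravel(), true.ravel())
        assert r2["moderate"] < r2["none"]

    def test_too_few_timepoints_rejected(self, truth5):
        d = CommunityDesign((1, 1, 1, 1, 1), micos.DEFAULT_POOL[:5])
        tb = simulate_glv(truth5, d, times=np.array([0.0, 8.0]))
        short = micos.TrajectoryTable(sample_id="s", design=d,
                                      times=tb.times[:1], X=tb.X[:1])
        with pytest.raises(ValueError, match="2 time points"):
            fit_glv([short])
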