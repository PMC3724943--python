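"""Tests for the SAMC sampler: single-step operations, convergence
properties and agreement with exhaustive enumeration on tiny instances.
"""

import numpy as np
import pytest

from brvd import Dataset
from brvd.model import ModelState, PriorConfig, log_psi
from brvd.samc import (
    Partition,
    SamcRun,
    SamcSettings,
    build_partition,
    estimate_bayes_factor,
    estimate_log_bayes_factor,
    estimate_marginal_inclusion,
    gain_factor,
    mh_accept_ratio,
    propose,
    run_samc,
    update_theta,
)

from oracles import enumerate_discrete_posterior

GRID = (-2.0, -1.0, 0.0, 1.0, 2.0)


def toy_settings(iterations=100_000, burnin=None, m=11, **kw):
    return SamcSettings(
        iterations=iterations,
        burnin=iterations // 10 if burnin is None else burnin,
        t0=500, m=m, coef_grid=GRID, sigma2_fixed=1.0, thin=0, **kw,
    )


class TestPartition:
    def test_equal_grid_band_assignment(self):
        part = Partition(m=3, u_min=0.0, u_max=10.0)
        # bands: (0, 5] -> index 1, (5, 10] -> index 2 (0-based)
        assert part.region_index(3.0, True) == 1
        assert part.region_index(5.0, True) == 1
        assert part.region_index(7.0, True) == 2
        # overflow conventions
        assert part.region_index(-4.0, True) == 1
        assert part.region_index(25.0, True) == 2

    def test_h0_always_region_zero(self):
        part = Partition(m=5, u_min=0.0, u_max=10.0)
        for e in (-100.0, 0.0, 3.3, 1e6):
            assert part.region_index(e, False) == 0

    def test_index_monotone_in_energy(self):
        part = Partition(m=7, u_min=-3.0, u_max=12.0)
        energies = np.linspace(-10, 20, 400)
        idx = [part.region_index(e, True) for e in energies]
        assert (np.diff(idx) >= 0).all()

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            Partition(m=1, u_min=0, u_max=1)
        with pytest.raises(ValueError):
            Partition(m=3, u_min=2.0, u_max=1.0)
        with pytest.raises(ValueError):
            build_partition(None, None, m=1)

    def test_default_bracket_orders(self, tiny_data, toy_cfg):
        part = build_partition(tiny_data, toy_cfg, m=11)
        assert part.u_min < part.u_max
        assert np.isfinite(part.u_min) and np.isfinite(part.u_max)


class TestGainFactor:
    def test_plateau_and_decay(self):
        assert gain_factor(0, 100) == 1.0
        assert gain_factor(100, 100) == 1.0
        assert gain_factor(200, 100) == 0.5
        with pytest.raises(ValueError):
            gain_factor(5, 0)

    def test_robbins_monro_conditions(self):
        # sum a_t diverges (harmonic tail), sum a_t^2 converges
        t0 = 50
        a = np.array([gain_factor(t, t0) for t in range(1, 200_001)])
        assert a.sum() > 100.0  # grows like t0 log t -> diverges
        tail = np.array([gain_factor(t, t0) for t in range(10**6, 10**6 + 10)])
        assert (np.diff(a) <= 0).all()
        assert (a**2).sum() < t0**2 * (np.pi**2 / 6) / t0 + t0  # bounded


class TestUpdateTheta:
    def _run(self, m=2):
        part = Partition(m=m, u_min=0.0, u_max=1.0)
        return SamcRun(
            theta=np.zeros(m), visit_counts=np.zeros(m, dtype=int),
            post_visit_counts=np.zeros(m, dtype=int), t=0, t0=10,
            partition=part, P=3, lambda0=0.5, lambda1=0.5,
        )

    def test_two_region_update(self):
        run = self._run(m=2)
        update_theta(run, 0)
        # raw update (+a/2, -a/2) with a=1, then recentred to theta_0=0
        assert run.theta == pytest.approx([0.0, -1.0])
        assert run.visit_counts.tolist() == [1, 0]
        assert run.t == 1

    def test_recentering_preserves_differences(self):
        run_a = self._run(m=4)
        run_b = self._run(m=4)
        run_b.theta = run_b.theta + 7.5  # same differences, shifted
        update_theta(run_a, 2)
        update_theta(run_b, 2)
        diff_a = run_a.theta[:, None] - run_a.theta[None, :]
        diff_b = run_b.theta[:, None] - run_b.theta[None, :]
        assert np.allclose(diff_a, diff_b)

    def test_long_run_visit_frequencies_match_target(self, tiny_data,
                                                     toy_cfg):
        # the self-adjusting mechanism: post-burn-in visit frequencies
        # of non-empty subregions approach the desired distribution
        part = build_partition(tiny_data, toy_cfg, m=5)
        settings = toy_settings(iterations=200_000, m=5)
        run = run_samc(tiny_data, toy_cfg, settings, partition=part, seed=5)
        freqs = run.post_visit_counts / run.post_visit_counts.sum()
        occupied = run.post_visit_counts > 0
        target = part.desired_pi[occupied] / part.desired_pi[occupied].sum()
        assert np.abs(freqs[occupied] - target).max() <= 0.03


class TestPropose:
    def _state(self, tiny_data, k):
        if k == 0:
            return ModelState.null(q=0, alpha=0.0, sigma2=1.0)
        return ModelState(True, list(range(k)), 0.0, [], [0.5] * k, 1.0)

    def test_walk_is_symmetric(self, tiny_data, toy_cfg, rng):
        settings = SamcSettings(iterations=2, burnin=1, informed_add=False)
        state = self._state(tiny_data, 2)
        found = False
        for _ in range(200):
            cand, logq = propose(state, tiny_data, toy_cfg, rng, settings)
            if cand is None:
                continue
            same_model = (cand.h1 and len(cand.included) == 2
                          and set(cand.included) == {0, 1}
                          and cand.sigma2 == state.sigma2)
            if same_model:
                assert logq == 0.0
                found = True
        assert found

    def test_add_delete_ratio_counts_and_density(self, tiny_data, toy_cfg,
                                                 rng):
        # uniform candidate choice: the exact ratio is the counting term
        # log(p_del/(k+1)) - log(p_add/(P-k)) minus the log density of
        # the drawn coefficient under its conditional prior
        from scipy.stats import norm

        settings = SamcSettings(iterations=2, burnin=1, informed_add=False)
        state = self._state(tiny_data, 1)
        P, k = tiny_data.P, 1
        seen_add = False
        for _ in range(400):
            cand, logq = propose(state, tiny_data, toy_cfg, rng, settings)
            if cand is None or not cand.h1 or len(cand.included) != k + 1:
                continue
            j_new = (set(cand.included) - set(state.included)).pop()
            b_new = cand.beta[list(cand.included).index(j_new)]
            expect = (np.log(settings.p_delete / (k + 1))
                      - np.log(settings.p_add / (P - k))
                      - norm.logpdf(b_new, 0, np.sqrt(state.sigma2)))
            assert logq == pytest.approx(expect)
            seen_add = True
        assert seen_add

    def test_delete_from_singleton_routes_to_h0(self, tiny_data, toy_cfg,
                                                rng):
        settings = SamcSettings(iterations=2, burnin=1, informed_add=False)
        state = self._state(tiny_data, 1)
        reached_h0 = False
        for _ in range(400):
            cand, _ = propose(state, tiny_data, toy_cfg, rng, settings)
            if cand is not None and not cand.h1:
                reached_h0 = True
                assert len(cand.included) == 0
        assert reached_h0

    def test_all_small_models_reachable(self, toy_cfg, rng):
        # transition-graph reachability on a P=5 toy: from H0, every
        # model of size <= 3 is reached with positive probability
        data = Dataset(y=[0, 1] * 5,
                       G=np.eye(5)[list(range(5)) * 2])
        settings = toy_settings(iterations=40_000, m=5)
        run = run_samc(data, toy_cfg, settings, partition=None, seed=3)
        assert run.n_h1_samples > 0
        mip = estimate_marginal_inclusion(run)
        assert (mip > 0).all()  # every variant was included at least once


class TestAcceptRatio:
    def test_neutral_proposal_gives_unity(self, tiny_data, toy_cfg):
        part = build_partition(tiny_data, toy_cfg, m=5)
        state = ModelState.null(q=0, alpha=0.1, sigma2=1.0)
        theta = np.zeros(5)
        r = mh_accept_ratio(state, state, theta, part, 0.0, tiny_data,
                            toy_cfg)
        assert r == pytest.approx(1.0)

    def test_theta_difference_scales_ratio(self, tiny_data, toy_cfg):
        part = build_partition(tiny_data, toy_cfg, m=5)
        state = ModelState.null(q=0, alpha=0.1, sigma2=1.0)
        # same state, but pretend candidate sits in a band whose theta
        # is ln 2 lower by shifting theta of region 0 artificially
        theta = np.zeros(5)
        r1 = mh_accept_ratio(state, state, theta, part, np.log(2.0),
                             tiny_data, toy_cfg)
        assert r1 == pytest.approx(2.0)

    def test_minus_inf_candidate_rejected(self, tiny_data, toy_cfg):
        part = build_partition(tiny_data, toy_cfg, m=5)
        state = ModelState.null(q=0, alpha=0.1, sigma2=1.0)
        bad = ModelState.null(q=0, alpha=0.1, sigma2=100.0)  # outside [l,u]
        r = mh_accept_ratio(state, bad, np.zeros(5), part, 0.0, tiny_data,
                            toy_cfg)
        assert r == 0.0


class TestRunSamc:
    def test_seed_determinism(self, tiny_data, toy_cfg):
        settings = toy_settings(iterations=5000, m=7)
        a = run_samc(tiny_data, toy_cfg, settings, seed=42)
        b = run_samc(tiny_data, toy_cfg, settings, seed=42)
        assert np.array_equal(a.theta, b.theta)
        assert np.array_equal(a.visit_counts, b.visit_counts)
        assert a.mip_den == b.mip_den
        c = run_samc(tiny_data, toy_cfg, settings, seed=43)
        assert not np.array_equal(a.theta, c.theta)

    def test_shift_invariance_of_estimators(self, tiny_data, toy_cfg):
        settings = toy_settings(iterations=20_000, m=7)
        run = run_samc(tiny_data, toy_cfg, settings, seed=1)
        bf = estimate_log_bayes_factor(run)
        run.theta = run.theta + 11.0
        run.theta_mean = run.theta_mean + 11.0
        assert estimate_log_bayes_factor(run) == pytest.approx(bf)

    def test_psi_global_scaling_leaves_bf_unchanged(self, tiny_data):
        # scaling psi by a constant shifts every energy equally; with
        # the same partition the BF estimate is unchanged in expectation
        # — here verified exactly through the lambda factors, which
        # rescale psi between hypotheses and cancel in the estimator
        cfg_a = PriorConfig(gammaL=0.5, gammaU=0.9, l=0.5, u=2.0,
                            lambda0=0.5, lambda1=0.5)
        cfg_b = PriorConfig(gammaL=0.5, gammaU=0.9, l=0.5, u=2.0,
                            lambda0=0.2, lambda1=0.8)
        part = build_partition(tiny_data, cfg_a, m=9)
        settings = toy_settings(iterations=150_000, m=9)
        bf_a = estimate_log_bayes_factor(
            run_samc(tiny_data, cfg_a, settings, partition=part, seed=7))
        bf_b = estimate_log_bayes_factor(
            run_samc(tiny_data, cfg_b, settings, partition=part, seed=7))
        assert bf_a == pytest.approx(bf_b, abs=0.5)

    def test_checkpoint_roundtrip(self, tiny_data, toy_cfg, tmp_path):
        settings = toy_settings(iterations=3000, m=5)
        run = run_samc(tiny_data, toy_cfg, settings, seed=9)
        path = tmp_path / "ckpt.json"
        run.save(path)
        back = SamcRun.load(path)
        assert np.allclose(back.theta, run.theta)
        assert np.allclose(back.theta_mean, run.theta_mean)
        assert estimate_log_bayes_factor(back) == pytest.approx(
            estimate_log_bayes_factor(run))


class TestOracleAgreement:
    def test_two_region_mass_ratio(self, toy_cfg):
        # degenerate partition (m=2): exp(theta_1 - theta_0) estimates
        # the H1:H0 mass ratio; check against exhaustive enumeration
        data = Dataset(y=[0, 1, 1, 0, 1, 0], G=[[1], [0], [2], [0], [1], [1]])
        lbf_oracle, _ = enumerate_discrete_posterior(data, toy_cfg, GRID, 1.0)
        part = Partition(m=2, u_min=0.0, u_max=1.0)
        settings = toy_settings(iterations=100_000, m=2)
        run = run_samc(data, toy_cfg, settings, partition=part, seed=21)
        lbf = estimate_log_bayes_factor(run)
        assert np.exp(lbf) == pytest.approx(np.exp(lbf_oracle), rel=0.10)

    def test_bf_and_mip_match_enumeration(self, tiny_data, toy_cfg):
        lbf_oracle, mip_oracle = enumerate_discrete_posterior(
            tiny_data, toy_cfg, GRID, 1.0)
        part = build_partition(tiny_data, toy_cfg, m=11)
        settings = toy_settings(iterations=250_000, m=11)
        run = run_samc(tiny_data, toy_cfg, settings, partition=part, seed=2)
        lbf = estimate_log_bayes_factor(run)
        mip = estimate_marginal_inclusion(run)
        assert np.exp(lbf) == pytest.approx(np.exp(lbf_oracle), rel=0.15)
        assert np.abs(mip - mip_oracle).max() <= 0.05

    def test_mip_sum_identity(self, tiny_data, toy_cfg):
        # sum_j mip_j equals the importance-weighted mean model size
        settings = toy_settings(iterations=30_000, m=7)
        run = run_samc(tiny_data, toy_cfg, settings, seed=4)
        mip = estimate_marginal_inclusion(run)
        assert mip.sum() == pytest.approx(run.mip_num.sum() / run.mip_den)

    def test_never_included_variant_has_zero_mip(self, toy_cfg):
        run = SamcRun(
            theta=np.zeros(3), visit_counts=np.array([5, 5, 5]),
            post_visit_counts=np.array([5, 5, 5]), t=15, t0=10,
            partition=Partition(m=3, u_min=0, u_max=1), P=4,
            lambda0=0.5, lambda1=0.5, mip_num=np.array([3.0, 0.0, 1.0, 0.0]),
            mip_den=4.0, n_h1_samples=4,
        )
        mip = estimate_marginal_inclusion(run)
        assert mip[1] == 0.0 and mip[3] == 0.0
        assert mip[0] == pytest.approx(0.75)
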