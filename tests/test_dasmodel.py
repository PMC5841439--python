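import numpy as np
import pytest
from scipy.special import betaln, gammaln
from statsmodels.stats.multitest import multipletests

from splicedas.dasmodel import (
    bh_adjust,
    call_das,
    estimate_psi,
    fit_beta_binomial,
    lrt_event,
    pooled_dispersion,
    run_das,
)
from splicedas.simulate import SimulationConfig, simulate_counts


def grid_oracle_loglik(k, n, gidx, n_groups, refine=4):
    """Independent dense grid search over (p per group, theta), iteratively
    refined around the best cell. For a shared theta the per-group optimal p
    separates, so each group is profiled on its own p-grid."""
    k = np.asarray(k, float)
    n = np.asarray(n, float)
    const = float(np.sum(gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)))
    p_lo, p_hi = 1e-3, 1 - 1e-3
    # same parameter domain the estimator optimises over
    T_MIN, T_MAX = -5.0, 10.0
    t_lo, t_hi = T_MIN, T_MAX
    best = -np.inf
    for _ in range(refine):
        ps = np.linspace(p_lo, p_hi, 120)
        ths = np.exp(np.linspace(t_lo, t_hi, 120))
        best_ps = np.zeros(n_groups)
        best_t = ths[0]
        best = -np.inf
        for th in ths:
            a = ps * th
            b = (1 - ps) * th
            total = 0.0
            arg = np.zeros(n_groups)
            for g in range(n_groups):
                kk, nn = k[gidx == g], n[gidx == g]
                ll = np.sum(
                    betaln(kk[None, :] + a[:, None], nn[None, :] - kk[None, :] + b[:, None])
                    - betaln(a, b)[:, None],
                    axis=1,
                )
                total += ll.max()
                arg[g] = ps[ll.argmax()]
            if total > best:
                best = total
                best_ps = arg
                best_t = th
        dp = (p_hi - p_lo) / 119 * 3
        p_lo = max(1e-6, best_ps.min() - dp)
        p_hi = min(1 - 1e-6, best_ps.max() + dp)
        dt = (t_hi - t_lo) / 119 * 3
        t_lo = max(T_MIN, np.log(best_t) - dt)
        t_hi = min(T_MAX, np.log(best_t) + dt)
    return best + const


class TestEstimatePsi:
    def test_pooled_across_samples(self):
        assert estimate_psi([30, 15], [10, 5]) == pytest.approx(45 / 60)

    def test_boundary_all_inclusion(self):
        assert estimate_psi([10, 5], [0, 0]) == 1.0

    def test_all_zero_totals_raise(self):
        with pytest.raises(ValueError):
            estimate_psi([0, 0], [0, 0])

    def test_monte_carlo_recovery(self, rng):
        """500 beta-binomial replicates (p=0.4, theta=20, 3 samples x depth
        200): the mean pooled estimate recovers p within +/-0.02."""
        p, theta, depth = 0.4, 20.0, 200
        estimates = []
        for _ in range(500):
            ps = rng.beta(p * theta, (1 - p) * theta, size=3)
            k = rng.binomial(depth, ps)
            estimates.append(estimate_psi(k, depth - k))
        assert abs(np.mean(estimates) - p) < 0.02


class TestBetaBinomialFit:
    def test_identical_groups_share_pooled_estimate(self):
        k = np.array([12, 15, 12, 15])
        n = np.array([40, 40, 40, 40])
        fit = fit_beta_binomial(k, n - k, groups=np.array([0, 0, 1, 1]))
        pooled = fit_beta_binomial(k, n - k)
        assert fit.p[0] == pytest.approx(fit.p[1], abs=1e-4)
        assert fit.p[0] == pytest.approx(pooled.p[0], abs=1e-4)

    def test_single_sample_per_group_matches_binomial_proportion(self):
        fit = fit_beta_binomial([8, 2], [2, 8], groups=np.array([0, 1]))
        assert fit.p[0] == pytest.approx(0.8, abs=1e-2)
        assert fit.p[1] == pytest.approx(0.2, abs=1e-2)

    def test_matches_grid_search_oracle(self, rng):
        """Spec'd instance {(9,1),(8,2)} vs {(3,7),(2,8)} plus random draws:
        attained log-likelihoods match the refined grid search to 1e-3."""
        k = np.array([9, 8, 3, 2])
        n = np.array([10, 10, 10, 10])
        gidx = np.array([0, 0, 1, 1])
        fit = fit_beta_binomial(k, n - k, groups=gidx)
        oracle = grid_oracle_loglik(k, n, gidx, 2)
        assert fit.loglik == pytest.approx(oracle, abs=1e-3)
        for _ in range(5):
            n = rng.integers(5, 40, size=4)
            k = rng.binomial(n, rng.uniform(0.2, 0.8))
            fit = fit_beta_binomial(k, n - k, groups=gidx)
            oracle = grid_oracle_loglik(k, n, gidx, 2)
            assert fit.loglik >= oracle - 1e-3
            assert fit.loglik == pytest.approx(oracle, abs=1e-3)

    def test_invalid_counts_rejected(self):
        with pytest.raises(ValueError):
            fit_beta_binomial([-1, 2], [3, 4])


class TestLrt:
    def test_identical_groups_give_null_result(self):
        k = np.array([10, 10, 10, 10])
        n = np.array([30, 30, 30, 30])
        stat, p, null, alt = lrt_event(k, n - k, np.array([0, 0, 1, 1]))
        assert stat == pytest.approx(0.0, abs=1e-6)
        assert p > 0.99
        assert alt.loglik >= null.loglik

    def test_alternative_never_below_null(self, rng):
        gidx = np.array([0, 0, 0, 1, 1, 1])
        for _ in range(20):
            n = rng.integers(5, 60, size=6)
            k = rng.binomial(n, rng.uniform(0.05, 0.95))
            stat, p, null, alt = lrt_event(k, n - k, gidx)
            assert alt.loglik >= null.loglik - 1e-9
            assert stat >= 0.0

    def test_label_swap_negates_dpsi_and_keeps_p(self):
        cfg = SimulationConfig(seed=3, planted_fraction=0.3)
        counts, _ = simulate_counts(cfg, [f"E{i}" for i in range(30)])
        fwd = run_das(counts, "case", "control")
        rev = run_das(counts, "control", "case")
        merged = fwd.merge(rev, on="event_id", suffixes=("_f", "_r"))
        assert np.allclose(merged.delta_psi_f, -merged.delta_psi_r)
        assert np.allclose(merged.p_f, merged.p_r, rtol=1e-4, atol=1e-6)


class TestPooledDispersion:
    def test_recovers_generating_theta(self, rng):
        theta = 10.0
        K = np.zeros((400, 6), int)
        N = np.zeros((400, 6), int)
        for i in range(400):
            tot = rng.poisson(100, 6) + 1
            ps = rng.beta(0.5 * theta, 0.5 * theta, 6)
            K[i] = rng.binomial(tot, ps)
            N[i] = tot
        est = pooled_dispersion(K, N - K, np.array([0, 0, 0, 1, 1, 1]))
        assert 0.7 * theta < est < 1.4 * theta

    def test_group_mean_shifts_do_not_inflate_dispersion(self, rng):
        """Within-group moments only: a large planted delta-PSI must leave
        the pooled precision essentially unchanged."""
        theta = 50.0
        gidx = np.array([0, 0, 0, 1, 1, 1])
        K0 = np.zeros((300, 6), int)
        K1 = np.zeros((300, 6), int)
        N = np.full((300, 6), 200, int)
        for i in range(300):
            ps_null = np.concatenate(
                [rng.beta(0.4 * theta, 0.6 * theta, 3)] * 2
            )
            ps_das = np.concatenate(
                [rng.beta(0.7 * theta, 0.3 * theta, 3), rng.beta(0.4 * theta, 0.6 * theta, 3)]
            )
            K0[i] = rng.binomial(N[i], ps_null)
            K1[i] = rng.binomial(N[i], ps_das)
        t0 = pooled_dispersion(K0, N - K0, gidx)
        t1 = pooled_dispersion(K1, N - K1, gidx)
        assert abs(np.log(t1 / t0)) < np.log(1.6)


class TestBhAdjust:
    def test_hand_worked_step_up(self):
        q = bh_adjust([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(q, [0.04, 0.04, 0.04, 0.04])

    def test_single_p_unchanged(self):
        assert bh_adjust([0.37])[0] == pytest.approx(0.37)

    def test_q_dominates_p_and_is_capped(self, rng):
        p = rng.uniform(size=50)
        q = bh_adjust(p)
        assert (q >= p - 1e-12).all() and (q <= 1.0).all()

    def test_matches_statsmodels_oracle(self, rng):
        p = rng.uniform(size=200)
        ours = bh_adjust(p)
        theirs = multipletests(p, method="fdr_bh")[1]
        assert np.allclose(ours, theirs)

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])


class TestCallDas:
    def test_thresholds_are_strict(self):
        import pandas as pd

        records = pd.DataFrame(
            {
                "event_id": ["a", "b", "c"],
                "psi_case": [0.5, 0.8, 0.5],
                "psi_control": [0.46, 0.5, 0.45],
                "delta_psi": [0.04, 0.30, 0.05],
                "lrt": [9.0, 25.0, 9.0],
                "p": [0.001, 0.001, 0.001],
                "q": [0.001, 0.04, 0.001],
            }
        )
        out = call_das(records)
        assert list(out.significant) == [False, True, False]

    def test_low_coverage_events_reported_na_and_out_of_bh(self):
        cfg = SimulationConfig(seed=8, planted_fraction=0.0, depth_mean=50.0)
        counts, _ = simulate_counts(cfg, [f"E{i}" for i in range(10)])
        starved = counts["event_id"] == "E0"
        counts.loc[starved, ["n_inc", "n_exc"]] = 0
        res = run_das(counts, "case", "control")
        assert res.loc[res.event_id == "E0", "p"].isna().all()
        assert res.loc[res.event_id != "E0", "q"].notna().all()
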