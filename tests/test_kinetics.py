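"""Dwell-time likelihood, MIL rate fitting, equilibrium predictions, schemes."""

import math

import numpy as np
import pytest
from scipy import integrate, linalg, optimize

from atdfret import (
    KineticParams,
    SchemeSpec,
    build_rate_matrix,
    compare_schemes,
    dissociation_constant,
    dwell_loglik,
    equilibrium_occupancy,
    fit_rates,
    predicted_dose_response,
    stationary_distribution,
)
from atdfret.idealize import DwellSequence, _merge_short_dwells

DEAD = 0.2


def _seq(dwells, dead_time=DEAD):
    return DwellSequence(dwells=dwells, dead_time=dead_time, frame_interval=0.1)


def _simulated_dwell_seqs(kp, n_traces, duration, seed, dead_time=DEAD):
    """Exact Gillespie dwells per trace with dead-time merging (no rendering)."""
    from atdfret import simulate_state_path

    q = build_rate_matrix(kp)
    seqs = []
    for i in range(n_traces):
        p = simulate_state_path(q, duration, seed=np.random.default_rng((seed, i)))
        runs = [(int(s), float(b - a)) for s, a, b in p.segments]
        merged = _merge_short_dwells(runs, dead_time)
        if merged and all(d >= dead_time for _, d in merged):
            seqs.append(_seq(merged, dead_time))
    return seqs


class TestDwellLoglik:
    def test_truncated_exponential_mle_matches_closed_form(self):
        """Optimizing the likelihood over exit rate reproduces 1/(mean − τd)."""
        rng = np.random.default_rng(0)
        lam_true = 1.3
        durs = rng.exponential(1 / lam_true, 400) + DEAD
        seqs = [_seq([(0, float(t)), (1, 5.0)]) for t in durs]
        scheme = SchemeSpec("linear", "free", conc=0.3)

        def neg(log_k01):
            rates = np.array([math.exp(log_k01), 0.4, 0.3, 0.9])
            return -dwell_loglik(seqs, scheme, rates, DEAD)

        res = optimize.minimize_scalar(neg, bounds=(-5, 5), method="bounded",
                                       options={"xatol": 1e-12})
        closed_form = 1.0 / (durs.mean() - DEAD)
        assert math.exp(res.x) == pytest.approx(closed_form, rel=1e-6)

    def test_zero_dead_time_optimum_within_two_se(self):
        rng = np.random.default_rng(1)
        lam_true = 2.0
        n = 5000
        durs = rng.exponential(1 / lam_true, n)
        seqs = [_seq([(0, float(t)), (1, 5.0)], dead_time=0.0) for t in durs]
        scheme = SchemeSpec("linear", "free", conc=0.3)

        def neg(log_k01):
            rates = np.array([math.exp(log_k01), 0.4, 0.3, 0.9])
            return -dwell_loglik(seqs, scheme, rates, dead_time=0.0)

        res = optimize.minimize_scalar(neg, bounds=(-5, 5), method="bounded",
                                       options={"xatol": 1e-12})
        se = lam_true / math.sqrt(n)
        assert abs(math.exp(res.x) - lam_true) < 2 * se

    def test_per_dwell_density_integrates_to_one(self):
        """Σ_j ∫_{τd}^∞ q_ij e^{−λ_i(t−τd)} dt = 1 by numerical quadrature."""
        rng = np.random.default_rng(2)
        for _ in range(5):
            scheme = SchemeSpec("linear", "free", conc=0.3)
            rates = 10 ** rng.uniform(-1, 1, 4)
            q = scheme.rate_matrix(rates)
            for i in (0, 1, 2):
                total = 0.0
                for j in range(3):
                    if q[i, j] <= 0 or i == j:
                        continue

                    def dens(t, j=j):
                        full = dwell_loglik([_seq([(i, t), (j, 5.0)])], scheme,
                                            rates, DEAD)
                        cens = dwell_loglik([_seq([(j, 5.0)])], scheme, rates, DEAD)
                        return math.exp(full - cens)

                    val, _ = integrate.quad(dens, DEAD, np.inf)
                    total += val
                assert total == pytest.approx(1.0, abs=1e-7)

    def test_invariant_to_trace_order(self):
        seqs = [_seq([(0, 1.0), (1, 0.5), (2, 2.0)]),
                _seq([(2, 0.7), (1, 0.4)]),
                _seq([(1, 3.0)])]
        scheme = SchemeSpec("linear", "independent_sites", conc=0.3)
        rates = np.array([1.0, 0.46])
        ll1 = dwell_loglik(seqs, scheme, rates, DEAD)
        ll2 = dwell_loglik(seqs[::-1], scheme, rates, DEAD)
        assert ll1 == pytest.approx(ll2, abs=1e-12)

    def test_sub_dead_time_dwell_rejected(self):
        with pytest.raises(ValueError):
            dwell_loglik([_seq([(0, 0.1)])], SchemeSpec("linear", "free", 0.3),
                         np.array([1, 1, 1, 1.0]), DEAD)

    def test_factorization_matches_matrix_exponential_oracle(self):
        """Interval likelihood equals the expm-based aggregated-state form.

        With a one-to-one state↔class mapping every within-class sub-generator
        is scalar, so exp(Q_ii·t)·q_ij is the exact interval likelihood.
        """
        scheme = SchemeSpec("linear", "independent_sites", conc=0.5)
        rates = np.array([0.8, 0.5])
        q = scheme.rate_matrix(rates)
        seqs = [_seq([(0, 1.2), (1, 0.9), (2, 2.5), (1, 0.6)]),
                _seq([(1, 0.8), (0, 3.0)])]
        ll = dwell_loglik(seqs, scheme, rates, DEAD)
        ll_oracle = 0.0
        for s in seqs:
            dw = s.dwells
            for idx, (i, t) in enumerate(dw):
                surv = linalg.expm(np.array([[q[i, i]]]) * (t - DEAD))[0, 0]
                if idx == len(dw) - 1:
                    ll_oracle += math.log(surv)
                else:
                    ll_oracle += math.log(surv * q[i, dw[idx + 1][0]])
        assert ll == pytest.approx(ll_oracle, abs=1e-10)


@pytest.fixture(scope="module")
def linear_truth_seqs(kp_default):
    return _simulated_dwell_seqs(kp_default, n_traces=300, duration=60.0, seed=9)


@pytest.fixture(scope="module")
def seqs(kp_default):
    return _simulated_dwell_seqs(kp_default, 150, 60.0, seed=33)


class TestFitRates:
    def test_constrained_recovery_within_15_percent(self, kp_default,
                                                    linear_truth_seqs):
        fit = fit_rates(linear_truth_seqs,
                        SchemeSpec("linear", "independent_sites", kp_default.conc))
        assert fit.rates["kon"] == pytest.approx(kp_default.kon, rel=0.15)
        assert fit.rates["koff"] == pytest.approx(kp_default.koff, rel=0.15)
        assert fit.converged

    def test_constrained_forward_ratio_is_exactly_two(self):
        scheme = SchemeSpec("linear", "independent_sites", conc=0.7)
        q = scheme.rate_matrix(np.array([1.3, 0.5]))
        assert q[0, 1] / q[1, 2] == pytest.approx(2.0, abs=1e-12)
        assert q[2, 1] / q[1, 0] == pytest.approx(2.0, abs=1e-12)

    def test_free_fit_recovers_two_to_one_structure(self, linear_truth_seqs,
                                                    kp_default):
        fit = fit_rates(linear_truth_seqs, SchemeSpec("linear", "free", kp_default.conc))
        r = fit.rates
        assert 1.6 <= r["k_R_RA"] / r["k_RA_RAA"] <= 2.4
        assert 1.6 <= r["k_RAA_RA"] / r["k_RA_R"] <= 2.4

    def test_standard_errors_reported_positive(self, linear_truth_seqs, kp_default):
        fit = fit_rates(linear_truth_seqs,
                        SchemeSpec("linear", "independent_sites", kp_default.conc))
        assert all(se > 0 for se in fit.ses.values())
        assert fit.kd_se is not None and fit.kd_se > 0

    def test_few_dwells_warns(self):
        seqs = [_seq([(0, 1.0), (1, 0.5)])]
        with pytest.warns(UserWarning, match="dwells"):
            fit_rates(seqs, SchemeSpec("linear", "independent_sites", 0.3), n_starts=1)


class TestKd:
    def test_kd_is_koff_over_kon(self):
        assert KineticParams(kon=1.0, koff=0.46, conc=1).kd == pytest.approx(0.46)
        assert KineticParams(kon=10.0, koff=4.6, conc=1).kd == pytest.approx(0.46)

    def test_free_fit_has_no_kd(self):
        seqs = _simulated_dwell_seqs(KineticParams(), 30, 60.0, seed=3)
        fit = fit_rates(seqs, SchemeSpec("linear", "free", 0.3), n_starts=1)
        with pytest.raises(ValueError):
            dissociation_constant(fit)

    def test_recovered_kd_close_to_generator_ratio(self, kp_default):
        seqs = _simulated_dwell_seqs(kp_default, 200, 60.0, seed=14)
        fit = fit_rates(seqs, SchemeSpec("linear", "independent_sites", kp_default.conc))
        kd, se = dissociation_constant(fit)
        assert kd == pytest.approx(kp_default.kd, rel=0.15)


class TestEquilibrium:
    def test_occupancy_at_kd_is_quarter_half_quarter(self):
        kp = KineticParams(kon=1.0, koff=0.46, conc=0.46)
        assert equilibrium_occupancy(kp) == pytest.approx((0.25, 0.5, 0.25))

    def test_saturation_fills_doubly_bound(self):
        kp = KineticParams(conc=1e9)
        assert equilibrium_occupancy(kp) == pytest.approx((0, 0, 1), abs=1e-6)

    def test_binomial_matches_rate_matrix_stationary(self):
        rng = np.random.default_rng(21)
        for _ in range(20):
            kp = KineticParams(kon=10 ** rng.uniform(-1, 1),
                               koff=10 ** rng.uniform(-1, 1),
                               conc=10 ** rng.uniform(-2, 2))
            pi = stationary_distribution(build_rate_matrix(kp))
            assert np.allclose(equilibrium_occupancy(kp), pi, atol=1e-8)

    def test_dose_response_half_max_at_kd_over_sqrt2_minus_1(self):
        kp = KineticParams(kon=1.0, koff=0.46, conc=1.0)
        c_half = kp.kd / (math.sqrt(2) - 1)
        grid = np.array([c_half])
        assert predicted_dose_response(kp, grid)[0] == pytest.approx(0.5, abs=1e-12)


class TestCompareSchemes:
    def test_triangular_fit_pins_direct_rates(self, kp_default):
        """On linear-truth data the direct R↔RAA rates hit the lower bound.

        Exact (unmerged) dwell sequences contain no apparent direct
        transitions, so the direct rates can only lower the likelihood and
        are driven to the bound.
        """
        clean = _simulated_dwell_seqs(kp_default, 150, 60.0, seed=33, dead_time=0.0)
        table = compare_schemes(
            clean,
            [SchemeSpec("linear", "free", kp_default.conc),
             SchemeSpec("triangular", "free", kp_default.conc)],
            dead_time=0.0,
            n_starts=3)
        tri = table[table.topology == "triangular"].iloc[0]
        assert "k_R_RAA" in tri.pinned or "k_RAA_R" in tri.pinned

    def test_constrained_vs_free_likelihood_ratio_small(self, seqs, kp_default):
        """Constrained truth: LR statistic within the χ²(2 df) 99.9% quantile."""
        table = compare_schemes(
            seqs,
            [SchemeSpec("linear", "free", kp_default.conc),
             SchemeSpec("linear", "independent_sites", kp_default.conc)],
            n_starts=3)
        ll_free = table[table.constraint == "free"].loglik.iloc[0]
        ll_cons = table[table.constraint == "independent_sites"].loglik.iloc[0]
        assert ll_free >= ll_cons - 1e-6
        assert 2 * (ll_free - ll_cons) < 13.82

    def test_identical_schemes_give_identical_rows(self, seqs, kp_default):
        sc = SchemeSpec("linear", "independent_sites", kp_default.conc)
        table = compare_schemes(seqs, [sc, sc], n_starts=2)
        a, b = table.iloc[0], table.iloc[1]
        assert a.loglik == b.loglik and a.pinned == b.pinned

    def test_triangular_requires_free(self):
        with pytest.raises(ValueError):
            SchemeSpec("triangular", "independent_sites", 0.3)
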