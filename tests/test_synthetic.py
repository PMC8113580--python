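"""Generator: rate matrix, Gillespie paths, rendering, and reproducibility."""

import numpy as np
import pytest
from scipy import stats

from atdfret import (
    EmissionParams,
    KineticParams,
    PhotophysicsParams,
    build_rate_matrix,
    compute_fret,
    render_trace,
    simulate_experiment,
    simulate_state_path,
    stationary_distribution,
)
from atdfret.synthetic import StatePath, read_traceset, write_traceset

from conftest import NO_BLEACH


class TestRateMatrix:
    def test_structure_and_conservation(self):
        q = build_rate_matrix(KineticParams(kon=2.0, koff=0.5, conc=1.5))
        assert q[0, 1] == pytest.approx(2 * 2.0 * 1.5)
        assert q[1, 2] == pytest.approx(2.0 * 1.5)
        assert q[1, 0] == pytest.approx(0.5)
        assert q[2, 1] == pytest.approx(2 * 0.5)
        assert q[0, 2] == 0 and q[2, 0] == 0
        assert np.allclose(q.sum(axis=1), 0.0)

    def test_zero_concentration_absorbs_into_resting(self):
        q = build_rate_matrix(KineticParams(conc=0.0))
        assert q[0, 1] == 0 and q[1, 2] == 0
        assert np.allclose(stationary_distribution(q), [1.0, 0.0, 0.0])

    def test_stationary_at_kd_is_quarter_half_quarter(self):
        kp = KineticParams(kon=1.3, koff=0.7, conc=0.7 / 1.3)
        pi = stationary_distribution(build_rate_matrix(kp))
        assert np.allclose(pi, [0.25, 0.5, 0.25], atol=1e-9)

    def test_stationary_is_binomial_for_random_parameters(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            kp = KineticParams(kon=10 ** rng.uniform(-1, 1),
                               koff=10 ** rng.uniform(-1, 1),
                               conc=10 ** rng.uniform(-2, 2))
            pi = stationary_distribution(build_rate_matrix(kp))
            theta = kp.conc / (kp.conc + kp.kd)
            expect = [(1 - theta) ** 2, 2 * theta * (1 - theta), theta**2]
            assert np.allclose(pi, expect, atol=1e-8)

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            KineticParams(kon=-1.0)
        with pytest.raises(ValueError):
            KineticParams(kon=np.nan)
        with pytest.raises(ValueError):
            KineticParams(conc=-0.1)


class TestGillespie:
    def test_all_zero_rates_single_segment(self):
        path = simulate_state_path(np.zeros((3, 3)), 10.0, start_state=1, seed=0)
        assert path.segments == [(1, 0.0, 10.0)]

    def test_invalid_rate_matrix_rejected(self):
        q = np.array([[1.0, -1.0], [0.5, -0.5]])
        with pytest.raises(ValueError):
            simulate_state_path(q, 1.0, seed=0)

    def test_dwell_distributions_match_exit_rates(self, kp_default):
        """Complete dwells per state are Exp(λ_state); mean RAA dwell = 1/(2·koff)."""
        from conftest import gillespie_dwell_table

        q = build_rate_matrix(kp_default)
        states, durs = gillespie_dwell_table(q, 10_000, seed=42)
        lam = -np.diag(q)
        for s in range(3):
            d = durs[states == s]
            ks = stats.kstest(d, "expon", args=(0, 1 / lam[s]))
            assert ks.pvalue > 0.001, f"state {s}: KS p={ks.pvalue:g}"
        d2 = durs[states == 2]
        mean, se = d2.mean(), d2.std(ddof=1) / np.sqrt(len(d2))
        assert abs(mean - 1 / (2 * kp_default.koff)) < 3 * se

    def test_long_run_occupancy_matches_stationary(self, kp_default):
        q = build_rate_matrix(kp_default)
        path = simulate_state_path(q, 20_000.0, seed=3)
        occ = np.zeros(3)
        for s, a, b in path.segments:
            occ[s] += b - a
        occ /= occ.sum()
        assert np.allclose(occ, stationary_distribution(q), atol=0.02)

    def test_no_direct_high_low_jumps(self, kp_default):
        q = build_rate_matrix(kp_default)
        for seed in range(10):
            path = simulate_state_path(q, 300.0, seed=seed)
            assert np.all(np.abs(np.diff(path.states)) == 1)


class TestRenderTrace:
    def test_zero_noise_round_trip_is_exact(self, em_default):
        em = EmissionParams(noise_sd=0.0)
        for s, mean in enumerate(em.state_means):
            path = StatePath(np.array([s]), np.array([0.0, 5.0]))
            tr = render_trace(path, em, NO_BLEACH, seed=0)
            ft = compute_fret(tr, em.crosstalk, em.gamma)
            assert np.allclose(ft.fret, mean, atol=1e-12)

    def test_frame_averaging_over_sub_frame_transition(self):
        """A mid-frame transition gives the time-weighted mean of the two states."""
        em = EmissionParams(noise_sd=0.0)
        path = StatePath(np.array([0, 2]), np.array([0.0, 0.13, 1.0]))
        ft = compute_fret(render_trace(path, em, NO_BLEACH, seed=0),
                          em.crosstalk, em.gamma)
        expect = 0.3 * em.state_means[0] + 0.7 * em.state_means[2]
        assert ft.fret[1] == pytest.approx(expect, abs=1e-12)
        assert ft.fret[0] == pytest.approx(em.state_means[0], abs=1e-12)

    def test_fret_is_zero_after_acceptor_bleach(self):
        em = EmissionParams(noise_sd=0.0)
        ph = PhotophysicsParams(donor_bleach_mean=1e9, acceptor_bleach_mean=20.0)
        path = StatePath(np.array([0]), np.array([0.0, 60.0]))
        tr = render_trace(path, em, ph, seed=5)
        t_acc = tr.truth["t_acceptor_bleach"]
        assert t_acc < 60.0
        ft = compute_fret(tr, em.crosstalk, em.gamma)
        after = ft.fret[int(t_acc / 0.1) + 1:]
        assert np.allclose(after, 0.0, atol=1e-9)

    def test_channels_fall_to_background_after_donor_bleach(self):
        em = EmissionParams(noise_sd=0.0)
        ph = PhotophysicsParams(donor_bleach_mean=15.0, acceptor_bleach_mean=1e9,
                                background_level=7.0)
        path = StatePath(np.array([1]), np.array([0.0, 60.0]))
        tr = render_trace(path, em, ph, seed=2)
        k = int(tr.truth["t_donor_bleach"] / 0.1) + 1
        assert np.allclose(tr.donor[k:], 7.0, atol=1e-9)
        assert np.allclose(tr.acceptor[k:], 7.0, atol=1e-9)

    def test_noise_propagates_to_configured_fret_width(self, em_default):
        """Empirical per-frame FRET SD matches the delta-method prediction."""
        path = StatePath(np.array([1]), np.array([0.0, 2000.0]))
        tr = render_trace(path, em_default, NO_BLEACH, seed=11)
        ft = compute_fret(tr, em_default.crosstalk, em_default.gamma)
        predicted = em_default.fret_noise_sd(em_default.state_means[1])
        assert predicted == pytest.approx(0.055, abs=0.01)
        assert np.nanstd(ft.fret) == pytest.approx(predicted, rel=0.10)

    def test_bad_frame_interval_rejected(self, em_default):
        path = StatePath(np.array([0]), np.array([0.0, 1.0]))
        with pytest.raises(ValueError):
            render_trace(path, em_default, NO_BLEACH, frame_interval=0.0, seed=0)


class TestSimulateExperiment:
    def test_same_seed_is_bit_identical(self, kp_default):
        a = simulate_experiment(kp_default, n_movies=2, traces_per_movie=3, seed=9)
        b = simulate_experiment(kp_default, n_movies=2, traces_per_movie=3, seed=9)
        for x, y in zip(a.traces, b.traces):
            assert np.array_equal(x.donor, y.donor)
            assert np.array_equal(x.acceptor, y.acceptor)

    def test_counts_and_movie_ids(self, kp_default):
        ts = simulate_experiment(kp_default, n_movies=5, traces_per_movie=12, seed=2)
        assert len(ts) == 60
        assert ts.movie_ids == [1, 2, 3, 4, 5]

    def test_concentration_contrast_spans_state_means(self, em_default):
        """0 vs saturating ligand shifts mean FRET by ≈ high − low state mean."""
        means = []
        for conc in (0.0, 1000.0):
            ts = simulate_experiment(KineticParams(conc=conc), em_default, NO_BLEACH,
                                     n_movies=1, traces_per_movie=15, duration=30,
                                     seed=4)
            vals = [np.nanmean(compute_fret(t).fret) for t in ts.traces]
            means.append(np.mean(vals))
        expect = em_default.state_means[0] - em_default.state_means[2]
        assert means[0] - means[1] == pytest.approx(expect, abs=0.02)

    def test_tsv_round_trip(self, tmp_path, kp_default):
        ts = simulate_experiment(kp_default, n_movies=2, traces_per_movie=2,
                                 duration=5.0, seed=13)
        write_traceset(ts, tmp_path / "run")
        back = read_traceset(tmp_path / "run")
        assert len(back) == len(ts)
        orig = {t.trace_id: t for t in ts.traces}
        for t in back.traces:
            assert np.allclose(t.donor, orig[t.trace_id].donor, atol=1e-5)
            assert t.movie_id == orig[t.trace_id].movie_id
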