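import dataclasses

import numpy as np
import pytest
from scipy import stats

from nanoswitch._types import BOUND, UNBOUND
from nanoswitch.errors import InputError
from nanoswitch.kinetics import (
    Injection,
    KineticParams,
    SampleSchedule,
    drift_factor,
    generate_experiment,
    preset_schedule,
    render_trajectory,
    simulate_state_sequence,
)


class TestKineticParams:
    def test_defaults_valid(self, params):
        assert params.k_off_sw == 0.1
        assert params.R_bound < params.R_free

    @pytest.mark.parametrize("field,value", [
        ("k_off_sw", -0.1), ("EC50_kin", 0.0), ("frame_rate", 0.0),
        ("R_bound", 0.5), ("D_bound", 1.0), ("sigma_loc", -1e-3),
    ])
    def test_invalid_rejected(self, params, field, value):
        with pytest.raises(InputError):
            dataclasses.replace(params, **{field: value})

    def test_lambda_on_saturates(self, params):
        lam_inf = params.lambda_bg + params.lambda_max
        assert params.lambda_on(0) == params.lambda_bg
        assert params.lambda_on(params.EC50_kin) == pytest.approx(
            params.lambda_bg + params.lambda_max / 2)
        assert params.lambda_on(1e9) == pytest.approx(lam_inf, rel=1e-5)


class TestSimulateStateSequence:
    def test_zero_rate_single_unbound_interval(self, params):
        p = dataclasses.replace(params, lambda_bg=0.0)
        seq = simulate_state_sequence(p, 0.0, 500.0, seed=0)
        assert seq.n_intervals == 1
        assert seq.states[0] == UNBOUND
        assert seq.duration == pytest.approx(500.0)
        assert len(seq.utb_times()) == 0

    def test_negative_inputs_rejected(self, params):
        with pytest.raises(InputError):
            simulate_state_sequence(params, -1.0, 10.0, seed=0)
        with pytest.raises(InputError):
            simulate_state_sequence(params, 10.0, -5.0, seed=0)

    def test_mean_bound_dwell_is_inverse_koff(self, params):
        # mean of Exp(k) is 1/k; >= 1e4 uncensored dwells
        seq = simulate_state_sequence(params, 4000.0, 6.0e5, seed=1)
        dwells = seq.dwell_times(BOUND)
        assert len(dwells) >= 10_000
        se = dwells.std(ddof=1) / np.sqrt(len(dwells))
        assert abs(dwells.mean() - 10.0) < 3 * se

    def test_dwells_exponential_ks(self, params):
        seq = simulate_state_sequence(params, 4000.0, 6.0e5, seed=2)
        for state, rate in [(BOUND, params.k_off_sw),
                            (UNBOUND, params.lambda_on(4000.0))]:
            dwells = seq.dwell_times(state)
            assert len(dwells) >= 10_000
            p = stats.kstest(dwells, "expon", args=(0, 1.0 / rate)).pvalue
            assert p > 0.01

    def test_long_run_utb_rate_matches_stationary_form(self):
        # oracle: renewal theory.  rate = lam*k/(lam+k); count variance over
        # horizon T is T * sigma_cycle^2 / mu_cycle^3
        p = KineticParams(lambda_max=0.05, EC50_kin=1000.0, lambda_bg=0.0,
                          k_off_sw=0.1)
        lam = p.lambda_on(1000.0)
        assert lam == pytest.approx(0.025)
        T = 1e5
        seq = simulate_state_sequence(p, 1000.0, T, seed=3)
        n_events = len(seq.utb_times())
        rate = lam * p.k_off_sw / (lam + p.k_off_sw)
        mu_c = 1 / lam + 1 / p.k_off_sw
        var_c = 1 / lam**2 + 1 / p.k_off_sw**2
        se = np.sqrt(T * var_c / mu_c**3)
        assert abs(n_events - rate * T) < 3 * se

    def test_stationary_bound_fraction(self, params):
        seq = simulate_state_sequence(params, 1000.0, 3.0e5, seed=4)
        expect = params.bound_fraction(1000.0)
        durations = seq.t_end - seq.t_start
        is_bound = seq.states == BOUND
        # block bootstrap over dwell cycles for the SE of the time fraction
        rng = np.random.default_rng(0)
        n = seq.n_intervals
        boot = []
        for _ in range(200):
            idx = rng.integers(0, n, n)
            boot.append(durations[idx][is_bound[idx]].sum()
                        / durations[idx].sum())
        se = np.std(boot, ddof=1)
        assert abs(seq.bound_fraction() - expect) < 3 * se

    def test_seed_reproducibility(self, params):
        a = simulate_state_sequence(params, 500.0, 1e4, seed=7)
        b = simulate_state_sequence(params, 500.0, 1e4, seed=7)
        assert np.array_equal(a.t_start, b.t_start)
        assert np.array_equal(a.t_end, b.t_end)
        assert list(a.states) == list(b.states)


class TestRenderTrajectory:
    def test_bound_confinement_without_noise(self, params):
        p = dataclasses.replace(params, sigma_loc=0.0)
        seq = simulate_state_sequence(
            dataclasses.replace(p, lambda_bg=1e9, lambda_max=0.0, k_off_sw=0.0),
            0.0, 60.0, seed=0)
        assert all(s == BOUND for s in seq.states)
        traj = render_trajectory(seq, p, seed=1)
        r = np.hypot(traj.x_um, traj.y_um)
        assert np.all(r <= p.R_bound + 1e-12)

    def test_free_diffusion_msd(self):
        # closed form MSD = 4 D dt for unconfined Brownian motion
        p = KineticParams(D_free=0.3, R_free=1e6, R_bound=1.0, sigma_loc=0.0,
                          lambda_bg=0.0)
        seq = simulate_state_sequence(p, 0.0, 4000.0, seed=0)  # all unbound
        traj = render_trajectory(seq, p, seed=2)
        sq = np.diff(traj.x_um) ** 2 + np.diff(traj.y_um) ** 2
        assert len(sq) >= 100_000
        dt = 1.0 / p.frame_rate
        d_hat = sq / (4 * dt)
        se = d_hat.std(ddof=1) / np.sqrt(len(d_hat))
        assert abs(d_hat.mean() - 0.3) < 3 * se

    def test_pure_localization_noise_variance(self):
        # frozen particle: displacement variance per axis = 2 sigma^2
        p = KineticParams(D_free=0.0, D_bound=0.0, sigma_loc=0.02,
                          lambda_bg=0.0)
        seq = simulate_state_sequence(p, 0.0, 2000.0, seed=0)
        traj = render_trajectory(seq, p, seed=3)
        dx = np.diff(traj.x_um)
        se = np.sqrt(2.0 / (len(dx) - 1)) * dx.var(ddof=1)
        assert abs(dx.var(ddof=1) - 2 * 0.02**2) < 3 * se

    def test_seed_reproducibility(self, params):
        seq = simulate_state_sequence(params, 500.0, 30.0, seed=5)
        a = render_trajectory(seq, params, seed=6)
        b = render_trajectory(seq, params, seed=6)
        assert np.array_equal(a.x_um, b.x_um) and np.array_equal(a.y_um, b.y_um)


class TestGenerateExperiment:
    def test_blank_schedule_zero_counts(self, params):
        p = dataclasses.replace(params, lambda_bg=0.0)
        sched = SampleSchedule(
            [Injection(0.0, "blank", n_measure_intervals=5)] * 3,
            drift_rate=0.0)
        exp = generate_experiment(sched, p, 1000, mode="counts", seed=0)
        assert (exp.records["counts"] == 0).all()

    def test_unknown_mode_rejected(self, params):
        sched = SampleSchedule([Injection(100.0, "blind")])
        with pytest.raises(InputError):
            generate_experiment(sched, params, 10, mode="video", seed=0)

    def test_poisson_dispersion_index(self, params):
        # brute-force resampling null: DI quantiles of true Poisson samples
        sched = SampleSchedule(
            [Injection(250.0, "blind", n_measure_intervals=100)],
            drift_rate=0.0)
        exp = generate_experiment(sched, params, 4000, mode="counts", seed=11)
        counts = exp.records["counts"].to_numpy()
        di = counts.var(ddof=1) / counts.mean()
        rng = np.random.default_rng(0)
        mean = 4000 * params.utb_rate(250.0) * 60.0
        null = rng.poisson(mean, size=(4000, 100))
        null_di = null.var(axis=1, ddof=1) / null.mean(axis=1)
        lo, hi = np.quantile(null_di, [0.025, 0.975])
        assert lo < di < hi

    def test_drift_count_ratio_over_nine_hours(self, params):
        assert drift_factor(9.0, 0.05) == pytest.approx(0.95**9)
        assert 0.95**9 == pytest.approx(0.630, abs=5e-3)
        sched = SampleSchedule(
            [Injection(500.0, "blind", flow_duration_min=0.0,
                       n_measure_intervals=1),
             Injection(500.0, "blind", flow_duration_min=539.0,
                       n_measure_intervals=1)],
            drift_rate=0.05)
        exp = generate_experiment(sched, params, 2_000_000, mode="counts",
                                  seed=12)
        c0, c9 = exp.records["counts"].to_numpy()
        assert c9 / c0 == pytest.approx(0.95**9, rel=0.01)

    def test_counts_reproducible(self, params):
        sched = preset_schedule("figure3_series")
        a = generate_experiment(sched, params, 400, mode="counts", seed=3)
        b = generate_experiment(sched, params, 400, mode="counts", seed=3)
        assert a.records.equals(b.records)

    def test_trajectories_mode_carries_ground_truth(self, params):
        sched = SampleSchedule(
            [Injection(1000.0, "blind", n_measure_intervals=2)],
            drift_rate=0.0)
        exp = generate_experiment(sched, params, 3, mode="trajectories", seed=4)
        assert len(exp.trajectories) == 3
        assert len(exp.gt_states) == 3
        # the records' counts equal the event log histogrammed on the edges
        edges = exp.interval_edges_s
        total = sum(
            np.histogram(seq.utb_times(), bins=edges)[0].sum()
            for seq in exp.gt_states)
        assert exp.records["counts"].sum() == total

    def test_counts_vs_trajectories_mean_activity(self, params):
        # cross-fidelity: the two modes agree on mean activity within 10%
        sched = SampleSchedule(
            [Injection(1000.0, "blind", n_measure_intervals=5)],
            drift_rate=0.0)
        exp = generate_experiment(sched, params, 100, mode="trajectories",
                                  seed=5)
        gt_activity = exp.records["counts"].sum() / 100 / 5
        expect = params.utb_rate(1000.0) * 60.0
        assert gt_activity == pytest.approx(expect, rel=0.10)


class TestPresets:
    def test_figure3_series(self):
        sched = preset_schedule("figure3_series")
        concs = sorted({inj.concentration_pM for inj in sched.injections})
        assert concs == [0.0, 31.3, 62.5, 125.0, 250.0, 500.0, 1000.0]
        top = [i for i in sched.injections if i.concentration_pM == 1000.0]
        assert len(top) == 5  # five repeated series
        assert all(i.flow_duration_min == 1.0 for i in sched.injections)
        assert all(i.n_measure_intervals == 10 for i in sched.injections)
        assert 7.5 * 60 <= sched.total_duration_min <= 10 * 60
        # per-series sweep is ascending in concentration
        per_series = [i.concentration_pM for i in sched.injections[:7]]
        assert per_series == sorted(per_series)

    def test_figure4_milk(self):
        sched = preset_schedule("figure4_milk")
        norm = {i.concentration_pM for i in sched.injections
                if i.role == "norm_reference"}
        assert norm == {125.0, 506.0}
        assert all(i.flow_duration_min == 3.5 for i in sched.injections)
        assert all(i.n_measure_intervals == 8 for i in sched.injections)

    def test_figure5_blind(self):
        sched = preset_schedule("figure5_blind")
        roles = {i.role for i in sched.injections}
        assert roles == {"calibrant", "norm_reference", "blind", "blank"}
        cal = [i for i in sched.injections if i.role == "calibrant"]
        assert len({i.concentration_pM for i in cal}) == 5

    @pytest.mark.parametrize("name", ["figure3_series", "figure4_milk",
                                      "figure5_blind"])
    def test_presets_satisfy_invariants(self, name):
        sched = preset_schedule(name)  # constructor validates invariants
        assert 0 <= sched.drift_rate < 1
        assert all(i.concentration_pM >= 0 for i in sched.injections)

    def test_unknown_preset(self):
        with pytest.raises(InputError):
            preset_schedule("figure9_nope")
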