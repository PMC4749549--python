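"""Tests of the synthetic-data generator against closed forms and its
own stated invariants."""

import numpy as np
import pandas as pd
import pytest

from caldrift.config import ENVIRONMENTS, InvalidConfigError, SimConfig
from caldrift.decoders import AcrossEnvTimeDecoder, build_activity_vectors
from caldrift.synthetic import (build_ensemble_model, calcium_kernel,
                                generate_dataset, render_fluorescence,
                                render_footprints, simulate_events,
                                simulate_trajectory)


def tiny_config(**kw):
    base = dict(n_cells=10, day_values=(1, 3), trials_per_session=2,
                trial_duration=60.0, seed=0)
    base.update(kw)
    return SimConfig(**base)


# ---------------------------------------------------------------------------
# trajectory
# ---------------------------------------------------------------------------

class TestTrajectory:
    def test_constant_speed_lap_count(self):
        # 20 cm/s for 180 s on a 96 cm track: floor(3600/96) = 37 turns
        cfg = SimConfig(n_cells=2, day_values=(1,), trials_per_session=1,
                        pause_mean=0.0, run_speed=20.0, seed=0)
        traj = simulate_trajectory(cfg)[("A", 1, 1)]
        flips = np.sum(np.diff(np.sign(traj.velocity)) != 0)
        assert flips == 37

    def test_position_bounds_and_occupancy_conservation(self):
        cfg = tiny_config(pause_mean=2.0)
        trajs = simulate_trajectory(cfg)
        for traj in trajs.values():
            assert traj.position.min() >= 0.0
            assert traj.position.max() <= cfg.track_length
            # summed occupancy equals the trial duration
            assert len(traj.position) / cfg.frame_rate == cfg.trial_duration
            # speed bound: |dx| <= v_max * dt
            assert np.all(np.abs(np.diff(traj.position))
                          <= cfg.run_speed / cfg.frame_rate + 1e-9)

    def test_stationary_dwell_epochs_present(self):
        cfg = tiny_config(pause_mean=2.0)
        traj = simulate_trajectory(cfg)[("A", 1, 1)]
        assert np.sum(traj.velocity == 0.0) > 0

    def test_invalid_config_rejected(self):
        with pytest.raises(InvalidConfigError):
            SimConfig(trial_duration=-1.0).validate()
        with pytest.raises(InvalidConfigError):
            SimConfig(frame_rate=0.0).validate()


# ---------------------------------------------------------------------------
# ensemble model
# ---------------------------------------------------------------------------

class TestEnsembleModel:
    def test_zero_place_fraction_all_flat(self):
        model = build_ensemble_model(tiny_config(place_cell_fraction=0.0))
        gain = model.tuning("A", np.linspace(0, 96, 50))
        assert np.allclose(gain, 1.0)

    def test_no_drift_limit_rates_constant(self):
        cfg = tiny_config(day_values=(1, 3, 5, 7), shared_drift_sigma=0.0,
                          env_drift_sigma=0.0, recruitment_persistence=1.0,
                          active_fraction=1.0)
        model = build_ensemble_model(cfg)
        for k in range(1, cfg.n_days):
            assert np.array_equal(model.rate(k, "A"), model.rate(0, "A"))

    def test_field_centers_constant_across_days_and_remap(self):
        model = build_ensemble_model(tiny_config(remap_mode=True,
                                                 place_cell_fraction=1.0,
                                                 n_cells=50))
        # remap: environments get independent centers
        assert not np.allclose(model.field_center[:, 0], model.field_center[:, 1])
        same = build_ensemble_model(tiny_config(remap_mode=False,
                                                place_cell_fraction=1.0,
                                                n_cells=50))
        assert np.allclose(same.field_center[:, 0], same.field_center[:, 1])

    def test_markov_chain_matches_closed_form(self):
        # P(active at d+k | active at d) = pi + (1-pi) * (p11 - p01)^k
        cfg = SimConfig(n_cells=2000, seed=7)
        model = build_ensemble_model(cfg)
        p11, pi = cfg.recruitment_persistence, cfg.active_fraction
        p01 = pi * (1 - p11) / (1 - pi)
        lam = p11 - p01
        act = model.active[:, 0, :]  # env A
        for k in (1, 3, 7):
            num = den = 0
            for d in range(cfg.n_days - k):
                num += np.sum(act[d] & act[d + k])
                den += np.sum(act[d])
            obs = num / den
            pred = pi + (1 - pi) * lam ** k
            se = np.sqrt(pred * (1 - pred) / den)
            assert abs(obs - pred) < 3 * se


# ---------------------------------------------------------------------------
# events
# ---------------------------------------------------------------------------

class TestSimulateEvents:
    def test_zero_rate_empty_table(self):
        cfg = tiny_config(base_rate=1e-12, rate_spread=0.0)
        ds = generate_dataset(cfg)
        assert len(ds.events) == 0

    def test_homogeneous_poisson_count_within_99_interval(self):
        # lambda = 0.1 ev/s, active always, flat tuning, 120 s x 2 trials
        from scipy.stats import poisson
        cfg = tiny_config(n_cells=50, base_rate=0.1, rate_spread=0.0,
                          place_cell_fraction=0.0, shared_drift_sigma=0.0,
                          env_drift_sigma=0.0, env_gain_sigma=0.0,
                          recruitment_persistence=1.0,
                          active_fraction=1.0, seed=3)
        ds = generate_dataset(cfg)
        # per cell-session expectation: 0.1 * 120 s = 12 events
        counts = (ds.events.groupby(["env", "day", "cell_id"]).size()
                  .reindex(pd.MultiIndex.from_product(
                      [list(ENVIRONMENTS), [1, 3], range(50)]), fill_value=0))
        lo, hi = poisson.ppf([0.005, 0.995], 12.0)
        frac_inside = np.mean((counts >= lo) & (counts <= hi))
        assert frac_inside > 0.95

    def test_place_cell_events_concentrate_in_field(self):
        cfg = tiny_config(n_cells=30, place_cell_fraction=1.0,
                          field_width=10.0, base_rate=0.2, pause_mean=0.0,
                          seed=4)
        ds = generate_dataset(cfg)
        model = ds.model
        ev = ds.events[(ds.events["env"] == "A")
                       & (ds.events["velocity_cm_s"].abs() > 1.0)]
        inside = 0
        for cid, grp in ev.groupby("cell_id"):
            c = model.field_center[cid, 0]
            inside += np.sum(np.abs(grp["position_cm"] - c) <= cfg.field_width)
        assert inside / len(ev) >= 0.8

    def test_mismatched_sessions_error(self):
        cfg = tiny_config()
        model = build_ensemble_model(cfg)
        trajs = simulate_trajectory(cfg)
        trajs.pop(("B", 3, 2))
        with pytest.raises(ValueError, match="trajectory set"):
            simulate_events(model, trajs)


# ---------------------------------------------------------------------------
# fluorescence forward model
# ---------------------------------------------------------------------------

class TestRenderFluorescence:
    def test_zero_events_zero_trace(self):
        cfg = tiny_config(noise_sigma=0.0)
        empty = pd.DataFrame(columns=["cell_id", "env", "day", "trial",
                                      "time_s", "amplitude", "position_cm",
                                      "velocity_cm_s"])
        ts = render_fluorescence(empty, cfg)
        assert all(np.all(arr == 0.0) for arr in ts.traces.values())

    def test_single_event_peak_matches_analytic(self):
        cfg = tiny_config(noise_sigma=0.0)
        ev = pd.DataFrame([{"cell_id": 0, "env": "A", "day": 1, "trial": 1,
                            "time_s": 10.0, "amplitude": 1.0,
                            "position_cm": 0.0, "velocity_cm_s": 0.0}])
        ts = render_fluorescence(ev, cfg)
        # kernel is normalized to unit peak, so the trace max is the amplitude
        assert ts.traces[("A", 1)][0].max() == pytest.approx(1.0, rel=0.01)

    def test_superposition(self):
        cfg = tiny_config(noise_sigma=0.0)
        mk = lambda t, a: {"cell_id": 0, "env": "A", "day": 1, "trial": 1,
                           "time_s": t, "amplitude": a, "position_cm": 0.0,
                           "velocity_cm_s": 0.0}
        e1 = pd.DataFrame([mk(5.0, 0.7)])
        e2 = pd.DataFrame([mk(20.0, 1.3)])
        both = pd.concat([e1, e2], ignore_index=True)
        t1 = render_fluorescence(e1, cfg).traces[("A", 1)]
        t2 = render_fluorescence(e2, cfg).traces[("A", 1)]
        tb = render_fluorescence(both, cfg).traces[("A", 1)]
        assert np.allclose(tb, t1 + t2, atol=1e-12)

    def test_kernel_requires_valid_time_constants(self):
        with pytest.raises(InvalidConfigError):
            calcium_kernel(tiny_config(kernel_rise=1.0, kernel_decay=0.5))


# ---------------------------------------------------------------------------
# footprints
# ---------------------------------------------------------------------------

class TestFootprints:
    def test_zero_jitter_identical_across_sessions(self):
        cfg = tiny_config(n_cells=15, footprint_jitter=0.0,
                          recruitment_persistence=1.0, active_fraction=1.0)
        model = build_ensemble_model(cfg)
        fps = render_footprints(model, cfg)
        keys = list(fps.sessions)
        a = {r.cell_id: (r.patch, r.offset) for r in fps.sessions[keys[0]]}
        b = {r.cell_id: (r.patch, r.offset) for r in fps.sessions[keys[1]]}
        for cid in a:
            assert a[cid][1] == b[cid][1]
            assert np.array_equal(a[cid][0], b[cid][0])

    def test_jittered_centroids_close_to_truth(self):
        # 2D Gaussian jitter of 2 µm/axis: P(|r| < 5 µm) = 1-exp(-25/8) ≈ 0.956
        cfg = SimConfig(n_cells=200, day_values=(1,), footprint_jitter=2.0,
                        active_fraction=1.0, seed=9)
        model = build_ensemble_model(cfg)
        fps = render_footprints(model, cfg)
        recs = fps.sessions[("A", 1)]
        d = np.array([np.linalg.norm(r.centroid_um - fps.true_centroids_um[r.cell_id])
                      for r in recs])
        assert np.mean(d < 5.0) >= 0.90  # binomial slack below the 0.956 mean

    def test_min_separation_respected(self):
        cfg = tiny_config(n_cells=40, min_separation=20.0)
        model = build_ensemble_model(cfg)
        fps = render_footprints(model, cfg)
        c = fps.true_centroids_um
        d = np.linalg.norm(c[:, None] - c[None, :], axis=2)
        np.fill_diagonal(d, np.inf)
        assert d.min() >= 20.0


# ---------------------------------------------------------------------------
# end-to-end dataset
# ---------------------------------------------------------------------------

class TestGenerateDataset:
    def test_fixed_seed_bit_identical(self):
        cfg = tiny_config(seed=42)
        a = generate_dataset(cfg)
        b = generate_dataset(cfg)
        pd.testing.assert_frame_equal(a.events, b.events)
        assert np.array_equal(a.model.eta_shared, b.model.eta_shared)

    def test_session_bookkeeping(self, default_dataset):
        cfg = default_dataset.config
        ev = default_dataset.events
        # 8 days x 2 envs, trials 1..5, times within the trial
        assert set(ev["day"]) == set(cfg.day_values)
        assert set(ev["env"]) == {"A", "B"}
        assert ev["trial"].between(1, cfg.trials_per_session).all()
        assert ((ev["time_s"] >= 0) & (ev["time_s"] < cfg.trial_duration)).all()
        assert ev["cell_id"].between(0, cfg.n_cells - 1).all()
        n_trials = ev.groupby(["env", "day"])["trial"].nunique()
        assert (n_trials <= cfg.trials_per_session).all()

    def test_shared_drift_creates_cross_env_day_signal(self):
        # shared walk only: same-day across-env correlation > 14-day-apart
        same, far = [], []
        for seed in range(10):
            cfg = SimConfig(n_cells=120, shared_drift_sigma=0.25,
                            env_drift_sigma=0.0, seed=300 + seed)
            ds = generate_dataset(cfg)
            av = {e: build_activity_vectors(
                ds.events, e, list(cfg.day_values),
                cfg.trials_per_session, list(range(cfg.n_cells)))
                for e in ENVIRONMENTS}
            sa, sb = av["A"].sessions, av["B"].sessions
            same.append(np.mean([np.corrcoef(sa[d], sb[d])[0, 1]
                                 for d in range(8)]))
            far.append(np.corrcoef(sa[0], sb[7])[0, 1] / 2
                       + np.corrcoef(sa[7], sb[0])[0, 1] / 2)
        assert np.mean(same) > np.mean(far)
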