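"""Time-decoder tests: activity-vector construction, the ordinal decoder
against a brute-force enumeration oracle, the within/across-environment
decoders with their normalization and exclusion rules, and the shuffle
controls."""

from itertools import permutations

import numpy as np
import pandas as pd
import pytest

from caldrift.config import SimConfig
from caldrift.decoders import (AcrossEnvTimeDecoder, OrdinalTimeDecoder,
                               WithinEnvTimeDecoder, build_activity_vectors,
                               ordering_classes, segment_vectors,
                               shuffle_day_labels)
from caldrift.synthetic import generate_dataset


def brute_force_ordering(corr):
    """Oracle: maximize the mean neighbor correlation over ALL orderings."""
    n = corr.shape[0]
    best, best_obj = None, -np.inf
    for p in permutations(range(n)):
        obj = np.mean([corr[p[j], p[j + 1]] for j in range(n - 1)])
        if obj > best_obj + 1e-12:
            best, best_obj = p, obj
    return best, best_obj


@pytest.fixture(scope="module")
def default_vectors(default_dataset, default_cells):
    cfg = default_dataset.config
    return {env: build_activity_vectors(
        default_dataset.events, env, list(cfg.day_values),
        cfg.trials_per_session, default_cells) for env in ("A", "B")}


class TestBuildActivityVectors:
    def test_session_equals_sum_of_trials(self, default_vectors):
        av = default_vectors["A"]
        assert np.array_equal(av.sessions, av.trials.sum(axis=1))

    def test_vector_length_is_master_count(self, default_vectors,
                                           default_cells):
        av = default_vectors["A"]
        assert av.trials.shape[2] == len(default_cells)

    def test_run_stationary_partition_bounded_by_total(self, default_dataset,
                                                       default_cells):
        cfg = default_dataset.config
        kw = dict(days=list(cfg.day_values), n_trials=cfg.trials_per_session,
                  master_cells=default_cells, track_length=cfg.track_length)
        full = build_activity_vectors(default_dataset.events, "A", **kw)
        run = build_activity_vectors(default_dataset.events, "A", epoch="run",
                                     **kw)
        stat = build_activity_vectors(default_dataset.events, "A",
                                      epoch="stationary", **kw)
        total = run.trials + stat.trials
        assert np.all(total <= full.trials)
        assert run.trials.sum() > 0 and stat.trials.sum() > 0
        # end-zone running events are excluded from the run subset
        assert total.sum() < full.trials.sum()

    def test_unregistered_cell_error(self, default_dataset, default_cells):
        cfg = default_dataset.config
        mm = {(env, d): {} for env in ("A", "B") for d in cfg.day_values}
        with pytest.raises(ValueError, match="unregistered"):
            build_activity_vectors(default_dataset.events, "A",
                                   list(cfg.day_values),
                                   cfg.trials_per_session, default_cells,
                                   master_map=mm)

    def test_time_window_restriction(self, default_dataset, default_cells):
        cfg = default_dataset.config
        kw = dict(days=list(cfg.day_values), n_trials=cfg.trials_per_session,
                  master_cells=default_cells)
        half = build_activity_vectors(default_dataset.events, "A",
                                      time_window=(0.0, 90.0), **kw)
        full = build_activity_vectors(default_dataset.events, "A", **kw)
        assert half.trials.sum() < full.trials.sum()
        assert np.all(half.trials <= full.trials)


class TestOrdinalDecoder:
    def test_number_of_ordering_classes(self):
        assert len(ordering_classes(8)) == 20160  # 8!/2
        assert len(ordering_classes(4)) == 12

    def test_three_day_toy_matrix(self):
        # hand-checkable instance: ordering (1,2,3) wins with (0.9+0.5)/2
        corr = np.array([[1.0, 0.9, 0.2], [0.9, 1.0, 0.5], [0.2, 0.5, 1.0]])
        perms = ordering_classes(3)
        objs = corr[perms[:, :-1], perms[:, 1:]].mean(axis=1)
        assert len(perms) == 3
        best = perms[np.argmax(objs)]
        assert tuple(best) == (0, 1, 2)
        assert objs.max() == pytest.approx(0.7)

    @pytest.mark.parametrize("n_days", [3, 4, 5, 6])
    def test_matches_brute_force_oracle(self, n_days, rng):
        for _ in range(8):
            X = rng.standard_normal((n_days, 30))
            dec = OrdinalTimeDecoder().fit(X)
            oracle, oracle_obj = brute_force_ordering(np.corrcoef(X))
            assert dec.objective_ == pytest.approx(oracle_obj)
            assert dec.ordering_ in (oracle, oracle[::-1])

    def test_objective_invariant_under_reversal(self, rng):
        X = rng.standard_normal((6, 25))
        corr = np.corrcoef(X)
        perms = ordering_classes(6)
        rev = perms[:, ::-1]
        obj = corr[perms[:, :-1], perms[:, 1:]].mean(axis=1)
        obj_rev = corr[rev[:, :-1], rev[:, 1:]].mean(axis=1)
        assert np.allclose(obj, obj_rev)

    def test_toeplitz_decay_recovers_sorted_order(self, rng):
        # correlations strictly decreasing in |day gap|: construct vectors
        # from a slowly drifting latent so corr ~ rho^|i-j|
        latent = np.cumsum(rng.standard_normal((8, 500)), axis=0)
        dec = OrdinalTimeDecoder().fit(latent)
        assert dec.recovers_order_

    def test_unique_maximum_gives_minimum_p(self, rng):
        latent = np.cumsum(rng.standard_normal((8, 500)), axis=0)
        dec = OrdinalTimeDecoder().fit(latent)
        assert dec.p_value_ == pytest.approx(1.0 / 20160.0)
        assert dec.p_value_ <= 5e-5

    def test_both_environments_joint_objective(self, default_vectors):
        XA = default_vectors["A"].sessions
        XB = default_vectors["B"].sessions
        dec = OrdinalTimeDecoder().fit([XA, XB])
        assert dec.recovers_order_
        single = OrdinalTimeDecoder().fit(XA)
        ca, cb = np.corrcoef(XA), np.corrcoef(XB)
        ident = np.arange(8)
        expected = (ca[ident[:-1], ident[1:]].mean()
                    + cb[ident[:-1], ident[1:]].mean()) / 2
        assert dec.chronological_objective_ == pytest.approx(expected)
        assert single.chronological_objective_ == pytest.approx(
            ca[ident[:-1], ident[1:]].mean())


class TestWithinEnvDecoder:
    def test_dominant_correlation_day_inferred(self, rng):
        # trials of each day share a day-specific pattern, uncorrelated
        # across days: every trial decodes to its own day
        patterns = rng.uniform(0.0, 10.0, (8, 60))
        trials = np.stack([[patterns[d] + 0.01 * rng.standard_normal(60)
                            for _ in range(5)] for d in range(8)])
        dec = WithinEnvTimeDecoder().fit(trials)
        assert dec.predict().accuracy == 1.0

    def test_default_synthetic_high_accuracy(self, default_vectors):
        res = WithinEnvTimeDecoder().fit(default_vectors["A"].trials).predict()
        assert res.accuracy > 0.9

    def test_exclude_same_day_errors_concentrate_on_neighbors(self,
                                                              default_vectors):
        dec = WithinEnvTimeDecoder(exclude_same_day=True)
        res = dec.fit(default_vectors["A"].trials).predict()
        assert (res.results["error"] != 0).all()
        # modal |error| is one recording day
        mode = res.results["error"].abs().value_counts().idxmax()
        assert mode == 1
        assert res.neighbor_rate > 0.5

    def test_zero_variance_test_trial_skipped(self, rng):
        trials = rng.uniform(1.0, 5.0, (8, 5, 20))
        trials[2, 1] = 3.0  # constant vector: Pearson undefined
        res = WithinEnvTimeDecoder().fit(trials).predict()
        row = res.results[(res.results["true_day_index"] == 2)
                          & (res.results["trial"] == 2)]
        assert row["inferred_day_index"].isna().all()

    def test_label_shuffle_chance(self, default_vectors):
        # per-shuffle accuracies are over-dispersed relative to independent
        # trials (all 40 trials of a shuffle share its permutations), so the
        # mean is compared at its empirical standard error
        accs = []
        for env, seed in (("A", 0), ("B", 1)):
            for sh in shuffle_day_labels(default_vectors[env].trials, 20,
                                         seed=seed):
                dec = WithinEnvTimeDecoder().fit(sh)
                accs.append(dec.predict(default_vectors[env].trials).accuracy)
        accs = np.array(accs)
        se = accs.std(ddof=1) / np.sqrt(len(accs))
        assert abs(accs.mean() - 0.125) < 3 * se

    def test_segment_accuracy_monotone_in_duration(self, default_dataset,
                                                   default_cells,
                                                   default_vectors):
        cfg = default_dataset.config
        accs = []
        for tau in (1.0, 10.0, 60.0, 180.0):
            seg = segment_vectors(default_dataset.events, "A",
                                  list(cfg.day_values),
                                  cfg.trials_per_session, default_cells,
                                  tau, cfg.trial_duration, seed=0)
            dec = WithinEnvTimeDecoder().fit(default_vectors["A"].trials)
            accs.append(dec.predict(seg.trials).accuracy)
        assert all(a <= b + 1e-9 for a, b in zip(accs[:-1], accs[1:]))
        assert accs[-1] > accs[0]


class TestAcrossEnvDecoder:
    def test_identical_environments_perfect(self, default_vectors):
        av = default_vectors["A"]
        dec = AcrossEnvTimeDecoder(level="session").fit(av.sessions)
        assert dec.predict(av.sessions).accuracy == 1.0

    def test_trial_level_identical_environments_perfect(self, default_vectors):
        av = default_vectors["A"]
        dec = AcrossEnvTimeDecoder(level="trial").fit(av.trials)
        res = dec.predict(av.trials)
        assert res.accuracy > 0.9

    def test_above_chance_iff_shared_drift(self):
        n_seeds, n = 8, 150
        hits_on = hits_off = trials = 0
        for seed in range(n_seeds):
            for shared, env_sig in ((0.25, 0.12), (0.0, 0.2)):
                cfg = SimConfig(n_cells=n, shared_drift_sigma=shared,
                                env_drift_sigma=env_sig, seed=400 + seed)
                ds = generate_dataset(cfg)
                av = {e: build_activity_vectors(
                    ds.events, e, list(cfg.day_values),
                    cfg.trials_per_session, list(range(n)))
                    for e in ("A", "B")}
                dec = AcrossEnvTimeDecoder(level="session").fit(
                    av["B"].sessions)
                acc = dec.predict(av["A"].sessions).accuracy
                if shared > 0:
                    hits_on += acc * 8
                else:
                    hits_off += acc * 8
                trials += 8
        from scipy.stats import binomtest
        n_tests = n_seeds * 8
        # shared drift present: above chance at p < 0.01
        assert binomtest(int(round(hits_on)), n_tests, 0.125,
                         alternative="greater").pvalue < 0.01
        # no shared component: within binomial noise of 12.5%
        assert binomtest(int(round(hits_off)), n_tests, 0.125).pvalue > 0.01

    def test_exclude_same_day_removes_candidate(self, default_vectors):
        dec = AcrossEnvTimeDecoder(level="session", exclude_same_day=True)
        dec.fit(default_vectors["B"].sessions)
        res = dec.predict(default_vectors["A"].sessions)
        assert (res.results["error"].dropna() != 0).all()


class TestShuffleDayLabels:
    def test_per_cell_multiset_preserved(self, default_vectors):
        X = default_vectors["A"].trials
        sh = shuffle_day_labels(X, 3, seed=1)
        for s in sh:
            for c in range(0, X.shape[2], 17):
                orig = np.sort(X[:, :, c].sum(axis=1))
                new = np.sort(s[:, :, c].sum(axis=1))
                assert np.array_equal(orig, new)

    def test_total_events_conserved(self, default_vectors):
        X = default_vectors["A"].trials
        for s in shuffle_day_labels(X, 3, seed=2):
            assert s.sum() == X.sum()

    def test_shuffling_destroys_ordinal_structure(self, default_vectors):
        X = default_vectors["A"].sessions
        orig = OrdinalTimeDecoder().fit(X).chronological_objective_
        wins = 0
        for s in shuffle_day_labels(default_vectors["A"].trials, 10, seed=3):
            sh_obj = OrdinalTimeDecoder().fit(s.sum(axis=1)
                                              ).chronological_objective_
            wins += int(sh_obj < orig)
        assert wins >= 9

    def test_accuracy_monotone_in_shared_drift(self):
        # 3-point sweep of the shared walk at fixed noise, averaged seeds
        means = []
        for sigma in (0.05, 0.15, 0.3):
            accs = []
            for seed in range(6):
                cfg = SimConfig(n_cells=120, shared_drift_sigma=sigma,
                                env_drift_sigma=0.0, seed=500 + seed)
                ds = generate_dataset(cfg)
                av = build_activity_vectors(ds.events, "A",
                                            list(cfg.day_values),
                                            cfg.trials_per_session,
                                            list(range(120)))
                dec = AcrossEnvTimeDecoder(level="session").fit(
                    build_activity_vectors(ds.events, "B",
                                           list(cfg.day_values),
                                           cfg.trials_per_session,
                                           list(range(120))).sessions)
                accs.append(dec.predict(av.sessions).accuracy)
            means.append(np.mean(accs))
        assert means[0] <= means[1] <= means[2]
        assert means[2] > means[0]
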