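"""Kinetic Zimm-Bragg generator: determinism, constraints, recovery, balance."""

import numpy as np
import pytest

from helixtraj import (
    HelixKineticsParams,
    RunEnsemble,
    decorate_states,
    enumerate_boltzmann,
    make_paperlike_ensemble,
    recover_parameters,
    simulate_states,
    simulate_trajectory,
    summarize_runs,
    triad_stats,
    unfolding_time,
)


def quick_params(**kw):
    kw.setdefault("n_frames", 200)
    return HelixKineticsParams(**kw)


class TestDeterminism:
    def test_same_seed_same_trajectory(self):
        a = simulate_trajectory(quick_params(), seed=5)
        b = simulate_trajectory(quick_params(), seed=5)
        assert (a.labels == b.labels).all()

    def test_different_seeds_differ(self):
        a = simulate_trajectory(quick_params(), seed=5)
        b = simulate_trajectory(quick_params(), seed=6)
        assert (a.labels != b.labels).any()

    def test_ensemble_reproducible(self):
        p = quick_params(n_frames=50)
        e1 = make_paperlike_ensemble(4, p, seed=9)
        e2 = make_paperlike_ensemble(4, p, seed=9)
        assert len(e1) == 4
        for m1, m2 in zip(e1.members, e2.members):
            assert (m1.labels == m2.labels).all()


class TestConstraints:
    def test_min_run_preserved_in_states(self):
        p = quick_params(n_frames=500, min_run=4)
        states = simulate_states(p, "all-helix", rng=3)
        for row in states:
            run = 0
            for x in row:
                if x:
                    run += 1
                else:
                    assert run == 0 or run >= 4
                    run = 0
            assert run == 0 or run >= 4

    def test_no_triad_anomalies_with_min_run_4(self):
        ens = make_paperlike_ensemble(5, quick_params(n_frames=400), seed=11)
        assert triad_stats(ens).anomaly_count == 0

    def test_invalid_initial_state_rejected(self):
        p = quick_params(min_run=4)
        bad = np.zeros(20, dtype=bool)
        bad[3:5] = True  # 2-residue run
        with pytest.raises(ValueError, match="min_run"):
            simulate_states(p, bad, rng=0)

    def test_strong_propensity_never_unfolds(self):
        p = quick_params(n_frames=300, s=np.full(20, 50.0))
        traj = simulate_trajectory(p, "all-helix", seed=2)
        assert unfolding_time(traj) is None
        assert (traj.labels == "H").mean() > 0.99


class TestEmission:
    def test_neutral_model_occupancy_half(self):
        # s=1, sigma=1: every flip is accepted, stationary occupancy 1/2
        p = HelixKineticsParams(n_frames=10_000, s=np.ones(20), sigma=1.0,
                                min_run=1, p_decorate_G=0.0, p_decorate_T=0.0)
        states = simulate_states(p, "all-coil", rng=4)
        occ = states[200:].mean(axis=0)  # short burn-in
        se = 0.5 / np.sqrt(len(states) - 200)
        # correlated samples: allow a generous multiple of the iid error
        assert np.all(np.abs(occ - 0.5) < 12 * se)

    def test_boundary_decoration_labels(self):
        states = np.array([[False, True, True, True, True, False, False]])
        p = HelixKineticsParams(n_residues=7, n_frames=1, s=np.ones(7),
                                p_decorate_G=1.0, p_decorate_T=0.0)
        labels = decorate_states(states, p, rng=0)
        assert "".join(labels[0]) == "GHHHHGO"

    def test_interior_coil_is_O(self):
        states = np.zeros((3, 8), dtype=bool)
        p = HelixKineticsParams(n_residues=8, n_frames=3, s=np.ones(8))
        labels = decorate_states(states, p, rng=0)
        assert (labels == "O").all()


class TestRecovery:
    def test_c_destabilized_direction(self):
        ens = make_paperlike_ensemble(50, seed=1234)
        rec = recover_parameters(ens)
        assert rec.p_hh[18] < rec.p_hh[1]  # residue 19 flickers more than 2
        _, stats = summarize_runs(ens)
        assert stats.count_first("C") > stats.count_first("N")

    def test_uniform_model_flat_retention(self):
        p = HelixKineticsParams(n_frames=3000, s=np.ones(20), sigma=1.0,
                                min_run=1, p_decorate_G=0.0, p_decorate_T=0.0)
        ens = make_paperlike_ensemble(4, p, seed=77)
        rec = recover_parameters(ens)
        pooled = np.nansum(rec.p_hh * rec.n_h_sources) / rec.n_h_sources.sum()
        assert np.all(np.abs(rec.p_hh - pooled) <= 3 * rec.p_hh_se)

    def test_decoration_probabilities_recovered(self):
        p = quick_params(n_frames=1500, p_decorate_G=0.2, p_decorate_T=0.5)
        ens = make_paperlike_ensemble(4, p, seed=21)
        rec = recover_parameters(ens)
        se_g = np.sqrt(0.2 * 0.8 / rec.n_boundary)
        assert abs(rec.p_decorate_G_hat - 0.2) <= 3 * se_g
        se_t = np.sqrt(0.5 * 0.5 / (rec.n_boundary * 0.8))
        assert abs(rec.p_decorate_T_hat - 0.5) <= 3 * se_t


class TestStationarity:
    def test_chain_samples_boltzmann_distribution(self):
        # 8-residue chain vs brute-force partition function over 2^8 states
        p = HelixKineticsParams(n_residues=8, n_frames=100_000, s=np.full(8, 2.0),
                                sigma=0.1, min_run=1, p_decorate_G=0.0,
                                p_decorate_T=0.0, sweep_moves=8)
        states = simulate_states(p, "all-coil", rng=7)
        codes = (states.astype(int) * (1 << np.arange(8))).sum(axis=1)
        empirical = np.bincount(codes, minlength=256) / len(codes)
        exact, marginal = enumerate_boltzmann(p)
        tv = 0.5 * np.abs(empirical - exact).sum()
        assert tv < 0.02
        # per-residue marginals agree even more tightly
        assert np.all(np.abs(states.mean(axis=0) - marginal) < 0.01)

    def test_constrained_chain_never_visits_invalid_states(self):
        p = HelixKineticsParams(n_residues=8, n_frames=20_000, s=np.full(8, 1.5),
                                sigma=0.2, min_run=4, p_decorate_G=0.0,
                                p_decorate_T=0.0, sweep_moves=8)
        states = simulate_states(p, "all-coil", rng=13)
        exact, _ = enumerate_boltzmann(p)
        codes = (states.astype(int) * (1 << np.arange(8))).sum(axis=1)
        empirical = np.bincount(codes, minlength=256) / len(codes)
        assert empirical[exact == 0].sum() == 0.0
        assert 0.5 * np.abs(empirical - exact).sum() < 0.05
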