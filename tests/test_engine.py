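import numpy as np
import pytest

from cfcsim.chainmech import ChainSolver, PinningProfile
from cfcsim.engine import (ChainConditioner, Ensemble, SimConfig,
                           run_transient, tni_site_indices)
from cfcsim.kinetics import (FREE, STRONG, WEAK, RateConstants,
                             build_transition_probs)
from cfcsim.params import ParameterError


def small_config(**kw):
    base = dict(A_tot=0.5e-6, M_tot=5e-6, duration=0.01, n_strands=20,
                n_sites=21, dt=1e-5, seed=3, record_interval=100,
                burn_in=0.0)
    base.update(kw)
    return SimConfig(**base)


@pytest.fixture(scope="module")
def small_conditioner(params):
    return ChainConditioner(params, 21)


class TestConfigValidation:
    def test_odd_strand_count_rejected(self):
        with pytest.raises(ParameterError):
            small_config(n_strands=3)

    def test_negative_duration_rejected(self):
        with pytest.raises(ParameterError):
            small_config(duration=-1.0)

    def test_zero_dt_rejected(self):
        with pytest.raises(ParameterError):
            small_config(dt=0.0)


class TestRegulatorySiteLayout:
    def test_every_seventh_from_third(self):
        idx = tni_site_indices(700)
        assert idx.size == 100
        assert idx[0] == 2 and idx[1] == 9 and idx[-1] == 695

    def test_strand_geometry(self, params):
        assert 700 * params.monomer_spacing == pytest.approx(3850.0)


class TestInitialisation:
    def test_cold_start_all_tni_bound(self, params, rates, small_conditioner):
        ens = Ensemble(small_config(), params, rates, small_conditioner)
        assert ens.tni_bound.all()
        assert (ens.site_state == FREE).all()
        assert ens.n_tni_bound == ens.tni_bound.size

    def test_zero_calcium_limit_is_absorbing(self, params, small_conditioner):
        # k_-I -> 0: TnI never detaches, chain stays pinned everywhere
        rates = RateConstants(k_TnI_off=0.0)
        ens = Ensemble(small_config(burn_in=0.02), params, rates,
                       small_conditioner, backend="numpy")
        ens.equilibrate()
        assert ens.tni_bound.all()

    def test_high_calcium_burn_in_unbinds_most_tni(self, params, rates,
                                                   small_conditioner):
        ens = Ensemble(small_config(n_strands=100, burn_in=0.05), params,
                       rates, small_conditioner)
        ens.equilibrate()
        # K_B = 12: bound fraction ~ k_I_eff/(k_I_eff + k_-I) ~ 0.1
        assert ens.n_tni_bound / ens.tni_bound.size < 0.4
        assert ens.time == 0.0


class TestStepInvariants:
    def test_all_rates_zero_freezes_state(self, params, small_conditioner):
        zero = RateConstants(0, 0, 0, 0, 0, 0)
        ens = Ensemble(small_config(), params, zero, small_conditioner,
                       backend="numpy")
        before = ens.snapshot()
        for _ in range(50):
            ens.step()
        after = ens.snapshot()
        assert np.array_equal(before["site_state"], after["site_state"])
        assert np.array_equal(before["tni_bound"], after["tni_bound"])

    def test_counters_track_state_arrays(self, params, rates,
                                         small_conditioner):
        ens = Ensemble(small_config(duration=0.02, n_strands=50), params,
                       rates, small_conditioner, backend="numpy")
        for _ in range(300):
            ens.step()
        assert ens.n_weak == int((ens.site_state == WEAK).sum())
        assert ens.n_strong == int((ens.site_state == STRONG).sum())
        assert ens.n_tni_bound == int(ens.tni_bound.sum())
        # pin codes consistent with state
        strong_mask = ens.site_state == STRONG
        assert np.array_equal(ens.pin_code == 2, strong_mask)

    def test_myosin_bookkeeping(self, params, rates, small_conditioner):
        cfg = small_config(duration=0.02, n_strands=50)
        rec = Ensemble(cfg, params, rates, small_conditioner, backend="numpy")
        out = rec.run()
        f = np.asarray(out.frac_weak) + np.asarray(out.frac_strong)
        expected_M = np.maximum(cfg.M_tot - f * cfg.A_tot, 0.0)
        assert np.asarray(out.M_free) == pytest.approx(expected_M, abs=1e-18)


class TestDeterminism:
    @pytest.mark.parametrize("backend", ["numpy", "numba"])
    def test_same_seed_same_transient(self, params, rates, small_conditioner,
                                      backend):
        out = []
        for _ in range(2):
            ens = Ensemble(small_config(duration=0.01), params, rates,
                           small_conditioner, backend=backend)
            ens.equilibrate()
            out.append(ens.run())
        assert out[0].frac_not_R == out[1].frac_not_R
        assert out[0].frac_tni_bound == out[1].frac_tni_bound

    def test_different_seeds_differ(self, params, rates, small_conditioner):
        recs = []
        for seed in (1, 2):
            ens = Ensemble(small_config(duration=0.01, seed=seed), params,
                           rates, small_conditioner)
            recs.append(ens.run())
        assert recs[0].frac_not_R != recs[1].frac_not_R


class TestExponentialDecayLimit:
    @pytest.mark.parametrize("backend", ["numpy", "numba"])
    def test_pure_weak_detachment(self, params, small_conditioner, backend):
        # only k_-M1 active from an all-weak start: occupancy ~ e^(-20 t)
        rates = RateConstants(0.0, 20.0, 0.0, 0.0, 0.0, 0.0)
        cfg = small_config(A_tot=0, M_tot=0, duration=0.05, n_strands=100,
                           dt=1e-4, record_interval=100)
        ens = Ensemble(cfg, params, rates, small_conditioner, backend=backend)
        ens.site_state[:] = WEAK
        ens.n_weak = ens.n_A
        ens._invalidate_kernel()
        rec = ens.run()
        expected = np.exp(-20.0 * 0.05)
        n = ens.n_A
        se = np.sqrt(expected * (1 - expected) / n)
        assert rec.frac_weak[-1] == pytest.approx(expected, abs=3 * se + 2e-3)


class TestTelegraphStationarity:
    def test_single_site_occupancy_matches_analytic(self, params):
        # one regulatory site per 7-monomer strand, no myosin: two-state
        # telegraph with chain-weighted rebinding; stationary occupancy
        # p = k_I_eff / (k_I_eff + k_-I)
        rates = RateConstants(k_TnI_off=1200.0, k_TnI_on=100.0)
        cond = ChainConditioner(params, 7)
        cfg = SimConfig(A_tot=0, M_tot=0, duration=0.06, n_strands=400,
                        n_sites=7, dt=1e-5, seed=5, record_interval=200,
                        burn_in=0.0)
        ens = Ensemble(cfg, params, rates, cond)
        rec = ens.run()
        # chain-weighted rebinding rate from the exact solver (independent path)
        solver = ChainSolver(params, 7, refine=4)
        free = solver.chain_state_at_sites(PinningProfile(7))
        from cfcsim.kinetics import weight_TnI_rebind
        site = int(tni_site_indices(7)[0])
        r_I = weight_TnI_rebind(free.phi_bar_deg[site], free.sigma_deg[site],
                                params.phi_minus_deg)
        r_I_o = weight_TnI_rebind(0.0, params.sigma_o_deg, params.phi_minus_deg)
        k_eff = r_I / r_I_o * rates.k_TnI_on
        expected = k_eff / (k_eff + rates.k_TnI_off)
        observed = np.mean(rec.frac_tni_bound[20:])
        se = np.sqrt(expected * (1 - expected) / cfg.n_strands)
        assert observed == pytest.approx(expected, abs=3 * se)


def naive_reference_run(params, rates, cfg, conditioner_unused, n_steps, seed):
    """Per-site uniform-draw sampler built directly on the spec'd per-site
    transition bins and the exact whole-chain solver; oracle for the
    thinning scheme."""
    rng = np.random.default_rng(seed)
    S, N = cfg.n_strands, cfg.n_sites
    tni_cols = tni_site_indices(N)
    I = tni_cols.size
    solver = ChainSolver(params, N, refine=4)
    site_state = np.zeros((S, N), dtype=np.uint8)
    tni_bound = np.ones((S, I), dtype=bool)
    traj = []
    for step in range(n_steps):
        f = float((site_state != FREE).sum()) / (S * N)
        M_free = max(cfg.M_tot - f * cfg.A_tot, 0.0)
        delta = 1.0 - 0.82 * f
        new_state = site_state.copy()
        new_bound = tni_bound.copy()
        for s in range(S):
            prof = PinningProfile.from_occupancy(
                (tni_cols[tni_bound[s]] + 1).tolist(),
                (np.flatnonzero(site_state[s] == STRONG) + 1).tolist(),
                N, params.phi_minus_deg, params.phi_plus_deg)
            sol = solver.chain_state_at_sites(prof)
            tp = build_transition_probs(site_state[s], tni_bound[s], tni_cols,
                                        sol.phi_bar_deg, sol.sigma_deg,
                                        params, rates, cfg.dt, M_free, delta,
                                        warn_threshold=1.0)
            u_t = rng.random(I)
            for t in range(I):
                if tni_bound[s, t]:
                    if u_t[t] < tp.p_mI[t]:
                        new_bound[s, t] = False
                else:
                    if u_t[t] < tp.p_I[t]:
                        new_bound[s, t] = True
            u_m = rng.random(N)
            for i in range(N):
                st = site_state[s, i]
                if st == FREE:
                    if u_m[i] < tp.p_M1[i]:
                        # TnI rebinding this step takes precedence
                        t = int(np.searchsorted(tni_cols, i))
                        if t < I and tni_cols[t] == i \
                                and new_bound[s, t] and not tni_bound[s, t]:
                            continue
                        new_state[s, i] = WEAK
                elif st == WEAK:
                    if u_m[i] < tp.p_mM1[i]:
                        new_state[s, i] = FREE
                    elif u_m[i] < tp.p_mM1[i] + tp.p_M2[i]:
                        new_state[s, i] = STRONG
                else:
                    if u_m[i] < tp.p_mM2[i]:
                        new_state[s, i] = WEAK
        site_state, tni_bound = new_state, new_bound
        traj.append((float((site_state == WEAK).sum()) / (S * N),
                     float((site_state == STRONG).sum()) / (S * N),
                     float(tni_bound.sum()) / (S * I)))
    return np.asarray(traj)


class TestThinningAgainstNaiveSampler:
    @pytest.mark.parametrize("backend", ["numpy", "numba"])
    def test_state_fraction_trajectories_agree(self, params, small_conditioner,
                                               backend):
        rates = RateConstants(k_TnI_off=300.0)
        cfg = small_config(n_strands=40, duration=0.015, dt=5e-5,
                           M_tot=5e-6, A_tot=0.5e-6, record_interval=1)
        n_steps = 300
        ref = naive_reference_run(params, rates, cfg, None, n_steps, seed=17)
        ens = Ensemble(cfg, params, rates, small_conditioner, backend=backend)
        rec = ens.run()
        sim = np.column_stack([rec.frac_weak[1:], rec.frac_strong[1:],
                               rec.frac_tni_bound[1:]])[:n_steps]
        # strand-level SE for the final-state fractions
        for col, name in ((0, "weak"), (1, "strong"), (2, "tni")):
            a, b = ref[-1, col], sim[-1, col]
            n = cfg.n_strands * (cfg.n_sites if col < 2 else 3)
            se = np.sqrt(max(a * (1 - a), 1e-6) / n)
            assert b == pytest.approx(a, abs=4 * np.sqrt(2) * se), name


class TestSnapshotRestore:
    def test_round_trip_idempotent(self, params, rates, small_conditioner):
        ens = Ensemble(small_config(duration=0.01, n_strands=30), params,
                       rates, small_conditioner, backend="numpy")
        for _ in range(150):
            ens.step()
        snap = ens.snapshot()
        ens2 = Ensemble(small_config(duration=0.01, n_strands=30), params,
                        rates, small_conditioner, backend="numpy")
        ens2.restore(snap)
        snap2 = ens2.snapshot()
        assert np.array_equal(snap["site_state"], snap2["site_state"])
        assert np.array_equal(snap["tni_bound"], snap2["tni_bound"])
        assert ens2.n_weak == ens.n_weak and ens2.n_strong == ens.n_strong

    def test_low_calcium_snapshot_profile(self, params, small_conditioner):
        rates = RateConstants(k_TnI_off=0.0)
        ens = Ensemble(small_config(n_strands=4, burn_in=0.0), params, rates,
                       small_conditioner, backend="numpy")
        phi, sig = ens.chain_profile(0)
        cols = tni_site_indices(21)
        assert phi[cols] == pytest.approx(params.phi_minus_deg, abs=1e-9)
        assert sig[cols] == pytest.approx(0.0, abs=1e-9)
        # mid-span the chain relaxes back towards the closed angle
        midspan = np.array([5, 6, 12, 13])
        assert np.all(phi[midspan] > params.phi_minus_deg)
        assert np.all(phi[midspan] < 0.0)


class TestConditionerMatchesExactSolver:
    def test_pairwise_vs_global_chain_state(self, params, conditioner, rng):
        # the engine's windowed conditioning against the whole-chain solve
        solver = ChainSolver(params, 700, refine=4)
        tni = tni_site_indices(700)
        bound = tni[rng.random(tni.size) < 0.5]
        strong = np.flatnonzero((rng.random(700) < 0.15)
                                & ~np.isin(np.arange(700), bound))
        prof = PinningProfile.from_occupancy(
            (bound + 1).tolist(), (strong + 1).tolist(), 700,
            params.phi_minus_deg, params.phi_plus_deg)
        ref = solver.chain_state_at_sites(prof)
        pc = np.zeros((1, 700), dtype=np.int8)
        pc[0, bound] = 1
        pc[0, strong] = 2
        sites = np.arange(700)
        phi, sig = conditioner.evaluate(pc, np.zeros(700, dtype=int), sites,
                                        params.phi_minus_deg,
                                        params.phi_plus_deg)
        assert np.abs(phi - ref.phi_bar_deg).max() / 25.0 < 0.01
        assert np.abs(sig - ref.sigma_deg).max() / params.sigma_o_deg < 0.01


class TestTimestepConvergence:
    def test_halving_dt_within_monte_carlo_error(self, params, rates,
                                                 conditioner):
        # default dt vs half, matched conditions, high-calcium excess myosin
        outs = {}
        for dt in (1e-5, 5e-6):
            cfg = SimConfig(A_tot=0.5e-6, M_tot=5e-6, duration=0.06,
                            n_strands=100, dt=dt, seed=23, burn_in=0.02,
                            record_interval=int(round(0.002 / dt)))
            tr = run_transient(cfg, params, rates, conditioner=conditioner)
            outs[dt] = np.asarray(tr.frac_not_R)
        a, b = outs[1e-5], outs[5e-6]
        # per-strand binomial SE of the not-R fraction at each record
        se = np.sqrt(np.maximum(a * (1 - a), 1e-6) / (100 * 700))
        # correlated sites inflate the error; use strand-level bound instead
        se_strand = np.sqrt(np.maximum(a * (1 - a), 1e-6) / 100)
        assert np.all(np.abs(a - b) <= 3 * se_strand + 0.01)
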