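"""Single-step semantics and the compiled trajectory loop."""

import math

import numpy as np
import pytest
from scipy import stats

import nanodomain as nd
from nanodomain.domains import CLATHRIN, OUTSIDE, TETRASPANIN


def single_domain_map(params, comp=TETRASPANIN, center=(0.05, 0.05)):
    return nd.DomainMap(
        centers=np.array([list(center)]),
        types=np.array([comp]),
        r_dom=params.r_dom,
        L=params.L,
    )


class TestTransitionBarrier:
    @pytest.mark.parametrize(
        "liganded,frm,to,expected",
        [
            (False, OUTSIDE, TETRASPANIN, 11.5),
            (False, TETRASPANIN, OUTSIDE, 13.0),
            (True, OUTSIDE, CLATHRIN, 1.0),
            (True, CLATHRIN, OUTSIDE, 4.5),
            (True, OUTSIDE, TETRASPANIN, 0.0),
            (True, TETRASPANIN, OUTSIDE, 0.0),
            (False, OUTSIDE, CLATHRIN, 0.0),
            (False, CLATHRIN, OUTSIDE, 0.0),
            # direct domain-to-domain moves sum the two boundary terms
            (False, TETRASPANIN, CLATHRIN, 13.0),
            (False, CLATHRIN, TETRASPANIN, 11.5),
            (True, TETRASPANIN, CLATHRIN, 1.0),
            (True, CLATHRIN, TETRASPANIN, 4.5),
        ],
    )
    def test_barrier_lookup(self, defaults, liganded, frm, to, expected):
        assert nd.transition_barrier(liganded, frm, to, defaults) == expected

    def test_same_compartment_rejected(self, defaults):
        with pytest.raises(ValueError):
            nd.transition_barrier(False, OUTSIDE, OUTSIDE, defaults)

    def test_unknown_compartment_rejected(self, defaults):
        with pytest.raises(ValueError, match="unknown"):
            nd.transition_barrier(False, 7, OUTSIDE, defaults)

    def test_detailed_balance_of_barrier_pair(self, defaults):
        dE_in = nd.transition_barrier(False, OUTSIDE, TETRASPANIN, defaults)
        dE_out = nd.transition_barrier(False, TETRASPANIN, OUTSIDE, defaults)
        assert math.exp(dE_out - dE_in) == pytest.approx(math.exp(1.5))


class TestMetropolisAccept:
    def test_zero_barrier_always_accepted(self, rng):
        assert all(nd.metropolis_accept(0.0, rng) for _ in range(100))

    def test_negative_barrier_rejected(self, rng):
        with pytest.raises(ValueError):
            nd.metropolis_accept(-0.1, rng)

    def test_acceptance_rate_matches_boltzmann_factor(self, rng):
        n = 200_000
        acc = sum(nd.metropolis_accept(1.0, rng) for _ in range(n))
        lo, hi = stats.binom.interval(0.999, n, math.exp(-1.0))
        assert lo <= acc <= hi


class TestAttemptStep:
    def test_step_moves_to_a_neighbour_and_advances_time(self, defaults, rng):
        dm = single_domain_map(defaults)
        s0 = nd.ReceptorState(site=(10, 10))
        s1 = nd.attempt_step(s0, dm, defaults, rng)
        assert abs(s1.site[0] - 10) + abs(s1.site[1] - 10) == 1
        assert s1.t == pytest.approx(defaults.dt)

    def test_periodic_wrap_at_lattice_edge(self, defaults):
        dm = single_domain_map(defaults)
        n = defaults.n_side
        seen = set()
        for seed in range(40):
            s1 = nd.attempt_step(
                nd.ReceptorState(site=(0, 0)), dm, defaults, np.random.default_rng(seed)
            )
            seen.add(s1.site)
        assert seen <= {(1, 0), (n - 1, 0), (0, 1), (0, n - 1), (0, 0)}
        assert (n - 1, 0) in seen or (0, n - 1) in seen

    def test_rejected_barrier_crossing_still_consumes_time(self, defaults):
        # site adjacent to a tetraspanin centre: crossing inward is ~never
        # accepted at 11.5 kT, but t must advance regardless
        dm = single_domain_map(defaults)
        c = round(0.05 / defaults.dx)
        edge = (c - 3, c)  # just outside (r_dom = 2.8 sites)
        assert nd.membership(edge, dm, defaults.dx) == OUTSIDE
        moved_inward = 0
        for seed in range(200):
            s1 = nd.attempt_step(
                nd.ReceptorState(site=edge), dm, defaults, np.random.default_rng(seed)
            )
            assert s1.t > 0
            if nd.membership(s1.site, dm, defaults.dx) == TETRASPANIN:
                moved_inward += 1
        assert moved_inward == 0  # p ~ exp(-11.5)*50 ~ 5e-4

    def test_dead_receptor_cannot_step(self, defaults, rng):
        dm = single_domain_map(defaults)
        with pytest.raises(ValueError):
            nd.attempt_step(nd.ReceptorState(site=(0, 0), alive=False), dm, defaults, rng)


class TestUpdateReactions:
    def test_no_binding_outside_domains(self, defaults, rng):
        dm = single_domain_map(defaults)
        p = defaults.replace(k_bind=1e5)
        s = nd.ReceptorState(site=(0, 0))
        for _ in range(1000):
            s = nd.update_reactions(s, dm, p, rng)
        assert not s.liganded

    def test_unliganded_receptor_never_removed_in_clathrin(self, defaults, rng):
        dm = single_domain_map(defaults, comp=CLATHRIN)
        c = round(0.05 / defaults.dx)
        p = defaults.replace(k_remove=199_999.0)  # p_remove ~ 1 per step
        s = nd.ReceptorState(site=(c, c))
        for _ in range(1000):
            s = nd.update_reactions(s, dm, p, rng)
        assert s.alive and not s.liganded

    def test_binding_probability_per_step(self, defaults):
        dm = single_domain_map(defaults)
        c = round(0.05 / defaults.dx)
        p = defaults.replace(k_bind=2e4)  # p_bind = 0.1 per step
        n = 5000
        bound = 0
        rng = np.random.default_rng(0)
        for _ in range(n):
            s = nd.update_reactions(nd.ReceptorState(site=(c, c)), dm, p, rng)
            bound += s.liganded
        lo, hi = stats.binom.interval(0.999, n, 0.1)
        assert lo <= bound <= hi


class TestSimulateTrajectory:
    def test_no_binding_pathway_censors_at_horizon(self, fast_params):
        rec = nd.simulate_trajectory(fast_params.replace(k_bind=0.0), seed=1)
        assert rec.censored and rec.t_bind is None and rec.t_remove is None
        assert rec.lifetime == pytest.approx(fast_params.T_max)
        assert not rec.intervals.liganded.any()
        rec.validate()

    def test_determinism_bit_identical_reruns(self, fast_params):
        p = fast_params.replace(k_bind=10.0)
        a = nd.simulate_trajectory(p, seed=42)
        b = nd.simulate_trajectory(p, seed=42)
        assert a.intervals.equals(b.intervals)
        assert np.array_equal(a.time_in, b.time_in)
        assert a.t_bind == b.t_bind and a.t_remove == b.t_remove

    def test_intervals_partition_lifetime_exactly(self, fast_params):
        rec = nd.simulate_trajectory(fast_params.replace(k_bind=5.0), seed=3)
        rec.validate()
        iv = rec.intervals
        assert iv.t_start.iloc[0] == 0.0
        np.testing.assert_allclose(iv.t_end.iloc[:-1], iv.t_start.iloc[1:])
        fr = nd.compartment_time_fractions(rec)
        assert fr["f_tet"] + fr["f_cla"] + fr["f_outside"] == pytest.approx(1.0)

    def test_event_ordering_with_instant_binding(self, defaults):
        # barrier-free entry and near-instant binding in tetraspanin: the
        # receptor binds at first tetraspanin entry, then is eventually
        # removed from a liganded clathrin interval
        p = defaults.replace(
            E_entry_tet=0.0, E_exit_tet=0.0, E_entry_cla=0.0, E_exit_cla=0.0,
            k_bind=1e5, k_remove=1.0, T_max=200.0,
        )
        rec = nd.simulate_trajectory(p, seed=11)
        rec.validate()
        assert rec.t_bind is not None and rec.t_remove is not None
        assert rec.t_bind == pytest.approx(rec.t_first_tet, abs=20 * p.dt)
        first_lig = rec.intervals[rec.intervals.liganded].iloc[0]
        assert first_lig.compartment == TETRASPANIN
        last = rec.intervals.iloc[-1]
        assert last.compartment == CLATHRIN and last.liganded

    def test_no_bind_event_outside_tetraspanin(self, defaults):
        p = defaults.replace(k_bind=50.0, k_remove=0.0, T_max=300.0)
        for seed in (1, 2, 3):
            rec = nd.simulate_trajectory(p, seed=seed)
            if rec.t_bind is None:
                continue
            row = rec.intervals[rec.intervals.liganded].iloc[0]
            assert row.compartment == TETRASPANIN

    def test_removal_waiting_time_is_exponential_with_mean_1_over_k(self, defaults):
        # trap the liganded receptor in clathrin (exit disabled) so the
        # removal wait is a clean exponential clock at k_remove = 0.05/s
        p = defaults.replace(
            E_entry_tet=0.0, E_exit_tet=0.0, E_entry_cla=0.0, E_exit_cla=50.0,
            k_bind=1e4, k_remove=0.05, T_max=400.0,
        )
        waits = []
        for seed in range(40):
            rec = nd.simulate_trajectory(p, seed=seed, record_events=True)
            if rec.t_remove is None:
                continue
            last = rec.intervals.iloc[-1]
            waits.append(rec.t_remove - last.t_start)
        waits = np.array(waits)
        assert len(waits) >= 30
        expected = 1 / p.k_remove
        assert abs(waits.mean() - expected) < 3.5 * expected / math.sqrt(len(waits))


class TestEmpiricalAcceptance:
    def test_inline_generator_matches_boltzmann_rate(self):
        n = 2_000_000
        acc = nd.empirical_acceptance(1.0, n, seed=5)
        lo, hi = stats.binom.interval(0.999, n, math.exp(-1.0))
        assert lo <= acc * n <= hi


class TestSimulatePositions:
    def test_free_diffusion_msd_recovers_nominal_diffusivity(self):
        p = nd.SimParams(n_tet=0, n_cla=0, T_max=10.0)
        tracks = [
            nd.simulate_positions(p, T=5.0, dump_interval=5e-4, seed=s) for s in range(200)
        ]
        D = nd.estimate_diffusion_msd(tracks, 5e-4)
        assert D == pytest.approx(0.2, rel=0.1)

    def test_positions_are_unwrapped(self):
        p = nd.SimParams(n_tet=0, n_cla=0, T_max=1000.0)
        pos = nd.simulate_positions(p, T=500.0, dump_interval=0.5, seed=2)
        # after 500 s the walk has explored far beyond one 0.2 um box period
        assert np.ptp(pos) > p.L


class TestChildSeeds:
    def test_streams_are_deterministic_and_distinct(self):
        a = nd.child_seeds(99, 10)
        b = nd.child_seeds(99, 10)
        assert np.array_equal(a, b)
        assert len(set(a.tolist())) == 10
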