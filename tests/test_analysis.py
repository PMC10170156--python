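"""Ensemble confinement statistics, first-passage times and MSD estimation."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

import nanodomain as nd
from nanodomain.domains import CLATHRIN, OUTSIDE, TETRASPANIN


def make_record(segments, t_bind=None, t_remove=None):
    """Build a TrajectoryRecord from (duration, compartment, liganded) tuples."""
    t = 0.0
    rows = []
    time_in = np.zeros((3, 2))
    for dur, comp, lig in segments:
        rows.append((t, t + dur, comp, lig))
        time_in[comp, int(lig)] += dur
        t += dur
    iv = pd.DataFrame(rows, columns=["t_start", "t_end", "compartment", "liganded"])
    return nd.TrajectoryRecord(
        intervals=iv, time_in=time_in, lifetime=t, censored=t_remove is None,
        t_bind=t_bind, t_remove=t_remove, t_first_tet=None, seed=0,
    )


durations = st.lists(
    st.tuples(
        st.floats(0.01, 50.0),
        st.sampled_from([OUTSIDE, TETRASPANIN, CLATHRIN]),
        st.booleans(),
    ),
    min_size=1,
    max_size=12,
)


class TestCompartmentTimeFractions:
    def test_all_outside_record(self):
        fr = nd.compartment_time_fractions(make_record([(5.0, OUTSIDE, False)]))
        assert (fr["f_tet"], fr["f_cla"], fr["f_outside"]) == (0.0, 0.0, 1.0)
        assert math.isnan(fr["f_liganded_in_domains"])
        assert fr["lifetime"] == 5.0

    def test_hand_built_mixture(self):
        rec = make_record(
            [(30.0, TETRASPANIN, False), (20.0, CLATHRIN, False), (50.0, OUTSIDE, False)]
        )
        fr = nd.compartment_time_fractions(rec)
        assert fr["f_tet"] == pytest.approx(0.3)
        assert fr["f_cla"] == pytest.approx(0.2)
        assert fr["f_outside"] == pytest.approx(0.5)
        assert fr["lifetime"] == pytest.approx(100.0)

    def test_liganded_fractions_cover_post_binding_time_only(self):
        rec = make_record(
            [
                (10.0, OUTSIDE, False),
                (10.0, TETRASPANIN, True),
                (20.0, OUTSIDE, True),
                (10.0, CLATHRIN, True),
            ],
            t_bind=10.0,
        )
        fr = nd.compartment_time_fractions(rec)
        assert fr["f_liganded_in_domains"] == pytest.approx(0.5)  # 20 of 40 s
        assert fr["f_liganded_cla"] == pytest.approx(0.25)

    @given(durations)
    def test_fractions_partition_unity(self, segs):
        fr = nd.compartment_time_fractions(make_record(segs))
        assert fr["f_tet"] + fr["f_cla"] + fr["f_outside"] == pytest.approx(1.0)

    def test_empty_record_rejected(self):
        rec = make_record([(1.0, OUTSIDE, False)])
        rec.lifetime = 0.0
        with pytest.raises(ValueError):
            nd.compartment_time_fractions(rec)


class TestEnsembleConfinement:
    def test_lifetime_weighting_of_two_records(self):
        recs = [
            make_record([(10.0, TETRASPANIN, False)]),
            make_record([(30.0, OUTSIDE, False)]),
        ]
        s = nd.ensemble_confinement(recs, n_boot=0)
        assert s.f_confined_all == pytest.approx(0.25)  # (10*1 + 30*0)/40
        assert s.f_tet == pytest.approx(0.25)
        assert s.f_cla == 0.0

    def test_identical_records_have_zero_bootstrap_se(self):
        recs = [make_record([(5.0, TETRASPANIN, False), (5.0, OUTSIDE, False)])] * 6
        s = nd.ensemble_confinement(recs, n_boot=200)
        assert s.f_confined_all == pytest.approx(0.5)
        assert s.se_confined_all == pytest.approx(0.0, abs=1e-12)

    @given(st.lists(durations, min_size=1, max_size=6))
    def test_weighted_mean_identity(self, seg_lists):
        # lifetime-weighted mean fraction == total ensemble time in domains
        # over total ensemble lifetime
        recs = [make_record(s) for s in seg_lists]
        s = nd.ensemble_confinement(recs, n_boot=0)
        tot_dom = sum(r.time_in[1:].sum() for r in recs)
        tot_life = sum(r.lifetime for r in recs)
        assert s.f_confined_all == pytest.approx(tot_dom / tot_life)

    def test_no_bound_trajectories_flagged(self):
        recs = [make_record([(5.0, OUTSIDE, False)])]
        s = nd.ensemble_confinement(recs, n_boot=10)
        assert s.n_bound == 0 and math.isnan(s.f_confined_liganded)

    def test_empty_ensemble_rejected(self):
        with pytest.raises(ValueError):
            nd.ensemble_confinement([])


@pytest.fixture(scope="module")
def small_sweep(defaults):
    p = defaults.replace(T_max=10.0)
    return nd.sweep_binding_rates(p, rates=[0.0, 0.5, 5.0], n_traj=8, seed=3, n_boot=50)


class TestSweepBindingRates:

    def test_tidy_output_one_row_per_rate(self, small_sweep):
        assert list(small_sweep.k_bind) == [0.0, 0.5, 5.0]
        assert small_sweep.n_traj.eq(8).all()

    def test_fractions_bounded_and_additive(self, small_sweep):
        f = small_sweep
        assert ((f.f_tet >= 0) & (f.f_cla >= 0) & (f.f_tet + f.f_cla <= 1)).all()
        assert np.allclose(f.f_confined_all, f.f_tet + f.f_cla)

    def test_zero_rate_has_no_liganded_statistics(self, small_sweep):
        row = small_sweep.iloc[0]
        assert row.n_bound == 0 and math.isnan(row.f_confined_liganded)

    def test_sweep_reproducible(self, defaults, small_sweep):
        p = defaults.replace(T_max=10.0)
        again = nd.sweep_binding_rates(p, rates=[0.0, 0.5, 5.0], n_traj=8, seed=3, n_boot=50)
        pd.testing.assert_frame_equal(small_sweep, again)

    def test_negative_rate_rejected(self, defaults):
        with pytest.raises(ValueError):
            nd.sweep_binding_rates(defaults.replace(T_max=1.0), rates=[-0.1], n_traj=1)


class TestFirstEntryTimes:
    def test_barrier_free_entry_is_much_faster(self, defaults):
        slow = nd.first_entry_times(defaults.replace(T_max=400.0), n_reps=30, seed=5)
        fast = nd.first_entry_times(
            defaults.replace(E_entry_tet=0.0, T_max=400.0), n_reps=30, seed=5
        )
        assert fast.mean < slow.mean / 10

    def test_impassable_barrier_censors_all_replicates(self, defaults):
        es = nd.first_entry_times(defaults.replace(E_entry_tet=60.0, T_max=2.0), n_reps=10, seed=1)
        assert es.n == 0 and es.n_censored == 10 and math.isnan(es.mean)

    def test_se_shrinks_with_replicates(self, defaults):
        p = defaults.replace(E_entry_tet=0.0, T_max=400.0)
        small = nd.first_entry_times(p, n_reps=20, seed=2)
        large = nd.first_entry_times(p, n_reps=80, seed=2)
        assert large.se < small.se

    def test_single_replicate_has_undefined_se(self, defaults):
        es = nd.first_entry_times(defaults.replace(E_entry_tet=0.0, T_max=400.0), n_reps=1, seed=0)
        assert es.n == 1 and math.isnan(es.se)


class TestEstimateDiffusionMsd:
    def test_round_trip_on_gaussian_tracks(self):
        tracks = nd.generate_free_diffusion_tracks(
            nd.TrackSpec(D=0.2, interval=0.05, n_tracks=300, track_length=100), seed=8
        )
        assert nd.estimate_diffusion_msd(tracks, 0.05) == pytest.approx(0.2, rel=0.1)

    def test_stationary_track_gives_zero(self):
        tracks = np.zeros((3, 50, 2))
        assert nd.estimate_diffusion_msd(tracks, 0.05) == 0.0

    def test_halving_interval_doubles_estimate(self):
        tracks = nd.generate_free_diffusion_tracks(
            nd.TrackSpec(D=0.1, interval=0.05, n_tracks=100, track_length=100), seed=9
        )
        d1 = nd.estimate_diffusion_msd(tracks, 0.05)
        d2 = nd.estimate_diffusion_msd(tracks, 0.025)
        assert d2 == pytest.approx(2 * d1, rel=1e-9)

    def test_degenerate_tracks_rejected(self):
        with pytest.raises(ValueError):
            nd.estimate_diffusion_msd([np.zeros((1, 2))], 0.05)
        with pytest.raises(ValueError):
            nd.estimate_diffusion_msd([], 0.05)


class TestEquilibriumEnrichment:
    def test_equal_barriers_give_unit_ratio(self, defaults):
        p = defaults.replace(E_entry_tet=1.0, E_exit_tet=1.0)
        r = nd.equilibrium_enrichment(p, T_obs=400.0, seed=4, n_reps=3)
        assert r == pytest.approx(1.0, rel=0.15)

    def test_barrier_free_domains_are_not_enriched(self, defaults):
        # the liganded state sees no tetraspanin barriers; equivalently a
        # walker with both tetraspanin barriers zeroed
        p = defaults.replace(E_entry_tet=0.0, E_exit_tet=0.0)
        r = nd.equilibrium_enrichment(p, T_obs=400.0, seed=4, n_reps=3)
        assert r == pytest.approx(1.0, rel=0.15)

    def test_unreachable_domains_flagged(self, defaults):
        p = defaults.replace(E_entry_tet=60.0)
        with pytest.warns(UserWarning, match="no tetraspanin"):
            r = nd.equilibrium_enrichment(p, T_obs=1.0, seed=0)
        assert math.isnan(r)


class TestIO:
    def test_csv_and_manifest_round_trip(self, fast_params, tmp_path):
        recs = [nd.simulate_trajectory(fast_params, seed=int(s)) for s in nd.child_seeds(5, 3)]
        nd.save_ensemble(tmp_path, recs, fast_params, root_seed=5)
        df = pd.read_csv(tmp_path / "trajectories.csv")
        assert set(df.columns) == {"traj_id", "t_start", "t_end", "compartment", "liganded"}
        assert df.traj_id.nunique() == 3
        import json

        manifest = json.loads((tmp_path / "manifest.json").read_text())
        assert manifest["n_trajectories"] == 3
        assert manifest["params"]["dt"] == pytest.approx(fast_params.dt)

    def test_counter_only_records_cannot_be_exported(self, fast_params):
        rec = nd.simulate_trajectory(fast_params, seed=1, record_events=False)
        with pytest.raises(ValueError, match="interval log"):
            nd.records_to_frame([rec])
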