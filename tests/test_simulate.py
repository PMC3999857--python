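"""Simulator contracts: kinetic means, anchor geometry, noise statistics,
survival laws and determinism."""

import numpy as np
import pytest

import patrolfret as pf


class TestPatrolTrace:
    def test_mean_cycle_duration_noiseless(self, no_noise):
        # 32 exponential 1-nt waits at 16 /s -> mean cycle 2.0 s
        cons = pf.ConstructSpec(track_length_nt=32)
        kin = pf.KineticParams(k_step_max=32.0, K_M=100.0, release_time=0.0)
        _, truth = pf.simulate_patrol_trace(cons, kin, 100.0, no_noise, 500.0, seed=11)
        cycles = np.diff(truth.event_times)
        assert len(cycles) > 150
        assert np.mean(cycles) == pytest.approx(2.0, abs=0.1)

    def test_fret_spans_anchor_interval(self, kin, no_noise):
        # mid-labeled substrate: pre-noise FRET confined to [0.37, 0.58]
        cons = pf.ConstructSpec(
            track_length_nt=32, labeling_scheme="junction_mid",
            fret_anchor_low=0.37, fret_anchor_high=0.58,
        )
        _, truth = pf.simulate_patrol_trace(cons, kin, 20.0, no_noise, 120.0, seed=1)
        e = truth.e_ideal
        assert e.min() == pytest.approx(0.37)
        assert e.max() <= 0.58 + 1e-12
        # the top anchor is approached to within one step of the track
        assert e.max() >= 0.58 - 1.5 * (0.58 - 0.37) / 32

    def test_half_saturation_rate(self, no_noise):
        # S = K_M -> realized stepping rate ~ k_step_max / 2
        cons = pf.ConstructSpec(track_length_nt=40)
        kin = pf.KineticParams(k_step_max=20.0, K_M=100.0)
        _, truth = pf.simulate_patrol_trace(cons, kin, 100.0, no_noise, 1100.0, seed=3)
        n_steps = np.sum(np.diff(truth.state_path) == 1)
        assert n_steps > 10_000
        realized = n_steps / truth.state_times[-1]
        assert realized == pytest.approx(10.0, rel=0.03)

    def test_cycle_count_consistent_with_duration(self, sawtooth_construct, kin, noise):
        _, truth = pf.simulate_patrol_trace(
            sawtooth_construct, kin, 20.0, noise, 90.0, seed=5
        )
        n = len(truth.event_times)
        mean_cycle = np.diff(truth.event_times).mean()
        assert abs(n * mean_cycle - 90.0) <= 2 * mean_cycle

    @pytest.mark.parametrize(
        "kwargs,msg",
        [
            (dict(duration_s=-1.0), "duration"),
            (dict(atp_uM=0.0), "atp"),
        ],
    )
    def test_invalid_inputs_rejected(self, sawtooth_construct, kin, noise, kwargs, msg):
        base = dict(duration_s=10.0, atp_uM=20.0)
        base.update(kwargs)
        with pytest.raises(ValueError, match=msg):
            pf.simulate_patrol_trace(
                sawtooth_construct, kin, base["atp_uM"], noise, base["duration_s"], seed=0
            )

    def test_post_noise_mean_recovers_ideal(self, sawtooth_construct, kin, noise):
        tr, truth = pf.simulate_patrol_trace(
            sawtooth_construct, kin, 20.0, noise, 60.0, seed=8
        )
        ft = pf.compute_fret(tr)
        assert np.nanmean(ft.E[ft.valid]) == pytest.approx(truth.e_ideal.mean(), abs=0.02)


class TestG4Trace:
    def test_extreme_plateau_levels_are_anchors(self, g4_construct, kin, no_noise):
        _, truth = pf.simulate_g4_trace(g4_construct, kin, 20.0, no_noise, 20, seed=2)
        assert truth.e_ideal.max() == pytest.approx(0.75)
        assert truth.e_ideal.min() == pytest.approx(0.30)

    def test_refolding_dwell_mean(self, g4_construct, no_noise):
        kin = pf.KineticParams(refold_rate=5.0)
        _, truth = pf.simulate_g4_trace(g4_construct, kin, 500.0, no_noise, 1500, seed=4)
        dt5 = truth.cycle_dwells["dt5"]
        assert dt5.mean() == pytest.approx(0.2, abs=3 * 0.2 / np.sqrt(len(dt5)))

    def test_total_intensity_conserved_without_noise(self, g4_construct, kin, no_noise):
        tr, _ = pf.simulate_g4_trace(g4_construct, kin, 20.0, no_noise, 10, seed=6)
        total = tr.I_D + tr.I_A
        assert np.allclose(total, total[0])

    def test_stage_dwells_are_hidden_step_sums(self, kin, no_noise):
        # zero patrol track: dt1..dt3 are pure Gamma(substeps) sums
        cons = pf.ConstructSpec(
            track_length_nt=0, payload="G4_TP",
            fret_anchor_low=0.30, fret_anchor_high=0.75,
        )
        r = 85.0 * 20.0 / 130.0
        _, truth = pf.simulate_g4_trace(cons, kin, 20.0, no_noise, 2000, seed=9)
        for key, subs in zip(("dt1", "dt2", "dt3"), kin.g4_stage_substeps):
            d = truth.cycle_dwells[key]
            expected = subs / r
            assert d.mean() == pytest.approx(expected, rel=0.1)

    def test_wrong_payload_rejected(self, sawtooth_construct, kin, noise):
        with pytest.raises(ValueError, match="payload"):
            pf.simulate_g4_trace(sawtooth_construct, kin, 20.0, noise, 5, seed=0)


class TestUnwindingAssay:
    def test_count_at_time_zero_is_n_spots(self):
        s = pf.simulate_unwinding_assay(777, 6.3, [0.0, 1.0, 5.0], seed=0)
        assert s.counts[0] == 777

    def test_survival_at_one_time_constant(self):
        n = 10_000
        s = pf.simulate_unwinding_assay(n, 6.3, [0.0, 6.3], seed=1)
        p = np.exp(-1.0)
        sd = np.sqrt(n * p * (1 - p))
        assert abs(s.counts[1] - n * p) <= 3 * sd

    def test_mean_counts_match_closed_form(self):
        n, tau = 2000, 6.3
        obs = np.array([0.0, 2.0, 5.0, 10.0, 20.0])
        sums = np.zeros_like(obs)
        n_seeds = 100
        for seed in range(n_seeds):
            sums += pf.simulate_unwinding_assay(n, tau, obs, seed=seed).counts
        means = sums / n_seeds
        expected = n * np.exp(-obs / tau)
        sd_mean = np.sqrt(np.maximum(expected * (1 - np.exp(-obs / tau)), 1e-9) / n_seeds)
        assert np.all(np.abs(means - expected) <= 4 * sd_mean + 1.0)

    def test_counts_monotone_non_increasing(self):
        s = pf.simulate_unwinding_assay(500, 2.0, np.linspace(0, 10, 21), seed=3)
        assert np.all(np.diff(s.counts) <= 0)

    def test_empty_obs_times_rejected(self):
        with pytest.raises(ValueError, match="obs_times"):
            pf.simulate_unwinding_assay(100, 6.3, [], seed=0)


class TestTitration:
    def test_bound_fractions_follow_binding_isotherm(self):
        concs = [1.0, 3.0, 7.0, 15.0, 40.0, 100.0]
        n = 1000
        df, truth = pf.simulate_titration(7.0, concs, n, seed=5)
        for c in concs:
            p = c / (c + 7.0)
            frac = df[df.concentration_nM == c]["bound"].mean()
            assert abs(frac - p) <= 3 * np.sqrt(p * (1 - p) / n)

    def test_half_occupancy_at_kd(self):
        df, _ = pf.simulate_titration(7.0, [7.0], 4000, seed=6)
        assert df["bound"].mean() == pytest.approx(0.5, abs=0.025)

    def test_vanishing_occupancy_at_low_concentration(self):
        df, _ = pf.simulate_titration(7.0, [0.01], 2000, seed=7)
        assert df["bound"].mean() < 0.01

    def test_zero_molecules_rejected(self):
        with pytest.raises(ValueError, match="n_molecules"):
            pf.simulate_titration(7.0, [1.0], 0)


class TestNoiseAndDeterminism:
    def test_poisson_noise_is_shot_limited(self, sawtooth_construct, kin):
        noise = pf.NoiseModel(noise_kind="poisson")
        tr, truth = pf.simulate_patrol_trace(
            sawtooth_construct, kin, 20.0, noise, 120.0, seed=10
        )
        mu_D = (1.0 - truth.e_ideal) * noise.total_photons_mean
        mu_A = truth.e_ideal * noise.total_photons_mean
        fano_D = np.mean((tr.I_D - mu_D) ** 2 / np.maximum(mu_D, 1.0))
        fano_A = np.mean((tr.I_A - mu_A) ** 2 / np.maximum(mu_A, 1.0))
        assert fano_D == pytest.approx(1.0, abs=0.1)
        assert fano_A == pytest.approx(1.0, abs=0.1)

    def test_identical_seed_bitwise_identical(self, sawtooth_construct, g4_construct, kin, noise):
        a1, t1 = pf.simulate_patrol_trace(sawtooth_construct, kin, 20.0, noise, 30.0, seed=99)
        a2, t2 = pf.simulate_patrol_trace(sawtooth_construct, kin, 20.0, noise, 30.0, seed=99)
        assert np.array_equal(a1.I_D, a2.I_D) and np.array_equal(a1.I_A, a2.I_A)
        assert np.array_equal(t1.event_times, t2.event_times)
        g1, _ = pf.simulate_g4_trace(g4_construct, kin, 20.0, noise, 10, seed=7)
        g2, _ = pf.simulate_g4_trace(g4_construct, kin, 20.0, noise, 10, seed=7)
        assert np.array_equal(g1.I_D, g2.I_D) and np.array_equal(g1.I_A, g2.I_A)

    def test_spawned_seeds_are_stable_and_distinct(self):
        s1 = pf.spawn_seeds(123, 10)
        s2 = pf.spawn_seeds(123, 10)
        assert s1 == s2
        assert len(set(s1)) == 10
        assert all(0 <= s < 2**31 for s in s1)
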