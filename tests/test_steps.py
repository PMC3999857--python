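"""Step finding, cycle classification, plateau-level mixtures and dwell fits."""

import numpy as np
import pytest

import patrolfret as pf
from patrolfret.steps import dp_segment


def staircase(levels, lengths, sigma=0.0, seed=0, dt=0.030):
    rng = np.random.default_rng(seed)
    y = np.concatenate([np.full(n, lv) for lv, n in zip(levels, lengths)])
    if sigma > 0:
        y = y + rng.normal(0.0, sigma, y.size)
    t = np.arange(y.size) * dt
    return t, y


class TestFindSteps:
    def test_noiseless_staircase_exact(self):
        t, y = staircase([0.75, 0.60, 0.45, 0.30], [30, 20, 25, 35])
        fit = pf.find_steps((t, y))
        assert fit.n_steps == 3
        assert list(fit.boundaries) == [30, 50, 75]
        assert np.allclose(fit.levels, [0.75, 0.60, 0.45, 0.30], atol=1e-12)
        assert fit.residual_sse == pytest.approx(0.0, abs=1e-9)

    def test_flat_segment_zero_steps_quality_undefined(self):
        t, y = staircase([0.5], [60])
        fit = pf.find_steps((t, y))
        assert fit.n_steps == 0
        assert fit.quality is None

    def test_sse_history_monotone_non_increasing(self):
        t, y = staircase([0.8, 0.5, 0.65, 0.3], [40, 30, 30, 40], sigma=0.05, seed=1)
        fit = pf.find_steps((t, y))
        assert np.all(np.diff(fit.sse_history) <= 1e-12)

    def test_greedy_matches_dp_optimum_on_small_traces(self):
        # high-SNR traces <=200 frames, <=4 steps: greedy boundaries within
        # 1 frame and plateau levels within 0.01 of the global DP optimum
        rng = np.random.default_rng(2)
        for case in range(25):
            k = int(rng.integers(1, 5))
            lengths = rng.integers(15, 50, size=k + 1)
            levels = rng.permutation(np.linspace(0.2, 0.9, k + 1))
            t, y = staircase(levels, lengths, sigma=0.02, seed=100 + case)
            greedy = pf.find_steps((t, y))
            if greedy.n_steps == 0:
                continue
            dp_bounds, dp_sse = dp_segment(y, greedy.n_steps)
            assert np.all(np.abs(np.array(dp_bounds) - greedy.boundaries) <= 1)
            edges = [0, *dp_bounds, len(y)]
            dp_levels = np.array(
                [y[a:b].mean() for a, b in zip(edges[:-1], edges[1:])]
            )
            assert np.allclose(greedy.levels, dp_levels, atol=0.01)

    def test_oracle_step_count_agreement(self):
        # the acceptance-grade statistic: >=95% count agreement with the DP
        # oracle on 200 small high-SNR instances
        rng = np.random.default_rng(3)
        agree = 0
        n_cases = 200
        for case in range(n_cases):
            k = int(rng.integers(0, 4))
            lengths = rng.integers(10, max(11, 60 // (k + 1)), size=k + 1)
            levels = np.linspace(0.85, 0.25, k + 1)
            sigma = (0.6 / max(k, 1)) / 8  # per-step SNR of 8
            t, y = staircase(levels, lengths, sigma=sigma, seed=500 + case)
            greedy = pf.find_steps((t, y))
            _, k_dp, _ = pf.dp_find_steps(y, max_steps=6)
            agree += greedy.n_steps == k_dp
        assert agree / n_cases >= 0.95

    def test_short_segment_rejected(self):
        with pytest.raises(ValueError, match="frames"):
            pf.find_steps((np.arange(5) * 0.03, np.ones(5)))


class TestClassifyCycle:
    def test_known_stage_dwells_recovered_within_two_frames(self, kin):
        # slow refolding + moderate noise so all five dwells are resolvable
        cons = pf.ConstructSpec(
            track_length_nt=10, payload="G4_TP",
            fret_anchor_low=0.30, fret_anchor_high=0.75,
        )
        slow_kin = pf.KineticParams(refold_rate=1.5)
        noise = pf.NoiseModel(snr=10.0)
        tr, truth = pf.simulate_g4_trace(cons, slow_kin, 20.0, noise, 8, seed=21)
        ft = pf.compute_fret(tr)
        cycles, _ = pf.analyze_g4_trace(ft, folded_level=0.75, unfolded_level=0.30)
        matched = 0
        dwell_truth = truth.cycle_dwells
        for cyc in cycles:
            if not cyc.canonical:
                continue
            # match against the nearest truth cycle by dt1
            errs = np.abs(dwell_truth.values - np.array(cyc.dwells)).max(axis=1)
            if errs.min() <= 3 * 0.030 + 1e-9:
                matched += 1
        assert matched >= 2

    def test_two_step_cycle_flagged_non_canonical(self):
        fit = pf.StepFitResult(
            plateaus=[(0.75, 0.0, 1.0), (0.50, 1.0, 1.6), (0.30, 1.6, 2.4)],
            n_steps=2, residual_sse=0.0, quality=2.0,
        )
        cyc = pf.classify_unwinding_cycle(fit, 0.75, 0.30)
        assert not cyc.canonical
        assert cyc.n_down_steps == 2
        assert np.isnan(cyc.dt1)

    def test_canonical_cycle_dwells_and_levels(self):
        fit = pf.StepFitResult(
            plateaus=[(0.75, 0.0, 2.0), (0.60, 2.0, 2.6), (0.45, 2.6, 3.3),
                      (0.30, 3.3, 4.1), (0.38, 4.1, 4.3)],
            n_steps=4, residual_sse=0.0, quality=2.0,
        )
        cyc = pf.classify_unwinding_cycle(fit, 0.75, 0.30, cycle_end_s=4.3)
        assert cyc.canonical
        assert cyc.dwells == pytest.approx((2.0, 0.6, 0.7, 0.8, 0.2))
        assert cyc.level_unfolded == pytest.approx(0.30)

    def test_inverted_anchors_rejected(self):
        fit = pf.StepFitResult(plateaus=[(0.5, 0.0, 1.0)], n_steps=0,
                               residual_sse=0.0, quality=None)
        with pytest.raises(ValueError, match="inverted"):
            pf.classify_unwinding_cycle(fit, 0.30, 0.75)


class TestLevelDistribution:
    def test_single_tight_level_selects_one_component(self):
        rng = np.random.default_rng(4)
        dist = pf.fit_level_distribution(rng.normal(0.5, 0.01, 300))
        assert dist.n_components == 1

    def test_four_level_pool_selects_four_components(self):
        true_means = [0.30, 0.45, 0.60, 0.75]
        hits = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            pool = np.concatenate(
                [rng.normal(m, 0.025, 150) for m in true_means]
            )
            dist = pf.fit_level_distribution(pool, seed=seed)
            if dist.n_components == 4:
                hits += 1
                assert np.allclose(dist.means, true_means, atol=0.03)
        assert hits >= 8

    def test_too_few_levels_rejected(self):
        with pytest.raises(ValueError, match="levels"):
            pf.fit_level_distribution(np.full(10, 0.5))


class TestDwellDistributions:
    @staticmethod
    def _cycles_from_truth(dwells):
        return [
            pf.UnwindingCycle(
                dt1=r.dt1, dt2=r.dt2, dt3=r.dt3, dt4=r.dt4, dt5=r.dt5,
                level_folded=0.75, level_I1=0.60, level_I2=0.45, level_unfolded=0.30,
            )
            for r in dwells.itertuples()
        ]

    def test_stage_shapes_ordered_by_substep_counts(self, kin, no_noise):
        cons = pf.ConstructSpec(
            track_length_nt=0, payload="G4_TP",
            fret_anchor_low=0.30, fret_anchor_high=0.75,
        )
        _, truth = pf.simulate_g4_trace(cons, kin, 20.0, no_noise, 1500, seed=31)
        fits = pf.fit_dwell_distributions(self._cycles_from_truth(truth.cycle_dwells))
        shapes = [fits[k].n for k in ("dt1", "dt2", "dt3")]
        assert shapes[0] < shapes[1] < shapes[2]  # substeps 4 < 8 < 9
        for k in ("dt1", "dt2", "dt3", "dt4"):
            assert fits[k].n - 1.0 >= 2 * fits[k].n_se

    def test_refolding_dwell_exponential_mean(self, kin, no_noise):
        cons = pf.ConstructSpec(
            track_length_nt=0, payload="G4_TP",
            fret_anchor_low=0.30, fret_anchor_high=0.75,
        )
        _, truth = pf.simulate_g4_trace(cons, kin, 20.0, no_noise, 1000, seed=32)
        fits = pf.fit_dwell_distributions(self._cycles_from_truth(truth.cycle_dwells))
        assert fits["dt5"]["mean_s"] == pytest.approx(0.2, rel=0.15)

    def test_exponential_stage_gives_unit_shape(self):
        rng = np.random.default_rng(6)
        import pandas as pd

        dwells = pd.DataFrame(
            {
                "dt1": rng.exponential(1.0, 400),
                "dt2": rng.gamma(8, 0.05, 400),
                "dt3": rng.gamma(9, 0.05, 400),
                "dt4": rng.gamma(10, 0.05, 400),
                "dt5": rng.exponential(0.2, 400),
            }
        )
        fits = pf.fit_dwell_distributions(self._cycles_from_truth(dwells))
        assert abs(fits["dt1"].n - 1.0) <= 3 * fits["dt1"].n_se
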