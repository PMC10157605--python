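"""The synthetic-data generator: noise model, perturbations, chromatograms."""

import numpy as np
import pytest

from specdiff import simulate
from specdiff.diffs import FAVector, observed_mean_between
from specdiff.io import average_scans


class TestDrawFaVector:
    def test_simplex_constraint(self):
        fa = simulate.draw_fa_vector(20, seed=0)
        assert abs(fa.values.sum() - 1.0) < 1e-12
        assert np.all(fa.values >= 0)

    def test_determinism(self):
        a = simulate.draw_fa_vector(20, seed=123)
        b = simulate.draw_fa_vector(20, seed=123)
        assert np.array_equal(a.values, b.values)

    def test_large_concentration_near_uniform(self):
        fa = simulate.draw_fa_vector(10, concentration=1e6, seed=0)
        assert np.allclose(fa.values, 0.1, atol=1e-3)


class TestPerturbIsomer:
    def test_hand_arithmetic_two_channel_move(self):
        fa = FAVector(values=np.array([0.25, 0.25, 0.25, 0.25]))
        out = simulate.perturb_isomer(fa, effect_size=0.1, n_affected=2, seed=0)
        moved = out.values - fa.values
        assert sorted(np.round(moved, 12)) == [-0.1, 0.0, 0.0, 0.1]

    def test_zero_effect_is_identity(self):
        fa = simulate.draw_fa_vector(10, seed=1)
        out = simulate.perturb_isomer(fa, effect_size=0.0, n_affected=4, seed=2)
        assert np.allclose(out.values, fa.values)

    def test_conservation(self):
        fa = simulate.draw_fa_vector(20, seed=3)
        out = simulate.perturb_isomer(fa, 0.05, 4, seed=4)
        assert abs(out.values.sum() - 1.0) < 1e-12

    def test_infeasible_effect_rejected(self):
        fa = FAVector(values=np.array([0.01, 0.01, 0.49, 0.49]))
        with pytest.raises(ValueError, match="donor"):
            simulate.perturb_isomer(fa, effect_size=0.99, n_affected=4, seed=0)


class TestSimulateScans:
    def test_channel_mean_fa_within_three_se(self):
        fa = simulate.draw_fa_vector(20, seed=5)
        series = simulate.simulate_scans(fa, n_scans=100, tic_mean=1e6, tic_rsd=10, seed=6)
        avg = average_scans(series)
        est = avg.intensity / avg.intensity.sum()
        # binomial SE of the 100-scan averaged fractional abundance
        se = np.sqrt(fa.values * (1 - fa.values) / 1e8)
        assert np.all(np.abs(est - fa.values) < 3 * se + 1e-9)

    def test_zero_rsd_constant_tic(self):
        fa = simulate.draw_fa_vector(5, seed=7)
        series = simulate.simulate_scans(fa, n_scans=10, tic_mean=1e5, tic_rsd=0, seed=8)
        assert np.allclose(series.tics(), 1e5)

    def test_determinism_byte_identical(self):
        fa = simulate.draw_fa_vector(10, seed=9)
        s1 = simulate.simulate_scans(fa, 20, 1e5, 10, seed=10)
        s2 = simulate.simulate_scans(fa, 20, 1e5, 10, seed=10)
        for a, b in zip(s1.spectra, s2.spectra):
            assert np.array_equal(a.mz, b.mz) and np.array_equal(a.intensity, b.intensity)

    def test_replicate_floor_shrinks_with_tic(self):
        fa = simulate.draw_fa_vector(20, seed=11)

        def floor(tic, seed):
            a = simulate.simulate_scans(fa, 50, tic, 10, seed=seed)
            b = simulate.simulate_scans(fa, 50, tic, 10, seed=seed + 1)
            return observed_mean_between(average_scans(a), average_scans(b)).observed_mean

        low = np.mean([floor(1e4, 100 + i) for i in range(5)])
        high = np.mean([floor(1e6, 200 + i) for i in range(5)])
        # multinomial counting noise: floor should scale roughly like 1/sqrt(TIC)
        assert high < low / 3

    def test_counting_regime_enforced(self):
        fa = simulate.draw_fa_vector(5, seed=12)
        with pytest.raises(ValueError, match="1000"):
            simulate.simulate_scans(fa, 10, tic_mean=10, seed=0)


class TestMixture:
    def test_endpoint_identity(self):
        a = simulate.draw_fa_vector(10, seed=13)
        b = simulate.perturb_isomer(a, seed=14)
        assert np.array_equal(simulate.mixture_fa(a, b, 0.0).values, a.values)

    def test_hand_arithmetic(self):
        a = FAVector(values=np.array([0.5, 0.3, 0.2]))
        b = FAVector(values=np.array([0.4, 0.4, 0.2]))
        mix = simulate.mixture_fa(a, b, 0.25)
        assert np.allclose(mix.values, [0.475, 0.325, 0.2])

    def test_convexity_preserves_sum(self):
        a = simulate.draw_fa_vector(15, seed=15)
        b = simulate.perturb_isomer(a, seed=16)
        for x in (0.1, 0.33, 0.9):
            assert abs(simulate.mixture_fa(a, b, x).values.sum() - 1.0) < 1e-12


class TestEffectMonotonicity:
    def test_observed_mean_increases_with_effect(self):
        # spiky spectrum so donor channels can afford the largest move (0.1 each)
        fa = simulate.draw_fa_vector(20, concentration=1.0, seed=1)
        means = []
        for effect in (0.01, 0.05, 0.1, 0.2):
            vals = []
            # averaged over perturbation seeds: the affected channels (and
            # hence the per-channel normalization) vary draw to draw
            for rep in range(20):
                pert = simulate.perturb_isomer(fa, effect, 4, seed=500 + rep)
                a = simulate.simulate_scans(fa, 50, 1e6, 10, seed=300 + rep)
                b = simulate.simulate_scans(pert, 50, 1e6, 10, seed=400 + rep)
                vals.append(
                    observed_mean_between(average_scans(a), average_scans(b)).observed_mean
                )
            means.append(np.mean(vals))
        assert all(a < b for a, b in zip(means, means[1:]))


class TestChromatogram:
    def test_blocks_contiguous_and_truth_recorded(self):
        spec = simulate.default_lc_scenario(seed=0)
        series, table = simulate.simulate_chromatogram(spec, seed=1)
        assert table["truth"].tolist().count("coeluting") == 1
        # observed peaks tile the run contiguously
        assert table["scan_start"].iloc[0] == 0
        for i in range(1, len(table)):
            assert table["scan_start"].iloc[i] == table["scan_end"].iloc[i - 1] + 1
        assert table["scan_end"].iloc[-1] == len(series) - 1
        # retention times non-decreasing, peak labels include a repeated peptide
        assert (table["peptide_label"] == "P1").sum() == 2

    def test_coeluting_block_fa_drifts(self):
        spec = simulate.default_lc_scenario(seed=2)
        series, table = simulate.simulate_chromatogram(spec, seed=3)
        row = table[table["truth"] == "coeluting"].iloc[0]
        s0, s1 = int(row["scan_start"]), int(row["scan_end"])
        lead = average_scans(series, (s0, s0 + 40))
        trail = average_scans(series, (s1 - 40, s1))
        drift = observed_mean_between(lead, trail).observed_mean
        hom = table[table["truth"] == "single"].iloc[1]
        h0, h1 = int(hom["scan_start"]), int(hom["scan_end"])
        ref = observed_mean_between(
            average_scans(series, (h0, h0 + 40)), average_scans(series, (h1 - 40, h1))
        ).observed_mean
        assert drift > 10 * ref

    def test_ground_truth_json(self, tmp_path):
        import json

        spec = simulate.default_lc_scenario(seed=4)
        series, table = simulate.simulate_chromatogram(spec, seed=5)
        path = tmp_path / "truth.json"
        simulate.write_ground_truth(str(path), spec, table, seed=5)
        truth = json.loads(path.read_text())
        assert truth["seed"] == 5
        assert len(truth["peaks"]) == len(spec.peaks)
        assert truth["co_elution"] == [[6, 7]]
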