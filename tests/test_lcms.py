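"""LC-MS scan-window arithmetic, edge/center comparisons, classification."""

import numpy as np
import pytest

from specdiff import simulate
from specdiff.inference import HypothesizedMean, one_sample_test
from specdiff.io import ScanSeries, Spectrum
from specdiff.lcms import (
    CATEGORY_COELUTING,
    CATEGORY_CONFIRMED,
    CATEGORY_NON_ISOMER,
    CATEGORY_UNCONFIRMED,
    ChromPeak,
    classify_peaks,
    compare_peaks,
    edge_comparison,
    lc_hypothesized_mean,
    peaks_from_table,
    read_peak_table,
    scan_window,
    screen,
)


def make_peak(label="P", start=0, end=99):
    return ChromPeak(peptide_label=label, scan_start=start, scan_end=end)


class TestScanWindow:
    def test_minimum_144_gives_72(self):
        peaks = [make_peak(end=n - 1) for n in (200, 180, 144, 150)]
        assert scan_window(peaks) == 72

    def test_single_peak_halved(self):
        assert scan_window([make_peak(end=99)]) == 50

    def test_odd_minimum_floored(self):
        assert scan_window([make_peak(end=4)]) == 2

    def test_order_invariant_global_minimum(self):
        counts = [200, 144, 180, 150]
        p1 = [make_peak(end=n - 1) for n in counts]
        p2 = [make_peak(end=n - 1) for n in reversed(counts)]
        assert scan_window(p1) == scan_window(p2) == 72

    def test_no_peaks_rejected(self):
        with pytest.raises(ValueError):
            scan_window([])


class TestEdgeComparison:
    def test_noiseless_homogeneous_peak_is_zero(self):
        fa = np.array([0.5, 0.3, 0.2])
        mz = np.array([200.0, 300.0, 400.0])
        series = ScanSeries(
            [Spectrum(mz=mz, intensity=1e5 * fa, scan_id=i) for i in range(20)]
        )
        d = edge_comparison(make_peak(end=19), window=8, series=series)
        assert d.observed_mean == 0.0

    def test_homogeneous_noisy_peak_at_replicate_floor(self):
        fa = simulate.draw_fa_vector(20, seed=0)
        series = simulate.simulate_scans(fa, 100, 1e6, 10, seed=1)
        d = edge_comparison(make_peak(end=99), window=50, series=series)
        assert d.observed_mean < 0.01

    def test_two_half_peaks_of_different_isomers_inflated(self):
        fa_a = simulate.draw_fa_vector(20, seed=2)
        fa_b = simulate.perturb_isomer(fa_a, seed=3)
        first = simulate.simulate_scans(fa_a, 50, 1e6, 10, seed=4)
        second = simulate.simulate_scans(fa_b, 50, 1e6, 10, seed=5, scan_id_start=50)
        series = ScanSeries(first.spectra + second.spectra)
        d = edge_comparison(make_peak(end=99), window=50, series=series)
        assert d.observed_mean > 0.05

    def test_oversized_window_rejected(self):
        fa = simulate.draw_fa_vector(5, seed=6)
        series = simulate.simulate_scans(fa, 10, 1e5, 0, seed=7)
        with pytest.raises(ValueError, match="too large"):
            edge_comparison(make_peak(end=9), window=6, series=series)


class TestLcHypothesizedMean:
    def test_upper_quartile_type7(self):
        means = [0.01, 0.02, 0.03, 0.04, 0.05, 0.06, 0.07, 0.08]
        mu0 = lc_hypothesized_mean(means, rule="upper_quartile")
        assert mu0.value == pytest.approx(0.0625)
        assert mu0.rule == "upper_quartile"

    def test_constant_list_either_rule(self):
        assert lc_hypothesized_mean([0.03] * 4, "upper_quartile").value == pytest.approx(0.03)
        assert lc_hypothesized_mean([0.03] * 4, "mean_plus_3sd").value == pytest.approx(0.03)

    def test_mean_plus_3sd_hand_value(self):
        mu0 = lc_hypothesized_mean([0.02, 0.04], rule="mean_plus_3sd")
        assert mu0.value == pytest.approx(0.03 + 3 * 0.0141421, abs=1e-5)

    def test_quartile_needs_four_values(self):
        with pytest.raises(ValueError, match=">= 4"):
            lc_hypothesized_mean([0.01, 0.02, 0.03], rule="upper_quartile")


class TestComparePeaks:
    def setup_method(self):
        fa = simulate.draw_fa_vector(20, seed=8)
        self.fa = fa
        self.iso = simulate.perturb_isomer(fa, seed=9)
        a = simulate.simulate_scans(fa, 100, 1e6, 10, seed=10)
        b = simulate.simulate_scans(fa, 100, 1e6, 10, seed=11, scan_id_start=100)
        c = simulate.simulate_scans(self.iso, 100, 1e6, 10, seed=12, scan_id_start=200)
        self.series = ScanSeries(a.spectra + b.spectra + c.spectra)
        self.p1 = make_peak("X", 0, 99)
        self.p2 = make_peak("X", 100, 199)
        self.p3 = make_peak("X", 200, 299)
        self.mu0 = HypothesizedMean.manual(0.005)

    def test_same_isomer_not_distinguished(self):
        r = compare_peaks(self.p1, self.p2, 50, self.mu0, self.series)
        assert r.verdict == "not_distinguished"

    def test_different_isomers_flagged(self):
        r = compare_peaks(self.p1, self.p3, 50, self.mu0, self.series)
        assert r.verdict == "different"
        assert r.observed_mean > 0.05

    def test_peak_against_itself_zero(self):
        r = compare_peaks(self.p1, self.p1, 50, self.mu0, self.series)
        assert r.observed_mean == 0.0
        assert r.verdict == "not_distinguished"


class TestClassifyPeaks:
    def stub_result(self, p):
        from specdiff.diffs import DifferenceSet

        x = np.array([0.3, 0.4, 0.35, 0.2]) if p < 0.05 else np.array(
            [0.001, 0.002, 0.0015, 0.001]
        )
        ds = DifferenceSet(
            channel_mz=np.arange(4.0),
            fa_a=np.full(4, 0.25),
            fa_b=np.full(4, 0.25),
            signed=np.zeros(4),
            absolute=np.zeros(4),
            normalized=x,
            observed_mean=float(x.mean()),
        )
        return one_sample_test(ds, 0.05)

    def test_decision_table(self):
        sig, nonsig = self.stub_result(0.01), self.stub_result(0.9)
        single_quiet = make_peak("A", 0, 99)
        single_loud = make_peak("B", 100, 199)
        pair1, pair2 = make_peak("C", 200, 299), make_peak("C", 300, 399)
        pair3, pair4 = make_peak("D", 400, 499), make_peak("D", 500, 599)
        groups = {
            "A": [single_quiet],
            "B": [single_loud],
            "C": [pair1, pair2],
            "D": [pair3, pair4],
        }
        edge = {single_quiet.key: nonsig, single_loud.key: sig}
        cross = {(pair1.key, pair2.key): sig, (pair3.key, pair4.key): nonsig}
        cats = {
            tuple(p.key for p in c.peak_refs): c.category
            for c in classify_peaks(groups, edge, cross)
        }
        assert cats[(single_quiet.key,)] == CATEGORY_NON_ISOMER
        assert cats[(single_loud.key,)] == CATEGORY_COELUTING
        assert cats[(pair1.key, pair2.key)] == CATEGORY_CONFIRMED
        assert cats[(pair3.key, pair4.key)] == CATEGORY_UNCONFIRMED

    def test_missing_comparison_named(self):
        p = make_peak("A")
        with pytest.raises(ValueError, match=p.key):
            classify_peaks({"A": [p]}, {}, {})


class TestScreenEndToEnd:
    def test_planted_truth_recovered(self):
        spec = simulate.default_lc_scenario(seed=0)
        series, table = simulate.simulate_chromatogram(spec, seed=1000)
        result = screen(series, peaks_from_table(table), rule="upper_quartile")
        cats = {}
        for c in result.classifications:
            key = tuple(sorted({p.peptide_label for p in c.peak_refs}))
            cats[key] = c.category
        assert cats[("P1",)] == CATEGORY_CONFIRMED
        assert cats[("P6",)] == CATEGORY_COELUTING
        for single in ("P2", "P3", "P4", "P5"):
            assert cats[(single,)] == CATEGORY_NON_ISOMER
        assert result.window == 72  # narrowest planted peak has 144 scans

    def test_report_frame_and_json(self):
        spec = simulate.default_lc_scenario(seed=1)
        series, table = simulate.simulate_chromatogram(spec, seed=1001)
        result = screen(series, peaks_from_table(table), rule="upper_quartile")
        df = result.to_frame()
        assert set(df["category"]) >= {CATEGORY_CONFIRMED, CATEGORY_NON_ISOMER}
        import json

        summary = json.loads(result.to_json())
        assert summary["window"] == 72
        assert summary["hypothesized_mean"]["rule"] == "upper_quartile"

    def test_peak_table_round_trip(self, tmp_path):
        spec = simulate.default_lc_scenario(seed=2)
        series, table = simulate.simulate_chromatogram(spec, seed=1002)
        path = tmp_path / "peaks.tsv"
        table.drop(columns=["truth"]).to_csv(path, sep="\t", index=False)
        peaks = read_peak_table(str(path))
        assert len(peaks) == len(table)
        assert peaks[0].n_scans == int(table["scan_end"][0]) - int(table["scan_start"][0]) + 1
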