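"""LC-MS/MS isomer screening.

Chromatographic peaks of the same peptide are compared with the observed-
mean statistic under scan-count discipline: every extraction uses the same
window, half the scan count of the narrowest peak in the run.  Each peak's
leading and trailing edges are compared against each other to measure
within-peak reproducibility (and to expose co-eluting isomers); the edge
means of single peaks set the run's hypothesized mean; apex-centred windows
of different peaks of one peptide are then compared all-vs-all.

Peak-level outcomes:

* ``non_isomer``          single peak, edge comparison not significant
* ``coeluting_isomer``    single peak, edge comparison significant
* ``confirmed_isomer``    separate peaks, cross comparison significant
* ``unconfirmed_isomer``  separate peaks, cross comparison not significant
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .diffs import DifferenceSet, observed_mean_between
from .inference import ComparisonResult, HypothesizedMean, one_sample_test
from .io import ScanSeries, average_scans

CATEGORY_NON_ISOMER = "non_isomer"
CATEGORY_CONFIRMED = "confirmed_isomer"
CATEGORY_UNCONFIRMED = "unconfirmed_isomer"
CATEGORY_COELUTING = "coeluting_isomer"


@dataclass
class ChromPeak:
    """A chromatographic elution peak: a contiguous block of MS2 scans.

    ``scan_start``/``scan_end`` are inclusive positional indices into the
    run's :class:`~specdiff.io.ScanSeries`.  ``apex_index`` defaults to the
    centre of the block when no apex is supplied.
    """

    peptide_label: str
    scan_start: int
    scan_end: int
    rt_start: float | None = None
    rt_apex: float | None = None
    rt_end: float | None = None
    precursor_mz: float | None = None
    charge: int | None = None
    apex_index: int | None = None

    def __post_init__(self) -> None:
        if self.n_scans < 4:
            raise ValueError(
                f"peak {self.peptide_label}@{self.scan_start}: needs >= 4 scans"
            )
        if self.apex_index is None:
            self.apex_index = (self.scan_start + self.scan_end) // 2
        if not self.scan_start <= self.apex_index <= self.scan_end:
            raise ValueError("apex must lie within the peak")

    @property
    def n_scans(self) -> int:
        return self.scan_end - self.scan_start + 1

    @property
    def scan_ids(self) -> range:
        return range(self.scan_start, self.scan_end + 1)

    @property
    def key(self) -> str:
        return f"{self.peptide_label}@{self.scan_start}"


def read_peak_table(path: str) -> list[ChromPeak]:
    """Read a TSV peak table: peptide_label, precursor_mz, charge, scan_start, scan_end[, rt_apex]."""
    df = pd.read_csv(path, sep="\t")
    required = {"peptide_label", "scan_start", "scan_end"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing peak-table columns {sorted(missing)}")
    peaks = []
    for _, row in df.iterrows():
        peaks.append(
            ChromPeak(
                peptide_label=str(row["peptide_label"]),
                scan_start=int(row["scan_start"]),
                scan_end=int(row["scan_end"]),
                rt_apex=float(row["rt_apex"]) if "rt_apex" in df.columns else None,
                precursor_mz=float(row["precursor_mz"])
                if "precursor_mz" in df.columns
                else None,
                charge=int(row["charge"]) if "charge" in df.columns else None,
            )
        )
    return peaks


def peaks_from_table(table: pd.DataFrame) -> list[ChromPeak]:
    """Build peaks from an in-memory table (as produced by the simulator)."""
    return [
        ChromPeak(
            peptide_label=str(r["peptide_label"]),
            scan_start=int(r["scan_start"]),
            scan_end=int(r["scan_end"]),
            rt_apex=float(r["rt_apex"]) if "rt_apex" in table.columns else None,
            precursor_mz=float(r["precursor_mz"]) if "precursor_mz" in table.columns else None,
            charge=int(r["charge"]) if "charge" in table.columns else None,
        )
        for _, r in table.iterrows()
    ]


def detect_peaks(
    series: ScanSeries,
    min_scans: int = 4,
    mz_tolerance: float = 10.0,
    tic_threshold: float = 0.0,
) -> list[ChromPeak]:
    """Thin peak finder: contiguous runs of MS2 scans sharing one precursor.

    Scans are grouped while the precursor m/z stays within ``mz_tolerance``
    ppm and the TIC stays above ``tic_threshold``; runs shorter than
    ``min_scans`` are discarded.  Intended for synthetic or pre-segmented
    data — real chromatographic peak picking is out of scope.
    """
    peaks: list[ChromPeak] = []
    start = None
    ref_mz = None
    for i, s in enumerate(series.spectra):
        ok = s.precursor_mz is not None and s.tic > tic_threshold
        same = (
            ok
            and ref_mz is not None
            and abs(s.precursor_mz - ref_mz) <= ref_mz * mz_tolerance * 1e-6
        )
        if same:
            continue
        if start is not None and i - start >= min_scans:
            peaks.append(
                ChromPeak(peptide_label=f"mz{ref_mz:.3f}", scan_start=start, scan_end=i - 1)
            )
        start, ref_mz = (i, s.precursor_mz) if ok else (None, None)
    if start is not None and len(series) - start >= min_scans:
        peaks.append(
            ChromPeak(
                peptide_label=f"mz{ref_mz:.3f}", scan_start=start, scan_end=len(series) - 1
            )
        )
    return peaks


# ---------------------------------------------------------------------------
# scan-window arithmetic and comparisons


def scan_window(peaks: list[ChromPeak]) -> int:
    """Half the scan count of the narrowest peak, floored.

    This single window is used for every extraction in the run so that all
    comparisons average an equal number of scans (a run whose narrowest
    peak holds 144 scans yields a 72-scan window).
    """
    if not peaks:
        raise ValueError("no peaks supplied")
    m = min(p.n_scans for p in peaks)
    if m < 4:
        raise ValueError("peak too narrow: fewer than 4 scans")
    return m // 2


def edge_comparison(
    peak: ChromPeak,
    window: int,
    series: ScanSeries,
    mz_tolerance: float = 10.0,
) -> DifferenceSet:
    """Leading vs. trailing edge of one peak.

    Averages the first ``window`` scans and the last ``window`` scans of the
    peak's block and computes their difference set.  For a homogeneous peak
    this measures within-run reproducibility; for co-eluting isomers the two
    edges sample different mixtures and the difference is inflated.
    """
    if 2 * window > peak.n_scans:
        raise ValueError(
            f"window {window} too large for peak {peak.key} of {peak.n_scans} scans"
        )
    lead = average_scans(series, (peak.scan_start, peak.scan_start + window - 1), mz_tolerance)
    trail = average_scans(series, (peak.scan_end - window + 1, peak.scan_end), mz_tolerance)
    return observed_mean_between(lead, trail, mz_tolerance)


def lc_hypothesized_mean(
    edge_means: list[float] | np.ndarray, rule: str = "mean_plus_3sd", k_sd: float = 3.0
) -> HypothesizedMean:
    """Hypothesized mean from single-peak edge means.

    ``mean_plus_3sd`` suits simple mixtures whose single peaks are all
    trustworthy replicates; ``upper_quartile`` (75th percentile, linear
    interpolation) is robust for complex samples where some apparently
    single peaks may hide isomers and would inflate the mean and SD.
    """
    means = np.asarray(edge_means, dtype=float)
    if rule == "mean_plus_3sd":
        if means.size < 2:
            raise ValueError("need >= 2 edge means for mean_plus_3sd")
        from .inference import hypothesized_mean_from_replicates

        return hypothesized_mean_from_replicates(means, k_sd=k_sd)
    if rule == "upper_quartile":
        if means.size < 4:
            raise ValueError("need >= 4 edge means for upper_quartile")
        return HypothesizedMean(
            value=float(np.quantile(means, 0.75)),
            rule="upper_quartile",
            replicate_means=[float(m) for m in means],
        )
    raise ValueError("rule must be 'mean_plus_3sd' or 'upper_quartile'")


def _center_range(peak: ChromPeak, window: int) -> tuple[int, int]:
    # apex-centred; for even windows the extra scan falls on the left
    start = peak.apex_index - (window // 2)
    start = max(peak.scan_start, min(start, peak.scan_end - window + 1))
    return start, start + window - 1


def compare_peaks(
    peak_x: ChromPeak,
    peak_y: ChromPeak,
    window: int,
    mu0: HypothesizedMean,
    series: ScanSeries,
    alpha: float = 0.05,
    mz_tolerance: float = 10.0,
) -> ComparisonResult:
    """Compare apex-centred windows of two peaks against the hypothesized mean."""
    for p in (peak_x, peak_y):
        if window > p.n_scans:
            raise ValueError(f"window {window} exceeds peak {p.key} of {p.n_scans} scans")
    if (
        peak_x.precursor_mz is not None
        and peak_y.precursor_mz is not None
        and abs(peak_x.precursor_mz - peak_y.precursor_mz)
        > peak_x.precursor_mz * mz_tolerance * 1e-6
    ):
        raise ValueError("peaks have different precursor masses; not comparable")
    cx = average_scans(series, _center_range(peak_x, window), mz_tolerance)
    cy = average_scans(series, _center_range(peak_y, window), mz_tolerance)
    diffs = observed_mean_between(cx, cy, mz_tolerance)
    return one_sample_test(diffs, mu0, alpha=alpha, label=f"{peak_x.key} vs {peak_y.key}")


@dataclass
class PeakClassification:
    """One classified outcome (a single peak or a peak pair)."""

    category: str
    peak_refs: list[ChromPeak]
    supporting: list[ComparisonResult]

    def to_row(self) -> dict:
        r = self.supporting[0]
        return {
            "category": self.category,
            "peaks": " | ".join(p.key for p in self.peak_refs),
            "observed_mean": r.observed_mean,
            "hypothesized_mean": r.hypothesized_mean.value,
            "p_value": r.p_value_t,
            "stars": r.stars,
        }


def classify_peaks(
    groups: dict[str, list[ChromPeak]],
    edge_results: dict[str, ComparisonResult],
    cross_results: dict[tuple[str, str], ComparisonResult],
    alpha: float = 0.05,
) -> list[PeakClassification]:
    """Apply the peak-outcome decision table.

    ``groups`` maps peptide label to its peaks; ``edge_results`` maps a peak
    key to its edge self-comparison; ``cross_results`` maps ordered key
    pairs of same-peptide peaks to their centre-window comparison.  Every
    single-elution peptide must have an edge result and every multi-peak
    peptide all pairwise cross results.
    """
    out: list[PeakClassification] = []
    for label, peaks in groups.items():
        if len(peaks) == 1:
            p = peaks[0]
            if p.key not in edge_results:
                raise ValueError(f"missing edge comparison for single peak {p.key}")
            r = edge_results[p.key]
            cat = CATEGORY_COELUTING if r.p_value_t < alpha else CATEGORY_NON_ISOMER
            out.append(PeakClassification(category=cat, peak_refs=[p], supporting=[r]))
        else:
            for i in range(len(peaks)):
                for j in range(i + 1, len(peaks)):
                    a, b = peaks[i], peaks[j]
                    r = cross_results.get((a.key, b.key)) or cross_results.get(
                        (b.key, a.key)
                    )
                    if r is None:
                        raise ValueError(
                            f"missing cross comparison for pair {a.key} / {b.key}"
                        )
                    cat = CATEGORY_CONFIRMED if r.p_value_t < alpha else CATEGORY_UNCONFIRMED
                    out.append(
                        PeakClassification(category=cat, peak_refs=[a, b], supporting=[r])
                    )
    return out


@dataclass
class ScreenResult:
    """Full outcome of an LC-MS isomer screen."""

    window: int
    mu0: HypothesizedMean
    edge_results: dict[str, ComparisonResult]
    cross_results: dict[tuple[str, str], ComparisonResult]
    classifications: list[PeakClassification]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([c.to_row() for c in self.classifications])

    def to_json(self) -> str:
        return json.dumps(
            {
                "window": self.window,
                "hypothesized_mean": {
                    "value": self.mu0.value,
                    "rule": self.mu0.rule,
                    "edge_means": self.mu0.replicate_means,
                },
                "edge_comparisons": {k: r.to_dict() for k, r in self.edge_results.items()},
                "cross_comparisons": {
                    f"{a} | {b}": r.to_dict() for (a, b), r in self.cross_results.items()
                },
                "classifications": [c.to_row() for c in self.classifications],
            },
            indent=2,
        )


def screen(
    series: ScanSeries,
    peaks: list[ChromPeak],
    rule: str = "mean_plus_3sd",
    alpha: float = 0.05,
    mz_tolerance: float = 10.0,
    mu0: HypothesizedMean | None = None,
) -> ScreenResult:
    """Run the complete LC-MS isomer screen on one run.

    Computes the global scan window, the edge self-comparison of every peak,
    the hypothesized mean from the edge means of single-elution peaks
    (unless ``mu0`` is supplied), the all-vs-all centre comparisons within
    each multi-peak peptide (each unordered pair once), and the final
    classification.
    """
    window = scan_window(peaks)
    groups: dict[str, list[ChromPeak]] = {}
    for p in peaks:
        groups.setdefault(p.peptide_label, []).append(p)

    edge_results: dict[str, ComparisonResult] = {}
    edge_means_single: list[float] = []
    edge_sets: dict[str, DifferenceSet] = {}
    for p in peaks:
        d = edge_comparison(p, window, series, mz_tolerance)
        edge_sets[p.key] = d
        if len(groups[p.peptide_label]) == 1:
            edge_means_single.append(d.observed_mean)

    if mu0 is None:
        mu0 = lc_hypothesized_mean(edge_means_single, rule=rule)

    for p in peaks:
        edge_results[p.key] = one_sample_test(
            edge_sets[p.key], mu0, alpha=alpha, label=f"{p.key} edges"
        )

    cross_results: dict[tuple[str, str], ComparisonResult] = {}
    for label, group in groups.items():
        for i in range(len(group)):
            for j in range(i + 1, len(group)):
                a, b = group[i], group[j]
                cross_results[(a.key, b.key)] = compare_peaks(
                    a, b, window, mu0, series, alpha=alpha, mz_tolerance=mz_tolerance
                )

    classifications = classify_peaks(groups, edge_results, cross_results, alpha=alpha)
    return ScreenResult(
        window=window,
        mu0=mu0,
        edge_results=edge_results,
        cross_results=cross_results,
        classifications=classifications,
    )
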