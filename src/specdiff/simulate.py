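"""Synthetic MS/MS data with the statistical structure the method assumes.

The noise model is log-normal total-ion-current drift (source fluctuation)
times multinomial allocation of ions to fragment channels (competition
between dissociation channels).  Multinomial allocation reproduces the
near-zero-sum behaviour of fractional abundances — counts lost by one
channel appear in others — and makes the replicate floor of the observed
mean scale like 1/sqrt(TIC).

Isomers are emulated as zero-sum perturbations of a fractional-abundance
vector: a fixed total abundance is moved from donor channels to acceptor
channels, mirroring how isomerized residues repartition dissociation
channels without creating new fragment masses.

Defaults (20 channels, TIC 1e6, TIC RSD 10%, 100 scans, effect 0.05 over 4
channels) emulate a stable direct-infusion acquisition: 100 scans per run,
TIC drift below the 15% stability gate, and an isomer effect small enough
that spectra look nearly identical by eye.

Channels are abstract m/z slots (default grid 200, 225, ... Th); no
fragmentation chemistry is modelled.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .diffs import FAVector
from .io import ScanSeries, Spectrum

DEFAULT_N_CHANNELS = 20
DEFAULT_TIC_MEAN = 1e6
DEFAULT_TIC_RSD = 10.0
DEFAULT_N_SCANS = 100
DEFAULT_EFFECT_SIZE = 0.05
DEFAULT_N_AFFECTED = 4
DEFAULT_CONCENTRATION = 5.0


@dataclass
class SyntheticConfig:
    """Parameters of the default direct-infusion generator."""

    n_channels: int = DEFAULT_N_CHANNELS
    effect_size: float = DEFAULT_EFFECT_SIZE
    n_affected: int = DEFAULT_N_AFFECTED
    n_scans: int = DEFAULT_N_SCANS
    tic_mean: float = DEFAULT_TIC_MEAN
    tic_rsd: float = DEFAULT_TIC_RSD
    concentration: float = DEFAULT_CONCENTRATION
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.effect_size < 1.0:
            raise ValueError("effect_size must lie in [0, 1)")
        if self.n_affected < 2 or self.n_affected % 2:
            raise ValueError("n_affected must be an even number >= 2")
        if self.tic_rsd < 0:
            raise ValueError("tic_rsd must be non-negative")


def channel_grid(n_channels: int, start: float = 200.0, spacing: float = 25.0) -> np.ndarray:
    """Abstract fragment m/z slots, well separated relative to ppm tolerances."""
    return start + spacing * np.arange(n_channels, dtype=float)


def draw_fa_vector(
    n_channels: int = DEFAULT_N_CHANNELS,
    concentration: float = DEFAULT_CONCENTRATION,
    seed: int | np.random.Generator = 0,
) -> FAVector:
    """Random fractional-abundance vector: a symmetric Dirichlet draw.

    ``concentration`` is the per-channel Dirichlet parameter; large values
    approach the uniform vector, small values produce spiky spectra.
    """
    if n_channels < 2:
        raise ValueError("need at least 2 channels")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    values = rng.dirichlet(np.full(n_channels, float(concentration)))
    return FAVector(values=values, channel_mz=channel_grid(n_channels))


def perturb_isomer(
    fa: FAVector,
    effect_size: float = DEFAULT_EFFECT_SIZE,
    n_affected: int = DEFAULT_N_AFFECTED,
    seed: int | np.random.Generator = 0,
) -> FAVector:
    """Zero-sum isomer perturbation of an FA vector.

    Moves ``effect_size`` total abundance off ``n_affected/2`` randomly
    chosen donor channels onto ``n_affected/2`` acceptor channels (equal
    share each), so the output still sums to 1.  Donors are drawn only from
    channels that can afford their share without going negative.
    """
    if n_affected < 2 or n_affected % 2:
        raise ValueError("n_affected must be an even number >= 2")
    if n_affected > fa.n_channels:
        raise ValueError("n_affected exceeds the number of channels")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    half = n_affected // 2
    share = effect_size / half
    eligible = np.flatnonzero(fa.values > share)
    if eligible.size < half:
        raise ValueError("not enough abundance on donor channels for this effect size")
    donors = rng.choice(eligible, size=half, replace=False)
    rest = np.setdiff1d(np.arange(fa.n_channels), donors)
    acceptors = rng.choice(rest, size=half, replace=False)
    values = fa.values.copy()
    values[donors] -= share
    values[acceptors] += share
    return FAVector(values=values, channel_mz=fa.channel_mz.copy())


def mixture_fa(fa_a: FAVector, fa_b: FAVector, x: float) -> FAVector:
    """Convex combination ``(1-x)*fa_a + x*fa_b`` (x = fraction of B)."""
    if not 0.0 <= x <= 1.0:
        raise ValueError("mixture fraction must lie in [0, 1]")
    if fa_a.n_channels != fa_b.n_channels or not np.allclose(fa_a.channel_mz, fa_b.channel_mz):
        raise ValueError("FA vectors must share the same channels")
    return FAVector(
        values=(1.0 - x) * fa_a.values + x * fa_b.values,
        channel_mz=fa_a.channel_mz.copy(),
    )


def _lognormal_tics(
    rng: np.random.Generator, n: int, tic_mean: float, tic_rsd: float
) -> np.ndarray:
    if tic_rsd == 0.0:
        return np.full(n, tic_mean)
    cv = tic_rsd / 100.0
    sigma2 = np.log1p(cv * cv)
    mu = np.log(tic_mean) - 0.5 * sigma2
    return rng.lognormal(mean=mu, sigma=np.sqrt(sigma2), size=n)


def simulate_scans(
    fa: FAVector,
    n_scans: int = DEFAULT_N_SCANS,
    tic_mean: float = DEFAULT_TIC_MEAN,
    tic_rsd: float = DEFAULT_TIC_RSD,
    seed: int | np.random.Generator = 0,
    scan_id_start: int = 0,
    source_label: str = "synthetic",
) -> ScanSeries:
    """Replicate MS2 scans of one analyte.

    Per scan, the total ion count is drawn log-normally with the stated mean
    and RSD (percent), then allocated to channels by a multinomial draw with
    probabilities ``fa``.  Channels receiving zero ions are absent from that
    scan, as they would be in centroided data.
    """
    if tic_mean < 1000:
        raise ValueError("tic_mean must be >= 1000 (ion-counting regime)")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    tics = np.rint(_lognormal_tics(rng, n_scans, tic_mean, tic_rsd)).astype(np.int64)
    spectra = []
    for k, total in enumerate(tics):
        counts = rng.multinomial(int(total), fa.values)
        present = counts > 0
        spectra.append(
            Spectrum(
                mz=fa.channel_mz[present],
                intensity=counts[present].astype(float),
                scan_id=scan_id_start + k,
            )
        )
    return ScanSeries(spectra, source_label=source_label)


def replicate_pair(
    config: SyntheticConfig, fa: FAVector | None = None
) -> tuple[ScanSeries, ScanSeries]:
    """Two independent scan series of the same analyte under ``config``."""
    rng = np.random.default_rng(config.seed)
    if fa is None:
        fa = draw_fa_vector(config.n_channels, config.concentration, rng)
    a = simulate_scans(fa, config.n_scans, config.tic_mean, config.tic_rsd, rng)
    b = simulate_scans(fa, config.n_scans, config.tic_mean, config.tic_rsd, rng)
    return a, b


def isomer_pair(config: SyntheticConfig) -> tuple[ScanSeries, ScanSeries, FAVector, FAVector]:
    """Scan series of an analyte and of its perturbed isomer under ``config``."""
    rng = np.random.default_rng(config.seed)
    fa_a = draw_fa_vector(config.n_channels, config.concentration, rng)
    fa_b = perturb_isomer(fa_a, config.effect_size, config.n_affected, rng)
    a = simulate_scans(fa_a, config.n_scans, config.tic_mean, config.tic_rsd, rng)
    b = simulate_scans(fa_b, config.n_scans, config.tic_mean, config.tic_rsd, rng)
    return a, b, fa_a, fa_b


# ---------------------------------------------------------------------------
# chromatograms


@dataclass
class ElutionPeak:
    """One analyte's elution profile: Gaussian envelope over a scan block.

    ``apex_frac`` places the envelope apex within the block (0.5 = centred);
    ``width_scans`` is the Gaussian sigma in scans.
    """

    label: str
    fa: FAVector
    n_scans: int
    width_scans: float
    apex_frac: float = 0.5
    precursor_mz: float = 500.0
    charge: int = 2

    def __post_init__(self) -> None:
        if self.n_scans < 4:
            raise ValueError("each elution peak needs at least 4 scans")


@dataclass
class ChromSpec:
    """A synthetic LC-MS run: elution peaks plus declared co-elutions.

    ``co_elution`` lists index pairs of ``peaks`` that overlap under one
    apparent chromatographic peak; the pair is merged into a single scan
    block whose per-scan FA is the envelope-weighted mixture of the two
    components.  All other peaks elute separately.
    """

    peaks: list[ElutionPeak]
    co_elution: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen: set[int] = set()
        for i, j in self.co_elution:
            if i in seen or j in seen:
                raise ValueError("a peak may appear in at most one co-elution pair")
            seen.update((i, j))


def _envelope(n: int, apex_frac: float, width: float) -> np.ndarray:
    s = np.arange(n, dtype=float)
    return np.exp(-0.5 * ((s - apex_frac * (n - 1)) / width) ** 2)


def simulate_chromatogram(
    spec: ChromSpec,
    tic_mean: float = DEFAULT_TIC_MEAN,
    tic_rsd: float = DEFAULT_TIC_RSD,
    seed: int | np.random.Generator = 0,
    scan_interval: float = 1.0,
) -> tuple[ScanSeries, pd.DataFrame]:
    """Simulate an LC-MS/MS run and return (scan series, ground-truth peak table).

    Each observed chromatographic peak occupies a contiguous block of MS2
    scans.  The apex-scan TIC equals ``tic_mean``; the Gaussian envelope
    scales the expected TIC of the other scans, with log-normal noise on
    top.  Declared co-eluting pairs produce one merged block whose FA drifts
    from the first component toward the second across the elution profile.

    The peak table has one row per observed peak: ``peptide_label,
    precursor_mz, charge, scan_start, scan_end, rt_apex, truth`` where
    ``truth`` is ``single`` or ``coeluting`` (ground truth for harnesses).
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed

    merged_members = {i for pair in spec.co_elution for i in pair}
    blocks: list[tuple[list[int], str]] = []
    for idx in range(len(spec.peaks)):
        if idx in merged_members:
            continue
        blocks.append(([idx], "single"))
    for i, j in spec.co_elution:
        blocks.append(([i, j], "coeluting"))
    # keep declaration order of the first member
    blocks.sort(key=lambda b: b[0][0])

    spectra = []
    rows = []
    scan_cursor = 0
    for members, truth in blocks:
        lead = spec.peaks[members[0]]
        n = max(spec.peaks[m].n_scans for m in members)
        envs = np.array(
            [
                _envelope(n, spec.peaks[m].apex_frac, spec.peaks[m].width_scans)
                for m in members
            ]
        )
        total_env = envs.sum(axis=0)
        total_env /= total_env.max()
        weights = envs / envs.sum(axis=0, keepdims=True)
        fas = np.array([spec.peaks[m].fa.values for m in members])
        noise = _lognormal_tics(rng, n, 1.0, tic_rsd)
        apex_scan = scan_cursor + int(np.argmax(total_env))
        for k in range(n):
            fa_k = weights[:, k] @ fas
            total = int(round(tic_mean * total_env[k] * noise[k]))
            total = max(total, 100)  # keep tail scans non-empty
            counts = rng.multinomial(total, fa_k)
            present = counts > 0
            gid = scan_cursor + k
            spectra.append(
                Spectrum(
                    mz=lead.fa.channel_mz[present],
                    intensity=counts[present].astype(float),
                    scan_id=gid,
                    retention_time=gid * scan_interval,
                    precursor_mz=lead.precursor_mz,
                    precursor_charge=lead.charge,
                )
            )
        rows.append(
            {
                "peptide_label": lead.label,
                "precursor_mz": lead.precursor_mz,
                "charge": lead.charge,
                "scan_start": scan_cursor,
                "scan_end": scan_cursor + n - 1,
                "rt_apex": apex_scan * scan_interval,
                "truth": truth,
            }
        )
        scan_cursor += n

    return ScanSeries(spectra, source_label="synthetic-lc"), pd.DataFrame(rows)


def default_lc_scenario(seed: int = 0) -> ChromSpec:
    """The standard validation chromatogram: all four peak-level outcomes.

    One peptide elutes twice as resolved isomers (a confirmed-isomer pair),
    four peptides elute once as homogeneous peaks (non-isomers), and one
    peptide hides a co-eluting isomer pair under a single apparent peak.
    Peak widths vary modestly; every block carries at least 144 scans so
    the half-minimum scan window is well defined.
    """
    rng = np.random.default_rng(seed)
    conc = DEFAULT_CONCENTRATION
    nch = DEFAULT_N_CHANNELS

    def fa():
        return draw_fa_vector(nch, conc, rng)

    def iso(f):
        return perturb_isomer(f, DEFAULT_EFFECT_SIZE, DEFAULT_N_AFFECTED, rng)

    fa_p1 = fa()
    fa_p6 = fa()
    peaks = [
        ElutionPeak("P1", fa_p1, n_scans=200, width_scans=36.0, precursor_mz=450.0),
        ElutionPeak("P1", iso(fa_p1), n_scans=180, width_scans=32.0, precursor_mz=450.0),
        ElutionPeak("P2", fa(), n_scans=160, width_scans=30.0, precursor_mz=500.0),
        ElutionPeak("P3", fa(), n_scans=150, width_scans=28.0, precursor_mz=550.0),
        ElutionPeak("P4", fa(), n_scans=144, width_scans=26.0, precursor_mz=600.0),
        ElutionPeak("P5", fa(), n_scans=170, width_scans=30.0, precursor_mz=650.0),
        # co-eluting pair: same apparent peak, apexes offset by ~2/3 sigma each way
        ElutionPeak("P6", fa_p6, n_scans=180, width_scans=30.0, apex_frac=0.38,
                    precursor_mz=700.0),
        ElutionPeak("P6", iso(fa_p6), n_scans=180, width_scans=30.0, apex_frac=0.62,
                    precursor_mz=700.0),
    ]
    return ChromSpec(peaks=peaks, co_elution=[(6, 7)])


def write_ground_truth(path: str, spec: ChromSpec, table: pd.DataFrame, seed: int) -> None:
    """Persist planted FA vectors and categories alongside generated data."""
    truth = {
        "seed": seed,
        "peaks": [
            {
                "label": p.label,
                "fa": [float(v) for v in p.fa.values],
                "channel_mz": [float(m) for m in p.fa.channel_mz],
                "n_scans": p.n_scans,
                "width_scans": p.width_scans,
                "apex_frac": p.apex_frac,
            }
            for p in spec.peaks
        ],
        "co_elution": [list(pair) for pair in spec.co_elution],
        "observed_peaks": table.to_dict(orient="records"),
    }
    with open(path, "w") as fh:
        json.dump(truth, fh, indent=2)
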