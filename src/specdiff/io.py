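"""Centroided MS/MS spectrum containers and I/O.

Spectra are held as sorted (m/z, intensity) arrays.  Readers accept mzML
(MS-level-2 scans), MGF, and plain CSV/TSV peak tables with columns
``scan, mz, intensity`` plus optional ``rt`` and ``precursor_mz``.  Only
centroided data are accepted; profile mzML scans raise :class:`FormatError`.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd


class FormatError(ValueError):
    """Raised when an input file cannot be parsed as the named format."""


class Peak(NamedTuple):
    """A single centroided peak: m/z in Thomson, intensity in counts."""

    mz: float
    intensity: float


@dataclass
class Spectrum:
    """One centroided MS2 scan.

    Parameters
    ----------
    mz, intensity
        Parallel arrays sorted by strictly increasing m/z; intensities are
        non-negative ion counts (arbitrary units).
    scan_id
        Acquisition-order scan index.
    retention_time
        Seconds, optional.
    precursor_mz, precursor_charge
        Isolation target, optional.
    """

    mz: np.ndarray
    intensity: np.ndarray
    scan_id: int = 0
    retention_time: float | None = None
    precursor_mz: float | None = None
    precursor_charge: int | None = None

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.mz.shape != self.intensity.shape or self.mz.ndim != 1:
            raise ValueError("mz and intensity must be 1-D arrays of equal length")
        if self.mz.size and np.any(self.mz <= 0):
            raise ValueError("all m/z values must be positive")
        if np.any(self.intensity < 0):
            raise ValueError("negative intensity encountered")
        if self.mz.size > 1 and np.any(np.diff(self.mz) <= 0):
            raise ValueError("peaks must be sorted by strictly increasing m/z")

    @property
    def tic(self) -> float:
        """Total ion current: summed intensity of the scan."""
        return float(self.intensity.sum())

    @property
    def peaks(self) -> list[Peak]:
        return [Peak(m, i) for m, i in zip(self.mz, self.intensity)]

    def __len__(self) -> int:
        return self.mz.size


@dataclass
class ScanSeries:
    """An ordered collection of MS2 scans from one acquisition.

    ``acquisition_params`` records instrument settings (isolation width,
    activation energy, resolution, ...) so that runs compared against each
    other can be audited for matched conditions.
    """

    spectra: list[Spectrum]
    source_label: str = ""
    acquisition_params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = [s.scan_id for s in self.spectra]
        if any(b <= a for a, b in zip(ids, ids[1:])):
            raise ValueError("scan_id must be strictly increasing")
        rts = [s.retention_time for s in self.spectra if s.retention_time is not None]
        if any(b < a for a, b in zip(rts, rts[1:])):
            raise ValueError("retention times must be non-decreasing")

    def __len__(self) -> int:
        return len(self.spectra)

    def __getitem__(self, i):
        return self.spectra[i]

    def tics(self) -> np.ndarray:
        return np.array([s.tic for s in self.spectra])


@dataclass
class FragmentPanel:
    """Fragment channels present in both of two spectra.

    ``channel_mz`` is the per-channel representative m/z (mean of the paired
    peak positions); ``intensities_a``/``intensities_b`` are the per-channel
    intensities from spectrum A and B.
    """

    channel_mz: np.ndarray
    intensities_a: np.ndarray
    intensities_b: np.ndarray

    def __post_init__(self) -> None:
        self.channel_mz = np.asarray(self.channel_mz, dtype=float)
        self.intensities_a = np.asarray(self.intensities_a, dtype=float)
        self.intensities_b = np.asarray(self.intensities_b, dtype=float)
        n = self.channel_mz.size
        if self.intensities_a.size != n or self.intensities_b.size != n:
            raise ValueError("panel arrays must have equal length")
        if n < 2:
            raise ValueError("panel too small for statistics")
        if np.any(np.diff(self.channel_mz) <= 0):
            raise ValueError("channel_mz must be strictly increasing")
        if np.any(self.intensities_a < 0) or np.any(self.intensities_b < 0):
            raise ValueError("negative intensity in panel")

    @property
    def n_channels(self) -> int:
        return self.channel_mz.size


# ---------------------------------------------------------------------------
# readers / writers

_CSV_REQUIRED = ("scan", "mz", "intensity")


def _infer_format(path: str) -> str:
    ext = os.path.splitext(path)[1].lower()
    return {".mzml": "mzml", ".mgf": "mgf", ".csv": "csv", ".tsv": "csv", ".txt": "csv"}.get(
        ext, "csv"
    )


def read_spectra(path: str, format: str | None = None) -> ScanSeries:
    """Read all MS2 scans from ``path`` in acquisition order.

    ``format`` is one of ``mzml``, ``mgf``, ``csv``; inferred from the file
    extension when omitted.  Raises :class:`FormatError` for unparseable
    files and when no MS2 scans are found.
    """
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    fmt = format or _infer_format(path)
    if fmt == "csv":
        series = _read_csv(path)
    elif fmt == "mgf":
        series = _read_mgf(path)
    elif fmt == "mzml":
        series = _read_mzml(path)
    else:
        raise ValueError(f"unknown format {fmt!r}")
    if not series.spectra:
        raise FormatError(f"{path}: no MS2 scans found")
    return series


def _read_csv(path: str) -> ScanSeries:
    sep = "\t" if path.lower().endswith(".tsv") else ","
    try:
        df = pd.read_csv(path, sep=sep)
    except Exception as exc:  # pragma: no cover - delegated parse errors
        raise FormatError(f"{path}: {exc}") from exc
    missing = [c for c in _CSV_REQUIRED if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required columns {missing}")
    spectra = []
    for scan_id, grp in df.groupby("scan", sort=True):
        grp = grp.sort_values("mz")
        try:
            spectra.append(
                Spectrum(
                    mz=grp["mz"].to_numpy(),
                    intensity=grp["intensity"].to_numpy(),
                    scan_id=int(scan_id),
                    retention_time=float(grp["rt"].iloc[0]) if "rt" in grp else None,
                    precursor_mz=float(grp["precursor_mz"].iloc[0])
                    if "precursor_mz" in grp
                    else None,
                )
            )
        except ValueError as exc:
            raise FormatError(f"{path}: scan {scan_id}: {exc}") from exc
    return ScanSeries(spectra, source_label=os.path.basename(path))


def _read_mgf(path: str) -> ScanSeries:
    from pyteomics import mgf

    spectra = []
    try:
        with mgf.read(path) as reader:
            for i, entry in enumerate(reader):
                params = entry.get("params", {})
                pep = params.get("pepmass")
                charge = params.get("charge")
                order = np.argsort(entry["m/z array"])
                spectra.append(
                    Spectrum(
                        mz=np.asarray(entry["m/z array"])[order],
                        intensity=np.asarray(entry["intensity array"])[order],
                        scan_id=int(params.get("scans", i)),
                        retention_time=float(params["rtinseconds"])
                        if "rtinseconds" in params
                        else None,
                        precursor_mz=float(pep[0]) if pep else None,
                        precursor_charge=int(charge[0]) if charge else None,
                    )
                )
    except (ValueError, KeyError) as exc:
        raise FormatError(f"{path}: {exc}") from exc
    return ScanSeries(spectra, source_label=os.path.basename(path))


def _read_mzml(path: str) -> ScanSeries:
    from pyteomics import mzml

    spectra = []
    try:
        with mzml.read(path) as reader:
            for i, entry in enumerate(reader):
                if entry.get("ms level") != 2:
                    continue
                if "profile spectrum" in entry:
                    raise FormatError(
                        f"{path}: scan {i}: profile data not supported; centroid first"
                    )
                prec_mz = prec_z = None
                try:
                    ion = entry["precursorList"]["precursor"][0]["selectedIonList"][
                        "selectedIon"
                    ][0]
                    prec_mz = float(ion.get("selected ion m/z"))
                    if "charge state" in ion:
                        prec_z = int(ion["charge state"])
                except (KeyError, IndexError, TypeError):
                    pass
                rt = None
                for cv in entry.get("scanList", {}).get("scan", [{}]):
                    if "scan start time" in cv:
                        t = cv["scan start time"]
                        # pyteomics yields minutes (unitfloat) for most files
                        rt = float(t) * 60.0 if getattr(t, "unit_info", "") == "minute" else float(t)
                order = np.argsort(entry["m/z array"])
                spectra.append(
                    Spectrum(
                        mz=np.asarray(entry["m/z array"])[order],
                        intensity=np.asarray(entry["intensity array"])[order],
                        scan_id=int(entry.get("index", i)),
                        retention_time=rt,
                        precursor_mz=prec_mz,
                        precursor_charge=prec_z,
                    )
                )
    except FormatError:
        raise
    except Exception as exc:
        raise FormatError(f"{path}: {exc}") from exc
    return ScanSeries(spectra, source_label=os.path.basename(path))


def write_spectra_csv(series: ScanSeries, path: str) -> None:
    """Write a scan series as a canonical CSV peak table (full precision)."""
    rows = []
    for s in series.spectra:
        for m, i in zip(s.mz, s.intensity):
            row = {"scan": int(s.scan_id), "mz": repr(float(m)), "intensity": repr(float(i))}
            if s.retention_time is not None:
                row["rt"] = repr(float(s.retention_time))
            if s.precursor_mz is not None:
                row["precursor_mz"] = repr(float(s.precursor_mz))
            rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# quality control


def tic_rsd(series: ScanSeries) -> float:
    """Relative standard deviation of the per-scan total ion current, percent.

    Uses the sample standard deviation (n-1 denominator).  Spray stability
    is conventionally accepted when this is below 15%.
    """
    if len(series) < 2:
        raise ValueError("insufficient scans for RSD")
    tics = series.tics()
    return float(100.0 * tics.std(ddof=1) / tics.mean())


def tic_stable(series: ScanSeries, threshold: float = 15.0) -> bool:
    """True when the TIC RSD is below ``threshold`` percent (default 15)."""
    return tic_rsd(series) < threshold


# ---------------------------------------------------------------------------
# averaging, top-N extraction, channel matching


def average_scans(
    series: ScanSeries,
    scan_range: tuple[int, int] | None = None,
    mz_tolerance: float = 10.0,
) -> Spectrum:
    """Average scans ``scan_range`` (inclusive positional indices) into one spectrum.

    Peaks within ``mz_tolerance`` ppm across scans are merged into a single
    channel.  The channel intensity is the arithmetic mean over the selected
    scans, with scans lacking the channel contributing zero, so the result is
    invariant to the number of scans averaged.  The channel m/z is the
    intensity-weighted mean of the merged peak positions.
    """
    if scan_range is None:
        scan_range = (0, len(series) - 1)
    lo, hi = scan_range
    if lo < 0 or hi >= len(series) or hi < lo:
        raise ValueError(f"scan range {scan_range} outside series of {len(series)} scans")
    selected = series.spectra[lo : hi + 1]
    n = len(selected)
    if n == 1:
        return selected[0]

    all_mz = np.concatenate([s.mz for s in selected])
    all_int = np.concatenate([s.intensity for s in selected])
    order = np.argsort(all_mz, kind="stable")
    all_mz, all_int = all_mz[order], all_int[order]

    # greedy single-pass clustering: extend the current channel while the next
    # peak lies within tolerance of the channel's intensity-weighted mean m/z
    ch_mz: list[float] = []
    ch_int: list[float] = []
    cur_wsum = cur_isum = 0.0
    cur_mean = -np.inf
    for m, i in zip(all_mz, all_int):
        if cur_isum > 0 and (m - cur_mean) <= cur_mean * mz_tolerance * 1e-6:
            cur_wsum += m * i
            cur_isum += i
            if cur_isum > 0:
                cur_mean = cur_wsum / cur_isum
        else:
            if cur_isum > 0:
                ch_mz.append(cur_mean)
                ch_int.append(cur_isum)
            cur_wsum, cur_isum, cur_mean = m * i, i, m
    if cur_isum > 0:
        ch_mz.append(cur_mean)
        ch_int.append(cur_isum)

    first = selected[0]
    return Spectrum(
        mz=np.array(ch_mz),
        intensity=np.array(ch_int) / n,
        scan_id=first.scan_id,
        retention_time=first.retention_time,
        precursor_mz=first.precursor_mz,
        precursor_charge=first.precursor_charge,
    )


def extract_top_fragments(
    spectrum: Spectrum,
    n_top: int = 25,
    exclude_windows: Sequence[tuple[float, float]] = (),
) -> Spectrum:
    """Keep the ``n_top`` most intense peaks outside all excluded m/z windows.

    ``exclude_windows`` is a list of (low, high) m/z intervals, typically a
    +/- 2 Th window around the precursor to remove the surviving precursor
    ion.  If fewer than ``n_top`` peaks remain, all are kept.
    """
    if n_top < 2:
        raise ValueError("n_top must be >= 2")
    keep = np.ones(len(spectrum), dtype=bool)
    for lo, hi in exclude_windows:
        keep &= ~((spectrum.mz >= lo) & (spectrum.mz <= hi))
    if not keep.any():
        raise ValueError("no fragments remain after exclusion")
    mz, inten = spectrum.mz[keep], spectrum.intensity[keep]
    if mz.size > n_top:
        top = np.argsort(inten, kind="stable")[-n_top:]
        top.sort()  # restore ascending m/z
        mz, inten = mz[top], inten[top]
    return Spectrum(
        mz=mz,
        intensity=inten,
        scan_id=spectrum.scan_id,
        retention_time=spectrum.retention_time,
        precursor_mz=spectrum.precursor_mz,
        precursor_charge=spectrum.precursor_charge,
    )


def precursor_window(spectrum: Spectrum, half_width: float = 2.0) -> list[tuple[float, float]]:
    """Exclusion window of +/- ``half_width`` Th around the precursor, if known."""
    if spectrum.precursor_mz is None:
        return []
    return [(spectrum.precursor_mz - half_width, spectrum.precursor_mz + half_width)]


def match_channels(
    spec_a: Spectrum,
    spec_b: Spectrum,
    mz_tolerance: float = 10.0,
    tolerance_unit: str = "ppm",
    unmatched: str = "drop",
) -> FragmentPanel:
    """Pair fragment channels between two spectra.

    Peaks are paired greedily by smallest m/z gap within ``mz_tolerance``
    (``ppm`` by default; ``th`` for an absolute window, e.g. ion-trap data),
    each peak used at most once.  By default only channels present in BOTH
    spectra are kept (common-ion policy); ``unmatched="zero_fill"`` instead
    keeps unmatched peaks with zero intensity on the missing side.
    """
    if len(spec_a) == 0 or len(spec_b) == 0:
        raise ValueError("cannot match channels of an empty spectrum")
    if tolerance_unit not in ("ppm", "th"):
        raise ValueError("tolerance_unit must be 'ppm' or 'th'")

    pairs = []  # (gap, ia, ib)
    j0 = 0
    for ia, ma in enumerate(spec_a.mz):
        tol = ma * mz_tolerance * 1e-6 if tolerance_unit == "ppm" else mz_tolerance
        # advance lower bound in b
        while j0 < len(spec_b) and spec_b.mz[j0] < ma - tol:
            j0 += 1
        j = j0
        while j < len(spec_b) and spec_b.mz[j] <= ma + tol:
            pairs.append((abs(spec_b.mz[j] - ma), ia, j))
            j += 1
    pairs.sort()
    used_a: set[int] = set()
    used_b: set[int] = set()
    matched: list[tuple[float, float, float]] = []
    for _, ia, ib in pairs:
        if ia in used_a or ib in used_b:
            continue
        used_a.add(ia)
        used_b.add(ib)
        matched.append(
            (
                0.5 * (spec_a.mz[ia] + spec_b.mz[ib]),
                spec_a.intensity[ia],
                spec_b.intensity[ib],
            )
        )
    if unmatched == "zero_fill":
        for ia in range(len(spec_a)):
            if ia not in used_a:
                matched.append((spec_a.mz[ia], spec_a.intensity[ia], 0.0))
        for ib in range(len(spec_b)):
            if ib not in used_b:
                matched.append((spec_b.mz[ib], 0.0, spec_b.intensity[ib]))
    elif unmatched != "drop":
        raise ValueError("unmatched must be 'drop' or 'zero_fill'")

    matched.sort()
    if len(matched) < 2:
        raise ValueError("panel too small for statistics")
    arr = np.array(matched)
    return FragmentPanel(channel_mz=arr[:, 0], intensities_a=arr[:, 1], intensities_b=arr[:, 2])
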