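"""The spectral-difference statistic.

For two spectra restricted to their common fragment channels, each channel's
*fractional abundance* (FA) is its intensity divided by the summed intensity
over the compared channels, so each FA vector sums to 1.  The per-channel
absolute FA difference is normalized to the mean FA of that channel across
the two spectra, and the mean of the normalized values over channels is the
*observed mean* — the single number the hypothesis tests act on.

The signed FA differences sum to (numerically) zero because both FA vectors
sum to 1: abundance lost by one fragmentation channel reappears in others,
a near-zero-sum behaviour that makes the signed mean uninformative and
motivates the absolute, per-fragment-normalized form.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import FragmentPanel, Spectrum, match_channels

_SUM_TOL = 1e-12


@dataclass
class FAVector:
    """Fractional abundances over a set of fragment channels (sums to 1)."""

    values: np.ndarray
    channel_mz: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.channel_mz is None:
            self.channel_mz = np.arange(self.values.size, dtype=float) + 1.0
        self.channel_mz = np.asarray(self.channel_mz, dtype=float)
        if self.values.size != self.channel_mz.size:
            raise ValueError("values and channel_mz must have equal length")
        if np.any(self.values < 0):
            raise ValueError("fractional abundances must be non-negative")
        if abs(self.values.sum() - 1.0) > 1e-9:
            raise ValueError(f"fractional abundances sum to {self.values.sum()}, not 1")

    @property
    def n_channels(self) -> int:
        return self.values.size

    def __len__(self) -> int:
        return self.values.size


@dataclass
class DifferenceSet:
    """Per-channel FA differences between two spectra plus their summary.

    ``normalized[i] = |fa_a[i] - fa_b[i]| / ((fa_a[i] + fa_b[i]) / 2)`` and
    ``observed_mean = mean(normalized)``.  Channels where both abundances
    are zero contribute a normalized difference of 0 (possible only under
    zero-fill matching).
    """

    channel_mz: np.ndarray
    fa_a: np.ndarray
    fa_b: np.ndarray
    signed: np.ndarray
    absolute: np.ndarray
    normalized: np.ndarray
    observed_mean: float

    @property
    def n_channels(self) -> int:
        return self.normalized.size

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "channel_mz": self.channel_mz,
                "fa_a": self.fa_a,
                "fa_b": self.fa_b,
                "signed": self.signed,
                "absolute": self.absolute,
                "normalized": self.normalized,
            }
        )

    def to_tsv(self, path_or_buf) -> None:
        """Serialize as TSV; the header comment line carries the observed mean."""
        buf = _io.StringIO()
        buf.write(f"# observed_mean\t{self.observed_mean!r}\n")
        self.to_frame().to_csv(buf, sep="\t", index=False)
        text = buf.getvalue()
        if hasattr(path_or_buf, "write"):
            path_or_buf.write(text)
        else:
            with open(path_or_buf, "w") as fh:
                fh.write(text)


def fractional_abundance(
    intensities: np.ndarray, channel_mz: np.ndarray | None = None
) -> FAVector:
    """FA vector: each intensity divided by the summed intensity.

    Scale-invariant: multiplying all intensities by a positive constant
    leaves the result unchanged.
    """
    intensities = np.asarray(intensities, dtype=float)
    if intensities.size < 2:
        raise ValueError("need at least 2 channels")
    if np.any(intensities < 0):
        raise ValueError("intensities must be non-negative")
    total = intensities.sum()
    if total <= 0:
        raise ValueError("empty spectrum: all intensities are zero")
    return FAVector(values=intensities / total, channel_mz=channel_mz)


def difference_set(fa_a: FAVector, fa_b: FAVector) -> DifferenceSet:
    """Signed/absolute/normalized per-channel FA differences and their mean."""
    if fa_a.n_channels != fa_b.n_channels or not np.allclose(
        fa_a.channel_mz, fa_b.channel_mz
    ):
        raise ValueError("FA vectors must be defined on the same channel list")
    a, b = fa_a.values, fa_b.values
    signed = a - b
    absolute = np.abs(signed)
    mean_fa = 0.5 * (a + b)
    normalized = np.divide(
        absolute, mean_fa, out=np.zeros_like(absolute), where=mean_fa > 0
    )
    return DifferenceSet(
        channel_mz=np.asarray(fa_a.channel_mz),
        fa_a=a,
        fa_b=b,
        signed=signed,
        absolute=absolute,
        normalized=normalized,
        observed_mean=float(normalized.mean()),
    )


def panel_difference(panel: FragmentPanel) -> DifferenceSet:
    """Difference set for an already-matched fragment panel.

    FA is computed over the common panel (renormalized), since the statistic
    is defined on the ions shared by both spectra.
    """
    fa_a = fractional_abundance(panel.intensities_a, panel.channel_mz)
    fa_b = fractional_abundance(panel.intensities_b, panel.channel_mz)
    return difference_set(fa_a, fa_b)


def observed_mean_between(
    spec_a: Spectrum,
    spec_b: Spectrum,
    mz_tolerance: float = 10.0,
    tolerance_unit: str = "ppm",
    unmatched: str = "drop",
) -> DifferenceSet:
    """Match channels between two spectra and compute their difference set."""
    panel = match_channels(
        spec_a, spec_b, mz_tolerance, tolerance_unit=tolerance_unit, unmatched=unmatched
    )
    return panel_difference(panel)
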