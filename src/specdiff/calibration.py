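"""Quantification of binary isomeric mixtures by linear calibration.

The observed mean between a mixture and a pure endpoint isomer grows
(nearly) linearly with the fraction of the other isomer, so an ordinary
least-squares line fitted to (fraction, observed mean) points can be
inverted to estimate the composition of an unknown mixture.  Duplicate
points at the same fraction are fitted jointly (not averaged first) to
preserve residual degrees of freedom, and points are unweighted.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np


@dataclass
class CalibrationCurve:
    """OLS line of observed mean versus isomer fraction (fractions in [0, 1])."""

    slope: float
    intercept: float
    r_squared: float
    points: list[tuple[float, float]]
    reference_label: str = ""
    residuals: np.ndarray = field(default_factory=lambda: np.array([]))

    @property
    def n_points(self) -> int:
        return len(self.points)

    @property
    def residual_sd(self) -> float:
        """Residual standard deviation about the line (n-2 denominator)."""
        if self.n_points <= 2:
            return 0.0
        return float(np.sqrt((self.residuals**2).sum() / (self.n_points - 2)))

    def predict_mean(self, fraction: float) -> float:
        return self.intercept + self.slope * fraction

    def to_dict(self) -> dict:
        return {
            "slope": self.slope,
            "intercept": self.intercept,
            "r_squared": self.r_squared,
            "reference_label": self.reference_label,
            "points": [[float(x), float(y)] for x, y in self.points],
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2)

    def plot(self, ax=None):
        """Plot points and fitted line (requires matplotlib)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        x, y = zip(*self.points)
        ax.plot(x, y, "o", label="calibration points")
        grid = np.linspace(min(x), max(x), 50)
        ax.plot(grid, self.intercept + self.slope * grid, "r--",
                label=f"fit (R$^2$={self.r_squared:.4f})")
        ax.set_xlabel("isomer fraction")
        ax.set_ylabel("observed mean")
        ax.legend()
        return ax


@dataclass
class FractionEstimate:
    """Inverse-prediction result: composition fraction with standard error."""

    fraction: float
    standard_error: float
    clipped: bool = False


def fit_calibration(
    points: list[tuple[float, float]], reference_label: str = ""
) -> CalibrationCurve:
    """Fit the OLS calibration line through (fraction, observed_mean) points.

    Requires at least 3 points whose fractions span at least 0.2 of the unit
    interval.  R^2 is defined as 0 for a flat response (zero variance in the
    observed means).
    """
    pts = [(float(x), float(y)) for x, y in points]
    if len(pts) < 3:
        raise ValueError("need at least 3 calibration points")
    x = np.array([p[0] for p in pts])
    y = np.array([p[1] for p in pts])
    if np.any((x < 0) | (x > 1)):
        raise ValueError("fractions must lie in [0, 1]")
    if x.max() - x.min() < 0.2:
        raise ValueError("fractions must span at least 0.2 of the unit interval")
    if np.ptp(x) == 0:
        raise ValueError("zero variance in fractions")

    if np.ptp(y) == 0:  # flat response: define slope 0, R^2 = 0
        return CalibrationCurve(
            slope=0.0,
            intercept=float(y[0]),
            r_squared=0.0,
            points=pts,
            reference_label=reference_label,
            residuals=np.zeros_like(y),
        )
    slope, intercept = np.polyfit(x, y, 1)
    fitted = intercept + slope * x
    residuals = y - fitted
    ss_tot = ((y - y.mean()) ** 2).sum()
    r_squared = 0.0 if ss_tot == 0 else float(1.0 - (residuals**2).sum() / ss_tot)
    return CalibrationCurve(
        slope=float(slope),
        intercept=float(intercept),
        r_squared=r_squared,
        points=pts,
        reference_label=reference_label,
        residuals=residuals,
    )


def predict_fraction(curve: CalibrationCurve, observed_mean: float) -> FractionEstimate:
    """Invert the calibration line at ``observed_mean``.

    The standard error is the first-order inverse-prediction (calibration)
    error ``(s/|b|) * sqrt(1 + 1/n + (x0 - xbar)^2 / Sxx)`` built from the
    residual standard deviation ``s`` of the fit.  Estimates outside [0, 1]
    are clipped and flagged as extrapolated.
    """
    if curve.slope == 0.0:
        raise ValueError("curve is flat; mixture not quantifiable")
    x0 = (observed_mean - curve.intercept) / curve.slope
    xs = np.array([p[0] for p in curve.points])
    sxx = ((xs - xs.mean()) ** 2).sum()
    se = abs(curve.residual_sd / curve.slope) * np.sqrt(
        1.0 + 1.0 / curve.n_points + (x0 - xs.mean()) ** 2 / sxx
    )
    clipped = not (0.0 <= x0 <= 1.0)
    return FractionEstimate(
        fraction=float(np.clip(x0, 0.0, 1.0)),
        standard_error=float(se),
        clipped=clipped,
    )
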