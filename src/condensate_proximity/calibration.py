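"""Concentration <-> intensity calibrations.

Two kinds of calibration are used when converting droplet fluorescence into
concentrations and expected signals:

* :class:`CalibrationCurve` — a monotone, typically superlinear reporter
  curve I(c) (a proximity-dependent probe such as a tetramerizing
  fluorescent protein measured over a concentration series, e.g. 1-50 uM).
  It is the I(.) that enters the occupancy model; a shape-preserving
  monotone interpolant (PCHIP) through optionally isotonic-regressed points
  guarantees the monotonicity the occupancy solver relies on.
* :class:`LinearCalibration` — an ordinary least-squares line for a directly
  conjugated dye (Cy5 on the client, Cy3 on the scaffold), inverted to read
  absolute concentrations off measured droplet intensities, with explicit
  flagging of extrapolation beyond the fitted range.

An analytic :class:`FunctionCurve` (e.g. a power law I = a*c^n) implements
the same evaluation interface and is useful both as a surrogate calibration
and as a closed-form oracle.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Callable

import numpy as np
import pandas as pd
from scipy.interpolate import PchipInterpolator
from sklearn.isotonic import IsotonicRegression

__all__ = [
    "CalibrationCurve",
    "FunctionCurve",
    "power_law_curve",
    "LinearCalibration",
    "InvertedConcentration",
    "build_curve",
    "expected_intensity",
    "ExpectedIntensity",
    "fit_linear",
    "invert_linear",
    "enrichment_fold",
]


@dataclass(frozen=True)
class CalibrationCurve:
    """Monotone concentration -> intensity mapping with a validity range.

    Evaluation is continuous and nondecreasing on [c_min, c_max]; calling the
    curve outside that range extrapolates the interpolant and should be
    checked with :meth:`in_range` (see :func:`expected_intensity`).
    """

    c_grid: np.ndarray
    i_values: np.ndarray
    c_min: float
    c_max: float
    _interp: Callable

    def __call__(self, c) -> float | np.ndarray:
        out = self._interp(c)
        return float(out) if np.isscalar(c) else np.asarray(out)

    def in_range(self, c) -> bool | np.ndarray:
        if np.isscalar(c):
            return bool(self.c_min <= c <= self.c_max)
        c = np.asarray(c)
        return (self.c_min <= c) & (c <= self.c_max)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "method": "pchip",
            "c_grid_uM": list(map(float, self.c_grid)),
            "i_values_au": list(map(float, self.i_values)),
            "c_min_uM": self.c_min,
            "c_max_uM": self.c_max,
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "CalibrationCurve":
        payload = json.loads(Path(path).read_text())
        return build_curve(
            pd.DataFrame(
                {
                    "concentration_uM": payload["c_grid_uM"],
                    "intensity_au": payload["i_values_au"],
                }
            ),
            isotonic=False,
        )


@dataclass(frozen=True)
class FunctionCurve:
    """Analytic I(c) with the same evaluation interface as CalibrationCurve.

    ``c_max`` may be ``inf`` for a curve valid at all concentrations.
    """

    func: Callable[[float], float]
    c_min: float = 0.0
    c_max: float = np.inf

    def __call__(self, c):
        if np.isscalar(c):
            return float(self.func(c))
        return np.asarray([self.func(ci) for ci in np.asarray(c, dtype=float)])

    def in_range(self, c) -> bool | np.ndarray:
        if np.isscalar(c):
            return bool(self.c_min <= c <= self.c_max)
        c = np.asarray(c)
        return (self.c_min <= c) & (c <= self.c_max)


def power_law_curve(
    coefficient: float, exponent: float, c_min: float = 0.0, c_max: float = np.inf
) -> FunctionCurve:
    """I(c) = coefficient * c**exponent, monotone for positive parameters."""
    if coefficient <= 0 or exponent <= 0:
        raise ValueError("coefficient and exponent must be positive")
    return FunctionCurve(lambda c: coefficient * c**exponent, c_min=c_min, c_max=c_max)


def build_curve(
    table: pd.DataFrame,
    isotonic: bool = True,
    max_isotonic_shift: float = 0.20,
) -> CalibrationCurve:
    """Build a monotone interpolated calibration curve from a (c, I) table.

    Parameters
    ----------
    table
        DataFrame with columns ``concentration_uM`` (strictly increasing,
        >= 4 points) and ``intensity_au``.
    isotonic
        Project intensities onto the nearest nondecreasing sequence before
        interpolating (recommended for noisy measurements); the shape-
        preserving cubic interpolant then cannot overshoot into
        non-monotonicity.
    max_isotonic_shift
        Upper bound on the relative L1 mass moved by the isotonic projection;
        a larger shift indicates the data are not credibly monotone and
        raises instead.
    """
    c = np.asarray(table["concentration_uM"], dtype=float)
    i = np.asarray(table["intensity_au"], dtype=float)
    if len(c) < 4:
        raise ValueError(f"need at least 4 calibration points, got {len(c)}")
    if np.any(np.diff(c) <= 0):
        raise ValueError("concentration grid must be strictly increasing")
    if isotonic:
        iso = IsotonicRegression(increasing=True).fit_transform(c, i)
        denom = float(np.abs(i).sum())
        if denom > 0 and float(np.abs(iso - i).sum()) / denom > max_isotonic_shift:
            raise ValueError(
                "calibration intensities are severely non-monotone "
                f"(isotonic projection moved more than {max_isotonic_shift:.0%} "
                "of the intensity mass)"
            )
        i = iso
    elif np.any(np.diff(i) < 0):
        raise ValueError("intensities must be nondecreasing when isotonic=False")
    # interpolate in log-log space when possible: power-law-like stretches of
    # the reporter curve become straight lines there, so sparse log-spaced
    # grids reconstruct the curve far more accurately; monotonicity and exact
    # interpolation at the grid are preserved by the log transform
    if np.all(c > 0) and np.all(i > 0):
        log_interp = PchipInterpolator(np.log(c), np.log(i), extrapolate=True)
        interp = lambda x: np.exp(log_interp(np.log(x)))
    else:
        interp = PchipInterpolator(c, i, extrapolate=True)
    return CalibrationCurve(
        c_grid=c, i_values=i, c_min=float(c[0]), c_max=float(c[-1]), _interp=interp
    )


@dataclass(frozen=True)
class ExpectedIntensity:
    value: float
    out_of_range: bool


def expected_intensity(curve, c_actual: float) -> ExpectedIntensity:
    """Evaluate the reporter curve at an actual concentration.

    Returns the intensity with a flag set when ``c_actual`` falls outside the
    curve's validity range (the value is still the interpolant/extension).
    """
    if c_actual < 0:
        raise ValueError("c_actual must be nonnegative")
    return ExpectedIntensity(
        value=float(curve(c_actual)), out_of_range=not bool(curve.in_range(c_actual))
    )


@dataclass(frozen=True)
class LinearCalibration:
    """OLS line I = slope * c + intercept for a direct dye reporter."""

    slope: float
    intercept: float
    c_min: float
    c_max: float
    allow_extrapolation: bool = True

    def __post_init__(self) -> None:
        if not self.slope > 0:
            raise ValueError(f"slope must be positive, got {self.slope}")

    def forward(self, c: float) -> float:
        return self.slope * c + self.intercept


@dataclass(frozen=True)
class InvertedConcentration:
    concentration_uM: float
    extrapolated: bool


def fit_linear(
    table: pd.DataFrame,
    through_origin: bool = False,
    allow_extrapolation: bool = True,
) -> LinearCalibration:
    """Ordinary least squares fit of intensity against concentration.

    ``through_origin`` pins the intercept at zero; by default it is free.
    """
    c = np.asarray(table["concentration_uM"], dtype=float)
    i = np.asarray(table["intensity_au"], dtype=float)
    if len(c) < 2:
        raise ValueError("need at least 2 points for a linear fit")
    if through_origin:
        slope = float(np.dot(c, i) / np.dot(c, c))
        intercept = 0.0
    else:
        slope, intercept = (float(v) for v in np.polyfit(c, i, 1))
    if slope <= 0:
        raise ValueError(f"fitted slope is not positive ({slope:.4g} a.u./uM)")
    return LinearCalibration(
        slope=slope,
        intercept=intercept,
        c_min=float(c.min()),
        c_max=float(c.max()),
        allow_extrapolation=allow_extrapolation,
    )


def invert_linear(cal: LinearCalibration, intensity: float) -> InvertedConcentration:
    """Concentration from intensity: c = (I - intercept) / slope.

    Inversion outside the fitted concentration range is flagged, and refused
    entirely when the calibration disallows extrapolation (the scaffold-dye
    workflow deliberately extrapolates; client reads normally do not need to).
    """
    if intensity < cal.intercept:
        raise ValueError(
            f"intensity {intensity} is below the calibration intercept {cal.intercept}"
        )
    c = (intensity - cal.intercept) / cal.slope
    extrapolated = not (cal.c_min <= c <= cal.c_max)
    if extrapolated and not cal.allow_extrapolation:
        raise ValueError(
            f"inverted concentration {c:.4g} uM lies outside the fitted range "
            f"[{cal.c_min:g}, {cal.c_max:g}] uM and extrapolation is disallowed"
        )
    return InvertedConcentration(concentration_uM=float(c), extrapolated=extrapolated)


def enrichment_fold(c_inside: float, c_added: float) -> float:
    """Client enrichment: concentration inside droplets over bulk added concentration."""
    if c_inside <= 0 or c_added <= 0:
        raise ValueError("concentrations must be positive")
    return c_inside / c_added
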