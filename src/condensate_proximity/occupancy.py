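"""Two-state occupancy model of client proximity enhancement in condensates.

Clients recruited into a condensate are assumed to occupy only a fraction
f_occupy = V_occupy / V_total of the droplet volume, locally concentrated
around the scaffold network. With a nonlinear (superlinear) reporter curve
I(c), the measured global concentration and droplet signal then satisfy

    c_actual   = c_occupy * f_occupy
    I_observed = I(c_occupy) * f_occupy

where c_occupy is the effective concentration felt by clients in the
occupied sub-volume. Given (c_actual, I_observed) and a calibration I(.),
these two relations are solved numerically for f_occupy; the overall
proximity enhancement factor is 1/f_occupy. The volume reduction maps to an
effective client-scaffold binding free energy per molecule,

    epsilon = k_B * T * ln(f_occupy)   (<= 0, favorable),

so a 16-fold enhancement at 300 K corresponds to |epsilon| ~ 1.65 kcal/mol.

For a pure power-law reporter I(c) = a * c^n the model has the closed form
enhancement = (I_observed / I(c_actual))^(1/(n-1)), which serves as an
independent oracle for the numerical solver. An exactly linear reporter
makes the model non-identifiable: I(c/f)*f is constant in f, so no degree
of localization changes the droplet signal.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd
from scipy.optimize import brentq

__all__ = [
    "KB_KCAL_PER_MOL_K",
    "DropletMeasurement",
    "OccupancySolution",
    "DiffusionEstimate",
    "solve_occupancy",
    "observed_over_expected",
    "binding_free_energy",
    "diffusion_length",
    "cm2_per_s_to_um2_per_s",
    "batch_solve",
    "summarize_batch",
]

#: Boltzmann constant x Avogadro in kcal/(mol*K); k_B*T = 0.596 kcal/mol at 300 K.
KB_KCAL_PER_MOL_K = 1.987204259e-3

#: Default temperature (K) when none is given.
DEFAULT_TEMPERATURE_K = 300.0

_F_TOL = 1e-12  # solver tolerance on f_occupy
_LINEAR_REL_TOL = 1e-9  # objective variation below this (rel. to I_observed) => linear


@dataclass(frozen=True)
class DropletMeasurement:
    """One droplet: actual (dye-derived) client concentration and reporter signal."""

    c_actual: float
    i_observed: float
    droplet_id: int | str = 0

    def __post_init__(self) -> None:
        if not self.c_actual > 0:
            raise ValueError("c_actual must be positive")
        if self.i_observed < 0:
            raise ValueError("i_observed must be nonnegative")


@dataclass(frozen=True)
class OccupancySolution:
    """Solved occupancy for one droplet.

    ``status`` is one of ``ok``, ``no_enhancement`` (observed signal at or
    below the expected signal, f pinned to 1), ``out_of_range`` (the implied
    effective concentration exceeds the calibration limit; f and the
    enhancement are not reported, mirroring measurements that cannot be
    solved within the calibrated range), or ``non_identifiable`` (the
    reporter is numerically linear over the bracket).
    """

    droplet_id: int | str
    status: str
    f_occupy: float | None
    c_occupy: float | None
    enhancement: float | None
    i_expected: float
    epsilon_kcal_mol: float | None
    temperature_K: float


@dataclass(frozen=True)
class DiffusionEstimate:
    """RMS displacement sqrt(6*D*t) of a freely diffusing protein in 3D."""

    D_um2_per_s: float
    t_s: float
    mean_displacement_um: float


def cm2_per_s_to_um2_per_s(d_cm2_per_s: float) -> float:
    """Convert a diffusion coefficient from cm^2/s to um^2/s (1e-6 cm^2/s = 100 um^2/s)."""
    return d_cm2_per_s * 1e8


def solve_occupancy(
    m: DropletMeasurement,
    curve,
    temperature_K: float = DEFAULT_TEMPERATURE_K,
) -> OccupancySolution:
    """Invert the two-state model for one droplet measurement.

    Solves I(c_actual / f) * f = I_observed for f in (0, 1] by bracketed
    root finding on [c_actual / c_max, 1]. For a superlinear reporter the
    left side is strictly decreasing in f, so the root is unique.

    Raises
    ------
    ValueError
        If ``c_actual`` lies outside the curve's validity range.
    """
    if not curve.in_range(m.c_actual):
        raise ValueError(
            f"c_actual = {m.c_actual:g} uM is outside the calibration range "
            f"[{curve.c_min:g}, {curve.c_max:g}] uM"
        )
    i_expected = float(curve(m.c_actual))

    def _solution(status, f=None):
        return OccupancySolution(
            droplet_id=m.droplet_id,
            status=status,
            f_occupy=f,
            c_occupy=None if f is None else m.c_actual / f,
            enhancement=None if f is None else 1.0 / f,
            i_expected=i_expected,
            epsilon_kcal_mol=None
            if f is None
            else binding_free_energy(f, temperature_K),
            temperature_K=temperature_K,
        )

    if m.i_observed <= i_expected:
        return _solution("no_enhancement", f=1.0)

    f_lo = m.c_actual / curve.c_max if np.isfinite(curve.c_max) else _F_TOL

    def objective(f: float) -> float:
        return float(curve(m.c_actual / f)) * f - m.i_observed

    g_lo = objective(f_lo)
    g_hi = i_expected - m.i_observed  # objective(1.0)
    if abs(g_lo - g_hi) <= _LINEAR_REL_TOL * max(m.i_observed, 1.0):
        return _solution("non_identifiable")
    if g_lo < 0:
        # even at c_occupy = c_max the model cannot produce the observed
        # signal: the implied effective concentration exceeds the calibration
        return _solution("out_of_range")

    f = brentq(objective, f_lo, 1.0, xtol=_F_TOL, rtol=8.9e-16)
    return _solution("ok", f=float(f))


def observed_over_expected(m: DropletMeasurement, curve) -> float:
    """Ratio of the observed droplet signal to the signal expected at c_actual.

    Under a power-law reporter I ~ c^n this ratio equals enhancement^(n-1);
    for n = 2 it is the enhancement factor itself.
    """
    i_expected = float(curve(m.c_actual))
    if i_expected <= 0:
        raise ValueError("expected intensity is zero at c_actual")
    return m.i_observed / i_expected


def binding_free_energy(
    f_occupy: float, temperature_K: float = DEFAULT_TEMPERATURE_K
) -> float:
    """Effective client-scaffold binding free energy epsilon = k_B*T*ln(f_occupy).

    Returned signed (<= 0; negative = favorable binding). The magnitude
    |epsilon| = k_B*T*ln(enhancement) is what is conventionally quoted.
    """
    if not 0 < f_occupy <= 1:
        raise ValueError(f"f_occupy must lie in (0, 1], got {f_occupy}")
    if temperature_K <= 0:
        raise ValueError("temperature_K must be positive")
    return KB_KCAL_PER_MOL_K * temperature_K * math.log(f_occupy)


def diffusion_length(d_um2_per_s: float, t_s: float) -> DiffusionEstimate:
    """Mean 3D diffusion displacement sqrt(6*D*t).

    A protein with D = 1e-6 cm^2/s (100 um^2/s) covers ~190 um in 60 s,
    ample to traverse a cell with no active transport.
    """
    if d_um2_per_s < 0 or t_s < 0:
        raise ValueError("D and t must be nonnegative")
    return DiffusionEstimate(
        D_um2_per_s=d_um2_per_s,
        t_s=t_s,
        mean_displacement_um=math.sqrt(6.0 * d_um2_per_s * t_s),
    )


def batch_solve(
    measurements: pd.DataFrame | Iterable[DropletMeasurement],
    curve,
    temperature_K: float = DEFAULT_TEMPERATURE_K,
) -> pd.DataFrame:
    """Solve the occupancy model per droplet; one row per measurement.

    ``measurements`` is either an iterable of :class:`DropletMeasurement` or
    a DataFrame with columns ``droplet_id``, ``c_actual_uM``,
    ``i_observed_au``. Per-row statuses are recorded; a row that cannot be
    solved does not abort the batch.
    """
    if isinstance(measurements, pd.DataFrame):
        ms = [
            DropletMeasurement(
                c_actual=row.c_actual_uM,
                i_observed=row.i_observed_au,
                droplet_id=row.droplet_id,
            )
            for row in measurements.itertuples()
        ]
    else:
        ms = list(measurements)
    rows = []
    for m in ms:
        sol = solve_occupancy(m, curve, temperature_K=temperature_K)
        rows.append(
            {
                "droplet_id": sol.droplet_id,
                "status": sol.status,
                "f_occupy": sol.f_occupy,
                "c_occupy_uM": sol.c_occupy,
                "enhancement": sol.enhancement,
                "i_expected_au": sol.i_expected,
                "epsilon_kcal_mol": sol.epsilon_kcal_mol,
                "c_actual_uM": m.c_actual,
                "i_observed_au": m.i_observed,
            }
        )
    return pd.DataFrame(rows)


def summarize_batch(solutions: pd.DataFrame) -> dict:
    """Aggregate a batch: mean/SD of the solved enhancements plus status counts."""
    ok = solutions[solutions["status"] == "ok"]
    counts = solutions["status"].value_counts().to_dict()
    return {
        "n_droplets": int(len(solutions)),
        "n_ok": int(len(ok)),
        "mean_enhancement": float(ok["enhancement"].mean()) if len(ok) else float("nan"),
        "sd_enhancement": float(ok["enhancement"].std(ddof=1)) if len(ok) > 1 else 0.0,
        "mean_abs_epsilon_kcal_mol": float(-ok["epsilon_kcal_mol"].mean())
        if len(ok)
        else float("nan"),
        "status_counts": counts,
    }
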