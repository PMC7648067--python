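"""FRAP (fluorescence recovery after photobleaching) normalization and fitting.

The raw observables are two time series: the intensity of the bleached
region (ROB) and of the whole field/nucleus (TOT). Whole-field acquisition
bleaching affects both, so the analysis works on the ratio r(t) = ROB/TOT,
normalized so that r = 1 pre-bleach and 0 at the first post-bleach sample.
The post-bleach recovery is fit to the first-order exponential

    f(t) = A * (1 - exp(-t / tau))

with t re-zeroed at the bleach. A is the mobile fraction (amplitude of
recovery) and the half-life is t_1/2 = ln(2) * tau.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

__all__ = [
    "FrapTrace",
    "NormalizedTrace",
    "FrapFit",
    "autodetect_bleach_index",
    "normalize_trace",
    "fit_recovery",
    "fit_trace",
]

#: Soft upper bound on the mobile fraction; small overshoot is tolerated but flagged.
AMPLITUDE_SOFT_MAX = 1.05


@dataclass(frozen=True)
class FrapTrace:
    """Bleach-recovery time series.

    ``bleach_index`` is the index of the first post-bleach sample; samples
    before it are the pre-bleach baseline.
    """

    time_s: np.ndarray
    i_rob: np.ndarray
    i_tot: np.ndarray
    bleach_index: int

    def __post_init__(self) -> None:
        t = np.asarray(self.time_s, dtype=float)
        rob = np.asarray(self.i_rob, dtype=float)
        tot = np.asarray(self.i_tot, dtype=float)
        if not (t.shape == rob.shape == tot.shape) or t.ndim != 1:
            raise ValueError("time_s, i_rob, i_tot must be 1D arrays of equal length")
        if np.any(np.diff(t) <= 0):
            raise ValueError("time must be strictly increasing")
        if np.any(tot <= 0):
            raise ValueError("i_tot must be positive everywhere")
        if not 0 < self.bleach_index < len(t):
            raise ValueError("bleach_index must lie strictly inside the trace")
        object.__setattr__(self, "time_s", t)
        object.__setattr__(self, "i_rob", rob)
        object.__setattr__(self, "i_tot", tot)

    @property
    def ratio(self) -> np.ndarray:
        """r(t) = I_ROB / I_TOT; cancels whole-field bleaching."""
        return self.i_rob / self.i_tot


@dataclass(frozen=True)
class NormalizedTrace:
    """Ratio series rescaled to 1 pre-bleach and 0 at the first post-bleach sample."""

    time_s: np.ndarray
    n: np.ndarray
    bleach_index: int

    @property
    def post_time_s(self) -> np.ndarray:
        """Post-bleach time re-zeroed at the bleach sample."""
        t = self.time_s[self.bleach_index :]
        return t - t[0]

    @property
    def post_n(self) -> np.ndarray:
        return self.n[self.bleach_index :]


@dataclass(frozen=True)
class FrapFit:
    """First-order recovery fit: mobile fraction, time constant, half-life."""

    amplitude_A: float
    tau_s: float
    t_half_s: float
    residual_rms: float
    amplitude_flagged: bool = False

    def __post_init__(self) -> None:
        if not np.isclose(self.t_half_s, np.log(2) * self.tau_s, rtol=1e-12):
            raise ValueError("t_half_s must equal ln(2) * tau_s")


def autodetect_bleach_index(time_s, i_rob, i_tot) -> int:
    """Locate the bleach as the largest single-step drop in r = ROB/TOT."""
    r = np.asarray(i_rob, dtype=float) / np.asarray(i_tot, dtype=float)
    steps = np.diff(r)
    return int(np.argmin(steps)) + 1


def normalize_trace(trace: FrapTrace) -> NormalizedTrace:
    """Normalize r(t) = ROB/TOT to the 1-pre / 0-at-bleach convention.

    n(t) = (r(t) - r0) / (r_pre - r0), where r_pre is the mean of the
    pre-bleach samples and r0 = r(bleach_index). The pre-bleach mean of n is
    then exactly 1 and n(bleach_index) = 0.
    """
    if trace.bleach_index < 2:
        raise ValueError("need at least 2 pre-bleach samples")
    r = trace.ratio
    r_pre = float(r[: trace.bleach_index].mean())
    r0 = float(r[trace.bleach_index])
    depth = r_pre - r0
    if depth == 0:
        raise ValueError("no bleach depth: pre-bleach mean equals post-bleach value")
    n = (r - r0) / depth
    return NormalizedTrace(time_s=trace.time_s.copy(), n=n, bleach_index=trace.bleach_index)


def _recovery_model(t, amplitude, tau):
    return amplitude * (1.0 - np.exp(-t / tau))


def _initial_guess(t: np.ndarray, n: np.ndarray) -> tuple[float, float]:
    # A0 = last value; tau0 = time at which the trace first reaches A0*(1 - 1/e)
    a0 = float(n[-1])
    target = a0 * (1.0 - np.exp(-1.0))
    reached = np.nonzero(n >= target)[0]
    if a0 > 0 and reached.size:
        tau0 = float(t[reached[0]])
    else:
        tau0 = float(t[-1]) / 3.0
    if tau0 <= 0:
        tau0 = float(t[1])
    if a0 <= 0:
        a0 = 0.5
    return a0, tau0


def fit_recovery(norm: NormalizedTrace, maxfev: int = 10000) -> FrapFit:
    """Least-squares fit of A(1 - exp(-t/tau)) to the post-bleach series.

    Initialization is deterministic (A0 = last value, tau0 = time to reach
    A0(1 - 1/e)), so the fit is reproducible. The mobile fraction is not
    hard-clipped; values above 1.05 raise, values in (1, 1.05] are flagged.
    """
    t = norm.post_time_s
    n = norm.post_n
    if len(t) < 5:
        raise ValueError("need at least 5 post-bleach samples")
    a0, tau0 = _initial_guess(t, n)
    try:
        popt, _ = curve_fit(
            _recovery_model, t, n, p0=(a0, tau0), maxfev=maxfev
        )
    except RuntimeError as exc:  # non-convergence
        raise RuntimeError(
            f"recovery fit did not converge (p0=A={a0:.4g}, tau={tau0:.4g} s, "
            f"maxfev={maxfev}): {exc}"
        ) from exc
    amplitude, tau = float(popt[0]), float(abs(popt[1]))
    flagged = amplitude > 1.0
    if amplitude > AMPLITUDE_SOFT_MAX:
        warnings.warn(
            f"fitted mobile fraction {amplitude:.3f} exceeds {AMPLITUDE_SOFT_MAX}; "
            "check normalization",
            stacklevel=2,
        )
    resid = n - _recovery_model(t, amplitude, tau)
    return FrapFit(
        amplitude_A=amplitude,
        tau_s=tau,
        t_half_s=float(np.log(2) * tau),
        residual_rms=float(np.sqrt(np.mean(resid**2))),
        amplitude_flagged=flagged,
    )


def fit_trace(trace: FrapTrace) -> FrapFit:
    """Convenience: normalize then fit one raw trace."""
    return fit_recovery(normalize_trace(trace))
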