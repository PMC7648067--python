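"""Synthetic ground-truth generators for every pipeline input.

No raw microscopy data ship with this package, so each analysis stage is
exercised against synthetic inputs generated with known truth:

* droplet images — circular dense-phase disks with prescribed inside/outside
  intensity ratios on a uniform background, plus the exact label mask;
* a monomer-tetramer equilibrium reporter (4M <=> T mass action) standing in
  for a proximity-dependent fluorescent probe: only tetramer-bound monomers
  fluoresce, so the signal is superlinear at low concentration and saturates
  toward linear at high concentration;
* calibration tables (concentration, intensity) over the working range;
* droplet measurement tables generated *exactly* under the two-state
  occupancy model, so the solver's recovery of f_occupy can be checked
  against truth;
* FRAP traces with first-order recovery and optional whole-field
  acquisition bleaching that the ratio normalization must cancel.

All generators are deterministic under a fixed seed. Image noise is additive
Gaussian; intensity/measurement noise is multiplicative lognormal with unit
mean and a stated coefficient of variation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
from scipy.optimize import brentq

from .frap import FrapTrace
from .image_quant import ChannelImage

__all__ = [
    "ImageSpec",
    "DropletSpec",
    "TetramerEquilibrium",
    "MeasurementTruth",
    "generate_droplet_image",
    "monomer_concentration",
    "tetramer_signal",
    "generate_calibration_table",
    "default_concentration_grid",
    "generate_droplet_measurements",
    "generate_frap_trace",
    "write_image_with_truth",
]


@dataclass(frozen=True)
class ImageSpec:
    """Geometry and noise of one synthetic frame."""

    height_px: int = 256
    width_px: int = 256
    pixel_size_um: float = 0.1
    background_level: float = 100.0
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.height_px < 8 or self.width_px < 8:
            raise ValueError("image must be at least 8x8 pixels")
        if not self.pixel_size_um > 0:
            raise ValueError("pixel_size_um must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")


@dataclass(frozen=True)
class DropletSpec:
    """One circular dense-phase region.

    ``inside_over_outside`` is the true partition ratio; a scalar applies to
    all channels, a sequence gives one ratio per channel.
    """

    center_rowcol: tuple[float, float]
    radius_um: float
    inside_over_outside: float | tuple[float, ...]

    def __post_init__(self) -> None:
        if not self.radius_um > 0:
            raise ValueError("radius_um must be positive")
        ratios = self.ratios(1) if np.isscalar(self.inside_over_outside) else self.inside_over_outside
        if any(r <= 0 for r in np.atleast_1d(ratios)):
            raise ValueError("inside_over_outside must be positive")

    def ratios(self, n_channels: int) -> tuple[float, ...]:
        if np.isscalar(self.inside_over_outside):
            return (float(self.inside_over_outside),) * n_channels
        r = tuple(float(v) for v in self.inside_over_outside)
        if len(r) != n_channels:
            raise ValueError(
                f"droplet has {len(r)} ratios but {n_channels} channels requested"
            )
        return r


@dataclass(frozen=True)
class TetramerEquilibrium:
    """Single-step 4M <=> T mass-action equilibrium reporter.

    [T] = k_tet * [M]^4, so mass balance at total concentration c reads
    4*k_tet*m^4 + m = c with exactly one root m >= 0. Only tetramer-bound
    monomers fluoresce: signal = brightness * 4*k_tet*m^4.

    k_tet is in uM^-3, brightness in a.u. per uM of tetramer-bound monomer.
    """

    k_tet: float = 1e-4
    brightness: float = 100.0

    def __post_init__(self) -> None:
        if not self.k_tet > 0 or not self.brightness > 0:
            raise ValueError("k_tet and brightness must be positive")


@dataclass(frozen=True)
class MeasurementTruth:
    """Ground truth behind one droplet-measurement condition."""

    c_added: float = 1.0
    enrichment_true: float = 5.0
    f_occupy_true: float = 1.0 / 16.0
    noise_cv: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.f_occupy_true <= 1:
            raise ValueError("f_occupy_true must lie in (0, 1]")
        if self.enrichment_true < 1:
            raise ValueError("enrichment_true must be >= 1")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be nonnegative")
        if not self.c_added > 0:
            raise ValueError("c_added must be positive")


def _lognormal_factors(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    """Unit-mean multiplicative noise with coefficient of variation cv."""
    if cv == 0:
        return np.ones(size)
    sigma = np.sqrt(np.log1p(cv**2))
    return rng.lognormal(mean=-0.5 * sigma**2, sigma=sigma, size=size)


# ---------------------------------------------------------------------------
# droplet images


def generate_droplet_image(
    spec: ImageSpec, droplets: list[DropletSpec], n_channels: int = 1
) -> tuple[list[ChannelImage], np.ndarray]:
    """Render droplets onto a uniform background, with the exact label mask.

    Pixels whose centers fall inside droplet *i* (1-based label) take
    expected intensity ``background_level * inside_over_outside``; all other
    pixels take ``background_level``. Additive Gaussian noise of standard
    deviation ``spec.noise_sd`` is applied per channel (clipped at zero so
    intensities stay valid). Later droplets overwrite earlier ones where
    disks overlap.

    Returns
    -------
    (channels, mask)
        One :class:`~condensate_proximity.image_quant.ChannelImage` per
        channel and the int32 ground-truth label mask.
    """
    h, w = spec.height_px, spec.width_px
    radius_px_all = [d.radius_um / spec.pixel_size_um for d in droplets]
    for d, rad in zip(droplets, radius_px_all):
        r0, c0 = d.center_rowcol
        if r0 - rad < 0 or r0 + rad > h - 1 or c0 - rad < 0 or c0 + rad > w - 1:
            raise ValueError(
                f"droplet at {d.center_rowcol} with radius {d.radius_um} um "
                f"({rad:.1f} px) does not fit inside the {h}x{w} frame"
            )
    rows, cols = np.mgrid[0:h, 0:w]
    mask = np.zeros((h, w), dtype=np.int32)
    channels_expected = [np.full((h, w), spec.background_level) for _ in range(n_channels)]
    for i, (d, rad) in enumerate(zip(droplets, radius_px_all), start=1):
        r0, c0 = d.center_rowcol
        inside = (rows - r0) ** 2 + (cols - c0) ** 2 <= rad**2  # pixel-center membership
        mask[inside] = i
        for ch, ratio in zip(channels_expected, d.ratios(n_channels)):
            ch[inside] = spec.background_level * ratio
    rng = np.random.default_rng(spec.seed)
    images = []
    for ch in channels_expected:
        if spec.noise_sd > 0:
            ch = ch + rng.normal(0.0, spec.noise_sd, size=ch.shape)
            ch = np.clip(ch, 0.0, None)
        images.append(ChannelImage(pixels=ch, pixel_size_um=spec.pixel_size_um))
    return images, mask


def write_image_with_truth(
    path: str | Path,
    channels: list[ChannelImage],
    mask: np.ndarray,
    spec: ImageSpec,
    droplets: list[DropletSpec],
) -> None:
    """Write channels as a multi-page TIFF with a mask TIFF and JSON sidecar."""
    path = Path(path)
    tifffile.imwrite(path, np.stack([c.pixels.astype(np.float32) for c in channels]))
    tifffile.imwrite(path.with_suffix(".mask.tif"), mask.astype(np.int32))
    sidecar = {
        "pixel_size_um": spec.pixel_size_um,
        "background_level": spec.background_level,
        "noise_sd": spec.noise_sd,
        "seed": spec.seed,
        "droplets": [
            {
                "center_rowcol": list(d.center_rowcol),
                "radius_um": d.radius_um,
                "inside_over_outside": d.ratios(len(channels)),
            }
            for d in droplets
        ],
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))


# ---------------------------------------------------------------------------
# tetramer equilibrium reporter


def monomer_concentration(eq: TetramerEquilibrium, c_total: float) -> float:
    """Unique nonnegative root m of the mass balance 4*k_tet*m^4 + m = c_total."""
    if c_total < 0:
        raise ValueError("c_total must be nonnegative")
    if c_total == 0:
        return 0.0
    g = lambda m: 4.0 * eq.k_tet * m**4 + m - c_total
    # g(0) = -c_total < 0, g(c_total) >= 0: bracketed and strictly increasing
    return float(brentq(g, 0.0, c_total, xtol=1e-15, rtol=8.9e-16))


def tetramer_signal(eq: TetramerEquilibrium, c_total) -> float | np.ndarray:
    """Reporter intensity at total concentration c_total.

    Equals brightness x (tetramer-bound monomer concentration)
    = brightness * 4*k_tet*m^4 = brightness * (c_total - m). Strictly
    increasing in c_total, superlinear in the transition regime, and
    approaching brightness * c_total when tetramers dominate.
    """
    if np.isscalar(c_total):
        m = monomer_concentration(eq, float(c_total))
        return eq.brightness * (float(c_total) - m)
    return np.asarray([tetramer_signal(eq, c) for c in np.asarray(c_total, dtype=float)])


def default_concentration_grid(
    c_min: float = 1.0, c_max: float = 50.0, n: int = 16
) -> np.ndarray:
    """Log-spaced calibration grid over the standard 1-50 uM working range."""
    return np.geomspace(c_min, c_max, n)


def generate_calibration_table(
    eq: TetramerEquilibrium,
    c_grid: np.ndarray | None = None,
    noise_cv: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Tabulate (concentration_uM, intensity_au) for the reporter.

    The noiseless table is strictly increasing; multiplicative unit-mean
    lognormal noise with the stated CV is applied otherwise.
    """
    if c_grid is None:
        c_grid = default_concentration_grid()
    c_grid = np.asarray(c_grid, dtype=float)
    if np.any(c_grid < 0):
        raise ValueError("concentrations must be nonnegative")
    if np.any(np.diff(c_grid) <= 0):
        raise ValueError("concentration grid must be strictly increasing")
    signal = tetramer_signal(eq, c_grid)
    rng = np.random.default_rng(seed)
    signal = signal * _lognormal_factors(rng, noise_cv, len(c_grid))
    return pd.DataFrame({"concentration_uM": c_grid, "intensity_au": signal})


# ---------------------------------------------------------------------------
# occupancy-model droplet measurements


def generate_droplet_measurements(
    truth: MeasurementTruth, eq: TetramerEquilibrium, n_droplets: int = 33
) -> pd.DataFrame:
    """Per-droplet measurements generated exactly under the two-state model.

    Noiselessly: c_actual = c_added * enrichment_true,
    c_occupy = c_actual / f_occupy_true, and
    i_observed = I(c_occupy) * f_occupy_true with I the equilibrium reporter.
    Multiplicative unit-mean noise (CV = ``truth.noise_cv``) perturbs
    c_actual and i_observed independently per droplet. Truth columns are
    stored alongside so recovery can be scored.
    """
    if n_droplets < 1:
        raise ValueError("n_droplets must be >= 1")
    rng = np.random.default_rng(truth.seed)
    c_actual_true = truth.c_added * truth.enrichment_true
    c_occupy_true = c_actual_true / truth.f_occupy_true
    i_observed_true = float(tetramer_signal(eq, c_occupy_true)) * truth.f_occupy_true
    c_actual = c_actual_true * _lognormal_factors(rng, truth.noise_cv, n_droplets)
    i_observed = i_observed_true * _lognormal_factors(rng, truth.noise_cv, n_droplets)
    return pd.DataFrame(
        {
            "droplet_id": np.arange(1, n_droplets + 1),
            "c_actual_uM": c_actual,
            "i_observed_au": i_observed,
            "c_added_uM_true": truth.c_added,
            "enrichment_true": truth.enrichment_true,
            "f_occupy_true": truth.f_occupy_true,
            "c_actual_uM_true": c_actual_true,
            "c_occupy_uM_true": c_occupy_true,
            "i_observed_au_true": i_observed_true,
        }
    )


# ---------------------------------------------------------------------------
# FRAP traces


def generate_frap_trace(
    amplitude: float = 0.86,
    tau_s: float = 26.40,
    bleach_depth: float = 0.8,
    whole_field_decay_rate: float = 0.0,
    dt_s: float = 1.0,
    t_pre_s: float = 10.0,
    t_post_s: float = 120.0,
    noise_sd: float = 0.0,
    seed: int = 0,
    tot_baseline: float = 1000.0,
) -> FrapTrace:
    """Synthesize a raw ROB/TOT pair whose normalized ratio recovers as A(1-e^{-t/tau}).

    The pre-bleach ratio is 1; the bleach drops it by ``bleach_depth``; the
    post-bleach ratio recovers with amplitude ``amplitude`` (mobile
    fraction) and time constant ``tau_s``. A global exponential decay with
    rate ``whole_field_decay_rate`` (1/s) multiplies both raw columns,
    emulating acquisition bleaching; it cancels exactly in the ratio.
    Gaussian noise of SD ``noise_sd`` is added to the ratio before scaling
    back to raw intensities. Defaults emulate a fast client probe (mobile
    fraction 0.86, half-life ~18.3 s).
    """
    if not 0 < amplitude <= 1:
        raise ValueError("amplitude must lie in (0, 1]")
    if not tau_s > 0:
        raise ValueError("tau_s must be positive")
    if not 0 < bleach_depth <= 1:
        raise ValueError("bleach_depth must lie in (0, 1]")
    n_pre = int(round(t_pre_s / dt_s))
    n_post = int(round(t_post_s / dt_s)) + 1
    if n_pre < 2:
        raise ValueError("need at least 2 pre-bleach samples")
    time_s = np.concatenate(
        [np.arange(-n_pre, 0) * dt_s, np.arange(0, n_post) * dt_s]
    )
    bleach_index = n_pre
    t_post = time_s[bleach_index:]
    ratio = np.ones_like(time_s)
    ratio[bleach_index:] = (1.0 - bleach_depth) + bleach_depth * amplitude * (
        1.0 - np.exp(-t_post / tau_s)
    )
    rng = np.random.default_rng(seed)
    if noise_sd > 0:
        ratio = ratio + rng.normal(0.0, noise_sd, size=ratio.shape)
    elapsed = time_s - time_s[0]
    i_tot = tot_baseline * np.exp(-whole_field_decay_rate * elapsed)
    i_rob = ratio * i_tot
    return FrapTrace(time_s=time_s, i_rob=i_rob, i_tot=i_tot, bleach_index=bleach_index)
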