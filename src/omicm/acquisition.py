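"""Acquisition geometry and instrument response for TCSPC lifetime imaging.

A TCSPC acquisition records, at every pixel, a histogram of photon arrival
times over ``n_bins`` discrete time bins spanning one laser repetition
period (``window_ns``).  The measured decay is the ideal fluorescence decay
convolved with the instrument response function (IRF), whose width is
conventionally quoted as a full width at half maximum in picoseconds.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "NADH",
    "FAD",
    "CHANNELS",
    "AcquisitionSpec",
    "IRF",
    "gaussian_irf",
    "delta_irf",
]

NADH = "NADH"
FAD = "FAD"
CHANNELS = (NADH, FAD)

#: FWHM = 2*sqrt(2*ln 2) * sigma for a Gaussian
_FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


@dataclass(frozen=True)
class AcquisitionSpec:
    """Geometry and timing of one TCSPC channel acquisition.

    Parameters
    ----------
    width, height : int
        Image size in pixels.
    n_bins : int
        Number of time bins per per-pixel decay histogram.
    window_ns : float
        Full measurement window in nanoseconds (one laser repetition
        period; 12.5 ns for an 80 MHz Ti:sapphire source).
    irf_fwhm_ps : float
        Nominal IRF full width at half maximum in picoseconds.
    channel : str
        Which coenzyme channel this acquisition records ("NADH" or "FAD").
    """

    width: int = 256
    height: int = 256
    n_bins: int = 256
    window_ns: float = 12.5
    irf_fwhm_ps: float = 260.0
    channel: str = NADH

    def __post_init__(self) -> None:
        if self.width < 1 or self.height < 1 or self.n_bins < 1:
            raise ValueError("width, height and n_bins must be >= 1")
        if self.window_ns <= 0:
            raise ValueError("window_ns must be positive")
        if self.irf_fwhm_ps <= 0:
            raise ValueError("irf_fwhm_ps must be positive")
        if self.channel not in CHANNELS:
            raise ValueError(f"channel must be one of {CHANNELS}, got {self.channel!r}")

    @property
    def bin_width_ns(self) -> float:
        return self.window_ns / self.n_bins

    def time_axis(self) -> np.ndarray:
        """Bin-center times in nanoseconds."""
        return (np.arange(self.n_bins) + 0.5) * self.bin_width_ns


@dataclass(frozen=True)
class IRF:
    """Discretized instrument response: non-negative kernel summing to one."""

    kernel: np.ndarray
    fwhm_ps: float

    def __post_init__(self) -> None:
        k = np.asarray(self.kernel, dtype=float)
        if k.ndim != 1 or k.size < 1:
            raise ValueError("IRF kernel must be a 1-D array")
        if np.any(k < 0):
            raise ValueError("IRF kernel must be non-negative")
        s = k.sum()
        if not np.isfinite(s) or s <= 0:
            raise ValueError("IRF kernel must have positive mass")
        object.__setattr__(self, "kernel", k / s)

    @property
    def peak_bin(self) -> int:
        return int(np.argmax(self.kernel))


def gaussian_irf(
    fwhm_ps: float, spec: AcquisitionSpec, center_ns: float | None = None
) -> IRF:
    """Analytic Gaussian surrogate for a measured IRF.

    The kernel is the Gaussian density integrated over each time bin
    (difference of CDFs), centered early in the window so the convolved
    decay retains most of its tail.  A FWHM much narrower than one bin
    degenerates gracefully to a single-bin delta.
    """
    if fwhm_ps <= 0:
        raise ValueError("fwhm_ps must be positive")
    dt = spec.bin_width_ns
    if center_ns is None:
        # early in the window: leaves ~ the full window for the decay tail
        center_ns = max(4.0 * fwhm_ps * 1e-3 * _FWHM_TO_SIGMA, 1.5 * dt)
    sigma_ns = fwhm_ps * 1e-3 * _FWHM_TO_SIGMA
    from scipy.stats import norm

    edges = np.arange(spec.n_bins + 1) * dt
    mass = np.diff(norm.cdf(edges, loc=center_ns, scale=sigma_ns))
    if mass.sum() <= 0:  # pathologically narrow: all mass inside one bin
        mass = np.zeros(spec.n_bins)
        mass[min(int(center_ns / dt), spec.n_bins - 1)] = 1.0
    return IRF(kernel=mass, fwhm_ps=fwhm_ps)


def delta_irf(spec: AcquisitionSpec) -> IRF:
    """Ideal (no temporal blur) response: all mass in the first bin."""
    k = np.zeros(spec.n_bins)
    k[0] = 1.0
    return IRF(kernel=k, fwhm_ps=1e-6)


def shift_kernel(kernel: np.ndarray, shift_bins: float) -> np.ndarray:
    """Shift a kernel by a (possibly fractional) number of bins.

    Linear interpolation; mass shifted past either edge is dropped, so the
    result is renormalized only implicitly by the caller's convolution.
    """
    if shift_bins == 0:
        return kernel
    n = kernel.size
    idx = np.arange(n) - shift_bins
    return np.interp(idx, np.arange(n), kernel, left=0.0, right=0.0)
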