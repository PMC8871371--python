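"""Time axis and instrument response function (IRF) for TCSPC histograms.

A TCSPC acquisition bins photon arrival times into a fixed number of bins
spanning one laser repetition period. The default axis is 256 bins over a
12.5 ns window (80 MHz repetition rate), i.e. ~48.8 ps per bin. The IRF is
modeled as a normalized single-mode kernel over the same bins; its width is
reported as full width at half maximum (FWHM), 260 ps by default.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["TimeAxis", "IRFKernel", "make_irf", "measure_fwhm_ps"]

_GAUSS_FWHM_TO_SIGMA = 2.0 * np.sqrt(2.0 * np.log(2.0))


@dataclass(frozen=True)
class TimeAxis:
    """Uniform time binning of a TCSPC measurement window.

    Parameters
    ----------
    n_bins : int
        Number of time bins (>= 8).
    window : float
        Total measurement window in ns.
    """

    n_bins: int = 256
    window: float = 12.5

    def __post_init__(self) -> None:
        if self.n_bins < 8:
            raise ValueError(f"n_bins must be >= 8, got {self.n_bins}")
        if not np.isfinite(self.window) or self.window <= 0:
            raise ValueError(f"window must be positive, got {self.window}")

    @property
    def bin_width(self) -> float:
        """Width of one bin in ns; n_bins * bin_width == window by construction."""
        return self.window / self.n_bins

    @property
    def centers(self) -> np.ndarray:
        """Bin-center times in ns."""
        return (np.arange(self.n_bins) + 0.5) * self.bin_width

    @classmethod
    def from_bin_width(cls, n_bins: int, bin_width: float) -> "TimeAxis":
        return cls(n_bins=n_bins, window=n_bins * bin_width)


def measure_fwhm_ps(values: np.ndarray, time_axis: TimeAxis) -> float:
    """FWHM of a sampled kernel in ps, via linear interpolation of the
    half-maximum crossings on either side of the peak."""
    v = np.asarray(values, dtype=float)
    peak = int(np.argmax(v))
    half = v[peak] / 2.0

    # left crossing (in bin units, relative to peak sample positions)
    left = peak - 0.5  # default: crossing inside the peak bin itself
    for i in range(peak, 0, -1):
        if v[i - 1] < half <= v[i]:
            left = (i - 1) + (half - v[i - 1]) / (v[i] - v[i - 1])
            break
    right = peak + 0.5
    for i in range(peak, len(v) - 1):
        if v[i] >= half > v[i + 1]:
            right = i + (v[i] - half) / (v[i] - v[i + 1])
            break
    return (right - left) * time_axis.bin_width * 1e3


@dataclass(frozen=True)
class IRFKernel:
    """Normalized instrument response kernel sampled on a TimeAxis."""

    values: np.ndarray
    fwhm_ps: float

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if np.any(v < 0):
            raise ValueError("IRF values must be nonnegative")
        s = v.sum()
        if s <= 0:
            raise ValueError("IRF must have positive total weight")
        object.__setattr__(self, "values", v / s)

    @property
    def peak_bin(self) -> int:
        return int(np.argmax(self.values))


def make_irf(fwhm_ps: float, time_axis: TimeAxis, peak_bin: int = 25) -> IRFKernel:
    """Gaussian IRF with a given FWHM (ps), centered at ``peak_bin``.

    ``fwhm_ps=0`` yields a delta kernel (all mass in the peak bin). The
    interpolated FWHM of the sampled kernel matches ``fwhm_ps`` to within
    one bin width.
    """
    if fwhm_ps < 0:
        raise ValueError(f"fwhm_ps must be nonnegative, got {fwhm_ps}")
    if fwhm_ps * 1e-3 > time_axis.window:
        raise ValueError(
            f"fwhm_ps={fwhm_ps} exceeds the measurement window "
            f"({time_axis.window} ns)"
        )
    if not 0 <= peak_bin < time_axis.n_bins:
        raise ValueError(f"peak_bin {peak_bin} outside [0, {time_axis.n_bins})")

    n = time_axis.n_bins
    if fwhm_ps == 0:
        v = np.zeros(n)
        v[peak_bin] = 1.0
        return IRFKernel(values=v, fwhm_ps=0.0)

    sigma_bins = (fwhm_ps * 1e-3 / time_axis.bin_width) / _GAUSS_FWHM_TO_SIGMA
    i = np.arange(n)
    v = np.exp(-0.5 * ((i - peak_bin) / sigma_bins) ** 2)
    return IRFKernel(values=v, fwhm_ps=float(fwhm_ps))
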